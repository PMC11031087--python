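"""Shared fixtures and independent oracles.

Oracles here deliberately re-derive results from definitions (exhaustive
enumeration, closed forms, library cross-checks) and never call the code
paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirevo.scan import MirnaRecord, UtrRecord

RNA = "ACGU"
COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
WOBBLE = {"G": "U", "U": "G"}  # miRNA base -> UTR partner


def oracle_scan(utr_seq: str, mature: str, allow_wobble: bool = False, max_wobble: int = 0):
    """Definitional site enumeration: for every window test the pairing rules
    directly and classify.  Returns (start, end, class, wobbles) tuples."""
    u = utr_seq.upper().replace("T", "U")
    m = mature.upper().replace("T", "U")
    n = len(u)
    out = []
    for s in range(n - 5):
        wob = 0
        good = True
        for k in range(6):
            mir_base = m[6 - k]  # miRNA position 7-k (1-based)
            utr_base = u[s + k]
            if utr_base == COMP.get(mir_base):
                continue
            if allow_wobble and WOBBLE.get(mir_base) == utr_base:
                wob += 1
                continue
            good = False
            break
        if not good or wob > (max_wobble if allow_wobble else 0):
            continue
        has_m8 = s - 1 >= 0 and u[s - 1] == COMP.get(m[7])
        has_a1 = s + 6 < n and u[s + 6] == "A"
        if has_m8 and has_a1:
            out.append((s - 1, s + 7, "8mer", wob))
        elif has_m8:
            out.append((s - 1, s + 6, "7mer-m8", wob))
        elif has_a1:
            out.append((s, s + 7, "7mer-A1", wob))
        else:
            out.append((s, s + 6, "6mer", wob))
    return out


def random_rna(rng: np.random.Generator, length: int, probs=None) -> str:
    return "".join(rng.choice(list(RNA), size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def mirna():
    return MirnaRecord("mir-x", "UACGUACGUACGUACGUACGUA", cluster="c1", species="sp1")


@pytest.fixture
def utr_factory():
    def make(seq: str, gene: str = "gene1", transcript: str = "tx1", species: str = "sp1", **kw):
        return UtrRecord(gene=gene, transcript=transcript, seq=seq, species=species, **kw)

    return make
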