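"""Seed-match target prediction over 3'UTR sequences.

A target site is a stretch of a 3'UTR whose sense strand pairs, antiparallel,
with the seed region (nucleotides 2-7, 1-based) of a mature miRNA.  Sites are
classified with the canonical taxonomy:

* ``6mer``    -- Watson-Crick (or tolerated G:U wobble) match to the seed only;
* ``7mer-m8`` -- seed match plus a Watson-Crick match to miRNA position 8;
* ``7mer-A1`` -- seed match plus an adenine on the UTR opposite miRNA
  position 1 (the adenine is required regardless of the miRNA base);
* ``8mer``    -- both the m8 match and the A1 adenine.

All coordinates are 0-based half-open offsets on the UTR sequence.  Inputs
are normalized to the RNA alphabet (``T`` -> ``U``, uppercase); ambiguity
codes never pair.  Scanning "tiers" emulate external predictors of different
stringency; a transcript is a predicted target of a miRNA when *any* tier
reports at least one site (union semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
# miRNA base -> UTR base forming a G:U wobble pair.
_WOBBLE_PARTNER = {"G": "U", "U": "G"}

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}

SEED_START = 1  # 0-based offset of seed nt 2
SEED_END = 7    # exclusive; seed covers mature[1:7]


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe a nucleotide string into the RNA alphabet."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space; non-ACGU characters map to ``N``."""
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(normalize_rna(seq)))


@dataclass(frozen=True)
class MirnaRecord:
    """One mature miRNA with its family/cluster membership."""

    name: str
    mature_seq: str
    cluster: str = ""
    family: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", normalize_rna(self.mature_seq))
        if len(self.mature_seq) < 8:
            raise ValueError(
                f"mature sequence of {self.name!r} is shorter than 8 nt"
            )

    @property
    def seed(self) -> str:
        """Seed region: nucleotides 2-7 (1-based) of the mature sequence."""
        return self.mature_seq[SEED_START:SEED_END]


@dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR sequence on the transcript sense strand, 5'->3'.

    ``genomic_intervals``, when present, lists ``(chrom, start, end, strand)``
    blocks (0-based half-open) in transcript order whose lengths sum to the
    sequence length.
    """

    gene: str
    transcript: str
    seq: str
    species: str = ""
    genomic_intervals: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not self.seq:
            raise ValueError(f"UTR of {self.transcript!r} is empty")
        if self.genomic_intervals is not None:
            ivs = tuple(tuple(iv) for iv in self.genomic_intervals)
            object.__setattr__(self, "genomic_intervals", ivs)
            total = sum(end - start for _, start, end, _ in ivs)
            if total != len(self.seq):
                raise ValueError(
                    f"genomic intervals of {self.transcript!r} span {total} bp "
                    f"but the sequence is {len(self.seq)} nt"
                )


@dataclass(frozen=True)
class TargetSite:
    """A classified seed-match site in UTR coordinates (0-based half-open)."""

    mirna: str
    transcript: str
    start: int
    end: int
    site_class: str
    wobble_count: int = 0
    predictor_tier: str = "default"

    def __post_init__(self) -> None:
        if self.site_class not in CLASS_RANK:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("site coordinates must satisfy 0 <= start < end")
        if self.end - self.start not in (6, 7, 8):
            raise ValueError("site length must be 6, 7 or 8")


def extract_seed(mirna: MirnaRecord) -> str:
    """Return the seed (nucleotides 2-7, 1-based) of a mature miRNA."""
    return mirna.seed


def _pairs(mirna_base: str, utr_base: str, allow_wobble: bool) -> tuple[bool, bool]:
    """(pairs?, is_wobble?) for one duplex column, miRNA vs UTR base."""
    if utr_base == _COMPLEMENT.get(mirna_base):
        return True, False
    if allow_wobble and _WOBBLE_PARTNER.get(mirna_base) == utr_base:
        return True, True
    return False, False


def scan_utr(
    utr: UtrRecord,
    mirna: MirnaRecord,
    allow_wobble: bool = False,
    max_wobble: int = 1,
    min_class: str = "6mer",
    tier: str = "default",
) -> list[TargetSite]:
    """Find and classify every seed-match site of ``mirna`` in ``utr``.

    The UTR is read 5'->3'; the duplex is antiparallel, so the UTR base at
    offset ``s + k`` of a seed match starting at ``s`` pairs with miRNA
    position ``7 - k`` (1-based).  The m8 match (miRNA position 8) sits at
    ``s - 1`` and must be Watson-Crick; the A1 position sits at ``s + 6`` and
    must be an adenine.  With ``allow_wobble`` up to ``max_wobble`` G:U pairs
    are tolerated inside the seed duplex; extensions are never wobbled.

    One site is emitted per seed-match core; nested classes at the same core
    collapse to the highest class (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    useq = utr.seq
    mature = mirna.mature_seq
    n = len(useq)
    budget = max_wobble if allow_wobble else 0
    min_rank = CLASS_RANK[min_class]
    sites: list[TargetSite] = []
    for s in range(n - 5):
        wobbles = 0
        ok = True
        for k in range(6):
            # UTR offset s+k is opposite miRNA position 7-k, i.e. mature[6-k].
            paired, wob = _pairs(mature[6 - k], useq[s + k], allow_wobble)
            if not paired:
                ok = False
                break
            if wob:
                wobbles += 1
                if wobbles > budget:
                    ok = False
                    break
        if not ok:
            continue
        m8 = s >= 1 and useq[s - 1] == _COMPLEMENT.get(mature[7], "?")
        a1 = s + 6 < n and useq[s + 6] == "A"
        if m8 and a1:
            cls, start, end = "8mer", s - 1, s + 7
        elif m8:
            cls, start, end = "7mer-m8", s - 1, s + 6
        elif a1:
            cls, start, end = "7mer-A1", s, s + 7
        else:
            cls, start, end = "6mer", s, s + 6
        if CLASS_RANK[cls] < min_rank:
            continue
        sites.append(
            TargetSite(
                mirna=mirna.name,
                transcript=utr.transcript,
                start=start,
                end=end,
                site_class=cls,
                wobble_count=wobbles,
                predictor_tier=tier,
            )
        )
    return sites


@dataclass(frozen=True)
class ScanTier:
    """One scanning stringency, emulating an external predictor."""

    name: str
    min_class: str = "7mer-A1"
    allow_wobble: bool = False
    max_wobble: int = 0

    def __post_init__(self) -> None:
        if self.min_class not in CLASS_RANK:
            raise ValueError(f"unknown site class {self.min_class!r}")


#: Default tiers: a strict >=7mer Watson-Crick tier and a permissive tier
#: allowing 6mers with one G:U wobble.  These emulate the stringency range of
#: external prediction databases and are NOT derived from any one of them.
DEFAULT_TIERS = (
    ScanTier("strict", min_class="7mer-A1", allow_wobble=False, max_wobble=0),
    ScanTier("relaxed", min_class="6mer", allow_wobble=True, max_wobble=1),
)


class TargetMap:
    """Per-species map miRNA -> target transcripts with their sites."""

    def __init__(self) -> None:
        self._sites: dict[str, dict[str, dict[str, list[TargetSite]]]] = {}
        self._seen: set[tuple[str, str, str, int, str]] = set()
        self.tx2gene: dict[str, dict[str, str]] = {}

    def add_site(self, species: str, site: TargetSite, gene: str | None = None) -> bool:
        """Register a site; duplicates (same mirna/tx/start/class) are ignored."""
        key = (species, site.mirna, site.transcript, site.start, site.site_class)
        if key in self._seen:
            return False
        self._seen.add(key)
        (
            self._sites.setdefault(species, {})
            .setdefault(site.mirna, {})
            .setdefault(site.transcript, [])
            .append(site)
        )
        if gene is not None:
            self.tx2gene.setdefault(species, {})[site.transcript] = gene
        return True

    def species(self) -> list[str]:
        return sorted(self._sites)

    def mirnas(self, species: str) -> list[str]:
        return sorted(self._sites.get(species, {}))

    def transcripts(self, species: str, mirna: str) -> set[str]:
        return set(self._sites.get(species, {}).get(mirna, {}))

    def sites(
        self, species: str, mirna: str | None = None, transcript: str | None = None
    ) -> list[TargetSite]:
        out: list[TargetSite] = []
        by_mirna = self._sites.get(species, {})
        for m, by_tx in by_mirna.items():
            if mirna is not None and m != mirna:
                continue
            for tx, sites in by_tx.items():
                if transcript is not None and tx != transcript:
                    continue
                out.extend(sites)
        return sorted(out, key=lambda s: (s.mirna, s.transcript, s.start))

    def gene_of(self, species: str, transcript: str) -> str:
        return self.tx2gene.get(species, {}).get(transcript, transcript)

    def target_genes(self, species: str, mirna: str | None = None) -> set[str]:
        """Unique target genes of one miRNA (or the whole family)."""
        genes = set()
        by_mirna = self._sites.get(species, {})
        for m, by_tx in by_mirna.items():
            if mirna is not None and m != mirna:
                continue
            genes.update(self.gene_of(species, tx) for tx in by_tx)
        return genes

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species():
            for site in self.sites(sp):
                rows.append(
                    {
                        "species": sp,
                        "mirna": site.mirna,
                        "transcript": site.transcript,
                        "gene": self.gene_of(sp, site.transcript),
                        "start": site.start,
                        "end": site.end,
                        "site_class": site.site_class,
                        "wobble_count": site.wobble_count,
                        "tier": site.predictor_tier,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "species",
                "mirna",
                "transcript",
                "gene",
                "start",
                "end",
                "site_class",
                "wobble_count",
                "tier",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TargetMap":
        tmap = cls()
        for row in frame.itertuples(index=False):
            site = TargetSite(
                mirna=row.mirna,
                transcript=row.transcript,
                start=int(row.start),
                end=int(row.end),
                site_class=row.site_class,
                wobble_count=int(row.wobble_count),
                predictor_tier=row.tier,
            )
            tmap.add_site(row.species, site, gene=getattr(row, "gene", None))
        return tmap


def predict_targets(
    mirnas: Iterable[MirnaRecord],
    utrs: Iterable[UtrRecord],
    tiers: Sequence[ScanTier] = DEFAULT_TIERS,
) -> TargetMap:
    """Scan every same-species (miRNA, UTR) pair under every tier.

    A transcript is a predicted target of a miRNA when any tier yields at
    least one site; sites carry the label of the first tier that found them.
    """
    tiers = tuple(tiers)
    if not tiers:
        raise ValueError("at least one scan tier is required")
    names = [t.name for t in tiers]
    if len(set(names)) != len(names):
        raise ValueError("tier names must be unique")
    tmap = TargetMap()
    utrs = list(utrs)
    for mir in mirnas:
        for utr in utrs:
            if mir.species != utr.species:
                continue
            for tier in tiers:
                found = scan_utr(
                    utr,
                    mir,
                    allow_wobble=tier.allow_wobble,
                    max_wobble=tier.max_wobble,
                    min_class=tier.min_class,
                    tier=tier.name,
                )
                for site in found:
                    tmap.add_site(utr.species, site, gene=utr.gene)
    return tmap
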