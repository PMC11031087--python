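"""Transposon-origin screening for miRNA loci.

Three primitives support the screen: exact Smith-Waterman local alignment
with affine gaps (a gap of length k costs ``gap_open + k * gap_extend``),
a base-pair-maximization hairpin-capability heuristic (Nussinov-style, with
a single-stem topology requirement in place of thermodynamic folding), and a
directional substitution spectrum over a pre-aligned family.

The identity threshold screen flags TE consensus sequences that align to
miRNA loci at high identity in every supplied species set; hairpin and
spectrum thresholds here are package defaults, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .scan import normalize_rna

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return "".join(_DNA_COMPLEMENT.get(b, "N") for b in reversed(_to_dna(seq)))


@dataclass(frozen=True)
class TeRecord:
    name: str
    consensus: str
    family_class: str = "DNA transposon"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"TE {self.name!r} has an empty consensus")


@dataclass(frozen=True)
class AlignmentResult:
    query: str
    subject: str
    score: float
    identity: float  # matches / aligned columns (gaps count as columns)
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    gaps: int
    n_columns: int
    aligned_query: str = ""
    aligned_subject: str = ""


_NEG = float("-inf")


def local_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    query: str = "a",
    subject: str = "b",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLASTN-like
    defaults).  Runs in DNA space after U->T normalization.
    """
    a = _to_dna(a)
    b = _to_dna(b)
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gapped column
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Ei[j - 1] + gap_extend, Hi[j - 1] + first)
            Fi[j] = max(Fp[j] + gap_extend, Hp[j] + first)
            s = match if ai == b[j - 1] and ai != "N" else mismatch
            h = max(0.0, Hp[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    cols_q: list[str] = []
    cols_s: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            s = match if a[i - 1] == b[j - 1] and a[i - 1] != "N" else mismatch
            if h == H[i - 1][j - 1] + s:
                cols_q.append(a[i - 1])
                cols_s.append(b[j - 1])
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols_q.append("-")
            cols_s.append(b[j - 1])
            if E[i][j] == H[i][j - 1] + first:
                state = "H"
            j -= 1
        else:  # F
            cols_q.append(a[i - 1])
            cols_s.append("-")
            if F[i][j] == H[i - 1][j] + first:
                state = "H"
            i -= 1
    aligned_q = "".join(reversed(cols_q))
    aligned_s = "".join(reversed(cols_s))
    n_cols = len(aligned_q)
    matches = sum(
        1 for x, y in zip(aligned_q, aligned_s) if x == y and x != "-" and x != "N"
    )
    gaps = sum(1 for x, y in zip(aligned_q, aligned_s) if x == "-" or y == "-")
    return AlignmentResult(
        query=query,
        subject=subject,
        score=float(best),
        identity=matches / n_cols if n_cols else 0.0,
        q_start=i,
        q_end=bi,
        s_start=j,
        s_end=bj,
        gaps=gaps,
        n_columns=n_cols,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
    )


@dataclass
class ScreenResult:
    hits: pd.DataFrame  # te, species, locus, strand, identity, span, score
    ranking: pd.DataFrame  # te, n_loci, n_species
    universal: list[str]  # TEs hitting >= 1 locus in every species


def screen_te_sources(
    te_library: Iterable[TeRecord],
    loci_by_species: dict[str, dict[str, str]],
    identity_min: float = 0.94,
    min_span: int = 50,
    strand: str = "both",
) -> ScreenResult:
    """All (TE, locus) local alignments passing identity and span thresholds.

    ``loci_by_species`` maps species -> {locus name: sequence}.  Both strands
    of each locus are searched when ``strand="both"``.  TEs are ranked by the
    number of loci hit; TEs hitting loci in every supplied species are
    flagged as "universal" candidates.
    """
    te_library = list(te_library)
    if not te_library:
        raise ValueError("empty TE library")
    if not 0 < identity_min <= 1:
        raise ValueError("identity_min must lie in (0, 1]")
    if min_span <= 0:
        raise ValueError("min_span must be > 0")
    strands = ("+", "-") if strand == "both" else (strand,)
    rows = []
    for te in te_library:
        for sp, loci in sorted(loci_by_species.items()):
            for locus, seq in sorted(loci.items()):
                for st in strands:
                    target = seq if st == "+" else revcomp_dna(seq)
                    res = local_align(te.consensus, target, query=te.name, subject=locus)
                    if res.identity >= identity_min and res.n_columns >= min_span:
                        rows.append(
                            {
                                "te": te.name,
                                "species": sp,
                                "locus": locus,
                                "strand": st,
                                "identity": res.identity,
                                "span": res.n_columns,
                                "score": res.score,
                            }
                        )
    hits = pd.DataFrame(
        rows, columns=["te", "species", "locus", "strand", "identity", "span", "score"]
    )
    if len(hits):
        per_te = (
            hits.groupby("te")
            .agg(n_loci=("locus", "nunique"), n_species=("species", "nunique"))
            .reset_index()
            .sort_values(["n_loci", "te"], ascending=[False, True], ignore_index=True)
        )
        universal = sorted(
            per_te.loc[per_te["n_species"] == len(loci_by_species), "te"]
        )
    else:
        per_te = pd.DataFrame(columns=["te", "n_loci", "n_species"])
        universal = []
    return ScreenResult(hits=hits, ranking=per_te, universal=universal)


_RNA_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _can_pair(x: str, y: str) -> bool:
    return (x, y) in _RNA_PAIRS


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> tuple[int, list[tuple[int, int]]]:
    """Maximum base-pairing (Watson-Crick + G:U) with a minimum loop length.

    Returns the optimal pair count and one optimal nested pair list from the
    traceback.
    """
    s = normalize_rna(seq)
    n = len(s)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(dp[i + 1][j], dp[i][j - 1])
            if _can_pair(s[i], s[j]):
                best = max(best, dp[i + 1][j - 1] + 1)
            for k in range(i + 1, j):
                cand = dp[i][k] + dp[k + 1][j]
                if cand > best:
                    best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
        elif dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
        elif _can_pair(s[i], s[j]) and dp[i][j] == dp[i + 1][j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i][j] == dp[i][k] + dp[k + 1][j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return (dp[0][n - 1] if n else 0), sorted(pairs)


def longest_helix(seq: str, min_loop: int = 3) -> tuple[int, int, int]:
    """Longest contiguous stacked helix (no bulges), honoring the loop minimum.

    Returns ``(length, i, j)`` where ``(i, j)`` is the outermost pair of the
    best helix.  This is the dominant-stem statistic: a long stacked run is
    what distinguishes a genuine inverted repeat from the incidental pairing
    a maximum-matching structure finds in random sequence.
    """
    s = normalize_rna(seq)
    n = len(s)
    best, bi, bj = 0, 0, 0
    length = [[0] * n for _ in range(n)]  # L[i][j]: helix with outermost pair (i, j)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if _can_pair(s[i], s[j]):
                inner = length[i + 1][j - 1] if span >= min_loop + 3 else 0
                length[i][j] = inner + 1
                if length[i][j] > best:
                    best, bi, bj = length[i][j], i, j
    return best, bi, bj


def _is_single_stem(pairs: list[tuple[int, int]]) -> bool:
    """True when the nested pair set forms one stem-loop (no multiloop).

    Each pair may directly enclose at most one other pair, and at most one
    pair may sit at the outermost level; bulges and internal loops are fine.
    """
    if not pairs:
        return False
    ordered = sorted(pairs)
    stack: list[tuple[int, int]] = []
    children: dict[tuple[int, int] | None, int] = {}
    for p in ordered:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children[parent] = children.get(parent, 0) + 1
        if children[parent] > 1:
            return False
        stack.append(p)
    return True


def dot_bracket(length: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


@dataclass(frozen=True)
class HairpinReport:
    sequence_id: str
    stem_length: int  # paired positions in the best window
    loop_length: int
    paired_fraction: float
    is_hairpin: bool
    window_start: int
    window_end: int
    structure: str  # dot-bracket of the best window


def hairpin_check(
    seq: str,
    sequence_id: str = "seq",
    window: int = 100,
    min_loop: int = 3,
    min_pairs: int = 18,
    min_paired_fraction: float = 0.3,
    step: int | None = None,
) -> HairpinReport:
    """Hairpin-capability heuristic via windowed base-pair maximization.

    Each window is scored two ways: the Nussinov maximum pair count gives the
    paired fraction, and a contiguous stacked-helix DP gives the dominant
    stem (maximum-matching alone cannot discriminate, since random sequence
    also pairs heavily, but only an inverted repeat yields a long unbroken
    stack).  ``is_hairpin`` requires a dominant stem of ``min_pairs`` stacked
    pairs and a window paired fraction of ``min_paired_fraction``.  DNA input
    is transcribed before analysis.
    """
    s = normalize_rna(seq)
    if len(s) < 2 * min_pairs + min_loop:
        raise ValueError("sequence too short for the requested stem")
    window = min(window, len(s))
    step = step if step is not None else max(1, window // 4)
    starts = list(range(0, len(s) - window + 1, step))
    if starts[-1] != len(s) - window:
        starts.append(len(s) - window)
    best = None  # (helix, pair count, window start, helix i, helix j)
    for w0 in starts:
        sub = s[w0 : w0 + window]
        helix, hi, hj = longest_helix(sub, min_loop=min_loop)
        count, _ = nussinov_max_pairs(sub, min_loop=min_loop)
        if best is None or (helix, count) > (best[0], best[1]):
            best = (helix, count, w0, hi, hj)
    helix, count, w0, hi, hj = best
    fraction = 2.0 * count / window if window else 0.0
    stem_pairs = [(hi + t, hj - t) for t in range(helix)]
    loop_len = (hj - helix + 1) - (hi + helix - 1) - 1 if helix else 0
    return HairpinReport(
        sequence_id=sequence_id,
        stem_length=helix,
        loop_length=loop_len,
        paired_fraction=fraction,
        is_hairpin=bool(helix >= min_pairs and fraction >= min_paired_fraction),
        window_start=w0,
        window_end=w0 + window,
        structure=dot_bracket(window, stem_pairs),
    )


@dataclass
class SubstitutionSpectrum:
    """Directional substitution counts over the RNA alphabet."""

    counts: dict[tuple[str, str], int]
    reference_policy: str

    def __post_init__(self) -> None:
        for (x, y), c in self.counts.items():
            if x == y:
                raise ValueError("diagonal cells must be absent")
            if c < 0:
                raise ValueError("counts must be >= 0")

    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, *cells: tuple[str, str]) -> float:
        tot = self.total()
        return sum(self.counts.get(c, 0) for c in cells) / tot if tot else 0.0

    def to_frame(self) -> pd.DataFrame:
        bases = ("A", "C", "G", "U")
        data = [
            [self.counts.get((x, y), 0) if x != y else 0 for y in bases] for x in bases
        ]
        return pd.DataFrame(data, index=bases, columns=bases)


def substitution_spectrum(
    family: dict[str, str] | list[str],
    reference_policy: str = "consensus",
    outgroup: str | None = None,
) -> SubstitutionSpectrum:
    """Column-wise reference->member substitution tally over aligned sequences.

    Sequences must be pre-aligned (equal lengths, ``-`` for gaps).  The
    per-column reference base is the majority consensus (ties broken in
    A<C<G<U order) or the designated outgroup's base; columns where the
    reference or the member carries a gap are skipped.
    """
    if isinstance(family, dict):
        names = list(family)
        seqs = {k: normalize_rna(v) for k, v in family.items()}
    else:
        names = [f"seq{i}" for i in range(len(family))]
        seqs = {n: normalize_rna(s) for n, s in zip(names, family)}
    if len(seqs) < 2:
        raise ValueError("need >= 2 aligned sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    length = lengths.pop()
    if reference_policy == "designated_outgroup":
        if outgroup is None or outgroup not in seqs:
            raise ValueError("outgroup name required and must be in the family")
        reference = seqs[outgroup]
        members = [n for n in names if n != outgroup]
    elif reference_policy == "consensus":
        ref_chars = []
        for col in range(length):
            bases = [seqs[n][col] for n in names if seqs[n][col] in "ACGU"]
            if not bases:
                ref_chars.append("-")
                continue
            counts = {b: bases.count(b) for b in "ACGU"}
            ref_chars.append(max("ACGU", key=lambda b: (counts.get(b, 0), )))
        reference = "".join(ref_chars)
        members = names
    else:
        raise ValueError("reference_policy must be 'consensus' or 'designated_outgroup'")
    tally: dict[tuple[str, str], int] = {}
    for name in members:
        seq = seqs[name]
        for col in range(length):
            ref, alt = reference[col], seq[col]
            if ref not in "ACGU" or alt not in "ACGU" or ref == alt:
                continue
            tally[(ref, alt)] = tally.get((ref, alt), 0) + 1
    return SubstitutionSpectrum(counts=tally, reference_policy=reference_policy)
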