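"""Synthetic input generation with a ground-truth ledger.

Every pipeline input can be emulated here at desk scale: a miRNA family
descended from a transposon-like ancestor by biased substitution, orthologous
3'UTR sets with implanted seed-match sites, negative-binomial count matrices
in which knockout lines perturb the implanted targets in either direction,
per-base conservation tracks elevated inside true sites, allele-frequency
tables per feature class, and binomial competition assays.

Randomness discipline: a single seed in :class:`SimConfig` feeds one
:func:`stage_rng` stream per stage, keyed by the stage name, so adding a stage
never perturbs the draws of earlier stages and identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import CompetitionAssay
from .conservation import ConservationTrack, mnd
from .scan import (
    MirnaRecord,
    TargetSite,
    UtrRecord,
    _COMPLEMENT,
    _WOBBLE_PARTNER,
    reverse_complement,
)

BASES = ("A", "C", "G", "U")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one run seed and a stage name."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class SimConfig:
    """Parameters for every synthetic stage (all free parameters; the source
    study reports no effect-size magnitudes for these quantities)."""

    rng_seed: int = 0
    n_species: int = 2
    n_genes: int = 200
    utr_len_range: tuple[int, int] = (150, 300)
    n_clusters: int = 5
    mirnas_per_cluster: int = 4
    seed_len: int = 6
    substitution_bias: dict[str, float] = field(
        default_factory=lambda: {"U>C": 2.0, "A>G": 2.0, "other": 1.0}
    )
    site_elevation_delta: float = 0.5
    target_log2fc: float = -2.0
    dispersion: float = 0.05
    depth: float = 1e6
    # plumbing knobs
    mature_len: int = 22
    locus_len: int = 100
    subs_per_locus: int = 6
    seed_protection: float = 0.2
    ortholog_fraction: float = 0.8
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_replicates: int = 3
    base_mean: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        lo, hi = self.utr_len_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("utr_len_range must be positive with min <= max")
        if self.n_clusters < 0 or self.mirnas_per_cluster < 0:
            raise ValueError("cluster counts must be >= 0")
        weights = list(self.substitution_bias.values())
        if any(w < 0 for w in weights):
            raise ValueError("substitution bias weights must be nonnegative")
        if weights and not any(w > 0 for w in weights):
            raise ValueError("substitution bias weights must not all be zero")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not np.isclose(sum(self.base_probs), 1.0):
            raise ValueError("base_probs must sum to 1")
        if self.mature_len < 8:
            raise ValueError("mature_len must be >= 8")


@dataclass
class FamilyTruth:
    """Ground truth of one simulated miRNA family."""

    ancestor_te: str
    loci: dict[str, str]
    parent: dict[str, str]
    substitutions: list[tuple[str, int, str, str]]  # (mirna, locus pos, ref, alt)
    mature_offset: int
    stem_len: int
    loop_len: int


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(BASES, size=length, p=list(probs)))


@dataclass(frozen=True)
class AncestorSpec:
    """A hairpin-capable ancestral locus shared by a simulated family."""

    seq: str
    mature_offset: int
    stem_len: int
    loop_len: int


def build_ancestor(cfg: SimConfig, rng: np.random.Generator | None = None) -> AncestorSpec:
    """Draw one transposon-like ancestor; reuse it across species so that a
    single TE consensus explains every species' family."""
    rng = rng if rng is not None else stage_rng(cfg.rng_seed, "ancestor")
    seq, mat_off, stem, loop = _build_hairpin_ancestor(cfg, rng)
    return AncestorSpec(seq=seq, mature_offset=mat_off, stem_len=stem, loop_len=loop)


def _build_hairpin_ancestor(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Ancestor locus containing a long inverted repeat (hairpin-capable)."""
    stem = max(20, (cfg.locus_len - 10) // 3)
    loop = 6
    flank = cfg.locus_len - (2 * stem + loop)
    left = flank // 2
    right = flank - left
    arm = _random_seq(rng, stem, cfg.base_probs)
    seq = (
        _random_seq(rng, left, cfg.base_probs)
        + arm
        + _random_seq(rng, loop, cfg.base_probs)
        + reverse_complement(arm)
        + _random_seq(rng, right, cfg.base_probs)
    )
    mature_offset = left + 2  # mature miRNA sits in the 5' stem arm
    return seq, mature_offset, stem, loop


def _substitute(
    seq: list[str],
    n_subs: int,
    bias: dict[str, float],
    protected: range,
    protection: float,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Apply ``n_subs`` sequential substitutions drawn from the bias weights.

    Unlisted substitution types take the weight of the ``"other"`` key
    (default 0, so a degenerate bias like ``{"U>C": 1}`` only ever produces
    U->C events).  Positions inside ``protected`` are down-weighted by
    ``protection``.
    """
    other = bias.get("other", 0.0)
    events: list[tuple[int, str, str]] = []
    for _ in range(n_subs):
        moves: list[tuple[int, str]] = []
        weights: list[float] = []
        for pos, ref in enumerate(seq):
            factor = protection if pos in protected else 1.0
            for alt in BASES:
                if alt == ref:
                    continue
                w = bias.get(f"{ref}>{alt}", other) * factor
                if w > 0:
                    moves.append((pos, alt))
                    weights.append(w)
        if not moves:
            raise ValueError("no substitution has positive weight; bias exhausted")
        total = float(np.sum(weights))
        idx = rng.choice(len(moves), p=np.asarray(weights) / total)
        pos, alt = moves[idx]
        events.append((pos, seq[pos], alt))
        seq[pos] = alt
    return events


def simulate_mirna_family(
    cfg: SimConfig,
    species: str = "sp1",
    n_substitutions: int | None = None,
    rng: np.random.Generator | None = None,
    ancestor: AncestorSpec | None = None,
) -> tuple[list[MirnaRecord], FamilyTruth]:
    """Descend a miRNA family from a hairpin-capable transposon-like ancestor.

    Each descendant locus is a copy of the ancestor with recorded
    substitutions drawn from ``cfg.substitution_bias``; seed positions
    (mature nt 2-7) substitute at a ``cfg.seed_protection`` lower rate.  The
    mature miRNA is a fixed-offset slice of the locus; descendants are grouped
    into ``cfg.n_clusters`` clusters.  Pass the same :class:`AncestorSpec` to
    several calls to descend multiple species' families from one ancestor.
    """
    if cfg.n_clusters == 0 or cfg.mirnas_per_cluster == 0:
        raise ValueError("empty family: n_clusters and mirnas_per_cluster must be > 0")
    rng = rng if rng is not None else stage_rng(cfg.rng_seed, f"mirna_family:{species}")
    n_subs = cfg.subs_per_locus if n_substitutions is None else n_substitutions
    if ancestor is None:
        ancestor = build_ancestor(cfg, rng)
    mat_off, stem, loop = ancestor.mature_offset, ancestor.stem_len, ancestor.loop_len
    ancestor = ancestor.seq
    seed_positions = range(mat_off + 1, mat_off + 1 + cfg.seed_len)
    mirnas: list[MirnaRecord] = []
    loci: dict[str, str] = {}
    parent: dict[str, str] = {}
    subs: list[tuple[str, int, str, str]] = []
    for ci in range(cfg.n_clusters):
        for mi in range(cfg.mirnas_per_cluster):
            name = f"{species}-mir-c{ci + 1}-{mi + 1}"
            locus = list(ancestor)
            events = _substitute(
                locus, n_subs, cfg.substitution_bias, seed_positions, cfg.seed_protection, rng
            )
            locus_seq = "".join(locus)
            loci[name] = locus_seq
            parent[name] = "ancestor"
            subs.extend((name, pos, ref, alt) for pos, ref, alt in events)
            mirnas.append(
                MirnaRecord(
                    name=name,
                    mature_seq=locus_seq[mat_off : mat_off + cfg.mature_len],
                    cluster=f"{species}-c{ci + 1}",
                    family="simfam",
                    species=species,
                )
            )
    truth = FamilyTruth(
        ancestor_te=ancestor,
        loci=loci,
        parent=parent,
        substitutions=subs,
        mature_offset=mat_off,
        stem_len=stem,
        loop_len=loop,
    )
    return mirnas, truth


class OrthologMap:
    """Explicit orthology over simulated genes.

    Shared genes keep one identifier across all species; species-private
    genes have no ortholog anywhere.
    """

    def __init__(self, shared: set[str], per_species: dict[str, set[str]]):
        self.shared = set(shared)
        self.per_species = {sp: set(genes) for sp, genes in per_species.items()}

    def ortholog(self, gene: str, to_species: str) -> str | None:
        if gene in self.shared and gene in self.per_species.get(to_species, set()):
            return gene
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "species": sp, "shared": g in self.shared}
            for sp, genes in sorted(self.per_species.items())
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "species", "shared"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologMap":
        shared = set(frame.loc[frame["shared"], "gene"])
        per_species: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            per_species.setdefault(row.species, set()).add(row.gene)
        return cls(shared, per_species)


@dataclass
class Transcriptome:
    utrs: dict[str, list[UtrRecord]]
    orthologs: OrthologMap


def simulate_transcriptome(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> Transcriptome:
    """Per-species 3'UTR sets with a declared ortholog fraction.

    Each gene is shared across all species with probability
    ``cfg.ortholog_fraction`` (identical sequence everywhere); otherwise each
    species carries a private gene with an independent sequence.  UTR lengths
    are uniform over ``cfg.utr_len_range``.  Every UTR is given a single-block
    genomic interval on its own per-transcript contig so coordinate mapping
    has a well-defined inverse.
    """
    rng = rng if rng is not None else stage_rng(cfg.rng_seed, "transcriptome")
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    lo, hi = cfg.utr_len_range
    utrs: dict[str, list[UtrRecord]] = {sp: [] for sp in species}
    shared: set[str] = set()
    per_species: dict[str, set[str]] = {sp: set() for sp in species}

    def make_utr(sp: str, gene: str, seq: str) -> UtrRecord:
        tx = f"{gene}.t1" if cfg.n_species == 1 or gene in shared else f"{gene}.t1"
        tx = f"{sp}:{tx}"
        return UtrRecord(
            gene=gene,
            transcript=tx,
            seq=seq,
            species=sp,
            genomic_intervals=((tx, 0, len(seq), "+"),),
        )

    for i in range(cfg.n_genes):
        base = f"g{i:04d}"
        is_shared = rng.random() < cfg.ortholog_fraction
        if is_shared:
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length, cfg.base_probs)
            shared.add(base)
            for sp in species:
                per_species[sp].add(base)
                utrs[sp].append(make_utr(sp, base, seq))
        else:
            for sp in species:
                gene = f"{base}_{sp}"
                length = int(rng.integers(lo, hi + 1))
                seq = _random_seq(rng, length, cfg.base_probs)
                per_species[sp].add(gene)
                utrs[sp].append(make_utr(sp, gene, seq))
    return Transcriptome(utrs=utrs, orthologs=OrthologMap(shared, per_species))


@dataclass
class ImplantTruth:
    sites: list[TargetSite]
    skipped: list[tuple[str, str]]  # (transcript, reason)

    def sites_by_transcript(self) -> dict[str, list[TargetSite]]:
        out: dict[str, list[TargetSite]] = {}
        for s in self.sites:
            out.setdefault(s.transcript, []).append(s)
        return out


def implant_target_sites(
    utrs: list[UtrRecord],
    mirnas: list[MirnaRecord],
    sites_per_target: int = 1,
    wobble_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[list[UtrRecord], ImplantTruth]:
    """Write exact 8mer seed-match sites into UTRs and record the truth.

    miRNAs are assigned to UTRs round-robin.  Each implanted site writes the
    m8 complement, the reverse-complemented seed (each G/U seed base wobbled
    with probability ``wobble_rate``), and the A1 adenine at non-overlapping
    positions kept >= 2 nt apart.  UTRs too short for a requested site are
    skipped with a warning and recorded in the truth ledger.
    """
    if not mirnas:
        raise ValueError("no miRNAs supplied")
    rng = rng if rng is not None else stage_rng(seed, "implant")
    out_utrs: list[UtrRecord] = []
    truth = ImplantTruth(sites=[], skipped=[])
    for i, utr in enumerate(utrs):
        mir = mirnas[i % len(mirnas)]
        seq = list(utr.seq)
        n = len(seq)
        occupied: list[tuple[int, int]] = []
        for _ in range(sites_per_target):
            # candidate core starts: full 8mer footprint [s-1, s+7) in bounds,
            # >=2 nt clear of previously implanted footprints
            candidates = [
                s
                for s in range(1, n - 6)
                if all(s + 7 + 2 <= a or s - 1 - 2 >= b for a, b in occupied)
            ]
            if not candidates:
                warnings.warn(
                    f"UTR {utr.transcript} too short for requested site; skipped",
                    stacklevel=2,
                )
                truth.skipped.append((utr.transcript, "too_short"))
                continue
            s = int(rng.choice(candidates))
            seed_rna = mir.seed
            wobbles = 0
            for k in range(6):
                mbase = seed_rna[5 - k]  # miRNA position 7-k pairs UTR offset s+k
                if mbase in _WOBBLE_PARTNER and rng.random() < wobble_rate:
                    seq[s + k] = _WOBBLE_PARTNER[mbase]
                    wobbles += 1
                else:
                    seq[s + k] = _COMPLEMENT[mbase]
            seq[s - 1] = _COMPLEMENT[mir.mature_seq[7]]
            seq[s + 6] = "A"
            occupied.append((s - 1, s + 7))
            truth.sites.append(
                TargetSite(
                    mirna=mir.name,
                    transcript=utr.transcript,
                    start=s - 1,
                    end=s + 7,
                    site_class="8mer",
                    wobble_count=wobbles,
                    predictor_tier="truth",
                )
            )
        out_utrs.append(dataclasses.replace(utr, seq="".join(seq)))
    return out_utrs, truth


def simulate_counts(
    design: dict[str, int],
    truth: dict[str, dict[str, float]],
    cfg: SimConfig,
    genes: list[str],
    rng: np.random.Generator | None = None,
):
    """Negative-binomial count matrix for a WT vs KO-lines layout.

    ``design`` maps line label -> replicate count (must include ``"WT"``);
    ``truth`` maps KO line -> {gene: log2 fold change} applied to that line's
    mean.  Expected library size is ``cfg.depth`` for every sample.
    """
    from .de import CountMatrix

    if "WT" not in design:
        raise ValueError("design must include a 'WT' line")
    if cfg.depth <= 0 or cfg.dispersion <= 0:
        raise ValueError("depth and dispersion must be > 0")
    for line, de in truth.items():
        missing = set(de) - set(genes)
        if missing:
            raise ValueError(f"true DE genes absent from gene list: {sorted(missing)[:3]}")
    rng = rng if rng is not None else stage_rng(cfg.rng_seed, "counts")
    genes = list(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    base = base / base.sum() * cfg.depth
    nb_n = 1.0 / cfg.dispersion
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for line in sorted(design):
        mu = base.copy()
        for g, lfc in truth.get(line, {}).items():
            mu[genes.index(g)] *= 2.0**lfc
        for rep in range(1, design[line] + 1):
            p = nb_n / (nb_n + mu)
            sample = f"{line}_r{rep}"
            columns[sample] = rng.negative_binomial(nb_n, p)
            meta_rows.append({"sample": sample, "line": line, "replicate": rep})
    counts = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts=counts, samples=samples)


def simulate_conservation_track(
    utrs: list[UtrRecord],
    true_sites: list[TargetSite],
    base_mean: float = 0.5,
    site_elevation_delta: float = 0.5,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> ConservationTrack:
    """Per-base Normal(base_mean, noise_sd) scores with +delta inside sites.

    The track is keyed by each UTR's genomic contig (per-transcript contigs
    as produced by :func:`simulate_transcriptome`).
    """
    rng = rng if rng is not None else stage_rng(seed, "conservation")
    by_tx: dict[str, list[TargetSite]] = {}
    for s in true_sites:
        by_tx.setdefault(s.transcript, []).append(s)
    track = ConservationTrack(semantics="phylop")
    for utr in utrs:
        n = len(utr.seq)
        values = rng.normal(base_mean, noise_sd, size=n) if noise_sd > 0 else np.full(n, float(base_mean))
        for site in by_tx.get(utr.transcript, []):
            values[site.start : site.end] += site_elevation_delta
        if utr.genomic_intervals and len(utr.genomic_intervals) == 1:
            chrom = utr.genomic_intervals[0][0]
        else:
            chrom = utr.transcript
        track.add_array(chrom, 0, values)
    return track


def simulate_population_alleles(
    class_specs: dict[str, tuple[int, tuple[float, float]]],
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant table with Beta-distributed derived allele frequencies per class.

    ``class_specs`` maps feature class -> (n_variants, (alpha, beta)).
    Classes with zero variants are absent from the output.
    """
    rng = rng if rng is not None else stage_rng(seed, "alleles")
    rows = []
    for cls in sorted(class_specs):
        n, (a, b) = class_specs[cls]
        if n == 0:
            continue
        dafs = rng.beta(a, b, size=n)
        for i, daf in enumerate(dafs):
            rows.append(
                {
                    "variant": f"{cls}:v{i:05d}",
                    "feature_class": cls,
                    "position": i,
                    "daf": float(daf),
                    "mnd": float(mnd(daf)),
                }
            )
    return pd.DataFrame(rows, columns=["variant", "feature_class", "position", "daf", "mnd"])


def simulate_competition_assay(
    n_offspring: int,
    true_fraction: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    assay_type: str = "mixed_IVF",
    ratio: tuple[float, float] = (1.0, 1.0),
    replicate: str | None = None,
) -> CompetitionAssay:
    """Binomial(n_offspring, true_fraction) count of genotype-A offspring."""
    if n_offspring <= 0:
        raise ValueError("empty assay: n_offspring must be > 0")
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    rng = rng if rng is not None else stage_rng(seed, "competition")
    a = int(rng.binomial(n_offspring, true_fraction))
    return CompetitionAssay(
        assay_type=assay_type,
        count_a=a,
        count_b=n_offspring - a,
        ratio_a=ratio[0],
        ratio_b=ratio[1],
        replicate=replicate,
    )


@dataclass
class SimTruth:
    """Everything a recovery test needs to score the pipeline."""

    ancestor_te: str
    family_tree: dict[str, str]
    true_sites: list[TargetSite]
    true_targets: dict[str, dict[str, list[str]]]  # species -> mirna -> genes
    true_de_genes: dict[str, dict[str, float]]  # KO line -> gene -> log2fc
    true_fraction: float

    def to_json(self) -> str:
        payload = {
            "ancestor_te": self.ancestor_te,
            "family_tree": self.family_tree,
            "true_sites": [dataclasses.asdict(s) for s in self.true_sites],
            "true_targets": self.true_targets,
            "true_de_genes": self.true_de_genes,
            "true_fraction": self.true_fraction,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        sites = [TargetSite(**s) for s in payload["true_sites"]]
        return cls(
            ancestor_te=payload["ancestor_te"],
            family_tree=payload["family_tree"],
            true_sites=sites,
            true_targets=payload["true_targets"],
            true_de_genes=payload["true_de_genes"],
            true_fraction=payload["true_fraction"],
        )
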