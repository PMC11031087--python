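"""Cross-species target sharing and target-load statistics.

Given per-species target maps and an explicit orthology table, this module
computes which reference genes are targeted in which species (three-way Venn
and pairwise overlaps), per-miRNA unique-target counts within a gene
universe, per-transcript family-site counts, and the overlap of 3'UTR
annotations with a transposon family's intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import TargetMap

logger = logging.getLogger(__name__)


def _welch(a, b) -> tuple[float | None, float | None, str]:
    """Welch t-test with explicit statuses for degenerate inputs."""
    if len(a) < 2 or len(b) < 2:
        return None, None, "insufficient groups"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(p):
        return None, None, "degenerate"
    return float(t), float(p), "ok"


@dataclass
class SharedTargets:
    membership: dict[str, frozenset]  # reference gene -> species where targeted
    venn: dict[tuple[str, ...], int]  # sorted species combo -> count
    pairwise: pd.DataFrame  # species_a, species_b, shared, pct_of_reference
    reference_species: str
    reference_size: int
    unmapped: dict[str, list[str]]  # species -> reference genes with no ortholog

    def shared_all(self) -> int:
        species = sorted({sp for m in self.membership.values() for sp in m})
        return sum(1 for m in self.membership.values() if m == frozenset(species))


def shared_targets(
    reference_set: set[str],
    target_maps: dict[str, TargetMap],
    ortholog_map,
    reference_species: str,
) -> SharedTargets:
    """Map reference genes through orthology and count species sharing.

    A reference gene is "shared" with species S when any family miRNA of S
    targets its ortholog there.  Genes absent from the ortholog map count as
    unshared for that species and are logged.  Reference genes always belong
    to the reference species' set.
    """
    species = sorted(target_maps)
    if reference_species not in species:
        raise ValueError(f"no target map for reference species {reference_species!r}")
    targeted_by_species = {sp: target_maps[sp].target_genes(sp) for sp in species}
    membership: dict[str, frozenset] = {}
    unmapped: dict[str, list[str]] = {sp: [] for sp in species if sp != reference_species}
    for gene in sorted(reference_set):
        hits = {reference_species}
        for sp in species:
            if sp == reference_species:
                continue
            ortho = ortholog_map.ortholog(gene, sp)
            if ortho is None:
                unmapped[sp].append(gene)
                continue
            if ortho in targeted_by_species[sp]:
                hits.add(sp)
        membership[gene] = frozenset(hits)
    for sp, genes in unmapped.items():
        if genes:
            logger.info("%d reference genes have no ortholog in %s", len(genes), sp)
    venn: dict[tuple[str, ...], int] = {}
    for m in membership.values():
        key = tuple(sorted(m))
        venn[key] = venn.get(key, 0) + 1
    n_ref = len(reference_set)
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            shared = sum(1 for m in membership.values() if a in m and b in m)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "shared": shared,
                    "pct_of_reference": 100.0 * shared / n_ref if n_ref else 0.0,
                }
            )
    pairwise = pd.DataFrame(rows, columns=["species_a", "species_b", "shared", "pct_of_reference"])
    return SharedTargets(
        membership=membership,
        venn=venn,
        pairwise=pairwise,
        reference_species=reference_species,
        reference_size=n_ref,
        unmapped=unmapped,
    )


@dataclass
class TargetsPerMirna:
    counts: dict[str, dict[str, int]]  # species -> mirna -> unique target count
    means: dict[str, float]
    t_stat: float | None
    pvalue: float | None
    status: str  # "ok" | "insufficient groups"


def targets_per_mirna(
    target_maps: dict[str, TargetMap],
    universe: set[str],
    compare: tuple[str, str] | None = None,
) -> TargetsPerMirna:
    """Unique universe targets per miRNA, with a two-species Welch comparison.

    A miRNA absent from the map counts 0; species with fewer than two miRNAs
    decline the comparison with an explicit status.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    counts: dict[str, dict[str, int]] = {}
    for sp, tmap in sorted(target_maps.items()):
        counts[sp] = {
            m: len(tmap.target_genes(sp, m) & universe) for m in tmap.mirnas(sp)
        }
    means = {
        sp: float(np.mean(list(c.values()))) if c else float("nan")
        for sp, c in counts.items()
    }
    if compare is None:
        species = sorted(counts)
        compare = (species[0], species[1]) if len(species) >= 2 else None
    t_stat = pvalue = None
    status = "insufficient groups"
    if compare is not None:
        a = list(counts.get(compare[0], {}).values())
        b = list(counts.get(compare[1], {}).values())
        t_stat, pvalue, status = _welch(a, b)
    return TargetsPerMirna(counts=counts, means=means, t_stat=t_stat, pvalue=pvalue, status=status)


@dataclass
class SitesPerTranscript:
    counts: dict[str, dict[str, int]]  # species -> transcript -> total site count
    t_stat: float | None
    pvalue: float | None
    status: str

    def ecdf_frame(self) -> pd.DataFrame:
        rows = []
        for sp, c in sorted(self.counts.items()):
            vals = np.sort(np.array(list(c.values())))
            n = len(vals)
            for i, v in enumerate(vals, start=1):
                rows.append({"species": sp, "sites": int(v), "ecdf": i / n})
        return pd.DataFrame(rows, columns=["species", "sites", "ecdf"])


def sites_per_transcript(
    target_maps: dict[str, TargetMap],
    universe: set[str] | None = None,
    compare: tuple[str, str] | None = None,
) -> SitesPerTranscript:
    """Total family target sites per transcript, compared across species."""
    counts: dict[str, dict[str, int]] = {}
    for sp, tmap in sorted(target_maps.items()):
        per_tx: dict[str, int] = {}
        for site in tmap.sites(sp):
            gene = tmap.gene_of(sp, site.transcript)
            if universe is not None and gene not in universe:
                continue
            per_tx[site.transcript] = per_tx.get(site.transcript, 0) + 1
        counts[sp] = per_tx
    if compare is None:
        species = sorted(counts)
        compare = (species[0], species[1]) if len(species) >= 2 else None
    t_stat = pvalue = None
    status = "insufficient groups"
    if compare is not None:
        a = list(counts.get(compare[0], {}).values())
        b = list(counts.get(compare[1], {}).values())
        t_stat, pvalue, status = _welch(a, b)
    return SitesPerTranscript(counts=counts, t_stat=t_stat, pvalue=pvalue, status=status)


@dataclass
class TeOverlapResult:
    containing: pd.DataFrame  # transcript, chrom, te_name, overlap_bp
    n_containing: int
    n_in_det_pool: int
    det_hits: set[str]


def te_containing_transcripts(
    utr_annotations: list,
    te_annotations: list,
    te_family: str | None = None,
    det_pool: set[str] | None = None,
    max_distance: int = 0,
) -> TeOverlapResult:
    """Transcripts whose 3'UTR overlaps a TE family interval, joined to DETs.

    Annotations are (chrom, start, end, name[, strand]) tuples or objects
    with those attributes, 0-based half-open.  "Containing" means >= 1 bp
    overlap; ``max_distance`` > 0 relaxes this to closest-feature semantics
    within that many bp.  Disjoint chromosome name sets are reported as a
    likely naming mismatch.
    """

    def unpack(rec):
        if hasattr(rec, "chrom"):
            return rec.chrom, rec.start, rec.end, getattr(rec, "name", "")
        return rec[0], rec[1], rec[2], rec[3] if len(rec) > 3 else ""

    utrs = [unpack(r) for r in utr_annotations]
    tes = [unpack(r) for r in te_annotations]
    if te_family is not None:
        tes = [t for t in tes if te_family in t[3]]
    utr_chroms = {u[0] for u in utrs}
    te_chroms = {t[0] for t in tes}
    if utrs and tes and not (utr_chroms & te_chroms):
        raise ValueError(
            "chromosome naming mismatch: UTR and TE annotations share no contig "
            f"(e.g. {sorted(utr_chroms)[0]!r} vs {sorted(te_chroms)[0]!r})"
        )
    # sorted sweep per chromosome
    te_by_chrom: dict[str, list] = {}
    for t in tes:
        te_by_chrom.setdefault(t[0], []).append(t)
    for lst in te_by_chrom.values():
        lst.sort(key=lambda t: t[1])
    rows = []
    for chrom, ustart, uend, uname in sorted(utrs, key=lambda u: (u[0], u[1])):
        for _, tstart, tend, tname in te_by_chrom.get(chrom, []):
            if tstart >= uend + max_distance:
                break
            overlap = min(uend, tend) - max(ustart, tstart)
            if overlap >= 1 or (max_distance > 0 and overlap > -max_distance):
                rows.append(
                    {
                        "transcript": uname,
                        "chrom": chrom,
                        "te_name": tname,
                        "overlap_bp": max(overlap, 0),
                    }
                )
    containing = pd.DataFrame(rows, columns=["transcript", "chrom", "te_name", "overlap_bp"])
    hit_tx = set(containing["transcript"]) if len(containing) else set()
    det_hits = hit_tx & det_pool if det_pool is not None else set()
    return TeOverlapResult(
        containing=containing,
        n_containing=len(hit_tx),
        n_in_det_pool=len(det_hits),
        det_hits=det_hits,
    )
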