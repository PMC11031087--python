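"""Per-base conservation mapping and population-frequency summaries.

Conservation scores live on genomic (or per-transcript) contigs and are
mapped into UTR coordinates through the transcript's genomic blocks.  The
headline contrast compares mean scores inside predicted/true target sites
against the remaining UTR bases, paired per gene.  Feature-class summaries
use a Kruskal-Wallis omnibus with Dunn/Holm post hocs; per-site diversity is
summarized as ``mnd = 2 * daf * (1 - daf)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scan import TargetSite, UtrRecord

logger = logging.getLogger(__name__)


class ConservationTrack:
    """Per-contig arrays of per-base scores, 0-based.

    ``semantics`` labels the score type: ``"phylop"`` (signed) or
    ``"phastcons"`` (probabilities in [0, 1]).  Positions not covered by any
    stored segment read back as NaN.
    """

    def __init__(self, semantics: str = "phylop"):
        if semantics not in ("phylop", "phastcons"):
            raise ValueError("semantics must be 'phylop' or 'phastcons'")
        self.semantics = semantics
        # chrom -> list of (start, values array), kept sorted, non-overlapping
        self._segments: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_array(self, chrom: str, start: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if self.semantics == "phastcons" and values.size:
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("phastcons scores must lie in [0, 1]")
        end = start + len(values)
        segs = self._segments.setdefault(chrom, [])
        for s, vals in segs:
            if start < s + len(vals) and s < end:
                raise ValueError(f"overlapping segment on {chrom} at [{start}, {end})")
        segs.append((start, values))
        segs.sort(key=lambda seg: seg[0])

    def add_value(self, chrom: str, start: int, end: int, value: float) -> None:
        self.add_array(chrom, start, np.full(end - start, float(value)))

    def chroms(self) -> list[str]:
        return sorted(self._segments)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered positions are NaN."""
        out = np.full(end - start, np.nan)
        for s, vals in self._segments.get(chrom, []):
            e = s + len(vals)
            lo, hi = max(start, s), min(end, e)
            if lo < hi:
                out[lo - start : hi - start] = vals[lo - s : hi - s]
        return out


def map_scores_to_utr(track: ConservationTrack, utr: UtrRecord) -> np.ndarray:
    """Concatenate track scores over the UTR's genomic blocks, 5'->3'.

    Minus-strand blocks are reversed so index 0 is the UTR 5' end; score
    values are left untouched (conservation is strandless).  Positions
    outside the track extent become NaN with a warning.
    """
    if not utr.genomic_intervals:
        raise ValueError(f"UTR {utr.transcript} has no genomic intervals")
    parts = []
    for chrom, start, end, strand in utr.genomic_intervals:
        vals = track.values(chrom, start, end)
        if strand == "-":
            vals = vals[::-1]
        parts.append(vals)
    out = np.concatenate(parts)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} UTR position(s) of {utr.transcript} fall outside the track",
            stacklevel=2,
        )
    return out


@dataclass
class ContrastResult:
    """Site vs non-site conservation contrast, paired per gene."""

    table: pd.DataFrame  # gene, site_mean, nonsite_mean, diff
    t_stat: float
    pvalue: float
    mean_difference: float
    n_genes: int
    excluded: list[str]
    method: str
    pooled_t: float | None = None
    pooled_pvalue: float | None = None
    site_ecdf: np.ndarray = field(default_factory=lambda: np.array([]))
    nonsite_ecdf: np.ndarray = field(default_factory=lambda: np.array([]))


def site_vs_nonsite_contrast(
    scores_by_gene: dict[str, np.ndarray],
    sites_by_gene: dict[str, list[TargetSite]],
    use_wilcoxon: bool = False,
    compute_pooled: bool = True,
) -> ContrastResult:
    """Per-gene paired contrast of site bases vs the remaining UTR bases.

    Each gene contributes one pair (mean over the union of site bases, mean
    over all other bases); the primary test is a paired t-test over genes
    (Wilcoxon behind ``use_wilcoxon``).  Genes lacking a non-missing base on
    either side are excluded and logged.  Pooled per-base ECDFs, and
    optionally a pooled Welch test, are reported as secondary outputs.
    """
    rows = []
    excluded: list[str] = []
    pooled_site: list[np.ndarray] = []
    pooled_non: list[np.ndarray] = []
    for gene in sorted(scores_by_gene):
        scores = np.asarray(scores_by_gene[gene], dtype=float)
        mask = np.zeros(len(scores), dtype=bool)
        for site in sites_by_gene.get(gene, []):
            if site.end > len(scores):
                raise ValueError(f"site beyond UTR scores for {gene}")
            mask[site.start : site.end] = True
        site_vals = scores[mask]
        non_vals = scores[~mask]
        site_vals = site_vals[np.isfinite(site_vals)]
        non_vals = non_vals[np.isfinite(non_vals)]
        if site_vals.size == 0 or non_vals.size == 0:
            excluded.append(gene)
            logger.info("gene %s excluded from contrast (no scored bases)", gene)
            continue
        rows.append(
            {
                "gene": gene,
                "site_mean": float(site_vals.mean()),
                "nonsite_mean": float(non_vals.mean()),
                "diff": float(site_vals.mean() - non_vals.mean()),
            }
        )
        pooled_site.append(site_vals)
        pooled_non.append(non_vals)
    table = pd.DataFrame(rows, columns=["gene", "site_mean", "nonsite_mean", "diff"])
    if len(table) < 2:
        raise ValueError("need >= 2 genes with both site and non-site scores")
    if use_wilcoxon:
        res = stats.wilcoxon(table["site_mean"], table["nonsite_mean"])
        t_stat, pvalue, method = float(res.statistic), float(res.pvalue), "wilcoxon"
    else:
        t_stat, pvalue = stats.ttest_rel(table["site_mean"], table["nonsite_mean"])
        t_stat, pvalue, method = float(t_stat), float(pvalue), "paired_t"
    site_all = np.concatenate(pooled_site)
    non_all = np.concatenate(pooled_non)
    pooled_t = pooled_p = None
    if compute_pooled:
        pt, pp = stats.ttest_ind(site_all, non_all, equal_var=False)
        pooled_t, pooled_p = float(pt), float(pp)
    return ContrastResult(
        table=table,
        t_stat=t_stat,
        pvalue=pvalue,
        mean_difference=float(table["diff"].mean()),
        n_genes=len(table),
        excluded=excluded,
        method=method,
        pooled_t=pooled_t,
        pooled_pvalue=pooled_p,
        site_ecdf=np.sort(site_all),
        nonsite_ecdf=np.sort(non_all),
    )


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int
    end: int
    feature_class: str
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("feature interval must satisfy start < end")


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis omnibus.

    Uses the pooled-rank z approximation with tie correction; p-values are
    adjusted across all pairs (Holm by default).
    """
    labels = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    offset = 0
    for k in labels:
        n_k = len(groups[k])
        mean_ranks[k] = float(ranks[offset : offset + n_k].mean())
        sizes[k] = n_k
        offset += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(max(var_base, 0.0) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "pvalue": float(p)})
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "pvalue"])
    if len(table):
        table["p_adjusted"] = multipletests(table["pvalue"], method=adjust)[1]
    else:
        table["p_adjusted"] = []
    return table


@dataclass
class ClassSummary:
    per_feature: pd.DataFrame  # name, feature_class, mean_score, n_bases
    class_means: pd.Series
    kw_stat: float | None
    kw_pvalue: float | None
    posthoc: pd.DataFrame | None
    excluded_classes: list[str]
    status: str  # "ok" | "declined"


def feature_class_summary(
    track: ConservationTrack,
    features: list[FeatureInterval],
    per_feature: bool = True,
) -> ClassSummary:
    """Mean conservation per feature class with omnibus and post-hoc tests.

    The test unit is one mean per feature (avoiding per-base
    pseudoreplication); ``per_feature=False`` switches to pooled per-base
    observations.  Classes with fewer than two observations are excluded from
    the tests and reported.
    """
    if not features:
        raise ValueError("empty feature list")
    rows = []
    obs: dict[str, list[np.ndarray]] = {}
    for i, feat in enumerate(features):
        vals = track.values(feat.chrom, feat.start, feat.end)
        vals = vals[np.isfinite(vals)]
        name = feat.name or f"feature{i}"
        rows.append(
            {
                "name": name,
                "feature_class": feat.feature_class,
                "mean_score": float(vals.mean()) if vals.size else np.nan,
                "n_bases": int(vals.size),
            }
        )
        if vals.size:
            obs.setdefault(feat.feature_class, []).append(vals)
    table = pd.DataFrame(rows, columns=["name", "feature_class", "mean_score", "n_bases"])
    if per_feature:
        groups = {
            cls: table.loc[
                (table["feature_class"] == cls) & table["mean_score"].notna(), "mean_score"
            ].to_numpy()
            for cls in table["feature_class"].unique()
        }
    else:
        groups = {cls: np.concatenate(arrs) for cls, arrs in obs.items()}
    excluded = sorted(cls for cls, v in groups.items() if len(v) < 2)
    testable = {cls: v for cls, v in groups.items() if len(v) >= 2}
    class_means = table.groupby("feature_class")["mean_score"].mean()
    if len(testable) < 2:
        return ClassSummary(table, class_means, None, None, None, excluded, "declined")
    try:
        kw_stat, kw_p = stats.kruskal(*testable.values())
    except ValueError:  # all observations identical
        kw_stat, kw_p = 0.0, 1.0
    if not np.isfinite(kw_stat):  # fully tied data divides out to nan
        kw_stat, kw_p = 0.0, 1.0
    posthoc = dunn_posthoc(testable)
    return ClassSummary(
        per_feature=table,
        class_means=class_means,
        kw_stat=float(kw_stat),
        kw_pvalue=float(kw_p),
        posthoc=posthoc,
        excluded_classes=excluded,
        status="ok",
    )


def mnd(daf):
    """Mean nucleotide diversity of a site: ``2 * daf * (1 - daf)``.

    Accepts scalars or arrays; inputs must lie in [0, 1].
    """
    arr = np.asarray(daf, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("daf must lie in [0, 1]")
    out = 2.0 * arr * (1.0 - arr)
    return float(out) if np.isscalar(daf) or arr.ndim == 0 else out


@dataclass
class PopgenCompare:
    per_class: pd.DataFrame
    tests: dict[str, dict]
    status: str


def popgen_class_compare(
    alleles: pd.DataFrame,
    classes: list[str] | None = None,
) -> PopgenCompare:
    """Kruskal-Wallis comparison of DAF and MND distributions across classes.

    ``alleles`` needs ``feature_class``, ``daf`` and (optionally) ``mnd``
    columns; ``mnd`` is recomputed from ``daf`` when absent.  A single class
    declines the omnibus with an explicit status.
    """
    df = alleles.copy()
    if "mnd" not in df.columns:
        df["mnd"] = mnd(df["daf"].to_numpy())
    present = list(df["feature_class"].unique())
    if classes is not None:
        unknown = set(classes) - set(present)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        df = df[df["feature_class"].isin(classes)]
        present = list(classes)
    summary = (
        df.groupby("feature_class")
        .agg(n=("daf", "size"), mean_daf=("daf", "mean"), mean_mnd=("mnd", "mean"))
        .reset_index()
    )
    if len(present) < 2:
        return PopgenCompare(summary, {}, "declined")
    tests: dict[str, dict] = {}
    for col in ("daf", "mnd"):
        groups = {cls: df.loc[df["feature_class"] == cls, col].to_numpy() for cls in present}
        stat, p = stats.kruskal(*groups.values())
        tests[col] = {
            "kw_stat": float(stat),
            "kw_pvalue": float(p),
            "posthoc": dunn_posthoc(groups),
        }
    return PopgenCompare(summary, tests, "ok")
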