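"""Differential expression and differentially-expressed-target selection.

The built-in DE test is deliberately lightweight: median-of-ratios size
factors, log2 fold change of mean normalized counts with a 0.5 pseudocount,
a per-gene Welch t-test on log2 normalized counts, and Benjamini-Hochberg
FDR.  External DE tables (gene, log2fc, pvalue, fdr, line) can be ingested
instead when a full DE engine has already been run.

Selection logic: DEGs satisfy |fold change| >= fc_min in either direction
AND fdr < fdr_max (strict).  Per KO line, DETs are DEGs intersected with the
predicted family targets; genes supported by at least ``min_lines`` KO lines
form the pooled DET set, and the all-lines intersection is reported too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scan import TargetMap


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample line/replicate metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample name; columns: line, replicate

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:3]}")
        if "line" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'line' column")

    def lines(self) -> list[str]:
        return sorted(self.samples["line"].unique())

    def columns_for(self, line: str) -> list[str]:
        names = self.samples.index[self.samples["line"] == line]
        return [c for c in self.counts.columns if c in set(names)]


@dataclass(frozen=True)
class DeRecord:
    gene: str
    ko_line: str
    log2fc: float
    pvalue: float
    fdr: float


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Falls back to library-size ratios when no gene is expressed in every
    sample.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() >= 1:
        log_arr = np.log(arr[positive])
        log_gm = log_arr.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(log_arr - log_gm, axis=0))
    else:
        lib = arr.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("degenerate group: all-zero library")
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Standard BH step-up adjusted values (monotone in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_expression(
    cm: CountMatrix,
    ko_line: str,
    wt_line: str = "WT",
    pseudocount: float = 0.5,
) -> list[DeRecord]:
    """Per-gene KO-vs-WT fold change and Welch p-value on log2 normalized counts."""
    wt_cols = cm.columns_for(wt_line)
    ko_cols = cm.columns_for(ko_line)
    if len(wt_cols) < 2 or len(ko_cols) < 2:
        raise ValueError("need >= 2 replicates per compared group")
    sub = cm.counts[wt_cols + ko_cols]
    if (sub.sum(axis=0) == 0).any():
        raise ValueError("degenerate group: all-zero library")
    sf = size_factors(sub)
    norm = sub / sf
    wt = norm[wt_cols].to_numpy()
    ko = norm[ko_cols].to_numpy()
    log2fc = np.log2(ko.mean(axis=1) + pseudocount) - np.log2(wt.mean(axis=1) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            np.log2(ko + pseudocount), np.log2(wt + pseudocount), axis=1, equal_var=False
        )
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    fdr = benjamini_hochberg(pvals)
    return [
        DeRecord(gene=g, ko_line=ko_line, log2fc=float(l), pvalue=float(p), fdr=float(q))
        for g, l, p, q in zip(cm.counts.index, log2fc, pvals, fdr)
    ]


def de_frame(records: list[DeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "line": r.ko_line,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
            }
            for r in records
        ],
        columns=["gene", "line", "log2fc", "pvalue", "fdr"],
    )


def records_from_frame(frame: pd.DataFrame) -> list[DeRecord]:
    """Ingest an external DE table (gene, log2fc, pvalue, fdr, line)."""
    required = {"gene", "log2fc", "pvalue", "fdr", "line"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return [
        DeRecord(
            gene=row.gene,
            ko_line=row.line,
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue),
            fdr=float(row.fdr),
        )
        for row in frame.itertuples(index=False)
    ]


def select_degs(
    de: list[DeRecord],
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> set[str]:
    """Genes with |fold change| >= fc_min (either direction) and fdr < fdr_max."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    lfc_min = np.log2(fc_min)
    return {r.gene for r in de if abs(r.log2fc) >= lfc_min and r.fdr < fdr_max}


@dataclass
class DetPool:
    """Per-line DET sets and the pooled (>= min_lines support) DET set."""

    per_line: dict[str, set[str]]
    pooled: dict[str, int]  # gene -> number of supporting lines
    all_lines: set[str]
    fc_min: float
    fdr_max: float
    min_lines: int
    per_line_signs: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def pooled_genes(self) -> set[str]:
        return set(self.pooled)


def select_dets(
    deg_sets: dict[str, set[str]],
    target_map: TargetMap | set[str],
    min_lines: int = 2,
    species: str | None = None,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    signs: dict[str, dict[str, int]] | None = None,
) -> DetPool:
    """Intersect per-line DEGs with predicted family targets and pool.

    ``target_map`` may be a :class:`TargetMap` (``species`` required when it
    holds several) or a plain gene set.  Pooling is by gene identity only;
    per-line fold-change signs, when supplied, are carried through for
    reporting.
    """
    if min_lines > len(deg_sets):
        raise ValueError("min_lines exceeds the number of KO lines supplied")
    if isinstance(target_map, TargetMap):
        all_species = target_map.species()
        if species is None:
            if len(all_species) != 1:
                raise ValueError("species required for a multi-species target map")
            species = all_species[0]
        targeted = target_map.target_genes(species)
    else:
        targeted = set(target_map)
    per_line = {line: degs & targeted for line, degs in deg_sets.items()}
    support: dict[str, int] = {}
    for dets in per_line.values():
        for g in dets:
            support[g] = support.get(g, 0) + 1
    pooled = {g: n for g, n in support.items() if n >= min_lines}
    all_lines = set.intersection(*per_line.values()) if per_line else set()
    return DetPool(
        per_line=per_line,
        pooled=pooled,
        all_lines=all_lines,
        fc_min=fc_min,
        fdr_max=fdr_max,
        min_lines=min_lines,
        per_line_signs=signs or {},
    )
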