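"""Statistics for sperm-competition assays and fertility phenotypes.

Covers Pearson goodness-of-fit of offspring paternity counts against an
expected sperm-mix ratio, Wilson intervals for the sired fraction, the
litter-size trend regression, and paired rate comparisons.  No continuity
correction is applied to the chi-squared test (the plain test is the default
at these sample sizes); an exact binomial alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

ASSAY_TYPES = ("sequential_mating", "mixed_IVF", "co_AI")


@dataclass(frozen=True)
class CompetitionAssay:
    """Offspring counts by sire genotype with an expected mix ratio rA:rB."""

    assay_type: str
    count_a: int
    count_b: int
    ratio_a: float = 1.0
    ratio_b: float = 1.0
    replicate: str | None = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("counts must be >= 0")
        if self.count_a + self.count_b == 0:
            raise ValueError("assay has zero total offspring")
        if self.ratio_a <= 0 or self.ratio_b <= 0:
            raise ValueError("expected ratio components must be > 0")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    @property
    def expected(self) -> tuple[float, float]:
        w = self.ratio_a + self.ratio_b
        return (self.total * self.ratio_a / w, self.total * self.ratio_b / w)


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    pvalue: float
    expected: tuple[float, float]
    low_expected: bool  # any expected cell < 1: exact test advised


def paternity_gof(assay: CompetitionAssay) -> GofResult:
    """Pearson goodness-of-fit of observed counts against the expected ratio.

    One degree of freedom for two genotypes; no continuity correction.
    """
    exp = assay.expected
    obs = (assay.count_a, assay.count_b)
    chi2, p = stats.chisquare(f_obs=obs, f_exp=exp)
    return GofResult(
        chi2=float(chi2),
        df=1,
        pvalue=float(p),
        expected=exp,
        low_expected=min(exp) < 1.0,
    )


def paternity_exact(assay: CompetitionAssay) -> float:
    """Two-sided exact binomial p-value against the expected ratio."""
    p0 = assay.ratio_a / (assay.ratio_a + assay.ratio_b)
    return float(stats.binomtest(assay.count_a, assay.total, p0).pvalue)


@dataclass(frozen=True)
class FractionCi:
    fraction: float
    low: float
    high: float
    confidence: float


def paternity_fraction_ci(assay: CompetitionAssay, confidence: float = 0.95) -> FractionCi:
    """Point fraction sired by genotype A with a Wilson score interval."""
    low, high = proportion_confint(
        assay.count_a, assay.total, alpha=1.0 - confidence, method="wilson"
    )
    return FractionCi(
        fraction=assay.count_a / assay.total,
        low=float(low),
        high=float(high),
        confidence=confidence,
    )


def counts_from_percent(percent: float, n: int) -> tuple[int, int]:
    """Reconstruct integer counts from a printed (percentage, total).

    Accepts either a percent in (1, 100] or a fraction in [0, 1]; rounds to
    the nearest integer and checks that the two counts sum back to ``n``.
    """
    if n <= 0:
        raise ValueError("total n must be > 0")
    frac = percent / 100.0 if percent > 1.0 else percent
    if not 0.0 <= frac <= 1.0:
        raise ValueError("percentage out of range")
    a = int(round(frac * n))
    b = n - a
    if a + b != n:  # defensive; rounding preserves the sum by construction
        raise ValueError("count reconstruction failed to preserve the total")
    return a, b


@dataclass(frozen=True)
class LitterSeries:
    """Litter-size observations per genotype, indexed by the number of family
    miRNAs inactivated in that genotype."""

    mirnas_inactivated: tuple[float, ...]
    litter_sizes: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.mirnas_inactivated) != len(self.litter_sizes):
            raise ValueError("one litter-size group per genotype required")
        if any(x < 0 for x in self.mirnas_inactivated):
            raise ValueError("miRNA counts must be >= 0")
        if any(y < 0 for grp in self.litter_sizes for y in grp):
            raise ValueError("litter sizes must be >= 0")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    f_pvalue: float


def litter_trend(series: LitterSeries) -> TrendResult:
    """OLS of mean litter size per genotype on the number of miRNAs inactivated.

    The F-test p-value for the slope equals the two-sided t-test p-value in
    simple regression.
    """
    x = np.asarray(series.mirnas_inactivated, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")
    y = np.array([float(np.mean(grp)) for grp in series.litter_sizes])
    fit = stats.linregress(x, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        f_pvalue=float(fit.pvalue),
    )


@dataclass(frozen=True)
class RateCompareResult:
    t_stat: float | None
    pvalue: float | None
    wilcoxon_pvalue: float | None
    n_pairs: int
    status: str  # "ok" | "degenerate"


def rate_compare(pairs: list[tuple[float, float]]) -> RateCompareResult:
    """Paired t-test on per-replicate (rate_A, rate_B) differences.

    A Wilcoxon signed-rank p-value is reported alongside as a sensitivity
    check.  All-identical pairs give t = 0, p = 1; a nonzero constant
    difference has zero variance and returns an explicit degenerate status.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 paired replicates")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return RateCompareResult(0.0, 1.0, None, len(pairs), "ok")
        return RateCompareResult(None, None, None, len(pairs), "degenerate")
    t, p = stats.ttest_rel(a, b)
    try:
        w_p = float(stats.wilcoxon(a, b).pvalue)
    except ValueError:
        w_p = None
    return RateCompareResult(float(t), float(p), w_p, len(pairs), "ok")
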