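"""Classical statistics of the mapping study.

Covers the segregation chi-square test against a Mendelian ratio, Welch
two-sample t-tests computed from either raw samples or published
mean/SD/n summaries, percent change between group means, pairwise LD r²
on inbred dosages, and the haplotype-group association (group t-test plus
percent variance explained from the one-way group model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segsim import HaplotypePanel


@dataclass
class SegregationCounts:
    """Observed phenotype-class counts against an expected a:b ratio."""

    n_class_a: int  # normal
    n_class_b: int  # mutant
    expected_ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_class_a < 0 or self.n_class_b < 0:
            raise ValueError("counts must be >= 0")
        if self.expected_ratio[0] <= 0 or self.expected_ratio[1] <= 0:
            raise ValueError("ratio components must be > 0")

    @property
    def df(self) -> int:
        return 1


@dataclass
class TraitSummary:
    """Published mean ± SD with group size for one trait in one group."""

    mean: float
    sd: float
    n: int
    trait: str = ""
    location: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def chisq_segregation(counts: SegregationCounts, alpha: float = 0.05) -> tuple[float, int, bool]:
    """Goodness-of-fit chi-square against the expected ratio.

    No continuity correction.  Returns (chi2, df, significant) where
    significance compares the statistic to the upper-alpha critical value
    at df = classes - 1.
    """
    total = counts.n_class_a + counts.n_class_b
    if total <= 0:
        raise ValueError("total count must be > 0")
    ra, rb = counts.expected_ratio
    exp_a = total * ra / (ra + rb)
    exp_b = total * rb / (ra + rb)
    if exp_a == 0 or exp_b == 0:
        raise ValueError("zero expected count")
    chi2 = (counts.n_class_a - exp_a) ** 2 / exp_a + (counts.n_class_b - exp_b) ** 2 / exp_b
    crit = chi2_critical(alpha, counts.df)
    return float(chi2), counts.df, bool(chi2 > crit)


def chi2_critical(alpha: float, df: int) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def welch_t_from_summary(
    s1: TraitSummary, s2: TraitSummary
) -> tuple[float, float, float]:
    """Welch two-sample t-test from mean/SD/n summaries.

    Returns (t, Welch–Satterthwaite df, two-sided p).  t is signed as
    group 2 minus group 1.  Degenerate zero-variance inputs give p = 1
    for equal means and p = 0 otherwise.
    """
    v1 = s1.sd**2 / s1.n
    v2 = s2.sd**2 / s2.n
    if v1 + v2 == 0:
        if s1.mean == s2.mean:
            return 0.0, float(s1.n + s2.n - 2), 1.0
        return float("inf"), float(s1.n + s2.n - 2), 0.0
    t = (s2.mean - s1.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_t_from_summary(
    s1: TraitSummary, s2: TraitSummary
) -> tuple[float, float, float]:
    """Student (pooled-variance) variant of the summary t-test."""
    df = s1.n + s2.n - 2
    sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
    if sp2 == 0:
        if s1.mean == s2.mean:
            return 0.0, float(df), 1.0
        return float("inf"), float(df), 0.0
    t = (s2.mean - s1.mean) / np.sqrt(sp2 * (1 / s1.n + 1 / s2.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def summarize(sample: np.ndarray, **kwargs) -> TraitSummary:
    """TraitSummary from a raw sample (ddof = 1)."""
    sample = np.asarray(sample, dtype=float)
    return TraitSummary(
        mean=float(sample.mean()), sd=float(sample.std(ddof=1)), n=len(sample), **kwargs
    )


def percent_change(mean_ref: float, mean_alt: float) -> float:
    """Signed percent change of alt relative to ref, to 1 decimal place."""
    if mean_ref == 0:
        raise ValueError("reference mean must be nonzero")
    return round(100.0 * (mean_alt - mean_ref) / mean_ref, 1)


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages (inbred-panel r²).

    Monomorphic input has no defined correlation; returns NaN.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def haplotype_association(
    panel: HaplotypePanel,
) -> tuple[float, float, float, dict[str, float]]:
    """Two-group haplotype association on the trait.

    Welch t between Hap1 and Hap2 lines (unassigned lines excluded) and
    percent variance explained as 100 × R² of the one-way group model
    (between-group sum of squares over total sum of squares).  Returns
    (t, p, pve_percent, group_means).
    """
    k1 = panel.krn[panel.haplotype == "Hap1"]
    k2 = panel.krn[panel.haplotype == "Hap2"]
    if len(k1) == 0 or len(k2) == 0:
        raise ValueError("both haplotype groups must be non-empty")
    grand = np.concatenate([k1, k2])
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    if ss_total == 0:
        pve = 0.0
    else:
        ss_between = len(k1) * (k1.mean() - grand.mean()) ** 2 + len(k2) * (
            k2.mean() - grand.mean()
        ) ** 2
        pve = 100.0 * float(ss_between) / ss_total
    if len(k1) < 2 or len(k2) < 2:
        t, p = float("nan"), float("nan")
    else:
        res = stats.ttest_ind(k1, k2, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    means = {"Hap1": float(k1.mean()), "Hap2": float(k2.mean())}
    return t, p, pve, means
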