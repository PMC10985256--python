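"""Cohort-level statistics for digital activity measures.

Covers the full battery used for digital outcome evaluation in small
observational cohorts:

* cross-sectional group comparison with a normality-gated choice between
  Welch's t-test and the Mann-Whitney U test;
* Bonferroni correction over the family of distinct activity measures
  (waist and wrist versions of one measure share a single family slot);
* Spearman correlation of digital measures with clinical scores;
* paired longitudinal change tests (paired t or Wilcoxon signed-rank);
* test-retest reliability via ICC(2,1) -> SEM -> MDC95;
* responsiveness via the standardized response mean (SRM) and the implied
  two-arm trial sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .epochs import EpochSeries
from .metrics import ActivitySummary, CutPoints, FREEDSON_ADULT, summarize_subject
from .wear import valid_wear_days

__all__ = [
    "GroupComparison",
    "PairedChange",
    "ReliabilityResult",
    "ResponsivenessResult",
    "compare_groups",
    "bonferroni",
    "spearman_matrix",
    "paired_change_test",
    "odd_even_split",
    "icc",
    "mdc_from_icc",
    "srm",
    "sample_size_from_srm",
    "responsiveness",
]

ODD_WEEKDAYS = frozenset({0, 2, 4})   # Monday, Wednesday, Friday
EVEN_WEEKDAYS = frozenset({1, 3, 5})  # Tuesday, Thursday, Saturday


@dataclass
class GroupComparison:
    test: str          # "welch_t" or "mann_whitney"
    statistic: float
    pvalue: float
    n1: int
    n2: int


@dataclass
class PairedChange:
    test: str          # "paired_t" or "wilcoxon"
    statistic: float
    pvalue: float
    mean_change: float
    sd_change: float
    n: int


@dataclass
class ReliabilityResult:
    icc: float
    sem: float
    mdc95: float
    n_subjects: int
    split_label: str = ""


@dataclass
class ResponsivenessResult:
    srm: float
    n_per_arm: int
    alpha: float = 0.05
    power: float = 0.80
    delta: float = 1.0

    @property
    def category(self) -> str:
        """Conventional responsiveness label: large >= 0.8, moderate 0.5-0.8,
        low < 0.5 (on |SRM|)."""
        a = abs(self.srm)
        return "large" if a >= 0.8 else "moderate" if a >= 0.5 else "low"


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk gate; degenerate (constant) samples fail the gate."""
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= alpha


def compare_groups(x, y, normality_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a distribution-driven test choice.

    Both samples pass Shapiro-Wilk at ``normality_alpha`` -> Welch's t-test;
    otherwise Mann-Whitney U (two-sided).  Requires >= 3 values per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 values per group")
    if _is_normal(x, normality_alpha) and _is_normal(y, normality_alpha):
        res = sps.ttest_ind(x, y, equal_var=False)
        return GroupComparison("welch_t", float(res.statistic), float(res.pvalue), x.size, y.size)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison("mann_whitney", float(res.statistic), float(res.pvalue), x.size, y.size)


def bonferroni(p_values, n_families: int = 7) -> np.ndarray:
    """Bonferroni-adjust p-values for a family of ``n_families`` distinct
    measures (p_adj = min(1, p * m)).

    The family size is the number of unrelated measures, not the length of
    the input: waist and wrist versions of the same measure are one family
    member, so both are multiplied by the same ``m``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * n_families)


def spearman_matrix(
    clinical_scores: pd.DataFrame, digital_measures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every clinical x digital variable pair.

    Inputs are aligned on their index (subjects); rows missing either value
    of a pair are dropped pairwise.
    """
    clinical, digital = clinical_scores.align(digital_measures, join="inner", axis=0)
    rho = pd.DataFrame(index=clinical.columns, columns=digital.columns, dtype=float)
    pval = rho.copy()
    for c in clinical.columns:
        for d in digital.columns:
            pair = pd.concat([clinical[c], digital[d]], axis=1).dropna()
            if len(pair) < 3:
                continue
            res = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.loc[c, d] = float(res.statistic)
            pval.loc[c, d] = float(res.pvalue)
    return rho, pval


def paired_change_test(
    baseline, followup, normality_alpha: float = 0.05, method: str = "auto"
) -> PairedChange:
    """Longitudinal change test on subject-paired values.

    Pairs with a missing visit are dropped.  ``method="auto"`` applies the
    same Shapiro-Wilk gate as :func:`compare_groups` to the change scores;
    Wilcoxon signed-rank is the tie-break when the gate cannot decide.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.size != followup.size:
        raise ValueError("baseline and follow-up must be subject-paired")
    keep = ~(np.isnan(baseline) | np.isnan(followup))
    changes = followup[keep] - baseline[keep]
    n = changes.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    mean_c = float(changes.mean())
    sd_c = float(changes.std(ddof=1))

    if method == "auto":
        method = "ttest" if _is_normal(changes, normality_alpha) else "wilcoxon"
    if method == "ttest":
        res = sps.ttest_rel(followup[keep], baseline[keep])
        return PairedChange("paired_t", float(res.statistic), float(res.pvalue), mean_c, sd_c, n)
    if method != "wilcoxon":
        raise ValueError(f"unknown method {method!r}")
    if np.all(changes == 0):
        return PairedChange("wilcoxon", 0.0, 1.0, 0.0, 0.0, n)
    res = sps.wilcoxon(changes)
    return PairedChange("wilcoxon", float(res.statistic), float(res.pvalue), mean_c, sd_c, n)


def odd_even_split(
    series: EpochSeries,
    cutpoints: CutPoints = FREEDSON_ADULT,
    min_wear_hours: float = 8.0,
) -> tuple[ActivitySummary, ActivitySummary]:
    """Split one recording into odd (Mon/Wed/Fri) and even (Tue/Thu/Sat)
    weekday halves and summarize each independently.

    Sundays are excluded from both halves.  An empty half (no valid days of
    that parity) is an error, mirroring the subject-exclusion rule.
    """
    wds = valid_wear_days(series, min_wear_hours)
    odd_days = {d for d in wds.valid_days if d.weekday() in ODD_WEEKDAYS}
    even_days = {d for d in wds.valid_days if d.weekday() in EVEN_WEEKDAYS}
    if not odd_days or not even_days:
        raise ValueError("odd/even split needs valid days on both weekday parities")
    odd = summarize_subject(series, cutpoints, min_wear_hours, day_filter=odd_days)
    even = summarize_subject(series, cutpoints, min_wear_hours, day_filter=even_days)
    return odd, even


def icc(pairs, split_label: str = "") -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``pairs`` is an (n, 2) array of the same measure under two conditions
    (e.g. odd vs even weekday halves).  Computed from the two-way ANOVA mean
    squares; SEM and MDC95 are derived from the pooled SD of all
    measurements.  Requires >= 5 complete pairs and non-zero total variance.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n, k = arr.shape
    if n < 5:
        raise ValueError("need at least 5 complete pairs for ICC")
    if np.ptp(arr) == 0:
        raise ValueError("zero total variance: ICC undefined")

    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((arr - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_val = float((msr - mse) / denom)

    sd = float(arr.std(ddof=1))
    mdc = mdc_from_icc(sd, icc_val)
    sem = sd * math.sqrt(1.0 - min(max(icc_val, 0.0), 1.0))
    return ReliabilityResult(icc_val, sem, mdc, n, split_label)


def mdc_from_icc(sd: float, icc: float, confidence: float = 0.95) -> float:
    """Minimal detectable change from a reliability coefficient.

    ``SEM = sd * sqrt(1 - ICC)`` (ICC clipped to [0, 1] so the SEM stays
    real) and ``MDC = z * sqrt(2) * SEM`` with z the two-sided normal
    quantile of ``confidence`` (1.96 at 95%).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    icc_c = min(max(icc, 0.0), 1.0)
    sem = sd * math.sqrt(1.0 - icc_c)
    z = sps.norm.ppf((1.0 + confidence) / 2.0)
    return float(z * math.sqrt(2.0) * sem)


def srm(changes) -> float:
    """Standardized response mean: mean change / SD of change."""
    c = np.asarray(changes, dtype=float)
    c = c[~np.isnan(c)]
    if c.size < 2:
        raise ValueError("need at least 2 change scores")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("zero change variance: SRM undefined")
    return float(c.mean() / sd)


def sample_size_from_srm(
    srm: float,
    alpha: float = 0.05,
    power: float = 0.80,
    delta: float = 1.0,
    solver: str = "normal",
) -> int:
    """Per-arm sample size of a two-arm trial detecting a ``delta`` fraction
    of the observed standardized change.

    The normal-approximation closed form is
    ``n = ceil(2 * (z_{1-alpha/2} + z_{power})^2 / (delta * SRM)^2)``;
    ``solver="t"`` instead iterates the noncentral-t power of the two-sample
    t-test (slightly larger n at small sizes).
    """
    if srm == 0:
        raise ValueError("SRM of zero implies no detectable effect")
    if not (0 < delta <= 1):
        raise ValueError("delta must be in (0, 1]")
    effect = abs(srm) * delta
    if solver == "normal":
        z_a = sps.norm.ppf(1.0 - alpha / 2.0)
        z_b = sps.norm.ppf(power)
        return int(math.ceil(2.0 * (z_a + z_b) ** 2 / effect**2))
    if solver == "t":
        from statsmodels.stats.power import TTestIndPower

        n = TTestIndPower().solve_power(effect_size=effect, alpha=alpha, power=power, ratio=1.0)
        return int(math.ceil(n))
    raise ValueError(f"unknown solver {solver!r}")


def responsiveness(
    changes,
    alpha: float = 0.05,
    power: float = 0.80,
    delta: float = 1.0,
    solver: str = "normal",
) -> ResponsivenessResult:
    """SRM of observed change scores plus the implied trial size."""
    s = srm(changes)
    n = sample_size_from_srm(s, alpha, power, delta, solver)
    return ResponsivenessResult(s, n, alpha, power, delta)
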