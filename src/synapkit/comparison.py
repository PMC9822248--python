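"""Control normalization and the standard-test selection policy.

Knockout measurements are normalized to the mean of their own (genetically
matched) control group so that two lines can be compared on a common
dimensionless scale.  Two-group comparisons follow a fixed policy:
parametric tests are used when both groups pass Shapiro-Wilk normality at
alpha or when both have n >= 30; Student's t when an F-ratio test accepts
equal variances, Welch's t otherwise; and Mann-Whitney as the
non-parametric fallback.  Aligned line profiles are compared by a two-way
(condition x position) ANOVA restricted to a 200-nm window around the
active-zone peak, with Bonferroni-adjusted per-position comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedMetricError

__all__ = [
    "NormalizedSet", "TestDecision", "ProfileTestResult",
    "normalize_to_control", "choose_test", "factorial_profile_test",
]


@dataclass(frozen=True)
class NormalizedSet:
    """Per-cell knockout values divided by their control group mean."""

    line: str
    values: np.ndarray        # dimensionless
    control_mean: float       # original units


@dataclass(frozen=True)
class TestDecision:
    """Outcome of the test-selection policy for one two-group comparison."""

    test: str                     # 'student_t' | 'welch_t' | 'mann_whitney'
    p_value: float
    statistic: float
    normal: tuple[bool, bool]     # Shapiro-Wilk pass per group
    large_sample: bool            # both n >= 30
    equal_variance: bool | None   # F-ratio verdict (None on the nonparametric branch)
    n: tuple[int, int]
    alpha: float


@dataclass(frozen=True)
class ProfileTestResult:
    """Two-way ANOVA on a profile window plus per-position post-hoc tests."""

    anova: pd.DataFrame
    per_position: pd.DataFrame    # position_nm, p_raw, p_adj, significant
    window: tuple[float, float]
    n_positions: int


def normalize_to_control(ko_values: np.ndarray, control_values: np.ndarray,
                         line: str = "") -> NormalizedSet:
    """Divide each knockout cell's value by the control-group mean of its line."""
    ko = np.asarray(ko_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size == 0:
        raise InputError("control group is empty")
    mean = float(ctrl.mean())
    if mean == 0.0:
        raise UndefinedMetricError("control mean is zero; normalization undefined")
    return NormalizedSet(line=line, values=ko / mean, control_mean=mean)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:       # constant sample: Shapiro-Wilk undefined
        return False
    return stats.shapiro(x).pvalue > alpha


def choose_test(group_a: np.ndarray, group_b: np.ndarray,
                alpha: float = 0.05) -> TestDecision:
    """Run the comparison prescribed by the test-selection policy.

    Parametric iff both groups pass Shapiro-Wilk at ``alpha`` or both have
    n >= 30; then Student's t if a two-sided F-ratio test accepts equal
    variances at ``alpha``, Welch's t otherwise; Mann-Whitney U (two-sided)
    as the non-parametric fallback.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InputError("need at least 3 values per group")
    normal = (bool(_is_normal(a, alpha)), bool(_is_normal(b, alpha)))
    large = a.size >= 30 and b.size >= 30
    parametric = (normal[0] and normal[1]) or large

    if parametric:
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        cdf = stats.f.cdf(f, a.size - 1, b.size - 1)
        p_var = 2.0 * min(cdf, 1.0 - cdf)
        equal_var = bool(p_var > alpha)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
    else:
        equal_var = None
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return TestDecision(test=name, p_value=float(res.pvalue),
                        statistic=float(res.statistic), normal=normal,
                        large_sample=large, equal_variance=equal_var,
                        n=(a.size, b.size), alpha=alpha)


def factorial_profile_test(profiles: dict[str, np.ndarray], axis_nm: np.ndarray,
                           window: tuple[float, float],
                           alpha: float = 0.05) -> ProfileTestResult:
    """Two-way (condition x position) ANOVA on a window of aligned profiles.

    ``profiles`` maps condition labels to (n_profiles, n_positions) arrays
    on the common ``axis_nm``; the analysis is restricted to axis positions
    inside ``window`` (a 200-nm span centered on the active-zone peak in the
    standard usage).  Per-position condition comparisons are
    Bonferroni-adjusted by the number of in-window positions.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    axis_nm = np.asarray(axis_nm, dtype=float)
    lo, hi = window
    if lo >= hi:
        raise InputError("window must be (low, high) with low < high")
    if lo < axis_nm.min() - 1e-9 or hi > axis_nm.max() + 1e-9:
        raise InputError("window extends outside the profile axis")
    sel = (axis_nm >= lo) & (axis_nm <= hi)
    positions = axis_nm[sel]
    if positions.size == 0:
        raise InputError("window contains no axis positions")

    rows = []
    for cond, arr in profiles.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != axis_nm.size:
            raise InputError(f"profiles for {cond!r} must be (n, {axis_nm.size})")
        for i in range(arr.shape[0]):
            for p, v in zip(positions, arr[i, sel]):
                if np.isfinite(v):
                    rows.append((cond, p, v))
    df = pd.DataFrame(rows, columns=["condition", "position", "value"])
    model = ols("value ~ C(condition) * C(position)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    conds = sorted(profiles)
    per_pos = []
    for p in positions:
        groups = [df.loc[(df.condition == c) & (df.position == p), "value"].to_numpy()
                  for c in conds]
        if len(conds) == 2:
            p_raw = float(stats.ttest_ind(groups[0], groups[1]).pvalue)
        else:
            p_raw = float(stats.f_oneway(*groups).pvalue)
        p_adj = min(1.0, p_raw * positions.size)
        per_pos.append((p, p_raw, p_adj, p_adj < alpha))
    table = pd.DataFrame(per_pos,
                         columns=["position_nm", "p_raw", "p_adj", "significant"])
    return ProfileTestResult(anova=anova, per_position=table,
                             window=(lo, hi), n_positions=int(positions.size))
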