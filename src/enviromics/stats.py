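"""Shared statistical primitives: two-sample t-tests with degenerate-input
conventions, and Dunnett many-to-one comparisons against the control arm.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps


def two_sample_t(
    group: np.ndarray,
    control: np.ndarray,
    equal_var: bool = True,
) -> float:
    """Two-sample t-test p-value with explicit degenerate conventions.

    With fewer than two observations in either arm the p-value is
    undefined (NaN, with a warning). When both arms have zero variance the
    p-value is 1 for equal means and 0 otherwise — the limiting behaviour
    of the t statistic.
    """
    group = np.asarray(group, dtype=float)
    control = np.asarray(control, dtype=float)
    if group.size < 2 or control.size < 2:
        warnings.warn(
            "fewer than 2 observations in an arm: p-value undefined",
            stacklevel=2,
        )
        return float("nan")
    if group.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        return 1.0 if group.mean() == control.mean() else 0.0
    with warnings.catch_warnings():
        # one arm exactly constant (e.g. threshold-imputed) is legitimate
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred",
            category=RuntimeWarning,
        )
        res = sps.ttest_ind(group, control, equal_var=equal_var)
    return float(res.pvalue)


def dunnett_pvalues(
    treated: list[np.ndarray],
    control: np.ndarray,
    random_state: int = 0,
) -> np.ndarray:
    """Dunnett many-to-one two-sided p-values for each treated arm vs control.

    The multivariate-t integration inside SciPy is quasi-random; a fixed
    ``random_state`` keeps results reproducible run to run.
    """
    control = np.asarray(control, dtype=float)
    arms = [np.asarray(t, dtype=float) for t in treated]
    if all(a.var(ddof=1) == 0 for a in arms) and control.var(ddof=1) == 0:
        return np.array(
            [1.0 if a.mean() == control.mean() else 0.0 for a in arms]
        )
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred",
            category=RuntimeWarning,
        )
        res = sps.dunnett(
            *arms, control=control,
            random_state=np.random.default_rng(random_state),
        )
    return np.asarray(res.pvalue, dtype=float)


def one_way_anova_p(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p-value with the zero-variance convention."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if all(a.var(ddof=1) == 0 for a in arrs):
        means = [a.mean() for a in arrs]
        return 1.0 if np.ptp(means) == 0 else 0.0
    return float(sps.f_oneway(*arrs).pvalue)
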