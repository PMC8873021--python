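"""Post-search proteome statistics.

Ingest starts at a protein x sample intensity matrix (peptide-to-protein
rollup, reporter-ion extraction and search-engine FDR are upstream
concerns). The processing order follows the study: log2 transform, then
quantile normalization; proteins with any missing value are excluded from
statistics (complete-case filtering, no imputation); differential calls
combine a one-way ANOVA omnibus test with Dunnett-style many-to-one
post-hoc comparisons against the vehicle control, plus a separate
pairwise (group vs control) t-test analysis.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@contextmanager
def _quiet_near_constant():
    """Silence SciPy's precision-loss warning for near-constant rows; the
    degenerate-row conventions below handle those cases explicitly."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        yield

from enviromics.stats import dunnett_pvalues, one_way_anova_p, two_sample_t

ALPHA_DEFAULT = 0.05


@dataclass
class ProteinMatrix:
    """Protein x sample intensities (linear scale) with group/donor labels."""

    intensities: pd.DataFrame  # NaN = missing
    groups: pd.Series
    donors: pd.Series

    def __post_init__(self) -> None:
        cols = list(self.intensities.columns)
        if set(cols) - set(self.groups.index) or set(cols) - set(self.donors.index):
            raise ValueError("group/donor labels must cover every sample")
        self.groups = self.groups.reindex(cols)
        self.donors = self.donors.reindex(cols)
        if (self.intensities <= 0).any().any():
            raise ValueError("intensities must be positive where present")

    @property
    def mask(self) -> pd.DataFrame:
        return self.intensities.isna()


@dataclass
class QCReport:
    """Reproducibility QC: intensity summaries, CVs, sample correlations."""

    sample_summaries: pd.DataFrame  # per-sample quartiles of log2 intensity
    cv_table: pd.DataFrame  # protein x group CV (linear scale)
    group_median_cv: pd.Series
    r2: pd.DataFrame  # sample x sample squared Pearson on log2 values

    def to_dict(self) -> dict:
        return {
            "sample_summaries": self.sample_summaries.to_dict(orient="index"),
            "group_median_cv": self.group_median_cv.to_dict(),
            "r2_min_within_group": _min_within_group_r2(self.r2,
                                                        self._groups),
        }

    _groups: pd.Series | None = None


def _min_within_group_r2(r2: pd.DataFrame, groups: pd.Series | None):
    if groups is None:
        return None
    out = {}
    for g in groups.unique():
        cols = [c for c in r2.columns if groups[c] == g]
        if len(cols) < 2:
            continue
        sub = r2.loc[cols, cols].to_numpy()
        out[g] = float(sub[np.triu_indices(len(cols), k=1)].min())
    return out


def complete_case_filter(matrix: ProteinMatrix) -> ProteinMatrix:
    """Keep proteins quantified in every sample; report the count."""
    keep = ~matrix.mask.any(axis=1)
    if not keep.any():
        raise ValueError("no protein is complete across all samples")
    return ProteinMatrix(
        intensities=matrix.intensities.loc[keep].copy(),
        groups=matrix.groups,
        donors=matrix.donors,
    )


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force all columns onto the common distribution of row means.

    Each column's sorted values are replaced by the row means of the
    column-sorted matrix; ties (and fractional average ranks) receive the
    mean of the tied reference values via linear interpolation.
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    ref = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = sps.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_quantile_normalize(matrix: ProteinMatrix) -> pd.DataFrame:
    """log2 transform then quantile-normalize; returns the log2 matrix.

    Requires complete data — run :func:`complete_case_filter` first (or
    drop incomplete proteins otherwise).
    """
    if matrix.mask.any().any():
        raise ValueError(
            "quantile normalization requires complete columns; "
            "apply complete_case_filter first"
        )
    return quantile_normalize(np.log2(matrix.intensities))


def qc_report(matrix: ProteinMatrix) -> QCReport:
    """Per-sample distribution summaries, per-group CVs, sample r^2 matrix.

    CVs are computed on linear-scale intensities (sd/mean per protein per
    group); correlations are squared Pearson on log2 values.
    """
    for g, cols in matrix.groups.groupby(matrix.groups):
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    log2 = np.log2(matrix.intensities)
    summaries = log2.describe().T[["mean", "std", "25%", "50%", "75%"]]

    cv = {}
    for g in matrix.groups.unique():
        cols = [c for c in matrix.intensities.columns if matrix.groups[c] == g]
        sub = matrix.intensities[cols]
        cv[g] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    cv_table = pd.DataFrame(cv)
    group_median_cv = cv_table.median(axis=0, skipna=True)

    complete = log2.dropna(axis=0)
    r2 = complete.corr(method="pearson") ** 2
    report = QCReport(summaries, cv_table, group_median_cv, r2)
    report._groups = matrix.groups
    return report


def anova_posthoc(
    normalized: pd.DataFrame,
    groups: pd.Series,
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
    random_state: int = 0,
) -> pd.DataFrame:
    """Omnibus one-way ANOVA plus Dunnett post-hoc vs the control arm.

    Returns one row per protein: ``anova_p``, then per treated group
    ``p_<group>`` and ``dir_<group>`` (+1/-1, reported only where the
    omnibus AND post-hoc are both below alpha, else 0). A protein is
    "differential in group g" iff both tests pass.
    """
    labels = groups.reindex(normalized.columns)
    group_names = [g for g in labels.unique() if g != control]
    col_idx = {g: [c for c in normalized.columns if labels[c] == g]
               for g in labels.unique()}
    if any(len(v) < 2 for v in col_idx.values()):
        raise ValueError("every group needs at least 2 samples")

    arr = normalized.to_numpy(dtype=float)
    col_pos = {g: [normalized.columns.get_loc(c) for c in cols]
               for g, cols in col_idx.items()}

    # vectorized omnibus ANOVA across proteins
    with _quiet_near_constant():
        anova_p = sps.f_oneway(
            *[arr[:, col_pos[g]] for g in labels.unique()], axis=1
        ).pvalue
    # degenerate rows (zero variance everywhere): convention p=1 / p=0
    degenerate = np.isnan(anova_p)
    for i in np.flatnonzero(degenerate):
        anova_p[i] = one_way_anova_p(
            [arr[i, col_pos[g]] for g in labels.unique()]
        )

    records = []
    for i, protein in enumerate(normalized.index):
        row = {"protein": protein, "anova_p": float(anova_p[i])}
        ctrl = arr[i, col_pos[control]]
        if anova_p[i] < alpha:
            treated = [arr[i, col_pos[g]] for g in group_names]
            pvals = dunnett_pvalues(treated, ctrl, random_state=random_state)
            for g, p, t in zip(group_names, pvals, treated):
                row[f"p_{g}"] = float(p)
                sig = p < alpha
                row[f"dir_{g}"] = int(np.sign(t.mean() - ctrl.mean())) if sig else 0
                row[f"diff_{g}"] = bool(sig)
        else:
            for g in group_names:
                row[f"p_{g}"] = float("nan")
                row[f"dir_{g}"] = 0
                row[f"diff_{g}"] = False
        records.append(row)
    return pd.DataFrame(records).set_index("protein")


def pairwise_vs_control(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group: str,
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t-test restricted to {group, control}.

    Returns columns ``log2_diff`` (mean group - mean control on the log2
    scale), ``p_value`` and ``called`` (strict p < alpha). This is the
    group-stratified analysis behind the per-group differential counts.
    """
    labels = groups.reindex(normalized.columns)
    gcols = [c for c in normalized.columns if labels[c] == group]
    ccols = [c for c in normalized.columns if labels[c] == control]
    if len(gcols) < 2 or len(ccols) < 2:
        raise ValueError("both arms need at least 2 samples")
    garr = normalized[gcols].to_numpy(dtype=float)
    carr = normalized[ccols].to_numpy(dtype=float)
    with _quiet_near_constant():
        res = sps.ttest_ind(garr, carr, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    for i in np.flatnonzero(np.isnan(p)):
        p[i] = two_sample_t(garr[i], carr[i], equal_var=equal_var)
    diff = garr.mean(axis=1) - carr.mean(axis=1)
    return pd.DataFrame(
        {"log2_diff": diff, "p_value": p, "called": p < alpha},
        index=normalized.index,
    )


def differential_counts(
    normalized: pd.DataFrame,
    groups: pd.Series,
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
) -> pd.Series:
    """Number of proteins called per treated group in the pairwise analysis."""
    labels = groups.reindex(normalized.columns)
    out = {}
    for g in labels.unique():
        if g == control:
            continue
        out[g] = int(
            pairwise_vs_control(normalized, groups, g, control, alpha)[
                "called"
            ].sum()
        )
    return pd.Series(out)
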