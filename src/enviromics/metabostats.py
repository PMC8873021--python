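"""Blank-based detection, imputation and differential statistics for the
metabolite intensity matrix.

The detection rule mirrors the study's in-house pipeline: a peak counts as
detected in a sample only when its height reaches a per-analyte threshold
of ``max(sn_multiple * mean(blank heights), floor)`` with the S/N multiple
at 3 and the floor at 10,000 arbitrary units. Non-detections are imputed
with the threshold itself so fold changes stay estimable, except when the
control arm is entirely undetected — then the fold change is reported as
infinite rather than a floor-bound artefact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from enviromics.quant import IntensityMatrix
from enviromics.stats import two_sample_t

ALPHA_DEFAULT = 0.05


@dataclass
class DetectionThresholds:
    """Per-analyte detection thresholds (arbitrary units)."""

    thresholds: pd.Series
    sn_multiple: float = 3.0
    floor: float = 10_000.0

    def __post_init__(self) -> None:
        if (self.thresholds < self.floor).any():
            raise ValueError("every threshold must be at least the floor")


@dataclass
class CorrectedMatrix:
    """Blank-corrected matrix: sample columns only, non-detections imputed.

    ``values`` holds measured heights where detected and the analyte
    threshold where not; ``detected`` is the boolean mask; ``groups`` and
    ``donors`` label the columns.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    thresholds: pd.Series
    groups: pd.Series
    donors: pd.Series

    def provenance(self) -> pd.DataFrame:
        """Per-cell 'measured' / 'imputed' flags."""
        return self.detected.replace({True: "measured", False: "imputed"})


@dataclass(frozen=True)
class DifferentialResult:
    """One analyte's group-vs-control comparison."""

    analyte: str
    group: str
    log2fc: float  # may be +/-inf
    p_value: float  # NaN when undefined
    significant: bool
    inf_reason: str  # 'none' | 'control_undetected' | 'group_undetected'


def compute_thresholds(
    matrix: IntensityMatrix,
    sn_multiple: float = 3.0,
    floor: float = 10_000.0,
) -> DetectionThresholds:
    """Per-analyte threshold = max(sn_multiple * mean blank height, floor)."""
    blanks = matrix.blank_columns
    if not blanks:
        raise ValueError("detection thresholds require at least one blank run")
    blank_mean = matrix.heights[blanks].mean(axis=1)
    thresholds = (sn_multiple * blank_mean).clip(lower=floor)
    return DetectionThresholds(thresholds, sn_multiple, floor)


def apply_detection(
    matrix: IntensityMatrix, thresholds: DetectionThresholds
) -> CorrectedMatrix:
    """Impute the threshold wherever a sample height falls below it.

    A height exactly at the threshold counts as detected (inclusive
    boundary).
    """
    missing = set(matrix.heights.index) - set(thresholds.thresholds.index)
    if missing:
        raise ValueError(f"thresholds missing for analytes: {sorted(missing)}")
    samples = matrix.sample_columns
    heights = matrix.heights[samples]
    thr = thresholds.thresholds.reindex(heights.index)
    detected = heights.ge(thr, axis=0)
    values = heights.where(detected, thr, axis=0)
    return CorrectedMatrix(
        values=values,
        detected=detected,
        thresholds=thr,
        groups=matrix.groups[samples],
        donors=matrix.donors[samples],
    )


def differential(
    corrected: CorrectedMatrix,
    group: str,
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> list[DifferentialResult]:
    """Group-vs-control log2 fold changes and t-test p-values per analyte.

    Fold changes and tests use the imputed values. When every control
    sample is undetected but at least one group sample is detected the
    fold change is +inf (``control_undetected``); the mirrored case gives
    -inf. Significance is the strict rule p < alpha.
    """
    gcols = [c for c in corrected.values.columns if corrected.groups[c] == group]
    ccols = [c for c in corrected.values.columns if corrected.groups[c] == control]
    if not gcols or not ccols:
        raise ValueError("both group and control must have samples")
    small = len(gcols) < 2 or len(ccols) < 2
    results = []
    for analyte in corrected.values.index:
        g = corrected.values.loc[analyte, gcols].to_numpy(dtype=float)
        c = corrected.values.loc[analyte, ccols].to_numpy(dtype=float)
        gdet = corrected.detected.loc[analyte, gcols].to_numpy(dtype=bool)
        cdet = corrected.detected.loc[analyte, ccols].to_numpy(dtype=bool)
        if not cdet.any() and gdet.any():
            log2fc, reason = math.inf, "control_undetected"
        elif not gdet.any() and cdet.any():
            log2fc, reason = -math.inf, "group_undetected"
        else:
            log2fc, reason = float(np.log2(g.mean() / c.mean())), "none"
        if small:
            warnings.warn(
                f"n<2 for {analyte!r}: p-value undefined", stacklevel=2
            )
            p = float("nan")
        else:
            p = two_sample_t(g, c, equal_var=equal_var)
        significant = bool(p < alpha) if not math.isnan(p) else False
        results.append(
            DifferentialResult(analyte, group, log2fc, p, significant, reason)
        )
    return results


def cluster_order(
    corrected: CorrectedMatrix | pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Row and column leaf orderings from agglomerative clustering.

    Euclidean distance, complete linkage, on the imputed values — the
    orderings a heatmap export would use. Constant matrices cluster at
    distance zero; the (deterministic) linkage order is kept with a
    warning.
    """
    values = corrected.values if isinstance(corrected, CorrectedMatrix) else corrected
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    arr = values.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        warnings.warn("constant matrix: cluster order is arbitrary",
                      stacklevel=2)
    row_order = leaves_list(linkage(pdist(arr), method="complete"))
    col_order = leaves_list(linkage(pdist(arr.T), method="complete"))
    return (
        [values.index[i] for i in row_order],
        [values.columns[i] for i in col_order],
    )


def volcano_table(
    results: list[DifferentialResult],
    sentinel_abscissa: float = 10.0,
) -> pd.DataFrame:
    """Per-analyte volcano coordinates, sorted by p-value.

    Rows with infinite fold change are flagged and placed at the signed
    sentinel abscissa so they remain plottable.
    """
    if not results:
        raise ValueError("no differential results to tabulate")
    rows = []
    for r in results:
        infinite = math.isinf(r.log2fc)
        x = math.copysign(sentinel_abscissa, r.log2fc) if infinite else r.log2fc
        neglog = float(-np.log10(r.p_value)) if r.p_value > 0 else math.inf
        if math.isnan(r.p_value):
            neglog = float("nan")
        rows.append(
            dict(analyte=r.analyte, group=r.group, log2fc=x,
                 neg_log10_p=neglog, significant=r.significant,
                 infinite_fc=infinite, inf_reason=r.inf_reason)
        )
    df = pd.DataFrame(rows)
    return df.sort_values("neg_log10_p", ascending=False, kind="stable",
                          na_position="last").reset_index(drop=True)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional extra column)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Differential results as a tidy DataFrame with a BH-FDR column."""
    df = pd.DataFrame(
        dict(
            analyte=[r.analyte for r in results],
            group=[r.group for r in results],
            log2fc=[r.log2fc for r in results],
            p_value=[r.p_value for r in results],
            significant=[r.significant for r in results],
            inf_reason=[r.inf_reason for r in results],
        )
    )
    finite_p = df["p_value"].to_numpy(dtype=float)
    if np.isnan(finite_p).all():
        df["fdr"] = float("nan")
    else:
        df["fdr"] = bh_fdr(np.nan_to_num(finite_p, nan=1.0))
    return df
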