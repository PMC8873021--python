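"""DNA-content cell-cycle deconvolution and apoptosis/DNA-damage quadrant
statistics.

The DNA-content model is Dean-Jett-Fox style: Gaussian G1 and G2/M peaks
(G2/M constrained to 1.8-2.2x the G1 mean), an S-phase plateau between
them broadened by the peak widths, and a sub-G1 band — DNA content below
the G1 peak, a proxy for apoptotic fragmentation — counted directly from
raw events below G1 minus three G1 standard deviations. The quadrant
panel assigns each event by strict threshold exceedance on the cleaved-
PARP and phospho-H2AX channels, with thresholds derived from an upper
quantile of an unstained sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from enviromics.stats import dunnett_pvalues, one_way_anova_p

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class CellCycleFractions:
    """Sub-G1/G1/S/G2-M proportions plus fit diagnostics."""

    sub_g1: float
    g1: float
    s: float
    g2m: float
    g1_mean: float
    g1_sd: float
    g2_mean: float
    g2_sd: float
    residual: float  # relative L2 residual of the histogram fit
    low_confidence: bool = False

    def __post_init__(self) -> None:
        total = self.sub_g1 + self.g1 + self.s + self.g2m
        if abs(total - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")
        for f in (self.sub_g1, self.g1, self.s, self.g2m):
            if not (0.0 <= f <= 1.0):
                raise ValueError("each fraction must lie in [0, 1]")
        if not (1.8 <= self.g2_mean / self.g1_mean <= 2.2):
            raise ValueError("G2/M mean must lie in [1.8, 2.2] x G1 mean")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sub_g1, self.g1, self.s, self.g2m)


@dataclass(frozen=True)
class QuadrantResult:
    """Event counts and percentages per quadrant for one sample."""

    thresholds: tuple[float, float]  # (PARP, pH2AX)
    counts: dict[str, int]  # double_neg, parp_only, double_pos, h2ax_only
    percentages: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def parp_positive_pct(self) -> float:
        """PARP+ overall (single and double positive)."""
        return self.percentages["parp_only"] + self.percentages["double_pos"]

    @property
    def h2ax_positive_pct(self) -> float:
        return self.percentages["h2ax_only"] + self.percentages["double_pos"]


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _local_gaussian_fit(centers, counts, mu0, sigma0):
    """Refine a peak by least squares on bins within ~2 sigma of the mode."""
    window = (centers > mu0 - 2.5 * sigma0) & (centers < mu0 + 2.5 * sigma0)
    x, y = centers[window], counts[window]
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=[y.max(), mu0, sigma0],
            bounds=([0, mu0 - 2 * sigma0, sigma0 / 5],
                    [np.inf, mu0 + 2 * sigma0, sigma0 * 5]),
            maxfev=2000,
        )
        return float(popt[1]), float(popt[2])
    except Exception:
        return float(mu0), float(sigma0)


def fit_dna_content(
    events: np.ndarray,
    bins: int = 256,
    g2_window: tuple[float, float] = (1.8, 2.2),
    subg1_sigmas: float = 3.0,
    residual_flag: float = 0.15,
) -> CellCycleFractions:
    """Deconvolve a DNA-content histogram into sub-G1/G1/S/G2-M fractions.

    The histogram spans [0, 1.1 x 99.5th percentile]; G1 is the dominant
    mode, locally refined by a Gaussian fit; the G2/M Gaussian is
    constrained to ``g2_window`` times the G1 mean; the S component is a
    uniform density between the two means convolved with the peak widths.
    Component amplitudes come from non-negative least squares on the bins
    at or above the sub-G1 cut (G1 mean - ``subg1_sigmas`` G1 SDs); the
    sub-G1 fraction is the raw share of events below that cut.

    All quantities scale with the data, so the fit is equivariant under a
    uniform rescaling of the channel.
    """
    v = np.asarray(events, dtype=float)
    if v.size < 1000:
        raise ValueError("DNA-content fitting needs at least 1000 events")
    if np.any(v <= 0):
        raise ValueError("DNA-content values must be positive")
    upper = 1.1 * np.percentile(v, 99.5)
    counts, edges = np.histogram(v, bins=bins, range=(0.0, upper))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    mode_idx = int(np.argmax(smoothed))
    if mode_idx == 0 or mode_idx >= bins - 1:
        raise ValueError("no resolvable G1 mode in the DNA-content histogram")
    mu1_0 = centers[mode_idx]
    sigma1_0 = max(0.04 * mu1_0, width)
    mu1, sigma1 = _local_gaussian_fit(centers, counts, mu1_0, sigma1_0)

    # G2/M: strongest bin inside the allowed window, locally refined
    lo2, hi2 = g2_window[0] * mu1, g2_window[1] * mu1
    in_window = (centers >= lo2) & (centers <= hi2)
    if not in_window.any():
        raise ValueError("G2/M search window is outside the histogram range")
    g2_idx = np.flatnonzero(in_window)[np.argmax(smoothed[in_window])]
    mu2_0 = centers[g2_idx]
    sigma2_0 = sigma1 * mu2_0 / mu1  # constant CV
    mu2, sigma2 = _local_gaussian_fit(centers, counts, mu2_0, sigma2_0)
    mu2 = float(np.clip(mu2, lo2, hi2))

    cut = mu1 - subg1_sigmas * sigma1
    fit_bins = centers >= cut
    x = centers[fit_bins]
    y = counts[fit_bins].astype(float)

    def _basis(m1, s1, m2, s2):
        b1 = sps.norm.pdf(x, m1, s1) * width
        b2 = sps.norm.pdf(x, m2, s2) * width
        bs = (
            (sps.norm.cdf((x - m1) / s1) - sps.norm.cdf((x - m2) / s2))
            / (m2 - m1)
            * width
        )
        return np.column_stack([b1, bs, b2])

    def _solve(params):
        amps, rnorm = optimize.nnls(_basis(*params), y)
        return amps, rnorm

    # joint refinement: the sequential G2 estimate is biased by the S
    # plateau, so re-fit (mu1, sigma1, mu2, sigma2) with amplitudes
    # profiled out by NNLS at each step (variable projection)
    def _profiled_residual(params):
        basis = _basis(*params)
        amps, _ = optimize.nnls(basis, y)
        return basis @ amps - y

    lo2c, hi2c = g2_window[0] * mu1, g2_window[1] * mu1
    try:
        sol = optimize.least_squares(
            _profiled_residual,
            x0=[mu1, sigma1, np.clip(mu2, lo2c, hi2c), sigma2],
            bounds=(
                [mu1 - 2 * sigma1, sigma1 / 3, lo2c, sigma2 / 3],
                [mu1 + 2 * sigma1, sigma1 * 3, hi2c, sigma2 * 3],
            ),
            xtol=1e-10,
            max_nfev=200,
        )
        mu1, sigma1, mu2, sigma2 = (float(p) for p in sol.x)
    except Exception:
        pass  # keep the sequential estimates
    mu2 = float(np.clip(mu2, g2_window[0] * mu1, g2_window[1] * mu1))

    # final amplitudes on the region defined by the refined G1 peak
    cut = mu1 - subg1_sigmas * sigma1
    fit_bins = centers >= cut
    x = centers[fit_bins]
    y = counts[fit_bins].astype(float)
    amps, rnorm = _solve((mu1, sigma1, mu2, sigma2))
    resid = float(rnorm / max(np.linalg.norm(y), 1e-12))

    # amplitudes are per-component event counts (bases integrate to ~1)
    a1, a_s, a2 = amps
    total_fit = a1 + a_s + a2
    if total_fit <= 0:
        raise ValueError("degenerate DNA-content fit: zero total amplitude")
    sub_raw = float(np.mean(v < cut))
    rest = 1.0 - sub_raw
    f = np.array([a1, a_s, a2]) / total_fit * rest
    fractions = np.array([sub_raw, f[0], f[1], f[2]])
    fractions = fractions / fractions.sum()

    return CellCycleFractions(
        sub_g1=float(fractions[0]),
        g1=float(fractions[1]),
        s=float(fractions[2]),
        g2m=float(fractions[3]),
        g1_mean=mu1,
        g1_sd=sigma1,
        g2_mean=mu2,
        g2_sd=sigma2,
        residual=resid,
        low_confidence=resid > residual_flag,
    )


def derive_thresholds(
    unstained: pd.DataFrame,
    quantile: float = 0.999,
    channels: tuple[str, str] = ("parp", "h2ax"),
) -> tuple[float, float]:
    """Per-channel gate = upper quantile of the unstained sample."""
    if len(unstained) < 1000:
        raise ValueError("threshold derivation needs >= 1000 unstained events")
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    return tuple(
        float(np.quantile(unstained[c].to_numpy(dtype=float), quantile))
        for c in channels
    )


def quadrant_gate(
    events: pd.DataFrame,
    thresholds: tuple[float, float],
    channels: tuple[str, str] = ("parp", "h2ax"),
) -> QuadrantResult:
    """Assign every event to exactly one quadrant by strict > threshold."""
    if len(events) == 0:
        raise ValueError("cannot gate an empty event set")
    tx, ty = thresholds
    if tx <= 0 or ty <= 0:
        raise ValueError("thresholds must be positive")
    x = events[channels[0]].to_numpy(dtype=float)
    y = events[channels[1]].to_numpy(dtype=float)
    xpos = x > tx
    ypos = y > ty
    counts = {
        "double_neg": int(np.sum(~xpos & ~ypos)),
        "parp_only": int(np.sum(xpos & ~ypos)),
        "double_pos": int(np.sum(xpos & ypos)),
        "h2ax_only": int(np.sum(~xpos & ypos)),
    }
    total = len(events)
    percentages = {k: 100.0 * c / total for k, c in counts.items()}
    return QuadrantResult((float(tx), float(ty)), counts, percentages)


def fold_change_vs_control(
    percentages: pd.DataFrame,
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
    random_state: int = 0,
) -> pd.DataFrame:
    """Group fold changes of per-sample percentages, with ANOVA + Dunnett.

    ``percentages`` has one row per sample with a ``group`` column and one
    column per statistic (e.g. parp_pct, double_pos_pct, h2ax_pct).
    Percentages are averaged within group first; fold change is group mean
    over control mean. A zero control mean leaves the fold change NaN and
    flagged undefined.
    """
    if "group" not in percentages.columns:
        raise ValueError("percentages must carry a 'group' column")
    stats_cols = [c for c in percentages.columns if c != "group"]
    groups = [g for g in percentages["group"].unique() if g != control]
    ctrl_rows = percentages[percentages["group"] == control]
    if ctrl_rows.empty:
        raise ValueError("control group absent")
    records = []
    for stat in stats_cols:
        ctrl_vals = ctrl_rows[stat].to_numpy(dtype=float)
        ctrl_mean = ctrl_vals.mean()
        per_group = [
            percentages.loc[percentages["group"] == g, stat].to_numpy(dtype=float)
            for g in groups
        ]
        anova_p = one_way_anova_p([ctrl_vals] + per_group)
        if all(len(v) >= 2 for v in per_group) and len(ctrl_vals) >= 2:
            dunnett_p = dunnett_pvalues(per_group, ctrl_vals,
                                        random_state=random_state)
        else:
            dunnett_p = np.full(len(groups), np.nan)
        for g, vals, dp in zip(groups, per_group, dunnett_p):
            undefined = ctrl_mean == 0.0
            fc = float("nan") if undefined else vals.mean() / ctrl_mean
            records.append(
                dict(statistic=stat, group=g, fold_change=fc,
                     undefined=undefined, anova_p=anova_p,
                     posthoc_p=float(dp),
                     significant=bool(anova_p < alpha and dp < alpha)
                     if not np.isnan(dp) else False)
            )
    return pd.DataFrame(records)
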