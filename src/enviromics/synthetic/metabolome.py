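"""Synthetic centroided LC/MS metabolome runs with known apex heights.

Each analyte appears as a Gaussian chromatographic peak (fixed FWHM,
default 12 s) centred at its expected RT plus jitter; the apex is snapped
to the scan grid so the sampled maximum equals the recorded ground-truth
height exactly. Blank runs carry only uniform low-intensity background
(below a third of the detection floor) so they can never trigger the
blank-based detection rule by accident. One RNG stream per run, keyed by
(seed, sample_id), keeps runs independent of how many others exist.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from enviromics.design import StudyDesign
from enviromics.library import MetaboliteLibraryEntry
from enviromics.msio import Run, Spectrum

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class MetaboliteTruth:
    """Ground truth for one analyte: base level, per-group log2 effects, noise.

    ``effects`` maps group label -> log2 effect relative to ``base_height``.
    Finite values scale the level by ``2**effect``; ``-inf`` means the
    analyte is absent in that group; ``+inf`` means present at
    ``base_height`` in that group while absent in the vehicle control (the
    GTP pattern: infinite fold change through vehicle non-detection).
    """

    entry: MetaboliteLibraryEntry
    base_height: float
    effects: dict[str, float]
    noise_cv: float = 0.05
    rt_jitter_sd: float = 1.5  # seconds
    mz_jitter_ppm: float = 1.5

    def __post_init__(self) -> None:
        if self.base_height <= 0:
            raise ValueError("base_height must be positive")
        if not (0 <= self.noise_cv <= 0.5):
            raise ValueError("noise_cv must lie in [0, 0.5]")
        if self.rt_jitter_sd < 0 or self.mz_jitter_ppm < 0:
            raise ValueError("jitter magnitudes must be non-negative")

    def level(self, group: str, control: str) -> float:
        """True (noise-free) apex height of this analyte in ``group``."""
        eff = self.effects.get(group, 0.0)
        if math.isinf(eff):
            return 0.0 if eff < 0 else self.base_height
        if group == control and any(
            e == math.inf for e in self.effects.values()
        ):
            # some group encodes "absent in vehicle"
            return 0.0
        return self.base_height * 2.0**eff


def _run_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def _warn_coelution(truths: list[MetaboliteTruth], ppm_tol: float, fwhm: float) -> None:
    for i, a in enumerate(truths):
        for b in truths[i + 1 :]:
            ea, eb = a.entry, b.entry
            if ea.polarity != eb.polarity:
                continue
            tol = 2.0 * ppm_tol * 1e-6 * max(ea.theoretical_mz, eb.theoretical_mz)
            if (
                abs(ea.theoretical_mz - eb.theoretical_mz) < tol
                and abs(ea.expected_rt - eb.expected_rt) < fwhm
            ):
                warnings.warn(
                    f"co-elution ambiguity: {ea.name!r} and {eb.name!r} "
                    "overlap within 2x the m/z tolerance at the same RT",
                    stacklevel=3,
                )


def _background(
    rng: np.random.Generator,
    times: np.ndarray,
    floor: float,
    n_per_scan: int,
    mz_range: tuple[float, float],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Uniform low-intensity centroids, strictly below floor/3."""
    out = []
    for _ in times:
        mz = rng.uniform(*mz_range, size=n_per_scan)
        inten = rng.uniform(floor / 30.0, floor / 3.0 * 0.999, size=n_per_scan)
        out.append((mz, inten))
    return out


def gen_metabolome_runs(
    design: StudyDesign,
    truths: list[MetaboliteTruth],
    grid: float = 2.0,
    rt_span: tuple[float, float] = (0.0, 540.0),
    fwhm: float = 12.0,
    floor: float = 10_000.0,
    ppm_tol: float = 5.0,
    background_per_scan: int = 8,
) -> tuple[list[Run], pd.DataFrame]:
    """Simulate every run of a study plus the ground-truth apex table.

    Returns the runs (samples then blanks) and a DataFrame with one row
    per analyte x sample recording the sampled true apex height (0 where
    the analyte is absent).

    Scans alternate polarity on a staggered grid (positive scans on the
    grid, negative scans offset by half a step), emulating
    polarity-switching acquisition.
    """
    if grid <= 0 or grid > 2.0:
        raise ValueError("grid spacing must be in (0, 2] seconds")
    lo, hi = rt_span
    for t in truths:
        if not (lo <= t.entry.expected_rt <= hi):
            raise ValueError(
                f"expected RT of {t.entry.name!r} outside the run RT span"
            )
    _warn_coelution(truths, ppm_tol, fwhm)

    sigma = fwhm * FWHM_TO_SIGMA
    pos_times = np.arange(lo, hi, grid)
    neg_times = pos_times + grid / 2.0
    mz_values = [t.entry.theoretical_mz for t in truths]
    mz_range = (min(mz_values + [60.0]) - 10, max(mz_values + [1000.0]) + 10)

    runs: list[Run] = []
    truth_rows: list[dict] = []

    for sample_id, group, donor in design.sample_ids():
        rng = _run_rng(design.seed, sample_id)
        # per (run, analyte) peaks
        peaks = []  # (entry, apex_rt, apex_height, mz_obs_fn)
        for t in truths:
            level = t.level(group, design.control)
            if level <= 0:
                truth_rows.append(
                    dict(analyte=t.entry.name, sample_id=sample_id,
                         group=group, donor=donor, true_height=0.0)
                )
                continue
            if t.noise_cv > 0:
                sd = math.sqrt(math.log1p(t.noise_cv**2))
                noise = math.exp(rng.normal(-0.5 * sd**2, sd))
            else:
                noise = 1.0
            apex = level * noise
            rt_apex = t.entry.expected_rt + (
                rng.normal(0.0, t.rt_jitter_sd) if t.rt_jitter_sd > 0 else 0.0
            )
            # snap to the scan grid of the matching polarity so the sampled
            # maximum equals the recorded apex exactly
            times = pos_times if t.entry.polarity == "positive" else neg_times
            rt_apex = float(times[np.argmin(np.abs(times - rt_apex))])
            peaks.append((t, rt_apex, apex))
            truth_rows.append(
                dict(analyte=t.entry.name, sample_id=sample_id,
                     group=group, donor=donor, true_height=apex)
            )

        bg_pos = _background(rng, pos_times, floor, background_per_scan, mz_range)
        bg_neg = _background(rng, neg_times, floor, background_per_scan, mz_range)

        spectra: list[Spectrum] = []
        for polarity, times, bgs in (
            ("positive", pos_times, bg_pos),
            ("negative", neg_times, bg_neg),
        ):
            for time, (bg_mz, bg_int) in zip(times, bgs):
                mzs = [bg_mz]
                ints = [bg_int]
                for t, rt_apex, apex in peaks:
                    if t.entry.polarity != polarity:
                        continue
                    dt = time - rt_apex
                    if abs(dt) > 4.0 * sigma:
                        continue
                    h = apex * math.exp(-0.5 * (dt / sigma) ** 2)
                    if t.mz_jitter_ppm > 0:
                        mz_obs = t.entry.theoretical_mz * (
                            1.0 + rng.normal(0.0, t.mz_jitter_ppm) * 1e-6
                        )
                    else:
                        mz_obs = t.entry.theoretical_mz
                    mzs.append(np.array([mz_obs]))
                    ints.append(np.array([h]))
                spectra.append(
                    Spectrum(
                        rt=float(time),
                        polarity=polarity,
                        mz=np.concatenate(mzs),
                        intensity=np.concatenate(ints),
                    )
                )
        spectra.sort(key=lambda s: s.rt)
        runs.append(
            Run(sample_id=sample_id, spectra=spectra, role="sample",
                group=group, donor=donor)
        )

    for blank_id in design.blank_ids():
        rng = _run_rng(design.seed, blank_id)
        bg_pos = _background(rng, pos_times, floor, background_per_scan, mz_range)
        bg_neg = _background(rng, neg_times, floor, background_per_scan, mz_range)
        spectra = [
            Spectrum(rt=float(time), polarity=pol, mz=mz, intensity=inten)
            for pol, times, bgs in (
                ("positive", pos_times, bg_pos),
                ("negative", neg_times, bg_neg),
            )
            for time, (mz, inten) in zip(times, bgs)
        ]
        spectra.sort(key=lambda s: s.rt)
        runs.append(Run(sample_id=blank_id, spectra=spectra, role="blank"))

    truth = pd.DataFrame(truth_rows)
    return runs, truth
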