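"""Targeted peak-height extraction from centroided MS1 runs.

Extraction follows the two-stage targeting scheme used for the organoid
metabolome: for each library analyte, a study-wide consensus apex RT is
first located inside a wide search window (default +/- 30 s) around the
library retention time, then every run's peak height is taken as the
maximum centroid intensity within a narrow apex tolerance (default
+/- 7.5 s) of that consensus and a +/- 5 ppm m/z window. Peak height, not
area, is the quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
import pandas as pd

from enviromics.library import MetaboliteLibraryEntry
from enviromics.msio import Run, Spectrum

__all__ = [
    "ExtractionConfig",
    "PeakMeasurement",
    "IntensityMatrix",
    "Run",
    "Spectrum",
    "mz_window",
    "consensus_apex",
    "extract_peak",
    "build_matrix",
]


class PolarityMismatchError(ValueError):
    """Raised when a run has no scans matching an entry's polarity."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Tolerances for targeted extraction.

    ppm_tol:        relative m/z half-window, parts-per-million.
    apex_tol:       RT half-window (s) around the consensus apex.
    search_window:  RT half-window (s) around the library RT used to
                    locate the consensus apex across study samples.
    min_scans:      minimum number of scans with in-window signal for a
                    peak to count as found.
    """

    ppm_tol: float = 5.0
    apex_tol: float = 7.5
    search_window: float = 30.0
    min_scans: int = 1

    def __post_init__(self) -> None:
        if min(self.ppm_tol, self.apex_tol, self.search_window) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_scans < 1:
            raise ValueError("min_scans must be >= 1")
        if self.apex_tol > self.search_window:
            raise ValueError("apex_tol must not exceed search_window")


@dataclass(frozen=True)
class PeakMeasurement:
    """Result of extracting one analyte from one run."""

    analyte: str
    sample_id: str
    height: float
    apex_rt: float  # NaN when not found
    found: bool

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("height must be non-negative")
        if not self.found and self.height != 0:
            raise ValueError("not-found measurements must have zero height")


@dataclass
class IntensityMatrix:
    """Analyte x sample peak heights with run roles and metadata.

    ``heights`` has one row per library analyte and one column per run
    (blank columns included, flagged via ``roles``).
    """

    heights: pd.DataFrame
    roles: pd.Series  # 'sample' | 'blank' per column
    groups: pd.Series  # group label per column (blanks -> '')
    donors: pd.Series
    consensus_rt: pd.Series  # per-analyte consensus apex (NaN if absent)

    @property
    def blank_columns(self) -> list[str]:
        return [c for c in self.heights.columns if self.roles[c] == "blank"]

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.heights.columns if self.roles[c] == "sample"]


def mz_window(mz: float, ppm: float) -> tuple[float, float]:
    """Half-open m/z window [low, high) of +/- ``ppm`` around ``mz``."""
    if mz <= 0 or ppm <= 0:
        raise ValueError("m/z and ppm must be positive")
    return mz * (1.0 - ppm * 1e-6), mz * (1.0 + ppm * 1e-6)


def _scan_window_max(
    spectrum: Spectrum, low: float, high: float
) -> float:
    """Max intensity among centroids with m/z in [low, high); 0 if none."""
    i = np.searchsorted(spectrum.mz, low, side="left")
    j = np.searchsorted(spectrum.mz, high, side="left")
    if j <= i:
        return 0.0
    return float(spectrum.intensity[i:j].max())


def _run_apex(
    run: Run, entry: MetaboliteLibraryEntry, center: float, half: float, config: ExtractionConfig
) -> tuple[float, float, int]:
    """Best (apex_rt, height, n_signal_scans) inside the RT/mz window.

    Ties at equal maximum height resolve to the earliest RT. Returns
    height 0 when no in-window centroid exists.
    """
    low, high = mz_window(entry.theoretical_mz, config.ppm_tol)
    best_rt, best_h, n_signal = float("nan"), 0.0, 0
    for s in run.spectra:
        if s.polarity != entry.polarity:
            continue
        if abs(s.rt - center) > half:
            continue
        h = _scan_window_max(s, low, high)
        if h > 0:
            n_signal += 1
            if h > best_h:
                best_h, best_rt = h, s.rt
    return best_rt, best_h, n_signal


def consensus_apex(
    runs: list[Run], entry: MetaboliteLibraryEntry, config: ExtractionConfig
) -> float | None:
    """Median per-run apex RT across study samples, or None if absent.

    Only non-blank runs participate; runs without any in-window signal are
    skipped. ``None`` signals that the analyte was not seen anywhere.
    """
    study = [r for r in runs if r.role == "sample"]
    if not study:
        raise ValueError("consensus_apex requires at least one non-blank run")
    apexes = []
    for run in study:
        rt, h, _ = _run_apex(
            run, entry, entry.expected_rt, config.search_window, config
        )
        if h > 0:
            apexes.append(rt)
    if not apexes:
        return None
    return float(np.median(apexes))


def extract_peak(
    run: Run,
    entry: MetaboliteLibraryEntry,
    consensus: float,
    config: ExtractionConfig,
) -> PeakMeasurement:
    """Peak height for one analyte in one run at the consensus apex.

    Height is the maximum centroid intensity over scans within
    ``apex_tol`` of the consensus RT and inside the ppm window. Blanks are
    processed identically to samples.
    """
    if abs(consensus - entry.expected_rt) > config.search_window:
        raise ValueError(
            "consensus RT outside the library search window for "
            f"{entry.name!r}"
        )
    if not any(s.polarity == entry.polarity for s in run.spectra):
        raise PolarityMismatchError(
            f"run {run.sample_id!r} has no {entry.polarity} scans for "
            f"{entry.name!r}"
        )
    rt, h, n_signal = _run_apex(run, entry, consensus, config.apex_tol, config)
    found = h > 0 and n_signal >= config.min_scans
    if not found:
        return PeakMeasurement(entry.name, run.sample_id, 0.0, float("nan"), False)
    return PeakMeasurement(entry.name, run.sample_id, h, rt, True)


def build_matrix(
    runs: list[Run],
    library: list[MetaboliteLibraryEntry],
    config: ExtractionConfig | None = None,
) -> IntensityMatrix:
    """Quantify a whole study: one row per analyte, one column per run.

    Consensus apexes are located on the study samples; when an analyte is
    absent from every sample the library RT is used so blanks are still
    probed at a defined location.
    """
    config = config or ExtractionConfig()
    ids = [r.sample_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among runs")
    names = [e.name for e in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte name in library")

    heights = pd.DataFrame(0.0, index=names, columns=ids)
    consensus_rts = pd.Series(float("nan"), index=names, dtype=float)
    have_samples = any(r.role == "sample" for r in runs)
    for entry in library:
        consensus = (
            consensus_apex(runs, entry, config) if have_samples else None
        )
        if consensus is None:
            consensus = entry.expected_rt
        else:
            consensus_rts[entry.name] = consensus
        for run in runs:
            try:
                m = extract_peak(run, entry, consensus, config)
            except PolarityMismatchError:
                m = PeakMeasurement(
                    entry.name, run.sample_id, 0.0, float("nan"), False
                )
            heights.loc[entry.name, run.sample_id] = m.height

    roles = pd.Series({r.sample_id: r.role for r in runs})
    groups = pd.Series({r.sample_id: r.group or "" for r in runs})
    donors = pd.Series({r.sample_id: r.donor or "" for r in runs})
    return IntensityMatrix(heights, roles, groups, donors, consensus_rts)


def write_matrix(matrix: IntensityMatrix, heights_path, samples_path) -> None:
    """Write the heights TSV plus a sample sheet CSV (id, role, group, donor)."""
    matrix.heights.to_csv(heights_path, sep="\t", index_label="analyte")
    pd.DataFrame(
        {
            "sample_id": matrix.heights.columns,
            "role": [matrix.roles[c] for c in matrix.heights.columns],
            "group": [matrix.groups[c] for c in matrix.heights.columns],
            "donor": [matrix.donors[c] for c in matrix.heights.columns],
        }
    ).to_csv(samples_path, index=False)


def read_matrix(heights_path, samples_path) -> IntensityMatrix:
    heights = pd.read_csv(heights_path, sep="\t", index_col="analyte")
    sheet = pd.read_csv(samples_path, dtype=str).fillna("")
    sheet = sheet.set_index("sample_id")
    heights = heights[[c for c in heights.columns]]
    roles = sheet["role"].reindex(heights.columns)
    if roles.isna().any():
        raise ValueError("sample sheet does not cover every matrix column")
    return IntensityMatrix(
        heights=heights,
        roles=roles,
        groups=sheet["group"].reindex(heights.columns),
        donors=sheet["donor"].reindex(heights.columns),
        consensus_rt=pd.Series(float("nan"), index=heights.index),
    )
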