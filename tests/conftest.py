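import numpy as np
import pandas as pd
import pytest

from enviromics.design import StudyDesign
from enviromics.library import MetaboliteLibraryEntry
from enviromics.metabostats import CorrectedMatrix
from enviromics.msio import Run, Spectrum
from enviromics.quant import IntensityMatrix


@pytest.fixture
def small_design() -> StudyDesign:
    return StudyDesign(
        groups=("vehicle", "WIN", "ethanol"),
        donors_per_group=3,
        blanks=2,
        seed=11,
    )


@pytest.fixture
def phe_entry() -> MetaboliteLibraryEntry:
    return MetaboliteLibraryEntry(
        name="L-Phenylalanine",
        ion_type="[M+H]+",
        theoretical_mz=166.0863,
        polarity="positive",
        expected_rt=300.0,
    )


def make_run(
    sample_id: str,
    centroids: list[tuple[float, float, float]],
    polarity: str = "positive",
    rt_grid: tuple[float, float, float] = (270.0, 330.0, 2.0),
    role: str = "sample",
    group: str | None = None,
    donor: str | None = None,
) -> Run:
    """Build a run from (rt, mz, intensity) triples on a regular scan grid.

    Scans without a listed centroid get a single far-away background point
    so every scan is non-empty.
    """
    lo, hi, step = rt_grid
    by_rt: dict[float, list[tuple[float, float]]] = {}
    for rt, mz, inten in centroids:
        by_rt.setdefault(round(rt, 6), []).append((mz, inten))
    spectra = []
    for t in np.arange(lo, hi + step / 2, step):
        t = float(round(t, 6))
        points = by_rt.get(t, [(900.0, 1.0)])
        mz = np.array([p[0] for p in points])
        inten = np.array([p[1] for p in points])
        spectra.append(Spectrum(rt=t, polarity=polarity, mz=mz, intensity=inten))
    return Run(sample_id=sample_id, spectra=spectra, role=role, group=group,
               donor=donor)


def make_intensity_matrix(
    heights: pd.DataFrame,
    roles: dict[str, str],
    groups: dict[str, str] | None = None,
) -> IntensityMatrix:
    cols = list(heights.columns)
    groups = groups or {c: "" for c in cols}
    return IntensityMatrix(
        heights=heights,
        roles=pd.Series({c: roles[c] for c in cols}),
        groups=pd.Series({c: groups.get(c, "") for c in cols}),
        donors=pd.Series({c: "" for c in cols}),
        consensus_rt=pd.Series(np.nan, index=heights.index),
    )


def make_corrected(
    values: pd.DataFrame,
    detected: pd.DataFrame,
    thresholds: pd.Series,
    groups: dict[str, str],
) -> CorrectedMatrix:
    cols = list(values.columns)
    return CorrectedMatrix(
        values=values,
        detected=detected,
        thresholds=thresholds,
        groups=pd.Series({c: groups[c] for c in cols}),
        donors=pd.Series({c: "" for c in cols}),
    )
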