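"""Targeted metabolite library: analyte names, ion adducts, accurate masses
and expected retention times.

The default library covers the 18 polar metabolites reported as regulated
in the organoid study (amino acids, nucleotides, TCA/glycolysis
intermediates) with monoisotopic adduct masses and HILIC-scale retention
times. Retention times are nominal values for a ZIC-pHILIC-style gradient
and serve as the search anchors for extraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class MetaboliteLibraryEntry:
    """A targeted analyte: ion species, theoretical m/z and expected RT."""

    name: str
    ion_type: str
    theoretical_mz: float  # Thomsons
    polarity: str  # 'positive' | 'negative'
    expected_rt: float  # seconds

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical m/z must be positive")
        if self.expected_rt < 0:
            raise ValueError("expected RT must be non-negative")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown polarity {self.polarity!r}")


# name, ion_type, theoretical m/z (Th), polarity, expected RT (s)
_DEFAULT_ROWS = [
    ("3-Phosphoglyceric Acid", "[M-H]-", 184.9857, NEGATIVE, 430.0),
    ("Acetylcysteine", "[M-H]-", 162.0230, NEGATIVE, 150.0),
    ("Allantoin", "[M-H]-", 157.0367, NEGATIVE, 210.0),
    ("Creatinine", "[M+H]+", 114.0662, POSITIVE, 120.0),
    ("D-Ribose 5-Phosphate", "[M-H]-", 229.0119, NEGATIVE, 410.0),
    ("Guanosine Monophosphate", "[M-H]-", 362.0507, NEGATIVE, 440.0),
    ("Guanosine Triphosphate", "[M-H]-", 521.9834, NEGATIVE, 470.0),
    ("Inosine", "[M-H]-", 267.0735, NEGATIVE, 240.0),
    ("L-Leucine", "[M+H]+", 132.1019, POSITIVE, 170.0),
    ("L-Methionine", "[M+H]+", 150.0583, POSITIVE, 200.0),
    ("L-Phenylalanine", "[M+H]+", 166.0863, POSITIVE, 180.0),
    ("L-Tyrosine", "[M+H]+", 182.0812, POSITIVE, 230.0),
    ("L-Valine", "[M+H]+", 118.0863, POSITIVE, 260.0),
    ("N-Acetylglutamine", "[M-H]-", 187.0724, NEGATIVE, 280.0),
    ("N-Acetylornithine", "[M+H]+", 175.1077, POSITIVE, 300.0),
    ("Pyruvic Acid", "[M-H]-", 87.0088, NEGATIVE, 330.0),
    ("S-Adenosylhomocysteine", "[M+H]+", 385.1289, POSITIVE, 320.0),
    ("Succinic Acid", "[M-H]-", 117.0193, NEGATIVE, 360.0),
]


def default_library() -> list[MetaboliteLibraryEntry]:
    """The built-in 18-analyte targeted library."""
    return [MetaboliteLibraryEntry(*row) for row in _DEFAULT_ROWS]


def read_library(path: str | Path | io.IOBase) -> list[MetaboliteLibraryEntry]:
    """Read a library CSV with columns name, ion_type, mz, polarity, rt_seconds."""
    df = pd.read_csv(path)
    required = {"name", "ion_type", "mz", "polarity", "rt_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library CSV missing columns: {sorted(missing)}")
    return [
        MetaboliteLibraryEntry(
            name=str(r["name"]),
            ion_type=str(r["ion_type"]),
            theoretical_mz=float(r["mz"]),
            polarity=str(r["polarity"]),
            expected_rt=float(r["rt_seconds"]),
        )
        for _, r in df.iterrows()
    ]


def write_library(entries: list[MetaboliteLibraryEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "ion_type": [e.ion_type for e in entries],
            "mz": [e.theoretical_mz for e in entries],
            "polarity": [e.polarity for e in entries],
            "rt_seconds": [e.expected_rt for e in entries],
        }
    ).to_csv(path, index=False)
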