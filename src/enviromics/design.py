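"""Study design: treatment groups, donors and blank runs.

The design mirrors the paired layout of the organoid experiments: every
donor's iPSC-derived organoids are split across all treatment arms, so the
same donor labels recur in each group and donor is a blocking factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical treatment arms, vehicle control first.
DEFAULT_GROUPS = (
    "vehicle",
    "WIN",
    "IL17a",
    "cortisol",
    "nicotine",
    "ethanol",
    "endomorphin",
)


@dataclass(frozen=True)
class StudyDesign:
    """Treatment groups x donors layout with blank runs.

    Parameters
    ----------
    groups:
        Ordered group labels; the first entry is the vehicle control and
        must be named exactly once.
    donors_per_group:
        Number of donors; the same donor set appears in every group
        (paired design).
    blanks:
        Number of blank (extraction control) runs.
    seed:
        Base RNG seed for any synthetic data derived from this design.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    donors_per_group: int = 4
    blanks: int = 3
    seed: int = 0
    control: str = field(init=False)

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 2:
            raise ValueError("a design needs at least 2 groups")
        if len(set(groups)) != len(groups):
            raise ValueError("group labels must be unique")
        if "vehicle" not in groups:
            raise ValueError("the vehicle control group is required")
        if self.donors_per_group < 2:
            raise ValueError("need at least 2 donors per group")
        if self.blanks < 0:
            raise ValueError("blanks must be non-negative")
        object.__setattr__(self, "control", "vehicle")

    @property
    def donors(self) -> tuple[str, ...]:
        """Donor labels, identical across groups."""
        return tuple(f"donor{i + 1}" for i in range(self.donors_per_group))

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.donors_per_group

    def sample_ids(self) -> list[tuple[str, str, str]]:
        """All (sample_id, group, donor) triples, grouped by treatment."""
        return [
            (f"{g}_{d}", g, d) for g in self.groups for d in self.donors
        ]

    def blank_ids(self) -> list[str]:
        return [f"blank{i + 1}" for i in range(self.blanks)]
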