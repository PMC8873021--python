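"""Synthetic protein x sample intensity matrices with known group effects.

Intensities are log-normal around a per-protein base level, with additive
donor offsets (in log2) shared across groups — the paired-design signature
— and log2 group effects on a chosen subset of "affected" proteins.
Missing values are missing completely at random and written as empty
fields when serialized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from enviromics.design import StudyDesign


def gen_protein_matrix(
    design: StudyDesign,
    n_proteins: int = 1000,
    n_affected: int = 50,
    effect_sd: float = 0.5,
    noise_cv: float = 0.05,
    missing_rate: float = 0.01,
    donor_sd: float = 0.15,
    min_effect: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Simulate a TMT-style protein quantification matrix.

    Returns ``(matrix, groups, donors, truth)`` where ``matrix`` is
    proteins x samples on the linear scale with NaN for missing cells,
    ``groups``/``donors`` label the columns, and ``truth`` lists each
    affected (protein, group) pair with its signed log2 effect.

    Affected proteins receive a log2 shift drawn from a normal of scale
    ``effect_sd`` (magnitude floored at ``min_effect`` so every spiked
    effect is nominally detectable) in one or more non-control groups.
    """
    if n_affected > n_proteins:
        raise ValueError("n_affected cannot exceed n_proteins")
    if not (0 <= missing_rate < 0.5):
        raise ValueError("missing_rate must lie in [0, 0.5)")
    rng = np.random.default_rng([design.seed, 7])

    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    triples = design.sample_ids()
    columns = [sid for sid, _, _ in triples]
    groups = pd.Series({sid: g for sid, g, _ in triples})
    donors = pd.Series({sid: d for sid, _, d in triples})

    base_log2 = rng.normal(20.0, 2.0, size=n_proteins)
    donor_offsets = {
        d: rng.normal(0.0, donor_sd, size=n_proteins) for d in design.donors
    }

    treated = [g for g in design.groups if g != design.control]
    affected_idx = rng.choice(n_proteins, size=n_affected, replace=False)
    effect_map = np.zeros((n_proteins, len(design.groups)))
    truth_rows = []
    for idx in affected_idx:
        # each affected protein is shifted in 1-3 treated groups
        k = int(rng.integers(1, min(3, len(treated)) + 1))
        hit = rng.choice(len(treated), size=k, replace=False)
        for h in hit:
            eff = rng.normal(0.0, effect_sd)
            eff = float(np.sign(eff) if eff != 0 else 1.0) * max(
                abs(eff), min_effect
            )
            g = treated[h]
            effect_map[idx, design.groups.index(g)] = eff
            truth_rows.append(
                dict(protein=proteins[idx], group=g, log2_effect=eff,
                     sign=int(np.sign(eff)))
            )

    log2_noise_sd = np.sqrt(np.log1p(noise_cv**2)) / np.log(2)
    data = np.empty((n_proteins, len(columns)))
    for j, (sid, g, d) in enumerate(triples):
        gi = design.groups.index(g)
        mean_log2 = base_log2 + donor_offsets[d] + effect_map[:, gi]
        data[:, j] = mean_log2 + rng.normal(0.0, log2_noise_sd, size=n_proteins)
    matrix = pd.DataFrame(2.0**data, index=proteins, columns=columns)

    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        matrix = matrix.mask(mask)

    truth = pd.DataFrame(
        truth_rows, columns=["protein", "group", "log2_effect", "sign"]
    )
    return matrix, groups, donors, truth


def write_protein_matrix(matrix: pd.DataFrame, groups: pd.Series,
                         donors: pd.Series, matrix_path, samples_path) -> None:
    """Write the matrix TSV (missing cells as empty fields) + sample sheet."""
    matrix.to_csv(matrix_path, sep="\t", index_label="accession", na_rep="")
    pd.DataFrame(
        {"sample_id": matrix.columns,
         "group": [groups[c] for c in matrix.columns],
         "donor": [donors[c] for c in matrix.columns]}
    ).to_csv(samples_path, index=False)
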