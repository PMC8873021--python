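"""Synthetic flow-cytometry event clouds.

Two generators: univariate DNA-content events with sub-G1/G1/S/G2-M
structure (propidium-iodide style histograms), and bivariate cleaved-PARP
x phospho-H2AX event tables with four well-separated log-normal clusters
for quadrant gating. Event tables are plain arrays/CSV, not FCS — the
gating logic is format-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CytometryTruth:
    """Ground truth for one simulated cytometry sample.

    fractions:       (sub_g1, g1, s, g2m) DNA-content proportions.
    dna_cv:          coefficient of variation of the G1 peak.
    n_events:        events per sample.
    quadrant_probs:  (double_neg, parp_only, double_pos, h2ax_only)
                     membership probabilities for the damage panel.
    """

    fractions: tuple[float, float, float, float]
    dna_cv: float = 0.05
    n_events: int = 20_000
    quadrant_probs: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("DNA-content fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.quadrant_probs) - 1.0) > 1e-9:
            raise ValueError("quadrant probabilities must sum to 1")
        if any(p < 0 for p in self.quadrant_probs):
            raise ValueError("quadrant probabilities must be non-negative")
        if self.n_events < 1000:
            raise ValueError("need at least 1000 events")
        if self.dna_cv <= 0:
            raise ValueError("dna_cv must be positive")


def gen_dna_content_events(
    truth: CytometryTruth,
    g1_mean: float = 100.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate DNA-content channel values for one sample.

    G1 events ~ N(g1_mean, cv*g1_mean); G2/M ~ N(2*g1_mean, cv*2*g1_mean);
    S is uniform on (g1_mean, 2*g1_mean) convolved with the G1-width
    Gaussian; sub-G1 is uniform on (0.2*g1_mean, g1_mean - 3*cv*g1_mean).
    Realized class sizes are multinomial around the truth fractions.
    """
    if g1_mean <= 0:
        raise ValueError("g1_mean must be positive")
    cv = truth.dna_cv
    sub_hi = g1_mean * (1.0 - 3.0 * cv)
    if sub_hi <= 0.2 * g1_mean:
        raise ValueError(
            "dna_cv too large: no room for a sub-G1 band below the G1 peak"
        )
    rng = np.random.default_rng(rng)
    counts = rng.multinomial(truth.n_events, truth.fractions)
    n_sub, n_g1, n_s, n_g2 = (int(c) for c in counts)
    sigma1 = cv * g1_mean
    parts = [
        rng.uniform(0.2 * g1_mean, sub_hi, size=n_sub),
        rng.normal(g1_mean, sigma1, size=n_g1),
        rng.uniform(g1_mean, 2.0 * g1_mean, size=n_s)
        + rng.normal(0.0, sigma1, size=n_s),
        rng.normal(2.0 * g1_mean, 2.0 * sigma1, size=n_g2),
    ]
    events = np.concatenate(parts)
    events = np.clip(events, 1e-6, None)  # channel values stay positive
    rng.shuffle(events)
    return events


def gen_damage_events(
    truth: CytometryTruth,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
    negative_center: float = 10.0,
    positive_center: float = 1000.0,
    log10_sd: float = 0.2,
) -> pd.DataFrame:
    """Simulate a two-channel (PARP, pH2AX) event table.

    Four bivariate log-normal clusters — double-negative, PARP+ only,
    double-positive, pH2AX+ only — with multinomial membership at
    ``truth.quadrant_probs``. Negative and positive cluster centres sit
    two decades apart with sd 0.2 decades, so any threshold between them
    is >= 3 cluster SDs from both and the gating ground truth is
    unambiguous.
    """
    n = truth.n_events if n is None else int(n)
    if n < 1000:
        raise ValueError("need at least 1000 events")
    rng = np.random.default_rng(rng)
    counts = rng.multinomial(n, truth.quadrant_probs)
    lo, hi = np.log10(negative_center), np.log10(positive_center)
    centers = [  # (PARP decade, pH2AX decade)
        (lo, lo),  # double negative
        (hi, lo),  # PARP+ only
        (hi, hi),  # double positive
        (lo, hi),  # pH2AX+ only
    ]
    parp, h2ax, label = [], [], []
    names = ["double_neg", "parp_only", "double_pos", "h2ax_only"]
    for (cx, cy), k, name in zip(centers, counts, names):
        parp.append(10.0 ** rng.normal(cx, log10_sd, size=k))
        h2ax.append(10.0 ** rng.normal(cy, log10_sd, size=k))
        label.extend([name] * k)
    df = pd.DataFrame(
        {
            "parp": np.concatenate(parp),
            "h2ax": np.concatenate(h2ax),
            "true_quadrant": label,
        }
    )
    return df.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).reset_index(drop=True)


def gen_unstained_events(
    n: int = 10_000,
    rng: np.random.Generator | int | None = None,
    negative_center: float = 10.0,
    log10_sd: float = 0.2,
) -> pd.DataFrame:
    """Unstained (background-only) two-channel sample for threshold derivation."""
    rng = np.random.default_rng(rng)
    lo = np.log10(negative_center)
    return pd.DataFrame(
        {
            "parp": 10.0 ** rng.normal(lo, log10_sd, size=n),
            "h2ax": 10.0 ** rng.normal(lo, log10_sd, size=n),
        }
    )
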