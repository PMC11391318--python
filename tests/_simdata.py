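"""Simulated dyad tables with known fixed-effect structure."""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_dyad_table(
    n_ind: int = 12,
    seed: int = 0,
    beta_contact: float = -0.4,
    beta_genetic: float = -0.5,
    beta_weight: float = 0.3,
    beta_time: float = 0.01,
    beta_interaction: float = 0.0,
    interaction: str = "genetic_relatedness:social_contact",
    sd_individual: float = 0.08,
    sd_noise: float = 0.08,
) -> pd.DataFrame:
    """Directed dyad rows generated from a known (mostly main-effects) model.

    Predictors mimic the real score scales: genetic in [0, 0.5], contact and
    weight in [0, 1] (contact mostly zero), time difference antisymmetric in
    years.  The response adds random intercepts for both dyad members plus
    i.i.d. noise.
    """
    rng = np.random.default_rng(seed)
    ids = [f"i{k:02d}" for k in range(n_ind)]
    gen = np.zeros((n_ind, n_ind))
    con = np.zeros((n_ind, n_ind))
    wgt = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            gen[i, j] = gen[j, i] = rng.choice([0.0, 0.125, 0.25], p=[0.6, 0.2, 0.2])
            con[i, j] = con[j, i] = rng.choice([0.0, rng.uniform(0.1, 1.0)], p=[0.5, 0.5])
            wgt[i, j] = wgt[j, i] = rng.uniform(0.0, 1.0)
    years = rng.integers(0, 10, size=n_ind)
    u1 = rng.normal(scale=sd_individual, size=n_ind)
    u2 = rng.normal(scale=sd_individual, size=n_ind)
    rows = []
    parts = {p: k for k, p in enumerate(
        ["genetic_relatedness", "social_contact", "body_weight", "time_difference"]
    )}
    for i in range(n_ind):
        for j in range(n_ind):
            if i == j:
                continue
            x = {
                "genetic_relatedness": gen[i, j],
                "social_contact": con[i, j],
                "body_weight": wgt[i, j],
                "time_difference": float(years[i] - years[j]),
            }
            y = (
                0.5
                + beta_genetic * x["genetic_relatedness"]
                + beta_contact * x["social_contact"]
                + beta_weight * x["body_weight"]
                + beta_time * x["time_difference"]
                + u1[i]
                + u2[j]
                + rng.normal(scale=sd_noise)
            )
            if beta_interaction != 0.0:
                y += beta_interaction * np.prod(
                    [x[p] for p in interaction.split(":")]
                )
            rows.append(
                {
                    "individual1": ids[i],
                    "individual2": ids[j],
                    "sex": None,
                    "acoustic_dissimilarity": y,
                    "dyad_relationship": None,
                    **x,
                }
            )
    return pd.DataFrame(rows)
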