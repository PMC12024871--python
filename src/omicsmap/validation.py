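"""Recovery experiments: the simulator as an embedding-validation oracle.

These harnesses generate PS networks with known ground-truth coordinates,
run the embedder, and measure how well the angular (similarity) dimension is
recovered.  They are used both by the test suite and by the acceptance
script, so the experiment definition lives in the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .embedding import (EmbedConfig, circular_correlation, estimate_gamma,
                        hm_refine, labne_embed, log_likelihood)
from .network import largest_connected_component
from .simulate import PSParams, simulate_ps_network

# the windowed-search configuration used for recovery experiments: a quarter
# circle around the LaBNE angle at 90 candidates (~1 degree resolution)
RECOVERY_WINDOW = np.pi / 4
RECOVERY_GRID = 90


def angular_recovery_experiment(n: int = 1000, m: int = 4, gamma: float = 2.5,
                                temperature: float = 0.1, seeds=(0, 1, 2, 3, 4),
                                refine: bool = True,
                                window: float = RECOVERY_WINDOW,
                                grid: int = RECOVERY_GRID,
                                max_sweeps: int = 3) -> pd.DataFrame:
    """Embed PS networks and correlate inferred with true angles.

    For each seed: simulate, reduce to the largest connected component, run
    LaBNE (and optionally HM refinement) with the generation parameters, and
    report the absolute Fisher-Lee circular correlation between inferred and
    planted angles plus the PS log-likelihood before/after refinement.
    """
    rows = []
    for seed in seeds:
        params = PSParams(n=n, m=m, gamma=gamma, temperature=temperature,
                          seed=int(seed))
        net, truth = simulate_ps_network(params)
        lcc = largest_connected_component(net)
        config = EmbedConfig(gamma=gamma, temperature=max(temperature, 0.1),
                             window=window, grid=grid, max_sweeps=max_sweeps,
                             seed=int(seed))
        coords = labne_embed(lcc, config)
        true_theta = truth.set_index("id").loc[coords.ids, "theta"].to_numpy()
        row = {
            "seed": int(seed),
            "n_lcc": lcc.n_nodes,
            "labne_corr": abs(circular_correlation(coords.theta, true_theta)),
            "labne_ll": log_likelihood(lcc, coords, config),
        }
        if refine:
            refined = hm_refine(lcc, coords, config)
            row["refined_corr"] = abs(
                circular_correlation(refined.theta, true_theta))
            row["refined_ll"] = log_likelihood(lcc, refined, config)
        rows.append(row)
    return pd.DataFrame(rows)


def pareto_degrees(gamma: float, n: int, seed: int) -> np.ndarray:
    """Inverse-CDF sample from a pure Pareto tail with exponent gamma."""
    rng = np.random.default_rng(seed)
    return (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))


def gamma_recovery_experiment(gamma: float = 2.98, n: int = 10_000,
                              seeds=range(10)) -> list:
    """Fit the degree exponent on planted Pareto samples."""
    return [estimate_gamma(pareto_degrees(gamma, n, int(s))) for s in seeds]
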