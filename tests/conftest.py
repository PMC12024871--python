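import numpy as np
import pandas as pd
import pytest

from omicsmap import HyperbolicCoords, PSParams, make_toy_multiomics


@pytest.fixture(scope="session")
def toy_net_truth():
    """Small three-layer PS network with ground-truth coordinates."""
    params = PSParams(n=120, m=3, gamma=2.5, temperature=0.1, seed=11)
    return make_toy_multiomics(params, n_lipids=12, n_metabolites=8, seed=5)


@pytest.fixture(scope="session")
def toy_coords(toy_net_truth):
    """Ground-truth coordinate table of the toy network as HyperbolicCoords."""
    _, truth = toy_net_truth
    df = truth.rename(columns={"t": "birth"})
    df = df[["id", "r", "theta"]].copy()
    from omicsmap import infer_layer
    df["layer"] = [infer_layer(i) for i in df["id"]]
    return HyperbolicCoords(df)


@pytest.fixture()
def random_coords():
    """200 random protein/lipid/metabolite coordinates, fixed seed."""
    rng = np.random.default_rng(42)
    n_p, n_l, n_m = 150, 30, 20
    ids = ([f"Q{i:05d}" for i in range(n_p)]
           + [f"SLM:{i:09d}" for i in range(1, n_l + 1)]
           + [f"Pubchem:{i}" for i in range(1, n_m + 1)])
    layers = ["protein"] * n_p + ["lipid"] * n_l + ["metabolite"] * n_m
    df = pd.DataFrame({
        "id": ids,
        "layer": layers,
        "r": rng.uniform(0.0, 12.0, len(ids)),
        "theta": rng.uniform(0.0, 2 * np.pi, len(ids)),
    })
    return HyperbolicCoords(df)
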