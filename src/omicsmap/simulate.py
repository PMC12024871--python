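"""Popularity-similarity (PS) model simulator.

Generates synthetic networks with known ground-truth hyperbolic coordinates.
Node t is born at radius r_t = 2 ln t with a uniform angle; earlier nodes
drift outward as r_s(t) = beta * 2 ln s + (1 - beta) * 2 ln t, with
beta = 1/(gamma - 1).  At temperature T = 0 each newcomer links to its m
hyperbolically closest predecessors; at T > 0 it links to each predecessor
with the Fermi-Dirac probability p(x) = 1 / (1 + exp((x - R_t)/(2T))), where
the cutoff R_t is calibrated so the expected number of new links is m.  The
resulting degree distribution follows a power law with exponent gamma, and T
controls clustering (T -> 1 destroys the angular structure).

The simulator doubles as the fixture generator: :func:`make_toy_multiomics`
attaches lipid and metabolite nodes to the simulated protein layer with
hyperbolic-distance-decaying probability around a random anchor angle, so the
cross-layer nodes inherit the angular locality observed in the real map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import TWO_PI
from .network import Edge, MultiOmicsNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSParams:
    """Parameters of the PS generative model.

    n: final node count; m: target links added per newcomer; gamma: degree
    exponent (> 2); temperature: T in [0, 1); seed: RNG seed.
    """

    n: int
    m: int
    gamma: float = 2.5
    temperature: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 2:
            raise ValueError("gamma must be > 2")
        if not 0.0 <= self.temperature:
            raise ValueError("temperature must be >= 0")
        if self.temperature >= 1.0:
            raise ValueError("temperature >= 1 is not supported by the PS model")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n <= self.m:
            raise ValueError("n must exceed m")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gamma - 1.0)


def _hyperbolic_distance_arrays(r1, t1, r2, t2):
    dtheta = np.pi - np.abs(np.pi - np.abs(t1 - t2))
    arg = np.cosh(r1 - r2) + 2.0 * np.sinh(r1) * np.sinh(r2) * np.sin(dtheta / 2.0) ** 2
    return np.arccosh(np.maximum(arg, 1.0))


def ps_cutoff(t: int, m: int, beta: float, temperature: float) -> float:
    """Connection-radius cutoff R_t giving an expected m links for node t."""
    T = temperature
    numer = 2.0 * T * (1.0 - np.exp(-(1.0 - beta) * np.log(t)))
    denom = np.sin(T * np.pi) * m * (1.0 - beta)
    return 2.0 * np.log(t) - 2.0 * np.log(numer / denom)


def _node_ids(n: int):
    width = len(str(n))
    return [f"P{t:0{width}d}" for t in range(1, n + 1)]


def simulate_ps_network(params: PSParams):
    """Grow a PS network; returns (network, ground-truth table).

    The ground truth has one row per node: birth index ``t``, the angular
    coordinate ``theta`` and the final-snapshot radial coordinate ``r``
    (after outward drift, r_t(N) = 2*beta*ln t + 2*(1-beta)*ln N).
    """
    rng = np.random.default_rng(params.seed)
    n, m, beta, T = params.n, params.m, params.beta, params.temperature
    thetas = rng.uniform(0.0, TWO_PI, size=n)
    ids = _node_ids(n)
    edges: list = []

    ts = np.arange(1, n + 1, dtype=float)
    for t in range(2, n + 1):
        i = t - 1  # 0-based index of the newcomer
        # radii of existing nodes at the time node t arrives
        r_existing = 2.0 * beta * np.log(ts[:i]) + 2.0 * (1.0 - beta) * np.log(t)
        r_new = 2.0 * np.log(t)
        d = _hyperbolic_distance_arrays(r_existing, thetas[:i], r_new, thetas[i])
        if t <= m + 1:
            targets = np.arange(i)
        elif T == 0.0:
            # m hyperbolically closest predecessors; ties to the earlier node
            order = np.lexsort((np.arange(i), d))
            targets = order[:m]
        else:
            R_t = ps_cutoff(t, m, beta, T)
            p = 1.0 / (1.0 + np.exp((d - R_t) / (2.0 * T)))
            targets = np.flatnonzero(rng.random(i) < p)
        for s in targets:
            edges.append((int(s), i))

    net = MultiOmicsNetwork()
    for node_id in ids:
        net.add_node(node_id, layer="protein")
    for s, i in edges:
        net.add_edge(Edge(ids[s], ids[i], kinds=("ppi",), confidence=1.0))

    r_final = 2.0 * beta * np.log(ts) + 2.0 * (1.0 - beta) * np.log(n)
    truth = pd.DataFrame({"id": ids, "t": np.arange(1, n + 1),
                          "r": r_final, "theta": thetas})
    logger.info("simulate_ps_network: N=%d m=%d gamma=%.3g T=%.3g -> %d edges",
                n, m, params.gamma, T, net.n_edges)
    return net, truth


def make_toy_multiomics(params: PSParams, n_lipids: int, n_metabolites: int,
                        seed: int = 0):
    """Simulated three-layer network with ground-truth geometry.

    A PS protein network is generated (and reduced to its largest connected
    component, as the assembly pipeline would); each lipid/metabolite is then
    anchored at a random angle on the disk rim and attached to 1-3 proteins
    drawn with probability exp(-d/2) in the hyperbolic distance d from the
    anchor, giving cross-layer nodes the angular locality of the real map.

    Returns (network, truth) where truth lists every node's coordinates;
    cross-layer nodes carry their anchor position and a birth index of -1.
    """
    if n_lipids < 0 or n_metabolites < 0:
        raise ValueError("cross-layer node counts must be >= 0")
    net, truth = simulate_ps_network(params)
    if not nx.is_connected(net.graph):
        comps = [sorted(c) for c in nx.connected_components(net.graph)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        keep = comps[0]
        net = MultiOmicsNetwork(net.graph.subgraph(keep).copy())
        truth = truth[truth["id"].isin(keep)].reset_index(drop=True)
        logger.info("make_toy_multiomics: protein layer reduced to LCC of %d nodes",
                    len(keep))

    rng = np.random.default_rng(seed)
    prot_ids = truth["id"].to_numpy()
    prot_r = truth["r"].to_numpy()
    prot_theta = truth["theta"].to_numpy()
    rim = 2.0 * np.log(params.n)

    rows = []
    specs = ([("SLM:%09d" % (i + 1), "lipid") for i in range(n_lipids)]
             + [("Pubchem:%d" % (i + 1), "metabolite") for i in range(n_metabolites)])
    for node_id, layer in specs:
        anchor = rng.uniform(0.0, TWO_PI)
        d = _hyperbolic_distance_arrays(prot_r, prot_theta, rim, anchor)
        w = np.exp(-d / 2.0)
        w /= w.sum()
        k = int(rng.integers(1, 4))
        k = min(k, len(prot_ids))
        chosen = rng.choice(len(prot_ids), size=k, replace=False, p=w)
        net.add_node(node_id, layer=layer)
        for c in chosen:
            net.add_edge(Edge(prot_ids[c], node_id, kinds=("enzymatic",),
                              b_layer=layer))
        rows.append({"id": node_id, "t": -1, "r": rim, "theta": anchor})

    if rows:
        truth = pd.concat([truth, pd.DataFrame(rows)], ignore_index=True)
    return net, truth
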