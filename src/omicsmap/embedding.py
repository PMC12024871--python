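"""Hyperbolic embedding: LaBNE initialization + HyperMap-style refinement.

LaBNE (Laplacian-based network embedding) obtains angular coordinates from
the first two non-trivial eigenvectors of the symmetric normalized graph
Laplacian and radial coordinates from the degree ranking,

    r_i = 2*beta*ln i + 2*(1 - beta)*ln N,   beta = 1/(gamma - 1),

where i is the node's rank by decreasing degree.  The HyperMap (HM) stage
then sweeps the nodes in increasing-radius order (i.e. replaying the
popularity ordering) and moves each node's angle to the maximizer of its
local log-likelihood under the PS connection probability

    p(x) = 1 / (1 + exp((x - R)/(2T))),

searched on a grid of candidate angles inside a window w centered on the
current angle.  The current angle is always among the candidates, so the
total log-likelihood never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from ._util import TWO_PI, canonical_angle
from .coords import HyperbolicCoords, read_coords, write_coords  # noqa: F401
from .geometry import pairwise_distances
from .network import MultiOmicsNetwork
from .simulate import ps_cutoff

logger = logging.getLogger(__name__)

_DENSE_EIG_LIMIT = 2000


@dataclass
class EmbedConfig:
    """Embedding parameters.

    gamma: assumed degree exponent (> 2); temperature: PS temperature used in
    the likelihood (must be > 0 for refinement); window: angular search
    window w in radians (2*pi = full circle); grid: candidate angles per node
    per sweep; m / cutoff_R: PS calibration overrides (estimated from the
    mean degree / computed from (m, gamma, T, N) when None); max_sweeps and
    ll_tol control refinement convergence.
    """

    gamma: float = 2.98
    temperature: float = 0.84
    window: float = TWO_PI
    grid: int = 360
    eig_tol: float = 1e-10
    seed: int = 0
    m: Optional[int] = None
    cutoff_R: Optional[float] = None
    max_sweeps: int = 3
    ll_tol: float = 1e-6

    def __post_init__(self):
        if self.gamma <= 2:
            raise ValueError("gamma must be > 2")
        if not 0.0 < self.window <= TWO_PI:
            raise ValueError("window must be in (0, 2*pi]")
        if self.grid < 1:
            raise ValueError("grid must be >= 1")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gamma - 1.0)


# ---------------------------------------------------------------------------
# degree-exponent estimation


def estimate_gamma(degrees) -> float:
    """Continuous maximum-likelihood power-law exponent of a degree sequence.

    Uses the Hill/MLE estimator alpha = 1 + n / sum(ln(k/k_min)) with k_min
    selected by minimizing the Kolmogorov-Smirnov distance between the
    empirical tail and the fitted Pareto CDF.  The estimate is clipped to
    (2, 4], the range in which the PS radial rule is meaningful.
    """
    x = np.sort(np.asarray(degrees, dtype=float))
    if len(x) < 50:
        raise ValueError("need at least 50 degrees to fit an exponent")
    if np.any(x <= 0):
        raise ValueError("degrees must be positive")
    if x[0] == x[-1]:
        raise ValueError("degenerate (constant) degree sequence")

    candidates = np.unique(x)[:-1]  # need a non-empty strict tail
    best = (np.inf, None)
    for kmin in candidates:
        tail = x[x >= kmin]
        n = len(tail)
        if n < 10:
            break
        denom = np.sum(np.log(tail / kmin))
        if denom <= 0:
            continue
        alpha = 1.0 + n / denom
        # KS distance: empirical vs fitted Pareto CDF on the tail
        cdf = 1.0 - (tail / kmin) ** (1.0 - alpha)
        emp = np.arange(1, n + 1) / n
        ks = np.max(np.abs(cdf - emp))
        if ks < best[0]:
            best = (ks, alpha)
    if best[1] is None:
        raise ValueError("could not fit a power-law tail")
    return float(np.clip(best[1], 2.0 + 1e-9, 4.0))


# ---------------------------------------------------------------------------
# LaBNE


def _sorted_nodes_by_degree(graph: nx.Graph):
    # rank 1 = highest degree; ties by node id for determinism
    return sorted(graph.nodes, key=lambda n: (-graph.degree(n), n))


def labne_embed(net: MultiOmicsNetwork, config: EmbedConfig) -> HyperbolicCoords:
    """Laplacian-eigenmap angles + degree-rank radii.

    Angles come from atan2 over the two eigenvectors of the symmetric
    normalized Laplacian with the smallest non-zero eigenvalues.  Eigenvector
    signs are fixed so that each eigenvector's first non-zero entry, in
    lexicographic node-id order, is positive; this pins the otherwise
    arbitrary rotation/reflection gauge.
    """
    graph = net.graph
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("need at least 3 nodes to embed")
    if not nx.is_connected(graph):
        raise ValueError("network is disconnected; extract the largest "
                         "connected component first")
    node_order = sorted(graph.nodes)
    A = nx.to_scipy_sparse_array(graph, nodelist=node_order, format="csr",
                                 dtype=float, weight=None)
    deg = np.asarray(A.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    L = scipy.sparse.identity(n, format="csr") - \
        scipy.sparse.diags(d_isqrt) @ A @ scipy.sparse.diags(d_isqrt)

    if n <= _DENSE_EIG_LIMIT:
        vals, vecs = scipy.linalg.eigh(L.toarray())
    else:
        rng = np.random.default_rng(config.seed)
        v0 = rng.standard_normal(n)
        vals, vecs = scipy.sparse.linalg.eigsh(L, k=3, which="SA",
                                               v0=v0, tol=config.eig_tol)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    v1, v2 = vecs[:, 1].copy(), vecs[:, 2].copy()
    for v in (v1, v2):
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if len(nz) and v[nz[0]] < 0:
            v *= -1.0
    theta = canonical_angle(np.arctan2(v2, v1))

    beta = config.beta
    ranked = _sorted_nodes_by_degree(graph)
    radius = {node: 2.0 * beta * np.log(i) + 2.0 * (1.0 - beta) * np.log(n)
              for i, node in enumerate(ranked, start=1)}

    df = pd.DataFrame({
        "id": node_order,
        "layer": [graph.nodes[v]["layer"] for v in node_order],
        "r": [radius[v] for v in node_order],
        "theta": theta,
    })
    return HyperbolicCoords(df)


# ---------------------------------------------------------------------------
# PS likelihood


def connection_probability(x, R: float, T: float):
    """Fermi-Dirac PS connection probability; strictly decreasing in x."""
    if T <= 0:
        raise ValueError("connection probability requires T > 0; "
                         "use the deterministic closest-m rule at T = 0")
    u = (np.asarray(x, float) - R) / (2.0 * T)
    # exp overflows harmlessly to inf for very distant pairs (p -> 0)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(u))
    if out.ndim == 0:
        return float(out)
    return out


def _calibration(net: MultiOmicsNetwork, config: EmbedConfig):
    n = net.n_nodes
    if config.m is not None:
        m = config.m
    else:
        mean_deg = 2.0 * net.n_edges / n
        m = max(1, int(round(mean_deg / 2.0)))
    if config.cutoff_R is not None:
        R = config.cutoff_R
    else:
        R = ps_cutoff(n, m, config.beta, config.temperature)
    return m, R


_CLAMP = 1e-12


def log_likelihood(net: MultiOmicsNetwork, coords: HyperbolicCoords,
                   config: EmbedConfig) -> float:
    """PS log-likelihood of the observed adjacency given the coordinates.

    Sum over unordered node pairs of a_ij ln p(x_ij) + (1-a_ij) ln(1-p(x_ij))
    with p the Fermi-Dirac connection probability at the final-snapshot
    cutoff R; probabilities are clamped away from {0, 1}.
    """
    node_order = sorted(net.graph.nodes)
    missing = [v for v in node_order if v not in coords]
    if missing:
        raise ValueError(f"coordinates missing for nodes (e.g. {missing[:5]})")
    sub = coords.subset(node_order)
    _, R = _calibration(net, config)
    x = pairwise_distances(sub.r, sub.theta, sub.r, sub.theta)
    p = np.clip(connection_probability(x, R, config.temperature),
                _CLAMP, 1.0 - _CLAMP)
    A = nx.to_numpy_array(net.graph, nodelist=node_order, weight=None)
    ll = A * np.log(p) + (1.0 - A) * np.log(1.0 - p)
    iu = np.triu_indices(len(node_order), k=1)
    return float(ll[iu].sum())


# ---------------------------------------------------------------------------
# HyperMap refinement


def hm_refine(net: MultiOmicsNetwork, coords: HyperbolicCoords,
              config: EmbedConfig) -> HyperbolicCoords:
    """Likelihood refinement of the angular coordinates; radii unchanged.

    Nodes are visited in increasing-radius order (ties by id).  Each node's
    angle moves to the best of ``grid`` evenly spaced candidates inside the
    window centered on its current angle, plus the current angle itself, so
    every move is a non-strict improvement of the total log-likelihood.
    Sweeps repeat (updated angles feed into later visits) until the relative
    likelihood gain falls below ``ll_tol`` or ``max_sweeps`` is reached.
    """
    if config.temperature <= 0:
        raise ValueError("refinement requires temperature > 0")
    node_order = sorted(net.graph.nodes)
    sub = coords.subset(node_order)
    n = len(node_order)
    r = sub.r.copy()
    theta = sub.theta.copy()
    A = nx.to_numpy_array(net.graph, nodelist=node_order, weight=None).astype(bool)
    _, R = _calibration(net, config)
    T = config.temperature

    cosh_r, sinh_r = np.cosh(r), np.sinh(r)
    if config.grid == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-config.window / 2.0, config.window / 2.0,
                              config.grid, endpoint=config.window < TWO_PI)

    visit = sorted(range(n), key=lambda k: (r[k], node_order[k]))

    def total_ll():
        x = pairwise_distances(r, theta, r, theta)
        p = np.clip(connection_probability(x, R, T), _CLAMP, 1.0 - _CLAMP)
        ll = np.where(A, np.log(p), np.log(1.0 - p))
        iu = np.triu_indices(n, k=1)
        return float(ll[iu].sum())

    ll_prev = total_ll()
    for sweep in range(config.max_sweeps):
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        for k in visit:
            cand = np.concatenate([theta[k] + offsets, [theta[k]]])
            cos_c, sin_c = np.cos(cand), np.sin(cand)
            # cos(dtheta) between candidates and all nodes via outer products;
            # stable law-of-cosines rearrangement as in geometry
            cos_d = np.outer(cos_c, cos_t) + np.outer(sin_c, sin_t)
            arg = np.cosh(r[k] - r) + sinh_r[k] * sinh_r[None, :] * (1.0 - cos_d)
            x = np.arccosh(np.maximum(arg, 1.0))
            u = (x - R) / (2.0 * T)
            # a=1: ln p = -softplus(u); a=0: ln(1-p) = u - softplus(u)
            contrib = -np.logaddexp(0.0, u) + np.where(A[k][None, :], 0.0, u)
            contrib[:, k] = 0.0  # exclude self
            local = contrib.sum(axis=1)
            best = int(np.argmax(local))
            new_theta = canonical_angle(float(cand[best]))
            theta[k] = new_theta
            cos_t[k], sin_t[k] = np.cos(new_theta), np.sin(new_theta)
        ll_now = total_ll()
        gain = ll_now - ll_prev
        logger.info("hm_refine sweep %d: log-likelihood %.6f (gain %.3g)",
                    sweep + 1, ll_now, gain)
        if abs(gain) <= config.ll_tol * max(1.0, abs(ll_prev)):
            ll_prev = ll_now
            break
        ll_prev = ll_now

    df = pd.DataFrame({"id": node_order,
                       "layer": sub.layers,
                       "r": r, "theta": theta})
    return HyperbolicCoords(df)


# ---------------------------------------------------------------------------
# diagnostics


def circular_correlation(a, b) -> float:
    """Fisher-Lee circular correlation between two angle vectors.

    Invariant under rotation of either variable; reflection flips the sign,
    so recovery experiments compare absolute values.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    num = np.sum(np.sin(da) * np.sin(db)) / 2.0
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2)) / 2.0
    if den == 0:
        return 0.0
    return float(num / den)
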