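"""Hyperbolic geometry on the map: distances, angular gap clustering, ORA.

All distances use the hyperbolic law of cosines on the native disk,

    d(s, t) = acosh[ cosh(r_s) cosh(r_t) - sinh(r_s) sinh(r_t) cos(dtheta) ],

with the angular separation dtheta = pi - |pi - |theta_s - theta_t||.  The
acosh argument is clamped to >= 1 before evaluation; for nearly radially
aligned pairs the closed form |r_s - r_t| would otherwise be lost to
cancellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import TWO_PI, canonical_angle

logger = logging.getLogger(__name__)


def angular_separation(theta_s, theta_t):
    """Circular distance between two angles, in [0, pi].  Vectorized."""
    a = canonical_angle(theta_s)
    b = canonical_angle(theta_t)
    out = np.pi - np.abs(np.pi - np.abs(np.asarray(a) - np.asarray(b)))
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


def hyperbolic_distance(r_s, theta_s, r_t, theta_t):
    """Hyperbolic distance between points given in polar coordinates.

    Accepts scalars or broadcastable arrays; radii must be non-negative.
    """
    r_s = np.asarray(r_s, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    if np.any(r_s < 0) or np.any(r_t < 0):
        raise ValueError("radial coordinates must be non-negative")
    dtheta = angular_separation(theta_s, theta_t)
    # stable rearrangement of cosh(r_s)cosh(r_t) - sinh(r_s)sinh(r_t)cos(dtheta):
    # avoids catastrophic cancellation for nearly radially aligned pairs
    arg = np.cosh(r_s - r_t) + 2.0 * np.sinh(r_s) * np.sinh(r_t) \
        * np.sin(dtheta / 2.0) ** 2
    out = np.arccosh(np.maximum(arg, 1.0))
    if out.ndim == 0:
        return float(out)
    return out


def pairwise_distances(r_a, theta_a, r_b, theta_b):
    """|A| x |B| hyperbolic distance matrix between two coordinate sets."""
    r_a = np.asarray(r_a, float)[:, None]
    t_a = np.asarray(theta_a, float)[:, None]
    r_b = np.asarray(r_b, float)[None, :]
    t_b = np.asarray(theta_b, float)[None, :]
    return hyperbolic_distance(r_a, t_a, r_b, t_b)


# ---------------------------------------------------------------------------
# angular gap clustering


@dataclass(frozen=True)
class Cluster:
    label: int
    theta_start: float
    theta_end: float  # arc [theta_start, theta_end) on the circle, may wrap
    members: tuple


@dataclass(frozen=True)
class ClusterPartition:
    clusters: tuple

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict:
        return {m: c.label for c in self.clusters for m in c.members}

    def as_sets(self) -> set:
        """Label-free view for gauge-invariance comparisons."""
        return {frozenset(c.members) for c in self.clusters}


def gap_clusters(coords, min_proteins: int = 10, max_clusters=None) -> ClusterPartition:
    """Partition the map into angular sectors at the largest gaps.

    Nodes are sorted by angle; the circular gaps between consecutive nodes
    (including the wrap-around gap) are ranked by size and introduced as
    sector boundaries greedily from the largest down.  A boundary is accepted
    only if every resulting sector keeps at least ``min_proteins``
    protein-layer members; the first rejected gap stops the procedure.
    Lipids and metabolites belong to sectors but do not count toward the
    protein minimum.  Ties in gap size are broken by the smaller start angle.
    """
    ids = np.asarray(coords.ids)
    theta = canonical_angle(np.asarray(coords.theta, float))
    is_protein = np.asarray([l == "protein" for l in coords.layers])
    n = len(ids)
    if is_protein.sum() < min_proteins:
        raise ValueError(f"need at least {min_proteins} protein nodes, "
                         f"got {int(is_protein.sum())}")

    order = np.lexsort((ids, theta))
    theta_s, ids_s, prot_s = theta[order], ids[order], is_protein[order]

    gaps = np.empty(n)
    gaps[:-1] = theta_s[1:] - theta_s[:-1]
    gaps[-1] = theta_s[0] + TWO_PI - theta_s[-1]  # wrap-around gap
    if np.allclose(gaps[:-1], 0.0):
        logger.warning("gap_clusters: all angles identical; single cluster")
        return ClusterPartition((Cluster(1, 0.0, TWO_PI, tuple(sorted(ids_s))),))

    # gap i sits after sorted node i; rank by (size desc, start angle asc)
    ranked = sorted(range(n), key=lambda i: (-gaps[i], theta_s[i]))

    def protein_counts(bounds):
        # bounds: sorted gap indices; sector j = nodes (bounds[j-1], bounds[j]]
        counts = []
        bs = sorted(bounds)
        for j, b in enumerate(bs):
            prev = bs[j - 1]
            if b > prev:
                counts.append(int(prot_s[prev + 1:b + 1].sum()))
            else:  # wrapping sector
                counts.append(int(prot_s[prev + 1:].sum() + prot_s[:b + 1].sum()))
        return counts

    accepted: list = []
    for g in ranked:
        if max_clusters is not None and len(accepted) >= max_clusters:
            break
        trial = accepted + [g]
        if len(trial) == 1 or min(protein_counts(trial)) >= min_proteins:
            accepted = trial
        else:
            break  # stop at the first rejected gap

    if len(accepted) <= 1:
        members = tuple(sorted(ids_s))
        return ClusterPartition((Cluster(1, 0.0, TWO_PI, members),))

    bs = sorted(accepted)
    clusters = []
    for j, b in enumerate(bs):
        prev = bs[j - 1]
        if b > prev:
            member_ids = ids_s[prev + 1:b + 1]
        else:
            member_ids = np.concatenate([ids_s[prev + 1:], ids_s[:b + 1]])
        start = canonical_angle(theta_s[prev] + gaps[prev] / 2.0)
        end = canonical_angle(theta_s[b] + gaps[b] / 2.0)
        clusters.append((start, end, tuple(sorted(member_ids))))
    clusters.sort(key=lambda c: c[0])
    return ClusterPartition(tuple(
        Cluster(label, start, end, members)
        for label, (start, end, members) in enumerate(clusters, start=1)))


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_size: int
    overlap: int
    p_value: float
    p_adjusted: float


def overrepresentation_test(cluster_ids: Iterable[str],
                            annotation: Mapping[str, Iterable[str]],
                            background: Iterable[str]) -> list:
    """Hypergeometric upper-tail ORA with Benjamini-Hochberg correction.

    Each term's p-value is the probability of observing at least the seen
    overlap between the cluster and the term when drawing |cluster| ids from
    the background.  Term memberships outside the background are ignored.
    Results are sorted by adjusted p then term id.
    """
    cluster = set(cluster_ids)
    bg = set(background)
    if not cluster <= bg:
        missing = sorted(cluster - bg)[:5]
        raise ValueError(f"cluster ids not in background (e.g. {missing})")
    if not annotation:
        return []
    terms = sorted(annotation)
    M, n_draw = len(bg), len(cluster)
    rows = []
    for term in terms:
        members = set(annotation[term]) & bg
        k = len(members & cluster)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_draw))
        rows.append((term, len(members), k, min(p, 1.0)))
    _, padj, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [EnrichmentResult(term, size, k, p, float(q))
               for (term, size, k, p), q in zip(rows, padj)]
    results.sort(key=lambda r: (r.p_adjusted, r.term))
    return results
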