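"""Cross-omics association ranking by hyperbolic proximity.

Given a user subset S of molecules from one omics layer, every molecule t of
each other layer receives the score

    score(t) = 1 / sum of the n smallest hyperbolic distances from S to t

(n = 3 by default), so targets sitting close to several input molecules rank
highest.  Each ranked target carries an evidence trail: the n nearest input
molecules with their distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .coords import HyperbolicCoords
from .geometry import pairwise_distances
from .network import LAYERS

logger = logging.getLogger(__name__)

DEFAULT_N_NEAREST = 3


@dataclass(frozen=True)
class QuerySubset:
    raw: tuple
    valid: tuple            # deduplicated ids present in the map, sorted
    invalid: dict           # id -> reason
    layer: str


@dataclass(frozen=True)
class RankedAssociation:
    target: str
    layer: str
    score: float            # reciprocal distance sum; inf for coincident targets
    rank: int
    evidence: tuple         # ((source id, distance), ...) ascending distance
    distance_sum: float


def validate_subset(ids: Iterable[str], coords: HyperbolicCoords) -> QuerySubset:
    """Deduplicate, check against the map, and infer the input layer.

    All valid ids must belong to a single omics layer; mixed input or an
    entirely unmapped list is an error.
    """
    raw = [s.strip() for s in ids if s and s.strip()]
    if not raw:
        raise ValueError("empty input subset")
    seen: list = []
    for s in raw:
        if s not in seen:
            seen.append(s)
    valid, invalid = [], {}
    for s in seen:
        if s in coords:
            valid.append(s)
        else:
            invalid[s] = "not in map"
    if not valid:
        raise ValueError("no input molecules found in map")
    layers = {coords.layer_of(s) for s in valid}
    if len(layers) > 1:
        detail = ", ".join(f"{s} ({coords.layer_of(s)})" for s in sorted(valid))
        raise ValueError(f"input mixes omics layers: {detail}")
    if invalid:
        logger.warning("validate_subset: %d ids not in map: %s",
                       len(invalid), sorted(invalid)[:10])
    return QuerySubset(raw=tuple(raw), valid=tuple(sorted(valid)),
                       invalid=invalid, layer=layers.pop())


def rank_layer(subset: QuerySubset, target_layer: str, n: int,
               coords: HyperbolicCoords) -> list:
    """Score and rank every molecule of ``target_layer`` against the subset.

    For each target the min(n, |S_valid|) smallest distances are summed and
    inverted.  Coincident targets (distance sum exactly 0) get an infinite
    score and rank first.  All ties (distances among sources, scores among
    targets) are broken by identifier, so the output is fully deterministic.
    """
    if target_layer not in LAYERS:
        raise ValueError(f"unknown layer {target_layer!r}")
    if target_layer == subset.layer:
        raise ValueError("target layer must differ from the input layer")
    if n < 1:
        raise ValueError("n must be >= 1")
    targets = coords.by_layer(target_layer)
    if len(targets) == 0:
        raise ValueError(f"no {target_layer} molecules in map")
    sources = coords.subset(subset.valid)
    k = min(n, len(sources))
    if len(sources) < n:
        logger.warning("rank_layer: only %d valid input molecules; using all "
                       "of them instead of n=%d", len(sources), n)

    D = pairwise_distances(sources.r, sources.theta, targets.r, targets.theta)
    src_ids = sources.ids

    assocs = []
    for j, target in enumerate(targets.ids):
        col = D[:, j]
        order = np.lexsort((src_ids, col))[:k]
        dsum = float(col[order].sum())
        score = np.inf if dsum == 0.0 else 1.0 / dsum
        evidence = tuple((str(src_ids[i]), float(col[i])) for i in order)
        assocs.append((str(target), score, dsum, evidence))
    assocs.sort(key=lambda a: (-a[1], a[0]))
    return [RankedAssociation(target=t, layer=target_layer, score=s,
                              rank=i, evidence=ev, distance_sum=dsum)
            for i, (t, s, dsum, ev) in enumerate(assocs, start=1)]


def rank_all_layers(subset: QuerySubset, n: int,
                    coords: HyperbolicCoords) -> dict:
    """Rankings for every non-input layer present in the map."""
    out = {}
    for layer in LAYERS:
        if layer == subset.layer:
            continue
        if len(coords.by_layer(layer)) == 0:
            logger.warning("rank_all_layers: no %s molecules in map; skipped", layer)
            continue
        out[layer] = rank_layer(subset, layer, n, coords)
    return out


def format_evidence(assoc: RankedAssociation) -> str:
    """``source:distance`` pairs joined by ``;``, distances to 6 decimals."""
    if not assoc.evidence:
        raise ValueError("association has no evidence trail")
    return ";".join(f"{src}:{dist:.6f}" for src, dist in assoc.evidence)


def rankings_to_frame(assocs: list) -> pd.DataFrame:
    return pd.DataFrame({
        "rank": [a.rank for a in assocs],
        "id": [a.target for a in assocs],
        "score": [a.score for a in assocs],
        "evidence": [format_evidence(a) for a in assocs],
        "distance_sum": [a.distance_sum for a in assocs],
    })


# ---------------------------------------------------------------------------
# tissue-expression filter


def tissue_filter(protein_ids: Iterable[str], expression, tissues,
                  cutoff: float = 10.0) -> set:
    """Keep proteins expressed at >= cutoff nTPM in at least one tissue.

    ``expression`` is a TSV path or DataFrame with columns
    ``protein_id  tissue  ntpm``.  Proteins absent from the table are
    dropped (logged); an unknown tissue name is an error listing the
    available tissues; an empty result is a warning, not an error.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    tissues = set(tissues)
    if not tissues:
        raise ValueError("tissue selection must be non-empty")
    if isinstance(expression, pd.DataFrame):
        df = expression
    else:
        df = pd.read_csv(expression, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("protein_id", "tissue", "ntpm") if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    available = set(df["tissue"].unique())
    unknown = tissues - available
    if unknown:
        raise ValueError(f"unknown tissues {sorted(unknown)}; available: "
                         f"{sorted(available)}")
    protein_ids = list(protein_ids)
    sel = df[df["tissue"].isin(tissues) & (df["ntpm"].astype(float) >= cutoff)]
    expressed = set(sel["protein_id"])
    in_table = set(df["protein_id"])
    absent = [p for p in protein_ids if p not in in_table]
    if absent:
        logger.info("tissue_filter: %d proteins absent from the expression "
                    "table were dropped", len(absent))
    kept = {p for p in protein_ids if p in expressed}
    if not kept:
        logger.warning("tissue_filter: no protein passes the %.3g nTPM cutoff "
                       "in the selected tissues", cutoff)
    return kept
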