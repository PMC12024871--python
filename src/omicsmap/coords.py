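"""The node-coordinate table: one (r, theta) pair per molecule.

Everything downstream of the embedding (distances, sector clustering,
cross-omics ranking) consumes this table, so it is the package's central
exchange format: a TSV with columns ``id  layer  r  theta``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import atomic_write, canonical_angle, format_float
from .network import LAYERS, infer_layer

logger = logging.getLogger(__name__)

COLUMNS = ("id", "layer", "r", "theta")


class HyperbolicCoords:
    """Immutable per-node polar coordinates on the hyperbolic disk."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"coordinate table missing columns {missing}")
        df = table.loc[:, list(COLUMNS)].copy()
        df["r"] = df["r"].astype(float)
        df["theta"] = df["theta"].astype(float)
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
            raise ValueError(f"duplicate node ids in coordinate table (e.g. {dups})")
        if not np.isfinite(df[["r", "theta"]].to_numpy()).all():
            raise ValueError("non-finite coordinate values")
        if (df["r"] < 0).any():
            raise ValueError("negative radial coordinate")
        bad_layer = ~df["layer"].isin(LAYERS)
        if bad_layer.any():
            raise ValueError(f"unknown layers {sorted(df.loc[bad_layer, 'layer'].unique())}")
        n_wrapped = int(((df["theta"] < 0) | (df["theta"] >= 2 * np.pi)).sum())
        if n_wrapped:
            logger.info("canonicalized %d angular coordinates into [0, 2pi)", n_wrapped)
        df["theta"] = canonical_angle(df["theta"].to_numpy())
        self._df = df.reset_index(drop=True)
        self._index = {i: k for k, i in enumerate(self._df["id"])}

    # -- accessors --------------------------------------------------------

    @property
    def ids(self):
        return self._df["id"].to_numpy()

    @property
    def layers(self):
        return self._df["layer"].to_numpy()

    @property
    def r(self):
        return self._df["r"].to_numpy()

    @property
    def theta(self):
        return self._df["theta"].to_numpy()

    def __len__(self):
        return len(self._df)

    def __contains__(self, node_id):
        return node_id in self._index

    def get(self, node_id):
        """(r, theta) of one node."""
        k = self._index[node_id]
        return float(self._df["r"].iloc[k]), float(self._df["theta"].iloc[k])

    def layer_of(self, node_id):
        return self._df["layer"].iloc[self._index[node_id]]

    def subset(self, node_ids) -> "HyperbolicCoords":
        keep = [self._index[i] for i in node_ids]
        return HyperbolicCoords(self._df.iloc[keep])

    def by_layer(self, layer: str) -> "HyperbolicCoords":
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return HyperbolicCoords(self._df[self._df["layer"] == layer])

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def rotated(self, delta: float, reflect: bool = False) -> "HyperbolicCoords":
        """Gauge transform: theta -> (+-theta + delta) mod 2pi."""
        df = self._df.copy()
        theta = -df["theta"] if reflect else df["theta"]
        df["theta"] = canonical_angle(theta.to_numpy() + delta)
        return HyperbolicCoords(df)


def write_coords(coords: HyperbolicCoords, path) -> None:
    """Write the coordinate table at full float precision (round-trip safe)."""
    with atomic_write(path) as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for row in coords.to_frame().itertuples(index=False):
            fh.write(f"{row.id}\t{row.layer}\t{format_float(row.r)}\t"
                     f"{format_float(row.theta)}\n")


def read_coords(path) -> HyperbolicCoords:
    """Read an ``id  layer  r  theta`` TSV.

    A missing ``layer`` column is tolerated (inferred from the id prefix, as
    in externally produced tables); malformed rows raise with their row
    number; angles are canonicalized into [0, 2pi) with a logged count.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "layer" not in df.columns and "id" in df.columns:
        df["layer"] = [infer_layer(i) for i in df["id"]]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("r", "theta"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValueError(f"{path}: non-finite {col!r} at row {row}")
        df[col] = vals
    if (df["r"] < 0).any():
        row = int(np.flatnonzero((df["r"] < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative radius at row {row}")
    return HyperbolicCoords(df)
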