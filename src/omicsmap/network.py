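"""Assembly of the three-layer molecular network.

The network combines a confidence-filtered protein-protein interaction (PPI)
layer with cross-layer edges that attach plasma lipids (``SLM:`` accessions)
and metabolites (``Pubchem:`` CIDs) to proteins via enzymatic reactions or
GWAS loci.  The protein layer is reduced to its largest connected component
before attachment: proteins outside it cannot receive map coordinates and are
discarded, together with any cross-layer edge pointing at them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from ._util import atomic_write, format_float

logger = logging.getLogger(__name__)

LAYERS = ("protein", "lipid", "metabolite")
CROSS_SOURCES = ("enzymatic", "gwas")

NETWORK_FORMAT_STAMP = "# omicsmap-network v1"


class NetworkFormatError(ValueError):
    """Raised for malformed input files or version-stamp mismatches."""


def infer_layer(node_id: str) -> str:
    """Derive the omics layer from the identifier namespace.

    ``SLM:``-prefixed ids are SwissLipids lipids, ``Pubchem:``-prefixed ids
    are PubChem metabolites; anything else is treated as a (UniProt) protein.
    """
    if node_id.startswith("SLM:"):
        return "lipid"
    if node_id.startswith("Pubchem:"):
        return "metabolite"
    return "protein"


@dataclass(frozen=True)
class Node:
    id: str
    layer: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")


@dataclass(frozen=True)
class Edge:
    """Undirected edge; endpoints are stored in sorted order.

    ``kinds`` is a provenance tuple: ``('ppi',)`` for the protein layer, or a
    sorted subset of ``('enzymatic', 'gwas')`` for cross-layer edges (a pair
    reported by both sources collapses to a single edge carrying both tags).
    """

    a: str
    b: str
    kinds: tuple = ("ppi",)
    confidence: Optional[float] = None
    b_layer: Optional[str] = None  # declared layer of the non-protein endpoint

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a!r}")

    @property
    def key(self):
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


class MultiOmicsNetwork:
    """Undirected graph over proteins, lipids and metabolites.

    Thin wrapper around a :class:`networkx.Graph` whose nodes carry a
    ``layer`` attribute and whose edges carry ``kinds`` (provenance tuple)
    and optional ``confidence``.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, layer: Optional[str] = None):
        layer = layer or infer_layer(node_id)
        self.graph.add_node(node_id, layer=layer)

    def add_edge(self, edge: Edge):
        for end in (edge.a, edge.b):
            if end not in self.graph:
                self.add_node(end)
        a, b = edge.key
        if self.graph.has_edge(a, b):
            prev = self.graph.edges[a, b]
            kinds = tuple(sorted(set(prev["kinds"]) | set(edge.kinds)))
            conf = prev.get("confidence")
            if edge.confidence is not None:
                conf = max(conf, edge.confidence) if conf is not None else edge.confidence
            self.graph.edges[a, b].update(kinds=kinds, confidence=conf)
        else:
            self.graph.add_edge(a, b, kinds=tuple(sorted(edge.kinds)),
                                confidence=edge.confidence)

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_by_layer(self, layer: str) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["layer"] == layer)

    def layer_counts(self) -> dict:
        counts = {layer: 0 for layer in LAYERS}
        for _, d in self.graph.nodes(data=True):
            counts[d["layer"]] += 1
        return counts

    def edges(self) -> list:
        out = []
        for a, b, d in self.graph.edges(data=True):
            x, y = (a, b) if a <= b else (b, a)
            out.append(Edge(x, y, kinds=d["kinds"], confidence=d.get("confidence")))
        return sorted(out, key=lambda e: e.key)

    def validate(self) -> None:
        """Check the structural invariants of an assembled network.

        The protein-only subgraph must be connected, every cross-layer node
        must touch at least one protein, cross-layer edges must have exactly
        one protein endpoint, and every declared layer must match the layer
        inferable from the identifier prefix.
        """
        for n, d in self.graph.nodes(data=True):
            if infer_layer(n) != d["layer"]:
                raise ValueError(f"node {n!r}: declared layer {d['layer']!r} "
                                 f"contradicts its identifier prefix")
        proteins = [n for n, d in self.graph.nodes(data=True) if d["layer"] == "protein"]
        if proteins:
            sub = self.graph.subgraph(proteins)
            if not nx.is_connected(sub):
                raise ValueError("protein subgraph is not connected")
        for a, b, d in self.graph.edges(data=True):
            la, lb = self.graph.nodes[a]["layer"], self.graph.nodes[b]["layer"]
            if "ppi" in d["kinds"]:
                if not (la == lb == "protein"):
                    raise ValueError(f"ppi edge {a!r}-{b!r} with non-protein endpoint")
            else:
                if (la == "protein") == (lb == "protein"):
                    raise ValueError(f"cross-layer edge {a!r}-{b!r} must have exactly "
                                     f"one protein endpoint")
        for n, d in self.graph.nodes(data=True):
            if d["layer"] != "protein" and self.graph.degree(n) == 0:
                raise ValueError(f"{d['layer']} node {n!r} has no edge to the network")

    def __eq__(self, other):
        if not isinstance(other, MultiOmicsNetwork):
            return NotImplemented
        return (dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
                and self.edges() == other.edges())


# ---------------------------------------------------------------------------
# readers


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_ppi_edges(path, score_threshold: float = 0.71,
                   id_columns=(0, 1), score_column: int = 2) -> list:
    """Read a PPI edge list TSV and keep edges with confidence >= threshold.

    The file must have at least three columns; by default the first two are
    node identifiers and the third the confidence score in [0, 1].  HIPPIE
    dumps interleave gene symbols and Entrez ids with UniProt accessions, so
    the id columns are configurable; no identifier mapping is attempted.
    Duplicate undirected pairs collapse to one edge (keeping the maximum
    confidence); self-loops are dropped.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must be in [0, 1]")
    needed = max(*id_columns, score_column) + 1
    seen: dict = {}
    n_below = n_self = n_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < needed:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected at least {needed} tab-separated "
                f"fields, got {len(fields)}")
        a, b = fields[id_columns[0]].strip(), fields[id_columns[1]].strip()
        try:
            conf = float(fields[score_column])
        except ValueError:
            raise NetworkFormatError(
                f"{path}:{lineno}: non-numeric confidence "
                f"{fields[score_column]!r}") from None
        if not a or not b:
            raise NetworkFormatError(f"{path}:{lineno}: empty node identifier")
        if a == b:
            n_self += 1
            continue
        if conf < score_threshold:
            n_below += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            n_dup += 1
            seen[key] = max(seen[key], conf)
        else:
            seen[key] = conf
    logger.info("read_ppi_edges: kept %d edges; dropped %d below threshold, "
                "%d self-loops, %d duplicates", len(seen), n_below, n_self, n_dup)
    if not seen:
        raise NetworkFormatError(f"{path}: no edges pass threshold {score_threshold}")
    return [Edge(a, b, kinds=("ppi",), confidence=c)
            for (a, b), c in sorted(seen.items())]


def read_cross_layer_edges(path) -> list:
    """Read protein-to-lipid/metabolite edges.

    Columns: ``protein_id  partner_id  partner_layer  source`` with
    partner_layer in {lipid, metabolite} and source in {enzymatic, gwas}.
    A pair listed under both sources collapses to one edge carrying both
    provenance tags.  Partners lacking the prefix expected for their layer
    are kept with a warning.
    """
    header = ("protein_id", "partner_id", "partner_layer", "source")
    merged: dict = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if tuple(f.lower() for f in fields[:4]) == header:
            continue
        if len(fields) < 4:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}")
        prot, partner, layer, source = fields[:4]
        if layer not in ("lipid", "metabolite"):
            raise NetworkFormatError(
                f"{path}:{lineno}: unknown partner layer {layer!r} "
                f"(expected lipid or metabolite)")
        if source not in CROSS_SOURCES:
            raise NetworkFormatError(
                f"{path}:{lineno}: unknown source {source!r} "
                f"(expected one of {CROSS_SOURCES})")
        expected_prefix = "SLM:" if layer == "lipid" else "Pubchem:"
        if not partner.startswith(expected_prefix):
            logger.warning("%s:%d: partner %r lacks the %r prefix expected "
                           "for layer %s; row kept", path, lineno, partner,
                           expected_prefix, layer)
        key = (prot, partner)
        if key in merged:
            prev_layer, sources = merged[key]
            if prev_layer != layer:
                raise NetworkFormatError(
                    f"{path}:{lineno}: partner {partner!r} re-declared with "
                    f"layer {layer!r} (was {prev_layer!r})")
            sources.add(source)
        else:
            merged[key] = (layer, {source})
    per_source = {s: 0 for s in CROSS_SOURCES}
    for _, (_, sources) in merged.items():
        for s in sources:
            per_source[s] += 1
    logger.info("read_cross_layer_edges: %d collapsed edges (per source: %s)",
                len(merged), per_source)
    return [Edge(prot, partner, kinds=tuple(sorted(sources)), b_layer=layer)
            for (prot, partner), (layer, sources) in sorted(merged.items())]


# ---------------------------------------------------------------------------
# assembly


def largest_connected_component(net: MultiOmicsNetwork) -> MultiOmicsNetwork:
    """Induced subgraph on the largest component.

    Size ties are broken by the lexicographically smallest member id so the
    result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = components[0]
    return MultiOmicsNetwork(net.graph.subgraph(keep).copy())


def assemble_network(ppi: Iterable[Edge], cross: Iterable[Edge]) -> MultiOmicsNetwork:
    """Build the three-layer network.

    The PPI layer is reduced to its largest connected component first; the
    cross-layer edges whose protein endpoint fell outside it are dropped
    (logged), and lipids/metabolites left without any surviving edge are
    excluded entirely.
    """
    cross = list(cross)
    ppi_net = MultiOmicsNetwork()
    for e in ppi:
        ppi_net.add_edge(e)
    lcc = largest_connected_component(ppi_net)
    in_lcc = set(lcc.graph.nodes)

    net = MultiOmicsNetwork(lcc.graph.copy())
    kept = dropped = 0
    for e in cross:
        if e.a in in_lcc:
            layer = e.b_layer or infer_layer(e.b)
            net.add_node(e.b, layer=layer)
            net.add_edge(e)
            kept += 1
        else:
            dropped += 1
    if dropped:
        logger.info("assemble_network: dropped %d cross-layer edges whose "
                    "protein endpoint is outside the PPI LCC", dropped)
    if cross and kept == 0:
        logger.warning("assemble_network: no cross-layer edge survives; "
                       "returning a protein-only network")
    return net


# ---------------------------------------------------------------------------
# persistence (nodes.tsv / edges.tsv pair, version-stamped)


def write_network(net: MultiOmicsNetwork, prefix) -> None:
    """Persist as ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``.

    Deterministic ordering and float formatting: rewriting an unmodified
    network yields byte-identical files.
    """
    prefix = str(prefix)
    with atomic_write(prefix + ".nodes.tsv") as fh:
        fh.write(NETWORK_FORMAT_STAMP + "\n")
        fh.write("id\tlayer\n")
        for n, d in sorted(net.graph.nodes(data=True)):
            fh.write(f"{n}\t{d['layer']}\n")
    with atomic_write(prefix + ".edges.tsv") as fh:
        fh.write(NETWORK_FORMAT_STAMP + "\n")
        fh.write("a\tb\tkinds\tconfidence\n")
        for e in net.edges():
            conf = "" if e.confidence is None else format_float(e.confidence)
            fh.write(f"{e.a}\t{e.b}\t{','.join(e.kinds)}\t{conf}\n")


def read_network(prefix) -> MultiOmicsNetwork:
    prefix = str(prefix)
    net = MultiOmicsNetwork()
    for suffix in (".nodes.tsv", ".edges.tsv"):
        with open(prefix + suffix, encoding="utf-8") as fh:
            stamp = fh.readline().rstrip("\n")
            if stamp != NETWORK_FORMAT_STAMP:
                raise NetworkFormatError(
                    f"{prefix + suffix}: unrecognized format stamp {stamp!r} "
                    f"(expected {NETWORK_FORMAT_STAMP!r})")
    with open(prefix + ".nodes.tsv", encoding="utf-8") as fh:
        fh.readline()  # stamp
        fh.readline()  # header
        for line in fh:
            node_id, layer = line.rstrip("\n").split("\t")
            net.add_node(node_id, layer=layer)
    with open(prefix + ".edges.tsv", encoding="utf-8") as fh:
        fh.readline()
        fh.readline()
        for line in fh:
            a, b, kinds, conf = line.rstrip("\n").split("\t")
            net.add_edge(Edge(a, b, kinds=tuple(kinds.split(",")),
                              confidence=float(conf) if conf else None))
    return net
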