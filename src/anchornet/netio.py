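"""Core domain types and I/O for confidence-weighted interaction networks.

The background network is a mixed graph: protein-protein interactions
(PPIs) are undirected, protein-DNA interactions (PDIs, TF -> target) are
directed.  Every edge carries a confidence ``p`` in ``(0, 1]`` which is
turned into a nonnegative traversal cost ``-ln p``, so that minimum-cost
paths are maximum-likelihood paths (edge probabilities treated as
independent).

Two on-disk dialects are supported:

* **TSV** -- four columns ``node1  node2  confidence  kind`` with
  ``kind`` in ``{PPI, PDI}``; ``#``-prefixed lines are comments.
* **SIF** -- ``node1<TAB>type<TAB>node2`` with ``type`` in ``{pp, pd}``,
  confidences supplied in a companion edge-attribute TSV
  ``node1<TAB>node2<TAB>confidence``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

PPI = "PPI"
PDI = "PDI"

#: Identifier of the virtual super-root used by multi-anchor queries.
ROOT = "__root__"


class NetworkFormatError(ValueError):
    """Raised for malformed network files or invalid edge records."""


@dataclass(frozen=True)
class Edge:
    """A single interaction.

    For PPIs the endpoint order is canonicalized (``u <= v``); for PDIs
    the order is meaningful (``u`` regulates ``v``).
    """

    u: str
    v: str
    p: float
    kind: str = PPI

    @property
    def cost(self) -> float:
        return edge_cost(self.p)

    def key(self) -> tuple:
        if self.kind == PPI:
            a, b = sorted((self.u, self.v))
            return (PPI, a, b)
        return (PDI, self.u, self.v)


def edge_cost(p: float) -> float:
    """Map a confidence ``p`` in ``(0, 1]`` to the cost ``-ln p``.

    The transform is strictly decreasing and additive over paths, so a
    minimum-cost path is a maximum-likelihood path.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"confidence must be in (0, 1], got {p!r}")
    return -math.log(p)


class InteractionNetwork:
    """A validated mixed interaction graph with probabilistic edges.

    At most one edge exists per unordered PPI pair and per ordered PDI
    pair; self-loops are rejected.  Duplicate records collapse to the
    maximum confidence (optimistic merge).
    """

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = ()):
        self._edges: dict[tuple, Edge] = {}
        self._nodes: set[str] = set(nodes)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------

    def add_edge(self, e: Edge) -> None:
        if e.u == e.v:
            raise NetworkFormatError(f"self-loop on {e.u!r} is not allowed")
        edge_cost(e.p)  # validates the confidence range
        if e.kind not in (PPI, PDI):
            raise NetworkFormatError(f"unknown edge kind {e.kind!r}")
        if e.kind == PPI and e.u > e.v:
            e = Edge(e.v, e.u, e.p, PPI)
        k = e.key()
        old = self._edges.get(k)
        if old is not None:
            if e.p > old.p:
                logger.info("duplicate edge %s-%s: keeping max confidence %g", e.u, e.v, e.p)
                self._edges[k] = e
            else:
                logger.info("duplicate edge %s-%s: keeping max confidence %g", e.u, e.v, old.p)
        else:
            self._edges[k] = e
        self._nodes.add(e.u)
        self._nodes.add(e.v)

    def add_node(self, n: str) -> None:
        self._nodes.add(n)

    # -- views --------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        return sorted(self._edges.values(), key=Edge.key)

    def __len__(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def has_edge(self, u: str, v: str) -> bool:
        return self.get_edge(u, v) is not None

    def get_edge(self, u: str, v: str) -> Edge | None:
        """The edge joining ``u`` and ``v``; PDI only in its stated direction."""
        a, b = sorted((u, v))
        e = self._edges.get((PPI, a, b))
        if e is not None:
            return e
        return self._edges.get((PDI, u, v))

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        keep = set(nodes)
        return InteractionNetwork(
            (e for e in self._edges.values() if e.u in keep and e.v in keep),
            nodes=keep & self._nodes,
        )

    def without_nodes(self, nodes: Iterable[str]) -> "InteractionNetwork":
        drop = set(nodes)
        return InteractionNetwork(
            (e for e in self._edges.values() if e.u not in drop and e.v not in drop),
            nodes=self._nodes - drop,
        )

    def to_digraph(self) -> nx.DiGraph:
        """Directed view: each PPI contributes two arcs, each PDI one."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self._nodes))
        for e in self.edges:
            g.add_edge(e.u, e.v, cost=e.cost, p=e.p, kind=e.kind)
            if e.kind == PPI:
                g.add_edge(e.v, e.u, cost=e.cost, p=e.p, kind=e.kind)
        return g

    def to_undirected(self) -> nx.Graph:
        """Undirected view (PDI direction ignored), for neighborhoods/propagation."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self._nodes))
        for e in self.edges:
            g.add_edge(e.u, e.v, cost=e.cost, p=e.p, kind=e.kind)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges


@dataclass
class Query:
    """An endpoint query against a background network.

    ``alpha`` trades subnetwork size against total anchor-to-terminal
    path cost (``alpha = 1``: pure parsimony; ``alpha = 0``: pure
    shortest paths).
    """

    mode: str  # anchored | general | shortest_paths | local_search
    terminals: set[str]
    anchors: set[str] = field(default_factory=set)
    alpha: float = 0.25
    required_nodes: set[str] = field(default_factory=set)
    excluded_nodes: set[str] = field(default_factory=set)
    predict_tfs: bool = False
    predict_anchors: bool = False
    depth: int = 1

    MODES = ("anchored", "general", "shortest_paths", "local_search")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValueError(f"unknown query mode {self.mode!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        self.terminals = set(self.terminals)
        self.anchors = set(self.anchors)
        overlap = self.anchors & self.terminals
        if overlap:
            warnings.warn(
                f"nodes {sorted(overlap)} are both anchors and terminals; "
                "treating them as anchors only"
            )
            self.terminals -= overlap
        if not self.terminals:
            raise ValueError("query needs at least one terminal")
        if self.mode == "anchored" and not self.anchors:
            raise ValueError("anchored query needs at least one anchor")
        bad = self.excluded_nodes & (self.anchors | self.terminals | self.required_nodes)
        if bad:
            raise ValueError(f"excluded nodes overlap query nodes: {sorted(bad)}")


@dataclass
class SolutionNetwork:
    """An inferred subnetwork with per-terminal root paths and objective."""

    network: InteractionNetwork
    node_roles: dict[str, str]  # anchor | terminal | connector | tf | root
    paths: dict[str, list[str]]  # terminal -> node sequence root..terminal
    objective: tuple[float, float, float]  # (size_term, path_term, combined)
    alpha: float
    optimal: bool = False
    unreachable_terminals: set[str] = field(default_factory=set)
    root: str | None = None

    @property
    def biological_nodes(self) -> set[str]:
        return {n for n in self.network.nodes if n != ROOT}

    @property
    def size_term(self) -> float:
        return self.objective[0]

    @property
    def path_term(self) -> float:
        return self.objective[1]

    @property
    def combined(self) -> float:
        return self.objective[2]


# -- file I/O ----------------------------------------------------------


def _parse_float(tok: str, lineno: int, path) -> float:
    try:
        return float(tok)
    except ValueError:
        raise NetworkFormatError(f"{path}:{lineno}: not a number: {tok!r}") from None


def read_network(path, format: str = "tsv", attributes=None) -> InteractionNetwork:
    """Read a background network.

    ``format='tsv'`` expects four columns (node1, node2, confidence,
    kind); ``format='sif'`` expects ``node1 pp|pd node2`` and requires a
    companion edge-attribute file (``attributes``) with confidences,
    defaulting to ``<path>.ea`` next to the SIF file.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "sif":
        if attributes is None:
            attributes = path.with_suffix(path.suffix + ".ea")
        return _read_sif(path, Path(attributes))
    raise ValueError(f"unknown network format {format!r}")


def _records(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _read_tsv(path: Path) -> InteractionNetwork:
    net = InteractionNetwork()
    for lineno, toks in _records(path):
        if len(toks) != 4:
            raise NetworkFormatError(f"{path}:{lineno}: expected 4 columns, got {len(toks)}")
        u, v, p_s, kind = toks
        p = _parse_float(p_s, lineno, path)
        try:
            net.add_edge(Edge(u, v, p, kind.upper()))
        except (NetworkFormatError, ValueError) as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from None
    return net


_SIF_KIND = {"pp": PPI, "pd": PDI}
_KIND_SIF = {PPI: "pp", PDI: "pd"}


def _read_sif(path: Path, attributes: Path) -> InteractionNetwork:
    conf: dict[tuple[str, str], float] = {}
    for lineno, toks in _records(attributes):
        if len(toks) != 3:
            raise NetworkFormatError(
                f"{attributes}:{lineno}: expected 3 columns, got {len(toks)}"
            )
        conf[(toks[0], toks[1])] = _parse_float(toks[2], lineno, attributes)
    net = InteractionNetwork()
    for lineno, toks in _records(path):
        if len(toks) == 1:
            net.add_node(toks[0])
            continue
        if len(toks) != 3:
            raise NetworkFormatError(f"{path}:{lineno}: expected 3 columns, got {len(toks)}")
        u, sif_kind, v = toks
        if sif_kind not in _SIF_KIND:
            raise NetworkFormatError(f"{path}:{lineno}: unknown interaction type {sif_kind!r}")
        p = conf.get((u, v), conf.get((v, u)))
        if p is None:
            raise NetworkFormatError(f"{path}:{lineno}: no confidence for pair {u}-{v}")
        try:
            net.add_edge(Edge(u, v, p, _SIF_KIND[sif_kind]))
        except (NetworkFormatError, ValueError) as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from None
    return net


def write_network(net: InteractionNetwork, path, format: str = "tsv") -> None:
    """Write a network in either dialect (SIF writes ``<path>`` + ``<path>.ea``)."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# node1\tnode2\tconfidence\tkind\n")
            for e in net.edges:
                fh.write(f"{e.u}\t{e.v}\t{e.p:.10g}\t{e.kind}\n")
            # isolated nodes are not representable in the 4-column dialect
    elif format == "sif":
        ea = path.with_suffix(path.suffix + ".ea")
        covered: set[str] = set()
        with open(path, "w", encoding="utf-8") as fh, open(ea, "w", encoding="utf-8") as fa:
            for e in net.edges:
                fh.write(f"{e.u}\t{_KIND_SIF[e.kind]}\t{e.v}\n")
                fa.write(f"{e.u}\t{e.v}\t{e.p:.10g}\n")
                covered.update((e.u, e.v))
            for n in sorted(net.nodes - covered):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def write_solution(sol: SolutionNetwork, prefix) -> dict[str, Path]:
    """Write a solution as ``<prefix>.sif`` (+ ``.ea``) and ``<prefix>.nodes.tsv``.

    The virtual root and its zero-cost edges are omitted; the node table
    carries each node's role and, if attached, its chance-inclusion
    probability.
    """
    prefix = Path(prefix)
    bio = sol.biological_nodes
    net = sol.network.subnetwork(bio)
    sif = prefix.with_suffix(prefix.suffix + ".sif")
    write_network(net, sif, format="sif")
    nodefile = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    incl = getattr(sol, "inclusion_probability", {}) or {}
    with open(nodefile, "w", encoding="utf-8") as fh:
        fh.write("node\trole\tinclusion_probability\n")
        for n in sorted(bio):
            role = sol.node_roles.get(n, "connector")
            pr = incl.get(n)
            fh.write(f"{n}\t{role}\t{'' if pr is None else f'{pr:.6g}'}\n")
    return {"sif": sif, "edge_attributes": sif.with_suffix(sif.suffix + ".ea"), "nodes": nodefile}


def read_node_list(path) -> list[str]:
    """Read a node-list file (one identifier per line, ``#`` comments)."""
    out: list[str] = []
    for _lineno, toks in _records(Path(path)):
        out.append(toks[0])
    return out


def write_node_list(nodes: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in nodes:
            fh.write(f"{n}\n")
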