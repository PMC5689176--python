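"""Seeded synthetic data: background networks, planted anchored
pathways, and evidence tables.

Everything here is a pure function of its parameters and a seed, so any
pipeline in the package can be exercised without downloads.  Background
networks are Erdős–Rényi by default (simplest null); a preferential-
attachment option exists because propagation behaviour is
degree-sensitive.  Background confidences default to uniform(0.3, 0.7)
and planted pathway edges to 0.99, a separation wide enough that a
correct solver should recover planted routes essentially always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import PDI, PPI, Edge, InteractionNetwork
from .scoring import ConfidenceModel, EvidenceRecord, _sigmoid


def _node_name(i: int, width: int = 4) -> str:
    return f"N{i:0{width}d}"


def generate_background(
    n_nodes: int,
    mean_degree: float,
    pdi_fraction: float = 0.1,
    conf_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    topology: str = "er",
) -> InteractionNetwork:
    """Random background network with confidences.

    ``topology='er'`` draws each pair independently with probability
    ``mean_degree / (n_nodes - 1)``; ``'ba'`` grows a preferential-
    attachment graph with ``mean_degree / 2`` edges per new node.  Each
    edge is a PDI with probability ``pdi_fraction`` (random direction),
    otherwise a PPI; confidences are uniform on ``conf_range``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < mean_degree < n_nodes):
        raise ValueError("mean_degree must lie in (0, n_nodes)")
    lo, hi = conf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("confidence range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_nodes - 1)))
    names = [_node_name(i, width) for i in range(n_nodes)]
    pairs: list[tuple[int, int]] = []
    if topology == "er":
        p = mean_degree / (n_nodes - 1)
        iu, ju = np.triu_indices(n_nodes, k=1)
        mask = rng.random(iu.size) < p
        pairs = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    elif topology == "ba":
        m = max(1, int(round(mean_degree / 2)))
        repeated: list[int] = list(range(m))
        for new in range(m, n_nodes):
            targets: set[int] = set()
            while len(targets) < min(m, new):
                targets.add(int(repeated[rng.integers(len(repeated))]))
            for t in sorted(targets):
                pairs.append((t, new))
                repeated += [t, new]
    else:
        raise ValueError(f"unknown topology {topology!r}")

    net = InteractionNetwork(nodes=names)
    for i, j in pairs:
        p_conf = float(rng.uniform(lo, hi))
        if rng.random() < pdi_fraction:
            u, v = (i, j) if rng.random() < 0.5 else (j, i)
            net.add_edge(Edge(names[u], names[v], p_conf, PDI))
        else:
            net.add_edge(Edge(names[i], names[j], p_conf, PPI))
    return net


@dataclass
class PlantedInstance:
    """A background network with known anchored pathways planted in it."""

    network: InteractionNetwork
    anchors: set[str]
    terminals: set[str]
    true_connectors: set[str]
    true_edges: list[Edge]
    params: dict


def plant_instance(
    net: InteractionNetwork,
    n_anchors: int = 2,
    n_terminals: int = 5,
    path_len: int = 3,
    conf_high: float = 0.99,
    seed: int = 0,
) -> PlantedInstance:
    """Plant high-confidence anchor-to-terminal paths into a network.

    Selects disjoint anchors, terminals and per-path connector chains,
    then overwrites/creates PPI edges of confidence ``conf_high`` along
    each anchor -> connectors -> terminal route (anchors assigned round
    robin).  Returns the ground truth for recovery experiments.
    """
    if path_len < 1:
        raise ValueError("path_len must be at least 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    need = n_anchors + n_terminals + n_terminals * (path_len - 1)
    if len(nodes) < need:
        raise ValueError(f"network has {len(nodes)} nodes, planting needs {need}")
    pick = rng.choice(len(nodes), size=need, replace=False)
    chosen = [nodes[i] for i in pick]
    anchors = chosen[:n_anchors]
    terminals = chosen[n_anchors : n_anchors + n_terminals]
    connector_pool = chosen[n_anchors + n_terminals :]

    out = InteractionNetwork(net.edges, nodes=net.nodes)
    true_edges: list[Edge] = []
    connectors: set[str] = set()
    ci = 0
    for ti, t in enumerate(terminals):
        a = anchors[ti % n_anchors]
        chain = connector_pool[ci : ci + path_len - 1]
        ci += path_len - 1
        route = [a, *chain, t]
        connectors.update(chain)
        for u, v in zip(route, route[1:]):
            e = Edge(*sorted((u, v)), conf_high, PPI)
            # overwrite any existing edge between the endpoints
            old = out.get_edge(u, v)
            if old is not None:
                out._edges.pop(old.key())  # noqa: SLF001 - controlled rebuild
            out.add_edge(e)
            true_edges.append(e)
    return PlantedInstance(
        network=out,
        anchors=set(anchors),
        terminals=set(terminals),
        true_connectors=connectors,
        true_edges=true_edges,
        params={
            "n_anchors": n_anchors,
            "n_terminals": n_terminals,
            "path_len": path_len,
            "conf_high": conf_high,
            "seed": seed,
        },
    )


def generate_evidence(
    pairs,
    true_model: ConfidenceModel,
    seed: int = 0,
    mean_count: float = 1.0,
) -> tuple[list[EvidenceRecord], list[int]]:
    """Sample evidence counts and Bernoulli labels from a logistic model.

    Feature counts are Poisson(``mean_count``); each label is Bernoulli
    with success probability ``sigmoid(intercept + coef . features)``.
    ``pairs`` may be node pairs or an :class:`InteractionNetwork` (its
    edge pairs are used).
    """
    if isinstance(pairs, InteractionNetwork):
        pairs = [(e.u, e.v) for e in pairs.edges]
    rng = np.random.default_rng(seed)
    k = true_model.coefficients.size
    records: list[EvidenceRecord] = []
    labels: list[int] = []
    for pair in pairs:
        x = rng.poisson(mean_count, size=k).astype(float)
        p = float(_sigmoid(true_model.intercept + true_model.coefficients @ x))
        records.append(EvidenceRecord(tuple(pair), tuple(x.tolist())))
        labels.append(int(rng.random() < p))
    return records, labels


def random_small_instance(
    seed: int,
    max_nodes: int = 9,
    max_edges: int = 16,
    max_terminals: int = 3,
    alphas: tuple[float, ...] = (0.0, 0.25, 1.0),
):
    """A small random rooted instance for solver cross-validation.

    Draws a connected-enough random background, then picks anchors and
    root-reachable terminals; the alpha is drawn from ``alphas``.
    Returns a :class:`~anchornet.reconstruct.RootedInstance` or ``None``
    when the draw has no reachable terminal (caller may reseed).
    """
    from .reconstruct import INF, RootedInstance, dijkstra, directed_adjacency

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_nodes + 1))
    net = generate_background(
        n, mean_degree=min(3.0, n - 1), pdi_fraction=0.15, seed=int(rng.integers(2**31))
    )
    while net.n_edges() > max_edges:
        drop = net.edges[int(rng.integers(net.n_edges()))]
        net = InteractionNetwork(
            [e for e in net.edges if e.key() != drop.key()], nodes=net.nodes
        )
    nodes = sorted(net.nodes)
    n_anchors = int(rng.integers(1, 3))
    pick = rng.choice(len(nodes), size=min(len(nodes), n_anchors), replace=False)
    anchors = {nodes[i] for i in pick}
    dist: dict[str, float] = {}
    adj = directed_adjacency(net)
    for a in sorted(anchors):
        da, _ = dijkstra(adj, a)
        for k2, v in da.items():
            dist[k2] = min(dist.get(k2, INF), v)
    reach = sorted(set(dist) - anchors)
    if not reach:
        return None
    k = int(rng.integers(1, min(max_terminals, len(reach)) + 1))
    pick = rng.choice(len(reach), size=k, replace=False)
    terminals = {reach[i] for i in pick}
    alpha = float(alphas[int(rng.integers(len(alphas)))])
    return RootedInstance.build(net, anchors, terminals, alpha)
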