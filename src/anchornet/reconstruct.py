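"""Subnetwork reconstruction: anchored (approximate), general, shortest
paths and local-search queries.

The anchored objective combines two criteria: total subnetwork cost
("size", confidence-weighted) and the summed cost of root-to-terminal
paths inside the subnetwork.  For a trade-off parameter ``alpha`` in
``[0, 1]``::

    combined = alpha * size_term + (1 - alpha) * path_term

Multi-anchor queries are reduced to single-source by a virtual super-root
joined to every anchor with a zero-cost edge.  All tie-breaks (Dijkstra
predecessors, MST edge order, pruning order) are lexicographic on node
identifiers, so outputs are deterministic and relabeling-equivariant.
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field

from .netio import (
    PPI,
    ROOT,
    Edge,
    InteractionNetwork,
    Query,
    SolutionNetwork,
)

INF = math.inf
_EPS = 1e-12


@dataclass
class RootedInstance:
    """A background network rooted for a multi-source anchored query."""

    net: InteractionNetwork  # augmented with the virtual root if |anchors| > 1
    anchors: set[str]
    terminals: set[str]
    alpha: float
    root: str

    @classmethod
    def build(
        cls,
        net: InteractionNetwork,
        anchors: set[str],
        terminals: set[str],
        alpha: float = 0.25,
    ) -> "RootedInstance":
        anchors = set(anchors)
        terminals = set(terminals) - anchors
        if not anchors:
            raise ValueError("anchored instance needs at least one anchor")
        if not terminals:
            raise ValueError("anchored instance needs at least one terminal")
        if len(anchors) == 1:
            return cls(net, anchors, terminals, alpha, next(iter(anchors)))
        aug = InteractionNetwork(net.edges, nodes=net.nodes)
        for a in sorted(anchors):
            aug.add_edge(Edge(ROOT, a, 1.0, PPI))  # zero-cost root edge
        return cls(aug, anchors, terminals, alpha, ROOT)


# -- deterministic Dijkstra -------------------------------------------


def directed_adjacency(net: InteractionNetwork) -> dict[str, list[tuple[str, float]]]:
    """Sorted adjacency of the directed view (PPI: both arcs, PDI: one)."""
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in sorted(net.nodes)}
    for e in net.edges:
        adj[e.u].append((e.v, e.cost))
        if e.kind == PPI:
            adj[e.v].append((e.u, e.cost))
    for lst in adj.values():
        lst.sort()
    return adj


def dijkstra(
    adj: dict[str, list[tuple[str, float]]], source: str
) -> tuple[dict[str, float], dict[str, str | None]]:
    """Single-source shortest paths with lexicographic predecessor tie-break."""
    dist: dict[str, float] = {source: 0.0}
    hops: dict[str, int] = {source: 0}
    parent: dict[str, str | None] = {source: None}
    heap: list[tuple[float, str]] = [(0.0, source)]
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, c in adj.get(u, ()):
            nd = d + c
            cur = dist.get(v, INF)
            if nd < cur - _EPS:
                dist[v] = nd
                hops[v] = hops[u] + 1
                parent[v] = u
                heapq.heappush(heap, (nd, v))
            elif v not in done and abs(nd - cur) <= _EPS:
                # equal-cost tie: prefer fewer hops, then smaller predecessor;
                # hop ordering keeps parent chains acyclic on zero-cost edges
                if (hops[u] + 1, u) < (hops[v], parent[v] or u):
                    hops[v] = hops[u] + 1
                    parent[v] = u
    return dist, parent


def extract_path(parent: dict[str, str | None], target: str) -> list[str]:
    path = [target]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])  # type: ignore[arg-type]
    path.reverse()
    return path


def _path_edges(net: InteractionNetwork, path: list[str]) -> list[Edge]:
    out = []
    for u, v in zip(path, path[1:]):
        e = net.get_edge(u, v)
        if e is None:
            raise ValueError(f"path uses a non-edge {u}->{v}")
        out.append(e)
    return out


# -- objective ---------------------------------------------------------


def objective_value(
    inst: RootedInstance, H: InteractionNetwork
) -> tuple[float, float, float]:
    """(size_term, path_term, combined) of subgraph ``H`` for ``inst``.

    ``size_term`` is the summed edge cost of ``H``; ``path_term`` sums,
    over terminals, the minimum in-``H`` root-to-terminal path cost
    (PDI direction respected).  Raises if a terminal is unreachable.
    """
    size_term = sum(e.cost for e in H.edges)
    dist, _ = dijkstra(directed_adjacency(H), inst.root)
    path_term = 0.0
    for t in sorted(inst.terminals):
        d = dist.get(t, INF)
        if d == INF:
            raise ValueError(f"terminal {t!r} unreachable inside the subgraph")
        path_term += d
    combined = inst.alpha * size_term + (1.0 - inst.alpha) * path_term
    return size_term, path_term, combined


def path_likelihood(net: InteractionNetwork, path: list[str]) -> float:
    """Product of edge confidences along ``path`` (= exp(-total cost))."""
    like = 1.0
    for e in _path_edges(net, path):
        like *= e.p
    return like


# -- Steiner 2-approximation via metric closure ------------------------


def _steiner_union(
    net: InteractionNetwork, S: list[str]
) -> tuple[InteractionNetwork, bool]:
    """2-approximate Steiner subgraph over node set ``S``.

    Metric closure (pairwise direction-respecting shortest-path costs,
    symmetrized by the cheaper direction), minimum spanning tree,
    expansion to real paths, then repeated removal of non-``S`` leaves.
    Returns (subgraph, fully_connected_flag).
    """
    S = sorted(set(S))
    adj = directed_adjacency(net)
    sssp = {s: dijkstra(adj, s) for s in S}
    closure = []
    for s, t in itertools.combinations(S, 2):
        fwd = sssp[s][0].get(t, INF)
        rev = sssp[t][0].get(s, INF)
        if fwd == INF and rev == INF:
            continue
        w, direction = (fwd, "fwd") if fwd <= rev else (rev, "rev")
        closure.append((w, s, t, direction))
    closure.sort()
    # Kruskal on the closure
    comp = {s: s for s in S}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    sub = InteractionNetwork(nodes=S)
    n_joined = 0
    for w, s, t, direction in closure:
        rs, rt = find(s), find(t)
        if rs == rt:
            continue
        comp[max(rs, rt)] = min(rs, rt)
        n_joined += 1
        path = (
            extract_path(sssp[s][1], t) if direction == "fwd" else extract_path(sssp[t][1], s)
        )
        for e in _path_edges(net, path):
            sub.add_edge(e)
    connected = n_joined == len(S) - 1
    _trim_leaves(sub, set(S))
    return sub, connected


def _trim_leaves(sub: InteractionNetwork, keep: set[str]) -> None:
    """Repeatedly drop degree-1 nodes outside ``keep`` (in place by rebuild)."""
    while True:
        deg: dict[str, int] = {n: 0 for n in sub.nodes}
        for e in sub.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        drop = {n for n, d in deg.items() if d <= 1 and n not in keep}
        if not drop:
            return
        pruned = sub.without_nodes(drop)
        sub._edges = pruned._edges  # noqa: SLF001 - in-place rebuild
        sub._nodes = pruned._nodes  # noqa: SLF001


# -- anchored approximate solver ---------------------------------------


def _reachable_terminals(
    inst: RootedInstance, nodes: set[str]
) -> tuple[set[str], set[str], dict, dict]:
    adj = directed_adjacency(inst.net)
    dist, parent = dijkstra(adj, inst.root)
    reach = {t for t in nodes if dist.get(t, INF) < INF}
    return reach, nodes - reach, dist, parent


def _sp_union(
    inst: RootedInstance, targets: list[str], parent: dict[str, str | None]
) -> InteractionNetwork:
    sub = InteractionNetwork(nodes=[inst.root])
    for t in sorted(targets):
        for e in _path_edges(inst.net, extract_path(parent, t)):
            sub.add_edge(e)
    return sub


def _restrict_to_paths(
    inst: RootedInstance, H: InteractionNetwork, targets: set[str]
) -> InteractionNetwork:
    """Keep only edges on some chosen min-cost in-H root path (parsimony)."""
    _, parent = dijkstra(directed_adjacency(H), inst.root)
    sub = InteractionNetwork(nodes=[inst.root])
    for t in sorted(targets):
        for e in _path_edges(H, extract_path(parent, t)):
            sub.add_edge(e)
    return sub


def _feasible(inst: RootedInstance, H: InteractionNetwork, targets: set[str]) -> bool:
    dist, _ = dijkstra(directed_adjacency(H), inst.root)
    return all(dist.get(t, INF) < INF for t in targets)


def anchored_approx(
    inst: RootedInstance,
    required: set[str] | None = None,
    excluded: set[str] | None = None,
) -> SolutionNetwork:
    """Approximate anchored reconstruction.

    Builds two candidates -- the union of minimum-cost root-to-terminal
    paths, and a 2-approximate Steiner tree over root + terminals (+
    required nodes) -- keeps the one with the lower combined objective,
    then greedily prunes connectors and redundant edges while no
    terminal disconnects and the objective does not increase.

    Required nodes join the connectivity requirement but do not
    contribute to ``path_term``; excluded nodes are deleted up front.
    Terminals left unreachable are dropped with a warning.
    """
    required = set(required or ())
    excluded = set(excluded or ())
    if excluded & (inst.anchors | inst.terminals | required | {inst.root}):
        raise ValueError("cannot exclude anchors, terminals or required nodes")
    work = inst
    if excluded:
        work = RootedInstance(
            inst.net.without_nodes(excluded), inst.anchors, inst.terminals, inst.alpha, inst.root
        )

    reach, unreachable, dist0, parent0 = _reachable_terminals(work, work.terminals)
    if not reach:
        raise ValueError("no terminal is reachable from the anchors")
    if unreachable:
        warnings.warn(f"dropping unreachable terminals: {sorted(unreachable)}")
    req_reach = {r for r in required if dist0.get(r, INF) < INF}
    if required - req_reach:
        warnings.warn(f"dropping unreachable required nodes: {sorted(required - req_reach)}")

    eff = RootedInstance(work.net, work.anchors, reach, work.alpha, work.root)
    connect = sorted(reach | req_reach)

    cand_a = _sp_union(eff, connect, parent0)
    cand_b, _ = _steiner_union(eff.net, [eff.root, *connect])
    for t in connect:  # feasibility repair of the Steiner candidate
        if not _feasible(eff, cand_b, {t}):
            for e in _path_edges(eff.net, extract_path(parent0, t)):
                cand_b.add_edge(e)

    def combined(H: InteractionNetwork) -> float:
        size = sum(e.cost for e in H.edges)
        d, _ = dijkstra(directed_adjacency(H), eff.root)
        path = sum(d[t] for t in sorted(reach))
        return eff.alpha * size + (1.0 - eff.alpha) * path

    H = cand_a if combined(cand_a) <= combined(cand_b) + _EPS else cand_b

    # prune connectors whose removal keeps feasibility and the objective
    protected = eff.anchors | reach | req_reach | {eff.root}
    targets = reach | req_reach
    best = combined(H)
    changed = True
    while changed:
        changed = False
        for n in sorted(H.nodes - protected):
            trial = H.without_nodes({n})
            if _feasible(eff, trial, targets):
                val = combined(trial)
                if val <= best + _EPS:
                    H, best, changed = trial, val, True
    H = _restrict_to_paths(eff, H, targets)

    size_term, path_term, comb = objective_value(eff, H)
    _, parent_h = dijkstra(directed_adjacency(H), eff.root)
    paths = {t: extract_path(parent_h, t) for t in sorted(reach)}

    roles: dict[str, str] = {}
    for n in sorted(H.nodes):
        if n == ROOT:
            roles[n] = "root"
        elif n in eff.anchors:
            roles[n] = "anchor"
        elif n in reach:
            roles[n] = "terminal"
        else:
            roles[n] = "connector"
    return SolutionNetwork(
        network=H,
        node_roles=roles,
        paths=paths,
        objective=(size_term, path_term, comb),
        alpha=eff.alpha,
        optimal=False,
        unreachable_terminals=set(unreachable),
        root=eff.root,
    )


# -- other query modes -------------------------------------------------


def general_reconstruct(
    net: InteractionNetwork, terminals: set[str], alpha: float = 0.25
) -> SolutionNetwork:
    """Parsimonious network connecting the terminals (no anchors).

    A 2-approximate Steiner tree over the terminal set under edge costs;
    terminal groups in different connected components are solved
    per component (with a warning).  ``path_term`` is 0 by convention.
    """
    terminals = set(terminals)
    if len(terminals) < 2:
        raise ValueError("general reconstruction needs at least 2 terminals")
    missing = terminals - net.nodes
    if missing:
        raise ValueError(f"terminals not in network: {sorted(missing)}")
    sub, connected = _steiner_union(net, sorted(terminals))
    if not connected:
        warnings.warn("terminals span multiple connected components; solved per component")
    size_term = sum(e.cost for e in sub.edges)
    roles = {
        n: ("terminal" if n in terminals else "connector") for n in sorted(sub.nodes)
    }
    return SolutionNetwork(
        network=sub,
        node_roles=roles,
        paths={},
        objective=(size_term, 0.0, alpha * size_term),
        alpha=alpha,
        optimal=False,
        root=None,
    )


@dataclass
class PathResult:
    anchor: str
    terminal: str
    path: list[str] = field(default_factory=list)
    cost: float = INF
    likelihood: float = 0.0
    reachable: bool = False


def shortest_paths_query(
    net: InteractionNetwork, anchors: set[str], terminals: set[str]
) -> dict[tuple[str, str], PathResult]:
    """Most likely (minimum-cost) path for every anchor-terminal pair.

    Unreachable pairs are flagged, not errors.
    """
    adj = directed_adjacency(net)
    out: dict[tuple[str, str], PathResult] = {}
    for a in sorted(anchors):
        dist, parent = dijkstra(adj, a)
        for t in sorted(terminals):
            d = dist.get(t, INF)
            if d == INF:
                out[(a, t)] = PathResult(a, t)
            else:
                p = extract_path(parent, t)
                out[(a, t)] = PathResult(a, t, p, d, math.exp(-d), True)
    return out


def local_search(
    net: InteractionNetwork, terminals: set[str], depth: int
) -> InteractionNetwork:
    """Induced subgraph on nodes within ``depth`` hops (direction ignored)."""
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    frontier = set(terminals) & net.nodes
    seen = set(frontier)
    und: dict[str, set[str]] = {n: set() for n in net.nodes}
    for e in net.edges:
        und[e.u].add(e.v)
        und[e.v].add(e.u)
    for _ in range(depth):
        frontier = {v for u in frontier for v in und[u]} - seen
        if not frontier:
            break
        seen |= frontier
    return net.subnetwork(seen)


def solve_query(net: InteractionNetwork, query: Query, exact: bool = False):
    """Dispatch a query to the matching solver (library convenience)."""
    if query.mode == "anchored":
        inst = RootedInstance.build(
            net.without_nodes(query.excluded_nodes), query.anchors, query.terminals, query.alpha
        )
        if exact:
            from .exact import solve_exact

            return solve_exact(inst, required=query.required_nodes)
        return anchored_approx(inst, required=query.required_nodes)
    if query.mode == "general":
        return general_reconstruct(
            net.without_nodes(query.excluded_nodes), query.terminals, query.alpha
        )
    if query.mode == "shortest_paths":
        return shortest_paths_query(net, query.anchors, query.terminals)
    if query.mode == "local_search":
        return local_search(net, query.terminals, query.depth)
    raise ValueError(f"unknown query mode {query.mode!r}")
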