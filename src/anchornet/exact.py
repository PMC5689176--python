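"""Exact anchored reconstruction by integer linear programming.

The formulation carries one binary ``x_e`` per background edge, one
binary ``y_v`` per node, and per-terminal unit flows ``f_{t,a}`` over
arcs (each PPI contributes two arcs, each PDI one).  Flow conservation
routes one unit from the root to each terminal; ``f <= x`` couples
flows to selected edges; the objective is::

    alpha * sum_e cost(e) x_e + (1 - alpha) * sum_t sum_a cost(a) f_{t,a}

so the ILP minimizes exactly the combined objective of the approximate
solver.  Flows are continuous in [0, 1]: with binary ``x`` an optimal
extreme point is integral per terminal; integrality of the recovered
paths is verified and the solve falls back to binary flows otherwise.

The default backend is HiGHS via :func:`scipy.optimize.milp`; any
solver honouring the "minimize a linear objective under linear
constraints with binaries" contract can be swapped in.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .netio import PPI, ROOT, InteractionNetwork, SolutionNetwork
from .reconstruct import (
    RootedInstance,
    _restrict_to_paths,
    dijkstra,
    directed_adjacency,
    extract_path,
    objective_value,
)

INF = math.inf

#: Advisory wall-clock limit (seconds) after which the incumbent is
#: returned and the approximate solver is recommended.
DEFAULT_TIME_LIMIT = 1800.0


class InfeasibleInstanceError(ValueError):
    """A terminal cannot be reached from the root in the background net."""


def _check_reachability(inst: RootedInstance, sinks: set[str]) -> None:
    dist, _ = dijkstra(directed_adjacency(inst.net), inst.root)
    bad = sorted(s for s in sinks if dist.get(s, INF) == INF)
    if bad:
        raise InfeasibleInstanceError(f"unreachable from the anchors: {bad}")


def solve_exact(
    inst: RootedInstance,
    time_limit: float = DEFAULT_TIME_LIMIT,
    required: set[str] | None = None,
    integral_flows: bool = False,
) -> SolutionNetwork:
    """Solve the anchored reconstruction to proven optimality.

    Returns ``optimal=True`` when the solver proves optimality; if the
    time limit is hit the incumbent is returned with ``optimal=False``
    and a warning advising the approximation algorithm.  Required nodes
    receive a zero-cost flow (connectivity without a path-term
    contribution).
    """
    required = sorted(set(required or ()) - inst.anchors - inst.terminals)
    terminals = sorted(inst.terminals)
    sinks = terminals + [r for r in required if r not in terminals]
    _check_reachability(inst, set(sinks))

    edges = inst.net.edges
    nodes = sorted(inst.net.nodes)
    nidx = {n: i for i, n in enumerate(nodes)}
    n_e, n_v, n_s = len(edges), len(nodes), len(sinks)

    arcs: list[tuple[int, int, int, float]] = []  # (edge_idx, u, v, cost)
    for j, e in enumerate(edges):
        arcs.append((j, nidx[e.u], nidx[e.v], e.cost))
        if e.kind == PPI:
            arcs.append((j, nidx[e.v], nidx[e.u], e.cost))
    n_a = len(arcs)

    # variable layout: x (edges) | y (nodes) | f (sink-major over arcs)
    off_y = n_e
    off_f = n_e + n_v
    n_var = off_f + n_s * n_a

    c = np.zeros(n_var)
    for j, e in enumerate(edges):
        c[j] = inst.alpha * e.cost
    for s, sink in enumerate(sinks):
        if sink in inst.terminals:
            for a, (_, _, _, cost) in enumerate(arcs):
                c[off_f + s * n_a + a] = (1.0 - inst.alpha) * cost

    rows, cols, vals = [], [], []
    r = 0
    # f_{s,a} <= x_{e(a)}
    for s in range(n_s):
        for a, (j, _, _, _) in enumerate(arcs):
            rows += [r, r]
            cols += [off_f + s * n_a + a, j]
            vals += [1.0, -1.0]
            r += 1
    # x_e <= y_u, x_e <= y_v
    for j, e in enumerate(edges):
        for endpoint in (e.u, e.v):
            rows += [r, r]
            cols += [j, off_y + nidx[endpoint]]
            vals += [1.0, -1.0]
            r += 1
    n_ub = r
    a_ub = sp.csr_matrix((vals, (rows, cols)), shape=(n_ub, n_var))

    rows, cols, vals = [], [], []
    b_eq = np.zeros(n_s * n_v)
    r = 0
    root_i = nidx[inst.root]
    for s, sink in enumerate(sinks):
        for vi in range(n_v):
            b_eq[r] = 1.0 if vi == root_i else (-1.0 if vi == nidx[sink] else 0.0)
            r += 1
        for a, (_, ui, wi, _) in enumerate(arcs):
            col = off_f + s * n_a + a
            rows += [s * n_v + ui, s * n_v + wi]
            cols += [col, col]
            vals += [1.0, -1.0]
    a_eq = sp.csr_matrix((vals, (rows, cols)), shape=(n_s * n_v, n_var))

    integrality = np.zeros(n_var)
    integrality[: off_f] = 1
    if integral_flows:
        integrality[:] = 1
    bounds = Bounds(np.zeros(n_var), np.ones(n_var))

    res = milp(
        c=c,
        constraints=[
            LinearConstraint(a_ub, -np.inf, np.zeros(n_ub)),
            LinearConstraint(a_eq, b_eq, b_eq),
        ],
        integrality=integrality,
        bounds=bounds,
        options={"time_limit": float(time_limit)},
    )
    if res.x is None:
        raise RuntimeError(f"ILP solve failed: {res.message}")
    proven = res.status == 0
    if not proven:
        warnings.warn(
            "time limit reached before proven optimality; returning the "
            "incumbent -- consider the approximation algorithm instead"
        )

    chosen = [e for j, e in enumerate(edges) if res.x[j] > 0.5]
    H = InteractionNetwork(chosen, nodes=[inst.root])
    eff = RootedInstance(inst.net, inst.anchors, inst.terminals, inst.alpha, inst.root)

    # verify the continuous flows decompose into integral paths: each
    # terminal's flow cost must match its in-H shortest-path cost
    dist_h, _ = dijkstra(directed_adjacency(H), inst.root)
    ok = True
    for s, sink in enumerate(sinks):
        if sink not in inst.terminals:
            continue
        fcost = float(
            sum(res.x[off_f + s * n_a + a] * cost for a, (_, _, _, cost) in enumerate(arcs))
        )
        if not math.isclose(fcost, dist_h.get(sink, INF), abs_tol=1e-6):
            ok = False
            break
    if not ok and not integral_flows:
        return solve_exact(inst, time_limit, set(required), integral_flows=True)

    H = _restrict_to_paths(eff, H, set(sinks))
    size_term, path_term, combined = objective_value(eff, H)
    _, parent = dijkstra(directed_adjacency(H), inst.root)
    paths = {t: extract_path(parent, t) for t in terminals}

    roles = {}
    for n in sorted(H.nodes):
        if n == ROOT:
            roles[n] = "root"
        elif n in inst.anchors:
            roles[n] = "anchor"
        elif n in inst.terminals:
            roles[n] = "terminal"
        else:
            roles[n] = "connector"
    return SolutionNetwork(
        network=H,
        node_roles=roles,
        paths=paths,
        objective=(size_term, path_term, combined),
        alpha=inst.alpha,
        optimal=proven,
        root=inst.root,
    )


def brute_force_oracle(
    inst: RootedInstance,
    required: set[str] | None = None,
    max_edges: int = 20,
) -> SolutionNetwork:
    """Verification oracle: exhaustive enumeration over edge subsets.

    Keeps every subset in which all terminals (and required nodes) are
    root-reachable respecting PDI direction, and returns the one with
    the minimum combined objective; ties break on the lexicographically
    smallest edge set.  Guarded to at most ``max_edges`` edges.
    """
    required = set(required or ()) - inst.anchors - inst.terminals
    edges = inst.net.edges
    m = len(edges)
    if m > max_edges:
        raise ValueError(f"instance has {m} edges, above the enumeration guard {max_edges}")
    nodes = sorted(inst.net.nodes)
    nidx = {n: i for i, n in enumerate(nodes)}
    root_i = nidx[inst.root]
    term_is = sorted(nidx[t] for t in inst.terminals)
    sink_is = sorted({*term_is, *(nidx[rq] for rq in required)})
    costs = [e.cost for e in edges]
    arcs_of_edge = []
    for e in edges:
        a = [(nidx[e.u], nidx[e.v], e.cost)]
        if e.kind == PPI:
            a.append((nidx[e.v], nidx[e.u], e.cost))
        arcs_of_edge.append(a)

    # incremental subset sizes: size[mask] = size[mask minus low bit] + cost
    size = np.zeros(1 << m)
    for mask in range(1, 1 << m):
        low = mask & -mask
        size[mask] = size[mask ^ low] + costs[low.bit_length() - 1]

    alpha = inst.alpha
    best: tuple[float, tuple, int] | None = None
    for mask in range(1 << m):
        lower = alpha * size[mask]
        if best is not None and lower > best[0] + 1e-12:
            continue
        # Dijkstra from the root over arcs present in the mask
        adj: dict[int, list[tuple[int, float]]] = {}
        mm = mask
        while mm:
            low = mm & -mm
            for u, v, cst in arcs_of_edge[low.bit_length() - 1]:
                adj.setdefault(u, []).append((v, cst))
            mm ^= low
        dist = _mini_dijkstra(adj, root_i)
        if any(dist.get(si, INF) == INF for si in sink_is):
            continue
        combined = alpha * size[mask] + (1.0 - alpha) * sum(dist[t] for t in term_is)
        keys = tuple(edges[j].key() for j in range(m) if mask >> j & 1)
        if (
            best is None
            or combined < best[0] - 1e-12
            or (abs(combined - best[0]) <= 1e-12 and keys < best[1])
        ):
            best = (combined, keys, mask)
    if best is None:
        raise InfeasibleInstanceError("no edge subset connects the root to all terminals")

    chosen = [edges[j] for j in range(m) if best[2] >> j & 1]
    H = InteractionNetwork(chosen, nodes=[inst.root])
    eff = RootedInstance(inst.net, inst.anchors, inst.terminals, inst.alpha, inst.root)
    H = _restrict_to_paths(eff, H, set(inst.terminals) | required)
    size_term, path_term, combined = objective_value(eff, H)
    _, parent = dijkstra(directed_adjacency(H), inst.root)
    paths = {t: extract_path(parent, t) for t in sorted(inst.terminals)}
    roles = {
        n: (
            "root"
            if n == ROOT
            else "anchor"
            if n in inst.anchors
            else "terminal"
            if n in inst.terminals
            else "connector"
        )
        for n in sorted(H.nodes)
    }
    return SolutionNetwork(
        network=H,
        node_roles=roles,
        paths=paths,
        objective=(size_term, path_term, combined),
        alpha=inst.alpha,
        optimal=True,
        root=inst.root,
    )


def _mini_dijkstra(adj: dict[int, list[tuple[int, float]]], source: int) -> dict[int, float]:
    import heapq

    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, INF):
            continue
        for v, c in adj.get(u, ()):
            nd = d + c
            if nd < dist.get(v, INF) - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist
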