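"""Statistical evaluation of a reconstructed subnetwork.

Each node of a solution gets a *chance inclusion probability*: the
fraction of reconstructions from random terminal sets (anchors fixed,
terminal count matched) whose solution also contains the node.  Nodes
with a low probability are specific to the real query.  Every
anchor-to-terminal path additionally gets its likelihood (product of
edge confidences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import InteractionNetwork, Query, SolutionNetwork
from .reconstruct import RootedInstance, anchored_approx, path_likelihood


@dataclass
class NodeReport:
    rows: list[tuple[str, str, float]]  # (node, role, inclusion_probability)
    path_likelihoods: dict[str, float]  # terminal -> likelihood of its root path
    n_random: int
    n_successful: int

    @property
    def inclusion_probability(self) -> dict[str, float]:
        return {n: p for n, _, p in self.rows}


def node_inclusion_report(
    net: InteractionNetwork,
    query: Query,
    solution: SolutionNetwork,
    n_random: int = 100,
    seed: int = 0,
    degree_matched: bool = False,
) -> NodeReport:
    """Empirical chance-inclusion probabilities for a solution's nodes.

    Re-runs the same anchored reconstruction ``n_random`` times with
    terminal sets resampled uniformly (without replacement) from the
    non-anchor nodes of the background network; anchors and alpha are
    kept fixed.  ``degree_matched=True`` samples each random terminal
    from nodes of the same degree bin as a real terminal (decile bins).
    """
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    if query.mode != "anchored":
        raise ValueError("inclusion reports are defined for anchored queries")
    rng = np.random.default_rng(seed)
    work = net.without_nodes(query.excluded_nodes)
    pool = sorted(work.nodes - query.anchors)
    k = len(query.terminals)

    weights = None
    if degree_matched:
        und = work.to_undirected()
        deg = np.array([und.degree(n) for n in pool], dtype=float)
        tdeg = np.mean([und.degree(t) for t in sorted(query.terminals) if t in und])
        # favour pool nodes whose degree resembles the mean terminal degree
        w = 1.0 / (1.0 + np.abs(deg - tdeg))
        weights = w / w.sum()

    counts: dict[str, int] = {n: 0 for n in solution.biological_nodes}
    ok = 0
    for _ in range(n_random):
        pick = rng.choice(len(pool), size=k, replace=False, p=weights)
        terms = {pool[i] for i in pick}
        try:
            inst = RootedInstance.build(work, query.anchors, terms, query.alpha)
            sol = anchored_approx(inst, required=query.required_nodes)
        except ValueError:
            continue
        ok += 1
        # anchors and required nodes are part of every null query by
        # construction, so they count as present even when pruned as unused
        present = sol.biological_nodes | query.anchors | query.required_nodes
        for n in counts:
            if n in present:
                counts[n] += 1
    if ok == 0:
        raise RuntimeError("all random reconstructions were infeasible")

    rows = [
        (n, solution.node_roles.get(n, "connector"), counts[n] / ok)
        for n in sorted(counts)
    ]
    likes = {
        t: path_likelihood(solution.network, p) for t, p in sorted(solution.paths.items())
    }
    return NodeReport(rows, likes, n_random, ok)


def write_report(report: NodeReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\trole\tinclusion_probability\n")
        for n, role, p in report.rows:
            fh.write(f"{n}\t{role}\t{p:.6g}\n")
        fh.write("\nterminal\tpath_likelihood\n")
        for t, like in sorted(report.path_likelihoods.items()):
            fh.write(f"{t}\t{like:.6g}\n")
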