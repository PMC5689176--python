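"""Endpoint-set inference: transcription factors as refined terminals,
and anchors via network propagation with an empirical null.

Transcription-factor prediction asks which TFs are significantly
enriched for the query terminals among their known targets
(hypergeometric upper tail, Benjamini-Hochberg control).  Terminals not
covered by any enriched TF are eliminated, and the enriched TFs serve
as terminals of the subsequent anchored search.

Anchor prediction propagates terminal scores over the network:
``s_v <- (1 - beta) * prior_v + beta * mean_{u in N(v)} s_u`` until a
fixed point, then keeps candidate nodes whose score beats every one of
``n_random`` propagations seeded from random node sets of terminal
size.  Up to ``max_anchors`` top-scoring, pairwise non-adjacent
survivors are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import InteractionNetwork

DEFAULT_BETA = 0.8
DEFAULT_FDR = 0.05


# -- hypergeometric kernel ---------------------------------------------


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` successes in the universe, ``n`` draws,
    ``k`` observed successes.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n):
        raise ValueError(f"invalid hypergeometric arguments N={N} K={K} n={n} k={k}")
    if k <= 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# -- transcription-factor prediction -----------------------------------


@dataclass
class EnrichmentResult:
    tf: str
    n_targets: int
    overlap: int
    p_value: float
    q_value: float
    associated_terminals: set[str]
    enriched: bool = False


def predict_tfs(
    tf_targets: Mapping[str, set[str]],
    terminals: set[str],
    universe: set[str],
    fdr: float = DEFAULT_FDR,
) -> tuple[list[EnrichmentResult], set[str], set[str]]:
    """Enriched transcription factors for a terminal set.

    Tests every TF with at least one target inside the universe; a TF is
    enriched when its BH q-value is at most ``fdr``.  Returns
    ``(results, refined_terminals, tf_terminals)`` where
    ``refined_terminals`` keeps only terminals covered by some enriched
    TF and ``tf_terminals`` are the enriched TFs themselves (the
    terminal set of the downstream anchored query).
    """
    if not tf_targets:
        raise ValueError("no TF -> target table supplied")
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must lie in (0, 1)")
    terminals = set(terminals)
    universe = set(universe)
    if not terminals <= universe:
        raise ValueError("terminals must be contained in the universe")
    N = len(universe)
    n = len(terminals)
    results: list[EnrichmentResult] = []
    for tf in sorted(tf_targets):
        targets = set(tf_targets[tf]) & universe
        if not targets:
            continue
        assoc = targets & terminals
        p = hypergeom_upper_tail(N, len(targets), n, len(assoc))
        results.append(EnrichmentResult(tf, len(targets), len(assoc), p, 1.0, assoc))
    if not results:
        warnings.warn("no TF has targets inside the universe")
        return [], set(terminals), set()
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
        r.enriched = q <= fdr
    results.sort(key=lambda r: (r.p_value, r.tf))
    enriched = [r for r in results if r.enriched]
    if not enriched:
        warnings.warn("no enriched transcription factor; keeping the original terminals")
        return results, set(terminals), set()
    refined = set().union(*(r.associated_terminals for r in enriched))
    return results, refined, {r.tf for r in enriched}


# -- network propagation -----------------------------------------------


@dataclass
class PropagationResult:
    scores: dict[str, float]
    iterations: int
    converged: bool
    candidates: list[tuple[str, float, float]] = field(default_factory=list)


def _propagation_matrix(net: InteractionNetwork) -> tuple[list[str], sp.csr_matrix]:
    """Row-normalized undirected adjacency (neighbor-mean operator)."""
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for e in net.edges:
        rows += [idx[e.u], idx[e.v]]
        cols += [idx[e.v], idx[e.u]]
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    P = sp.diags(inv) @ A
    return nodes, P.tocsr()


def propagate(
    net: InteractionNetwork,
    priors: Mapping[str, float],
    beta: float = DEFAULT_BETA,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationResult:
    """Iterate ``s <- (1 - beta) * prior + beta * P s`` to a fixed point.

    ``P`` is the neighbor-mean operator on the undirected view; isolated
    nodes keep their prior.  ``beta`` in ``[0, 1)`` guarantees
    contraction and hence convergence.
    """
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must lie in [0, 1) for the update to contract")
    nodes, P = _propagation_matrix(net)
    prior = np.array([float(priors.get(n, 0.0)) for n in nodes])
    deg0 = np.asarray((P != 0).sum(axis=1)).ravel() == 0
    s = prior.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = (1.0 - beta) * prior + beta * (P @ s)
        new[deg0] = prior[deg0]
        delta = float(np.max(np.abs(new - s)))
        s = new
        if delta < tol:
            converged = True
            break
    return PropagationResult(dict(zip(nodes, s.tolist())), it, converged)


def predict_anchors(
    net: InteractionNetwork,
    terminals: set[str],
    n_candidates: int = 100,
    n_random: int = 100,
    max_anchors: int = 3,
    beta: float = DEFAULT_BETA,
    seed: int = 0,
    tol: float = 1e-6,
) -> tuple[list[str], PropagationResult]:
    """Propose up to ``max_anchors`` anchor proteins for a terminal set.

    1. Propagate with terminal priors 1 (others 0).
    2. Keep the top ``n_candidates`` non-terminal nodes by score.
    3. Run ``n_random`` propagations from random node sets of terminal
       size, drawn (seeded) from the non-terminal nodes.
    4. Retain candidates whose original score strictly exceeds their
       score in every random run.
    5. Greedily select survivors in descending score order, skipping any
       node adjacent (either direction, any edge kind) to one already
       selected.
    """
    terminals = set(terminals) & net.nodes
    if not terminals:
        raise ValueError("need at least one terminal present in the network")
    others = sorted(net.nodes - terminals)
    if len(others) < len(terminals):
        raise ValueError("network has fewer non-terminal nodes than terminals")

    base = propagate(net, {t: 1.0 for t in terminals}, beta=beta, tol=tol)
    ranked = sorted(others, key=lambda n: (-base.scores[n], n))
    candidates = ranked[:n_candidates]

    rng = np.random.default_rng(seed)
    n_ge = {c: 0 for c in candidates}  # random runs scoring >= the original
    pool = np.array(others)
    for _ in range(n_random):
        pick = rng.choice(pool.size, size=len(terminals), replace=False)
        rand_priors = {pool[i]: 1.0 for i in pick}
        res = propagate(net, rand_priors, beta=beta, tol=tol)
        for c in candidates:
            # a run that happens to draw the candidate itself as a seed
            # inflates its null score trivially; not a fair comparison
            if c in rand_priors:
                continue
            if res.scores[c] >= base.scores[c]:
                n_ge[c] += 1
    survivors = [c for c in candidates if n_ge[c] == 0]
    base.candidates = [
        (c, base.scores[c], (1 + n_ge[c]) / (n_random + 1)) for c in candidates
    ]

    und = net.to_undirected()
    selected: list[str] = []
    for c in sorted(survivors, key=lambda n: (-base.scores[n], n)):
        if len(selected) >= max_anchors:
            break
        if any(und.has_edge(c, s) for s in selected):
            continue
        selected.append(c)
    if not selected:
        warnings.warn("no candidate anchor survived the empirical null")
    return selected, base
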