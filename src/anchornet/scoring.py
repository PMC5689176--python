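"""Interaction confidence scoring by logistic regression.

Each interaction carries a vector of nonnegative evidence counts (one
per experimental evidence type, e.g. number of supporting two-hybrid
experiments, number of distinct publications).  A logistic model maps
evidence to a confidence in (0, 1) that is directly usable as an edge
probability by :mod:`anchornet.netio`.

Training data: curated *positive* interactions (e.g. pathway-database
edges) against *negative* interactions sampled from edges whose
endpoints are far apart once the edge itself is removed -- an edge that
is the only short route between its endpoints is unlikely to be a
spurious observation, so the far-apart ones make cleaner negatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .netio import InteractionNetwork


@dataclass(frozen=True)
class EvidenceRecord:
    """Evidence feature counts for one interaction pair."""

    pair: tuple[str, str]
    features: tuple[float, ...]


@dataclass
class ConfidenceModel:
    """Fitted logistic model: score = sigmoid(intercept + coef . features)."""

    intercept: float
    coefficients: np.ndarray
    lam: float
    schema: tuple[str, ...]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.schema) != self.coefficients.size:
            raise ValueError("feature schema length must match coefficient length")

    def predict(self, features) -> float:
        x = np.asarray(features, dtype=float)
        if x.size != self.coefficients.size:
            raise ValueError(
                f"expected {self.coefficients.size} features, got {x.size}"
            )
        return _sigmoid(self.intercept + float(self.coefficients @ x))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def build_training_set(
    net: InteractionNetwork,
    positives: Iterable[tuple[str, str]],
    min_distance: int = 3,
    n_negatives: int = 100,
    seed: int = 0,
) -> list[tuple[tuple[str, str], int]]:
    """Label curated positives 1 and sample distance-based negatives 0.

    An edge (u, v) is an eligible negative when the shortest-path hop
    distance between u and v in the network *with that edge removed* is
    at least ``min_distance`` (disconnection counts as infinite, hence
    eligible).  Negatives are sampled uniformly without replacement,
    seeded; positives are never sampled.  If fewer than ``n_negatives``
    edges are eligible, all of them are returned with a warning.
    """
    if min_distance < 2:
        raise ValueError("min_distance must be at least 2")
    pos_keys = set()
    for u, v in positives:
        e = net.get_edge(u, v)
        if e is None:
            raise ValueError(f"positive pair {u}-{v} is not an edge of the network")
        pos_keys.add(e.key())
    g = net.to_undirected()
    eligible = []
    for e in net.edges:
        if e.key() in pos_keys:
            continue
        g.remove_edge(e.u, e.v)
        try:
            d = nx.shortest_path_length(g, e.u, e.v)
        except nx.NetworkXNoPath:
            d = math.inf
        g.add_edge(e.u, e.v)
        if d >= min_distance:
            eligible.append(e)
    if len(eligible) < n_negatives:
        warnings.warn(
            f"only {len(eligible)} eligible negatives for requested {n_negatives}"
        )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=n_negatives, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    out = [((u, v), 1) for (u, v) in sorted((min(u, v), max(u, v)) for u, v in positives)]
    out += [((e.u, e.v), 0) for e in chosen]
    return out


def fit_confidence_model(
    records: Sequence[EvidenceRecord],
    labels: Sequence[int],
    lam: float = 1e-4,
    schema: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ConfidenceModel:
    """Maximize the L2-penalized Bernoulli log-likelihood (logit link).

    Damped Newton iterations on the convex objective
    ``-loglik + lam/2 * ||coef||^2`` (intercept unpenalized), stopped
    when the gradient max-norm falls below ``tol``.  Deterministic for
    fixed input.
    """
    if lam < 0:
        raise ValueError("regularization strength must be nonnegative")
    y = np.asarray(labels, dtype=float)
    if y.size == 0 or len(records) != y.size:
        raise ValueError("records and labels must be nonempty and aligned")
    if y.min() == y.max():
        raise ValueError("need at least one record of each label")
    X = np.array([r.features for r in records], dtype=float)
    n, k = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    pen = np.full(k + 1, lam)
    pen[0] = 0.0

    w = np.zeros(k + 1)

    def objective(wv):
        z = Xd @ wv
        # log(1 + exp(z)) - y z, stable
        return float(np.sum(np.logaddexp(0.0, z) - y * z) + 0.5 * np.sum(pen * wv**2))

    obj = objective(w)
    for _ in range(max_iter):
        z = Xd @ w
        p = _sigmoid(z)
        grad = Xd.T @ (p - y) + pen * w
        if np.max(np.abs(grad)) < tol:
            break
        wgt = np.clip(p * (1.0 - p), 1e-12, None)
        hess = (Xd * wgt[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t = 1.0
        while t > 1e-8:
            cand = w - t * step
            cobj = objective(cand)
            if cobj <= obj + 1e-15:
                w, obj = cand, cobj
                break
            t *= 0.5
        else:  # pragma: no cover - should not happen on a convex objective
            break
    if schema is None:
        schema = tuple(f"f{i}" for i in range(k))
    return ConfidenceModel(float(w[0]), w[1:], lam, tuple(schema))


def penalized_gradient(model: ConfidenceModel, records, labels) -> np.ndarray:
    """Gradient of the penalized negative log-likelihood at the model."""
    y = np.asarray(labels, dtype=float)
    X = np.array([r.features for r in records], dtype=float)
    Xd = np.hstack([np.ones((len(records), 1)), X])
    w = np.concatenate([[model.intercept], model.coefficients])
    pen = np.concatenate([[0.0], np.full(model.coefficients.size, model.lam)])
    p = _sigmoid(Xd @ w)
    return Xd.T @ (p - y) + pen * w


def score_interactions(
    model: ConfidenceModel, records: Sequence[EvidenceRecord]
) -> dict[tuple[str, str], float]:
    """Confidence score in (0, 1) for each record under the model."""
    out = {}
    for r in records:
        if len(r.features) != model.coefficients.size:
            raise ValueError(
                f"record {r.pair} has {len(r.features)} features, "
                f"model expects {model.coefficients.size}"
            )
        out[r.pair] = model.predict(r.features)
    return out
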