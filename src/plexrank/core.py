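"""Transition matrices and seed-biased PageRank on a two-layer network.

The walk operator for a layer is the transpose of the row-normalized
weight matrix (column-stochastic convention), so iterating

    x(n) = alpha * T x(n-1) + (1 - alpha) * p

conserves total probability mass exactly.  Dangling nodes (no edges in
the layer) have their outgoing mass redirected to the restart vector
each iteration.  Convergence is declared when the Euclidean distance
between consecutive iterates drops to the tolerance (default 1e-10).

The multiplex walk on layer B reweights each transition out of node j by
j's importance score from the layer-A walk, so that importance earned in
one layer biases the walk in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_io import SeedSet, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "RankVector",
    "ConvergenceError",
    "build_transition",
    "restart_vector",
    "pagerank_seeded",
    "multiplex_pagerank",
    "union_node_order",
    "DEFAULT_ALPHA",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

DEFAULT_ALPHA = 0.85
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


class ConvergenceError(RuntimeError):
    """Power iteration exceeded max_iter; carries the last error value."""

    def __init__(self, iterations: int, last_error: float):
        super().__init__(
            f"no convergence after {iterations} iterations (last error {last_error:.3e})"
        )
        self.iterations = iterations
        self.last_error = last_error


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-normalized transition probabilities for one layer.

    ``matrix[i, j]`` is the probability of stepping from node i to node j,
    i.e. w(i, j) = c(i, j) / sum_k c(i, k) over i's interacting partners.
    ``dangling`` flags nodes with no edge in this layer (all-zero row).
    """

    node_order: tuple[str, ...]
    matrix: sp.csr_matrix
    dangling: np.ndarray

    @property
    def n(self) -> int:
        return len(self.node_order)

    def walk_operator(self) -> sp.csr_matrix:
        """Column-stochastic operator T = matrix^T used in the iteration."""
        return self.matrix.T.tocsr()


@dataclass(frozen=True)
class RankVector:
    """Per-gene importance scores from one converged walk.

    ``provenance_tag`` is "A" for the single-layer walk on the association
    network and "AB" for the multiplex-coupled walk on the interaction
    network.  ``restart`` keeps the preference vector p actually used.
    """

    node_order: tuple[str, ...]
    scores: np.ndarray
    alpha: float
    iterations_used: int
    final_error: float
    provenance_tag: str
    restart: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        total = float(self.scores.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rank vector mass {total} deviates from 1 by > 1e-9")

    def score_of(self, node: str) -> float:
        return float(self.scores[self.node_order.index(node)])

    def as_dict(self) -> dict[str, float]:
        return {g: float(s) for g, s in zip(self.node_order, self.scores)}


def union_node_order(*nets: WeightedNetwork) -> tuple[str, ...]:
    """Lexicographic order over the union node set of all layers."""
    nodes: set[str] = set()
    for net in nets:
        nodes |= net.nodes
    return tuple(sorted(nodes))


def build_transition(net: WeightedNetwork, node_order: tuple[str, ...]) -> TransitionMatrix:
    """Row-normalize a layer's weights into a TransitionMatrix.

    ``node_order`` must cover the layer's nodes; nodes of the order absent
    from the layer (or isolated in it) are flagged dangling.
    """
    order = tuple(node_order)
    index = {g: i for i, g in enumerate(order)}
    missing = net.nodes - set(order)
    if missing:
        raise ValueError(f"node_order is missing layer nodes: {sorted(missing)[:5]}")

    m = len(order)
    rows, cols, vals = [], [], []
    for (u, v), w in net.edges.items():
        i, j = index[u], index[v]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    c = sp.csr_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)), shape=(m, m)
    )
    row_sums = np.asarray(c.sum(axis=1)).ravel()
    dangling = row_sums == 0
    if np.any((row_sums == 0) & (np.diff(c.indptr) > 0)):  # pragma: no cover
        raise ValueError("node with edges but zero total weight")
    inv = np.zeros(m)
    inv[~dangling] = 1.0 / row_sums[~dangling]
    w_mat = sp.diags(inv) @ c
    return TransitionMatrix(order, w_mat.tocsr(), dangling)


def restart_vector(seeds: SeedSet, node_order: tuple[str, ...]) -> np.ndarray:
    """Preference vector p: 1/k on each seed gene, 0 elsewhere."""
    if seeds.k < 1:
        raise ValueError("empty seed set")
    index = {g: i for i, g in enumerate(node_order)}
    p = np.zeros(len(node_order))
    for s in seeds:
        if s not in index:
            raise ValueError(f"seed {s!r} not in node order")
        p[index[s]] = 1.0 / seeds.k
    return p


def _check_walk_args(alpha: float, tol: float, p: np.ndarray, m: int) -> None:
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if not tol > 0:
        raise ValueError("tol must be positive")
    if p.shape != (m,):
        raise ValueError("restart vector length does not match node order")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("restart vector must be a probability vector")


def pagerank_seeded(
    W: TransitionMatrix,
    p: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    provenance_tag: str = "A",
) -> RankVector:
    """Seed-biased PageRank on one layer by power iteration.

    Starts from the uniform vector 1/m and iterates
    x(n) = alpha * (T x + dangling_mass * p) + (1 - alpha) * p until the
    Euclidean distance between consecutive iterates is <= tol.
    """
    m = W.n
    _check_walk_args(alpha, tol, p, m)
    T = W.walk_operator()
    d = W.dangling
    x = np.full(m, 1.0 / m)
    for it in range(1, max_iter + 1):
        x_new = alpha * (T @ x + x[d].sum() * p) + (1.0 - alpha) * p
        err = float(np.linalg.norm(x_new - x))
        x = x_new
        if err <= tol:
            return RankVector(W.node_order, x, alpha, it, err, provenance_tag, p)
    raise ConvergenceError(max_iter, err)


def _coupling_weights(x_A: RankVector, floor: float | None) -> np.ndarray:
    """Layer-A scores used to bias layer B, floored so layer-B-only genes
    (score exactly 0 in the A walk) are not annihilated by the coupling."""
    xa = np.asarray(x_A.scores, dtype=float).copy()
    positive = xa[xa > 0]
    if positive.size == 0:
        raise ValueError("layer-A rank vector has no positive entries to couple on")
    eps = float(positive.min()) if floor is None else float(floor)
    xa[xa <= 0] = eps
    return xa


def multiplex_pagerank(
    W_B: TransitionMatrix,
    x_A: RankVector,
    p: np.ndarray,
    alpha_B: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    coupling_mode: str = "literal",
    coupling_floor: float | None = None,
) -> RankVector:
    """Layer-B walk biased by layer-A importance scores.

    Implements x_i(n) = alpha_B * sum_j x_j(A) W_B(j, i) x_j(n-1)
    + (1 - alpha_B) * p(i).  In ``"literal"`` mode (default) the printed
    source-biased update is applied verbatim and the vector is
    L1-renormalized after each iteration; in ``"column_normalized"`` mode
    the layer-A score of the *target* node scales each transition and the
    coupled operator's columns are renormalized once up front — the
    multiplicative multiplex-PageRank variant (with uniform x_A it
    reduces to the plain seeded walk on layer B).  Target-side coupling is
    used there because a source-side factor cancels identically under
    column normalization.
    """
    m = W_B.n
    _check_walk_args(alpha_B, tol, p, m)
    if tuple(x_A.node_order) != tuple(W_B.node_order):
        raise ValueError("x_A and W_B do not share a node order")
    if coupling_mode not in ("literal", "column_normalized"):
        raise ValueError(f"unknown coupling_mode {coupling_mode!r}")

    T = W_B.walk_operator()
    xa = _coupling_weights(x_A, coupling_floor)

    if coupling_mode == "column_normalized":
        # target-biased multiplicative variant: M[i, j] = T[i, j] * xa[i] /
        # colmass[j] (source-side scaling would cancel under column
        # normalization); zero-mass columns dangle.
        M = T.multiply(xa[:, np.newaxis]).tocsr()
        colmass = np.asarray(M.sum(axis=0)).ravel()
        dangling = colmass == 0
        scale = np.zeros(m)
        scale[~dangling] = 1.0 / colmass[~dangling]
        M = M.multiply(scale[np.newaxis, :]).tocsr()
        x = np.full(m, 1.0 / m)
        for it in range(1, max_iter + 1):
            x_new = alpha_B * (M @ x + x[dangling].sum() * p) + (1.0 - alpha_B) * p
            err = float(np.linalg.norm(x_new - x))
            x = x_new
            if err <= tol:
                return RankVector(W_B.node_order, x, alpha_B, it, err, "AB", p)
        raise ConvergenceError(max_iter, err)

    # literal mode: verbatim update, then L1 renormalization each iteration
    d = W_B.dangling
    if not np.any(xa[~d] > 0) and np.any(~d):
        raise ValueError("coupled operator is all-zero: x_A vanishes on layer B")
    x = np.full(m, 1.0 / m)
    for it in range(1, max_iter + 1):
        v = xa * x
        x_new = alpha_B * (T @ v + v[d].sum() * p) + (1.0 - alpha_B) * p
        total = x_new.sum()
        if total <= 0:  # pragma: no cover - restart term keeps mass positive
            raise ValueError("coupled iteration lost all probability mass")
        x_new /= total
        err = float(np.linalg.norm(x_new - x))
        x = x_new
        if err <= tol:
            return RankVector(W_B.node_order, x, alpha_B, it, err, "AB", p)
    raise ConvergenceError(max_iter, err)
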