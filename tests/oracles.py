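"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain dense numpy and explicit loops,
deliberately sharing no code path with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dense_walk_matrix(edges: dict[tuple[str, str], float], nodes: list[str]) -> np.ndarray:
    """Column-stochastic walk operator T (T[i, j] = prob of step j -> i),
    built from scratch: symmetric weights, row-normalize, transpose."""
    m = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    C = np.zeros((m, m))
    for (u, v), w in edges.items():
        C[idx[u], idx[v]] = w
        C[idx[v], idx[u]] = w
    W = np.zeros((m, m))
    for i in range(m):
        s = C[i].sum()
        if s > 0:
            W[i] = C[i] / s
    return W.T


def solve_seeded_dense(
    edges: dict[tuple[str, str], float],
    nodes: list[str],
    alpha: float,
    p: np.ndarray,
) -> np.ndarray:
    """Direct linear solve of (I - alpha*T')x = (1-alpha)p where T' has the
    dangling columns replaced by the restart vector."""
    m = len(nodes)
    T = dense_walk_matrix(edges, nodes)
    for j in range(m):
        if T[:, j].sum() == 0:
            T[:, j] = p
    x = np.linalg.solve(np.eye(m) - alpha * T, (1 - alpha) * p)
    return x


def iterate_multiplex_dense(
    edges_B: dict[tuple[str, str], float],
    nodes: list[str],
    x_A: np.ndarray,
    p: np.ndarray,
    alpha: float,
    mode: str,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Independent dense fixed-point iteration of the coupled walk.

    The coupling weights are the layer-A scores with every non-positive
    entry replaced by the smallest positive entry.
    """
    m = len(nodes)
    T = dense_walk_matrix(edges_B, nodes)
    dangling = np.array([T[:, j].sum() == 0 for j in range(m)])
    xa = np.array(x_A, dtype=float)
    eps = min(v for v in xa if v > 0)
    xa = np.array([v if v > 0 else eps for v in xa])

    if mode == "column_normalized":
        # target-biased coupling: entry (i, j) scaled by the layer-A score
        # of the target i, each column renormalized
        M = np.zeros((m, m))
        for j in range(m):
            col = np.array([T[i, j] * xa[i] for i in range(m)])
            s = col.sum()
            if s > 0:
                M[:, j] = col / s
        dang = np.array([M[:, j].sum() == 0 for j in range(m)])
        x = np.full(m, 1.0 / m)
        for _ in range(max_iter):
            x_new = alpha * (M @ x + x[dang].sum() * p) + (1 - alpha) * p
            if math.sqrt(((x_new - x) ** 2).sum()) <= tol:
                return x_new
            x = x_new
        raise RuntimeError("oracle iteration did not converge")

    # literal mode: verbatim coupled update then explicit renormalization
    x = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        y = np.zeros(m)
        for i in range(m):
            acc = 0.0
            for j in range(m):
                acc += xa[j] * T[i, j] * x[j]
            y[i] = alpha * acc + (1 - alpha) * p[i]
        y += alpha * sum(xa[j] * x[j] for j in range(m) if dangling[j]) * p
        y = y / y.sum()
        if math.sqrt(((y - x) ** 2).sum()) <= tol:
            return y
        x = y
    raise RuntimeError("oracle iteration did not converge")


def brute_spearman(values: np.ndarray) -> np.ndarray:
    """Spearman by definition: midrank both vectors, Pearson on the ranks."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    g = values.shape[0]
    out = np.eye(g)
    ranked = [midranks(values[i]) for i in range(g)]
    for i in range(g):
        for j in range(i + 1, g):
            a, b = ranked[i], ranked[j]
            da, db = a - a.mean(), b - b.mean()
            denom = math.sqrt((da**2).sum() * (db**2).sum())
            r = 0.0 if denom == 0 else float((da * db).sum() / denom)
            out[i, j] = out[j, i] = r
    return out


def brute_clr(corr: np.ndarray) -> np.ndarray:
    """Double-loop CLR: per-gene background mean/sd of absolute
    off-diagonal correlations, zero-truncated quadratic combination."""
    g = corr.shape[0]
    a = np.abs(corr)
    stats = []
    for i in range(g):
        background = [a[i, j] for j in range(g) if j != i]
        mu = sum(background) / len(background)
        var = sum((v - mu) ** 2 for v in background) / len(background)
        stats.append((mu, math.sqrt(var)))
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            mu_i, sd_i = stats[i]
            mu_j, sd_j = stats[j]
            zi = 0.0 if sd_i == 0 else (a[i, j] - mu_i) / sd_i
            zj = 0.0 if sd_j == 0 else (a[j, i] - mu_j) / sd_j
            out[i, j] = math.sqrt(max(0.0, zi) ** 2 + max(0.0, zj) ** 2)
    return out


def confusion_oracle(inferred, reference, seeds, universe):
    """Four counts by direct per-node classification over non-seed nodes."""
    tp = fp = fn = tn = 0
    for node in universe:
        if node in seeds:
            continue
        in_mod = node in inferred
        in_ref = node in reference
        if in_mod and in_ref:
            tp += 1
        elif in_mod:
            fp += 1
        elif in_ref:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def exhaustive_set_means(scores: np.ndarray, size: int) -> np.ndarray:
    """Mean score of every node subset of the given size."""
    return np.array(
        [np.mean([scores[i] for i in combo])
         for combo in itertools.combinations(range(len(scores)), size)]
    )
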