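"""Module extraction from rank vectors and sampling-based significance.

A functional module is the seed genes plus the top-ranked non-seed genes,
together with every layer-A / layer-B edge among the selected nodes,
tagged by provenance (A-only, B-only, or shared).  Significance compares
the module's mean multiplex score against the null distribution of the
mean over randomly sampled same-size node sets, via a one-sample Z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import comb
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .core import RankVector
from .graph_io import SeedSet, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = ["Module", "ModuleEdge", "extract_module", "module_significance", "top_nodes"]


@dataclass(frozen=True)
class ModuleEdge:
    u: str
    v: str
    weight_A: float | None
    weight_B: float | None
    provenance: str  # "A", "B", or "AB"


@dataclass(frozen=True)
class Module:
    """Extracted node set with induced edges and (optionally) significance."""

    nodes: tuple[str, ...]
    edges: tuple[ModuleEdge, ...]
    seeds: tuple[str, ...]
    score: float | None = None  # mean multiplex score of member nodes
    z_score: float | None = None
    p_value: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_samples: int | None = None
    rng_seed: int | None = None
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        for e in self.edges:
            if e.u not in node_set or e.v not in node_set:
                raise ValueError(f"edge ({e.u}, {e.v}) endpoint outside module")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    def edge_counts(self) -> dict[str, int]:
        counts = {"A": 0, "B": 0, "AB": 0}
        for e in self.edges:
            counts[e.provenance] += 1
        return counts


def top_nodes(
    scores: np.ndarray,
    node_order: tuple[str, ...],
    seeds: SeedSet,
    n_top: int,
    tiebreak_scores: np.ndarray | None = None,
) -> tuple[str, ...]:
    """Seeds plus the highest-scoring non-seed nodes, |result| = n_top.

    Ties at the cutoff are broken by higher tiebreak score (if given),
    then lexicographic identifier.
    """
    m = len(node_order)
    if n_top < seeds.k:
        raise ValueError(f"n_top={n_top} smaller than seed count k={seeds.k}")
    if n_top > m:
        raise ValueError(f"n_top={n_top} exceeds total node count {m}")
    seed_set = set(seeds)
    tb = tiebreak_scores if tiebreak_scores is not None else np.zeros(m)
    candidates = [i for i, g in enumerate(node_order) if g not in seed_set]
    candidates.sort(key=lambda i: (-scores[i], -tb[i], node_order[i]))
    chosen = list(seeds.seeds)
    chosen.extend(node_order[i] for i in candidates[: n_top - seeds.k])
    return tuple(chosen)


def _induced_edges(
    nodes: tuple[str, ...], net_A: WeightedNetwork, net_B: WeightedNetwork
) -> tuple[ModuleEdge, ...]:
    node_set = set(nodes)
    pairs: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for (u, v), w in net_A.edges.items():
        if u in node_set and v in node_set:
            pairs[(u, v)] = (w, None)
    for (u, v), w in net_B.edges.items():
        if u in node_set and v in node_set:
            wa = pairs.get((u, v), (None, None))[0]
            pairs[(u, v)] = (wa, w)
    edges = []
    for (u, v), (wa, wb) in sorted(pairs.items()):
        prov = "AB" if (wa is not None and wb is not None) else ("A" if wa is not None else "B")
        edges.append(ModuleEdge(u, v, wa, wb, prov))
    return tuple(edges)


def extract_module(
    ranks_AB: RankVector,
    ranks_A: RankVector,
    seeds: SeedSet,
    net_A: WeightedNetwork,
    net_B: WeightedNetwork,
    n_top: int,
    selection_mode: str = "multiplex",
) -> Module:
    """Group seeds and top-ranked nodes into a module with induced edges.

    ``selection_mode="multiplex"`` ranks non-seed nodes by the coupled
    score x(AB) alone; ``"union"`` interleaves the per-layer x(A) ranking
    with the x(AB) ranking until n_top nodes are collected.  Edges are all
    layer-A and layer-B edges with both endpoints selected.
    """
    if tuple(ranks_A.node_order) != tuple(ranks_AB.node_order):
        raise ValueError("rank vectors do not share a node order")
    order = tuple(ranks_AB.node_order)
    if selection_mode == "multiplex":
        nodes = top_nodes(ranks_AB.scores, order, seeds, n_top, ranks_A.scores)
    elif selection_mode == "union":
        nodes = _interleaved_nodes(ranks_A, ranks_AB, seeds, n_top)
    else:
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    edges = _induced_edges(nodes, net_A, net_B)
    idx = {g: i for i, g in enumerate(order)}
    score = float(np.mean([ranks_AB.scores[idx[g]] for g in nodes]))
    return Module(nodes=nodes, edges=edges, seeds=tuple(seeds.seeds), score=score)


def _interleaved_nodes(
    ranks_A: RankVector, ranks_AB: RankVector, seeds: SeedSet, n_top: int
) -> tuple[str, ...]:
    m = len(ranks_AB.node_order)
    if n_top < seeds.k:
        raise ValueError(f"n_top={n_top} smaller than seed count k={seeds.k}")
    if n_top > m:
        raise ValueError(f"n_top={n_top} exceeds total node count {m}")
    seed_set = set(seeds)
    order = ranks_AB.node_order

    def ranking(primary: np.ndarray, secondary: np.ndarray) -> list[str]:
        idx = [i for i, g in enumerate(order) if g not in seed_set]
        idx.sort(key=lambda i: (-primary[i], -secondary[i], order[i]))
        return [order[i] for i in idx]

    by_ab = ranking(ranks_AB.scores, ranks_A.scores)
    by_a = ranking(ranks_A.scores, ranks_AB.scores)
    chosen = list(seeds.seeds)
    taken = set(chosen)
    ia = iab = 0
    # AB first, then A, alternating; skip already-selected nodes
    while len(chosen) < n_top:
        for lst, pos in ((by_ab, "ab"), (by_a, "a")):
            i = iab if pos == "ab" else ia
            while i < len(lst) and lst[i] in taken:
                i += 1
            if pos == "ab":
                iab = i
            else:
                ia = i
            if i < len(lst) and len(chosen) < n_top:
                chosen.append(lst[i])
                taken.add(lst[i])
    return tuple(chosen)


def _sampled_null(
    scores: np.ndarray,
    set_size: int,
    n_samples: int,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> tuple[float, float, np.ndarray]:
    """Mean/sd of the mean score over uniformly sampled node sets
    (without replacement within a set).  Returns the per-set means too."""
    m = scores.size
    means = np.empty(n_samples)
    done = 0
    while done < n_samples:
        b = min(chunk, n_samples - done)
        # random-key trick: the set_size smallest keys per row form a
        # uniform without-replacement sample of size set_size
        keys = rng.random((b, m))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        means[done : done + b] = scores[idx].mean(axis=1)
        done += b
    return float(means.mean()), float(means.std(ddof=1)), means


def module_significance(
    module: Module,
    ranks_AB: RankVector,
    n_samples: int = 1_000_000,
    rng_seed: int = 0,
    exclude_seeds: bool = False,
    empirical_p: bool = False,
) -> Module:
    """Fill the significance fields of a module by random sampling.

    The module statistic is the mean coupled score of its members.  The
    null is built from ``n_samples`` uniformly random node sets of the
    same size; Z = (mean - null_mean) / null_sd and the p-value is the
    one-sided upper tail of the standard normal.  Fully reproducible from
    ``rng_seed``.  Set ``empirical_p`` to additionally store the
    rank-based p-value under key ``"empirical_p"`` in the parameters.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    order = tuple(ranks_AB.node_order)
    idx = {g: i for i, g in enumerate(order)}
    missing = [g for g in module.nodes if g not in idx]
    if missing:
        raise ValueError(f"module nodes missing from rank vector: {missing[:5]}")
    scores = np.asarray(ranks_AB.scores, dtype=float)
    if exclude_seeds:
        keep = np.array([g not in set(module.seeds) for g in order])
        pool = scores[keep]
    else:
        pool = scores
    n = len(module.nodes)
    x_bar = float(scores[[idx[g] for g in module.nodes]].mean())

    if n >= pool.size:
        logger.warning("module covers the whole universe; p-value defined as 1")
        return replace(
            module, score=x_bar, z_score=0.0, p_value=1.0,
            null_mean=x_bar, null_sd=0.0, n_samples=n_samples, rng_seed=rng_seed,
        )

    rng = np.random.default_rng(rng_seed)
    u, sd, means = _sampled_null(pool, n, n_samples, rng)
    if np.ptp(pool) == 0.0:
        sd = 0.0  # identical scores: null variation is pure float jitter
    extra = dict(module.parameters)
    if empirical_p:
        extra["empirical_p"] = float((1 + np.sum(means >= x_bar)) / (n_samples + 1))
    if sd == 0.0:
        logger.warning("degenerate null (all sampled means identical); p defined as 1")
        return replace(
            module, score=x_bar, z_score=0.0, p_value=1.0,
            null_mean=u, null_sd=0.0, n_samples=n_samples, rng_seed=rng_seed,
            parameters=extra,
        )
    z = (x_bar - u) / sd
    p = float(norm.sf(z))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return replace(
        module, score=x_bar, z_score=float(z), p_value=p,
        null_mean=u, null_sd=sd, n_samples=n_samples, rng_seed=rng_seed,
        parameters=extra,
    )
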