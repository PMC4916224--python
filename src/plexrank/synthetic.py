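"""Planted-module multiplex benchmarks and toy expression matrices.

The generator embeds a known module of M nodes into two Erdos-Renyi
background layers over a shared universe of N nodes.  Within-module pairs
receive an edge with probability ``p_in`` in every layer that at least
one endpoint "carries": a fraction ``overlap_frac`` of module nodes
carries its within-module edges in both layers, the rest is split evenly
between layer-A-only and layer-B-only carriers.  This reproduces
the benchmark scenario where the module's signal is divided across two
partially overlapping layers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .association import ExpressionMatrix
from .graph_io import WeightedNetwork, build_network

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedParams",
    "PlantedMultiplex",
    "generate_planted_multiplex",
    "generate_module_expression",
    "write_planted_multiplex",
]

MIN_WEIGHT = 0.05


@dataclass(frozen=True)
class PlantedParams:
    n_nodes: int
    module_size: int
    p_in_A: float
    p_out_A: float
    p_in_B: float
    p_out_B: float
    overlap_frac: float = 1.0
    weight_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 2 <= self.module_size < self.n_nodes:
            raise ValueError("need 2 <= module_size < n_nodes")
        for p_in, p_out, tag in (
            (self.p_in_A, self.p_out_A, "A"),
            (self.p_in_B, self.p_out_B, "B"),
        ):
            if not (0.0 <= p_out < p_in <= 1.0):
                raise ValueError(f"layer {tag}: need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.overlap_frac <= 1.0:
            raise ValueError("overlap_frac must be in [0, 1]")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be nonnegative")


@dataclass(frozen=True)
class PlantedMultiplex:
    net_A: WeightedNetwork
    net_B: WeightedNetwork
    truth: frozenset[str]
    params: PlantedParams
    carriers_A: frozenset[str]  # module nodes whose within-module edges live in A
    carriers_B: frozenset[str]

    @property
    def universe(self) -> frozenset[str]:
        return self.net_A.nodes | self.net_B.nodes


def _node_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _edge_weights(n: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    w = 1.0 + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n))
    return np.maximum(w, MIN_WEIGHT)


def generate_planted_multiplex(params: PlantedParams) -> PlantedMultiplex:
    """Draw a two-layer network with a known planted module.

    Fully reproducible from ``params.rng_seed``.  Module membership and
    per-node layer carriage are sampled first, then every unordered node
    pair gets an independent Bernoulli edge per layer: probability p_in
    for within-module pairs with at least one endpoint carrying that
    layer, p_out otherwise.  Edge weights are 1.0 + Gaussian noise,
    floored at 0.05.
    """
    rng = np.random.default_rng(params.rng_seed)
    labels = _node_labels(params.n_nodes)
    truth_idx = np.sort(rng.choice(params.n_nodes, size=params.module_size, replace=False))
    truth = [labels[i] for i in truth_idx]

    # carriage: round(overlap_frac * M) nodes carry both layers, rest split A/B
    m = params.module_size
    n_both = int(round(params.overlap_frac * m))
    rest = [g for g in truth]
    rng.shuffle(rest)
    both = set(rest[:n_both])
    tail = rest[n_both:]
    a_only = set(tail[: len(tail) // 2 + len(tail) % 2])
    b_only = set(tail[len(a_only) :])
    carriers_A = both | a_only
    carriers_B = both | b_only

    truth_set = set(truth)
    nets = {}
    for layer, p_in, p_out, carriers in (
        ("A", params.p_in_A, params.p_out_A, carriers_A),
        ("B", params.p_in_B, params.p_out_B, carriers_B),
    ):
        triples = []
        pairs = []
        probs = []
        for i in range(params.n_nodes):
            for j in range(i + 1, params.n_nodes):
                u, v = labels[i], labels[j]
                # a within-module pair is elevated in every layer claimed by
                # at least one endpoint; remaining pairs are background
                if u in truth_set and v in truth_set and (u in carriers or v in carriers):
                    probs.append(p_in)
                else:
                    probs.append(p_out)
                pairs.append((u, v))
        probs_arr = np.asarray(probs)
        draw = rng.random(len(pairs)) < probs_arr
        idx = np.flatnonzero(draw)
        weights = _edge_weights(idx.size, params.weight_noise_sd, rng)
        for w, k in zip(weights, idx):
            u, v = pairs[k]
            triples.append((u, v, float(w)))
        nets[layer] = build_network(layer, triples, extra_nodes=labels)

    return PlantedMultiplex(
        net_A=nets["A"],
        net_B=nets["B"],
        truth=frozenset(truth),
        params=params,
        carriers_A=frozenset(carriers_A),
        carriers_B=frozenset(carriers_B),
    )


def generate_module_expression(
    truth: frozenset[str] | set[str],
    n_nodes: int,
    n_samples: int,
    signal_sd: float = 1.0,
    noise_sd: float = 0.25,
    rng_seed: int = 0,
) -> ExpressionMatrix:
    """Toy expression matrix with a co-expressed planted block.

    Module genes share one latent per-sample profile (sd = signal_sd)
    plus independent noise (sd = noise_sd); background genes are pure
    independent noise with the same noise sd.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples")
    if signal_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    labels = _node_labels(n_nodes)
    unknown = set(truth) - set(labels)
    if unknown:
        raise ValueError(f"truth gene(s) outside the node universe: {sorted(unknown)[:5]}")
    latent = rng.normal(0.0, signal_sd, size=n_samples) if signal_sd > 0 else np.zeros(n_samples)
    values = rng.normal(0.0, 1.0, size=(n_nodes, n_samples)) * noise_sd
    member = np.array([g in truth for g in labels])
    values[member] += latent[None, :]
    samples = tuple(f"s{j:02d}" for j in range(n_samples))
    return ExpressionMatrix(genes=tuple(labels), samples=samples, values=values)


def write_planted_multiplex(pm: PlantedMultiplex, out_dir: str | Path) -> dict[str, Path]:
    """Write both layers as edge-list TSVs plus a manifest JSON with the
    ground truth and all generator parameters."""
    from .graph_io import write_edge_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "layer_A": out / "layer_A.tsv",
        "layer_B": out / "layer_B.tsv",
        "manifest": out / "manifest.json",
    }
    write_edge_list(pm.net_A, paths["layer_A"])
    write_edge_list(pm.net_B, paths["layer_B"])
    manifest = {
        "truth": sorted(pm.truth),
        "carriers_A": sorted(pm.carriers_A),
        "carriers_B": sorted(pm.carriers_B),
        "params": asdict(pm.params),
    }
    with paths["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
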