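"""Reading and writing networks, seed lists, rank tables, and module reports.

All on-disk formats are plain text: whitespace/tab-separated edge lists,
SIF interaction files (read-only, unit weight), one-identifier-per-line
seed lists, TSV rank tables, and TSV + JSON module reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "SeedSet",
    "GraphIOError",
    "read_edge_list",
    "read_seeds",
    "write_edge_list",
    "write_rank_table",
    "read_rank_table",
    "write_module_report",
]


class GraphIOError(ValueError):
    """Raised for malformed or inconsistent network/seed input."""


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class WeightedNetwork:
    """One undirected weighted layer over gene/protein identifiers.

    ``edges`` maps lexicographically ordered node pairs to nonnegative
    weights.  ``nodes`` may include isolated nodes (present in the layer's
    universe but without any surviving edge).
    """

    layer_label: str
    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise GraphIOError(f"self-loop {u!r} in layer {self.layer_label}")
            if (u, v) != _edge_key(u, v):
                raise GraphIOError(f"edge key {(u, v)!r} not in canonical order")
            if not (w > 0):
                raise GraphIOError(f"edge {(u, v)!r} has non-positive weight {w!r}")
            if u not in self.nodes or v not in self.nodes:
                raise GraphIOError(f"edge {(u, v)!r} endpoint missing from node set")

    @property
    def node_list(self) -> list[str]:
        """Deterministic (lexicographic) node order."""
        return sorted(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, u: str, v: str) -> float | None:
        return self.edges.get(_edge_key(u, v))

    def degree_nonzero(self, node: str) -> bool:
        """True if the node has at least one incident edge in this layer."""
        return any(node in pair for pair in self.edges)


@dataclass(frozen=True)
class SeedSet:
    """Ordered list of distinct seed gene identifiers (k >= 1)."""

    seeds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise GraphIOError("seed set must contain at least one identifier")
        if len(set(self.seeds)) != len(self.seeds):
            raise GraphIOError("seed set contains duplicates")

    @property
    def k(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def __contains__(self, item) -> bool:
        return item in self.seeds


def build_network(
    layer_label: str,
    weighted_edges: Iterable[tuple[str, str, float]],
    extra_nodes: Iterable[str] = (),
    *,
    keep_self_loops: bool = False,
) -> WeightedNetwork:
    """Assemble a WeightedNetwork from raw (u, v, w) triples.

    Applies the read policies: self-loops dropped (unless permitted),
    zero-weight edges dropped, duplicate pairs merged keeping the maximum
    weight.  Negative weights are a hard error.
    """
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set(extra_nodes)
    n_loops = n_zero = n_dup = 0
    for u, v, w in weighted_edges:
        if w < 0:
            raise GraphIOError(f"negative weight {w!r} on edge ({u!r}, {v!r})")
        nodes.add(u)
        nodes.add(v)
        if u == v and not keep_self_loops:
            n_loops += 1
            continue
        if w == 0:
            n_zero += 1
            continue
        key = _edge_key(u, v)
        if key in edges:
            n_dup += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if n_loops:
        logger.warning("layer %s: dropped %d self-loop(s)", layer_label, n_loops)
    if n_zero:
        logger.warning("layer %s: dropped %d zero-weight edge(s)", layer_label, n_zero)
    if n_dup:
        logger.warning(
            "layer %s: merged %d duplicate edge line(s) (max weight kept)",
            layer_label,
            n_dup,
        )
    return WeightedNetwork(layer_label, frozenset(nodes), edges)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(path: str | Path, layer_label: str, fmt: str = "edgelist") -> WeightedNetwork:
    """Read a weighted undirected layer from a text file.

    ``fmt="edgelist"``: >= 3 whitespace-separated columns
    (source, target, weight); an optional header line is detected by a
    non-numeric third field on line 1.  ``fmt="sif"``: simple interaction
    format (node, relation, node...), every interaction gets unit weight.

    Node identifiers are case-sensitive and whitespace-stripped.
    """
    path = Path(path)
    if fmt not in ("edgelist", "sif"):
        raise GraphIOError(f"unknown edge-list format {fmt!r}")
    if not path.exists():
        raise GraphIOError(f"edge list not found: {path}")

    triples: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fmt == "sif":
                if len(fields) < 3:
                    raise GraphIOError(f"{path}:{lineno}: SIF line needs >= 3 fields")
                src = fields[0]
                for tgt in fields[2:]:
                    triples.append((src, tgt, 1.0))
                continue
            if len(fields) < 3:
                raise GraphIOError(
                    f"{path}:{lineno}: expected >= 3 columns (source target weight)"
                )
            if lineno == 1 and not _is_number(fields[2]):
                continue  # header row
            if not _is_number(fields[2]):
                raise GraphIOError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}")
            w = float(fields[2])
            if w < 0:
                raise GraphIOError(f"{path}:{lineno}: negative weight {w}")
            triples.append((fields[0], fields[1], w))

    net = build_network(layer_label, triples)
    if net.n_nodes == 0:
        raise GraphIOError(f"{path}: empty graph after filtering")
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write a layer as a headered, tab-separated edge list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in sorted(net.edges.items()):
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_seeds(path: str | Path, networks: list[WeightedNetwork]) -> SeedSet:
    """Read a seed list (one identifier per line; ``#`` comments, blanks skipped).

    Duplicates keep the first occurrence with a warning.  Every seed must
    occur in the union node set of the given layers; missing seeds are a
    hard error listing the offending identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise GraphIOError(f"seed file not found: {path}")
    seen: list[str] = []
    n_dup = 0
    with path.open() as fh:
        for raw in fh:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if token in seen:
                n_dup += 1
            else:
                seen.append(token)
    if n_dup:
        logger.warning("seed list %s: dropped %d duplicate entries", path, n_dup)
    if not seen:
        raise GraphIOError(f"seed file {path} contains no identifiers")
    universe: set[str] = set()
    for net in networks:
        universe |= net.nodes
    missing = [s for s in seen if s not in universe]
    if missing:
        raise GraphIOError(
            "seed gene(s) absent from every network layer: " + ", ".join(missing)
        )
    return SeedSet(tuple(seen))


def write_rank_table(ranks_A, ranks_AB, path: str | Path) -> None:
    """Write the per-gene score table for both walks.

    Columns: gene, score_A, score_AB, rank_AB.  Rows sorted by score_AB
    descending, ties broken lexicographically by gene.  Scores are printed
    with 17 significant digits so the file round-trips the in-memory
    vectors exactly at double precision.
    """
    if tuple(ranks_A.node_order) != tuple(ranks_AB.node_order):
        raise GraphIOError("rank vectors do not share a node order")
    path = Path(path)
    order = sorted(
        range(len(ranks_AB.node_order)),
        key=lambda i: (-ranks_AB.scores[i], ranks_AB.node_order[i]),
    )
    with path.open("w") as fh:
        fh.write("gene\tscore_A\tscore_AB\trank_AB\n")
        for rank, i in enumerate(order, start=1):
            fh.write(
                f"{ranks_AB.node_order[i]}\t{ranks_A.scores[i]:.17g}\t"
                f"{ranks_AB.scores[i]:.17g}\t{rank}\n"
            )


def read_rank_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read back a rank table as ``{gene: (score_A, score_AB)}``."""
    out: dict[str, tuple[float, float]] = {}
    with Path(path).open() as fh:
        next(fh)  # header
        for line in fh:
            gene, s_a, s_ab, _rank = line.rstrip("\n").split("\t")
            out[gene] = (float(s_a), float(s_ab))
    return out


def write_module_report(module, path_prefix: str | Path) -> tuple[Path, Path]:
    """Serialize an extracted module.

    Writes ``<prefix>.edges.tsv`` (source, target, weight_A, weight_B,
    provenance) and ``<prefix>.json`` (node count, per-provenance edge
    counts, Z-score, p-value, and all run parameters).  Returns the two
    paths written.
    """
    prefix = Path(path_prefix)
    edges_path = prefix.parent / (prefix.name + ".edges.tsv")
    json_path = prefix.parent / (prefix.name + ".json")

    counts = {"A": 0, "B": 0, "AB": 0}
    with edges_path.open("w") as fh:
        fh.write("source\ttarget\tweight_A\tweight_B\tprovenance\n")
        for edge in module.edges:
            counts[edge.provenance] += 1
            wa = "" if edge.weight_A is None else f"{edge.weight_A:.17g}"
            wb = "" if edge.weight_B is None else f"{edge.weight_B:.17g}"
            fh.write(f"{edge.u}\t{edge.v}\t{wa}\t{wb}\t{edge.provenance}\n")

    summary = {
        "nodes": list(module.nodes),
        "n_nodes": len(module.nodes),
        "edge_counts": counts,
        "n_edges": sum(counts.values()),
        "score": module.score,
        "z_score": module.z_score,
        "p_value": module.p_value,
        "null_mean": module.null_mean,
        "null_sd": module.null_sd,
        "n_samples": module.n_samples,
        "rng_seed": module.rng_seed,
        "parameters": dict(module.parameters) if module.parameters else {},
    }
    with json_path.open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return edges_path, json_path
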