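"""Build an expression-based association layer via Spearman-correlation CLR.

Each gene pair's absolute Spearman correlation is z-scored against both
genes' background distributions of absolute correlations; the two
zero-truncated z-scores are combined quadratically (classic context
likelihood of relatedness).  Pairs above a z threshold (default 4.3)
become weighted edges of layer "A".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph_io import WeightedNetwork, build_network

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "spearman_matrix",
    "clr_scores",
    "threshold_network",
    "DEFAULT_CLR_THRESHOLD",
]

DEFAULT_CLR_THRESHOLD = 4.3


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of pre-normalized expression values."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.samples) < 3:
            raise ValueError("need at least 3 samples for rank correlation")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene IDs in the first column and a sample header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=tuple(str(g) for g in df.index),
        samples=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.genes), columns=list(expr.samples))
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def spearman_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Pairwise Spearman rank correlation across samples (midrank ties).

    Constant-expression genes get correlation 0 to every partner (logged);
    the diagonal is 1.
    """
    ranks = rankdata(expr.values, axis=1)  # midranks
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant-expression gene(s) assigned zero correlation", constant.sum()
        )
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, np.sqrt((centered**2).sum(axis=1)))
    normed = centered / denom[:, None]
    corr = normed @ normed.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return (corr + corr.T) / 2.0


def clr_scores(corr: np.ndarray) -> np.ndarray:
    """Background-corrected association scores from a correlation matrix.

    z_i(j) = (|corr(i, j)| - mean_i) / sd_i over gene i's off-diagonal
    absolute correlations; CLR(i, j) = sqrt(max(0, z_i(j))^2 +
    max(0, z_j(i))^2).  Genes whose background sd is 0 get all-zero
    z-scores with a warning.
    """
    g = corr.shape[0]
    if corr.shape != (g, g) or not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be square and symmetric")
    a = np.abs(np.asarray(corr, dtype=float))
    off = a.copy()
    np.fill_diagonal(off, np.nan)
    mean = np.nanmean(off, axis=1)
    sd = np.nanstd(off, axis=1)  # population sd over the g-1 background values
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d gene(s) with zero background sd; z-scores set to 0", zero_sd.sum())
    safe_sd = np.where(zero_sd, 1.0, sd)
    z = (a - mean[:, None]) / safe_sd[:, None]  # z[i, j] = z_i(j)
    z[zero_sd, :] = 0.0
    z = np.maximum(z, 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return clr


def threshold_network(
    clr: np.ndarray,
    z_threshold: float = DEFAULT_CLR_THRESHOLD,
    genes: tuple[str, ...] | None = None,
    layer_label: str = "A",
) -> WeightedNetwork:
    """Keep pairs with CLR >= z_threshold as edges weighted by their score."""
    if z_threshold < 0:
        raise ValueError("z_threshold must be nonnegative")
    g = clr.shape[0]
    if genes is None:
        width = len(str(g))
        genes = tuple(f"g{i:0{width}d}" for i in range(g))
    if len(genes) != g:
        raise ValueError("gene labels do not match matrix size")
    triples = []
    iu, ju = np.triu_indices(g, k=1)
    for i, j in zip(iu, ju):
        if clr[i, j] >= z_threshold and clr[i, j] > 0:
            triples.append((genes[i], genes[j], float(clr[i, j])))
    if not triples:
        logger.warning("no pair reaches CLR threshold %.3g; empty edge set", z_threshold)
    return build_network(layer_label, triples, extra_nodes=genes)
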