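"""Condition-specific gene-gene relationship networks.

A relationship network is an undirected binary graph over the seed genes:
a pair is connected when the absolute Pearson correlation of the two
genes' expression profiles exceeds a threshold.  The threshold is either
given explicitly or derived as the (1 - top_fraction) quantile of all
defined pairwise |PCC| values, so that approximately ``top_fraction`` of
pairs qualify.

Strict inequality is used ("above" the threshold); pairs involving a
zero-variance gene have undefined correlation and never become edges,
but the gene itself stays in the node list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PccMatrix:
    """Symmetric matrix of absolute Pearson correlations in [0, 1].

    ``defined`` masks off-diagonal entries that are well-defined (neither
    gene has zero variance); the diagonal is never defined.
    """

    gene_ids: list[str]
    values: np.ndarray
    defined: np.ndarray

    def upper_values(self) -> np.ndarray:
        """Defined |PCC| values of the upper triangle as a flat array."""
        iu = np.triu_indices(len(self.gene_ids), 1)
        mask = self.defined[iu]
        return self.values[iu][mask]


@dataclass
class RelationshipNetwork:
    """Undirected binary adjacency over a gene list, with provenance."""

    gene_ids: list[str]
    adjacency: np.ndarray
    threshold: float | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.gene_ids),) * 2:
            raise ValueError("adjacency shape does not match gene list")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def abs_pcc_matrix(expr: ExpressionMatrix) -> PccMatrix:
    """Absolute Pearson correlation between every pair of gene rows.

    Requires at least 2 samples (and warns below 4, where the sample
    correlation is degenerate or extremely noisy).
    """
    x = expr.values
    g, n = x.shape
    if n < 2:
        raise ValueError(f"need >= 2 samples to correlate, got {n}")
    if n <= 3:
        logger.warning("only %d samples: pairwise PCC is nearly degenerate", n)
    centered = x - x.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    nonzero = ss > 0
    denom = np.sqrt(np.where(nonzero, ss, 1.0))
    normed = centered / denom[:, None]
    corr = np.abs(normed @ normed.T)
    np.clip(corr, 0.0, 1.0, out=corr)
    defined = np.outer(nonzero, nonzero)
    np.fill_diagonal(defined, False)
    corr[~defined] = np.nan
    n_const = int((~nonzero).sum())
    if n_const:
        logger.warning("%d zero-variance genes: their pairs are never edges", n_const)
    return PccMatrix(list(expr.gene_ids), corr, defined)


def select_threshold(pcc: PccMatrix, top_fraction: float) -> float:
    """Empirical (1 - top_fraction) quantile of the defined |PCC| values.

    Linear interpolation of order statistics; approximately ``top_fraction``
    of pairs lie strictly above the returned value.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    vals = pcc.upper_values()
    if vals.size == 0:
        raise ValueError("no defined pairwise correlation")
    if np.ptp(vals) == 0:
        raise ValueError("all |PCC| values identical: no discriminating threshold")
    return float(np.quantile(vals, 1.0 - top_fraction))


def build_network(
    pcc: PccMatrix, threshold: float, condition: str | None = None
) -> RelationshipNetwork:
    """Edges are pairs with defined |PCC| strictly above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    with np.errstate(invalid="ignore"):
        adj = (np.nan_to_num(pcc.values, nan=-1.0) > threshold) & pcc.defined
    net = RelationshipNetwork(
        list(pcc.gene_ids), adj.astype(np.int8), threshold=threshold, condition=condition
    )
    logger.info(
        "network (%s): %d edges among %d genes at threshold %.4g",
        condition, net.n_edges, net.n_genes, threshold,
    )
    return net


def count_pairs(g: int) -> int:
    """Number of unordered gene pairs among g genes: g(g-1)/2."""
    if g < 0:
        raise ValueError("g must be non-negative")
    return g * (g - 1) // 2


def write_network(net: RelationshipNetwork, node_path, edge_path,
                  pcc: PccMatrix | None = None) -> None:
    """Serialize as a node list (one symbol/line) + undirected edge TSV."""
    with open(node_path, "w") as fh:
        fh.write("\n".join(net.gene_ids) + "\n")
    iu = np.triu_indices(net.n_genes, 1)
    rows = []
    for i, j in zip(*iu):
        if net.adjacency[i, j]:
            w = pcc.values[i, j] if pcc is not None else np.nan
            rows.append((net.gene_ids[i], net.gene_ids[j], w))
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "abs_pcc"]).to_csv(
        edge_path, sep="\t", index=False
    )


def read_network(node_path, edge_path, condition: str | None = None,
                 threshold: float | None = None) -> RelationshipNetwork:
    with open(node_path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    index = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)), dtype=np.int8)
    edges = pd.read_csv(edge_path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    for a, b in zip(edges["gene_i"], edges["gene_j"]):
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = 1
    return RelationshipNetwork(genes, adj, threshold=threshold, condition=condition)
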