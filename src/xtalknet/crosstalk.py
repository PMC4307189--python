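"""Scoring and pathway intersection of resistant-specific gene pairs.

A gene pair is flagged as resistance-associated when the odds ratio of
its posterior edge probabilities (resistant over parental) and its
resistant posterior probability both clear inclusive thresholds
(defaults 10.0 and 0.5).  Cross-talk candidates are all pairs with one
gene in the pathway of interest (EGFR/ErbB) and the other in a different
pathway, excluding pairs whose two genes co-occur in either of those two
pathways.  The intersection of the two sets, annotated with pathway and
condition-averaged expression, is the cross-talk table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene-set collection with a designated pathway of interest."""

    name: str
    pathways: dict[str, set[str]]
    pathway_of_interest: str

    def __post_init__(self) -> None:
        if self.pathway_of_interest not in self.pathways:
            raise ValueError(
                f"pathway of interest {self.pathway_of_interest!r} not in collection"
            )
        for pname, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pname!r} is empty")


def read_gmt(path, name: str, pathway_of_interest: str) -> PathwayCollection:
    """Read a GMT file: per line, name, description, then member symbols."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            pathways[fields[0]] = {g for g in fields[2:] if g}
    return PathwayCollection(name, pathways, pathway_of_interest)


def read_pathway_dir(path, name: str, pathway_of_interest: str) -> PathwayCollection:
    """Read one-pathway-per-file exports: tab-delimited symbols, filename = name."""
    pathways: dict[str, set[str]] = {}
    for f in sorted(Path(path).iterdir()):
        if f.is_dir():
            continue
        genes = {g for g in f.read_text().replace("\n", "\t").split("\t") if g.strip()}
        if genes:
            pathways[f.stem] = genes
    return PathwayCollection(name, pathways, pathway_of_interest)


def odds_ratio(pr_R: float, pr_P: float) -> float:
    """Ratio of resistant to parental posterior edge probabilities.

    pr_P = 0 with pr_R > 0 gives +inf (sorting above any finite odds);
    0/0 is defined as 0 with a warning.
    """
    if not (0.0 <= pr_R <= 1.0 and 0.0 <= pr_P <= 1.0):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    if pr_P == 0.0:
        if pr_R == 0.0:
            logger.warning("odds ratio 0/0 defined as 0")
            return 0.0
        return float("inf")
    return pr_R / pr_P


def filter_resistant_pairs(
    edge_prob_R: np.ndarray,
    edge_prob_P: np.ndarray,
    gene_ids: list[str],
    odds_min: float = 10.0,
    pr_min: float = 0.5,
) -> dict[frozenset, tuple[float, float, float]]:
    """Unordered pairs with odds >= odds_min AND pr_R >= pr_min (inclusive).

    Returns a mapping from frozenset({gene_i, gene_j}) to (pr_R, pr_P, odds).
    """
    edge_prob_R = np.asarray(edge_prob_R, dtype=float)
    edge_prob_P = np.asarray(edge_prob_P, dtype=float)
    g = len(gene_ids)
    if edge_prob_R.shape != (g, g) or edge_prob_P.shape != (g, g):
        raise ValueError("probability matrices must be g x g")
    kept: dict[frozenset, tuple[float, float, float]] = {}
    iu = np.triu_indices(g, 1)
    for i, j in zip(*iu):
        pr_r = float(edge_prob_R[i, j])
        pr_p = float(edge_prob_P[i, j])
        if pr_r < pr_min:
            continue
        odds = odds_ratio(pr_r, pr_p)
        if odds >= odds_min:
            kept[frozenset((gene_ids[i], gene_ids[j]))] = (pr_r, pr_p, odds)
    logger.info("%d pairs pass odds >= %g, pr_R >= %g", len(kept), odds_min, pr_min)
    return kept


def enumerate_crosstalk_pairs(
    pathways: PathwayCollection, universe: list[str] | set[str]
) -> set[tuple[str, str, str]]:
    """All (gene_i, gene_j, pathway_j) candidate cross-talk triples.

    gene_i belongs to the pathway of interest, gene_j to another pathway,
    both restricted to ``universe``; pairs whose two genes co-occur in the
    pathway of interest or co-occur in pathway_j are excluded.  The same
    unordered pair may appear under several pathway_j values when pathways
    overlap, which is why the cross-talk count exceeds the distinct-pair
    count.
    """
    uni = set(universe)
    poi_name = pathways.pathway_of_interest
    poi = pathways.pathways[poi_name] & uni
    if not poi:
        raise ValueError("pathway of interest has no genes in the universe")
    triples: set[tuple[str, str, str]] = set()
    for qname, qgenes in pathways.pathways.items():
        if qname == poi_name:
            continue
        q = qgenes & uni
        for a in poi:
            for b in q:
                if a == b:
                    continue
                if b in poi:  # both in pathway of interest
                    continue
                if a in qgenes:  # both in pathway_j
                    continue
                triples.add((a, b, qname))
    return triples


CROSSTALK_COLUMNS = [
    "gene_i", "gene_j", "pathway_j", "pr_R", "pr_P", "odds",
    "avg_ge_i_P", "avg_ge_i_R", "avg_ge_j_P", "avg_ge_j_R",
]


def intersect_crosstalks(
    candidates: dict[frozenset, tuple[float, float, float]],
    crosstalks: set[tuple[str, str, str]],
    avg_ge: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join resistant-specific pairs with candidate cross-talk triples.

    ``avg_ge`` (optional) is a per-gene DataFrame with columns
    ``parental`` / ``resistant`` holding condition-averaged expression.
    One output row per (pair, pathway_j) triple whose unordered pair passed
    the filter, sorted by descending odds then gene_i, gene_j.
    """
    rows = []
    for a, b, pathway_j in crosstalks:
        key = frozenset((a, b))
        if key not in candidates:
            continue
        pr_r, pr_p, odds = candidates[key]
        ge = [np.nan] * 4
        if avg_ge is not None:
            ge = [
                avg_ge.at[a, "parental"], avg_ge.at[a, "resistant"],
                avg_ge.at[b, "parental"], avg_ge.at[b, "resistant"],
            ]
        rows.append((a, b, pathway_j, pr_r, pr_p, odds, *ge))
    table = pd.DataFrame(rows, columns=CROSSTALK_COLUMNS)
    table = table.sort_values(
        ["odds", "gene_i", "gene_j"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return table


def summarize_crosstalks(
    table: pd.DataFrame, multi: dict[str, pd.DataFrame] | None = None
) -> dict:
    """Counts over a cross-talk table: all, distinct pairs, other pathways.

    With ``multi`` (source name -> table), additionally counts distinct
    unordered pairs present in at least two sources' tables.
    """
    pairs = {frozenset((a, b)) for a, b in zip(table["gene_i"], table["gene_j"])}
    summary = {
        "n_crosstalks": int(len(table)),
        "n_distinct_pairs": len(pairs),
        "n_other_pathways": int(table["pathway_j"].nunique()) if len(table) else 0,
    }
    if multi is not None:
        counts: dict[frozenset, int] = {}
        for src_table in multi.values():
            for key in {frozenset((a, b))
                        for a, b in zip(src_table["gene_i"], src_table["gene_j"])}:
                counts[key] = counts.get(key, 0) + 1
        summary["n_pairs_in_2plus_sources"] = sum(1 for v in counts.values() if v >= 2)
    return summary
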