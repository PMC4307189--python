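"""Condition-level expression summaries and selection screens.

Per-condition mean profiles feed two screens used to interpret predicted
cross-talks:

* the up-regulation screen keeps cross-talk pairs in which BOTH genes
  have higher average expression under resistant than parental
  conditions (the compensatory-activation hypothesis);
* the fold-change-reversal screen selects genes whose response to
  treatment flips sign between the parental and resistant lines in at
  least one paired replicate.

Heatmap normalization follows the standard display convention: per-gene
z-scores of the condition means, rescaled by the gene's maximum absolute
z-score so every non-constant gene spans [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import CONDITIONS, PARENTAL, RESISTANT, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConditionProfile:
    """Per-gene averages over (condition, dose) groups.

    ``means`` is genes x conditions with a (condition, dose) MultiIndex on
    the columns; ``normalized`` (same shape) holds the z-scored,
    max-abs-scaled values in [-1, 1], filled by :func:`normalize_profile`.
    """

    means: pd.DataFrame
    normalized: pd.DataFrame | None = field(default=None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def conditions(self) -> list[tuple[str, float]]:
        return list(self.means.columns)

    def condition_average(self) -> pd.DataFrame:
        """Per-gene average of the condition means, one column per condition."""
        out = {}
        for cond in CONDITIONS:
            cols = [c for c in self.means.columns if c[0] == cond]
            out[cond] = self.means[cols].mean(axis=1)
        return pd.DataFrame(out)


def condition_means(expr: ExpressionMatrix) -> ConditionProfile:
    """Average replicate samples within each (condition, dose) group."""
    if expr.sample_info is None:
        raise ValueError("expression matrix has no sample condition/dose labels")
    info = expr.sample_info
    groups: dict[tuple[str, float], list[str]] = {}
    for s in expr.sample_ids:
        groups.setdefault((info.at[s, "condition"], float(info.at[s, "dose"])), []).append(s)
    cols = {}
    for key in sorted(groups, key=lambda k: (CONDITIONS.index(k[0]), k[1])):
        cols[key] = expr.data[groups[key]].mean(axis=1)
    means = pd.DataFrame(cols)
    means.columns = pd.MultiIndex.from_tuples(means.columns, names=["condition", "dose"])
    return ConditionProfile(means)


def normalize_profile(profile: ConditionProfile) -> ConditionProfile:
    """Fill ``normalized``: per-gene z-score then divide by max |z|.

    Population (1/n) standard deviation is used.  A constant gene row maps
    to all zeros.
    """
    m = profile.means.to_numpy(dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)  # population sd
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (m - mu) / sd
    zmax = np.abs(z).max(axis=1, keepdims=True)
    zmax[zmax == 0] = 1.0
    norm = z / zmax
    norm[constant] = 0.0
    profile.normalized = pd.DataFrame(
        norm, index=profile.means.index, columns=profile.means.columns
    )
    return profile


def select_upregulated_pairs(
    table: pd.DataFrame, profile: ConditionProfile
) -> tuple[pd.DataFrame, set[str]]:
    """Keep cross-talk records where both genes are up-regulated.

    "Up-regulated" means the average over all resistant condition means is
    strictly greater than the average over all parental condition means.
    Returns the subset table and the distinct genes involved.
    """
    avg = profile.condition_average()
    up = set(avg.index[avg[RESISTANT] > avg[PARENTAL]])
    keep = table["gene_i"].isin(up) & table["gene_j"].isin(up)
    subset = table[keep].reset_index(drop=True)
    genes = set(subset["gene_i"]) | set(subset["gene_j"])
    logger.info("%d of %d cross-talk records have both genes up-regulated",
                len(subset), len(table))
    return subset, genes


def fold_change_reversal(
    parental: ExpressionMatrix, resistant: ExpressionMatrix
) -> set[str]:
    """Genes whose treatment response flips sign in the resistant line.

    Per paired replicate s and gene: log2 fold-changes of every parental
    treatment dose vs. the parental basal (dose 0) sample of the same
    replicate, and of every resistant dose vs. that same parental basal.
    A gene is selected when, for SOME replicate, all parental-treatment
    log2FCs share one strict sign and all resistant-treatment log2FCs have
    the opposite strict sign.  Resistant basal fold-changes are computed
    but do not enter the predicate.  Non-positive expression values make
    the ratio undefined; such gene/replicate combinations are skipped with
    a warning.  A log2FC of exactly 0 counts as neither up- nor
    down-regulated.
    """
    for mat, label in ((parental, PARENTAL), (resistant, RESISTANT)):
        if mat.sample_info is None:
            raise ValueError(f"{label} matrix has no sample labels")
        if "replicate" not in mat.sample_info.columns:
            raise ValueError(f"{label} matrix has no replicate pairing")
    genes = [g for g in parental.gene_ids if g in set(resistant.gene_ids)]
    p_info, r_info = parental.sample_info, resistant.sample_info
    replicates = sorted(set(p_info["replicate"]) & set(r_info["replicate"]))
    selected: set[str] = set()
    n_skipped = 0
    for s in replicates:
        p_cols = p_info.index[p_info["replicate"] == s]
        r_cols = r_info.index[r_info["replicate"] == s]
        basal = [c for c in p_cols if float(p_info.at[c, "dose"]) == 0.0]
        if len(basal) != 1:
            raise ValueError(f"replicate {s}: need exactly one parental basal sample")
        p_treat = [c for c in p_cols if float(p_info.at[c, "dose"]) > 0.0]
        r_treat = [c for c in r_cols if float(r_info.at[c, "dose"]) > 0.0]
        if not p_treat or not r_treat:
            continue
        for gene in genes:
            ref = float(parental.data.at[gene, basal[0]])
            p_vals = parental.data.loc[gene, p_treat].to_numpy(dtype=float)
            r_vals = resistant.data.loc[gene, r_treat].to_numpy(dtype=float)
            if ref <= 0 or (p_vals <= 0).any() or (r_vals <= 0).any():
                n_skipped += 1
                continue
            p_fc = np.log2(p_vals / ref)
            r_fc = np.log2(r_vals / ref)
            if np.all(p_fc > 0) and np.all(r_fc < 0):
                selected.add(gene)
            elif np.all(p_fc < 0) and np.all(r_fc > 0):
                selected.add(gene)
    if n_skipped:
        logger.warning(
            "skipped %d gene/replicate fold-changes with non-positive values", n_skipped
        )
    return selected


def plot_heatmap(profile: ConditionProfile, path) -> None:
    """Optional genes x conditions heatmap (red = up, green = down).

    The normalized matrix TSV is the contract; this rendering is a
    convenience.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if profile.normalized is None:
        normalize_profile(profile)
    data = profile.normalized.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * data.shape[1]), max(4, 0.12 * data.shape[0]))
    )
    im = ax.imshow(data, cmap="RdYlGn_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(
        [f"{c}:{d:g}" for c, d in profile.normalized.columns], rotation=90, fontsize=7
    )
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(profile.normalized.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="normalized z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
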