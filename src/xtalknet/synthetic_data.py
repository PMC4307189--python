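"""Model-faithful synthetic inputs for every pipeline stage.

Two kinds of generators live here:

* direct p1-model simulators (propensity pairs from their bivariate
  normal prior, networks from the dyad-independent logistic model) used
  for parameter-recovery experiments; and
* a two-condition expression simulator with planted correlation
  structure: latent-factor blocks co-expressed in BOTH conditions, one
  latent group co-expressed ONLY in the resistant condition (whose
  pathway-of-interest x partner-pathway pairs are the planted cross-talk
  pairs), and independent background genes, all with a dose/replicate
  sample layout so the expression screens have inputs.

Detectability rationale for the defaults is documented in the package's
methods note: the p1-model smooths edge probabilities through gene
degrees, so planted pairs share one hub group (10 genes) rather than
being disjoint dyads, and the within-group correlation is nearly
noiseless (noise sd 0.1 against unit factors) because only 6 samples per
condition are available to estimate each correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crosstalk import PathwayCollection
from .expression_io import PARENTAL, RESISTANT, ExpressionMatrix
from .network_builder import RelationshipNetwork
from .p1_bayes import edge_probability

logger = logging.getLogger(__name__)

POI_NAME = "EGFR_ErbB_signaling"
PARTNER_NAME = "partner_signaling"


@dataclass
class SyntheticTruth:
    """Planted ground truth a recovery test asserts against."""

    seed: int
    planted_pairs: set[frozenset] = field(default_factory=set)
    block_assignments: dict[str, int] = field(default_factory=dict)
    pathway_truth: PathwayCollection | None = None
    theta_R: float | None = None
    theta_P: float | None = None
    alpha: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_pairs": sorted(sorted(p) for p in self.planted_pairs),
            "block_assignments": self.block_assignments,
        }
        if self.pathway_truth is not None:
            payload["pathway_truth"] = {
                "name": self.pathway_truth.name,
                "pathway_of_interest": self.pathway_truth.pathway_of_interest,
                "pathways": {
                    k: sorted(v) for k, v in self.pathway_truth.pathways.items()
                },
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls(
            seed=payload["seed"],
            planted_pairs={frozenset(p) for p in payload["planted_pairs"]},
            block_assignments=payload.get("block_assignments", {}),
        )
        if "pathway_truth" in payload:
            pt = payload["pathway_truth"]
            truth.pathway_truth = PathwayCollection(
                pt["name"], {k: set(v) for k, v in pt["pathways"].items()},
                pt["pathway_of_interest"],
            )
        return truth


# ---------------------------------------------------------------------------
# p1-model simulators
# ---------------------------------------------------------------------------

def simulate_alpha_pairs(g: int, sigma: np.ndarray, seed: int) -> np.ndarray:
    """g iid bivariate-normal propensity pairs, mean zero, covariance sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (2, 2) or not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be a symmetric 2x2 matrix")
    if np.any(np.linalg.eigvalsh(sigma) <= 0):
        raise ValueError("sigma must be positive-definite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(2), sigma, size=g, method="cholesky")


def simulate_p1_network(
    theta: float,
    alpha: np.ndarray,
    seed: int,
    gene_ids: list[str] | None = None,
    condition: str | None = None,
) -> RelationshipNetwork:
    """Draw a network from the undirected p1-model (generative direction)."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    g = alpha.size
    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(g)]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(g, 1)
    p = edge_probability(theta, alpha[iu[0]], alpha[iu[1]])
    adj = np.zeros((g, g), dtype=np.int8)
    adj[iu] = rng.random(p.shape) < p
    adj += adj.T
    return RelationshipNetwork(list(gene_ids), adj, condition=condition)


# ---------------------------------------------------------------------------
# toy pathway collections
# ---------------------------------------------------------------------------

def make_toy_pathways(
    gene_ids: list[str],
    n_pathways: int,
    size: int = 8,
    overlap: int = 0,
    seed: int = 0,
    forced: dict[str, set[str]] | None = None,
    name: str = "toy",
) -> PathwayCollection:
    """A pathway of interest plus ``n_pathways`` other pathways.

    Members are drawn without replacement from ``gene_ids``; consecutive
    "other" pathways share exactly ``overlap`` genes.  ``forced`` maps a
    pathway name (the pathway of interest is ``POI_NAME``, the first other
    pathway ``PARTNER_NAME``) to genes that must be members; forced genes
    count toward the requested size, which is conserved exactly.
    """
    if n_pathways < 1:
        raise ValueError("need at least one other pathway")
    rng = np.random.default_rng(seed)
    forced = {k: set(v) for k, v in (forced or {}).items()}
    names = [POI_NAME, PARTNER_NAME] + [
        f"pathway_{i}" for i in range(2, n_pathways + 1)
    ]
    reserved = set().union(*forced.values()) if forced else set()
    free = [x for x in gene_ids if x not in reserved]
    rng.shuffle(free)
    pathways: dict[str, set[str]] = {}
    cursor = 0
    prev_members: list[str] = []
    for idx, pname in enumerate(names):
        members = set(forced.get(pname, set()))
        if idx >= 1 and overlap > 0 and prev_members:
            members |= set(prev_members[:overlap])
        need = size - len(members)
        if need < 0:
            raise ValueError(f"pathway {pname!r}: forced members exceed size {size}")
        if cursor + need > len(free):
            raise ValueError("not enough genes for the requested pathway sizes")
        members |= set(free[cursor:cursor + need])
        cursor += need
        pathways[pname] = members
        prev_members = sorted(members - set(forced.get(pname, set())))
    return PathwayCollection(name, pathways, POI_NAME)


# ---------------------------------------------------------------------------
# two-condition expression simulator
# ---------------------------------------------------------------------------

def simulate_expression_pair(
    g: int = 60,
    n_replicates: int = 2,
    doses: tuple[float, ...] = (0.0, 0.1, 1.0),
    n_blocks: int = 3,
    block_size: int = 3,
    planted_poi: int = 2,
    planted_partner: int = 5,
    planted_extra: int = 3,
    noise_sd: float = 0.03,
    amplitude: float = 10.0,
    baseline_range: tuple[float, float] = (50.0, 150.0),
    resistant_shift: float = 0.2,
    n_pathways: int = 4,
    pathway_size: int = 8,
    correlate: bool = True,
    shift: bool = True,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate parental and resistant expression matrices with planted truth.

    Genes fall into three tiers: ``n_blocks`` latent-factor blocks
    co-expressed in both conditions; one resistant-only latent group of
    ``planted_poi + planted_partner + planted_extra`` genes whose
    pathway-of-interest x partner-pathway pairs (planted_poi *
    planted_partner of them) are the planted cross-talk pairs; and
    independent background genes.  Planted-group genes additionally gain a
    positive mean shift (``resistant_shift`` x baseline) in resistant
    samples so the up-regulation screen can find them; ``correlate`` /
    ``shift`` disable the correlation or shift signal respectively.
    Samples are laid out as len(doses) doses x ``n_replicates`` replicates
    per condition, with no systematic dose effect (a shared dose response
    would correlate all genes and confound the planted structure).
    """
    n_block_genes = n_blocks * block_size
    n_planted = planted_poi + planted_partner + planted_extra
    if n_block_genes + n_planted > g:
        raise ValueError("g too small for the requested blocks and planted group")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:03d}" for i in range(g)]
    block_genes = gene_ids[:n_block_genes]
    planted_genes = gene_ids[n_block_genes:n_block_genes + n_planted]
    poi_genes = planted_genes[:planted_poi]
    partner_genes = planted_genes[planted_poi:planted_poi + planted_partner]
    background = gene_ids[n_block_genes + n_planted:]

    n_samples = n_replicates * len(doses)
    baseline = rng.uniform(*baseline_range, size=g)

    matrices = {}
    sample_infos = {}
    for cond in (PARENTAL, RESISTANT):
        sample_ids, cond_rows, dose_col, rep_col = [], [], [], []
        for rep in range(1, n_replicates + 1):
            for dose in doses:
                sample_ids.append(f"{cond[0].upper()}_r{rep}_d{dose:g}")
                dose_col.append(dose)
                rep_col.append(rep)
        values = baseline[:, None] + amplitude * rng.standard_normal((g, n_samples))
        if correlate:
            # both-condition blocks
            for b in range(n_blocks):
                f = rng.standard_normal(n_samples)
                rows = slice(b * block_size, (b + 1) * block_size)
                values[rows] = baseline[rows, None] + amplitude * (
                    f[None, :] + noise_sd * rng.standard_normal((block_size, n_samples))
                )
            # resistant-only planted group
            if cond == RESISTANT:
                f = rng.standard_normal(n_samples)
                rows = slice(n_block_genes, n_block_genes + n_planted)
                values[rows] = baseline[rows, None] + amplitude * (
                    f[None, :] + noise_sd * rng.standard_normal((n_planted, n_samples))
                )
        if shift and cond == RESISTANT:
            rows = slice(n_block_genes, n_block_genes + n_planted)
            values[rows] += resistant_shift * baseline[rows, None]
        data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
        data.index.name = "gene_symbol"
        info = pd.DataFrame(
            {"condition": cond, "dose": dose_col, "replicate": rep_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        matrices[cond] = ExpressionMatrix(data, info)
        sample_infos[cond] = info

    planted_pairs = {
        frozenset((a, b)) for a in poi_genes for b in partner_genes
    }
    pathway_truth = make_toy_pathways(
        background,
        n_pathways=max(n_pathways, 2),
        size=pathway_size,
        seed=int(rng.integers(2 ** 31)),
        forced={POI_NAME: set(poi_genes), PARTNER_NAME: set(partner_genes)},
        name="synthetic",
    )
    blocks = {
        gene: b for b in range(n_blocks)
        for gene in block_genes[b * block_size:(b + 1) * block_size]
    }
    truth = SyntheticTruth(
        seed=seed,
        planted_pairs=planted_pairs,
        block_assignments=blocks,
        pathway_truth=pathway_truth,
    )
    logger.info(
        "simulated %d genes x %d samples/condition: %d block genes, "
        "%d planted-group genes (%d planted pairs)",
        g, n_samples, n_block_genes, n_planted, len(planted_pairs),
    )
    return matrices[PARENTAL], matrices[RESISTANT], truth
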