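"""End-to-end orchestration: expression -> networks -> posterior -> cross-talks.

``run_pipeline`` executes the stages behind a single :class:`RunConfig`
(loadable from a flat YAML file), writes every intermediate artifact into
the output directory, and returns a manifest with the configuration
echo, seed, stage timings and the headline counts (edges per network,
resistant-specific pairs, cross-talks all/distinct/other-pathways).

Any stage error aborts the run with the stage name; a ``FAILED`` marker
file is left next to whatever partial outputs were written.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crosstalk import (
    PathwayCollection,
    enumerate_crosstalk_pairs,
    filter_resistant_pairs,
    intersect_crosstalks,
    read_gmt,
    read_pathway_dir,
    summarize_crosstalks,
)
from .expression_io import (
    PARENTAL,
    RESISTANT,
    ExpressionMatrix,
    collapse_probes,
    read_expression_table,
    read_probe_annotation,
    read_sample_map,
    read_seed_genes,
    restrict_to_seed_genes,
    split_conditions,
    write_expression_table,
)
from .expression_profiles import (
    condition_means,
    fold_change_reversal,
    normalize_profile,
    plot_heatmap,
    select_upregulated_pairs,
)
from .network_builder import (
    abs_pcc_matrix,
    build_network,
    select_threshold,
    write_network,
)
from .p1_bayes import P1Config, P1Posterior, gibbs_fit

logger = logging.getLogger(__name__)


@dataclass
class PathwaySource:
    """One pathway collection input: a GMT file or a directory of lists."""

    name: str
    path: str
    pathway_of_interest: str
    format: str = "gmt"  # "gmt" | "dir"

    def load(self) -> PathwayCollection:
        if self.format == "gmt":
            return read_gmt(self.path, self.name, self.pathway_of_interest)
        if self.format == "dir":
            return read_pathway_dir(self.path, self.name, self.pathway_of_interest)
        raise ValueError(f"unknown pathway format {self.format!r}")


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Exactly one of (explicit per-condition thresholds, top_fraction) must
    be set.  ``annotation`` is optional: without it the expression table is
    taken to be gene-level already.  ``seed_genes`` is optional: without it
    every expressed gene is a network node.
    """

    expression: str
    sample_map: str
    out_dir: str
    seed: int
    pathways: list[PathwaySource] = field(default_factory=list)
    annotation: str | None = None
    annotation_header: bool = False
    seed_genes: str | None = None
    threshold_parental: float | None = None
    threshold_resistant: float | None = None
    top_fraction: float | None = None
    n_iter: int = 6000
    burn_in: int = 5000
    estimator: str = "mean"
    sampler: str = "polya_gamma"
    odds_min: float = 10.0
    pr_min: float = 0.5
    make_heatmap: bool = False

    def __post_init__(self) -> None:
        explicit = self.threshold_parental is not None or self.threshold_resistant is not None
        if explicit and self.top_fraction is not None:
            raise ValueError("set either explicit thresholds or top_fraction, not both")
        if not explicit and self.top_fraction is None:
            raise ValueError("one of explicit thresholds or top_fraction is required")
        if explicit and (self.threshold_parental is None or self.threshold_resistant is None):
            raise ValueError("explicit mode needs both per-condition thresholds")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["pathways"] = [
            p if isinstance(p, PathwaySource) else PathwaySource(**p)
            for p in raw.get("pathways", [])
        ]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "pathways"}
        d["pathways"] = [vars(p) for p in self.pathways]
        return d


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("xtalknet")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def save_posterior(posterior: P1Posterior, out_dir: Path) -> None:
    """Draws as a long TSV (iteration, parameter, value); edge-probability
    matrices as gzipped TSV with gene ids as header/index."""
    rows = []
    labels_theta = ("theta_R", "theta_P")
    for t in range(posterior.n_draws):
        for c in range(2):
            rows.append((t, labels_theta[c], posterior.theta[t, c]))
            rows.append((t, f"tau_{labels_theta[c]}", posterior.tau_theta[t, c]))
        rows.append((t, "sigma_RR", posterior.sigma[t, 0, 0]))
        rows.append((t, "sigma_RP", posterior.sigma[t, 0, 1]))
        rows.append((t, "sigma_PP", posterior.sigma[t, 1, 1]))
        for i, gene in enumerate(posterior.gene_ids):
            rows.append((t, f"alpha_R[{gene}]", posterior.alpha[t, i, 0]))
            rows.append((t, f"alpha_P[{gene}]", posterior.alpha[t, i, 1]))
    pd.DataFrame(rows, columns=["iteration", "parameter", "value"]).to_csv(
        out_dir / "posterior_draws.tsv", sep="\t", index=False
    )
    for label, mat in (("R", posterior.edge_prob_R), ("P", posterior.edge_prob_P)):
        pd.DataFrame(mat, index=posterior.gene_ids, columns=posterior.gene_ids).to_csv(
            out_dir / f"edge_prob_{label}.tsv.gz", sep="\t", compression="gzip"
        )
    posterior.diagnostics().to_csv(out_dir / "diagnostics.tsv", sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"xtalknet": __version__},
        "stages": {},
        "counts": {},
    }
    with open(out_dir / "config.echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    stage = "expression_io"
    t0 = time.perf_counter()
    try:
        # ------------------------------------------------ expression_io
        expr = read_expression_table(config.expression)
        if config.annotation:
            ann = read_probe_annotation(config.annotation, header=config.annotation_header)
            expr = collapse_probes(expr, ann)
        sample_map = read_sample_map(config.sample_map)
        if config.seed_genes:
            seeds = read_seed_genes(config.seed_genes)
            expr, missing = restrict_to_seed_genes(expr, seeds)
            manifest["counts"]["seed_genes_missing"] = len(missing)
        parental, resistant = split_conditions(expr, sample_map)
        for label, mat in ((PARENTAL, parental), (RESISTANT, resistant)):
            write_expression_table(mat, out_dir / f"expression_{label}.tsv")
        manifest["counts"]["genes"] = expr.n_genes
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ network_builder
        stage, t0 = "network_builder", time.perf_counter()
        networks = {}
        for label, mat in ((RESISTANT, resistant), (PARENTAL, parental)):
            pcc = abs_pcc_matrix(mat)
            if config.top_fraction is not None:
                thr = select_threshold(pcc, config.top_fraction)
            else:
                thr = (config.threshold_resistant if label == RESISTANT
                       else config.threshold_parental)
            net = build_network(pcc, thr, condition=label)
            write_network(net, out_dir / f"nodes_{label}.txt",
                          out_dir / f"edges_{label}.tsv", pcc)
            networks[label] = net
            manifest["counts"][f"edges_{label}"] = net.n_edges
            manifest["counts"][f"threshold_{label}"] = thr
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ p1_bayes (joint fit)
        stage, t0 = "p1_bayes", time.perf_counter()
        p1_config = P1Config(
            seed=config.seed,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            edge_prob_estimator=config.estimator,
            sampler=config.sampler,
        )
        posterior = gibbs_fit(networks[RESISTANT], networks[PARENTAL], p1_config)
        save_posterior(posterior, out_dir)
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ expression_profiles (means)
        stage, t0 = "expression_profiles", time.perf_counter()
        combined = ExpressionMatrix(
            pd.concat([parental.data, resistant.data], axis=1),
            pd.concat([parental.sample_info, resistant.sample_info]),
        )
        profile = normalize_profile(condition_means(combined))
        profile.means.to_csv(out_dir / "condition_means.tsv", sep="\t")
        profile.normalized.to_csv(out_dir / "profile_normalized.tsv", sep="\t")
        if config.make_heatmap:
            plot_heatmap(profile, out_dir / "heatmap.png")
        avg_ge = profile.condition_average()
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ crosstalk (per collection)
        stage, t0 = "crosstalk", time.perf_counter()
        candidates = filter_resistant_pairs(
            posterior.edge_prob_R, posterior.edge_prob_P, posterior.gene_ids,
            odds_min=config.odds_min, pr_min=config.pr_min,
        )
        manifest["counts"]["resistant_pairs"] = len(candidates)
        universe = posterior.gene_ids
        tables: dict[str, pd.DataFrame] = {}
        for source in config.pathways:
            collection = source.load()
            triples = enumerate_crosstalk_pairs(collection, universe)
            table = intersect_crosstalks(candidates, triples, avg_ge)
            table.to_csv(out_dir / f"crosstalks_{source.name}.csv", index=False)
            tables[source.name] = table
            summary = summarize_crosstalks(table)
            summary["n_candidate_crosstalks"] = len(triples)
            manifest["counts"][f"crosstalk_{source.name}"] = summary
        if len(tables) > 1:
            manifest["counts"]["pairs_in_2plus_sources"] = summarize_crosstalks(
                next(iter(tables.values())), multi=tables
            )["n_pairs_in_2plus_sources"]
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ expression screens
        stage, t0 = "screens", time.perf_counter()
        if tables:
            merged = pd.concat(
                [t.assign(source=name) for name, t in tables.items()],
                ignore_index=True,
            )
            upregulated, up_genes = select_upregulated_pairs(merged, profile)
            upregulated.to_csv(out_dir / "crosstalks_upregulated.csv", index=False)
            manifest["counts"]["upregulated_crosstalks"] = len(upregulated)
            manifest["counts"]["upregulated_genes"] = len(up_genes)
        try:
            reversal = fold_change_reversal(parental, resistant)
            (out_dir / "fold_change_reversal_genes.txt").write_text(
                "\n".join(sorted(reversal)) + ("\n" if reversal else "")
            )
            manifest["counts"]["reversal_genes"] = len(reversal)
        except ValueError as exc:
            logger.warning("fold-change reversal screen skipped: %s", exc)
        manifest["stages"][stage] = time.perf_counter() - t0
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    finally:
        logging.getLogger("xtalknet").removeHandler(handler)
        handler.close()

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest


# ---------------------------------------------------------------------------
# synthetic dataset writer (backs the `simulate` subcommand)
# ---------------------------------------------------------------------------

def write_synthetic_dataset(out_dir, seed: int, **sim_kwargs) -> dict:
    """Simulate a two-condition dataset and write it in pipeline input formats.

    Writes expression.tsv (both conditions side by side), sample_map.tsv,
    seed_genes.txt, pathways.gmt, truth.json and a ready-to-run config.yaml;
    returns the paths.
    """
    from .synthetic_data import simulate_expression_pair

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parental, resistant, truth = simulate_expression_pair(seed=seed, **sim_kwargs)
    expr = pd.concat([parental.data, resistant.data], axis=1)
    expr.index.name = "gene_symbol"
    paths = {
        "expression": out_dir / "expression.tsv",
        "sample_map": out_dir / "sample_map.tsv",
        "seed_genes": out_dir / "seed_genes.txt",
        "pathways": out_dir / "pathways.gmt",
        "truth": out_dir / "truth.json",
        "config": out_dir / "config.yaml",
    }
    expr.to_csv(paths["expression"], sep="\t")
    info = pd.concat([parental.sample_info, resistant.sample_info])
    info.to_csv(paths["sample_map"], sep="\t", index_label="sample_id")
    paths["seed_genes"].write_text("\n".join(expr.index) + "\n")
    collection = truth.pathway_truth
    with open(paths["pathways"], "w") as fh:
        for name, genes in collection.pathways.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
    truth.to_json(paths["truth"])
    config = {
        "expression": str(paths["expression"]),
        "sample_map": str(paths["sample_map"]),
        "seed_genes": str(paths["seed_genes"]),
        "pathways": [
            {
                "name": collection.name,
                "path": str(paths["pathways"]),
                "pathway_of_interest": collection.pathway_of_interest,
                "format": "gmt",
            }
        ],
        "threshold_parental": 0.95,
        "threshold_resistant": 0.95,
        "n_iter": 1500,
        "burn_in": 1000,
        "out_dir": str(out_dir / "results"),
        "seed": seed,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return {k: str(v) for k, v in paths.items()}
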