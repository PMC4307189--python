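"""Reading and reshaping expression tables.

Probe-level microarray intensity tables are read from TSV, collapsed to
gene-level matrices by averaging all probes annotated to the same gene
symbol, split into condition-specific matrices (parental vs. resistant)
via a user-supplied sample map, and restricted to a seed gene list
(e.g. a cancer gene census).

Gene-symbol matching is case-sensitive exact string matching throughout;
no alias resolution is attempted.  Expression values are used as provided
(no log transform is applied before correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARENTAL = "parental"
RESISTANT = "resistant"
CONDITIONS = (PARENTAL, RESISTANT)


class ExpressionParseError(ValueError):
    """Raised when an expression/annotation/sample-map file is malformed."""


@dataclass
class ExpressionMatrix:
    """A genes-by-samples (or probes-by-samples) real-valued matrix.

    ``data`` is a DataFrame indexed by feature identifier with sample
    identifiers as columns.  ``sample_info`` (optional) carries per-sample
    ``condition`` (parental/resistant), numeric ``dose`` and an integer
    ``replicate`` pairing index; it is attached by :func:`split_conditions`.
    """

    data: pd.DataFrame
    sample_info: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ExpressionParseError(f"duplicate feature identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ExpressionParseError(f"duplicate sample identifier: {dup!r}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy(dtype=float)))[0]
            raise ExpressionParseError(
                f"non-finite value at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.sample_info is not None and not self.sample_info.index.equals(
            self.data.columns
        ):
            self.sample_info = self.sample_info.reindex(self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression_table(path) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    Expected layout: one header row of unique sample identifiers, a leading
    feature-identifier column, and real-valued cells.  Any cell that does
    not parse as a finite number (including ``NA``) is a parse error naming
    the offending row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for s in header:
        if s in seen:
            raise ExpressionParseError(f"duplicate sample identifier in header: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = probe.isna() | ~np.isfinite(probe.to_numpy(dtype=float))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionParseError(
            f"non-numeric cell {raw.iloc[i, j]!r} at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    # numpy's string parser is correctly rounded, so written values round-trip
    numeric = pd.DataFrame(
        raw.to_numpy(dtype=object).astype(np.float64),
        index=raw.index, columns=raw.columns,
    )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = raw.index.name or "feature_id"
    return ExpressionMatrix(numeric)


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    """Write a matrix in the same TSV layout ``read_expression_table`` reads."""
    expr.data.to_csv(
        path, sep="\t", index_label=expr.data.index.name or "feature_id",
        float_format="%.17g",  # exact binary round trip
    )


def read_probe_annotation(path, header: bool = False) -> dict[str, str]:
    """Read a two-column TSV mapping probe id -> gene symbol.

    Probes that appear more than once (multi-mapping annotation rows) are
    dropped entirely with a warning; blank symbols mark unmapped probes and
    are skipped.
    """
    ann = pd.read_csv(
        path, sep="\t", header=0 if header else None, dtype=str, keep_default_na=False
    )
    if ann.shape[1] < 2:
        raise ExpressionParseError(f"annotation file {path} needs two columns")
    probes = ann.iloc[:, 0].astype(str)
    symbols = ann.iloc[:, 1].astype(str)
    multi = probes[probes.duplicated(keep=False)].unique()
    if len(multi):
        logger.warning("dropping %d multi-mapping probes", len(multi))
    mapping: dict[str, str] = {}
    for probe, symbol in zip(probes, symbols):
        if probe in multi or not symbol.strip():
            continue
        mapping[probe] = symbol.strip()
    return mapping


def collapse_probes(expr: ExpressionMatrix, annotation: dict[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Each output row is the per-sample arithmetic mean of all probe rows
    annotated to that gene symbol.  Unmapped probes are dropped.  Output
    gene order is lexicographic.
    """
    symbols = pd.Series(
        [annotation.get(p) for p in expr.data.index], index=expr.data.index
    )
    mapped = symbols.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.warning("dropping %d probes without a gene symbol", n_dropped)
    if not mapped.any():
        raise ExpressionParseError("no probe maps to any gene symbol")
    collapsed = expr.data.loc[mapped].groupby(symbols[mapped]).mean().sort_index()
    collapsed.index.name = "gene_symbol"
    return ExpressionMatrix(collapsed, expr.sample_info)


def read_sample_map(path) -> pd.DataFrame:
    """Read a sample map TSV: sample_id, condition, dose[, replicate].

    A header row is auto-detected (first row whose condition column is not a
    known condition label).  The replicate column, when absent, defaults to a
    per-(condition, dose) running index so fold-change screens can pair
    samples across conditions.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.shape[1] < 3:
        raise ExpressionParseError(f"sample map {path} needs >= 3 columns")
    first_cond = str(table.iloc[0, 1]) if len(table) else ""
    if table.columns[1].lower() != "condition" and first_cond in CONDITIONS:
        # no header: re-read without one
        table = pd.read_csv(path, sep="\t", dtype=str, header=None, keep_default_na=False)
    table = table.iloc[:, :4] if table.shape[1] >= 4 else table.iloc[:, :3]
    table.columns = ["sample_id", "condition", "dose", "replicate"][: table.shape[1]]
    table = table.set_index("sample_id")
    bad = ~table["condition"].isin(CONDITIONS)
    if bad.any():
        raise ExpressionParseError(
            f"unknown condition {table['condition'][bad].iloc[0]!r} for sample "
            f"{table.index[bad][0]!r}"
        )
    table["dose"] = pd.to_numeric(table["dose"], errors="raise").astype(float)
    if (table["dose"] < 0).any():
        raise ExpressionParseError("negative dose in sample map")
    if "replicate" in table.columns:
        table["replicate"] = pd.to_numeric(table["replicate"], errors="raise").astype(int)
    else:
        table["replicate"] = table.groupby(["condition", "dose"]).cumcount()
    return table


def split_conditions(
    expr: ExpressionMatrix, sample_map: pd.DataFrame
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition columns into (parental, resistant) matrices.

    Every sample of ``expr`` must appear in ``sample_map``; each condition
    must end up with at least one sample.  Gene order is preserved and dose /
    replicate labels are attached per column.
    """
    missing = [s for s in expr.sample_ids if s not in sample_map.index]
    if missing:
        raise ExpressionParseError(f"sample {missing[0]!r} absent from sample map")
    out = []
    for cond in CONDITIONS:
        cols = [s for s in expr.sample_ids if sample_map.loc[s, "condition"] == cond]
        if not cols:
            raise ExpressionParseError(f"no samples labelled {cond!r}")
        out.append(ExpressionMatrix(expr.data[cols].copy(), sample_map.loc[cols].copy()))
    return out[0], out[1]


def read_seed_genes(path) -> list[str]:
    """Read a seed-gene list: one symbol per line, blanks ignored."""
    with open(path) as fh:
        seeds = [line.strip() for line in fh if line.strip()]
    # preserve order, drop duplicates
    return list(dict.fromkeys(seeds))


def restrict_to_seed_genes(
    expr: ExpressionMatrix, seeds: list[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep only rows whose symbol is in ``seeds`` (exact match).

    Returns the restricted matrix (in the matrix's original row order) and
    the list of seed symbols that had no expression row.
    """
    present = set(expr.data.index)
    missing = [s for s in seeds if s not in present]
    keep = [g for g in expr.data.index if g in set(seeds)]
    if not keep:
        raise ExpressionParseError("no seed gene has an expression row")
    if missing:
        logger.info("%d of %d seed genes have no expression row", len(missing), len(seeds))
    return ExpressionMatrix(expr.data.loc[keep].copy(), expr.sample_info), missing
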