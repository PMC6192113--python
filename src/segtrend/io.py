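"""Readers and writers for expression matrices, time vectors and result tables.

Genes are rows and samples are columns, matching the usual bulk-expression
convention.  Matrices travel as tab- or comma-separated text with gene ids in
the first column and sample ids in the header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gene_model import GeneFit, TrendConfig, segment_pvalue
from .segreg import TimeVector
from .summary import breakpoint_distribution, top_genes, trend_matrix

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_times",
    "sort_by_time",
    "filter_low_expression",
    "write_results",
]

log = logging.getLogger("segtrend")


class ParseError(ValueError):
    """Malformed expression-matrix or time-vector file."""


@dataclass
class ExpressionMatrix:
    """G-by-N matrix of normalized expression values with row/column labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x samples)")
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.gene_ids)} genes"
                f" and {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g}")
            seen.add(g)
        self.values = v

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, sep: str | None = None) -> ExpressionMatrix:
    """Read a genes-by-samples matrix from delimited text.

    The first column holds gene ids and the header row sample ids.  The
    delimiter is inferred from the extension (.csv -> comma, otherwise tab)
    unless ``sep`` overrides it.  Ragged rows, non-numeric cells, duplicate
    gene ids and negative values raise :class:`ParseError` naming the culprit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate gene id(s) {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: non-numeric cell ({e})") from e
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing or non-numeric cell at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ParseError(
            f"{path}: negative expression at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}; input must be normalized non-negative"
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def write_expression(matrix: ExpressionMatrix, path, sep: str | None = None) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path, sep), float_format="%.10g")


def read_times(source, n_expected: int | None = None) -> TimeVector:
    """Parse a time vector from a file (one value per line, commas/whitespace
    allowed) or an in-memory sequence.

    The returned vector is sorted; use :func:`sort_by_time` to co-permute the
    matrix columns when the file order is not already time-sorted.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        raw = text.replace(",", " ").split()
    else:
        raw = list(source)
    try:
        vals = np.array([float(x) for x in raw], dtype=float)
    except (TypeError, ValueError) as e:
        raise ParseError(f"non-numeric time value: {e}") from e
    if n_expected is not None and vals.size != n_expected:
        raise ParseError(
            f"time vector has {vals.size} values; expected {n_expected}"
        )
    return TimeVector(np.sort(vals))


def sort_by_time(matrix: ExpressionMatrix, time_values) -> tuple[ExpressionMatrix, TimeVector]:
    """Stable-sort samples (matrix columns and times together) by time."""
    t = np.asarray(list(time_values), dtype=float)
    if t.size != matrix.n_samples:
        raise ParseError(
            f"time vector has {t.size} values; matrix has {matrix.n_samples} samples"
        )
    order = np.argsort(t, kind="stable")
    sorted_matrix = ExpressionMatrix(
        values=matrix.values[:, order],
        gene_ids=list(matrix.gene_ids),
        sample_ids=[matrix.sample_ids[i] for i in order],
    )
    return sorted_matrix, TimeVector(t[order])


def filter_low_expression(
    matrix: ExpressionMatrix, mean_cut: float
) -> tuple[ExpressionMatrix, dict]:
    """Keep genes with row mean strictly above ``mean_cut``.

    Returns the filtered matrix and a report dict with kept/removed counts and
    the removed gene ids.
    """
    if mean_cut < 0:
        raise ValueError("mean_cut must be >= 0")
    means = matrix.values.mean(axis=1)
    keep = means > mean_cut
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    filtered = ExpressionMatrix(
        values=matrix.values[keep],
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
    )
    report = {
        "input": matrix.n_genes,
        "kept": filtered.n_genes,
        "removed": len(removed),
        "removed_ids": removed,
    }
    return filtered, report


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def gene_table(fits: Sequence[GeneFit]) -> pd.DataFrame:
    """One row per gene: selected k, adjusted R², trend string, breakpoints."""
    rows = []
    for f in fits:
        rows.append(
            {
                "gene": f.gene_id,
                "k": f.k_selected,
                "adj_r2": _fmt(f.adj_r2),
                "trend": f.trend_string,
                "breakpoints": ",".join(_fmt(b) for b in f.breakpoints),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "k", "adj_r2", "trend", "breakpoints"])


def segment_table(fits: Sequence[GeneFit], times: TimeVector, config: TrendConfig) -> pd.DataFrame:
    """Long table: one row per fitted segment with slope, SE, p-value, label."""
    rows = []
    for f in fits:
        bounds = np.concatenate([[times.t_min], f.breakpoints, [times.t_max]])
        for i, (slope, se, label) in enumerate(
            zip(f.model.slopes, f.model.slope_se, f.segment_trends)
        ):
            p = segment_pvalue(
                float(slope), float(se), config.df_mode, times.n, f.k_selected
            )
            rows.append(
                {
                    "gene": f.gene_id,
                    "segment": i + 1,
                    "t_start": _fmt(bounds[i]),
                    "t_end": _fmt(bounds[i + 1]),
                    "slope": _fmt(slope),
                    "slope_se": _fmt(se),
                    "p_value": _fmt(p),
                    "label": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "segment", "t_start", "t_end",
            "slope", "slope_se", "p_value", "label",
        ],
    )


def write_results(
    fits: Sequence[GeneFit],
    times: TimeVector,
    out_dir,
    config: TrendConfig | None = None,
    filter_report: dict | None = None,
) -> dict[str, Path]:
    """Write the per-gene table, segment table, breakpoint distribution D_t,
    encoded trend matrix, the echoed config and a run log.

    The breakpoint distribution and trend matrix cover the top genes at the
    configured adjusted-R² cutoff.  Output is deterministic: re-running with
    the same config and seed reproduces byte-identical files.
    """
    cfg = config or TrendConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = gene_table(fits)
    paths["genes"] = out / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False)

    segs = segment_table(fits, times, cfg)
    paths["segments"] = out / "segments.tsv"
    segs.to_csv(paths["segments"], sep="\t", index=False)

    top = top_genes(fits, cfg.r2_cut)
    dist = breakpoint_distribution(top, times)
    paths["breakpoints"] = out / "breakpoint_distribution.tsv"
    dist.to_frame().to_csv(paths["breakpoints"], sep="\t", index=False)

    tm = trend_matrix(top, times)
    paths["trend_matrix"] = out / "trend_matrix.tsv"
    tm.to_csv(paths["trend_matrix"], sep="\t", index_label="gene")

    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(vars(cfg), fh, sort_keys=True)

    paths["log"] = out / "run.log"
    lines = [
        f"segtrend run: {len(fits)} genes fitted, {len(top)} top genes "
        f"(adj_r2 > {cfg.r2_cut})",
        f"parameters: max_k={cfg.max_k} min_seg={cfg.min_seg} "
        f"pval_cut={cfg.pval_cut} mean_cut={cfg.mean_cut} "
        f"df_mode={cfg.df_mode} seed={cfg.seed}",
        f"total breakpoints among top genes: {dist.total}",
    ]
    if filter_report is not None:
        lines.insert(
            1,
            f"mean-expression filter: {filter_report['kept']} of "
            f"{filter_report['input']} genes kept "
            f"({filter_report['removed']} removed)",
        )
    paths["log"].write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info(line)
    return paths
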