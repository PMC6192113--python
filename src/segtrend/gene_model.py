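"""Per-gene model selection, quality gating and trend classification.

For each gene the candidate models with k = 0..K breakpoints are fitted and
the breakpoint count is chosen by BIC.  An overfit guard then decrements the
chosen k while any segment holds fewer than ``min_seg`` samples.  The selected
model is scored by adjusted R-squared (the downstream "top gene" gate) and each
segment is labelled 'up', 'down' or 'same' from the sign and p-value of its
slope.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import log
from typing import Mapping

import numpy as np
from scipy import stats

from .segreg import (
    InfeasibleKError,
    SegmentedModel,
    TimeVector,
    fit_segmented,
)

__all__ = [
    "TrendConfig",
    "GeneFit",
    "UndefinedFitError",
    "bic_score",
    "select_model",
    "segment_sample_counts",
    "enforce_min_segment",
    "adjusted_r_squared",
    "segment_pvalue",
    "classify_segments",
    "fit_gene",
    "fit_matrix",
    "TREND_CODES",
]

TREND_CODES = {"up": 1, "down": -1, "same": 0}


class UndefinedFitError(ValueError):
    """Adjusted R-squared denominator is non-positive; gene cannot be scored."""


@dataclass
class TrendConfig:
    """Analysis parameters.

    max_k
        Maximum number of breakpoints considered per gene (default 3).
    min_seg
        Minimum number of samples required in every segment of the selected
        model; the overfit guard decrements k until satisfied (default 5).
    pval_cut
        Slope p-value above which a segment is labelled 'same' (default 0.1).
    r2_cut
        Adjusted R-squared threshold defining top dynamic genes (default 0.5).
    mean_cut
        Genes with row mean expression at or below this are filtered out
        before fitting (default 5).
    df_mode
        "paper": the slope t-statistic is compared to a t-distribution with
        one degree of freedom.  "residual": conventional residual degrees of
        freedom n - (2k + 2).
    tol, max_iter, n_starts, seed
        Breakpoint-optimiser controls passed through to the fitting engine.
    """

    max_k: int = 3
    min_seg: int = 5
    pval_cut: float = 0.1
    r2_cut: float = 0.5
    mean_cut: float = 5.0
    df_mode: str = "paper"
    tol: float = 1e-6
    max_iter: int = 50
    n_starts: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        if self.min_seg < 2:
            raise ValueError("min_seg must be >= 2")
        if not 0 < self.pval_cut < 1:
            raise ValueError("pval_cut must be in (0, 1)")
        if not 0 <= self.r2_cut <= 1:
            raise ValueError("r2_cut must be in [0, 1]")
        if self.df_mode not in ("paper", "residual"):
            raise ValueError("df_mode must be 'paper' or 'residual'")


@dataclass
class GeneFit:
    """Selection result for one gene."""

    gene_id: str
    k_selected: int
    model: SegmentedModel
    adj_r2: float
    bic_by_k: dict[int, float]
    segment_trends: list[str]
    trend_string: str

    @property
    def breakpoints(self) -> np.ndarray:
        return self.model.breakpoints

    @property
    def trend_codes(self) -> np.ndarray:
        """Numeric encoding of the segment labels: up=1, down=-1, same=0."""
        return np.array([TREND_CODES[s] for s in self.segment_trends])


def bic_score(loglik: float, n: int, k: int) -> float:
    """BIC = log(n)·(2k+3) − 2·loglik.

    The parameter count charges k breakpoints, k+1 segment slopes, an
    intercept and an error variance.  A +inf log-likelihood (perfect fit)
    yields −inf, which dominates the argmin; ties go to smaller k.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return log(n) * (2 * k + 3) - 2.0 * loglik


def select_model(models: Mapping[int, SegmentedModel], n: int) -> int | None:
    """BIC-argmin over converged candidate models; ties break to smaller k.

    Returns None when no candidate converged (the gene is unfittable and must
    be excluded downstream).
    """
    best_k = None
    best_bic = np.inf
    for k in sorted(models):
        m = models[k]
        if not m.converged:
            continue
        b = bic_score(m.loglik, n, k)
        if b < best_bic:
            best_k, best_bic = k, b
    return best_k


def segment_sample_counts(times: TimeVector, breakpoints) -> np.ndarray:
    """Samples per segment under half-open [lo, hi) intervals.

    A sample exactly at a breakpoint belongs to the following segment; the
    last segment is closed at t_T.  Replicates count individually.
    """
    b = np.asarray(breakpoints, dtype=float)
    idx = np.searchsorted(b, times.values, side="right")
    return np.bincount(idx, minlength=b.size + 1)


def enforce_min_segment(
    models: Mapping[int, SegmentedModel],
    k_selected: int,
    times: TimeVector,
    min_seg: int,
) -> int:
    """Overfit guard: decrement k while any segment has < min_seg samples.

    Each decrement re-checks the next smaller converged candidate (the k=0
    model has a single all-sample segment and always satisfies the guard for
    min_seg <= n).
    """
    k = k_selected
    while k > 0:
        m = models.get(k)
        if m is not None and m.converged:
            counts = segment_sample_counts(times, m.breakpoints)
            if np.all(counts >= min_seg):
                return k
        k -= 1
    return 0


def adjusted_r_squared(r2: float, n: int, k_selected: int) -> float:
    """R̄² = 1 − (1 − R²)(n − 1)/(n − (k̃+1) − 1); can be negative."""
    denom = n - (k_selected + 1) - 1
    if denom <= 0:
        raise UndefinedFitError(
            f"adjusted R^2 undefined for n={n}, k={k_selected}"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / denom


def segment_pvalue(
    slope: float,
    se: float,
    df_mode: str = "paper",
    n: int | None = None,
    k: int | None = None,
) -> float:
    """Two-sided p-value of the slope t-statistic.

    The default compares t = slope/se to a t-distribution with one degree of
    freedom (a Cauchy reference, deliberately conservative for labelling);
    "residual" mode uses n − (2k+2) degrees of freedom instead.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0:
        return 1.0 if slope == 0 else 0.0
    if not np.isfinite(se):
        return 1.0
    if df_mode == "paper":
        df = 1
    elif df_mode == "residual":
        if n is None or k is None:
            raise ValueError("residual df mode needs n and k")
        df = n - (2 * k + 2)
        if df <= 0:
            return 1.0
    else:
        raise ValueError("df_mode must be 'paper' or 'residual'")
    t = slope / se
    return float(2.0 * stats.t.sf(abs(t), df))


def classify_segments(
    model: SegmentedModel,
    pval_cut: float,
    df_mode: str = "paper",
    n: int | None = None,
) -> tuple[list[str], str]:
    """Label each segment 'up'/'down'/'same' from its slope sign and p-value."""
    labels = []
    # On (numerically) perfect fits the standard errors collapse to zero and a
    # slope at machine precision is an exact zero, not a significant trend.
    scale = float(np.max(np.abs(model.slopes))) if model.slopes.size else 0.0
    for slope, se in zip(model.slopes, model.slope_se):
        s = 0.0 if abs(slope) <= 1e-10 * max(1.0, scale) else float(slope)
        p = segment_pvalue(s, float(se), df_mode, n, model.k)
        if p > pval_cut or s == 0:
            labels.append("same")
        else:
            labels.append("up" if s > 0 else "down")
    return labels, "-".join(labels)


def fit_gene(
    y,
    times: TimeVector,
    config: TrendConfig | None = None,
    gene_id: str = "",
) -> GeneFit | None:
    """Full per-gene pipeline; returns None when no candidate model converges.

    Candidate breakpoint counts run from 0 to the smallest of ``max_k``, the
    feasibility cap floor(n/min_seg) − 1 and the sample-count limit; selection
    is by BIC with the min-segment guard applied afterwards.
    """
    cfg = config or TrendConfig()
    y = np.asarray(y, dtype=float)
    n = times.n
    k_cap = min(cfg.max_k, n // cfg.min_seg - 1, n // 2 - 1)
    k_cap = max(k_cap, 0)
    models: dict[int, SegmentedModel] = {}
    for k in range(k_cap + 1):
        try:
            models[k] = fit_segmented(
                y,
                times,
                k,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                n_starts=cfg.n_starts,
                seed=None if cfg.seed is None else (cfg.seed + k) % (2**31),
            )
        except InfeasibleKError:
            break
    k_sel = select_model(models, n)
    if k_sel is None:
        return None
    k_final = enforce_min_segment(models, k_sel, times, cfg.min_seg)
    model = models[k_final]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - model.rss / tss if tss > 0 else 0.0
    try:
        adj = adjusted_r_squared(r2, n, k_final)
    except UndefinedFitError:
        return None
    labels, tstring = classify_segments(model, cfg.pval_cut, cfg.df_mode, n)
    bic_by_k = {
        k: bic_score(m.loglik, n, k) for k, m in models.items() if m.converged
    }
    return GeneFit(
        gene_id=gene_id,
        k_selected=k_final,
        model=model,
        adj_r2=adj,
        bic_by_k=bic_by_k,
        segment_trends=labels,
        trend_string=tstring,
    )


def gene_seed(seed: int | None, gene_id: str) -> int | None:
    """Stable per-gene seed so results are independent of execution order."""
    if seed is None:
        return None
    return (int(seed) ^ zlib.crc32(gene_id.encode())) % (2**31)


def fit_matrix(
    matrix,
    times: TimeVector,
    config: TrendConfig | None = None,
    n_jobs: int = 1,
) -> tuple[list[GeneFit], list[str]]:
    """Fit every gene of an expression matrix.

    ``matrix`` is an :class:`segtrend.io.ExpressionMatrix`.  Genes are
    independent; per-gene seeds are derived from the global seed and the gene
    id, so any execution order (or ``n_jobs`` > 1) yields identical output.
    Returns (fits in input gene order, ids of genes with no converged model).
    """
    cfg = config or TrendConfig()

    def one(gid: str, row: np.ndarray) -> GeneFit | None:
        from dataclasses import replace

        local = replace(cfg, seed=gene_seed(cfg.seed, gid))
        return fit_gene(row, times, local, gene_id=gid)

    pairs = list(zip(matrix.gene_ids, matrix.values))
    if n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(g, r) for g, r in pairs)
    else:
        results = [one(g, r) for g, r in pairs]
    fits = [f for f in results if f is not None]
    unfit = [g for (g, _), f in zip(pairs, results) if f is None]
    return fits, unfit
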