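"""Segmented (piecewise-linear) least-squares regression over ordered conditions.

A gene's expression trajectory is modelled as a continuous piecewise-linear
function of an ordered condition value (time, developmental stage, pseudotime):
an intercept, a slope for the first segment, and a slope change at each of ``k``
unknown breakpoints.  The model is linear in the coefficients once the
breakpoints are fixed, via the hinge basis ``(t - b)_+ = max(t - b, 0)``; the
breakpoints themselves are estimated by the iterative linearization of Muggeo
(2003), safeguarded with step-halving, breakpoint clamping and multiple starts.

This module is a per-gene numerical engine: it knows nothing about gene ids,
BIC selection or trend labels (see :mod:`segtrend.gene_model` for those).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log, pi

import numpy as np


__all__ = [
    "TimeVector",
    "SegmentedModel",
    "InvalidBreakpointError",
    "InfeasibleKError",
    "build_design",
    "fit_segmented",
    "gaussian_loglik",
    "predict_segmented",
]

# Cap on the number of enumerated breakpoint-grid initialization candidates.
# Grids up to this size are scored exhaustively; larger grids are thinned.
_GRID_CAP = 600


class InvalidBreakpointError(ValueError):
    """Breakpoints are unordered or fall outside the open time range."""


class InfeasibleKError(ValueError):
    """Too few samples to fit the requested number of breakpoints."""


@dataclass(frozen=True)
class TimeVector:
    """Ordered condition value for each sample; replicates allowed.

    ``values`` must be finite and sorted non-decreasing, with at least two
    distinct values.  ``distinct`` holds the sorted unique values t_1..t_T.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("time vector needs at least two samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("time vector must be finite")
        if np.any(np.diff(v) < 0):
            raise ValueError("time vector must be sorted non-decreasing")
        if np.unique(v).size < 2:
            raise ValueError("time vector needs at least two distinct values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def distinct(self) -> np.ndarray:
        return np.unique(self.values)

    @property
    def t_min(self) -> float:
        return float(self.values[0])

    @property
    def t_max(self) -> float:
        return float(self.values[-1])

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    @property
    def min_gap(self) -> float:
        """Smallest positive spacing between consecutive distinct values."""
        return float(np.min(np.diff(self.distinct)))


@dataclass(frozen=True)
class SegmentedModel:
    """A fitted piecewise-linear model with ``k`` breakpoints.

    ``slopes`` are the per-segment slopes (k+1 of them, expression units per
    time unit); ``slope_se`` their standard errors from the fixed-breakpoint
    OLS covariance.  ``breakpoints`` are continuous time values strictly inside
    the observed range.  Adjacent segments meet at each breakpoint by
    construction of the hinge basis, so ``fitted`` is continuous in t.
    """

    k: int
    intercept: float
    slopes: np.ndarray
    slope_se: np.ndarray
    breakpoints: np.ndarray
    rss: float
    loglik: float
    fitted: np.ndarray
    converged: bool
    n_iter: int


def build_design(times: TimeVector, breakpoints) -> np.ndarray:
    """Hinge-basis design matrix: columns [1, t, (t-b_1)_+, ..., (t-b_k)_+].

    The coefficient on column ``2+i`` is the slope *increment* after b_i, so
    per-segment slopes are cumulative sums of the non-intercept coefficients.

    Raises :class:`InvalidBreakpointError` if breakpoints are non-increasing
    or not strictly inside (t_1, t_T).  Rank deficiency is not checked here;
    callers flag it from the least-squares rank.
    """
    t = times.values
    b = np.asarray(breakpoints, dtype=float)
    if b.ndim != 1:
        b = b.reshape(-1)
    if b.size:
        if np.any(np.diff(b) <= 0):
            raise InvalidBreakpointError(f"breakpoints not strictly increasing: {b}")
        if b[0] <= times.t_min or b[-1] >= times.t_max:
            raise InvalidBreakpointError(
                f"breakpoints {b} outside open range ({times.t_min}, {times.t_max})"
            )
    cols = [np.ones_like(t), t]
    for bi in b:
        cols.append(np.maximum(t - bi, 0.0))
    return np.column_stack(cols)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood given the residual sum of squares.

    Plugging the ML variance estimate sigma^2 = rss/n into the Gaussian
    likelihood gives L = -(n/2)(log(2 pi sigma^2) + 1).  A perfect fit
    (rss = 0) returns ``+inf`` as a sentinel: it dominates any model
    comparison, and callers break ties toward fewer parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        return float("inf")
    sigma2 = rss / n
    return -0.5 * n * (log(2.0 * pi * sigma2) + 1.0)


def predict_segmented(model: SegmentedModel, times: TimeVector) -> np.ndarray:
    """Evaluate the fitted piecewise-linear function at the given times."""
    coefs = np.concatenate(
        [[model.intercept, model.slopes[0]], np.diff(model.slopes)]
    )
    return build_design(times, model.breakpoints) @ coefs


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares fit returning (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def _hinge_design(t: np.ndarray, b: np.ndarray) -> np.ndarray:
    """build_design without validation, for hot loops on pre-checked b."""
    X = np.empty((t.size, b.size + 2))
    X[:, 0] = 1.0
    X[:, 1] = t
    if b.size:
        X[:, 2:] = np.maximum(t[:, None] - b[None, :], 0.0)
    return X


def _ols_fast(X: np.ndarray, y: np.ndarray):
    """Normal-equations solve with Cholesky; falls back to lstsq when the
    Gram matrix is not positive definite.  Returns (beta, rss, full_rank).

    The RSS is always computed from the actual residuals, so an
    ill-conditioned solve cannot report a spuriously good fit.
    """
    G = X.T @ X
    try:
        beta = np.linalg.solve(G, X.T @ y)
    except np.linalg.LinAlgError:
        beta, rss, rank = _ols(X, y)
        return beta, rss, rank == X.shape[1]
    if not np.all(np.isfinite(beta)):
        return beta, float("inf"), False
    resid = y - X @ beta
    return beta, float(resid @ resid), True


class _CandidateGrid:
    """Per-(times, k) cache of admissible midpoint-grid candidates.

    Stores the stacked hinge designs and their pseudoinverses so that scoring
    every candidate for one gene is a pair of batched matrix products.  Shared
    across genes of the same dataset.
    """

    def __init__(self, times: TimeVector, k: int):
        t = times.values
        combos = _grid_candidates(times, k)
        designs, pinvs, keep = [], [], []
        for c in combos:
            X = _hinge_design(t, c)
            if np.linalg.matrix_rank(X) == X.shape[1]:
                keep.append(c)
                designs.append(X)
                pinvs.append(np.linalg.pinv(X))
        self.combos = keep
        if keep:
            self.A = np.stack(designs)  # (C, n, p)
            self.P = np.stack(pinvs)  # (C, p, n)
        else:
            self.A = self.P = None

    def score(self, y: np.ndarray) -> list[tuple[float, np.ndarray]]:
        """(rss, breakpoints) per candidate, best first."""
        if not self.combos:
            return []
        beta = np.einsum("cpn,n->cp", self.P, y)
        resid = y[None, :] - np.einsum("cnp,cp->cn", self.A, beta)
        rss = np.einsum("cn,cn->c", resid, resid)
        order = np.argsort(rss, kind="stable")
        return [(float(rss[i]), self.combos[i]) for i in order]


_grid_cache: dict[tuple, _CandidateGrid] = {}


def _candidate_grid(times: TimeVector, k: int) -> _CandidateGrid:
    key = (times.values.tobytes(), k)
    grid = _grid_cache.get(key)
    if grid is None:
        if len(_grid_cache) > 32:
            _grid_cache.clear()
        grid = _grid_cache[key] = _CandidateGrid(times, k)
    return grid


def _snap_rss(rss: float, tss: float) -> float:
    # Residuals at machine precision are an exact fit for model comparison:
    # otherwise log(rss) noise at 1e-28 scale would swamp the BIC penalty.
    scale = tss if tss > 0 else 1.0
    return 0.0 if rss <= 1e-12 * scale else rss


def _project(b: np.ndarray, lo: float, hi: float, gap: float):
    """Clamp breakpoints into [lo, hi] and enforce ordering with a minimum gap.

    Returns the projected array, or None when the breakpoints cannot be
    separated inside the range (a collision)."""
    b = np.clip(np.sort(b), lo, hi)
    for i in range(1, b.size):
        if b[i] < b[i - 1] + gap:
            b[i] = b[i - 1] + gap
    if b.size and b[-1] > hi:
        return None
    return b


def _grid_candidates(times: TimeVector, k: int) -> list[np.ndarray]:
    """Admissible initialization candidates from inter-time midpoints.

    All k-combinations of midpoints between consecutive distinct times are
    enumerated when their number is modest; otherwise the midpoint set is
    thinned evenly so the enumeration stays bounded."""
    d = times.distinct
    mids = 0.5 * (d[:-1] + d[1:])
    m = mids.size
    while m > k and comb(m, k) > _GRID_CAP:
        m -= 1
    if m < mids.size:
        idx = np.unique(np.linspace(0, mids.size - 1, m).round().astype(int))
        mids = mids[idx]
    return [np.asarray(c, dtype=float) for c in combinations(mids, k)]


def _muggeo_refine(y, times: TimeVector, b0, tol: float, max_iter: int):
    """Safeguarded Muggeo iteration from one start.

    Alternates fixed-breakpoint OLS on the hinge design augmented with the gap
    covariates V_i = -1{t > b_i} with the breakpoint update b_i += gamma_i /
    delta_i, where gamma_i is the gap coefficient and delta_i the hinge
    coefficient.  Steps that increase the RSS are halved; breakpoints are kept
    ordered and interior.  Returns (b, rss, converged, n_iter) for the
    best-seen configuration, so the result is never worse than the start.
    """
    t = times.values
    lo = times.t_min + 0.5 * times.min_gap
    hi = times.t_max - 0.5 * times.min_gap
    gap = times.min_gap
    k = b0.size

    def rss_at(b):
        _, rss, ok = _ols_fast(_hinge_design(t, b), y)
        return rss if ok else np.inf

    b = _project(b0.copy(), lo, hi, gap)
    if b is None:
        return b0, np.inf, False, 0
    best_b, best_rss = b.copy(), rss_at(b)
    if not np.isfinite(best_rss):
        return best_b, best_rss, False, 0

    rss = best_rss
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.maximum(t[:, None] - b[None, :], 0.0)
        V = -(t[:, None] > b[None, :]).astype(float)
        Xa = np.column_stack([np.ones_like(t), t, U, V])
        beta, _, full_rank = _ols_fast(Xa, y)
        if not full_rank:
            # The augmented design lost rank; the hinge design at the best
            # breakpoints seen so far is still full rank, so stop there.
            converged = True
            break
        delta = beta[2 : 2 + k]
        gamma = beta[2 + k :]
        if np.any(np.abs(delta) < 1e-12):
            # A vanishing hinge coefficient means the breakpoint no longer
            # separates distinct slopes; treat as a stationary stop.
            converged = True
            break
        step = gamma / delta
        accepted = None
        h = 1.0
        for _ in range(12):
            cand = _project(b + h * step, lo, hi, gap)
            if cand is not None:
                cand_rss = rss_at(cand)
                if cand_rss <= rss:
                    accepted = (cand, cand_rss)
                    break
            h *= 0.5
        if accepted is None:
            # No improving direction within the line search: stationary.
            converged = True
            break
        b_new, rss_new = accepted
        moved = float(np.max(np.abs(b_new - b)))
        b, rss = b_new, rss_new
        if rss < best_rss:
            best_b, best_rss = b.copy(), rss
        if moved < tol * times.span:
            converged = True
            break
    return best_b, best_rss, converged, it


def fit_segmented(
    y,
    times: TimeVector,
    k: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 50,
    n_starts: int = 5,
    seed: int | None = None,
) -> SegmentedModel:
    """Fit the k-breakpoint piecewise-linear model to one gene.

    For k = 0 this is ordinary least squares on [1, t].  For k >= 1 the best
    candidates from an admissible midpoint grid (plus the evenly-spaced
    quantile configuration) seed the safeguarded Muggeo iteration, and the
    lowest-RSS converged refinement wins.  ``seed`` only affects the jitter
    applied to the quantile start and is kept for reproducibility of degenerate
    cases; the grid candidates are deterministic.

    Raises :class:`InfeasibleKError` when fewer than 2(k+1) samples are
    available.  A fit where no start converges (or the design is rank
    deficient) is returned with ``converged=False``; callers must exclude it
    from model selection.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != times.values.shape:
        raise ValueError("y and times must have the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if k < 0:
        raise ValueError("k must be >= 0")
    n = times.n
    if n < 2 * (k + 1):
        raise InfeasibleKError(f"{n} samples cannot support k={k} breakpoints")

    tss = float(np.sum((y - y.mean()) ** 2))

    if k == 0:
        X = build_design(times, [])
        beta, rss, rank = _ols(X, y)
        rss = _snap_rss(rss, tss)
        se = _slope_se(X, y, beta, rss, 0)
        return SegmentedModel(
            k=0,
            intercept=float(beta[0]),
            slopes=np.array([beta[1]]),
            slope_se=se,
            breakpoints=np.empty(0),
            rss=rss,
            loglik=gaussian_loglik(rss, n),
            fitted=X @ beta,
            converged=bool(rank == 2),
            n_iter=0,
        )

    rng = np.random.default_rng(seed)
    d = times.distinct
    quantile_start = np.quantile(d, np.arange(1, k + 1) / (k + 1))
    if quantile_start.size > 1:
        half = 0.5 * np.min(np.diff(quantile_start))
    else:
        half = 0.25 * times.span
    jittered = quantile_start + rng.uniform(-half, half, size=k)

    scored = _candidate_grid(times, k).score(y)
    starts = [c for _, c in scored[: max(1, n_starts - 4)]]
    starts.append(quantile_start)
    starts.append(jittered)

    best = None  # (rss, b, converged, n_iter)
    for b0 in starts:
        b, rss, conv, it = _muggeo_refine(y, times, np.asarray(b0, float), tol, max_iter)
        if not np.isfinite(rss):
            continue
        if best is None or rss < best[0]:
            best = (rss, b, conv, it)

    if best is None:
        # Every start collided or was rank deficient.
        return SegmentedModel(
            k=k,
            intercept=float("nan"),
            slopes=np.full(k + 1, np.nan),
            slope_se=np.full(k + 1, np.nan),
            breakpoints=np.full(k, np.nan),
            rss=float("inf"),
            loglik=float("-inf"),
            fitted=np.full(n, np.nan),
            converged=False,
            n_iter=0,
        )

    rss_best, b_best, conv, it = best
    X = build_design(times, b_best)
    beta, rss, rank = _ols(X, y)
    rss = _snap_rss(rss, tss)
    slopes = np.cumsum(beta[1:])
    se = _slope_se(X, y, beta, rss, k)
    return SegmentedModel(
        k=k,
        intercept=float(beta[0]),
        slopes=slopes,
        slope_se=se,
        breakpoints=b_best,
        rss=rss,
        loglik=gaussian_loglik(rss, n),
        fitted=X @ beta,
        converged=bool(conv and rank == X.shape[1]),
        n_iter=it,
    )


def _slope_se(X: np.ndarray, y: np.ndarray, beta: np.ndarray, rss: float, k: int) -> np.ndarray:
    """Standard errors of the per-segment slopes.

    Segment slope j is a linear combination c_j^T beta of the hinge-basis
    coefficients (1 on the t column and on the first j hinge columns), so its
    variance is c_j^T Cov(beta) c_j with the usual unbiased residual variance.
    """
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        return np.full(k + 1, np.inf)
    sigma2 = rss / dof
    try:
        xtx_inv = np.linalg.pinv(X.T @ X)
    except np.linalg.LinAlgError:
        return np.full(k + 1, np.inf)
    se = np.empty(k + 1)
    for j in range(k + 1):
        c = np.zeros(p)
        c[1 : 2 + j] = 1.0
        var = float(c @ xtx_inv @ c) * sigma2
        se[j] = np.sqrt(var) if var >= 0 else np.inf
    return se
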