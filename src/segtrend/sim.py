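"""Simulation harness: null (trendless) data, true-trend generation, and the
evaluation metrics used to validate the pipeline.

Two designs are reproduced end to end so the whole package is testable with no
external data:

* **Null shuffle** — columns of a technical-replicate-like matrix are drawn in
  permuted order and assigned time points under one of three spacing schemes
  (evenly spaced short, evenly spaced long, randomly spaced).  No gene has a
  real trend, so any "top dynamic gene" is a false positive.
* **True trends** — each gene gets a random breakpoint count, random segment
  directions from {up, down, same}, and a continuous piecewise-linear mean
  centred at a common level, plus i.i.d. Gaussian noise.  The ground truth is
  carried alongside the matrix for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .gene_model import GeneFit
from .io import ExpressionMatrix
from .segreg import TimeVector

__all__ = [
    "SimulatedDataset",
    "NOISE_PRESETS",
    "technical_replicates",
    "shuffle_null",
    "simulate_trends",
    "correct_k_rate",
    "trend_accuracy",
    "breakpoint_deviation",
]

# Gaussian noise standard deviations (expression units) for the true-trend
# generator.  With segment slopes drawn from +/-[0.5, 1.5] per time unit these
# presets put the low setting in the near-clean regime (k recovered for
# essentially all genes, trend labels limited by short middle segments) and
# the high setting in the regime where up/down segments start to blur into
# no-change; the high preset is analysed with pval_cut = 0.2.
NOISE_PRESETS = {"low": 0.10, "high": 0.20}

# Slope magnitudes for 'up'/'down' segments (expression units per time unit),
# and the minimum difference enforced between consecutive segment slopes so
# that every simulated breakpoint is identifiable in principle.
_SLOPE_RANGE = (0.5, 1.5)
_MIN_SLOPE_GAP = 0.5

# Common mean expression level; comfortably above the default mean filter.
_BASE_LEVEL = 20.0


@dataclass
class SimulatedDataset:
    """A synthetic expression matrix with per-gene ground truth."""

    matrix: ExpressionMatrix
    times: TimeVector
    truth_k: np.ndarray
    truth_breaks: list[np.ndarray]
    truth_trends: list[list[str]]

    def __post_init__(self) -> None:
        g = self.matrix.n_genes
        if not (len(self.truth_k) == len(self.truth_breaks) == len(self.truth_trends) == g):
            raise ValueError("truth arrays inconsistent with matrix dimensions")
        for k, b, tr in zip(self.truth_k, self.truth_breaks, self.truth_trends):
            if len(b) != k or len(tr) != k + 1:
                raise ValueError("per-gene truth inconsistent with its k")


def technical_replicates(
    n_genes: int,
    n_samples: int,
    seed: int | None = None,
    mean_log: float = np.log(20.0),
    sd_log: float = 2.0,
    cv: float = 0.15,
) -> ExpressionMatrix:
    """Synthetic technical-replicate-like matrix: no trend by construction.

    Gene mean levels are log-normal (spanning the dynamic range typical of
    normalized bulk RNA-seq) and samples vary around each mean with a small
    multiplicative log-normal noise, emulating tightly correlated technical
    replicates sequenced from one library.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean_log, sd_log, size=n_genes)
    noise = rng.lognormal(0.0, cv, size=(n_genes, n_samples))
    values = mu[:, None] * noise
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )


def _null_times(n_samples: int, scheme: str, rng: np.random.Generator) -> np.ndarray:
    if scheme in ("evenly_short", "short"):
        return np.arange(1.0, n_samples + 1.0)
    if scheme in ("evenly_long", "long"):
        return 1.0 + 5.0 * np.arange(n_samples)
    if scheme == "random":
        if n_samples > 125:
            raise ValueError("random scheme supports at most 125 samples")
        return np.sort(rng.choice(np.arange(1.0, 126.0), size=n_samples, replace=False))
    raise ValueError(f"unknown time scheme: {scheme}")


def shuffle_null(
    matrix: ExpressionMatrix,
    n_samples: int,
    time_assignment: str = "evenly_short",
    seed: int | None = None,
) -> SimulatedDataset:
    """Trendless dataset: sample columns without replacement in permuted order
    and assign time points by the chosen spacing scheme.

    Schemes: ``evenly_short`` (t = 1, 2, ...), ``evenly_long`` (t = 1, 6, 11,
    ... — step 5) and ``random`` (sampled from 1..125 without replacement,
    then sorted).  Every gene's truth is k = 0 with a flat ('same') trend.
    """
    if n_samples > matrix.n_samples:
        raise ValueError(
            f"requested {n_samples} samples from a {matrix.n_samples}-column matrix"
        )
    rng = np.random.default_rng(seed)
    cols = rng.permutation(matrix.n_samples)[:n_samples]
    times = _null_times(n_samples, time_assignment, rng)
    shuffled = ExpressionMatrix(
        values=matrix.values[:, cols],
        gene_ids=list(matrix.gene_ids),
        sample_ids=[matrix.sample_ids[c] for c in cols],
    )
    g = matrix.n_genes
    return SimulatedDataset(
        matrix=shuffled,
        times=TimeVector(times),
        truth_k=np.zeros(g, dtype=int),
        truth_breaks=[np.empty(0)] * g,
        truth_trends=[["same"]] * g,
    )


def _admissible_break_sets(n_times: int, k: int, min_seg_times: int) -> list[tuple[int, ...]]:
    """Midpoint indices (break between t_j and t_{j+1}) leaving every segment
    at least ``min_seg_times`` distinct time points."""
    lo, hi = min_seg_times, n_times - min_seg_times
    idx = range(lo, hi + 1)
    return [
        c
        for c in combinations(idx, k)
        if all(c[i + 1] - c[i] >= min_seg_times for i in range(k - 1))
    ]


def _segment_directions(k: int, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Random directions with identifiable breakpoints.

    Consecutive segments are never both 'same', and consecutive slopes differ
    by at least ``_MIN_SLOPE_GAP``; otherwise a simulated breakpoint would be
    undetectable by construction.
    """
    labels: list[str] = []
    slopes = np.zeros(k + 1)
    for i in range(k + 1):
        for _ in range(200):
            lab = str(rng.choice(["up", "down", "same"]))
            if lab == "same":
                s = 0.0
            else:
                mag = rng.uniform(*_SLOPE_RANGE)
                s = mag if lab == "up" else -mag
            if i == 0:
                break
            if labels[i - 1] == "same" and lab == "same":
                continue
            if abs(s - slopes[i - 1]) >= _MIN_SLOPE_GAP:
                break
        labels.append(lab)
        slopes[i] = s
    return labels, slopes


def simulate_trends(
    n_genes: int = 50,
    n_times: int = 8,
    reps: int = 3,
    max_true_k: int = 2,
    noise_sd: float | str = "low",
    seed: int | None = None,
    extra_reps: int = 1,
    min_seg_times: int = 2,
) -> SimulatedDataset:
    """Generate genes with known piecewise-linear trends.

    Defaults reproduce the validation design: 50 genes over 8 distinct time
    points (t = 1..8) with 3 replicates each plus one extra replicate at the
    first time point (N = 25); true breakpoint counts uniform on
    {0..max_true_k}; breakpoints placed uniformly over the midpoints that
    leave every segment at least ``min_seg_times`` distinct times; segment
    directions random over {up, down, same} subject to identifiability; each
    gene's continuous piecewise-linear mean is vertically centred at a common
    level so all genes share the same mean; i.i.d. Gaussian noise on top.

    ``noise_sd`` is either a float (expression units) or a preset name from
    :data:`NOISE_PRESETS` ("low"/"high").
    """
    if isinstance(noise_sd, str):
        try:
            noise_sd = NOISE_PRESETS[noise_sd]
        except KeyError:
            raise ValueError(f"unknown noise preset: {noise_sd!r}") from None
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    distinct = np.arange(1.0, n_times + 1.0)
    t = np.repeat(distinct, reps)
    if extra_reps:
        t = np.sort(np.concatenate([t, np.repeat(distinct[0], extra_reps)]))
    times = TimeVector(t)

    break_sets = {
        k: _admissible_break_sets(n_times, k, min_seg_times)
        for k in range(1, max_true_k + 1)
    }
    for k, sets in break_sets.items():
        if not sets:
            raise ValueError(
                f"no admissible breakpoint placement for k={k} with "
                f"{n_times} time points and min_seg_times={min_seg_times}"
            )

    values = np.empty((n_genes, times.n))
    truth_k = np.empty(n_genes, dtype=int)
    truth_breaks: list[np.ndarray] = []
    truth_trends: list[list[str]] = []
    for g in range(n_genes):
        k = int(rng.integers(0, max_true_k + 1))
        if k == 0:
            breaks = np.empty(0)
        else:
            sets = break_sets[k]
            choice = sets[int(rng.integers(len(sets)))]
            # Break between t_j and t_{j+1} (1-based j): midpoint j + 0.5.
            breaks = distinct[0] - 1.0 + np.array(choice, dtype=float) + 0.5
        labels, slopes = _segment_directions(k, rng)
        incr = np.concatenate([[slopes[0]], np.diff(slopes)])
        mean = np.zeros(times.n)
        mean += incr[0] * (t - times.t_min)
        for bi, dinc in zip(breaks, incr[1:]):
            mean += dinc * np.maximum(t - bi, 0.0)
        mean = mean - mean.mean() + _BASE_LEVEL
        values[g] = mean + rng.normal(0.0, noise_sd, size=times.n)
        truth_k[g] = k
        truth_breaks.append(breaks)
        truth_trends.append(labels)

    matrix = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(times.n)],
    )
    return SimulatedDataset(
        matrix=matrix,
        times=times,
        truth_k=truth_k,
        truth_breaks=truth_breaks,
        truth_trends=truth_trends,
    )


def _aligned(fits, truth: SimulatedDataset) -> list[tuple[GeneFit | None, int, np.ndarray, list[str]]]:
    by_id = {f.gene_id: f for f in fits if f is not None}
    unknown = set(by_id) - set(truth.matrix.gene_ids)
    if unknown:
        raise ValueError(f"fit gene ids not in truth: {sorted(unknown)[:5]}")
    out = []
    for gid, k, b, tr in zip(
        truth.matrix.gene_ids, truth.truth_k, truth.truth_breaks, truth.truth_trends
    ):
        out.append((by_id.get(gid), int(k), b, tr))
    return out


def correct_k_rate(fits, truth: SimulatedDataset, by_k: bool = False):
    """Fraction of genes whose selected breakpoint count equals the truth.

    Genes with no converged model count as incorrect.  With ``by_k=True``
    returns a dict {true k: fraction} instead.
    """
    rows = _aligned(fits, truth)
    if not rows:
        raise ValueError("no genes to score")
    if not by_k:
        return float(
            np.mean([f is not None and f.k_selected == k for f, k, _, _ in rows])
        )
    out: dict[int, float] = {}
    for k in sorted(set(int(x) for x in truth.truth_k)):
        sub = [f is not None and f.k_selected == k for f, kk, _, _ in rows if kk == k]
        out[k] = float(np.mean(sub))
    return out


def trend_accuracy(fits, truth: SimulatedDataset, by_k: bool = False):
    """Fraction of genes with the correct breakpoint count AND every segment
    direction label equal to the truth."""
    rows = _aligned(fits, truth)
    if not rows:
        raise ValueError("no genes to score")

    def ok(f, k, tr):
        return f is not None and f.k_selected == k and f.segment_trends == tr

    if not by_k:
        return float(np.mean([ok(f, k, tr) for f, k, _, tr in rows]))
    out: dict[int, float] = {}
    for k in sorted(set(int(x) for x in truth.truth_k)):
        sub = [ok(f, kk, tr) for f, kk, _, tr in rows if kk == k]
        out[k] = float(np.mean(sub))
    return out


def breakpoint_deviation(fits, truth: SimulatedDataset):
    """Mean signed and mean absolute deviation of estimated breakpoint times.

    Restricted to genes whose selected k equals the true k >= 1; estimated and
    true breakpoints are paired in sorted order.  Returns (signed, absolute)
    in time units, or None when no gene is eligible.
    """
    devs: list[float] = []
    for f, k, b, _ in _aligned(fits, truth):
        if f is None or k < 1 or f.k_selected != k:
            continue
        est = np.sort(np.asarray(f.breakpoints, dtype=float))
        devs.extend((est - np.sort(b)).tolist())
    if not devs:
        return None
    d = np.asarray(devs)
    return float(d.mean()), float(np.abs(d).mean())
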