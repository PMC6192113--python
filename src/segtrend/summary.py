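"""Transcriptome-level summaries of the per-gene fits.

Top-gene gating by adjusted R-squared, the breakpoint distribution D_t over
the distinct time points, the genes-by-time encoded trend matrix (for external
clustering), and pattern extraction on trend strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_model import TREND_CODES, GeneFit
from .segreg import TimeVector

__all__ = [
    "BreakpointDistribution",
    "top_genes",
    "bin_breakpoint",
    "breakpoint_distribution",
    "trend_matrix",
    "match_pattern",
    "PatternSyntaxError",
]


class PatternSyntaxError(ValueError):
    """A pattern token is not one of 'up', 'down', 'same'."""


@dataclass(frozen=True)
class BreakpointDistribution:
    """Count of breakpoints assigned to each distinct time point (D_t)."""

    times: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "breakpoints": self.counts})


def top_genes(fits: Sequence[GeneFit], r2_cutoff: float) -> list[GeneFit]:
    """Genes whose selected model has adjusted R-squared above the cutoff."""
    return [f for f in fits if f.adj_r2 > r2_cutoff]


def bin_breakpoint(b: float, distinct: np.ndarray) -> float:
    """Assign a continuous breakpoint to the nearest distinct observed time.

    Ties (exactly halfway between two times) go to the earlier time.
    """
    i = int(np.searchsorted(distinct, b))
    if i == 0:
        return float(distinct[0])
    if i == distinct.size:
        return float(distinct[-1])
    left, right = distinct[i - 1], distinct[i]
    return float(left) if b - left <= right - b else float(right)


def breakpoint_distribution(
    fits: Sequence[GeneFit], times: TimeVector
) -> BreakpointDistribution:
    """D_t: total breakpoints (over the given genes) binned per time point.

    The caller chooses the gene subset; summarising only the top dynamic
    genes (adjusted R-squared gate) is the recommended use.
    """
    d = times.distinct
    counts = np.zeros(d.size, dtype=int)
    for f in fits:
        for b in f.breakpoints:
            t = bin_breakpoint(float(b), d)
            counts[np.searchsorted(d, t)] += 1
    return BreakpointDistribution(times=d, counts=counts)


def trend_matrix(fits: Sequence[GeneFit], times: TimeVector) -> pd.DataFrame:
    """Genes-by-time matrix of encoded trends (up=1, down=-1, same=0).

    Each distinct time point receives the code of the segment containing it
    after the gene's breakpoints are binned to their nearest time points; a
    time equal to a binned breakpoint starts the next segment.  Suitable as
    input to external clustering.
    """
    d = times.distinct
    rows = np.zeros((len(fits), d.size), dtype=int)
    for i, f in enumerate(fits):
        binned = np.array(sorted(bin_breakpoint(float(b), d) for b in f.breakpoints))
        seg = np.searchsorted(binned, d, side="right")
        codes = f.trend_codes
        rows[i] = codes[np.minimum(seg, codes.size - 1)]
    return pd.DataFrame(rows, index=[f.gene_id for f in fits], columns=d)


def match_pattern(
    fits: Sequence[GeneFit],
    pattern: str,
    after_time: float | None = None,
) -> list[str]:
    """Gene ids whose trend string equals the '-'-joined pattern exactly.

    ``after_time`` additionally requires the first breakpoint to occur
    strictly after the given time (e.g. a delayed peak "same-up-down" whose
    first break falls after a reference stage).
    """
    tokens = pattern.split("-")
    bad = [t for t in tokens if t not in TREND_CODES]
    if bad:
        raise PatternSyntaxError(f"unknown pattern token(s): {bad}")
    query = "-".join(tokens)
    hits = []
    for f in fits:
        if f.trend_string != query:
            continue
        if after_time is not None:
            if f.k_selected < 1 or not f.breakpoints[0] > after_time:
                continue
        hits.append(f.gene_id)
    return hits
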