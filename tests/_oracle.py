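"""Independent brute-force oracles used to check the fitting engine.

These deliberately avoid the package's own design-matrix builder: designs are
assembled inline with plain numpy so the comparison is a genuine dual route.
"""

from __future__ import annotations

from itertools import combinations
from math import log, pi

import numpy as np


def grid_search_rss(y: np.ndarray, t: np.ndarray, k: int):
    """Exhaustive search over breakpoints at all midpoints between
    consecutive distinct times; returns (best rss, best breakpoints)."""
    d = np.unique(t)
    mids = 0.5 * (d[:-1] + d[1:])
    best_rss, best_b = np.inf, None
    for c in combinations(mids, k):
        cols = [np.ones_like(t), t] + [np.maximum(t - b, 0.0) for b in c]
        X = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            continue
        r = y - X @ beta
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best_b = rss, np.array(c)
    return best_rss, best_b


def gaussian_loglik_unsimplified(rss: float, n: int) -> float:
    """-(n/2)log(2*pi) - (n/2)log(sigma2) - rss/(2*sigma2) at sigma2 = rss/n."""
    sigma2 = rss / n
    return -0.5 * n * log(2 * pi) - 0.5 * n * log(sigma2) - rss / (2 * sigma2)
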