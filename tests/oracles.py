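"""Independent brute-force oracles used by the test-suite.

Each oracle recomputes a quantity by direct enumeration or per-window
arithmetic, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def baseline_by_enumeration(
    lengths, heights, majority_fraction=0.51
) -> tuple[float, float, tuple[int, ...]]:
    """Minimum-SD covering subset by full itertools enumeration.

    Returns (length-weighted mean, population SD, member index tuple) of the
    best subset under the key (SD, total length, lexicographic indices).
    """
    lengths = np.asarray(lengths, dtype=float)
    heights = np.asarray(heights, dtype=float)
    n = len(lengths)
    min_len = majority_fraction * lengths.sum()
    best = None
    for k in range(1, n + 1):
        for combo in combinations(range(n), k):
            idx = list(combo)
            total = lengths[idx].sum()
            if total < min_len:
                continue
            sd = float(np.std(heights[idx]))
            key = (sd, float(total), combo)
            if best is None or key < best:
                best = key
    assert best is not None
    sd, _, combo = best
    idx = list(combo)
    mean = float(np.average(heights[idx], weights=lengths[idx]))
    return mean, sd, combo


def kendall_tau_b_by_pairs(x, y) -> float:
    """Tau-b by explicit concordant/discordant pair counting."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    n0 = n * (n - 1) / 2

    def tie_term(v):
        counts = {}
        for val in v:
            counts[val] = counts.get(val, 0) + 1
        return sum(t * (t - 1) / 2 for t in counts.values())

    n1, n2 = tie_term(x), tie_term(y)
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return (concordant - discordant) / denom


def loess_by_window_wls(x, y, weights, span, degree) -> np.ndarray:
    """Per-window weighted least squares with tricube kernel, via lstsq."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = len(x)
    q = min(int(np.ceil(span * n)), n)
    fitted = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        window = np.argsort(dist, kind="stable")[:q]
        dmax = dist[window].max()
        if dmax == 0:
            kern = np.ones(q)
        else:
            kern = (1 - (dist[window] / dmax) ** 3) ** 3
            kern[kern < 0] = 0.0
        w = kern * weights[window]
        design = np.column_stack(
            [(x[window] - x[i]) ** p for p in range(degree + 1)]
        )
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[window] * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted
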