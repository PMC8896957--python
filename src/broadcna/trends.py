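"""Local-regression trends of per-count patient frequencies and event ordering.

For each selected (arm, direction) category, the fraction of patients
carrying it is computed at every broad-CNA count 1..max_count and smoothed by
locally weighted polynomial regression (tricube kernel over the span-nearest
fraction of points, observation weights = patients per count).  The smoothing
span is chosen automatically by minimizing the small-sample-corrected Akaike
information criterion.  The fitted trends are reduced to an acquisition-order
proposal via the count at which each trend first reaches half of its final
level (earlier half-rise = earlier acquisition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frequency import CohortEventMatrix, patient_frequency, subset_by_event_count
from .genome import Category
from .segio import ValidationError


def _window_fit(
    x: np.ndarray,
    y: np.ndarray,
    obs_weights: np.ndarray,
    span: float,
    degree: int,
) -> tuple[np.ndarray, float]:
    """Fitted values and smoother-matrix trace for one loess pass."""
    n = len(x)
    q = int(math.ceil(span * n))
    min_q = degree + 2
    if q < min_q:
        raise ValidationError(
            f"span {span} gives windows of {q} points; need >= {min_q} "
            f"(minimal feasible span {min_q / n:.3f})"
        )
    q = min(q, n)
    fitted = np.empty(n)
    trace = 0.0
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            kernel = np.ones(q)
        else:
            u = np.clip(d[idx] / dmax, 0.0, 1.0)
            kernel = (1.0 - u ** 3) ** 3
        w = kernel * obs_weights[idx]
        if np.count_nonzero(w) < degree + 1:
            raise ValidationError(
                f"window at x={x[i]} has fewer than {degree + 1} points with "
                f"positive weight; increase the span"
            )
        # design centered at x[i] for conditioning; fitted value = intercept
        dx = x[idx] - x[i]
        design = np.vander(dx, degree + 1, increasing=True)
        wd = design * w[:, None]
        gram = design.T @ wd
        rhs_matrix = np.linalg.solve(gram, wd.T)  # (degree+1, q)
        hat_row = rhs_matrix[0]  # row of the smoother matrix on window points
        fitted[i] = float(hat_row @ y[idx])
        local = np.flatnonzero(idx == i)
        if local.size:
            trace += float(hat_row[local[0]])
    return fitted, trace


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    span: float = 0.75,
    degree: int = 1,
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at each ``x``.

    ``weights`` are observation weights (e.g. patients per count, a binomial
    precision proxy); ``degree`` may be 1 or 2.  Exactly reproduces linear
    data at degree 1 for any feasible span.
    """
    x_arr = np.asarray(x, dtype=np.float64)
    y_arr = np.asarray(y, dtype=np.float64)
    if degree not in (1, 2):
        raise ValidationError("degree must be 1 or 2")
    if len(np.unique(x_arr)) < degree + 2:
        raise ValidationError(f"need at least {degree + 2} distinct x values")
    w = (
        np.ones_like(x_arr)
        if weights is None
        else np.asarray(weights, dtype=np.float64)
    )
    fitted, _ = _window_fit(x_arr, y_arr, w, span, degree)
    return fitted


def default_span_grid(n: int, degree: int = 1) -> tuple[float, ...]:
    lo = (degree + 2) / n
    grid = [round(s, 4) for s in np.arange(0.25, 1.0001, 0.05)]
    return tuple(s for s in grid if s >= lo) or (1.0,)


def select_span(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    degree: int = 1,
    span_grid: Sequence[float] | None = None,
) -> float:
    """Smoothing span minimizing the corrected Akaike information criterion.

    AICc = n*log(RSS/n) + 2(t+1) + 2(t+1)(t+2)/(n-t-2) with t the trace of
    the smoother matrix.  Deterministic; ties keep the first grid value.
    """
    x_arr = np.asarray(x, dtype=np.float64)
    y_arr = np.asarray(y, dtype=np.float64)
    n = len(x_arr)
    w = (
        np.ones_like(x_arr)
        if weights is None
        else np.asarray(weights, dtype=np.float64)
    )
    if span_grid is None:
        span_grid = default_span_grid(n, degree)

    best_span: float | None = None
    best_aicc = math.inf
    for span in span_grid:
        try:
            fitted, t = _window_fit(x_arr, y_arr, w, float(span), degree)
        except ValidationError:
            continue
        if n - t - 2 <= 0:
            continue
        rss = float(np.sum((y_arr - fitted) ** 2))
        aicc = (
            n * math.log(max(rss, 1e-300) / n)
            + 2 * (t + 1)
            + 2 * (t + 1) * (t + 2) / (n - t - 2)
        )
        if aicc < best_aicc:
            best_aicc = aicc
            best_span = float(span)
    if best_span is None:
        raise ValidationError("no feasible span in the grid")
    return best_span


@dataclass
class TrendSeries:
    category: Category
    x: np.ndarray  # counts with >= 1 patient, ascending
    raw_frequency: np.ndarray
    n_per_count: np.ndarray
    fitted: np.ndarray
    span: float


def categories_in_band(
    matrix: CohortEventMatrix,
    lo: float,
    hi: float | None = None,
    max_count: int = 10,
    tolerance: float = 0.025,
) -> list[Category]:
    """Categories whose patient frequency in the 1..max_count subset falls in
    the (lo, hi) band, widened by ``tolerance`` on both sides to honor the
    "approximately" reading of published band edges."""
    sub = subset_by_event_count(matrix, 1, max_count)
    freqs = patient_frequency(sub)
    out = []
    for cat in matrix.categories:
        f = freqs.values[cat]
        if f > lo - tolerance and (hi is None or f < hi + tolerance):
            out.append(cat)
    return out


def build_trends(
    matrix: CohortEventMatrix,
    categories: Sequence[Category],
    max_count: int = 10,
    degree: int = 1,
    span_grid: Sequence[float] | None = None,
) -> list[TrendSeries]:
    """Raw and loess-fitted per-count patient frequencies for each category."""
    if not categories:
        raise ValidationError("no categories requested")
    sub = subset_by_event_count(matrix, 1, max_count)
    if sub.n_patients == 0:
        raise ValidationError(f"no patients with 1..{max_count} events")

    by_count: dict[int, list] = {}
    for p in sub.patients:
        by_count.setdefault(p.broad_count, []).append(p)
    xs, ns = [], []
    for c in range(1, max_count + 1):
        group = by_count.get(c, [])
        if not group:
            warnings.warn(
                f"no patients with exactly {c} events; point omitted",
                stacklevel=2,
            )
            continue
        xs.append(c)
        ns.append(len(group))
    x = np.array(xs, dtype=np.float64)
    n_per_count = np.array(ns, dtype=np.float64)

    series = []
    for cat in categories:
        raw = np.array([
            sum(1 for p in by_count[c] if cat in p.events) / len(by_count[c])
            for c in xs
        ])
        span = select_span(x, raw, weights=n_per_count, degree=degree,
                           span_grid=span_grid)
        fitted = loess_fit(x, raw, weights=n_per_count, span=span, degree=degree)
        series.append(
            TrendSeries(
                category=cat, x=x, raw_frequency=raw,
                n_per_count=n_per_count, fitted=fitted, span=span,
            )
        )
    return series


@dataclass
class OrderProposal:
    tiers: list[list[Category]]
    criteria: dict[Category, float]  # half-rise count; inf when never reached
    flagged: frozenset[Category]


def _half_rise_count(series: TrendSeries) -> float:
    """Count at which the fitted trend first reaches half its final level."""
    fitted = series.fitted
    x = series.x
    target = fitted[-1] / 2.0
    if fitted[-1] <= 0:
        return math.inf
    for k in range(len(fitted)):
        if fitted[k] >= target:
            if k == 0:
                return float(x[0])
            x0, x1 = x[k - 1], x[k]
            y0, y1 = fitted[k - 1], fitted[k]
            if y1 == y0:
                return float(x1)
            return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))
    return math.inf


def propose_order(
    trends: Sequence[TrendSeries], tie_tolerance: float = 0.5
) -> OrderProposal:
    """Rank categories by half-rise count into ordered tiers.

    Categories whose criterion values chain within ``tie_tolerance`` of each
    other form one tie tier.  Trends that never reach half their final level
    are flagged and placed last.
    """
    if len(trends) < 2:
        raise ValidationError("need at least two trend series to order")
    criteria = {s.category: _half_rise_count(s) for s in trends}
    flagged = frozenset(c for c, v in criteria.items() if math.isinf(v))
    ranked = sorted(criteria.items(), key=lambda kv: (kv[1], str(kv[0])))

    tiers: list[list[Category]] = []
    current: list[Category] = []
    prev_value: float | None = None
    for cat, value in ranked:
        if prev_value is not None and (
            math.isinf(value) != math.isinf(prev_value)
            or (not math.isinf(value) and value - prev_value > tie_tolerance)
        ):
            tiers.append(current)
            current = []
        current.append(cat)
        prev_value = value
    if current:
        tiers.append(current)
    return OrderProposal(tiers=tiers, criteria=criteria, flagged=flagged)
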