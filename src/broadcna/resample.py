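"""Event-count-conditioned patient resampling and rank-correlation analysis.

``simulate_patients`` draws, for each patient in a target subset, that
patient's number of events from a reference frequency distribution via
inverse-CDF sampling of uniform variates, repeats for many iterations, and
compares the mean simulated frequencies against the source and the observed
subset with Kendall tau-b.  ``convergence_curve`` repeats the comparison over
expanding broad-CNA-count intervals (1..5, 1..10, ...) for CNA categories or
mutated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .frequency import (
    CohortEventMatrix,
    FrequencyTable,
    event_frequency,
    mutation_frequency,
    subset_by_event_count,
)
from .segio import ValidationError


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected) rank correlation.

    Raises on unequal lengths, fewer than two observations, or an
    all-constant vector (tau undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("kendall_tau requires equal-length 1-D vectors")
    if len(x) < 2:
        raise ValidationError("kendall_tau requires at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("kendall_tau is undefined for a constant vector")
    if np.array_equal(x, y):
        return 1.0  # self-correlation is exact, free of float round-off
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _tau_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    """Tau-b, degrading to NaN (with a warning) when tau is undefined."""
    try:
        return kendall_tau(x, y)
    except ValidationError as exc:
        warnings.warn(f"Kendall correlation undefined: {exc}", stacklevel=3)
        return float("nan")


def align_tables(
    a: FrequencyTable, b: FrequencyTable
) -> tuple[list, np.ndarray, np.ndarray]:
    """Zero-filled vectors of both tables over the union of observed keys."""
    keys = sorted(set(a.values) | set(b.values), key=str)
    xa = np.array([a.values.get(k, 0.0) for k in keys])
    xb = np.array([b.values.get(k, 0.0) for k in keys])
    return keys, xa, xb


@dataclass
class SimulationResult:
    source_frequencies: FrequencyTable
    target_event_counts: list[int]
    iterations: int
    categories: tuple
    per_iteration_frequencies: np.ndarray  # (iterations, n_categories)
    mean_frequencies: dict
    sd_frequencies: dict
    tau_vs_source: float
    tau_vs_subset: float | None


def simulate_patients(
    source: FrequencyTable,
    event_counts: Sequence[int],
    iterations: int = 1000,
    seed: int | None = None,
    reference: FrequencyTable | None = None,
    level: str = "event",
) -> SimulationResult:
    """Simulate patients whose event counts match a target subset.

    ``level="event"`` (CNA mode) requires an event-level source summing to 1
    and reports event-level simulated frequencies; ``level="patient"``
    (mutation mode) normalizes the source internally for sampling and reports
    the fraction of simulated patients carrying each category.  Repeated
    draws of one category within a patient are permitted, as are gain and
    loss on the same arm; both are rare enough to contribute only minimal
    error.  Deterministic for a fixed seed: draws are consumed in patient
    order.
    """
    if level not in ("event", "patient"):
        raise ValidationError(f"unknown simulation level {level!r}")
    counts = [int(c) for c in event_counts]
    if not counts or any(c < 1 for c in counts):
        raise ValidationError("event counts must be a non-empty list of >= 1")
    categories = tuple(sorted(source.values, key=str))
    probs = np.array([source.values[c] for c in categories], dtype=np.float64)
    if probs.sum() <= 0:
        raise ValidationError("source frequencies must have positive mass")
    if level == "event" and abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("event-level source frequencies must sum to 1")
    cum = np.cumsum(probs / probs.sum())
    ncat = len(categories)
    n_patients = len(counts)
    total = int(np.sum(counts))
    patient_index = np.repeat(np.arange(n_patients), counts)

    rng = np.random.default_rng(seed)
    per_iter = np.empty((iterations, ncat), dtype=np.float64)
    for it in range(iterations):
        u = rng.random(total)
        idx = np.minimum(np.searchsorted(cum, u, side="right"), ncat - 1)
        if level == "event":
            per_iter[it] = np.bincount(idx, minlength=ncat) / total
        else:
            keys = np.unique(patient_index.astype(np.int64) * ncat + idx)
            carriers = np.bincount(keys % ncat, minlength=ncat)
            per_iter[it] = carriers / n_patients

    mean = per_iter.mean(axis=0)
    sd = per_iter.std(axis=0)
    source_vec = np.array([source.values[c] for c in categories])
    tau_vs_source = _tau_or_nan(mean, source_vec)
    tau_vs_subset: float | None = None
    if reference is not None:
        mean_table = FrequencyTable(
            dict(zip(categories, mean)),
            mode=source.mode, n_patients=n_patients, n_events=total,
        )
        _, va, vb = align_tables(mean_table, reference)
        tau_vs_subset = _tau_or_nan(va, vb)

    return SimulationResult(
        source_frequencies=source,
        target_event_counts=counts,
        iterations=iterations,
        categories=categories,
        per_iteration_frequencies=per_iter,
        mean_frequencies=dict(zip(categories, mean)),
        sd_frequencies=dict(zip(categories, sd)),
        tau_vs_source=tau_vs_source,
        tau_vs_subset=tau_vs_subset,
    )


@dataclass(frozen=True)
class ConvergenceRow:
    interval_hi: int
    n_patients: int
    tau_subset_vs_simulated: float
    tau_subset_vs_all: float


@dataclass
class ConvergenceCurve:
    mode: str
    rows: list[ConvergenceRow]


def default_interval_grid(step: int = 5, stop: int = 120) -> list[int]:
    return list(range(step, stop + 1, step))


def _mode_tables(matrix: CohortEventMatrix, mode: str):
    if mode == "cna":
        source = event_frequency(matrix)

        def subset_table(sub: CohortEventMatrix) -> FrequencyTable:
            return event_frequency(sub)

        def subset_counts(sub: CohortEventMatrix) -> list[int]:
            return [p.broad_count for p in sub.patients]

        level = "event"
    elif mode == "mutation":
        source = mutation_frequency(matrix, min_frequency=0.0)

        def subset_table(sub: CohortEventMatrix) -> FrequencyTable:
            return mutation_frequency(sub, min_frequency=0.0)

        def subset_counts(sub: CohortEventMatrix) -> list[int]:
            return [
                len(p.genes) for p in sub.patients
                if p.genes is not None and len(p.genes) > 0
            ]

        level = "patient"
    else:
        raise ValidationError(f"unknown convergence mode {mode!r}")
    return source, subset_table, subset_counts, level


def convergence_curve(
    matrix: CohortEventMatrix,
    interval_his: Sequence[int] | None = None,
    iterations: int = 1000,
    seed: int | None = None,
    mode: str = "cna",
) -> ConvergenceCurve:
    """Kendall correlations over expanding event-count intervals.

    For each upper bound ``hi``: the patients with 1..hi broad CNAs are
    simulated from the all-patient source distribution (their own event
    counts; mutation counts in mutation mode) and the subset's observed
    frequencies are correlated against the mean simulated frequencies and
    against the all-patient frequencies.  Empty or degenerate subsets yield
    NaN taus with a warning.
    """
    if interval_his is None:
        interval_his = default_interval_grid()
    his = [int(h) for h in interval_his]
    if his != sorted(his):
        raise ValidationError("interval upper bounds must be sorted ascending")

    source, subset_table, subset_counts, level = _mode_tables(matrix, mode)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(his))

    rows: list[ConvergenceRow] = []
    for hi, child in zip(his, child_seeds):
        sub = subset_by_event_count(matrix, 1, hi)
        tau_sim = tau_all = float("nan")
        n_sub = sub.n_patients
        try:
            table = subset_table(sub)
            counts = subset_counts(sub)
            result = simulate_patients(
                source, counts, iterations=iterations,
                seed=child, reference=table, level=level,
            )
            _, va, vb = align_tables(table, source)
            tau_all = kendall_tau(va, vb)
            tau_sim = result.tau_vs_subset  # type: ignore[assignment]
        except ValidationError as exc:
            warnings.warn(
                f"interval 1..{hi}: correlations undefined ({exc})", stacklevel=2
            )
        rows.append(
            ConvergenceRow(
                interval_hi=hi,
                n_patients=n_sub,
                tau_subset_vs_simulated=float(tau_sim),
                tau_subset_vs_all=float(tau_all),
            )
        )
    return ConvergenceCurve(mode=mode, rows=rows)
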