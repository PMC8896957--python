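"""Synthetic tumor/normal segmented cohorts with known ground truth.

Tumors follow a staged acquisition model: arm-event categories are organized
in ordered stages, each with an acquisition probability.  A patient draws a
target number of broad events, then scans the stages in order (shuffling
within a stage) acquiring each event with its stage probability until the
target is met; any shortfall is filled with background events drawn from
categories outside the configured stages.  Truncation at the target count is
what makes early-stage events dominate low-count patients.

Alteration heights follow a log-ratio model: a clonal single-copy gain sits
at ``gain_level`` (default log2(3/2) ~ 0.58) and a clonal loss at
``loss_level`` (default log2(1/2) = -1.0), diluted multiplicatively by tumor
purity and shifted by a per-sample baseline.  Noise is one Gaussian draw per
segment, mimicking post-CBS data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import ARMS, AUTOSOMES, Category, parse_category
from .segio import (
    ArmMap,
    SampleMetadata,
    Segment,
    SegmentedProfile,
    MutationTable,
    grch38_arm_map,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AcquisitionStage:
    """One ordered tier of arm-event categories with an acquisition probability."""

    events: tuple[Category, ...]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigError(f"stage probability {self.probability} outside [0, 1]")
        for ev in self.events:
            if ev.chromosome not in AUTOSOMES or ev.arm not in ARMS:
                raise ConfigError(f"stage references invalid arm event {ev}")


def default_stages() -> tuple[AcquisitionStage, ...]:
    """Five-stage order used as ground truth throughout the test-suite.

    Mirrors the acquisition sequence proposed for TCGA-BRCA breast tumors:
    1qG/16qL first, then 16pG, 22qL, the {6qL, 8pL, 11qL, 17pL} tier, and
    finally 8qG.
    """

    def stage(names: Sequence[str], p: float) -> AcquisitionStage:
        return AcquisitionStage(tuple(parse_category(n) for n in names), p)

    return (
        stage(["1qG", "16qL"], 0.95),
        stage(["16pG"], 0.90),
        stage(["22qL"], 0.80),
        stage(["6qL", "8pL", "11qL", "17pL"], 0.60),
        stage(["8qG"], 0.50),
    )


def default_event_count_distribution() -> dict[int, float]:
    """Truncated-geometric-flavored distribution over 1..10 broad events."""
    weights = {k: 0.82 ** k for k in range(1, 11)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    seed: int = 0
    purity_range: tuple[float, float] = (0.5, 0.9)
    baseline_shift_sd: float = 0.05
    segment_noise_sd: float = 0.05
    gain_level: float = 0.58
    loss_level: float = -1.0
    acquisition_stages: tuple[AcquisitionStage, ...] = field(default_factory=default_stages)
    event_count_distribution: dict[int, float] = field(
        default_factory=default_event_count_distribution
    )
    mutation_freqs: dict[str, float] = field(
        default_factory=lambda: {
            "PIK3CA": 0.35, "TP53": 0.33, "CDH1": 0.13,
            "GATA3": 0.11, "MAP3K1": 0.08, "AKT1": 0.04,
        }
    )
    mutation_count_slope: float = 0.0  # log-odds of mutation per extra broad event
    normal_small_cna_rate: float = 1.0
    n_normals: int = 30
    segments_per_arm: tuple[int, int] = (2, 8)
    arm_map: ArmMap = field(default_factory=grch38_arm_map)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("purity_range must be within [0, 1]")
        if not self.event_count_distribution:
            raise ConfigError("event_count_distribution must be non-empty")
        total = sum(self.event_count_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("event_count_distribution must sum to 1")
        if any(k < 0 for k in self.event_count_distribution):
            raise ConfigError("event counts must be >= 0")
        if not self.acquisition_stages and any(
            k > 0 and p > 0 for k, p in self.event_count_distribution.items()
        ):
            raise ConfigError(
                "empty stage list with nonzero event counts; configure stages"
            )
        for gene, p in self.mutation_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"mutation probability for {gene} outside [0, 1]")

    @property
    def staged_categories(self) -> frozenset[Category]:
        return frozenset(
            ev for stage in self.acquisition_stages for ev in stage.events
        )


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    baseline: float
    purity: float
    events: tuple[Category, ...]
    mutated_genes: frozenset[str] = frozenset()

    @property
    def event_count(self) -> int:
        return len(self.events)


@dataclass
class TruthSet:
    patients: dict[str, PatientTruth]

    def with_mutations(self, mutations: MutationTable) -> "TruthSet":
        updated = {
            pid: PatientTruth(
                patient_id=pid,
                baseline=t.baseline,
                purity=t.purity,
                events=t.events,
                mutated_genes=mutations.genes_of(_tumor_id(pid)),
            )
            for pid, t in self.patients.items()
        }
        return TruthSet(updated)


def _tumor_id(patient_id: str) -> str:
    return f"{patient_id}-T"


def _normal_id(patient_id: str) -> str:
    return f"{patient_id}-N"


def _draw_count(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    counts = sorted(dist)
    probs = np.array([dist[k] for k in counts], dtype=np.float64)
    return int(rng.choice(counts, p=probs / probs.sum()))


def _draw_events(
    rng: np.random.Generator, config: GeneratorConfig, target: int
) -> tuple[Category, ...]:
    acquired: list[Category] = []
    used_arms: set[tuple[str, str]] = set()
    for stage in config.acquisition_stages:
        order = list(stage.events)
        rng.shuffle(order)  # avoid within-stage listing-order bias
        for ev in order:
            if len(acquired) >= target:
                return tuple(acquired)
            if (ev.chromosome, ev.arm) in used_arms:
                continue
            if rng.random() < stage.probability:
                acquired.append(ev)
                used_arms.add((ev.chromosome, ev.arm))
    # background fill: late, unordered events outside the configured stages.
    # Arms get heterogeneous propensities (a deterministic ramp) so cohort
    # event frequencies are well separated rather than artificially uniform.
    staged = config.staged_categories
    pool = [
        (c, float(w))
        for w, c in enumerate(_all_categories(), start=1)
        if c not in staged and (c.chromosome, c.arm) not in used_arms
    ]
    while len(acquired) < target and pool:
        weights = np.array([w for _, w in pool])
        i = int(rng.choice(len(pool), p=weights / weights.sum()))
        ev, _ = pool[i]
        pool = [
            (c, w) for c, w in pool
            if (c.chromosome, c.arm) != (ev.chromosome, ev.arm)
        ]
        acquired.append(ev)
        used_arms.add((ev.chromosome, ev.arm))
    return tuple(acquired)


def _all_categories() -> list[Category]:
    from .genome import ALL_CATEGORIES

    return list(ALL_CATEGORIES)


def _partition_arm(
    rng: np.random.Generator, start: int, end: int, n_parts: int
) -> list[tuple[int, int]]:
    """Split [start, end] into up to n_parts contiguous chunks of random size."""
    total = end - start + 1
    n_parts = max(1, min(n_parts, total))
    if n_parts == 1:
        return [(start, end)]
    cuts = np.unique(rng.integers(1, total, size=n_parts - 1))
    bounds = [0, *[int(c) for c in cuts], total]
    return [
        (start + bounds[i], start + bounds[i + 1] - 1)
        for i in range(len(bounds) - 1)
    ]


def _carve_spike(
    pieces: list[tuple[int, int, float]],
    spike_start: int,
    spike_len: int,
    spike_height: float,
) -> list[tuple[int, int, float]]:
    """Insert a short interval at ``spike_height`` inside one existing piece."""
    out: list[tuple[int, int, float]] = []
    for s, e, h in pieces:
        if not (s <= spike_start <= e):
            out.append((s, e, h))
            continue
        spike_end = min(spike_start + spike_len - 1, e)
        if spike_start > s:
            out.append((s, spike_start - 1, h))
        out.append((spike_start, spike_end, spike_height))
        if spike_end < e:
            out.append((spike_end + 1, e, h))
    return out


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SegmentedProfile], list[SegmentedProfile], dict[str, SampleMetadata], TruthSet]:
    """Generate tumor profiles, normal profiles, metadata, and the truth set.

    Deterministic given ``config.seed``: one generator drives all draws in a
    fixed patient order.
    """
    rng = np.random.default_rng(config.seed)
    arm_map = config.arm_map
    lo_p, hi_p = config.purity_range

    tumors: list[SegmentedProfile] = []
    normals: list[SegmentedProfile] = []
    metadata: dict[str, SampleMetadata] = {}
    truth: dict[str, PatientTruth] = {}

    for i in range(config.n_patients):
        patient_id = f"SYN{i:04d}"
        purity = float(rng.uniform(lo_p, hi_p))
        baseline = float(rng.normal(0.0, config.baseline_shift_sd)) if config.baseline_shift_sd > 0 else 0.0
        target = _draw_count(rng, config.event_count_distribution)
        events = _draw_events(rng, config, target)
        event_map = {(ev.chromosome, ev.arm): ev.direction for ev in events}

        segments: list[Segment] = []
        for chrom in AUTOSOMES:
            for arm in ARMS:
                a_start, a_end = arm_map.arm_interval(chrom, arm)
                direction = event_map.get((chrom, arm))
                level = 0.0
                if direction == "gain":
                    level = purity * config.gain_level
                elif direction == "loss":
                    level = purity * config.loss_level
                n_seg = int(rng.integers(config.segments_per_arm[0],
                                         config.segments_per_arm[1] + 1))
                for s, e in _partition_arm(rng, a_start, a_end, n_seg):
                    noise = (
                        float(rng.normal(0.0, config.segment_noise_sd))
                        if config.segment_noise_sd > 0 else 0.0
                    )
                    segments.append(
                        Segment(chrom, s, e, baseline + level + noise,
                                num_probes=max(1, (e - s + 1) // 50_000))
                    )
        sample_id = _tumor_id(patient_id)
        tumors.append(SegmentedProfile(sample_id, segments, sample_type="tumor"))
        metadata[sample_id] = SampleMetadata(
            sample_id=sample_id, patient_id=patient_id, sample_type="tumor"
        )
        truth[patient_id] = PatientTruth(
            patient_id=patient_id, baseline=baseline, purity=purity, events=events
        )

    for i in range(min(config.n_normals, config.n_patients)):
        patient_id = f"SYN{i:04d}"
        baseline = float(rng.normal(0.0, config.baseline_shift_sd)) if config.baseline_shift_sd > 0 else 0.0
        segments: list[Segment] = []
        for chrom in AUTOSOMES:
            for arm in ARMS:
                a_start, a_end = arm_map.arm_interval(chrom, arm)
                n_seg = int(rng.integers(config.segments_per_arm[0],
                                         config.segments_per_arm[1] + 1))
                pieces = [(s, e, baseline) for s, e in
                          _partition_arm(rng, a_start, a_end, n_seg)]
                n_spikes = int(rng.poisson(
                    config.normal_small_cna_rate / (2 * len(AUTOSOMES))
                ))
                for _ in range(n_spikes):
                    spike_len = int(rng.integers(50_000, 2_900_000))
                    if a_end - a_start + 1 <= spike_len:
                        continue
                    spike_start = int(rng.integers(a_start, a_end - spike_len + 1))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    spike_height = baseline + sign * float(rng.uniform(0.4, 1.0))
                    pieces = _carve_spike(pieces, spike_start, spike_len, spike_height)
                for s, e, h in pieces:
                    noise = (
                        float(rng.normal(0.0, config.segment_noise_sd))
                        if config.segment_noise_sd > 0 else 0.0
                    )
                    segments.append(
                        Segment(chrom, s, e, h + noise,
                                num_probes=max(1, (e - s + 1) // 50_000))
                    )
        sample_id = _normal_id(patient_id)
        normals.append(
            SegmentedProfile(sample_id, segments, sample_type="normal_blood")
        )
        metadata[sample_id] = SampleMetadata(
            sample_id=sample_id, patient_id=patient_id, sample_type="normal_blood"
        )

    return tumors, normals, metadata, TruthSet(truth)


def generate_mutation_table(config: GeneratorConfig, truth: TruthSet) -> MutationTable:
    """Draw per-patient gene mutations, optionally modulated by event count.

    Gene ``g`` is mutated with probability ``mutation_freqs[g]``; a nonzero
    ``mutation_count_slope`` shifts the log-odds by ``slope * (count - mean
    count)`` so genes can be enriched in low- or high-event patients.
    """
    rng = np.random.default_rng([config.seed, 1])
    counts = [t.event_count for t in truth.patients.values()]
    mean_count = float(np.mean(counts)) if counts else 0.0
    pairs: set[tuple[str, str]] = set()
    for patient_id in sorted(truth.patients):
        t = truth.patients[patient_id]
        for gene in sorted(config.mutation_freqs):
            p = config.mutation_freqs[gene]
            if config.mutation_count_slope != 0.0 and 0.0 < p < 1.0:
                logit = math.log(p / (1 - p)) + config.mutation_count_slope * (
                    t.event_count - mean_count
                )
                p = 1.0 / (1.0 + math.exp(-logit))
            if rng.random() < p:
                pairs.add((_tumor_id(patient_id), gene))
    return MutationTable(frozenset(pairs))
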