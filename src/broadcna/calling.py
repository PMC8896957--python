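"""Arm-level broad CNA calling from segmented copy-number profiles.

The calling chain, applied per cohort:

1. ``approximate_baseline`` — per sample, find the group of segments covering
   at least a majority of autosomal base pairs whose heights have the lowest
   standard deviation; its length-weighted mean height is the sample baseline.
2. ``derive_global_offsets`` — pool broad (>3 Mb) segments from all normal
   profiles, remove outlier heights, and turn the spread of the remainder
   into cohort-wide gain and loss offsets.
3. ``sample_thresholds`` — widen the cohort offsets by each sample's own
   baseline spread to obtain per-sample gain/loss thresholds.
4. ``call_alterations`` — threshold segments, drop putative subclonal
   alterations (deviation below ``clonality_fraction`` of the most extreme
   deviation), and merge adjacent same-direction segments into alteration
   calls, splitting where neighboring heights differ by at least
   ``split_fraction`` of the extreme deviation.
5. ``call_broad_cnas`` — keep alterations strictly longer than 3,000,000 bp
   and count them per patient.

Baselines assume the majority of the genome is copy-neutral; the search is
exact (full subset enumeration, vectorized) for profiles with up to
``exact_max_segments`` segments and falls back to a sorted-height
contiguous-run search above that.  The fallback evaluates, for every start
position in height order, the shortest run reaching the coverage constraint;
in practice the minimum-variance covering group is (very nearly) such a run
whenever a genuine baseline cluster exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genome import AUTOSOMES, Category
from .segio import ArmMap, SegmentedProfile, ValidationError

BROAD_BP = 3_000_000


@dataclass(frozen=True)
class BaselineEstimate:
    """The copy-neutral height level of one sample and its spread."""

    sample_id: str
    baseline: float
    baseline_sd: float
    member_segments: tuple[int, ...]  # indices into the autosomal segment list
    covered_fraction: float


@dataclass(frozen=True)
class ThresholdOffsets:
    """Cohort-wide gain/loss offsets derived from the pooled normal panel."""

    gain_offset: float
    loss_offset: float
    collection_baseline: float
    collection_sd: float
    n_segments_used: int

    def __post_init__(self) -> None:
        # offsets at floating-point noise level mean the panel had no spread
        if self.gain_offset <= 1e-12 or self.loss_offset <= 1e-12:
            raise ValidationError(
                "degenerate normal panel: derived offsets are not strictly "
                "positive; provide a larger or more variable normal panel"
            )


class SampleThresholds(NamedTuple):
    gain_threshold: float
    loss_threshold: float
    baseline: float


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    chromosome: str
    arm: str
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    mean_height: float
    deviation: float  # mean_height - sample baseline

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class BroadCNACall:
    sample_id: str
    chromosome: str
    arm: str
    direction: str
    start_bp: int
    end_bp: int
    mean_height: float
    deviation: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def category(self) -> Category:
        return Category(self.chromosome, self.arm, self.direction)


# ---------------------------------------------------------------------------
# baseline approximation
# ---------------------------------------------------------------------------

def _best_subset_exact(
    lengths: np.ndarray, heights: np.ndarray, min_length: float
) -> tuple[int, ...]:
    """Minimum-SD covering subset by full enumeration (n <= ~16).

    Selection key: (population SD of member heights, total length,
    lexicographically smallest index tuple).
    """
    n = len(lengths)
    masks = np.arange(1, 2 ** n, dtype=np.uint32)
    bits = (masks[:, None] >> np.arange(n)) & 1  # (2^n - 1, n)
    bits = bits.astype(np.float64)
    cover = bits @ lengths
    ok = cover >= min_length
    if not ok.any():
        raise ValidationError("no segment subset reaches the coverage constraint")
    bits, cover = bits[ok], cover[ok]
    m = bits.sum(axis=1)
    s1 = bits @ heights
    s2 = bits @ (heights * heights)
    var = s2 / m - (s1 / m) ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    best_sd = sd.min()
    tie = sd <= best_sd  # exact float ties only
    best_len = cover[tie].min()
    cand = np.flatnonzero(tie & (cover <= best_len))
    subsets = [tuple(np.flatnonzero(bits[i] > 0)) for i in cand]
    return min(subsets)


def _best_subset_runs(
    lengths: np.ndarray, heights: np.ndarray, min_length: float
) -> tuple[int, ...]:
    """Contiguous-run search in sorted-height order (scales to any n)."""
    order = np.argsort(heights, kind="stable")
    lens = lengths[order]
    hts = heights[order]
    cum_len = np.concatenate([[0.0], np.cumsum(lens)])
    cum_h = np.concatenate([[0.0], np.cumsum(hts)])
    cum_h2 = np.concatenate([[0.0], np.cumsum(hts * hts)])
    n = len(lengths)

    best: tuple[float, float, tuple[int, ...]] | None = None
    for i in range(n):
        # smallest j with run length >= min_length
        j = int(np.searchsorted(cum_len, cum_len[i] + min_length, side="left")) - 1
        if j >= n:
            break
        total = cum_len[j + 1] - cum_len[i]
        m = j - i + 1
        s1 = cum_h[j + 1] - cum_h[i]
        s2 = cum_h2[j + 1] - cum_h2[i]
        var = s2 / m - (s1 / m) ** 2
        sd = float(np.sqrt(max(var, 0.0)))
        members = tuple(sorted(int(k) for k in order[i : j + 1]))
        key = (sd, float(total), members)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValidationError("no segment subset reaches the coverage constraint")
    return best[2]


def _baseline_from_arrays(
    lengths: np.ndarray,
    heights: np.ndarray,
    majority_fraction: float,
    exact_max_segments: int,
) -> tuple[float, float, tuple[int, ...], float]:
    total = float(lengths.sum())
    if total <= 0:
        raise ValidationError("total segment length must be positive")
    min_length = majority_fraction * total
    if len(lengths) <= exact_max_segments:
        members = _best_subset_exact(lengths, heights, min_length)
    else:
        members = _best_subset_runs(lengths, heights, min_length)
    idx = list(members)
    baseline = float(np.average(heights[idx], weights=lengths[idx]))
    baseline_sd = float(np.std(heights[idx]))
    covered = float(lengths[idx].sum()) / total
    return baseline, baseline_sd, members, covered


def approximate_baseline(
    profile: SegmentedProfile,
    majority_fraction: float = 0.51,
    exact_max_segments: int = 14,
) -> BaselineEstimate:
    """Estimate a sample's copy-neutral baseline height.

    Among subsets of autosomal segments whose total length reaches at least
    ``majority_fraction`` of the autosomal base pairs, select the one whose
    heights have the lowest (population) standard deviation.  Returns the
    length-weighted mean height of the selected group as the baseline and the
    unweighted SD of member heights as ``baseline_sd``.
    """
    segs = profile.autosomal_segments()
    if not segs:
        raise ValidationError(f"sample {profile.sample_id}: no autosomal segments")
    lengths = np.array([s.length_bp for s in segs], dtype=np.float64)
    heights = np.array([s.height for s in segs], dtype=np.float64)
    baseline, sd, members, covered = _baseline_from_arrays(
        lengths, heights, majority_fraction, exact_max_segments
    )
    return BaselineEstimate(
        sample_id=profile.sample_id,
        baseline=baseline,
        baseline_sd=sd,
        member_segments=members,
        covered_fraction=covered,
    )


# ---------------------------------------------------------------------------
# cohort thresholds from normals
# ---------------------------------------------------------------------------

def tukey_fences(heights: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of heights inside the Tukey fences (q1-k*iqr, q3+k*iqr)."""
    q1, q3 = np.percentile(heights, [25, 75])
    iqr = q3 - q1
    return (heights >= q1 - k * iqr) & (heights <= q3 + k * iqr)


def derive_global_offsets(
    normal_profiles: Sequence[SegmentedProfile],
    broad_bp: int = BROAD_BP,
    tukey_k: float = 1.5,
    majority_fraction: float = 0.51,
    exact_max_segments: int = 14,
) -> ThresholdOffsets:
    """Derive conservative cohort gain/loss offsets from the normal panel.

    Pools all autosomal normal segments longer than ``broad_bp``, removes
    outlier heights by Tukey fences, estimates the pooled collection's
    baseline, and sets::

        gain_offset = (max height - collection_baseline) + SD(heights)
        loss_offset = (collection_baseline - min height) + SD(heights)

    over the post-outlier-removal heights.
    """
    lengths: list[float] = []
    heights: list[float] = []
    for prof in normal_profiles:
        for seg in prof.autosomal_segments():
            if seg.length_bp > broad_bp:
                lengths.append(float(seg.length_bp))
                heights.append(seg.height)
    if not heights:
        raise ValidationError(
            "no normal segments longer than the broad threshold; "
            "provide a larger normal panel"
        )
    lengths_arr = np.array(lengths)
    heights_arr = np.array(heights)
    keep = tukey_fences(heights_arr, tukey_k)
    if not keep.any():
        raise ValidationError("outlier removal emptied the normal segment pool")
    lengths_arr, heights_arr = lengths_arr[keep], heights_arr[keep]

    baseline, _, _, _ = _baseline_from_arrays(
        lengths_arr, heights_arr, majority_fraction, exact_max_segments
    )
    sd = float(np.std(heights_arr))
    return ThresholdOffsets(
        gain_offset=float(heights_arr.max()) - baseline + sd,
        loss_offset=baseline - float(heights_arr.min()) + sd,
        collection_baseline=baseline,
        collection_sd=sd,
        n_segments_used=int(len(heights_arr)),
    )


def sample_thresholds(
    estimate: BaselineEstimate, offsets: ThresholdOffsets
) -> SampleThresholds:
    """Per-sample thresholds: cohort offsets widened by the sample's own SD."""
    return SampleThresholds(
        gain_threshold=estimate.baseline + offsets.gain_offset + estimate.baseline_sd,
        loss_threshold=estimate.baseline - offsets.loss_offset - estimate.baseline_sd,
        baseline=estimate.baseline,
    )


# ---------------------------------------------------------------------------
# alteration calling
# ---------------------------------------------------------------------------

def call_alterations(
    profile: SegmentedProfile,
    thresholds: SampleThresholds,
    arm_map: ArmMap,
    clonality_fraction: float = 1 / 8,
    split_fraction: float = 1 / 4,
) -> list[AlterationCall]:
    """Call gain/loss alterations on a centromere-split profile.

    Steps: (1) classify each autosomal segment against the thresholds;
    (2) drop altered segments whose absolute deviation from the baseline is
    below ``clonality_fraction`` of the sample's most extreme deviation
    (subclonal); (3) merge genomically adjacent surviving segments of the same
    direction on the same arm, splitting between neighbors whose heights
    differ by at least ``split_fraction`` of the extreme deviation.
    """
    baseline = thresholds.baseline
    segs = profile.autosomal_segments()

    directions: list[str | None] = []
    for seg in segs:
        if seg.height > thresholds.gain_threshold:
            directions.append("gain")
        elif seg.height < thresholds.loss_threshold:
            directions.append("loss")
        else:
            directions.append(None)

    altered = [i for i, d in enumerate(directions) if d is not None]
    if not altered:
        return []
    extreme = max(abs(segs[i].height - baseline) for i in altered)
    floor = clonality_fraction * extreme
    surviving = {
        i for i in altered if abs(segs[i].height - baseline) >= floor
    }

    calls: list[AlterationCall] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        members = [segs[i] for i in run]
        lengths = np.array([s.length_bp for s in members], dtype=np.float64)
        heights = np.array([s.height for s in members])
        mean_height = float(np.average(heights, weights=lengths))
        calls.append(
            AlterationCall(
                sample_id=profile.sample_id,
                chromosome=members[0].chromosome,
                arm=arm_map.arm_of(
                    members[0].chromosome, members[0].start_bp, members[-1].end_bp
                ),
                start_bp=members[0].start_bp,
                end_bp=members[-1].end_bp,
                direction=directions[run[0]],  # type: ignore[arg-type]
                mean_height=mean_height,
                deviation=mean_height - baseline,
            )
        )
        run.clear()

    prev_idx: int | None = None
    for i, seg in enumerate(segs):
        if i not in surviving:
            flush()
            prev_idx = None
            continue
        if run:
            prev = segs[prev_idx]  # type: ignore[index]
            same_arm = (
                seg.chromosome == prev.chromosome
                and arm_map.arm_of(seg.chromosome, seg.start_bp, seg.end_bp)
                == arm_map.arm_of(prev.chromosome, prev.start_bp, prev.end_bp)
            )
            contiguous = prev_idx == i - 1
            same_direction = directions[i] == directions[prev_idx]
            jump = abs(seg.height - prev.height) >= split_fraction * extreme
            if not (same_arm and contiguous and same_direction) or jump:
                flush()
        run.append(i)
        prev_idx = i
    flush()
    return calls


def call_broad_cnas(
    alterations: Iterable[AlterationCall],
    arm_map: ArmMap | None = None,
    broad_bp: int = BROAD_BP,
) -> tuple[list[BroadCNACall], int]:
    """Keep autosomal alterations strictly longer than ``broad_bp``.

    Returns the broad calls and the per-patient autosomal broad-CNA count
    (number of broad alteration events, not arm-binarized; use
    ``arm_binary_events`` for the binarized view used by frequency analyses).
    """
    broad: list[BroadCNACall] = []
    for alt in alterations:
        if alt.chromosome not in AUTOSOMES:
            continue
        if alt.length_bp > broad_bp:
            broad.append(
                BroadCNACall(
                    sample_id=alt.sample_id,
                    chromosome=alt.chromosome,
                    arm=alt.arm,
                    direction=alt.direction,
                    start_bp=alt.start_bp,
                    end_bp=alt.end_bp,
                    mean_height=alt.mean_height,
                    deviation=alt.deviation,
                )
            )
    return broad, len(broad)


def arm_binary_events(broad_calls: Iterable[BroadCNACall]) -> frozenset[Category]:
    """Collapse broad calls to at most one (arm, direction) event each."""
    return frozenset(call.category for call in broad_calls)


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

@dataclass
class SampleCallResult:
    sample_id: str
    baseline: BaselineEstimate
    thresholds: SampleThresholds
    alterations: list[AlterationCall]
    broad_calls: list[BroadCNACall]
    broad_count: int
    events: frozenset[Category]


def call_cohort(
    tumor_profiles: Sequence[SegmentedProfile],
    normal_profiles: Sequence[SegmentedProfile],
    arm_map: ArmMap,
    majority_fraction: float = 0.51,
    clonality_fraction: float = 1 / 8,
    split_fraction: float = 1 / 4,
    broad_bp: int = BROAD_BP,
    tukey_k: float = 1.5,
) -> dict[str, SampleCallResult]:
    """Run the full calling chain over a cohort; one result per tumor sample."""
    from .segio import split_at_centromere

    offsets = derive_global_offsets(
        normal_profiles, broad_bp=broad_bp, tukey_k=tukey_k,
        majority_fraction=majority_fraction,
    )
    results: dict[str, SampleCallResult] = {}
    for prof in tumor_profiles:
        split = split_at_centromere(prof, arm_map)
        estimate = approximate_baseline(split, majority_fraction=majority_fraction)
        thresholds = sample_thresholds(estimate, offsets)
        alterations = call_alterations(
            split, thresholds, arm_map,
            clonality_fraction=clonality_fraction, split_fraction=split_fraction,
        )
        broad, count = call_broad_cnas(alterations, arm_map, broad_bp=broad_bp)
        results[prof.sample_id] = SampleCallResult(
            sample_id=prof.sample_id,
            baseline=estimate,
            thresholds=thresholds,
            alterations=alterations,
            broad_calls=broad,
            broad_count=count,
            events=arm_binary_events(broad),
        )
    return results
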