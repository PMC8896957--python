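from __future__ import annotations

import numpy as np
import pytest

from broadcna import examples, synthcohort
from broadcna.segio import ArmBounds, ArmMap, Segment, SegmentedProfile, grch38_arm_map


@pytest.fixture(scope="session")
def arm_map() -> ArmMap:
    return grch38_arm_map()


@pytest.fixture(scope="session")
def flat_arm_map() -> ArmMap:
    """All 22 autosomes 200 Mb long with the centromere at 100 Mb."""
    return ArmMap({
        str(c): ArmBounds(1, 100_000_000, 100_000_001, 200_000_000)
        for c in range(1, 23)
    })


@pytest.fixture(scope="session")
def early_cohort():
    return examples.early_onset_cohort()


@pytest.fixture(scope="session")
def staged_cohort_small():
    """A 150-patient staged cohort with truth, shared across tests."""
    cfg = synthcohort.GeneratorConfig(n_patients=150, seed=11, n_normals=20)
    tumors, normals, metadata, truth = synthcohort.generate_cohort(cfg)
    mutations = synthcohort.generate_mutation_table(cfg, truth)
    return cfg, tumors, normals, metadata, truth, mutations


def make_profile(sample_id, segs, sample_type="tumor") -> SegmentedProfile:
    """segs: iterable of (chrom, start, end, height)."""
    return SegmentedProfile(
        sample_id=sample_id,
        segments=[Segment(c, s, e, h) for c, s, e, h in segs],
        sample_type=sample_type,
    )


def single_chrom_profile(heights_and_lengths_mb, chrom="1", start=1, sample_id="S1"):
    """Build a one-chromosome profile from (length_mb, height) pairs."""
    segs = []
    pos = start
    for length_mb, height in heights_and_lengths_mb:
        length = int(round(length_mb * 1_000_000))
        segs.append(Segment(chrom, pos, pos + length - 1, height))
        pos += length
    return SegmentedProfile(sample_id=sample_id, segments=segs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
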