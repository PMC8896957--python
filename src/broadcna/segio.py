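"""Reading, writing, and normalizing the tabular formats the pipeline touches.

The copy-number input is the SEG dialect exported by TCGA: a tab-delimited
table with columns ``Sample, Chromosome, Start, End, Num_Probes,
Segment_Mean`` and 1-based inclusive coordinates (``length = end - start + 1``).
Auxiliary tables (arm boundaries, somatic mutations, sample metadata) are
plain TSV with documented headers.  All files are UTF-8, header line first,
no quoting.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome import (
    AUTOSOMES,
    GRCH38_CENTROMERE_BP,
    GRCH38_CHROM_LENGTH_BP,
)

SAMPLE_TYPES = ("tumor", "normal_tissue", "normal_blood")

SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean")
ARM_COLUMNS = ("chrom", "p_start", "p_end", "q_start", "q_end")
MUTATION_COLUMNS = ("sample_id", "gene")
METADATA_COLUMNS = (
    "sample_id", "patient_id", "sample_type", "is_ffpe", "date_created",
    "date_shipped", "in_other_project", "is_contaminated", "molecular_subtype",
)


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    if chrom in AUTOSOMES:
        return (int(chrom), "")
    return (100, chrom)


def normalize_chromosome(label: str) -> str:
    """Strip a ``chr`` prefix and canonicalize case for X/Y."""
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.lower() in ("x", "y"):
        return label.upper()
    return label


@dataclass(frozen=True)
class Segment:
    """One CBS-style segment: a genomic interval with a mean log-ratio height."""

    chromosome: str
    start_bp: int
    end_bp: int
    height: float
    num_probes: int = 0

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValidationError(f"segment start {self.start_bp} < 1")
        if self.end_bp < self.start_bp:
            raise ValidationError(
                f"segment end {self.end_bp} < start {self.start_bp}"
            )
        if self.num_probes < 0:
            raise ValidationError("num_probes must be >= 0")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SegmentedProfile:
    """One sample's segments, sorted by (chromosome, start) and non-overlapping."""

    sample_id: str
    segments: list[Segment]
    sample_type: str = "tumor"

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(f"unknown sample_type {self.sample_type!r}")
        self.segments = sorted(
            self.segments,
            key=lambda s: (_chrom_sort_key(s.chromosome), s.start_bp, s.end_bp),
        )
        prev: Segment | None = None
        for seg in self.segments:
            if (
                prev is not None
                and seg.chromosome == prev.chromosome
                and seg.start_bp <= prev.end_bp
            ):
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on "
                    f"chromosome {seg.chromosome} "
                    f"({prev.start_bp}-{prev.end_bp} vs {seg.start_bp}-{seg.end_bp})"
                )
            prev = seg

    def autosomal_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.chromosome in AUTOSOMES]


@dataclass(frozen=True)
class ArmBounds:
    p_start_bp: int
    p_end_bp: int
    q_start_bp: int
    q_end_bp: int

    def __post_init__(self) -> None:
        if not (self.p_start_bp <= self.p_end_bp < self.q_start_bp <= self.q_end_bp):
            raise ValidationError("arm bounds must satisfy p_start <= p_end < q_start <= q_end")


@dataclass
class ArmMap:
    """p/q boundaries for all 22 autosomes, derived from centromere locations."""

    arms: dict[str, ArmBounds]

    def __post_init__(self) -> None:
        missing = [c for c in AUTOSOMES if c not in self.arms]
        if missing:
            raise ValidationError(f"arm map missing autosomes: {', '.join(missing)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.arms

    def arm_of(self, chrom: str, start_bp: int, end_bp: int) -> str:
        """Assign an interval to 'p' or 'q'; straddling intervals are an error."""
        bounds = self.arms[chrom]
        if end_bp <= bounds.p_end_bp:
            return "p"
        if start_bp > bounds.p_end_bp:
            return "q"
        raise ValidationError(
            f"interval {chrom}:{start_bp}-{end_bp} straddles the centromere"
        )

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        bounds = self.arms[chrom]
        if arm == "p":
            return (bounds.p_start_bp, bounds.p_end_bp)
        return (bounds.q_start_bp, bounds.q_end_bp)


def grch38_arm_map() -> ArmMap:
    """Default arm map from approximate GRCh38 centromere midpoints."""
    arms = {}
    for chrom in AUTOSOMES:
        cen = GRCH38_CENTROMERE_BP[chrom]
        arms[chrom] = ArmBounds(1, cen, cen + 1, GRCH38_CHROM_LENGTH_BP[chrom])
    return ArmMap(arms)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    patient_id: str
    sample_type: str = "tumor"
    is_ffpe: bool = False
    date_created: str | None = None  # ISO dates; compared lexicographically
    date_shipped: str | None = None
    in_other_project: bool = False
    is_contaminated: bool = False
    molecular_subtype: str | None = None


@dataclass(frozen=True)
class MutationTable:
    """Unique (sample_id, gene) pairs plus per-sample gene-set access."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MutationTable":
        return cls(frozenset((str(s), str(g)) for s, g in pairs))

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs)

    def genes_of(self, sample_id: str) -> frozenset[str]:
        return frozenset(g for s, g in self.pairs if s == sample_id)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for col in required:
            if col not in header:
                raise ParseError(f"{path}: missing required column {col!r}")
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2) if row]
    return header, rows


def read_seg(path, sample_type: str = "tumor") -> list[SegmentedProfile]:
    """Read a SEG-style TSV into one profile per distinct sample.

    Chromosome labels are normalized (``chr`` prefix stripped); segments are
    sorted; ``Num_Probes`` is optional (0 when absent).
    """
    required = [c for c in SEG_COLUMNS if c != "Num_Probes"]
    header, rows = _read_tsv(path, required)
    idx = {name: header.index(name) for name in header}
    has_probes = "Num_Probes" in idx

    by_sample: dict[str, list[Segment]] = {}
    for lineno, row in rows:
        try:
            sample = row[idx["Sample"]].strip()
            chrom = normalize_chromosome(row[idx["Chromosome"]])
            start = int(row[idx["Start"]])
            end = int(row[idx["End"]])
            probes = int(row[idx["Num_Probes"]]) if has_probes and row[idx["Num_Probes"]] != "" else 0
            height = float(row[idx["Segment_Mean"]])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from None
        try:
            seg = Segment(chrom, start, end, height, probes)
        except ValidationError as exc:
            raise ParseError(f"{path}: invalid segment at line {lineno}: {exc}") from None
        by_sample.setdefault(sample, []).append(seg)

    return [
        SegmentedProfile(sample_id=sid, segments=segs, sample_type=sample_type)
        for sid, segs in by_sample.items()
    ]


def write_seg(profiles: Iterable[SegmentedProfile], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SEG_COLUMNS)
        for prof in profiles:
            for seg in prof.segments:
                writer.writerow(
                    [prof.sample_id, seg.chromosome, seg.start_bp, seg.end_bp,
                     seg.num_probes, repr(seg.height)]
                )


def read_arm_table(path) -> ArmMap:
    header, rows = _read_tsv(path, ARM_COLUMNS)
    idx = {name: header.index(name) for name in ARM_COLUMNS}
    arms: dict[str, ArmBounds] = {}
    for lineno, row in rows:
        chrom = normalize_chromosome(row[idx["chrom"]])
        if chrom not in AUTOSOMES:
            continue  # sex chromosomes tolerated on input, never used
        if chrom in arms:
            raise ValidationError(f"{path}: duplicate arm row for chromosome {chrom}")
        try:
            arms[chrom] = ArmBounds(
                int(row[idx["p_start"]]), int(row[idx["p_end"]]),
                int(row[idx["q_start"]]), int(row[idx["q_end"]]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from None
    return ArmMap(arms)


def write_arm_table(arm_map: ArmMap, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ARM_COLUMNS)
        for chrom in AUTOSOMES:
            b = arm_map.arms[chrom]
            writer.writerow([chrom, b.p_start_bp, b.p_end_bp, b.q_start_bp, b.q_end_bp])


def read_mutations(path) -> MutationTable:
    """Read (sample_id, gene) rows; duplicates collapse to one pair."""
    header, rows = _read_tsv(path, MUTATION_COLUMNS)
    idx = {name: header.index(name) for name in MUTATION_COLUMNS}
    pairs = set()
    for lineno, row in rows:
        try:
            pairs.add((row[idx["sample_id"]].strip(), row[idx["gene"]].strip()))
        except IndexError:
            raise ParseError(f"{path}: malformed row at line {lineno}") from None
    return MutationTable(frozenset(pairs))


def write_mutations(table: MutationTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MUTATION_COLUMNS)
        for sample, gene in sorted(table.pairs):
            writer.writerow([sample, gene])


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("1", "true", "yes")


def read_metadata(path) -> dict[str, SampleMetadata]:
    header, rows = _read_tsv(path, METADATA_COLUMNS)
    idx = {name: header.index(name) for name in METADATA_COLUMNS}
    out: dict[str, SampleMetadata] = {}
    for lineno, row in rows:
        sid = row[idx["sample_id"]].strip()
        if sid in out:
            raise ValidationError(f"{path}: duplicate metadata for sample {sid}")
        out[sid] = SampleMetadata(
            sample_id=sid,
            patient_id=row[idx["patient_id"]].strip(),
            sample_type=row[idx["sample_type"]].strip() or "tumor",
            is_ffpe=_parse_bool(row[idx["is_ffpe"]]),
            date_created=row[idx["date_created"]].strip() or None,
            date_shipped=row[idx["date_shipped"]].strip() or None,
            in_other_project=_parse_bool(row[idx["in_other_project"]]),
            is_contaminated=_parse_bool(row[idx["is_contaminated"]]),
            molecular_subtype=row[idx["molecular_subtype"]].strip() or None,
        )
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for sid in sorted(metadata):
            m = metadata[sid]
            writer.writerow([
                m.sample_id, m.patient_id, m.sample_type,
                int(m.is_ffpe), m.date_created or "", m.date_shipped or "",
                int(m.in_other_project), int(m.is_contaminated),
                m.molecular_subtype or "",
            ])


# ---------------------------------------------------------------------------
# sample deduplication
# ---------------------------------------------------------------------------

def _apply_priority_rules(
    group: list[SegmentedProfile], metadata: Mapping[str, SampleMetadata]
) -> SegmentedProfile:
    """Reduce duplicate profiles of one patient (and type) to a single keeper.

    Rules are applied in priority order, each only when it leaves at least one
    survivor: drop FFPE; drop later creation dates; drop later shipment dates;
    drop samples used in another project.  Remaining ties are broken by
    keeping the lexicographically smallest sample_id.
    """
    survivors = list(group)

    non_ffpe = [p for p in survivors if not metadata[p.sample_id].is_ffpe]
    if non_ffpe:
        survivors = non_ffpe

    for attr in ("date_created", "date_shipped"):
        dates = [getattr(metadata[p.sample_id], attr) for p in survivors]
        known = [d for d in dates if d is not None]
        if known:
            earliest = min(known)
            # a missing date is never grounds for removal
            survivors = [
                p for p, d in zip(survivors, dates) if d is None or d <= earliest
            ]

    own_project = [p for p in survivors if not metadata[p.sample_id].in_other_project]
    if own_project:
        survivors = own_project

    return min(survivors, key=lambda p: p.sample_id)


def dedup_samples(
    profiles: Sequence[SegmentedProfile],
    metadata: Mapping[str, SampleMetadata],
) -> list[SegmentedProfile]:
    """Deduplicate tumor and normal profiles per patient.

    Tumors: one profile per patient by the priority rules.  Normals: one
    profile per (patient, sample type) — tissue and blood normals may coexist;
    contaminated normals are dropped outright; normals whose patient has no
    surviving tumor are dropped.  Patients with no tumor profile at all raise
    a warning and are excluded entirely.
    """
    for prof in profiles:
        if prof.sample_id not in metadata:
            raise ValidationError(f"no metadata for sample {prof.sample_id}")

    tumors: dict[str, list[SegmentedProfile]] = {}
    normals: dict[tuple[str, str], list[SegmentedProfile]] = {}
    patients_seen: list[str] = []
    for prof in profiles:
        patient = metadata[prof.sample_id].patient_id
        if patient not in patients_seen:
            patients_seen.append(patient)
        if prof.sample_type == "tumor":
            tumors.setdefault(patient, []).append(prof)
        else:
            if metadata[prof.sample_id].is_contaminated:
                continue
            normals.setdefault((patient, prof.sample_type), []).append(prof)

    kept_tumors: dict[str, SegmentedProfile] = {}
    for patient, group in tumors.items():
        kept_tumors[patient] = _apply_priority_rules(group, metadata)

    result: list[SegmentedProfile] = []
    for patient in patients_seen:
        if patient not in kept_tumors:
            warnings.warn(
                f"patient {patient} has no surviving tumor profile; excluded",
                stacklevel=2,
            )
            continue
        result.append(kept_tumors[patient])
        for stype in ("normal_tissue", "normal_blood"):
            group = normals.get((patient, stype))
            if group:
                result.append(_apply_priority_rules(group, metadata))
    return result


# ---------------------------------------------------------------------------
# centromere splitting
# ---------------------------------------------------------------------------

def split_at_centromere(profile: SegmentedProfile, arm_map: ArmMap) -> SegmentedProfile:
    """Split centromere-straddling segments and drop sex chromosomes.

    Each straddling segment becomes two segments of identical height with the
    boundary at the end of the p arm; total covered base pairs on each
    autosome are conserved.
    """
    out: list[Segment] = []
    for seg in profile.segments:
        if seg.chromosome in ("X", "Y"):
            continue
        if seg.chromosome not in arm_map:
            raise ValidationError(
                f"sample {profile.sample_id}: chromosome {seg.chromosome} "
                "absent from arm map"
            )
        boundary = arm_map.arms[seg.chromosome].p_end_bp
        if seg.start_bp <= boundary < seg.end_bp:
            left_len = boundary - seg.start_bp + 1
            left_probes = int(round(seg.num_probes * left_len / seg.length_bp))
            out.append(replace(seg, end_bp=boundary, num_probes=left_probes))
            out.append(
                replace(seg, start_bp=boundary + 1,
                        num_probes=seg.num_probes - left_probes)
            )
        else:
            out.append(seg)
    return SegmentedProfile(
        sample_id=profile.sample_id, segments=out, sample_type=profile.sample_type
    )
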