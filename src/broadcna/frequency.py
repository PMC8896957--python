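"""Cohort event matrix and frequency profiles.

The :class:`CohortEventMatrix` holds, per patient, the autosomal broad-CNA
count, the arm-binarized (arm, direction) event set, the mutated gene set
(``None`` when the patient has no mutation data), and an optional molecular
subtype.  Frequency tables come in two modes:

* ``patient_level`` — fraction of patients carrying each category;
* ``event_level`` — share of each category among all binary events (sums to 1).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome import ALL_CATEGORIES, Category, format_category, parse_category
from .segio import MutationTable, SampleMetadata, ValidationError


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    broad_count: int
    events: frozenset[Category] = frozenset()
    genes: frozenset[str] | None = None  # None = no mutation data for patient
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.broad_count < 0:
            raise ValidationError("broad_count must be >= 0")


@dataclass
class CohortEventMatrix:
    patients: list[PatientRecord]
    categories: tuple[Category, ...] = ALL_CATEGORIES

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return sum(len(p.events) for p in self.patients)

    @classmethod
    def from_call_results(
        cls,
        results: Mapping[str, "SampleCallResult"],  # noqa: F821
        mutations: MutationTable | None = None,
        metadata: Mapping[str, SampleMetadata] | None = None,
    ) -> "CohortEventMatrix":
        """Assemble the matrix from per-sample calling results.

        Patient ids come from metadata when provided, else the sample id.
        Mutation data is attached only for samples present in the mutation
        table (others get ``genes=None`` and drop out of mutation
        denominators).
        """
        mutation_samples = mutations.samples if mutations is not None else frozenset()
        patients = []
        for sample_id in sorted(results):
            res = results[sample_id]
            meta = metadata.get(sample_id) if metadata else None
            genes: frozenset[str] | None = None
            if mutations is not None and sample_id in mutation_samples:
                genes = mutations.genes_of(sample_id)
            patients.append(
                PatientRecord(
                    patient_id=meta.patient_id if meta else sample_id,
                    broad_count=res.broad_count,
                    events=frozenset(res.events),
                    genes=genes,
                    subtype=meta.molecular_subtype if meta else None,
                )
            )
        return cls(patients)

    @classmethod
    def from_truth(
        cls, truth: "TruthSet", mutations: MutationTable | None = None  # noqa: F821
    ) -> "CohortEventMatrix":
        from .synthcohort import _tumor_id

        patients = []
        for pid in sorted(truth.patients):
            t = truth.patients[pid]
            genes: frozenset[str] | None = None
            if mutations is not None:
                genes = mutations.genes_of(_tumor_id(pid))
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    broad_count=t.event_count,
                    events=frozenset(t.events),
                    genes=genes,
                )
            )
        return cls(patients)


@dataclass
class FrequencyTable:
    values: dict
    mode: str  # "patient_level" | "event_level" | "mutation"
    n_patients: int
    n_events: int = 0

    def __getitem__(self, key):
        if isinstance(key, str) and key not in self.values:
            try:
                key = parse_category(key)
            except ValueError:
                pass
        return self.values.get(key, 0.0)


def subset_by_event_count(
    matrix: CohortEventMatrix, lo: int, hi: float
) -> CohortEventMatrix:
    """Patients whose autosomal broad-CNA count lies in [lo, hi]."""
    if lo > hi:
        raise ValidationError(f"lo {lo} > hi {hi}")
    return CohortEventMatrix(
        patients=[p for p in matrix.patients if lo <= p.broad_count <= hi],
        categories=matrix.categories,
    )


def patient_frequency(matrix: CohortEventMatrix) -> FrequencyTable:
    """Fraction of patients carrying each (arm, direction) category."""
    if matrix.n_patients == 0:
        raise ValidationError("empty cohort matrix")
    n = matrix.n_patients
    values = {
        cat: sum(1 for p in matrix.patients if cat in p.events) / n
        for cat in matrix.categories
    }
    return FrequencyTable(values, "patient_level", n_patients=n,
                          n_events=matrix.n_events)


def event_frequency(matrix: CohortEventMatrix) -> FrequencyTable:
    """Share of each category among all binary events across patients."""
    total = matrix.n_events
    if total == 0:
        raise ValidationError("cohort has zero events")
    values = {
        cat: sum(1 for p in matrix.patients if cat in p.events) / total
        for cat in matrix.categories
    }
    return FrequencyTable(values, "event_level", n_patients=matrix.n_patients,
                          n_events=total)


def mutation_frequency(
    matrix: CohortEventMatrix, min_frequency: float = 0.0
) -> FrequencyTable:
    """Per-gene fraction of patients with mutation data carrying the gene.

    Genes at or below ``min_frequency`` are excluded from the report (e.g.
    0.05 for a full cohort, 0.10 for a low-event subset).
    """
    with_data = [p for p in matrix.patients if p.genes is not None]
    if not with_data:
        raise ValidationError("no patients with mutation data")
    n = len(with_data)
    genes = sorted({g for p in with_data for g in p.genes})
    values = {}
    for gene in genes:
        f = sum(1 for p in with_data if gene in p.genes) / n
        if f > min_frequency:
            values[gene] = f
    return FrequencyTable(values, "mutation", n_patients=n)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def subtype_breakdown(
    matrix: CohortEventMatrix, lo: int, hi: float
) -> dict[str, tuple[int, int]]:
    """Subtype -> (count, percent) over subtyped patients with lo..hi events.

    Percentages are rounded half-up to the nearest integer of the subtyped
    total; subtypes absent from the subset report (0, 0).
    """
    sub = subset_by_event_count(matrix, lo, hi)
    known = [p for p in sub.patients if p.subtype is not None]
    if not known:
        raise ValidationError("no subtyped patients in the requested range")
    total = len(known)
    # subtype vocabulary spans the whole matrix so absent groups report zero
    counts = {
        p.subtype: 0 for p in matrix.patients if p.subtype is not None
    }
    for p in known:
        counts[p.subtype] += 1
    return {
        subtype: (count, _round_half_up(100.0 * count / total))
        for subtype, count in sorted(counts.items())
    }


# ---------------------------------------------------------------------------
# matrix TSV interchange
# ---------------------------------------------------------------------------

MATRIX_COLUMNS = ("patient_id", "broad_count", "events", "genes", "subtype")


def write_matrix(matrix: CohortEventMatrix, path) -> None:
    """Write the cohort matrix as TSV; gene column is '.' when data is absent."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MATRIX_COLUMNS)
        for p in matrix.patients:
            events = ",".join(sorted(format_category(c) for c in p.events))
            genes = "." if p.genes is None else ",".join(sorted(p.genes))
            writer.writerow(
                [p.patient_id, p.broad_count, events, genes, p.subtype or ""]
            )


def read_matrix(path) -> CohortEventMatrix:
    from .segio import _read_tsv

    header, rows = _read_tsv(path, MATRIX_COLUMNS)
    idx = {name: header.index(name) for name in MATRIX_COLUMNS}
    patients = []
    for lineno, row in rows:
        events_text = row[idx["events"]].strip()
        events = frozenset(
            parse_category(t) for t in events_text.split(",") if t
        )
        genes_text = row[idx["genes"]].strip()
        genes: frozenset[str] | None
        if genes_text == ".":
            genes = None
        else:
            genes = frozenset(g for g in genes_text.split(",") if g)
        patients.append(
            PatientRecord(
                patient_id=row[idx["patient_id"]].strip(),
                broad_count=int(row[idx["broad_count"]]),
                events=events,
                genes=genes,
                subtype=row[idx["subtype"]].strip() or None,
            )
        )
    return CohortEventMatrix(patients)


def write_frequency_table(table: FrequencyTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "frequency", "mode", "n_patients", "n_events"])
        for key in table.values:
            label = format_category(key) if isinstance(key, Category) else str(key)
            writer.writerow(
                [label, repr(table.values[key]), table.mode,
                 table.n_patients, table.n_events]
            )
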