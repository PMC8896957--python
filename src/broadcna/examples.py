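"""Worked-example cohorts built from published TCGA-BRCA summary counts.

These small matrices reproduce printed cohort summaries and serve as exact
fixtures for the frequency operations: a 14-patient early-onset subset (the
TCGA-BRCA patients with one or two autosomal broad CNAs) and the
subtype-labeled breakdown of low- versus high-event patients.
"""

from __future__ import annotations

from .frequency import CohortEventMatrix, PatientRecord
from .genome import parse_category


def early_onset_cohort() -> CohortEventMatrix:
    """The 14 TCGA-BRCA patients with 1-2 autosomal broad CNAs.

    Composition: 4 patients carry exactly one broad event (one of them 1qG,
    none 16qL); 10 patients carry exactly two, of whom 7 carry 1qG and 6
    carry 16qL (3 carry both).  GATA3 is mutated in 5 patients and AKT1 in 3.
    """

    def rec(pid: str, events: list[str], genes: list[str]) -> PatientRecord:
        ev = frozenset(parse_category(e) for e in events)
        return PatientRecord(
            patient_id=pid, broad_count=len(ev), events=ev,
            genes=frozenset(genes),
        )

    patients = [
        # one broad event
        rec("EP01", ["1qG"], []),
        rec("EP02", ["16pG"], ["GATA3"]),
        rec("EP03", ["8pL"], []),
        rec("EP04", ["17pL"], []),
        # two broad events: both 1qG and 16qL
        rec("EP05", ["1qG", "16qL"], ["GATA3"]),
        rec("EP06", ["1qG", "16qL"], ["GATA3"]),
        rec("EP07", ["1qG", "16qL"], ["AKT1"]),
        # two broad events: 1qG without 16qL
        rec("EP08", ["1qG", "16pG"], ["GATA3"]),
        rec("EP09", ["1qG", "8qG"], ["AKT1"]),
        rec("EP10", ["1qG", "22qL"], []),
        rec("EP11", ["1qG", "11qL"], []),
        # two broad events: 16qL without 1qG
        rec("EP12", ["16qL", "16pG"], ["GATA3"]),
        rec("EP13", ["16qL", "8pL"], ["AKT1"]),
        rec("EP14", ["16qL", "6qL"], []),
    ]
    return CohortEventMatrix(patients)


#: Molecular-subtype counts of TCGA-BRCA patients by broad-CNA burden:
#: 74 subtyped patients with 1-10 events, 447 subtyped patients with >10.
SUBTYPE_COUNTS_LOW_BURDEN = {
    "LumA": 60, "LumB": 11, "HER2": 0, "Normal": 2, "Basal": 1,
}
SUBTYPE_COUNTS_HIGH_BURDEN = {
    "LumA": 171, "LumB": 116, "HER2": 57, "Normal": 6, "Basal": 97,
}


def subtyped_cohort() -> CohortEventMatrix:
    """Cohort whose subtype composition matches the published breakdown.

    Low-burden patients are assigned 5 broad CNAs and high-burden patients
    20; only the count and subtype fields are meaningful here.
    """
    patients = []
    i = 0
    for subtype, n in SUBTYPE_COUNTS_LOW_BURDEN.items():
        for _ in range(n):
            patients.append(
                PatientRecord(patient_id=f"SP{i:03d}", broad_count=5,
                              subtype=subtype)
            )
            i += 1
    for subtype, n in SUBTYPE_COUNTS_HIGH_BURDEN.items():
        for _ in range(n):
            patients.append(
                PatientRecord(patient_id=f"SP{i:03d}", broad_count=20,
                              subtype=subtype)
            )
            i += 1
    return CohortEventMatrix(patients)
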