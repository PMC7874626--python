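"""Domain 1 raw measure: the PSI-90 weighted composite.

The composite is the weighted mean of a hospital's risk-adjusted PSI
component ratios under one AHRQ weight column.  Component results are
taken as already risk-adjusted (higher = worse); numerator/denominator
computation and reliability smoothing happen upstream in the AHRQ
software and are out of scope here.

Hospitals missing some components are scored on the components they have,
with the weights renormalized over that subset (zero-imputation would
reward non-reporting); the ``renormalized`` flag surfaces when this
happened.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .core import HospitalRecord, PsiWeightSet

__all__ = [
    "Psi90Result",
    "Domain1UnscorableError",
    "SkippedHospital",
    "CohortPsi90",
    "compute_psi90",
    "compute_psi90_cohort",
]


class Domain1UnscorableError(ValueError):
    """No overlap between a hospital's components and the weight set."""

    def __init__(self, hospital_id: str, version_label: str):
        self.hospital_id = hospital_id
        super().__init__(
            f"hospital {hospital_id!r}: no PSI component overlaps weight set "
            f"{version_label!r}; Domain 1 unscorable"
        )


@dataclass(frozen=True)
class Psi90Result:
    hospital_id: str
    composite: float
    n_components_used: int
    renormalized: bool


class SkippedHospital(NamedTuple):
    hospital_id: str
    reason: str


class CohortPsi90(NamedTuple):
    results: list[Psi90Result]
    skipped: list[SkippedHospital]


def compute_psi90(record: HospitalRecord, weight_set: PsiWeightSet) -> Psi90Result:
    """Weighted composite over the components present in both the record
    and the weight set: sum(w_i * r_i) / sum(w_i)."""
    used = [code for code in weight_set.weights if code in record.psi_components]
    if not used:
        raise Domain1UnscorableError(record.hospital_id, weight_set.version_label)
    wsum = sum(weight_set.weights[c] for c in used)
    composite = sum(weight_set.weights[c] * record.psi_components[c] for c in used) / wsum
    return Psi90Result(
        hospital_id=record.hospital_id,
        composite=composite,
        n_components_used=len(used),
        renormalized=len(used) < len(weight_set.weights),
    )


def compute_psi90_cohort(
    records: Sequence[HospitalRecord] | Iterable[HospitalRecord],
    weight_set: PsiWeightSet,
) -> CohortPsi90:
    """Element-wise :func:`compute_psi90`; unscorable hospitals land in a
    structured skip-list rather than being silently dropped.  Output order
    follows input order."""
    records = list(records)
    if not records:
        raise ValueError("cohort must be nonempty")
    results: list[Psi90Result] = []
    skipped: list[SkippedHospital] = []
    for record in records:
        try:
            results.append(compute_psi90(record, weight_set))
        except Domain1UnscorableError as err:
            skipped.append(SkippedHospital(record.hospital_id, str(err)))
    return CohortPsi90(results=results, skipped=skipped)
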