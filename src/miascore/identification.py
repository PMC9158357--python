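"""Per-aneurysm rupture prediction rules.

Four rules are evaluated against each other:

* ``score_largest`` — within each patient, the aneurysm(s) with the maximal
  aneurysm-specific prediction score are predicted ruptured (the score's
  intended use);
* ``diameter_largest`` — the same argmax on raw maximum diameter;
* ``shape_irregular`` — every irregular aneurysm is predicted ruptured,
  regardless of patient structure;
* ``location_is`` — every aneurysm at a target location is predicted
  ruptured. The merged target ``"AcomA+AA"`` reproduces the published
  grouping of the two anterior locations.

The membership rules (shape, location) are aneurysm-level classifiers: their
"predicted" totals are aneurysm counts, whereas the argmax rules predict
exactly one aneurysm per patient (absent ties), so their "predicted" totals
equal the patient count. Ties under argmax are surfaced explicitly: with
``tie_policy="flag_all"`` every maximal aneurysm is predicted, with
``"flag_none"`` no prediction is made for the tied patient; a tied ruptured
aneurysm counts as identified only if it is in the predicted set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

from .cohort import LOCATIONS, Cohort, Patient
from .errors import ConfigurationError, ContractError
from .scoring import DEFAULT_COEFFICIENTS, ScoreCoefficients, compute_score

__all__ = [
    "RuleKind",
    "TiePolicy",
    "PredictionRule",
    "PredictionResult",
    "predict",
    "misidentified_patients",
]

RuleKind = Literal["score_largest", "diameter_largest", "shape_irregular", "location_is"]
TiePolicy = Literal["flag_all", "flag_none"]

MERGED_ANTERIOR = "AcomA+AA"
_LOCATION_TARGETS = LOCATIONS + (MERGED_ANTERIOR,)


@dataclass(frozen=True)
class PredictionRule:
    kind: RuleKind
    location_target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "location_is":
            if self.location_target not in _LOCATION_TARGETS:
                raise ConfigurationError(
                    f"location_is rule needs a target in {_LOCATION_TARGETS}, "
                    f"got {self.location_target!r}"
                )
        elif self.location_target is not None:
            raise ConfigurationError(
                f"location_target is only valid for location_is, not {self.kind}"
            )

    @property
    def label(self) -> str:
        if self.kind == "location_is":
            return f"location_{self.location_target}"
        return self.kind

    def _matches_location(self, location: str) -> bool:
        if self.location_target == MERGED_ANTERIOR:
            return location in ("AcomA", "AA")
        return location == self.location_target


@dataclass(frozen=True)
class PredictionResult:
    """Predicted aneurysm ids per patient, with tie flags for argmax rules."""

    rule: PredictionRule
    predicted_ids: Mapping[str, frozenset[str]]
    tie_flags: Mapping[str, bool]

    def is_predicted(self, patient_id: str, aneurysm_id: str) -> bool:
        return aneurysm_id in self.predicted_ids.get(patient_id, frozenset())

    @property
    def n_predicted(self) -> int:
        return sum(len(ids) for ids in self.predicted_ids.values())


def _argmax_ids(
    patient: Patient, values: list[float], tie_policy: TiePolicy
) -> tuple[frozenset[str], bool]:
    best = max(values)
    ids = [a.aneurysm_id for a, v in zip(patient.aneurysms, values) if v == best]
    tie = len(ids) > 1
    if tie and tie_policy == "flag_none":
        return frozenset(), True
    return frozenset(ids), tie


def predict(
    cohort: Cohort,
    rule: PredictionRule,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    tie_policy: TiePolicy = "flag_all",
) -> PredictionResult:
    """Apply one prediction rule to every patient of a cohort."""
    predicted: dict[str, frozenset[str]] = {}
    ties: dict[str, bool] = {}
    for p in cohort.patients:
        if rule.kind == "score_largest":
            values = [compute_score(a, coefficients).score for a in p.aneurysms]
            predicted[p.patient_id], ties[p.patient_id] = _argmax_ids(
                p, values, tie_policy
            )
        elif rule.kind == "diameter_largest":
            values = [a.diameter_mm for a in p.aneurysms]
            predicted[p.patient_id], ties[p.patient_id] = _argmax_ids(
                p, values, tie_policy
            )
        elif rule.kind == "shape_irregular":
            predicted[p.patient_id] = frozenset(
                a.aneurysm_id for a in p.aneurysms if a.shape == "irregular"
            )
            ties[p.patient_id] = False
        elif rule.kind == "location_is":
            predicted[p.patient_id] = frozenset(
                a.aneurysm_id for a in p.aneurysms if rule._matches_location(a.location)
            )
            ties[p.patient_id] = False
        else:  # pragma: no cover - rule kinds are validated at construction
            raise ConfigurationError(f"unknown rule kind {rule.kind!r}")
    return PredictionResult(rule=rule, predicted_ids=predicted, tie_flags=ties)


def misidentified_patients(
    cohort: Cohort,
    rule: PredictionRule,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    tie_policy: TiePolicy = "flag_all",
) -> tuple[int, list[str]]:
    """Patients whose ruptured aneurysm is not in the rule's predicted set.

    Returns ``(count, patient_ids)``. Requires a validation-mode cohort.
    """
    if cohort.mode != "validation":
        raise ContractError("misidentified_patients requires a validation-mode cohort")
    result = predict(cohort, rule, coefficients, tie_policy)
    missed: list[str] = []
    for p in cohort.patients:
        (ruptured,) = p.ruptured_aneurysms
        if not result.is_predicted(p.patient_id, ruptured.aneurysm_id):
            missed.append(p.patient_id)
    return len(missed), missed
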