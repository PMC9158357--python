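"""The aneurysm-specific prediction score.

The score of one aneurysm is the sum of three components::

    A = 0.0427 * maximum diameter (mm)
    B = location coefficient
        (AcomA, AA: 0;  PcomA: -0.0104;  PC: -0.1831;  MCA: -0.4055;  ICA: -0.5973)
    C = 0 (regular shape) or 0.5387 (irregular shape)

Within a patient, the aneurysm with the largest score is the one predicted
to have ruptured. The coefficients were derived elsewhere by component-wise
gradient boosting with linear base learners; here they are fixed data. They
can be overridden from a YAML/JSON config for recalibration experiments, but
the defaults above are the published ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Literal, Mapping, Union

import yaml

from .cohort import LOCATIONS, Aneurysm, Cohort, Patient
from .errors import ConfigurationError

__all__ = [
    "ScoreCoefficients",
    "ScoredAneurysm",
    "DEFAULT_COEFFICIENTS",
    "compute_score",
    "score_cohort",
    "roc_feature_values",
    "load_coefficients",
]

RocFeature = Literal["A_size", "B_location", "C_shape", "score"]


@dataclass(frozen=True)
class ScoreCoefficients:
    """Coefficient set of the linear score; immutable once constructed."""

    size_coeff: float = 0.0427
    location_coeffs: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "AcomA": 0.0,
                "AA": 0.0,
                "PcomA": -0.0104,
                "PC": -0.1831,
                "MCA": -0.4055,
                "ICA": -0.5973,
            }
        )
    )
    irregular_bonus: float = 0.5387

    def __post_init__(self) -> None:
        missing = [loc for loc in LOCATIONS if loc not in self.location_coeffs]
        if missing:
            raise ConfigurationError(f"location_coeffs missing entries for {missing}")
        object.__setattr__(
            self, "location_coeffs", MappingProxyType(dict(self.location_coeffs))
        )


DEFAULT_COEFFICIENTS = ScoreCoefficients()


@dataclass(frozen=True)
class ScoredAneurysm:
    """An aneurysm with its score components; ``score == A + B + C`` exactly."""

    aneurysm: Aneurysm
    component_A: float
    component_B: float
    component_C: float
    score: float


def compute_score(
    aneurysm: Aneurysm, coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS
) -> ScoredAneurysm:
    """Score one aneurysm. Deterministic; reproduces published scores to 5 dp."""
    a = coefficients.size_coeff * aneurysm.diameter_mm
    b = coefficients.location_coeffs[aneurysm.location]
    c = coefficients.irregular_bonus if aneurysm.shape == "irregular" else 0.0
    return ScoredAneurysm(aneurysm, a, b, c, a + b + c)


def score_cohort(
    cohort: Cohort, coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS
) -> dict[str, tuple[ScoredAneurysm, ...]]:
    """Score every aneurysm, preserving the per-patient grouping and order."""
    return {
        p.patient_id: tuple(compute_score(a, coefficients) for a in p.aneurysms)
        for p in cohort.patients
    }


def roc_feature_values(
    aneurysm: Aneurysm,
    feature: RocFeature,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Continuous encoding of a single feature for ROC analysis.

    ``A_size`` and ``B_location`` are the score components; ``C_shape`` is
    the 0/1 irregularity indicator (the published ROC encoding — AUC is
    unchanged under the monotone map to 0/0.5387); ``score`` is the full sum.
    """
    scored = compute_score(aneurysm, coefficients)
    if feature == "A_size":
        return scored.component_A
    if feature == "B_location":
        return scored.component_B
    if feature == "C_shape":
        return 1.0 if aneurysm.shape == "irregular" else 0.0
    if feature == "score":
        return scored.score
    raise ConfigurationError(f"unknown ROC feature {feature!r}")


def load_coefficients(path: Union[str, Path]) -> ScoreCoefficients:
    """Load a coefficient override file (YAML or JSON).

    Expected keys: ``size_coeff``, ``location_coeffs`` (all six locations),
    ``irregular_bonus``. Missing keys fall back to the defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse coefficients file {path}: {exc}")
    if not isinstance(data, dict):
        raise ConfigurationError(f"coefficients file {path} must contain a mapping")
    kwargs = {}
    for key in ("size_coeff", "irregular_bonus"):
        if key in data:
            kwargs[key] = float(data[key])
    if "location_coeffs" in data:
        kwargs["location_coeffs"] = {
            str(k): float(v) for k, v in data["location_coeffs"].items()
        }
    return ScoreCoefficients(**kwargs)
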