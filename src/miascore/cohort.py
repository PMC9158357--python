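"""Domain model and CSV I/O for aneurysm-level cohort data.

One row per aneurysm: a patient identifier, the maximum diameter in mm, a
location category, a shape category and (in validation mode) the rupture
status. Patients group their aneurysms; a *validation-mode* cohort is the
multiple-aneurysm setting in which every patient has at least two aneurysms
of which exactly one has ruptured.

Location vocabulary (six labels; two of them — AcomA and AA — share a score
coefficient but stay distinct in the data model):

========  =================================================
PC        posterior circulation
AcomA     anterior communicating artery
AA        anterior cerebral artery (excluding AcomA)
PcomA     posterior communicating artery
MCA       middle cerebral artery
ICA       internal carotid artery (excluding PcomA)
========  =================================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Union

import pandas as pd

from .errors import CohortParseError, CohortValidationError

__all__ = [
    "LOCATIONS",
    "SHAPES",
    "Aneurysm",
    "Patient",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "table3_fixture",
]

LOCATIONS: tuple[str, ...] = ("PC", "AcomA", "AA", "PcomA", "MCA", "ICA")
SHAPES: tuple[str, ...] = ("regular", "irregular")

Mode = Literal["validation", "prediction"]

# case-insensitive synonyms accepted on input, canonical label on the right
_LOCATION_SYNONYMS = {
    "pc": "PC",
    "posterior circulation": "PC",
    "acoma": "AcomA",
    "anterior communicating artery": "AcomA",
    "aa": "AA",
    "aca": "AA",
    "anterior cerebral artery": "AA",
    "pcoma": "PcomA",
    "posterior communicating artery": "PcomA",
    "mca": "MCA",
    "middle cerebral artery": "MCA",
    "ica": "ICA",
    "internal carotid artery": "ICA",
}

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}

_COLUMNS = ["patient_id", "aneurysm_id", "diameter_mm", "location", "shape", "ruptured"]


def parse_location(label: str) -> str:
    """Map an input label to one of the six canonical location categories."""
    key = str(label).strip().lower()
    try:
        return _LOCATION_SYNONYMS[key]
    except KeyError:
        raise CohortParseError(f"unknown location label {label!r}") from None


def parse_shape(label: str) -> str:
    key = str(label).strip().lower()
    if key not in SHAPES:
        raise CohortParseError(f"unknown shape label {label!r}")
    return key


def parse_ruptured(value: object) -> bool:
    key = str(value).strip().lower()
    if key in _TRUE_TOKENS:
        return True
    if key in _FALSE_TOKENS:
        return False
    raise CohortParseError(f"unknown ruptured flag {value!r}")


@dataclass(frozen=True)
class Aneurysm:
    """A single lesion's morphology and (optionally) its rupture status.

    ``ruptured`` is ``None`` only in prediction mode, where the outcome is
    unknown. Diameters are consensus values in millimetres.
    """

    aneurysm_id: str
    diameter_mm: float
    location: str
    shape: str
    ruptured: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise CohortValidationError(
                f"aneurysm {self.aneurysm_id!r}: diameter must be positive, "
                f"got {self.diameter_mm}"
            )
        if self.location not in LOCATIONS:
            raise CohortValidationError(
                f"aneurysm {self.aneurysm_id!r}: location {self.location!r} "
                f"not in {LOCATIONS}"
            )
        if self.shape not in SHAPES:
            raise CohortValidationError(
                f"aneurysm {self.aneurysm_id!r}: shape {self.shape!r} not in {SHAPES}"
            )


@dataclass(frozen=True)
class Patient:
    """A patient and their aneurysms, in stable input order."""

    patient_id: str
    aneurysms: tuple[Aneurysm, ...]

    @property
    def n_aneurysms(self) -> int:
        return len(self.aneurysms)

    @property
    def ruptured_aneurysms(self) -> tuple[Aneurysm, ...]:
        return tuple(a for a in self.aneurysms if a.ruptured)

    def validate(self, mode: Mode, allow_single: bool = False) -> None:
        ids = [a.aneurysm_id for a in self.aneurysms]
        if len(set(ids)) != len(ids):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: duplicate aneurysm ids"
            )
        if len(self.aneurysms) < 2 and not allow_single:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: fewer than 2 aneurysms "
                "(set allow_single for prediction-only use)"
            )
        if mode == "validation":
            n_rupt = sum(1 for a in self.aneurysms if a.ruptured)
            if n_rupt != 1:
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: validation mode requires "
                    f"exactly one ruptured aneurysm, found {n_rupt}"
                )


@dataclass(frozen=True)
class Cohort:
    """A validated collection of patients; the unit of evaluation."""

    patients: tuple[Patient, ...]
    mode: Mode = "validation"
    allow_single: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        pids = [p.patient_id for p in self.patients]
        if len(set(pids)) != len(pids):
            raise CohortValidationError("duplicate patient ids in cohort")
        for p in self.patients:
            p.validate(self.mode, self.allow_single)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_aneurysms(self) -> int:
        return sum(p.n_aneurysms for p in self.patients)

    def iter_aneurysms(self) -> Iterator[tuple[Patient, Aneurysm]]:
        for p in self.patients:
            for a in p.aneurysms:
                yield p, a

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-aneurysm view, preserving input order."""
        rows = []
        for p, a in self.iter_aneurysms():
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "aneurysm_id": a.aneurysm_id,
                    "diameter_mm": a.diameter_mm,
                    "location": a.location,
                    "shape": a.shape,
                    "ruptured": a.ruptured,
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)


def _cohort_from_frame(df: pd.DataFrame, mode: Mode, allow_single: bool) -> Cohort:
    have_ruptured = "ruptured" in df.columns
    if mode == "validation" and not have_ruptured:
        raise CohortParseError("validation mode requires a 'ruptured' column")

    patients: dict[str, list[Aneurysm]] = {}
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based with header line
        try:
            ruptured: Optional[bool] = None
            if have_ruptured and not pd.isna(row["ruptured"]):
                ruptured = parse_ruptured(row["ruptured"])
            try:
                diameter = float(row["diameter_mm"])
            except (TypeError, ValueError):
                raise CohortParseError(
                    f"bad diameter {row['diameter_mm']!r}"
                ) from None
            aneurysm = Aneurysm(
                aneurysm_id=str(row["aneurysm_id"]),
                diameter_mm=diameter,
                location=parse_location(row["location"]),
                shape=parse_shape(row["shape"]),
                ruptured=ruptured,
            )
        except (CohortParseError, CohortValidationError) as exc:
            raise CohortParseError(f"row {rowno}: {exc}") from None
        patients.setdefault(str(row["patient_id"]), []).append(aneurysm)

    return Cohort(
        patients=tuple(
            Patient(pid, tuple(aneurysms)) for pid, aneurysms in patients.items()
        ),
        mode=mode,
        allow_single=allow_single,
    )


def read_cohort(
    path: Union[str, Path, io.TextIOBase],
    mode: Mode = "validation",
    allow_single: bool = False,
) -> Cohort:
    """Read a cohort CSV (UTF-8, header mandatory) and validate it.

    Rows are grouped by ``patient_id`` preserving file order within each
    patient. In prediction mode the ``ruptured`` column is optional.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing required columns: {missing}")
    return _cohort_from_frame(df, mode, allow_single)


def write_cohort(cohort: Cohort, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a cohort as CSV readable by :func:`read_cohort` (round-trip safe)."""
    df = cohort.to_frame()
    df["ruptured"] = df["ruptured"].map(
        lambda r: "" if r is None or pd.isna(r) else ("yes" if r else "no")
    )
    df.to_csv(path, index=False)


def table3_fixture() -> Cohort:
    """The packaged cohort of the 17 patients whose ruptured aneurysm did not
    attain the maximal score: 38 aneurysms with the sizes, locations, shapes
    and rupture statuses as printed (scores are always recomputed, never
    stored).
    """
    ref = resources.files("miascore.data").joinpath("table3_misidentified.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_cohort(fh, mode="validation")
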