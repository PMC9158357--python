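"""Seeded generator of synthetic multiple-aneurysm validation cohorts.

The generator emulates the structure of the validation cohort the score was
tested on: 134 patients carrying 290 aneurysms (115 patients with two, 16
with three, 3 with four), exactly one ruptured aneurysm per patient, and
group-wise morphology — diameters from truncated normals whose *truncated*
mean and sd equal the reported group moments (ruptured 7.88 ± 3.02 mm,
unruptured 5.02 ± 2.44 mm, confined to the observed 1.8–20.7 mm range; the
underlying normal is moment-matched so truncation does not bias the
realized mean), irregular-shape probabilities 0.709 / 0.231, and
location frequencies per rupture status over the five reported location
groups. Shape and location are drawn independently given rupture status
(only marginals are reported, so no dependence structure is assumed), and
draws from the merged anterior group split evenly between its two labels.

Each patient consumes an independent substream spawned deterministically
from the global seed, so cohorts are reproducible and patient ``i`` is
unchanged when ``n_patients`` grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import yaml

from .cohort import Aneurysm, Cohort, Patient
from .errors import ConfigurationError
from .evaluation import ConfusionCounts
from .identification import MERGED_ANTERIOR, PredictionRule

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate",
    "generate_from_counts",
    "load_generator_config",
    "save_generator_config",
]

LOCATION_GROUPS = ("PC", MERGED_ANTERIOR, "PcomA", "MCA", "ICA")

_PROB_TOL = 1e-9


def _check_dist(name: str, dist: Mapping, keys: tuple) -> None:
    if set(dist) != set(keys):
        raise ConfigurationError(f"{name} must have keys {keys}, got {tuple(dist)}")
    probs = np.array([dist[k] for k in keys], dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {probs.sum()}, not 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator; validated on creation."""

    n_patients: int
    aneurysms_per_patient_dist: Mapping[int, float]
    ruptured_size: tuple[float, float]  # (mean mm, sd mm)
    unruptured_size: tuple[float, float]
    irregular_prob_ruptured: float
    irregular_prob_unruptured: float
    location_probs_ruptured: Mapping[str, float]
    location_probs_unruptured: Mapping[str, float]
    size_range: tuple[float, float]  # (min mm, max mm)
    seed: int = 0
    deterministic_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        _check_dist("aneurysms_per_patient_dist", self.aneurysms_per_patient_dist, (2, 3, 4))
        for name, p in (
            ("irregular_prob_ruptured", self.irregular_prob_ruptured),
            ("irregular_prob_unruptured", self.irregular_prob_unruptured),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        _check_dist("location_probs_ruptured", self.location_probs_ruptured, LOCATION_GROUPS)
        _check_dist("location_probs_unruptured", self.location_probs_unruptured, LOCATION_GROUPS)
        lo, hi = self.size_range
        if not (0 < lo < hi):
            raise ConfigurationError("size_range must satisfy 0 < min < max")
        for name, (mean, sd) in (
            ("ruptured_size", self.ruptured_size),
            ("unruptured_size", self.unruptured_size),
        ):
            if sd <= 0:
                raise ConfigurationError(f"{name}: sd must be > 0")
            if lo > mean + 6 * sd or hi < mean - 6 * sd:
                raise ConfigurationError(
                    f"{name}: size_range {self.size_range} excludes mean ± 6 sd "
                    "(infeasible truncation)"
                )


def default_config(seed: int = 0, n_patients: int = 134) -> GeneratorConfig:
    """The study conditions: the reported cohort structure and group-wise
    morphology distributions."""
    return GeneratorConfig(
        n_patients=n_patients,
        aneurysms_per_patient_dist={2: 115 / 134, 3: 16 / 134, 4: 3 / 134},
        ruptured_size=(7.88, 3.02),
        unruptured_size=(5.02, 2.44),
        irregular_prob_ruptured=0.709,
        irregular_prob_unruptured=0.231,
        location_probs_ruptured={
            "PC": 0.037, MERGED_ANTERIOR: 0.179, "PcomA": 0.471, "MCA": 0.246, "ICA": 0.067,
        },
        location_probs_unruptured={
            "PC": 0.064, MERGED_ANTERIOR: 0.103, "PcomA": 0.244, "MCA": 0.333, "ICA": 0.256,
        },
        size_range=(1.8, 20.7),
        seed=seed,
    )


@lru_cache(maxsize=64)
def _match_truncated_moments(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose truncation to [lo, hi] has the
    requested mean and sd.

    The reported group moments describe diameters already confined to the
    observed range, so naive rejection from N(mean, sd) would bias the
    realized mean upward (the cut lower tail is the heavier one). Matching
    the truncated moments keeps the generator faithful to the printed values.
    """
    from scipy import optimize, stats as sps

    def residual(params):
        mu, log_sigma = params
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        residual, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ConfigurationError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lo}, {hi}]: {msg}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def _deterministic_counts(config: GeneratorConfig) -> list[int]:
    """Largest-remainder apportionment of patients over the 2/3/4 counts."""
    keys = (2, 3, 4)
    quotas = np.array(
        [config.n_patients * config.aneurysms_per_patient_dist[k] for k in keys]
    )
    base = np.floor(quotas).astype(int)
    short = config.n_patients - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for j in order[:short]:
        base[j] += 1
    counts: list[int] = []
    for k, n in zip(keys, base):
        counts.extend([k] * int(n))
    return counts


def _draw_size(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, max_tries: int = 100_000) -> float:
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ConfigurationError(  # pragma: no cover - ruled out by config check
        "truncated-normal rejection sampling failed to land in size_range"
    )


def _draw_location(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    p = np.array([probs[g] for g in LOCATION_GROUPS])
    group = LOCATION_GROUPS[rng.choice(len(LOCATION_GROUPS), p=p / p.sum())]
    if group == MERGED_ANTERIOR:
        return "AcomA" if rng.random() < 0.5 else "AA"
    return group


def generate(config: GeneratorConfig) -> Cohort:
    """Generate a validation-mode cohort; fully reproducible given the seed."""
    if config.deterministic_counts:
        counts = _deterministic_counts(config)
    else:
        counts = None
    lo, hi = config.size_range
    size_params = {
        True: _match_truncated_moments(*config.ruptured_size, lo, hi),
        False: _match_truncated_moments(*config.unruptured_size, lo, hi),
    }
    patients = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        if counts is not None:
            n_ia = counts[i]
        else:
            keys = (2, 3, 4)
            p = np.array([config.aneurysms_per_patient_dist[k] for k in keys])
            n_ia = keys[rng.choice(3, p=p / p.sum())]
        ruptured_idx = int(rng.integers(n_ia))
        aneurysms = []
        for j in range(n_ia):
            ruptured = j == ruptured_idx
            mu, sigma = size_params[ruptured]
            irr_p = (
                config.irregular_prob_ruptured
                if ruptured
                else config.irregular_prob_unruptured
            )
            loc_p = (
                config.location_probs_ruptured
                if ruptured
                else config.location_probs_unruptured
            )
            aneurysms.append(
                Aneurysm(
                    aneurysm_id=f"{i + 1}-{j + 1}",
                    diameter_mm=round(_draw_size(rng, mu, sigma, lo, hi), 1),
                    location=_draw_location(rng, loc_p),
                    shape="irregular" if rng.random() < irr_p else "regular",
                    ruptured=ruptured,
                )
            )
        patients.append(Patient(patient_id=str(i + 1), aneurysms=tuple(aneurysms)))
    return Cohort(patients=tuple(patients), mode="validation")


# --------------------------------------------------------------------------
# Inverse construction from confusion counts (fixture factory)


def generate_from_counts(
    rule: PredictionRule, counts: ConfusionCounts, seed: int = 0
) -> Cohort:
    """Build a minimal cohort on which ``rule`` reproduces ``counts`` exactly.

    For the argmax rules every patient contributes exactly one predicted
    aneurysm, so a count table is feasible only when ``fp == fn`` and the
    unruptured total fits between one and three per patient. For the
    membership rules the feature assignment is free, subject to the same
    patient-size bounds. Diameters are drawn from ``seed`` but ordered so
    the argmax structure is exact.
    """
    n_pat = counts.tp + counts.fn
    n_unrupt = counts.fp + counts.tn
    if n_pat < 1:
        raise ConfigurationError("need at least one ruptured aneurysm (one patient)")
    if not n_pat <= n_unrupt <= 3 * n_pat:
        raise ConfigurationError(
            f"unruptured total {n_unrupt} incompatible with {n_pat} patients "
            "holding 2-4 aneurysms each"
        )
    argmax = rule.kind in ("score_largest", "diameter_largest")
    if argmax and counts.fp != counts.fn:
        raise ConfigurationError(
            f"argmax rules predict one aneurysm per patient: fp ({counts.fp}) "
            f"must equal fn ({counts.fn})"
        )
    rng = np.random.default_rng(seed)

    # number of unruptured mates per patient: at least one, at most three
    mates = np.ones(n_pat, dtype=int)
    extra = n_unrupt - n_pat
    idx = 0
    while extra > 0:
        if mates[idx] < 3:
            mates[idx] += 1
            extra -= 1
        else:
            idx += 1
            if idx >= n_pat:  # pragma: no cover - excluded by bound check
                raise ConfigurationError("cannot place unruptured aneurysms")
    if argmax:
        return _argmax_cohort(rule, counts, mates, rng)
    return _membership_cohort(rule, counts, mates, rng)


def _sorted_diameters(rng: np.random.Generator, n: int) -> np.ndarray:
    """Strictly increasing diameters in a plausible 2-15 mm band."""
    d = np.sort(rng.uniform(2.0, 15.0, size=n))
    return d + np.arange(n) * 1e-3  # break accidental ties


def _argmax_cohort(
    rule: PredictionRule,
    counts: ConfusionCounts,
    mates: np.ndarray,
    rng: np.random.Generator,
) -> Cohort:
    # single location and shape: the score is strictly increasing in
    # diameter, so one construction serves both argmax rules
    patients = []
    for i, n_mates in enumerate(mates):
        correct = i < counts.tp
        d = _sorted_diameters(rng, n_mates + 1)
        aneurysms = []
        # the largest diameter goes to the ruptured aneurysm iff correct
        ruptured_pos = n_mates if correct else 0
        for j in range(n_mates + 1):
            aneurysms.append(
                Aneurysm(
                    aneurysm_id=f"{i + 1}-{j + 1}",
                    diameter_mm=float(d[j]),
                    location="AcomA",
                    shape="regular",
                    ruptured=j == ruptured_pos,
                )
            )
        patients.append(Patient(str(i + 1), tuple(aneurysms)))
    return Cohort(tuple(patients), mode="validation")


def _membership_cohort(
    rule: PredictionRule,
    counts: ConfusionCounts,
    mates: np.ndarray,
    rng: np.random.Generator,
) -> Cohort:
    if rule.kind == "shape_irregular":
        def featured(n: int) -> dict:
            return {"shape": "irregular", "location": "AcomA"}

        def plain(n: int) -> dict:
            return {"shape": "regular", "location": "AcomA"}
    else:
        target = rule.location_target
        in_locs = ("AcomA", "AA") if target == MERGED_ANTERIOR else (target,)
        out_loc = "MCA" if "MCA" not in in_locs else "PcomA"

        def featured(n: int) -> dict:
            return {"shape": "regular", "location": in_locs[n % len(in_locs)]}

        def plain(n: int) -> dict:
            return {"shape": "regular", "location": out_loc}

    n_pat = counts.tp + counts.fn
    fp_left = counts.fp
    patients = []
    serial = 0
    for i, n_mates in enumerate(mates):
        rupt_featured = i < counts.tp
        aneurysms = [
            Aneurysm(
                aneurysm_id=f"{i + 1}-1",
                diameter_mm=float(rng.uniform(2.0, 15.0)),
                ruptured=True,
                **featured(serial) if rupt_featured else plain(serial),
            )
        ]
        serial += 1
        for j in range(n_mates):
            give_fp = fp_left > 0
            if give_fp:
                fp_left -= 1
            aneurysms.append(
                Aneurysm(
                    aneurysm_id=f"{i + 1}-{j + 2}",
                    diameter_mm=float(rng.uniform(2.0, 15.0)),
                    ruptured=False,
                    **featured(serial) if give_fp else plain(serial),
                )
            )
            serial += 1
        patients.append(Patient(str(i + 1), tuple(aneurysms)))
    if fp_left:  # pragma: no cover - excluded by bound check
        raise ConfigurationError("could not place all false-positive aneurysms")
    return Cohort(tuple(patients), mode="validation")


# --------------------------------------------------------------------------
# Config round-trip


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["aneurysms_per_patient_dist"] = {
        int(k): float(v) for k, v in config.aneurysms_per_patient_dist.items()
    }
    d["ruptured_size"] = list(config.ruptured_size)
    d["unruptured_size"] = list(config.unruptured_size)
    d["size_range"] = list(config.size_range)
    return d


def save_generator_config(config: GeneratorConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = _config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def load_generator_config(path: Union[str, Path]) -> GeneratorConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"generator config {path} must contain a mapping")
    data["aneurysms_per_patient_dist"] = {
        int(k): float(v) for k, v in data["aneurysms_per_patient_dist"].items()
    }
    for key in ("ruptured_size", "unruptured_size", "size_range"):
        data[key] = tuple(float(x) for x in data[key])
    return GeneratorConfig(**data)
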