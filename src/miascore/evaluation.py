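"""Diagnostic-accuracy evaluation: confusion counts, the five headline
metrics, ROC/AUC with confidence intervals, group comparison statistics and
inter-rater agreement.

Metric conventions
------------------
All metrics are aneurysm-level percentages::

    SEN = 100 * tp / (tp + fn)          sensitivity
    SPE = 100 * tn / (fp + tn)          specificity
    beta = 100 - SEN                    (reported as "false omission rate")
    alpha = 100 - SPE                   (reported as "diagnostic error rate")
    DA  = 100 * (tp + tn) / total       diagnostic accuracy

``beta`` and ``alpha`` are implemented as complements of sensitivity and
specificity: that is the only reading consistent with every published value
(e.g. the diameter rule's 18.7 = 100*25/134 and 16.0 = 100*25/156). The
textbook false-omission rate ``fn / (fn + tn)`` is exposed separately on
:class:`ConfusionCounts` to avoid confusion.

AUC equals the tie-corrected concordance probability (a ruptured/unruptured
pair counts 1 if the ruptured value is larger, 1/2 on a tie), which is also
the area under the trapezoidal ROC curve. The default 95% CI is DeLong's;
a stratified bootstrap is available as the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score, roc_curve

from .cohort import Cohort
from .errors import ContractError
from .identification import (
    MERGED_ANTERIOR,
    PredictionResult,
    PredictionRule,
    predict,
)
from .scoring import (
    DEFAULT_COEFFICIENTS,
    RocFeature,
    ScoreCoefficients,
    compute_score,
    roc_feature_values,
)

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "RocResult",
    "RuleEvaluation",
    "confusion",
    "metrics",
    "evaluate_all_rules",
    "roc",
    "roc_for_feature",
    "cohort_summary",
    "cohens_kappa",
    "evaluation_report",
    "render_markdown",
    "format_p",
]

CiMethod = Literal["delong", "bootstrap"]

#: Row order of the standard rule comparison: argmax on diameter, the two
#: membership families, then the score rule.
STANDARD_RULES: tuple[PredictionRule, ...] = (
    PredictionRule("diameter_largest"),
    PredictionRule("shape_irregular"),
    PredictionRule("location_is", "PC"),
    PredictionRule("location_is", MERGED_ANTERIOR),
    PredictionRule("location_is", "PcomA"),
    PredictionRule("location_is", "MCA"),
    PredictionRule("location_is", "ICA"),
    PredictionRule("score_largest"),
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Aneurysm-level 2x2 counts for one identification rule."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def textbook_false_omission_rate(self) -> float:
        """fn / (fn + tn), in percent — the standard FOR, distinct from beta."""
        if self.fn + self.tn == 0:
            raise ContractError("textbook FOR undefined: no negative predictions")
        return 100.0 * self.fn / (self.fn + self.tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five headline metrics, in percent, at full precision.

    ``sen + beta == 100`` and ``spe + alpha == 100`` by construction.
    """

    sen: float
    spe: float
    beta: float
    alpha: float
    da: float

    def rounded(self, ndigits: int = 1) -> "DiagnosticMetrics":
        return DiagnosticMetrics(
            *(round(v, ndigits) for v in (self.sen, self.spe, self.beta, self.alpha, self.da))
        )


@dataclass(frozen=True)
class RocResult:
    """ROC operating points plus AUC with a 95% CI and a test of AUC = 0.5."""

    points: tuple[tuple[float, float, float], ...]  # (threshold, tpr, fpr)
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str


@dataclass(frozen=True)
class RuleEvaluation:
    rule: PredictionRule
    counts: ConfusionCounts
    metrics: DiagnosticMetrics
    n_ties: int


def confusion(cohort: Cohort, prediction: PredictionResult) -> ConfusionCounts:
    """Cross-tabulate rupture status against a rule's predicted flags."""
    if cohort.mode != "validation":
        raise ContractError("confusion requires a validation-mode cohort")
    cohort_pids = {p.patient_id for p in cohort.patients}
    if cohort_pids - set(prediction.predicted_ids):
        raise ContractError(
            "prediction does not cover this cohort's patients (id mismatch)"
        )
    tp = fp = fn = tn = 0
    for p, a in cohort.iter_aneurysms():
        flagged = prediction.is_predicted(p.patient_id, a.aneurysm_id)
        if a.ruptured:
            tp, fn = (tp + 1, fn) if flagged else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if flagged else (fp, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """The five metrics from a 2x2 table; full precision (round for display)."""
    if counts.tp + counts.fn == 0 or counts.fp + counts.tn == 0:
        raise ContractError("metrics undefined: one outcome class is empty")
    sen = 100.0 * counts.tp / (counts.tp + counts.fn)
    spe = 100.0 * counts.tn / (counts.fp + counts.tn)
    return DiagnosticMetrics(
        sen=sen,
        spe=spe,
        beta=100.0 - sen,
        alpha=100.0 - spe,
        da=100.0 * (counts.tp + counts.tn) / counts.total,
    )


def evaluate_all_rules(
    cohort: Cohort,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    tie_policy: str = "flag_all",
) -> list[RuleEvaluation]:
    """Evaluate the full rule comparison on one validation-mode cohort."""
    rows = []
    for rule in STANDARD_RULES:
        pred = predict(cohort, rule, coefficients, tie_policy)  # type: ignore[arg-type]
        counts = confusion(cohort, pred)
        rows.append(
            RuleEvaluation(
                rule=rule,
                counts=counts,
                metrics=metrics(counts),
                n_ties=sum(pred.tie_flags.values()),
            )
        )
    return rows


# --------------------------------------------------------------------------
# ROC / AUC


def _check_roc_input(values: np.ndarray, ruptured: np.ndarray) -> None:
    if values.shape != ruptured.shape or values.ndim != 1:
        raise ContractError("values and ruptured flags must be 1-d and equal length")
    if ruptured.all() or not ruptured.any():
        raise ContractError("ROC requires both ruptured and unruptured aneurysms")
    if np.unique(values).size < 2:
        raise ContractError("ROC requires at least two distinct feature values")


def _delong_se(values: np.ndarray, ruptured: np.ndarray) -> float:
    """DeLong standard error of the AUC via midrank placements."""
    pos = values[ruptured]
    neg = values[~ruptured]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n  # placements of positives
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def roc(
    values: Sequence[float],
    ruptured: Sequence[bool],
    ci_method: CiMethod = "delong",
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """ROC curve and AUC for one continuous feature.

    ``values`` and ``ruptured`` are aneurysm-level and aligned. The AUC is
    the tie-corrected concordance probability; the CI is DeLong's normal
    interval or a seeded stratified percentile bootstrap, and the p-value
    tests AUC = 0.5 with the corresponding normal approximation.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(ruptured, dtype=bool)
    _check_roc_input(v, y)

    auc = float(roc_auc_score(y, v))
    fpr, tpr, thresholds = roc_curve(y, v)
    points = tuple(zip(map(float, thresholds), map(float, tpr), map(float, fpr)))

    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        se = _delong_se(v, y)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = v[y], v[~y]
        boot = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bv = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)])
            boot[i] = roc_auc_score(by, bv) if np.unique(bv).size > 1 else 0.5
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        se = float(boot.std(ddof=1))
    else:
        raise ContractError(f"unknown ci_method {ci_method!r}")

    if se > 0:
        p = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(
        points=points,
        auc=auc,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        p_value=float(p),
        ci_method=ci_method,
    )


def roc_for_feature(
    cohort: Cohort,
    feature: RocFeature,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    **kwargs,
) -> RocResult:
    """ROC of one score component (or the full score) on a validation cohort."""
    if cohort.mode != "validation":
        raise ContractError("ROC needs rupture labels (validation-mode cohort)")
    values, flags = [], []
    for _, a in cohort.iter_aneurysms():
        values.append(roc_feature_values(a, feature, coefficients))
        flags.append(bool(a.ruptured))
    return roc(values, flags, **kwargs)


# --------------------------------------------------------------------------
# Group comparison (morphology summary) and agreement


def _compare_continuous(
    x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05
) -> tuple[float, str]:
    """Two-group comparison with a Shapiro–Wilk normality gate.

    Both groups normal at ``normality_alpha`` -> two-sample t test; otherwise
    Mann–Whitney U. Returns (p, test name).
    """
    normal = all(
        len(g) >= 3 and stats.shapiro(g).pvalue > normality_alpha for g in (x, y)
    )
    if normal:
        return float(stats.ttest_ind(x, y).pvalue), "t"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue), "mannwhitney"


def _chi2_p(table: np.ndarray, correction: bool = False) -> float:
    """Chi-squared p for a 2x2 table; no continuity correction by default."""
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")
    return float(stats.chi2_contingency(table, correction=correction)[1])


def cohort_summary(
    cohort: Cohort,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    normality_alpha: float = 0.05,
    continuity_correction: bool = False,
) -> dict:
    """Morphology summary by rupture status, with between-group p-values.

    Continuous rows (diameter, score): mean ± SD per group; normality-gated
    t test / Mann–Whitney U. Categorical rows (shape; the five location
    groups with the two anterior labels merged): count (%) per group;
    chi-squared on the 2x2 in-category vs not table.
    """
    if cohort.mode != "validation":
        raise ContractError("cohort_summary requires a validation-mode cohort")
    rows = [
        (bool(a.ruptured), a.diameter_mm, compute_score(a, coefficients).score,
         a.shape, MERGED_ANTERIOR if a.location in ("AcomA", "AA") else a.location)
        for _, a in cohort.iter_aneurysms()
    ]
    rupt = np.array([r[0] for r in rows])
    diam = np.array([r[1] for r in rows])
    score = np.array([r[2] for r in rows])
    shape = np.array([r[3] for r in rows])
    loc = np.array([r[4] for r in rows])

    def group_stats(x: np.ndarray) -> dict:
        return {
            "unruptured_mean": float(x[~rupt].mean()),
            "unruptured_sd": float(x[~rupt].std(ddof=1)) if (~rupt).sum() > 1 else 0.0,
            "ruptured_mean": float(x[rupt].mean()),
            "ruptured_sd": float(x[rupt].std(ddof=1)) if rupt.sum() > 1 else 0.0,
        }

    summary: dict = {
        "n_unruptured": int((~rupt).sum()),
        "n_ruptured": int(rupt.sum()),
    }
    for name, x in (("diameter_mm", diam), ("score", score)):
        p, test = _compare_continuous(x[~rupt], x[rupt], normality_alpha)
        summary[name] = {**group_stats(x), "p": p, "test": test}

    irregular = shape == "irregular"
    shape_table = np.array(
        [
            [int((irregular & ~rupt).sum()), int((~irregular & ~rupt).sum())],
            [int((irregular & rupt).sum()), int((~irregular & rupt).sum())],
        ]
    )
    summary["shape"] = {
        "unruptured_irregular": int((irregular & ~rupt).sum()),
        "ruptured_irregular": int((irregular & rupt).sum()),
        "unruptured_irregular_pct": 100.0 * (irregular & ~rupt).sum() / max(1, (~rupt).sum()),
        "ruptured_irregular_pct": 100.0 * (irregular & rupt).sum() / max(1, rupt.sum()),
        "p": _chi2_p(shape_table, continuity_correction),
    }
    summary["location"] = {}
    for target in ("PC", MERGED_ANTERIOR, "PcomA", "MCA", "ICA"):
        here = loc == target
        table = np.array(
            [
                [int((here & ~rupt).sum()), int((~here & ~rupt).sum())],
                [int((here & rupt).sum()), int((~here & rupt).sum())],
            ]
        )
        summary["location"][target] = {
            "unruptured": int((here & ~rupt).sum()),
            "ruptured": int((here & rupt).sum()),
            "unruptured_pct": 100.0 * (here & ~rupt).sum() / max(1, (~rupt).sum()),
            "ruptured_pct": 100.0 * (here & rupt).sum() / max(1, rupt.sum()),
            "p": _chi2_p(table, continuity_correction),
        }
    return summary


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa, (po - pe) / (1 - pe), for two raters' categorical calls.

    Perfect observed agreement returns 1.0 (including the degenerate case
    where both raters used a single category throughout).
    """
    if len(ratings_a) != len(ratings_b):
        raise ContractError("rating sequences must have equal length")
    if len(ratings_a) == 0:
        raise ContractError("rating sequences must be non-empty")
    a = list(map(str, ratings_a))
    b = list(map(str, ratings_b))
    if a == b:
        return 1.0
    return float(cohen_kappa_score(a, b))


# --------------------------------------------------------------------------
# Reporting


def format_p(p: float) -> str:
    """p-values to 3 decimals with the conventional '<0.001' floor."""
    if math.isnan(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def evaluation_report(
    cohort: Cohort,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    ci_method: CiMethod = "delong",
    seed: int = 0,
    tie_policy: str = "flag_all",
) -> dict:
    """Machine-readable report: morphology summary, rule comparison, AUC
    table for the three components and the score, and the misidentified
    patients under the score rule. All values are recomputed from the cohort.
    """
    from .identification import misidentified_patients  # avoid cycle at import

    rules = evaluate_all_rules(cohort, coefficients, tie_policy)
    auc_rows = {}
    for feature in ("A_size", "B_location", "C_shape", "score"):
        r = roc_for_feature(cohort, feature, coefficients, ci_method=ci_method, seed=seed)
        auc_rows[feature] = {
            "auc": round(r.auc, 3),
            "ci_low": round(r.ci_low, 3),
            "ci_high": round(r.ci_high, 3),
            "p": format_p(r.p_value),
        }
    n_miss, missed_ids = misidentified_patients(
        cohort, PredictionRule("score_largest"), coefficients, tie_policy  # type: ignore[arg-type]
    )
    return {
        "n_patients": cohort.n_patients,
        "n_aneurysms": cohort.n_aneurysms,
        "coefficients": {
            "size_coeff": coefficients.size_coeff,
            "location_coeffs": dict(coefficients.location_coeffs),
            "irregular_bonus": coefficients.irregular_bonus,
        },
        "summary": cohort_summary(cohort, coefficients),
        "rules": [
            {
                "rule": ev.rule.label,
                "counts": asdict(ev.counts),
                "metrics": asdict(ev.metrics.rounded(1)),
                "n_ties": ev.n_ties,
            }
            for ev in rules
        ],
        "auc": auc_rows,
        "misidentified": {"count": n_miss, "patient_ids": missed_ids},
    }


def render_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`evaluation_report` output."""
    lines = [
        "# Rupture identification report",
        "",
        f"Patients: {report['n_patients']}; aneurysms: {report['n_aneurysms']}",
        "",
        "## Morphology by rupture status",
        "",
        "| characteristic | unruptured | ruptured | p |",
        "|---|---|---|---|",
    ]
    s = report["summary"]
    for name in ("diameter_mm", "score"):
        row = s[name]
        lines.append(
            f"| {name} (mean ± SD) "
            f"| {row['unruptured_mean']:.2f} ± {row['unruptured_sd']:.2f} "
            f"| {row['ruptured_mean']:.2f} ± {row['ruptured_sd']:.2f} "
            f"| {format_p(row['p'])} |"
        )
    sh = s["shape"]
    lines.append(
        f"| irregular shape | {sh['unruptured_irregular']} ({sh['unruptured_irregular_pct']:.1f}%) "
        f"| {sh['ruptured_irregular']} ({sh['ruptured_irregular_pct']:.1f}%) | {format_p(sh['p'])} |"
    )
    for target, row in s["location"].items():
        lines.append(
            f"| location {target} | {row['unruptured']} ({row['unruptured_pct']:.1f}%) "
            f"| {row['ruptured']} ({row['ruptured_pct']:.1f}%) | {format_p(row['p'])} |"
        )
    lines += [
        "",
        "## Rule comparison (aneurysm-level, %)",
        "",
        "| rule | TP | FP | FN | TN | SEN | SPE | beta | alpha | DA |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for row in report["rules"]:
        c, m = row["counts"], row["metrics"]
        lines.append(
            f"| {row['rule']} | {c['tp']} | {c['fp']} | {c['fn']} | {c['tn']} "
            f"| {m['sen']} | {m['spe']} | {m['beta']} | {m['alpha']} | {m['da']} |"
        )
    lines += ["", "## AUC", "", "| feature | AUC | 95% CI | p |", "|---|---|---|---|"]
    for feat, row in report["auc"].items():
        lines.append(
            f"| {feat} | {row['auc']:.3f} | {row['ci_low']:.3f}-{row['ci_high']:.3f} "
            f"| {row['p']} |"
        )
    miss = report["misidentified"]
    lines += [
        "",
        f"## Misidentified patients under the score rule: {miss['count']}",
        "",
        ", ".join(miss["patient_ids"]) if miss["patient_ids"] else "(none)",
        "",
    ]
    return "\n".join(lines)
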