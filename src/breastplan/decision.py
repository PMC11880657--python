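"""Constraint-based choice between 3D-CRT and IMRT, with validation metrics.

The clinical rule: a plan is acceptable when ipsilateral-lung V20Gy < 30%,
heart V25Gy < 10% and mean heart dose < 3 Gy (all strict).  3D-CRT is the
default technique whenever its (predicted) plan passes; IMRT is chosen only
when 3D-CRT fails.  If both techniques fail, IMRT is recommended and the
case is flagged for human review.

Recommendations are validated against ground-truth technique labels with a
2x2 confusion matrix whose positive class is 3D-CRT, reporting accuracy,
recall, precision and F1 in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvh_engine import DVHMetrics

__all__ = [
    "ConstraintSet",
    "Decision",
    "ConfusionMatrix",
    "ClassificationReport",
    "check_constraints",
    "recommend",
    "build_confusion",
    "classification_report",
    "run_framework",
]

CRT, IMRT = "3DCRT", "IMRT"


@dataclass(frozen=True)
class ConstraintSet:
    """Organ-at-risk plan-acceptance thresholds (strict less-than)."""

    lung_V20_max: float = 30.0   # % of ipsilateral lung volume
    heart_V25_max: float = 10.0  # % of heart volume
    heart_Dmean_max: float = 3.0  # Gy

    def __post_init__(self):
        if min(self.lung_V20_max, self.heart_V25_max, self.heart_Dmean_max) <= 0:
            raise ValueError("all constraint thresholds must be > 0")


@dataclass
class Violation:
    constraint: str
    observed: float
    threshold: float


@dataclass
class Decision:
    case_id: str
    recommended: str
    crt_pass: bool
    imrt_pass: bool
    violations: list = field(default_factory=list)
    needs_review: bool = False


@dataclass
class ConfusionMatrix:
    """Counts with 3D-CRT as the positive class."""

    tp: int  # predicted 3DCRT, actually 3DCRT
    fp: int  # predicted 3DCRT, actually IMRT
    fn: int  # predicted IMRT, actually 3DCRT
    tn: int  # predicted IMRT, actually IMRT

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationReport:
    """Percent metrics; a metric with a zero denominator is None."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None

    def rounded(self, ndigits=1):
        r = lambda v: None if v is None else round(v, ndigits)
        return ClassificationReport(r(self.accuracy), r(self.recall),
                                    r(self.precision), r(self.f1))


def check_constraints(metrics: dict, constraints: ConstraintSet):
    """Evaluate the OAR constraints on one technique's DVH metrics.

    ``metrics`` must hold DVHMetrics under keys ``lung`` and ``heart``.
    Returns (pass_flag, violations); every failed comparison is listed.
    """
    for key in ("lung", "heart"):
        if not isinstance(metrics.get(key), DVHMetrics):
            raise ValueError(f"missing {key} DVH metrics; constraints cannot be checked")
    checks = [
        ("lung_V20Gy", metrics["lung"].V20Gy, constraints.lung_V20_max),
        ("heart_V25Gy", metrics["heart"].V25Gy, constraints.heart_V25_max),
        ("heart_Dmean", metrics["heart"].Dmean, constraints.heart_Dmean_max),
    ]
    violations = [Violation(name, obs, thr) for name, obs, thr in checks if not obs < thr]
    return len(violations) == 0, violations


def recommend(case_id, crt_metrics: dict, imrt_metrics: dict,
              constraints: ConstraintSet = ConstraintSet()) -> Decision:
    """3D-CRT by default when it passes; IMRT otherwise (flagged if it also fails)."""
    crt_ok, crt_viol = check_constraints(crt_metrics, constraints)
    imrt_ok, imrt_viol = check_constraints(imrt_metrics, constraints)
    if crt_ok:
        return Decision(case_id, CRT, True, imrt_ok, [])
    return Decision(case_id, IMRT, False, imrt_ok,
                    crt_viol + ([] if imrt_ok else imrt_viol),
                    needs_review=not imrt_ok)


def build_confusion(ground_truth, decisions) -> ConfusionMatrix:
    """Exact counts of recommended vs actual technique labels."""
    gt, dec = list(ground_truth), list(decisions)
    if len(gt) != len(dec):
        raise ValueError("ground truth and decisions differ in length")
    valid = {CRT, IMRT}
    if not set(gt) <= valid or not set(dec) <= valid:
        raise ValueError(f"labels must be in {valid}")
    gt = np.asarray(gt)
    dec = np.asarray(dec)
    return ConfusionMatrix(
        tp=int(np.sum((dec == CRT) & (gt == CRT))),
        fp=int(np.sum((dec == CRT) & (gt == IMRT))),
        fn=int(np.sum((dec == IMRT) & (gt == CRT))),
        tn=int(np.sum((dec == IMRT) & (gt == IMRT))),
    )


def classification_report(matrix: ConfusionMatrix) -> ClassificationReport:
    """Accuracy / recall / precision / F1 in percent (positive class 3D-CRT)."""
    if matrix.total <= 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    acc = (tp + tn) / matrix.total * 100.0
    rec = tp / (tp + fn) * 100.0 if tp + fn > 0 else None
    prec = tp / (tp + fp) * 100.0 if tp + fp > 0 else None
    if rec is None or prec is None or prec + rec == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return ClassificationReport(acc, rec, prec, f1)


def run_framework(records, constraints: ConstraintSet = ConstraintSet()):
    """End-to-end decision run over a cohort.

    ``records``: iterable of dicts with keys ``case_id``, ``crt_metrics``,
    ``imrt_metrics`` (each a {"lung", "heart"} DVHMetrics dict, optionally
    with PTV metrics that are reported but never gate the rule) and
    ``ground_truth``.

    Returns (decisions, ConfusionMatrix, ClassificationReport, audit table).
    """
    records = list(records)
    decisions = [recommend(r["case_id"], r["crt_metrics"], r["imrt_metrics"], constraints)
                 for r in records]
    matrix = build_confusion([r["ground_truth"] for r in records],
                             [d.recommended for d in decisions])
    report = classification_report(matrix)
    audit = pd.DataFrame([
        dict(case_id=d.case_id, recommended=d.recommended,
             ground_truth=r["ground_truth"], crt_pass=d.crt_pass,
             imrt_pass=d.imrt_pass, needs_review=d.needs_review,
             violations="; ".join(f"{v.constraint}={v.observed:.2f}>={v.threshold:g}"
                                  for v in d.violations),
             crt_lung_V20Gy=r["crt_metrics"]["lung"].V20Gy,
             crt_heart_V25Gy=r["crt_metrics"]["heart"].V25Gy,
             crt_heart_Dmean=r["crt_metrics"]["heart"].Dmean,
             imrt_lung_V20Gy=r["imrt_metrics"]["lung"].V20Gy,
             imrt_heart_V25Gy=r["imrt_metrics"]["heart"].V25Gy,
             imrt_heart_Dmean=r["imrt_metrics"]["heart"].Dmean)
        for d, r in zip(decisions, records)
    ])
    return decisions, matrix, report, audit
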