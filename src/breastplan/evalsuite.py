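"""Spatial agreement between clinical and predicted dose distributions.

Isodose volumes (superlevel sets of dose at a percentage of prescription)
are compared volumetrically per case with the Dice similarity coefficient;
a DSC curve sweeps thresholds (default 5%..100% in 5% steps, the 30-70%
band being the clinically emphasised mid-dose range).  Voxelwise signed
difference maps summarise residual errors inside the body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DSCPoint",
    "isodose_volume",
    "dsc",
    "dsc_curve",
    "mean_dsc",
    "dose_difference_map",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(range(5, 101, 5))  # % of prescription


@dataclass(frozen=True)
class DSCPoint:
    threshold_pct: float
    dsc: float
    case_id: str = ""
    regime: str = ""

    def __post_init__(self):
        if not (0.0 <= self.threshold_pct <= 100.0):
            raise ValueError("threshold_pct must be in [0, 100]")
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError("dsc must be in [0, 1]")


def isodose_volume(dose, threshold_pct, prescription):
    """Binary volume of voxels receiving >= threshold_pct% of prescription."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    values = dose.values if hasattr(dose, "values") else np.asarray(dose)
    return values >= (threshold_pct / 100.0) * prescription


def dsc(a, b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); both-empty is defined as 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0  # agreement on absence
    return 2.0 * int(np.sum(a & b)) / denom


def dsc_curve(clinical, predicted, prescription,
              thresholds=DEFAULT_THRESHOLDS, case_id="", regime=""):
    """One DSCPoint per threshold, computed volumetrically per case."""
    cv = clinical.values if hasattr(clinical, "values") else np.asarray(clinical)
    pv = predicted.values if hasattr(predicted, "values") else np.asarray(predicted)
    if cv.shape != pv.shape:
        raise ValueError("dose maps are not aligned")
    return [DSCPoint(float(t),
                     dsc(isodose_volume(clinical, t, prescription),
                         isodose_volume(predicted, t, prescription)),
                     case_id, regime)
            for t in thresholds]


def mean_dsc(points, lo=30.0, hi=70.0) -> float:
    """Mean DSC over thresholds in [lo, hi] (the mid-dose band)."""
    vals = [p.dsc for p in points if lo <= p.threshold_pct <= hi]
    if not vals:
        raise ValueError("no DSC points in the requested threshold band")
    return float(np.mean(vals))


def dose_difference_map(clinical, predicted, body=None):
    """Voxelwise clinical - predicted and body-restricted summary stats."""
    cv = clinical.values if hasattr(clinical, "values") else np.asarray(clinical)
    pv = predicted.values if hasattr(predicted, "values") else np.asarray(predicted)
    if cv.shape != pv.shape:
        raise ValueError("dose maps are not aligned")
    diff = cv.astype(np.float64) - pv.astype(np.float64)
    sel = diff[np.asarray(body).astype(bool)] if body is not None else diff.ravel()
    summary = {
        "mean_difference_gy": float(sel.mean()),
        "mean_absolute_difference_gy": float(np.abs(sel).mean()),
        "max_absolute_difference_gy": float(np.abs(sel).max()),
    }
    return diff, summary
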