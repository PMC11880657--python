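"""Cumulative dose--volume histograms, clinical DVH metrics and plan deltas.

Metrics follow whole-breast practice: V95% and mean dose for PTVs, V25 Gy /
mean dose for the heart and V20 Gy / mean dose for the ipsilateral lung
(plus D95% for PTVs, which clinical reports also quote).  Metric values are
computed by exact voxel statistics, never from binned curves; DVH curves
are only a reporting surface.

Dose metrics between a clinical and a predicted plan are compared as
``(clinical - predicted) / prescription x 100`` (percent of prescription);
volume metrics (V95, V20Gy, V25Gy) are compared as direct differences in
percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DVHCurve",
    "DVHMetrics",
    "MetricDelta",
    "StructureAbsentError",
    "compute_dvh",
    "extract_metrics",
    "compare_metrics",
    "cohort_metric_table",
]

DOSE_METRICS = ("Dmean", "D95")          # compared relative to prescription
VOLUME_METRICS = ("V95", "V20Gy", "V25Gy")  # compared in percentage points


class StructureAbsentError(ValueError):
    """Raised when metrics are requested for an empty/absent structure.

    Callers must treat the structure as not-applicable -- never as dose 0.
    """


@dataclass
class DVHCurve:
    dose_edges: np.ndarray       # ascending Gy grid
    volume_fraction: np.ndarray  # fraction of volume receiving >= edge dose
    structure: str
    total_volume_cm3: float


@dataclass
class DVHMetrics:
    Dmean: float
    D95: float
    V95: float    # % of volume receiving >= 95% of prescription
    V20Gy: float  # % receiving >= 20 Gy
    V25Gy: float  # % receiving >= 25 Gy
    structure: str

    def as_dict(self):
        return {m: getattr(self, m) for m in DOSE_METRICS + VOLUME_METRICS}


@dataclass
class MetricDelta:
    metric: str
    structure: str
    clinical: float
    predicted: float
    relative_delta: float  # % of prescription for dose metrics, pp for volume
    kind: str              # "dose_metric" | "volume_metric"


def _masked_doses(dose, mask, structure):
    mask = np.asarray(mask).astype(bool)
    if dose.values.shape != mask.shape:
        raise ValueError(f"dose grid {dose.values.shape} does not match mask {mask.shape}")
    d = dose.values[mask]
    if d.size == 0:
        raise StructureAbsentError(f"structure {structure!r} has no voxels")
    return np.asarray(d, dtype=np.float64)


def compute_dvh(dose, mask, bin_width=0.1, structure="structure",
                voxel_spacing=None) -> DVHCurve:
    """Cumulative DVH of ``dose`` inside ``mask`` on a regular Gy grid."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = _masked_doses(dose, mask, structure)
    spacing = voxel_spacing if voxel_spacing is not None else dose.voxel_spacing
    voxel_cm3 = spacing[0] * spacing[1] * spacing[2] / 1000.0
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    d_sorted = np.sort(d)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(d_sorted, edges, side="left") / d.size
    return DVHCurve(edges, frac, structure, float(d.size * voxel_cm3))


def extract_metrics(dose, mask, prescription, structure="structure",
                    voxel_spacing=None) -> DVHMetrics:
    """Exact voxel-statistics DVH metrics for one structure.

    D95 is the largest dose received by at least 95% of the volume,
    estimated as the 5th percentile of voxel doses with linear interpolation
    between order statistics.
    """
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    d = _masked_doses(dose, mask, structure)
    return DVHMetrics(
        Dmean=float(d.mean()),
        D95=float(np.quantile(d, 0.05)),
        V95=float(np.mean(d >= 0.95 * prescription) * 100.0),
        V20Gy=float(np.mean(d >= 20.0) * 100.0),
        V25Gy=float(np.mean(d >= 25.0) * 100.0),
        structure=structure,
    )


def compare_metrics(clinical: DVHMetrics, predicted: DVHMetrics,
                    prescription: float) -> dict[str, MetricDelta]:
    """Clinical-minus-predicted deltas for all five metrics."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    if clinical.structure != predicted.structure:
        raise ValueError("metrics refer to different structures")
    out = {}
    for m in DOSE_METRICS:
        c, p = getattr(clinical, m), getattr(predicted, m)
        out[m] = MetricDelta(m, clinical.structure, c, p,
                             (c - p) / prescription * 100.0, "dose_metric")
    for m in VOLUME_METRICS:
        c, p = getattr(clinical, m), getattr(predicted, m)
        out[m] = MetricDelta(m, clinical.structure, c, p, c - p, "volume_metric")
    return out


def cohort_metric_table(deltas) -> pd.DataFrame:
    """Mean +- sample SD of relative deltas per (regime, structure, metric).

    ``deltas``: iterable of (regime, MetricDelta).  Cases whose structure is
    absent simply contribute no row, so absent structures are excluded from
    their cell rather than zero-filled.
    """
    rows = [dict(regime=r, structure=d.structure, metric=d.metric,
                 relative_delta=d.relative_delta) for r, d in deltas]
    if not rows:
        return pd.DataFrame(columns=["regime", "structure", "metric", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    agg = (df.groupby(["regime", "structure", "metric"])["relative_delta"]
             .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
             .reset_index())
    return agg
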