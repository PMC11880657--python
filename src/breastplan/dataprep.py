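"""Slice preparation and patient-level cross-validation splitting.

Pipeline per axial slice: renormalize dose to the 50 Gy prescription, crop
to the body bounding box (plus margin), nearest-neighbour resample to a
fixed square (128x128 by default), normalize CT to [0, 1] and stack the
input channels in a fixed order.  The crop box and original shape are kept
on every ``TrainingSlice`` so predictions can be mapped back to the
original grid for volumetric DVH evaluation (the resampling stretch is
anisotropic and must be inverted).

Coordinates are row-major, 0-based; boxes are half-open.

Nearest-neighbour index rule (bit-exact contract): output pixel ``i`` of
``n_out`` copies input pixel ``floor((i + 0.5) * n_in / n_out)`` (clipped
to ``n_in - 1``), i.e. the source whose centre is nearest to the output
pixel centre, ties resolved toward the larger index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .phantom_sim import DoseMap, PatientCase, ValidationError

__all__ = [
    "PrepConfig",
    "TrainingSlice",
    "FoldPlan",
    "renormalize_dose",
    "crop_to_body",
    "resample_nn",
    "assemble_slices",
    "case_input_stack",
    "restore_to_grid",
    "kfold_split",
    "save_prep_config",
    "load_prep_config",
    "save_fold_plan",
    "load_fold_plan",
]

logger = logging.getLogger(__name__)

#: fixed channel order of the network input
CHANNEL_ORDER = ("ct", "body", "lung_ipsi", "heart", "ptv_breast", "ptv_nodes")


@dataclass(frozen=True)
class PrepConfig:
    target_size: tuple[int, int] = (128, 128)
    crop_margin: int = 2           # voxels around the body bounding box
    ct_window: float = 400.0       # HU window width for [0, 1] scaling
    ct_level: float = 40.0         # HU window centre
    resample_method: str = "nearest"

    def __post_init__(self):
        if any(s <= 0 for s in self.target_size):
            raise ValidationError("target_size components must be > 0")
        if self.crop_margin < 0:
            raise ValidationError("crop_margin must be >= 0")
        if self.ct_window <= 0:
            raise ValidationError("ct_window must be > 0")
        if self.resample_method != "nearest":
            raise ValidationError("only nearest-neighbour resampling is supported")


@dataclass
class TrainingSlice:
    input_channels: np.ndarray  # (H, W, C) float32, fixed CHANNEL_ORDER
    target: np.ndarray          # (H, W) float32 dose in Gy
    case_id: str
    slice_index: int
    crop_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    original_shape: tuple[int, int]


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict = field(default_factory=dict)  # case_id -> fold index
    seed: int = 0

    def fold_cases(self, fold):
        return sorted(cid for cid, f in self.assignments.items() if f == fold)

    def train_cases(self, fold):
        return sorted(cid for cid, f in self.assignments.items() if f != fold)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def renormalize_dose(dose: DoseMap, original_prescription: float) -> DoseMap:
    """Rescale a plan delivered at another prescription to 2 Gy x 25 = 50 Gy."""
    if original_prescription <= 0:
        raise ValidationError("original_prescription must be > 0")
    scale = 50.0 / original_prescription
    return replace(dose, values=dose.values * scale)


def _body_bbox(body: np.ndarray, margin: int):
    rows = np.any(body, axis=1)
    cols = np.any(body, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    h, w = body.shape
    return (max(int(r0) - margin, 0), max(int(c0) - margin, 0),
            min(int(r1) + 1 + margin, h), min(int(c1) + 1 + margin, w))


def crop_to_body(slice_ct, slice_masks, slice_dose, config: PrepConfig):
    """Crop CT, masks and dose to the body bounding box plus margin.

    Returns ``(ct, masks, dose, crop_box)``; raises if the body is empty
    (callers skip such slices with a warning).
    """
    body = np.asarray(slice_masks["body"]).astype(bool)
    if not body.any():
        raise ValidationError("empty body mask on slice")
    box = _body_bbox(body, config.crop_margin)
    r0, c0, r1, c1 = box
    cut = lambda g: np.asarray(g)[r0:r1, c0:c1]
    return cut(slice_ct), {k: cut(v) for k, v in slice_masks.items()}, \
        (None if slice_dose is None else cut(slice_dose)), box


def _nn_index(n_out, n_in):
    idx = np.floor((np.arange(n_out) + 0.5) * (n_in / n_out)).astype(np.intp)
    return np.minimum(idx, n_in - 1)


def resample_nn(grid: np.ndarray, out_size) -> np.ndarray:
    """Nearest-neighbour resample; every output value is a copied input value."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValidationError("cannot resample an empty grid")
    rows, cols = out_size
    if rows <= 0 or cols <= 0:
        raise ValidationError("out_size components must be > 0")
    return grid[np.ix_(_nn_index(rows, grid.shape[0]), _nn_index(cols, grid.shape[1]))]


def _normalize_ct(ct, config: PrepConfig):
    lo = config.ct_level - config.ct_window / 2.0
    return np.clip((ct - lo) / config.ct_window, 0.0, 1.0)


def _slice_channels(case, z, config):
    """Cropped + resampled input channel stack for one slice, or None."""
    masks2d = {k: v[z] for k, v in case.masks.items()}
    if not masks2d["body"].any():
        return None
    ct_c, masks_c, _, box = crop_to_body(case.ct[z], masks2d, None, config)
    chans = []
    for name in CHANNEL_ORDER:
        if name == "ct":
            g = _normalize_ct(ct_c, config)
        elif name in masks_c:
            g = masks_c[name]
        else:  # node-negative case: constant channel count
            g = np.zeros_like(ct_c)
        chans.append(resample_nn(g, config.target_size))
    return np.stack(chans, axis=-1).astype(np.float32), box


def assemble_slices(case: PatientCase, dose: DoseMap,
                    config: PrepConfig = PrepConfig()) -> list[TrainingSlice]:
    """One TrainingSlice per axial slice with a nonempty body mask."""
    if dose.values.shape != case.ct.shape:
        raise ValidationError("dose grid is not aligned with the case grid")
    out = []
    for z in range(case.ct.shape[0]):
        prep = _slice_channels(case, z, config)
        if prep is None:
            logger.warning("case %s slice %d has empty body; skipped", case.case_id, z)
            continue
        chans, box = prep
        r0, c0, r1, c1 = box
        target = resample_nn(dose.values[z, r0:r1, c0:c1], config.target_size)
        out.append(TrainingSlice(
            input_channels=chans,
            target=target.astype(np.float32),
            case_id=case.case_id,
            slice_index=z,
            crop_box=box,
            original_shape=case.ct.shape[1:],
        ))
    return out


def case_input_stack(case: PatientCase, config: PrepConfig = PrepConfig()):
    """Input channels + crop metadata for prediction (no dose needed).

    Returns (inputs (N, H, W, C), slice_indices, crop_boxes).
    """
    inputs, zs, boxes = [], [], []
    for z in range(case.ct.shape[0]):
        prep = _slice_channels(case, z, config)
        if prep is None:
            continue
        inputs.append(prep[0])
        zs.append(z)
        boxes.append(prep[1])
    if not inputs:
        raise ValidationError(f"case {case.case_id} has no slices with body voxels")
    return np.stack(inputs), zs, boxes


def restore_to_grid(pred2d: np.ndarray, crop_box, original_shape) -> np.ndarray:
    """Map a fixed-size prediction back onto the original slice grid.

    Inverse of crop+resample: NN-resample to the crop-box shape, then paste
    into a zero background.
    """
    r0, c0, r1, c1 = crop_box
    out = np.zeros(original_shape, dtype=pred2d.dtype)
    out[r0:r1, c0:c1] = resample_nn(pred2d, (r1 - r0, c1 - c0))
    return out


def save_prep_config(config: PrepConfig, path):
    """Serialize a PrepConfig to human-readable JSON."""
    Path(path).write_text(json.dumps(asdict(config), indent=1))


def load_prep_config(path) -> PrepConfig:
    data = json.loads(Path(path).read_text())
    data["target_size"] = tuple(data["target_size"])
    return PrepConfig(**data)


def save_fold_plan(plan: FoldPlan, path):
    Path(path).write_text(json.dumps(
        dict(k=plan.k, seed=plan.seed, assignments=plan.assignments), indent=1))


def load_fold_plan(path) -> FoldPlan:
    data = json.loads(Path(path).read_text())
    return FoldPlan(k=data["k"], assignments=dict(data["assignments"]),
                    seed=data["seed"])


def kfold_split(case_ids, k, seed=0) -> FoldPlan:
    """Patient-level k-fold partition; fold sizes differ by at most one."""
    ids = sorted(set(case_ids))
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds the number of cases ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = {ids[int(p)]: i % k for i, p in enumerate(perm)}
    return FoldPlan(k=k, assignments=assignments, seed=seed)
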