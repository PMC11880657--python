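"""2D U-Net dose regression: training regimes and slice-wise volume prediction.

The regressor maps a stack of 2D channels (normalized CT + one binary mask
channel per structure) to the 2D dose matrix of the same slice.  Training
minimises voxel-wise MSE with Adam (lr 1e-3, beta1 0.9, beta2 0.999) for a
fixed 20 epochs -- no validation split or early stopping.  Internally the
network regresses dose / prescription; predictions are rescaled to Gy.

Four regimes mirror a two-institution transfer setting:

* ModelA -- from scratch on the inst1 3D-CRT cohort (k-fold CV).
* ModelB -- ModelA fine-tuned on inst2 3D-CRT cases (all layers trainable).
* ModelC -- ModelA fine-tuned on inst2 IMRT cases.
* ModelD -- from scratch on inst2 IMRT cases (fine-tuning control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .dataprep import (FoldPlan, PrepConfig, assemble_slices, case_input_stack,
                       kfold_split, restore_to_grid)
from .phantom_sim import DoseMap, PatientCase, ValidationError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "RegimeLabel",
    "REGIMES",
    "build_model",
    "train",
    "run_cross_validation",
    "predict_case",
    "CVResult",
]


@dataclass(frozen=True)
class ModelConfig:
    input_channels: int = 6
    base_filters: int = 32
    depth: int = 4
    separable_convolutions: bool = True  # Xception-style blocks
    output_activation: str = "clamped_linear"  # non-negative dose head

    def __post_init__(self):
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.base_filters < 8:
            raise ValidationError("base_filters must be >= 8")
        if self.input_channels < 1:
            raise ValidationError("input_channels must be >= 1")
        if self.output_activation != "clamped_linear":
            raise ValidationError("only the clamped-linear non-negative head is supported")


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0
    mode: str = "from_scratch"  # or "fine_tune"
    k: int = 7
    dose_scale: float = 50.0    # Gy; network regresses dose / dose_scale

    def __post_init__(self):
        if self.loss != "mse":
            raise ValidationError("only MSE loss is supported")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.mode not in ("from_scratch", "fine_tune"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RegimeLabel:
    """Named training regime: data source and weight initialisation."""

    name: str               # ModelA..ModelD
    source_cohort: str      # e.g. "inst1/3DCRT"
    init_from: str | None   # regime whose weights initialise this one


REGIMES = {
    "ModelA": RegimeLabel("ModelA", "inst1/3DCRT", None),
    "ModelB": RegimeLabel("ModelB", "inst2/3DCRT", "ModelA"),
    "ModelC": RegimeLabel("ModelC", "inst2/IMRT", "ModelA"),
    "ModelD": RegimeLabel("ModelD", "inst2/IMRT", None),
}


def build_model(config: ModelConfig, seed: int, dose_scale: float = 50.0) -> nn.UNet2D:
    """Seeded construction; two builds with the same seed are identical."""
    return nn.UNet2D(
        in_channels=config.input_channels,
        base_filters=config.base_filters,
        depth=config.depth,
        separable=config.separable_convolutions,
        seed=seed,
        output_scale=dose_scale,
    )


def train(model: nn.UNet2D, dataset, config: TrainConfig, initial_weights=None):
    """Train on a list of TrainingSlice; returns (model, per-epoch loss history).

    In ``fine_tune`` mode ``initial_weights`` (from the source model) must be
    supplied; all layers are retrained.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValidationError("training dataset is empty")
    if config.mode == "fine_tune":
        if initial_weights is None:
            raise ValidationError("fine_tune mode requires initial weights")
        model.set_weights(initial_weights)
    elif initial_weights is not None:
        raise ValidationError("initial weights are only accepted in fine_tune mode")

    x = np.stack([s.input_channels for s in dataset]).astype(np.float32)
    y = (np.stack([s.target for s in dataset])[..., None] / config.dose_scale)
    y = y.astype(np.float32)

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            pred = model.forward(x[sel])
            loss, grad = nn.mse_loss_and_grad(pred, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss ({loss}) -- aborting")
            model.backward(grad)
            opt.step(model.gradients())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_case(model: nn.UNet2D, case: PatientCase,
                 config: PrepConfig = PrepConfig(), technique="3DCRT") -> DoseMap:
    """Slice-wise prediction mapped back to the case grid as a volume.

    Raw outputs are rescaled to Gy, clamped at 0, restored through each
    slice's crop box and zeroed outside the body mask; empty-body slices
    stay at zero dose.
    """
    inputs, zs, boxes = case_input_stack(case, config)
    preds = model.predict(inputs)[..., 0] * model.output_scale
    preds = np.maximum(preds, 0.0)
    vol = np.zeros(case.ct.shape, dtype=np.float32)
    for p, z, box in zip(preds, zs, boxes):
        vol[z] = restore_to_grid(p.astype(np.float32), box, case.ct.shape[1:])
    vol *= case.masks["body"]
    np.minimum(vol, 1.3 * case.prescription_dose, out=vol)
    return DoseMap(vol, case.voxel_spacing, technique, case.case_id)


@dataclass
class CVResult:
    regime: RegimeLabel
    fold_plan: FoldPlan
    models: list
    oof_predictions: dict  # case_id -> DoseMap
    histories: list


def run_cross_validation(cases_with_doses, regime: RegimeLabel,
                         model_config: ModelConfig, train_config: TrainConfig,
                         prep_config: PrepConfig = PrepConfig(),
                         source_weights=None, fold_plan: FoldPlan | None = None,
                         technique="3DCRT") -> CVResult:
    """k-fold CV: each case receives exactly one out-of-fold predicted volume.

    ``cases_with_doses``: list of (PatientCase, DoseMap) reference pairs.
    Regimes that fine-tune (init_from set) require ``source_weights``.
    """
    cases = {c.case_id: (c, d) for c, d in cases_with_doses}
    if len(cases) != len(cases_with_doses):
        raise ValidationError("duplicate case ids")
    if fold_plan is None:
        fold_plan = kfold_split(cases.keys(), train_config.k, train_config.seed)
    if set(fold_plan.assignments) != set(cases):
        raise ValidationError("fold plan does not cover the case set")
    if regime.init_from is not None and source_weights is None:
        raise ValidationError(f"{regime.name} initialises from {regime.init_from}; "
                              "source_weights are required")

    slices_by_case = {cid: assemble_slices(c, d, prep_config)
                      for cid, (c, d) in cases.items()}
    models, histories, oof = [], [], {}
    for fold in range(fold_plan.k):
        test_ids = fold_plan.fold_cases(fold)
        train_ids = fold_plan.train_cases(fold)
        if set(test_ids) & set(train_ids):  # structural leakage guard
            raise ValidationError(f"fold {fold}: case in both train and test")
        train_slices = [s for cid in train_ids for s in slices_by_case[cid]]
        model = build_model(model_config, seed=train_config.seed + fold,
                            dose_scale=train_config.dose_scale)
        if regime.init_from is not None:
            cfg = train_config if train_config.mode == "fine_tune" else \
                TrainConfig(**{**train_config.__dict__, "mode": "fine_tune"})
            model, hist = train(model, train_slices, cfg, initial_weights=source_weights)
        else:
            model, hist = train(model, train_slices, train_config)
        models.append(model)
        histories.append(hist)
        for cid in test_ids:
            oof[cid] = predict_case(model, cases[cid][0], prep_config, technique)
    assert set(oof) == set(cases), "every case must receive one OOF prediction"
    return CVResult(regime, fold_plan, models, oof, histories)
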