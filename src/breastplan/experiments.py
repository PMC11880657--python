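"""Desk-scale end-to-end experiments tying the pipeline together.

These are the canonical study conditions used by the test-suite and the
reproduction script: a 40-case 3D-CRT source cohort (inst1) with 4-fold
cross-validation of a reduced U-Net (depth 3, 16 base filters, 64x64
slices), a 15-case IMRT-style target cohort (inst2) for the fine-tune
versus from-scratch transfer comparison, and a fresh 30-case inst2 cohort
for validating the decision framework against ground-truth labels.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataprep import PrepConfig, assemble_slices
from .decision import ConstraintSet, run_framework
from .dosenet import (REGIMES, CVResult, ModelConfig, TrainConfig, build_model,
                      predict_case, run_cross_validation, train)
from .dvh_engine import extract_metrics
from .evalsuite import dsc_curve, mean_dsc
from .phantom_sim import CohortSpec, generate_cohort

__all__ = [
    "REDUCED_PREP",
    "REDUCED_MODEL",
    "crt_source_pipeline",
    "transfer_comparison",
    "decision_validation",
    "oracle_decision_run",
]

#: reduced configuration: 64x64 slices, depth-3 / 16-filter U-Net
REDUCED_PREP = PrepConfig(target_size=(64, 64))
REDUCED_MODEL = ModelConfig(input_channels=6, base_filters=16, depth=3)


@dataclass
class SourcePipelineResult:
    entries: list
    cv: CVResult
    mean_dsc_30_70: float
    per_case_dsc: dict
    heart_dmean_spearman: float


def _oof_dsc(entries, cv, dose_attr):
    per_case = {}
    for e in entries:
        ref = getattr(e, dose_attr)
        pts = dsc_curve(ref, cv.oof_predictions[e.case.case_id],
                        e.case.prescription_dose, case_id=e.case.case_id)
        per_case[e.case.case_id] = mean_dsc(pts)
    return per_case


def crt_source_pipeline(seed, n_cases=40, k=4, epochs=20,
                        prep=REDUCED_PREP, model_config=REDUCED_MODEL):
    """Cross-validated 3D-CRT dose prediction on the inst1-style cohort.

    Returns OOF spatial agreement (mean DSC over the 30-70% band) and the
    Spearman correlation between OOF-predicted and reference heart Dmean.
    """
    entries = generate_cohort(CohortSpec.for_institution("inst1", n_cases, seed=seed))
    tc = TrainConfig(epochs=epochs, batch_size=16, seed=seed, k=k)
    cv = run_cross_validation([(e.case, e.dose_3dcrt) for e in entries],
                              REGIMES["ModelA"], model_config, tc, prep)
    per_case = _oof_dsc(entries, cv, "dose_3dcrt")
    ref_h, pred_h = [], []
    for e in entries:
        ref_h.append(extract_metrics(e.dose_3dcrt, e.case.masks["heart"],
                                     e.case.prescription_dose, "heart").Dmean)
        pred_h.append(extract_metrics(cv.oof_predictions[e.case.case_id],
                                      e.case.masks["heart"],
                                      e.case.prescription_dose, "heart").Dmean)
    rho = float(stats.spearmanr(ref_h, pred_h).statistic)
    return SourcePipelineResult(entries, cv, float(np.mean(list(per_case.values()))),
                                per_case, rho)


def transfer_comparison(source_weights, seed, n_cases=15, n_train=10, epochs=20,
                        seeds=(0, 1, 2), prep=REDUCED_PREP,
                        model_config=REDUCED_MODEL):
    """Fine-tuning versus from-scratch on a small IMRT-style target cohort.

    For each repeat seed the cohort is split into ``n_train`` training and
    ``n_cases - n_train`` held-out cases; both regimes share the split and
    the training slices.  Returns (mean fine-tune DSC, mean scratch DSC)
    over the 30-70% band, averaged over held-out cases then repeats.
    """
    target = generate_cohort(CohortSpec.for_institution("inst2", n_cases, seed=seed + 101))
    ft_scores, sc_scores = [], []
    for rep in seeds:
        rng = np.random.default_rng(seed + 7 * rep + 1)
        order = rng.permutation(n_cases)
        tr, te = order[:n_train], order[n_train:]
        tr_slices = [s for i in tr
                     for s in assemble_slices(target[i].case, target[i].dose_imrt, prep)]
        for mode, scores in (("fine_tune", ft_scores), ("from_scratch", sc_scores)):
            model = build_model(model_config, seed=seed + 1000 + rep)
            tc = TrainConfig(epochs=epochs, batch_size=16, seed=seed + rep, mode=mode)
            if mode == "fine_tune":
                model, _ = train(model, tr_slices, tc, initial_weights=source_weights)
            else:
                model, _ = train(model, tr_slices, tc)
            vals = [mean_dsc(dsc_curve(target[i].dose_imrt,
                                       predict_case(model, target[i].case, prep, "IMRT"),
                                       target[i].case.prescription_dose))
                    for i in te]
            scores.append(float(np.mean(vals)))
    return float(np.mean(ft_scores)), float(np.mean(sc_scores))


def _oar_metrics(dose, case):
    return {
        "lung": extract_metrics(dose, case.masks["lung_ipsi"],
                                case.prescription_dose, "lung"),
        "heart": extract_metrics(dose, case.masks["heart"],
                                 case.prescription_dose, "heart"),
    }


def oracle_decision_run(entries, constraints=ConstraintSet()):
    """Decision framework fed with the simulated (reference) DVH metrics.

    Labels were defined by the same constraint rule, so this run must
    reproduce them exactly; it validates the end-to-end plumbing.
    """
    records = [dict(case_id=e.case.case_id,
                    crt_metrics=_oar_metrics(e.dose_3dcrt, e.case),
                    imrt_metrics=_oar_metrics(e.dose_imrt, e.case),
                    ground_truth=e.label)
               for e in entries]
    return run_framework(records, constraints)


def decision_validation(source_weights, seed, n_validation=30, n_finetune=15,
                        epochs=20, prep=REDUCED_PREP, model_config=REDUCED_MODEL,
                        constraints=ConstraintSet()):
    """Technique recommendation from *predicted* dose on a fresh cohort.

    Institution-2 models are produced by fine-tuning the source (3D-CRT)
    network on an inst2 fine-tuning cohort: once on its 3D-CRT plans and
    once on its IMRT plans.  Both are then applied to a held-out inst2
    validation cohort; the framework's recommendations are scored against
    the ground-truth labels.
    """
    tune = generate_cohort(CohortSpec.for_institution("inst2", n_finetune, seed=seed + 202))
    models = {}
    for technique, attr in (("3DCRT", "dose_3dcrt"), ("IMRT", "dose_imrt")):
        slices = [s for e in tune for s in assemble_slices(e.case, getattr(e, attr), prep)]
        model = build_model(model_config, seed=seed + 11)
        tc = TrainConfig(epochs=epochs, batch_size=16, seed=seed + 12, mode="fine_tune")
        model, _ = train(model, slices, tc, initial_weights=source_weights)
        models[technique] = model

    validation = generate_cohort(CohortSpec.for_institution("inst2", n_validation,
                                                            seed=seed + 303))
    records = []
    for e in validation:
        crt_pred = predict_case(models["3DCRT"], e.case, prep, "3DCRT")
        imrt_pred = predict_case(models["IMRT"], e.case, prep, "IMRT")
        records.append(dict(case_id=e.case.case_id,
                            crt_metrics=_oar_metrics(crt_pred, e.case),
                            imrt_metrics=_oar_metrics(imrt_pred, e.case),
                            ground_truth=e.label))
    decisions, matrix, report, audit = run_framework(records, constraints)
    return dict(decisions=decisions, matrix=matrix, report=report, audit=audit,
                validation=validation, models=models)
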