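import numpy as np
import pytest

from breastplan.dvh_engine import DVHMetrics
from breastplan.phantom_sim import (CohortSpec, DoseMap, PatientCase, build_case,
                                    generate_cohort)


@pytest.fixture(scope="session")
def easy_case():
    """Left-sided phantom with a deep heart: simple tangential geometry."""
    return build_case("easy", heart_proximity=0.05, curvature=0.2, ptv_size=0.3,
                      laterality="left")


@pytest.fixture(scope="session")
def hard_case():
    """Left-sided phantom with the heart abutting the chest wall."""
    return build_case("hard", heart_proximity=0.9, curvature=0.7, ptv_size=0.8,
                      laterality="left")


@pytest.fixture(scope="session")
def small_cohort():
    """Six inst2 phantoms with paired plans and ground-truth labels."""
    return generate_cohort(CohortSpec.for_institution("inst2", n_cases=6, seed=42))


@pytest.fixture(scope="session")
def paired_sweep():
    """50 phantoms across both institutions with paired 3D-CRT/IMRT plans."""
    return (generate_cohort(CohortSpec.for_institution("inst1", n_cases=25, seed=3))
            + generate_cohort(CohortSpec.for_institution("inst2", n_cases=25, seed=4)))


def tiny_case(nz=3, n=24, with_nodes=False, empty_body_slices=()):
    """Hand-built minimal PatientCase for dataprep/dosenet plumbing tests."""
    masks = {name: np.zeros((nz, n, n), dtype=np.uint8)
             for name in ("body", "lung_ipsi", "lung_contra", "heart", "ptv_breast")}
    if with_nodes:
        masks["ptv_nodes"] = np.zeros((nz, n, n), dtype=np.uint8)
    for z in range(nz):
        if z in empty_body_slices:
            continue
        masks["body"][z, 4:n - 4, 3:n - 3] = 1
        masks["lung_ipsi"][z, 10:16, 5:10] = 1
        masks["heart"][z, 12:18, 12:17] = 1
        masks["ptv_breast"][z, 5:9, 14:20] = 1
        if with_nodes:
            masks["ptv_nodes"][z, 5:7, 6:9] = 1
    ct = np.where(masks["body"] > 0, 20.0, -1000.0).astype(np.float32)
    return PatientCase("tiny", ct, (3.0, 3.0, 3.0), masks, "left").validate()


def tiny_dose(case, value=50.0):
    vals = np.where(case.masks["body"] > 0, value, 0.0).astype(np.float32)
    return DoseMap(vals, case.voxel_spacing, "3DCRT", case.case_id)


@pytest.fixture
def tiny_case_fixture():
    return tiny_case()


def uniform_metrics(lung_v20=10.0, heart_v25=2.0, heart_dmean=1.0):
    """DVHMetrics pair dict for decision tests with chosen OAR values."""
    return {
        "lung": DVHMetrics(Dmean=5.0, D95=1.0, V95=0.0, V20Gy=lung_v20,
                           V25Gy=5.0, structure="lung"),
        "heart": DVHMetrics(Dmean=heart_dmean, D95=0.5, V95=0.0, V20Gy=3.0,
                            V25Gy=heart_v25, structure="heart"),
    }


# ---------------------------------------------------------------------------
# heavy trained-pipeline fixtures (shared by dosenet tests and acceptance)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def crt_pipeline():
    """Cross-validated reduced U-Net on the 40-case 3D-CRT source cohort."""
    from breastplan.experiments import crt_source_pipeline

    return crt_source_pipeline(seed=11)


@pytest.fixture(scope="session")
def transfer_result(crt_pipeline):
    """Fine-tune vs from-scratch comparison seeded from the source model."""
    from breastplan.experiments import transfer_comparison

    source_weights = crt_pipeline.cv.models[0].get_weights()
    return transfer_comparison(source_weights, seed=11)
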