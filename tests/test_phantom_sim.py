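import numpy as np
import pytest

from breastplan.dvh_engine import extract_metrics
from breastplan.phantom_sim import (DEFAULT_ENGINE_PARAMS, CohortSpec,
                                    PatientCase, ValidationError, build_case,
                                    generate_case, generate_cohort, load_cohort,
                                    save_cohort, simulate_dose_3dcrt,
                                    simulate_dose_imrt)


class TestGenerateCase:
    def test_same_seed_and_index_is_bit_identical(self):
        spec = CohortSpec.for_institution("inst2", n_cases=3, seed=9)
        a, b = generate_case(spec, 1), generate_case(spec, 1)
        assert np.array_equal(a.ct, b.ct)
        assert set(a.masks) == set(b.masks)
        assert all(np.array_equal(a.masks[k], b.masks[k]) for k in a.masks)
        assert a.covariates == b.covariates

    def test_zero_node_probability_means_no_nodal_ptv(self):
        spec = CohortSpec.for_institution("inst1", n_cases=8, seed=2,
                                          node_positive_prob=0.0)
        for i in range(8):
            assert "ptv_nodes" not in generate_case(spec, i).masks

    def test_institution_slice_thickness(self):
        # inst1 scans at 3.75 mm, inst2 at 3 mm
        for inst, dz in (("inst1", 3.75), ("inst2", 3.0)):
            spec = CohortSpec.for_institution(inst, n_cases=4, seed=0)
            for i in range(4):
                assert generate_case(spec, i).voxel_spacing[2] == dz

    def test_case_invariants(self, small_cohort):
        for e in small_cohort:
            c = e.case.validate()
            body = c.masks["body"]
            for name, m in c.masks.items():
                assert m.shape == c.ct.shape
                assert set(np.unique(m)) <= {0, 1}
            for name in ("ptv_breast", "heart", "lung_ipsi"):
                assert not np.any(c.masks[name] & ~body)

    def test_invalid_spec_names_offending_field(self):
        with pytest.raises(ValidationError, match="node_positive_prob"):
            CohortSpec(n_cases=3, node_positive_prob=1.5).validate()
        with pytest.raises(ValidationError, match="n_cases"):
            CohortSpec(n_cases=0).validate()
        spec = CohortSpec.for_institution("inst1", n_cases=2)
        with pytest.raises(ValidationError, match="index"):
            generate_case(spec, 5)


class TestTangentialEngine:
    def test_easy_geometry_spares_heart(self, easy_case):
        dose = simulate_dose_3dcrt(easy_case)
        heart = extract_metrics(dose, easy_case.masks["heart"], 50.0, "heart")
        assert heart.Dmean < 3.0

    def test_hard_geometry_overdoses_heart(self, hard_case):
        dose = simulate_dose_3dcrt(hard_case)
        heart = extract_metrics(dose, hard_case.masks["heart"], 50.0, "heart")
        assert heart.Dmean > 3.0

    def test_ptv_receives_prescription(self, easy_case):
        dose = simulate_dose_3dcrt(easy_case)
        ptv = extract_metrics(dose, easy_case.masks["ptv_breast"], 50.0, "ptv")
        assert ptv.V95 > 99.0
        assert abs(ptv.Dmean - 50.0) < 2.5

    def test_no_target_means_no_high_dose(self, easy_case):
        bare = PatientCase("bare", easy_case.ct, easy_case.voxel_spacing,
                           {"body": easy_case.masks["body"],
                            "lung_ipsi": np.zeros_like(easy_case.masks["body"]),
                            "lung_contra": np.zeros_like(easy_case.masks["body"]),
                            "heart": np.zeros_like(easy_case.masks["body"]),
                            "ptv_breast": np.zeros_like(easy_case.masks["body"])},
                           "left")
        dose = simulate_dose_3dcrt(bare)
        assert dose.values.max() <= DEFAULT_ENGINE_PARAMS["imrt_bath_gy"]

    def test_heart_dose_monotone_in_proximity(self):
        # moving the heart toward the chest wall never lowers its mean dose
        dmeans = []
        for p in np.linspace(0.0, 1.0, 11):
            c = build_case("sweep", heart_proximity=float(p), curvature=0.5,
                           ptv_size=0.5, laterality="left")
            d = simulate_dose_3dcrt(c)
            dmeans.append(extract_metrics(d, c.masks["heart"], 50.0, "h").Dmean)
        assert all(b >= a - 1e-9 for a, b in zip(dmeans, dmeans[1:]))

    def test_unknown_engine_parameter_rejected(self, easy_case):
        with pytest.raises(ValidationError, match="unknown engine parameters"):
            simulate_dose_3dcrt(easy_case, {"nope": 1.0})


class TestPairedTechniqueContrast:
    def test_dose_maps_valid_on_sweep(self, paired_sweep):
        for e in paired_sweep:
            e.dose_3dcrt.validate(e.case)
            e.dose_imrt.validate(e.case)

    def test_imrt_spares_oars_and_spreads_low_dose(self, paired_sweep):
        """IMRT: equal-or-lower high-dose OAR spill, larger low-dose bath."""
        for e in paired_sweep:
            c = e.case
            crt, imrt = e.dose_3dcrt.values, e.dose_imrt.values
            heart = c.masks["heart"].astype(bool)
            lung = c.masks["lung_ipsi"].astype(bool)
            body = c.masks["body"].astype(bool)
            ptv = c.masks["ptv_breast"].astype(bool)
            assert np.mean(imrt[heart] >= 25) <= np.mean(crt[heart] >= 25)
            assert np.mean(imrt[lung] >= 20) <= np.mean(crt[lung] >= 20)
            assert np.mean(imrt[body] >= 5) >= np.mean(crt[body] >= 5)
            # PTV homogeneity equal or better
            assert imrt[ptv].std() <= crt[ptv].std() + 1e-9

    def test_hard_case_imrt_heart_strictly_lower(self, hard_case):
        crt = simulate_dose_3dcrt(hard_case)
        imrt = simulate_dose_imrt(hard_case)
        h_crt = extract_metrics(crt, hard_case.masks["heart"], 50.0, "h").Dmean
        h_imrt = extract_metrics(imrt, hard_case.masks["heart"], 50.0, "h").Dmean
        assert h_crt > 3.0
        assert h_imrt < h_crt

    def test_easy_case_both_techniques_pass(self, easy_case):
        from breastplan.decision import ConstraintSet, check_constraints

        for sim in (simulate_dose_3dcrt, simulate_dose_imrt):
            dose = sim(easy_case)
            metrics = {
                "lung": extract_metrics(dose, easy_case.masks["lung_ipsi"], 50.0, "lung"),
                "heart": extract_metrics(dose, easy_case.masks["heart"], 50.0, "heart"),
            }
            ok, violations = check_constraints(metrics, ConstraintSet())
            assert ok, violations


class TestCohort:
    def test_labels_follow_constraint_rule(self, small_cohort):
        from breastplan.decision import ConstraintSet, check_constraints

        for e in small_cohort:
            metrics = {
                "lung": extract_metrics(e.dose_3dcrt, e.case.masks["lung_ipsi"],
                                        50.0, "lung"),
                "heart": extract_metrics(e.dose_3dcrt, e.case.masks["heart"],
                                         50.0, "heart"),
            }
            ok, _ = check_constraints(metrics, ConstraintSet())
            assert e.label == ("3DCRT" if ok else "IMRT")

    def test_label_fraction_matches_validation_cohort_mix(self):
        # the inst2 mix targets roughly 23 of 30 cases acceptable for 3D-CRT
        labels = []
        for seed in (1, 2, 7):
            labels += [e.label for e in
                       generate_cohort(CohortSpec.for_institution("inst2", 30, seed=seed))]
        frac = labels.count("3DCRT") / len(labels)
        assert abs(frac - 23 / 30) < 0.15

    def test_all_easy_spec_is_all_crt(self):
        spec = CohortSpec.for_institution("inst2", n_cases=5, seed=6,
                                          heart_proximity_beta=(1.0, 50.0),
                                          curvature_range=(0.0, 0.2),
                                          ptv_size_range=(0.0, 0.3))
        assert all(e.label == "3DCRT" for e in generate_cohort(spec))

    def test_cohort_reproducible_from_seed(self):
        spec = CohortSpec.for_institution("inst2", n_cases=4, seed=5)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert [e.label for e in a] == [e.label for e in b]
        assert all(np.array_equal(x.dose_imrt.values, y.dose_imrt.values)
                   for x, y in zip(a, b))

    def test_save_load_round_trip(self, small_cohort, tmp_path):
        save_cohort(small_cohort[:2], tmp_path)
        loaded = load_cohort(tmp_path)
        assert len(loaded) == 2
        for orig, back in zip(small_cohort[:2], loaded):
            assert back.case.case_id == orig.case.case_id
            assert back.label == orig.label
            assert np.allclose(back.dose_3dcrt.values, orig.dose_3dcrt.values)
            assert np.array_equal(back.case.masks["ptv_breast"],
                                  orig.case.masks["ptv_breast"])
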