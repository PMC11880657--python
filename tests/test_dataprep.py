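import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breastplan.dataprep import (CHANNEL_ORDER, PrepConfig, assemble_slices,
                                 crop_to_body, kfold_split, renormalize_dose,
                                 resample_nn, restore_to_grid)
from breastplan.dvh_engine import extract_metrics
from breastplan.phantom_sim import DoseMap, ValidationError

from conftest import tiny_case, tiny_dose


class TestRenormalize:
    @pytest.mark.parametrize("orig,voxel,expected", [
        (50.0, 40.0, 40.0),            # identity scaling
        (40.0, 40.0, 50.0),            # 40 x 50/40
        (42.56, 42.56, 50.0),          # hypofractionated prescription
    ])
    def test_scaling(self, orig, voxel, expected):
        dose = DoseMap(np.full((1, 2, 2), voxel), (3.0, 3.0, 3.0), "3DCRT", "c")
        out = renormalize_dose(dose, orig)
        assert np.allclose(out.values, expected)
        assert out.technique == dose.technique

    def test_nonpositive_prescription_rejected(self):
        dose = DoseMap(np.zeros((1, 2, 2)), (3.0, 3.0, 3.0), "3DCRT", "c")
        with pytest.raises(ValidationError):
            renormalize_dose(dose, 0.0)


class TestCropToBody:
    def test_full_frame_body_margin_zero(self):
        body = np.ones((16, 16), dtype=np.uint8)
        _, _, _, box = crop_to_body(np.zeros((16, 16)), {"body": body},
                                    np.zeros((16, 16)), PrepConfig(crop_margin=0))
        assert box == (0, 0, 16, 16)

    def test_tight_bounding_box_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            body = np.zeros((40, 30), dtype=np.uint8)
            r0, c0 = rng.integers(0, 20, 2)
            r1, c1 = r0 + rng.integers(1, 15), c0 + rng.integers(1, 10)
            body[r0:r1, c0:c1] = 1
            _, _, _, box = crop_to_body(np.zeros(body.shape), {"body": body},
                                        np.zeros(body.shape), PrepConfig(crop_margin=0))
            ys, xs = np.nonzero(body)  # brute-force scan
            assert box == (ys.min(), xs.min(), ys.max() + 1, xs.max() + 1)

    def test_margin_clipped_at_edges(self):
        body = np.zeros((20, 20), dtype=np.uint8)
        body[0:4, 17:20] = 1
        _, _, _, box = crop_to_body(np.zeros((20, 20)), {"body": body},
                                    np.zeros((20, 20)), PrepConfig(crop_margin=5))
        assert box == (0, 12, 9, 20)

    def test_empty_body_raises(self):
        with pytest.raises(ValidationError, match="empty body"):
            crop_to_body(np.zeros((8, 8)), {"body": np.zeros((8, 8), np.uint8)},
                         np.zeros((8, 8)), PrepConfig())


def _nn_oracle(grid, out_size):
    """Independent nearest-source-centre lookup (ties to the larger index)."""
    n_r, n_c = grid.shape
    out = np.empty(out_size, dtype=grid.dtype)
    for i in range(out_size[0]):
        for j in range(out_size[1]):
            src = []
            for n_in, n_out, idx in ((n_r, out_size[0], i), (n_c, out_size[1], j)):
                centre = (idx + 0.5) * n_in / n_out - 0.5
                dist = np.abs(np.arange(n_in) - centre)
                best = np.flatnonzero(dist == dist.min()).max()
                src.append(best)
            out[i, j] = grid[src[0], src[1]]
    return out


class TestResampleNN:
    def test_identity(self):
        g = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(resample_nn(g, (3, 4)), g)

    def test_value_preservation(self):
        g = np.array([[1.0, 2.0], [3.0, 4.0]])
        up = resample_nn(g, (4, 4))
        assert set(np.unique(up)) <= {1.0, 2.0, 3.0, 4.0}
        mask = np.array([[0, 1], [1, 0]])
        assert set(np.unique(resample_nn(mask, (5, 7)))) <= {0, 1}

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 8), st.integers(1, 8), st.integers(1, 8),
           st.integers(1, 8), st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_nearest_source(self, nr, nc, mr, mc, seed):
        grid = np.random.default_rng(seed).random((nr, nc))
        assert np.array_equal(resample_nn(grid, (mr, mc)), _nn_oracle(grid, (mr, mc)))

    def test_zero_out_size_rejected(self):
        with pytest.raises(ValidationError):
            resample_nn(np.ones((2, 2)), (0, 4))


class TestAssembleSlices:
    def test_counts_skip_empty_body(self):
        case = tiny_case(nz=5, empty_body_slices=(0, 3))
        slices = assemble_slices(case, tiny_dose(case), PrepConfig(target_size=(32, 32)))
        assert len(slices) == 3
        assert [s.slice_index for s in slices] == [1, 2, 4]

    def test_node_negative_channel_all_zero(self):
        case = tiny_case(with_nodes=False)
        slices = assemble_slices(case, tiny_dose(case), PrepConfig(target_size=(32, 32)))
        ch = CHANNEL_ORDER.index("ptv_nodes")
        assert all(s.input_channels[..., ch].sum() == 0 for s in slices)
        assert all(s.input_channels.shape == (32, 32, len(CHANNEL_ORDER))
                   for s in slices)

    def test_masks_stay_binary_and_dose_nonnegative(self, small_cohort):
        e = small_cohort[0]
        slices = assemble_slices(e.case, e.dose_3dcrt, PrepConfig(target_size=(64, 64)))
        for s in slices:
            for ch in range(1, len(CHANNEL_ORDER)):
                assert set(np.unique(s.input_channels[..., ch])) <= {0.0, 1.0}
            assert s.target.min() >= 0

    def test_misaligned_dose_rejected(self):
        case = tiny_case()
        bad = DoseMap(np.zeros((2, 5, 5)), case.voxel_spacing, "3DCRT", case.case_id)
        with pytest.raises(ValidationError, match="aligned"):
            assemble_slices(case, bad, PrepConfig())

    def test_round_trip_preserves_volumetric_dvh(self, small_cohort):
        """Un-crop + un-resample of the prepared target reproduces the
        original-grid DVH to within 2% of prescription on the PTV mean."""
        e = small_cohort[1]
        prep = PrepConfig(target_size=(64, 64))
        slices = assemble_slices(e.case, e.dose_3dcrt, prep)
        restored = np.zeros_like(e.dose_3dcrt.values)
        for s in slices:
            restored[s.slice_index] = restore_to_grid(s.target, s.crop_box,
                                                      s.original_shape)
        back = DoseMap(restored, e.case.voxel_spacing, "3DCRT", e.case.case_id)
        for mask in ("ptv_breast", "heart", "lung_ipsi"):
            orig = extract_metrics(e.dose_3dcrt, e.case.masks[mask], 50.0, mask)
            rt = extract_metrics(back, e.case.masks[mask], 50.0, mask)
            assert abs(orig.Dmean - rt.Dmean) < 0.02 * 50.0


class TestKFold:
    def test_equal_partition(self):
        ids = [f"c{i}" for i in range(14)]
        plan = kfold_split(ids, k=7, seed=0)
        sizes = [len(plan.fold_cases(f)) for f in range(7)]
        assert sizes == [2] * 7

    def test_folds_cover_every_case_exactly_once(self):
        ids = [f"c{i}" for i in range(23)]
        plan = kfold_split(ids, k=7, seed=1)
        seen = [cid for f in range(7) for cid in plan.fold_cases(f)]
        assert sorted(seen) == sorted(ids)
        sizes = [len(plan.fold_cases(f)) for f in range(7)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(10)]
        assert kfold_split(ids, 3, seed=5).assignments == \
            kfold_split(ids, 3, seed=5).assignments

    def test_k_larger_than_cases_rejected(self):
        with pytest.raises(ValidationError):
            kfold_split(["a", "b"], k=3)


class TestConfigSerialization:
    def test_prep_config_round_trip(self, tmp_path):
        from breastplan.dataprep import load_prep_config, save_prep_config
        cfg = PrepConfig(target_size=(64, 64), crop_margin=3, ct_window=350.0)
        save_prep_config(cfg, tmp_path / "prep.json")
        assert load_prep_config(tmp_path / "prep.json") == cfg

    def test_fold_plan_round_trip(self, tmp_path):
        from breastplan.dataprep import load_fold_plan, save_fold_plan
        plan = kfold_split([f"c{i}" for i in range(9)], k=3, seed=2)
        save_fold_plan(plan, tmp_path / "folds.json")
        back = load_fold_plan(tmp_path / "folds.json")
        assert back.k == plan.k and back.assignments == plan.assignments
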