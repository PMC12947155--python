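"""ECV computation: scalar relation, erosion, voxel maps, phantom round trips."""

import numpy as np
import pytest

from synecv import (
    compute_ecv,
    compute_ecv_map,
    compute_synecv,
    compute_synecv_map,
    ellipsoid_masks,
    erode_mask,
    generate_volume_pair,
    published_models,
)
from synecv.ecv import load_volume_pair, save_ecv_map, save_volume_pair
from synecv.errors import DomainError, EmptyMaskError, ValidationError
from synecv.phantom import VolumePair


class TestScalarEcv:
    @pytest.mark.parametrize(
        "hct, dhu_myo, dhu_blood, expected",
        [
            (0.40, 30.0, 60.0, 0.30),
            (1.0, 123.0, 45.0, 0.0),
            (0.0, 37.0, 37.0, 1.0),
        ],
    )
    def test_direct_evaluation(self, hct, dhu_myo, dhu_blood, expected):
        assert compute_ecv(hct, dhu_myo, dhu_blood) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            compute_ecv(0.4, 30.0, 0.0)
        with pytest.raises(DomainError):
            compute_ecv(1.5, 30.0, 60.0)

    def test_out_of_range_values_returned_not_clipped(self):
        assert compute_ecv(0.4, 200.0, 60.0) > 1.0


class TestErosion:
    def test_cube_erodes_to_interior(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        eroded = erode_mask(mask, 1)
        expected = np.zeros_like(mask)
        expected[2:5, 2:5, 2:5] = True
        assert (eroded == expected).all()

    def test_zero_iterations_is_identity(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        assert (erode_mask(mask, 0) == mask).all()

    def test_single_voxel_erodes_to_empty(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(EmptyMaskError):
            erode_mask(mask, 1)

    def test_anti_extensive_and_decreasing(self):
        _, bp = ellipsoid_masks((32, 32, 32))
        prev = bp
        for it in (1, 2, 3):
            cur = erode_mask(bp, it)
            assert not (cur & ~prev).any()  # output subset of previous
            assert cur.sum() < prev.sum()
            prev = cur


class TestPhantomRoundTrip:
    def test_uniform_field_recovered(self):
        field = np.full((48, 48, 48), 0.32)
        pair = generate_volume_pair(field, hct=0.40, dhu_blood=60.0, noise_sd=0.0)
        result = compute_ecv_map(pair, hct=0.40, erosion_iterations=2)
        assert result.mean_lv_ecv == pytest.approx(0.32, abs=1e-12)
        assert result.dhu_blood == pytest.approx(60.0, abs=1e-12)
        assert result.n_flagged_voxels == 0

    def test_gradient_field_matches_voxelwise(self):
        """A transmural 0.25 -> 0.45 gradient is reproduced voxel by voxel."""
        shape = (48, 48, 48)
        z = np.linspace(0.25, 0.45, shape[2])
        field = np.broadcast_to(z, shape).copy()
        pair = generate_volume_pair(field, hct=0.42, dhu_blood=55.0, noise_sd=0.0)
        result = compute_ecv_map(pair, hct=0.42)
        lv = pair.lv_mask
        # independent oracle: evaluate the ECV relation voxel by voxel
        expected = (1 - 0.42) * (pair.lie_hu - pair.baseline_hu)[lv] / 55.0
        assert np.allclose(result.ecv[lv], expected, atol=1e-12)
        assert np.allclose(result.ecv[lv], field[lv], atol=1e-10)
        assert np.isnan(result.ecv[~lv]).all()

    def test_mean_equals_mask_mean(self):
        field = np.full((32, 32, 32), 0.30)
        pair = generate_volume_pair(field, 0.45, 50.0, noise_sd=3.0, seed=5)
        result = compute_ecv_map(pair, 0.45)
        assert result.mean_lv_ecv == pytest.approx(
            np.nanmean(result.ecv[pair.lv_mask]), abs=1e-14
        )

    def test_noisy_phantom_is_unbiased(self):
        """Mean LV ECV over many noise seeds converges on the field mean."""
        field = np.full((32, 32, 32), 0.32)
        means = []
        for seed in range(100):
            pair = generate_volume_pair(field, 0.40, 60.0, noise_sd=5.0, seed=seed)
            means.append(compute_ecv_map(pair, 0.40).mean_lv_ecv)
        means = np.array(means)
        mc_se = means.std(ddof=1) / 10.0
        assert abs(means.mean() - 0.32) < 4 * max(mc_se, 1e-4)

    def test_phantom_domain_errors(self):
        field = np.full((32, 32, 32), 0.32)
        with pytest.raises(DomainError):
            generate_volume_pair(field, hct=1.2, dhu_blood=60.0)
        with pytest.raises(DomainError):
            generate_volume_pair(field, hct=0.4, dhu_blood=-5.0)

    def test_masks_are_disjoint_and_nonempty(self):
        lv, bp = ellipsoid_masks((64, 64, 64))
        assert not (lv & bp).any()
        assert lv.any() and bp.any()
        with pytest.raises(ValidationError):
            VolumePair(
                baseline_hu=np.zeros((4, 4, 4)),
                lie_hu=np.zeros((4, 4, 4)),
                lv_mask=np.ones((4, 4, 4), bool),
                bp_mask=np.ones((4, 4, 4), bool),
            )


class TestSyntheticEcv:
    def test_chained_literature_prediction(self):
        """synHct from the literature model at HU 50 is 42.9% -> ECV 0.2855."""
        record = dict(hu_blood=50.0, sex="male", bmi=25.0)
        out = compute_synecv(record, published_models()["literature"], 30.0, 60.0)
        assert out == pytest.approx((1 - 0.429) * 0.5, abs=1e-12)

    def test_unroutable_record_flagged(self):
        record = dict(hu_blood=50.0, sex="female", bmi=20.0)
        assert compute_synecv(record, published_models()["combined"], 30.0, 60.0) is None

    def test_perfect_model_reproduces_conventional(self):
        from synecv import LinearHctModel

        record = dict(hu_blood=50.0, sex="male", bmi=25.0, hct=0.40)
        oracle = LinearHctModel(slope=0.0, intercept=40.0)
        syn = compute_synecv(record, oracle, 30.0, 60.0)
        assert syn == pytest.approx(compute_ecv(0.40, 30.0, 60.0), abs=1e-15)

    def test_syn_con_ratio_identity(self):
        """synECV / conECV = (1 - synHct)/(1 - Hct) for every voxel."""
        field = np.full((32, 32, 32), 0.32)
        hct = 0.40
        pair = generate_volume_pair(field, hct, 60.0, noise_sd=2.0, seed=3)
        con = compute_ecv_map(pair, hct)
        record = dict(hu_blood=50.0, sex="male", bmi=25.0)
        model = published_models()["literature"]
        syn = compute_synecv_map(pair, record, model)
        synhct = model.predict(50.0) / 100.0
        lv = pair.lv_mask
        ratio = syn.ecv[lv] / con.ecv[lv]
        assert np.allclose(ratio, (1 - synhct) / (1 - hct), atol=1e-12)


class TestNiftiIO:
    def test_volume_pair_roundtrip(self, tmp_path):
        field = np.full((24, 24, 24), 0.30)
        pair = generate_volume_pair(field, 0.42, 58.0, noise_sd=1.0, seed=2)
        save_volume_pair(pair, tmp_path / "pair")
        back = load_volume_pair(
            tmp_path / "pair" / "baseline.nii.gz",
            tmp_path / "pair" / "lie.nii.gz",
            tmp_path / "pair" / "lv_mask.nii.gz",
            tmp_path / "pair" / "bp_mask.nii.gz",
        )
        assert np.allclose(back.baseline_hu, pair.baseline_hu, atol=1e-4)
        assert (back.lv_mask == pair.lv_mask).all()
        assert back.voxel_spacing == pytest.approx(pair.voxel_spacing)

    def test_map_and_sidecar(self, tmp_path):
        import json

        import nibabel as nib

        field = np.full((24, 24, 24), 0.30)
        pair = generate_volume_pair(field, 0.42, 58.0)
        result = compute_ecv_map(pair, 0.42)
        out = tmp_path / "map.nii.gz"
        save_ecv_map(result, out)
        img = np.asarray(nib.load(out).dataobj)
        assert np.nanmax(np.abs(img[pair.lv_mask] - 0.30)) < 1e-5
        sidecar = json.loads((tmp_path / "map.json").read_text())
        assert sidecar["hct_used"] == pytest.approx(0.42)
        assert sidecar["mean_lv_ecv"] == pytest.approx(0.30, abs=1e-9)
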