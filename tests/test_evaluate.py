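"""Voxel/organ/lesion metrics, correlation analyses, masks and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from patlaknet import evaluate as ev


class TestEvalMask:
    def test_threshold_subsumes_negativity(self):
        ref = np.array([-1.0, 1e-5, 1e-3])
        assert ev.eval_mask(ref).tolist() == [False, False, True]

    def test_full_mask_when_all_above(self):
        assert ev.eval_mask(np.full(5, 1e-3)).all()

    def test_zero_threshold_excludes_exactly_negatives(self):
        ref = np.array([-2.0, 0.0, 3.0])
        assert ev.eval_mask(ref, threshold=0.0).tolist() == [False, True, True]

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            ev.eval_mask(np.full(4, -1.0))


class TestVoxelMetrics:
    def test_identity_pair(self):
        ref = np.random.default_rng(0).uniform(1e-4, 1e-3, size=(4, 8, 8))
        rep = ev.voxel_metrics(ref, ref, np.ones_like(ref, dtype=bool))
        assert rep.mae == rep.me == rep.mrae_pct == rep.re_pct == rep.mse == rep.rmse == 0.0
        assert rep.ssim == 1.0
        assert np.isinf(rep.psnr)

    def test_constant_offset(self):
        ref = np.full((3, 3), 2.0)
        rep = ev.voxel_metrics(ref + 0.5, ref, np.ones_like(ref, dtype=bool))
        assert rep.me == pytest.approx(0.5)
        assert rep.mae == pytest.approx(0.5)

    def test_doubling_gives_100_percent(self):
        ref = np.random.default_rng(1).uniform(0.5, 2.0, size=(5, 5))
        rep = ev.voxel_metrics(2 * ref, ref, np.ones_like(ref, dtype=bool))
        assert rep.mrae_pct == pytest.approx(100.0)
        assert rep.re_pct == pytest.approx(100.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 16))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0.5, 2.0, size=64)
        pred = ref + rng.normal(0, 0.2, size=64)
        rep = ev.voxel_metrics(pred, ref, np.ones_like(ref, dtype=bool))
        assert rep.mse == pytest.approx(rep.rmse ** 2, rel=1e-12)
        assert rep.mae >= abs(rep.me) - 1e-12
        assert rep.mrae_pct >= abs(rep.re_pct) - 1e-9
        assert -1.0 <= rep.ssim <= 1.0

    def test_psnr_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0.5, 2.0, size=4096)
        mask = np.ones_like(ref, dtype=bool)
        psnrs = []
        for amp in (0.01, 0.05, 0.2):
            vals = [ev.voxel_metrics(ref + rng.normal(0, amp, ref.shape), ref,
                                     mask).psnr for _ in range(20)]
            psnrs.append(np.mean(vals))
        assert psnrs[0] > psnrs[1] > psnrs[2]

    def test_ssim_symmetric(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 2.0, size=256)
        b = a + rng.normal(0, 0.3, size=256)
        mask = np.ones_like(a, dtype=bool)
        assert ev.voxel_metrics(a, b, mask).ssim == pytest.approx(
            ev.voxel_metrics(b, a, mask).ssim, rel=1e-9)

    def test_masked_out_voxels_are_ignored(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0.5, 2.0, size=100)
        pred = ref + rng.normal(0, 0.1, size=100)
        mask = rng.uniform(size=100) > 0.3
        rep1 = ev.voxel_metrics(pred, ref, mask)
        pred2, ref2 = pred.copy(), ref.copy()
        pred2[~mask] = 1e9
        ref2[~mask] = -7.0
        rep2 = ev.voxel_metrics(pred2, ref2, mask)
        assert rep1.to_dict() == rep2.to_dict()


class TestOrganMetrics:
    def test_sums_110_vs_100_gives_10_percent(self):
        pred = np.full(10, 11.0)
        ref = np.full(10, 10.0)
        out = ev.organ_metrics(pred, ref, {"liver": np.ones(10, dtype=bool)})
        assert out["liver"]["amre_pct"] == pytest.approx(10.0)

    def test_identity_gives_zero(self):
        ref = np.random.default_rng(0).uniform(1, 2, size=20)
        out = ev.organ_metrics(ref, ref, {"o": np.ones(20, dtype=bool)})
        assert out["o"]["ame"] == 0.0
        assert out["o"]["amre_pct"] == 0.0

    def test_antisymmetric_errors_cancel_in_ame(self):
        ref = np.full(10, 1.0)
        pred = ref.copy()
        pred[:5] += 0.2
        pred[5:] -= 0.2
        out = ev.organ_metrics(pred, ref, {"o": np.ones(10, dtype=bool)})
        assert out["o"]["ame"] == pytest.approx(0.0, abs=1e-12)
        rep = ev.voxel_metrics(pred, ref, np.ones(10, dtype=bool))
        assert rep.mae == pytest.approx(0.2)

    def test_zero_reference_sum_flagged(self):
        out = ev.organ_metrics(np.ones(4), np.zeros(4),
                               {"o": np.ones(4, dtype=bool)})
        assert out["o"]["undefined_amre"]
        assert np.isnan(out["o"]["amre_pct"])


class TestLesionMetrics:
    @staticmethod
    def _record(img_len=20):
        lm = np.zeros(img_len, dtype=bool)
        bm = np.zeros(img_len, dtype=bool)
        lm[:5] = True
        bm[5:] = True
        return ev.LesionRecord(lesion_voi=lm, background_voi=bm, label="l1")

    def test_tbr_arithmetic(self):
        rec = self._record()
        img = np.ones(20)
        img[2] = 5.0
        assert ev.lesion_metrics(img, rec)["tbr"] == pytest.approx(4.0)

    def test_cnr_is_tbr_over_background_sd(self):
        rec = self._record()
        img = np.ones(20)
        img[2] = 5.0
        img[5:] = np.array([1.5, 0.5] * 7 + [1.0])  # bg mean 1.0 approx
        out = ev.lesion_metrics(img, rec)
        bg = img[5:]
        assert out["cnr"] == pytest.approx(out["tbr"] / bg.std())

    def test_flat_lesion_gives_zero_tbr(self):
        rec = self._record()
        out = ev.lesion_metrics(np.ones(20), rec)
        assert out["tbr"] == 0.0
        assert np.isinf(out["cnr"])  # zero background SD sentinel

    def test_tbr_scale_invariant_cnr_scales_inversely(self):
        rec = self._record()
        rng = np.random.default_rng(0)
        img = rng.uniform(0.5, 2.0, size=20)
        a = ev.lesion_metrics(img, rec)
        b = ev.lesion_metrics(img * 10.0, rec)
        assert b["tbr"] == pytest.approx(a["tbr"], rel=1e-12)
        assert b["cnr"] == pytest.approx(a["cnr"] / 10.0, rel=1e-12)

    def test_nonpositive_background_rejected(self):
        rec = self._record()
        with pytest.raises(ValueError):
            ev.lesion_metrics(np.zeros(20), rec)


class TestJointHistogram:
    def test_identity_slope_one(self):
        ref = np.random.default_rng(0).uniform(0.5, 2.0, size=500)
        out = ev.joint_histogram(ref, ref, np.ones_like(ref, dtype=bool))
        assert out["slope"] == pytest.approx(1.0)
        assert out["correlation"] == pytest.approx(1.0)

    def test_attenuated_slope(self):
        ref = np.random.default_rng(1).uniform(0.5, 2.0, size=500)
        out = ev.joint_histogram(0.9 * ref, ref, np.ones_like(ref, dtype=bool))
        assert out["slope"] == pytest.approx(0.9)
        assert out["correlation"] == pytest.approx(1.0)

    def test_noisy_slope_within_ols_bounds(self):
        # analytic OLS sampling bound: se = sigma / (sd(ref) * sqrt(n))
        rng = np.random.default_rng(2)
        n = 100_000
        ref = rng.uniform(0.5, 2.0, size=n)
        sigma = 0.3
        pred = 0.8 * ref + rng.normal(0, sigma, size=n)
        out = ev.joint_histogram(pred, ref, np.ones(n, dtype=bool))
        se = sigma / (ref.std() * np.sqrt(n))
        assert abs(out["slope"] - 0.8) < 5 * se

    def test_constant_ref_flagged(self):
        out = ev.joint_histogram(np.arange(5.0), np.ones(5),
                                 np.ones(5, dtype=bool))
        assert out["undefined"]


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        ref = np.array([0.3, 1.2, 0.7, 2.5, 1.9, 0.1, 3.3, 2.2, 1.1, 0.9])
        rho, p = ev.spearman_by_organ(np.exp(ref), ref)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_reversed_ranks_give_minus_one(self):
        ref = np.arange(8.0)
        rho, _ = ev.spearman_by_organ(ref[::-1], ref)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        a, b = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=10).T
        rho, _ = ev.spearman_by_organ(a, b)
        oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_for_small_n(self):
        # n = 4: P(|rho| = 1) under exhaustive permutations is 2/24
        rho, p = ev.spearman_by_organ([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 9.0, 27.0])
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_ties_only_rejected(self):
        with pytest.raises(ValueError):
            ev.spearman_by_organ(np.ones(5), np.arange(5.0))


class TestCategorizeLesions:
    @staticmethod
    def _lesion(img_len=30):
        lm = np.zeros(img_len, dtype=bool)
        bm = np.zeros(img_len, dtype=bool)
        lm[:3] = True
        bm[10:] = True
        return ev.LesionRecord(lesion_voi=lm, background_voi=bm, label="x")

    @pytest.mark.parametrize("suv_peak, ki_peak, want", [
        (9.0, 9.0, (ev.VISIBLE_ON_BOTH, "")),
        (1.2, 9.0, (ev.VISIBLE_ON_EITHER, ev.INVISIBLE_SUV_VISIBLE_KI)),
        (9.0, 1.2, (ev.VISIBLE_ON_EITHER, ev.VISIBLE_SUV_INVISIBLE_KI)),
        (1.2, 1.2, (ev.INVISIBLE_ON_BOTH, "")),
    ])
    def test_categories_from_tbr_bits(self, suv_peak, ki_peak, want):
        lesion = self._lesion()
        suv = np.ones(30)
        ki = np.ones(30)
        suv[0] = suv_peak
        ki[0] = ki_peak
        out = ev.categorize_lesions([lesion], suv, ki, tbr_threshold=1.5)
        assert out["x"] == want

    def test_missing_image_rejected(self):
        with pytest.raises(ValueError):
            ev.categorize_lesions([self._lesion()], None, np.ones(30))


class TestLineProfile:
    def test_row_profile_has_image_width(self):
        img = np.random.default_rng(0).uniform(size=(32, 168))
        coords, vals = ev.line_profile(img, row=10)
        assert len(vals) == 168
        assert np.array_equal(vals, img[10])

    def test_constant_image_constant_profile(self):
        _, vals = ev.line_profile(np.full((16, 16), 3.0),
                                  endpoints=((2, 1), (13, 14)))
        assert np.all(vals == 3.0)

    def test_profile_peaks_at_gaussian_center(self):
        yy, xx = np.mgrid[:31, :31]
        blob = np.exp(-((yy - 17) ** 2 + (xx - 11) ** 2) / 18.0)
        coords, vals = ev.line_profile(blob, row=17)
        assert np.argmax(vals) == 11

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ev.line_profile(np.ones((8, 8)), endpoints=((3, 3), (3, 3)))


class TestVOI:
    def test_sphere_rasterizes_within_slice(self):
        voi = ev.VOI(center_mm=(20.0, 32.0, 32.0), diameter_mm=10.0, label="liver")
        mask = voi.rasterize((3, 16, 16), voxel_size_mm=4.0, slice_thickness_mm=40.0)
        assert mask.any()
        assert mask.sum(axis=(1, 2)).tolist()[1] == 0 or mask[0].any()

    def test_outside_grid_rejected(self):
        voi = ev.VOI(center_mm=(500.0, 500.0, 500.0))
        with pytest.raises(ValueError):
            voi.rasterize((2, 8, 8), 4.0, 40.0)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            ev.VOI(center_mm=(0, 0, 0), diameter_mm=0.0)
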