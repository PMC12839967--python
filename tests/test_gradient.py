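import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perilymph as pl
from perilymph import gradient as gr
from perilymph import simulate as sim
from perilymph.types import ImageStack, VesselMask

from conftest import brute_force_distance, random_mask


class TestDistanceMap:
    def test_all_true_mask_gives_zero_everywhere(self):
        dm = gr.distance_map(VesselMask(np.ones((5, 5), bool), (1.0, 1.0)))
        np.testing.assert_array_equal(dm.distance_um, 0.0)

    def test_single_pixel_corner_distance(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        dm = gr.distance_map(VesselMask(m, (1.0, 1.0)))
        assert dm.distance_um[0, 0] == pytest.approx(np.sqrt(8))
        assert dm.distance_um[2, 2] == 0.0

    def test_anisotropic_spacing(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        dm = gr.distance_map(VesselMask(m, (2.0, 1.0)))
        assert dm.distance_um[1, 1] == pytest.approx(np.sqrt(5))

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gr.distance_map(VesselMask(np.zeros((4, 4), bool), (1.0, 1.0)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), three_d=st.booleans())
    def test_matches_bruteforce_oracle(self, seed, three_d):
        rng = np.random.default_rng(seed)
        shape = (8, 16, 16) if three_d else (24, 24)
        spacing = tuple(rng.uniform(0.4, 2.0, len(shape)))
        m = random_mask(rng, shape)
        dm = gr.distance_map(VesselMask(m, spacing))
        oracle = brute_force_distance(m, spacing)
        np.testing.assert_allclose(dm.distance_um, oracle, atol=1e-8)


class TestBinProfile:
    def test_constant_image_gives_constant_bins(self, straight_tube_2d):
        img = ImageStack(np.full((64, 64), 7.0), (1.0, 1.0))
        prof = gr.bin_profile(img, gr.distance_map(straight_tube_2d), d_max=20, min_count=1)
        assert np.all(prof.mean_intensity[prof.defined] == 7.0)

    def test_rounding_half_away_from_zero(self):
        # pixel at exactly 2.5 µm goes to bin 3
        m = np.zeros((1, 8), bool)
        m[0, 0] = True
        dm = gr.distance_map(VesselMask(m, (0.5, 0.5)))
        img = ImageStack(np.arange(8, dtype=float)[None, :], (0.5, 0.5))
        prof = gr.bin_profile(img, dm, d_max=4, min_count=1)
        # pixel index 5 is at exactly 2.5 µm; it must land in bin 3 (with
        # the 3.0 µm pixel), leaving bin 2 holding only the 2.0 µm pixel
        assert dm.distance_um[0, 5] == 2.5
        # half-away-from-zero: bin 2 holds {1.5, 2.0} µm pixels, bin 3
        # holds {2.5, 3.0}; banker's rounding would pull 2.5 into bin 2
        assert prof.mean_intensity[2] == pytest.approx((3.0 + 4.0) / 2)
        assert prof.mean_intensity[3] == pytest.approx((5.0 + 6.0) / 2)

    def test_on_vessel_pixels_excluded_by_default(self, straight_tube_2d):
        img = ImageStack(np.full((64, 64), 3.0), (1.0, 1.0))
        dm = gr.distance_map(straight_tube_2d)
        prof = gr.bin_profile(img, dm, d_max=10, min_count=1)
        on = int(straight_tube_2d.data.sum())
        assert prof.n_pixels.sum() + on >= straight_tube_2d.data.size - (
            (dm.distance_um > 10.5).sum()
        )
        with_vessel = gr.bin_profile(
            img, dm, d_max=10, min_count=1, include_vessel_as_zero=True
        )
        assert with_vessel.n_pixels[0] == prof.n_pixels[0] + on

    def test_groupby_oracle_on_noiseless_field(self, straight_tube_2d):
        img = sim.make_gradient_image(
            straight_tube_2d,
            sim.GradientFieldParams(amplitude=500, background=50, decay_length_um=12, noise_sd=0),
        )
        dm = gr.distance_map(straight_tube_2d)
        prof = gr.bin_profile(img, dm, d_max=25, min_count=1)
        # oracle: direct pandas group-by over off-vessel pixels
        off = ~straight_tube_2d.data
        bins = np.floor(dm.distance_um[off] + 0.5).astype(int)
        means = pd.Series(img.data[off]).groupby(bins).mean()
        for b in means.index:
            if b <= 25:
                assert prof.mean_intensity[b] == pytest.approx(means[b], rel=1e-9)

    def test_min_count_marks_bins_missing(self, straight_tube_2d):
        img = ImageStack(np.ones((64, 64)), (1.0, 1.0))
        prof = gr.bin_profile(img, gr.distance_map(straight_tube_2d), d_max=80, min_count=10)
        # distances beyond the image extent: zero pixels -> missing, not 0
        assert np.isnan(prof.mean_intensity[60])
        assert prof.n_pixels[60] == 0

    def test_shape_mismatch_errors(self, straight_tube_2d):
        img = ImageStack(np.ones((8, 8)), (1.0, 1.0))
        with pytest.raises(ValueError, match="match"):
            gr.bin_profile(img, gr.distance_map(straight_tube_2d))

    def test_spacing_scale_equivariance(self):
        # doubling the spacing doubles each pixel's distance, relabelling
        # bins without changing member intensities
        rng = np.random.default_rng(4)
        m = random_mask(rng, (16, 16), p=0.05)
        img_data = rng.random((16, 16)) * 100
        p1 = gr.bin_profile(
            ImageStack(img_data, (1.0, 1.0)),
            gr.distance_map(VesselMask(m, (1.0, 1.0))),
            d_max=40,
            min_count=1,
        )
        p2 = gr.bin_profile(
            ImageStack(img_data, (2.0, 2.0)),
            gr.distance_map(VesselMask(m, (2.0, 2.0))),
            d_max=80,
            min_count=1,
        )
        d1 = gr.distance_map(VesselMask(m, (1.0, 1.0))).distance_um
        off = ~m
        for b in np.unique(np.floor(2 * d1[off] + 0.5).astype(int)):
            sel = np.floor(2 * d1[off] + 0.5).astype(int) == b
            assert p2.mean_intensity[b] == pytest.approx(img_data[off][sel].mean())

    def test_monotone_field_gives_monotone_bins(self, straight_tube_2d):
        img = sim.make_gradient_image(
            straight_tube_2d, sim.GradientFieldParams(amplitude=1000, background=0, noise_sd=0)
        )
        prof = gr.bin_profile(img, gr.distance_map(straight_tube_2d), d_max=25, min_count=1)
        v = prof.mean_intensity[prof.defined]
        assert np.all(np.diff(v) <= 1e-9)


class TestAverageProfiles:
    def _profile(self, values, n_pixels=None):
        values = np.asarray(values, dtype=float)
        n = np.full(len(values), 100) if n_pixels is None else np.asarray(n_pixels)
        n = np.where(np.isnan(values), 0, n)
        return gr.IntensityProfile(np.arange(len(values)), values, n)

    def test_identical_profiles_average_to_themselves(self):
        p = self._profile([5, 4, 3, 2])
        avg = gr.average_profiles([p] * 5)
        np.testing.assert_allclose(avg.mean_intensity, p.mean_intensity)
        assert np.all(avg.n_units == 5)

    def test_two_values_average(self):
        avg = gr.average_profiles([self._profile([0, 4]), self._profile([2, 8])])
        assert avg.mean_intensity[1] == 6.0

    def test_missing_bin_uses_available_inputs_only(self):
        # hand check: bin 1 missing in one of three profiles
        profs = [self._profile([1, 2]), self._profile([3, np.nan]), self._profile([5, 6])]
        avg = gr.average_profiles(profs)
        assert avg.mean_intensity[1] == pytest.approx((2 + 6) / 2)
        assert avg.n_units[1] == 2
        assert avg.n_units[0] == 3

    def test_bins_missing_everywhere_stay_missing(self):
        avg = gr.average_profiles([self._profile([1, np.nan]), self._profile([2, np.nan])])
        assert np.isnan(avg.mean_intensity[1])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no profiles"):
            gr.average_profiles([])

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grid"):
            gr.average_profiles([self._profile([1, 2]), self._profile([1, 2, 3])])


class TestNormalizeProfiles:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return gr.IntensityProfile(np.arange(len(values)), values, np.full(len(values), 100))

    def test_reference_becomes_one_at_vessel(self):
        out = gr.normalize_profiles({"WT": self._profile([200, 100, 50])}, "WT")
        assert out["WT"].mean_intensity[0] == 1.0
        assert out["WT"].normalized

    def test_other_conditions_scaled_by_reference(self):
        profs = {"WT": self._profile([200, 80]), "mut": self._profile([120, 50])}
        out = gr.normalize_profiles(profs, "WT")
        assert out["mut"].mean_intensity[1] == pytest.approx(50 / 200)

    def test_missing_reference_bin_errors(self):
        with pytest.raises(ValueError, match="0 µm"):
            gr.normalize_profiles({"WT": self._profile([np.nan, 1.0])}, "WT")

    def test_idempotent(self):
        profs = {"WT": self._profile([200, 80]), "mut": self._profile([120, 50])}
        once = gr.normalize_profiles(profs, "WT")
        twice = gr.normalize_profiles(once, "WT")
        for k in profs:
            np.testing.assert_allclose(
                twice[k].mean_intensity, once[k].mean_intensity, rtol=1e-12
            )


class TestProfileSummaryAndFit:
    def _exp_profile(self, a, lam, b, d_max=70):
        d = np.arange(d_max + 1)
        return gr.IntensityProfile(d, b + a * np.exp(-d / lam), np.full(d_max + 1, 200))

    def test_flat_profile_ratio_is_one(self):
        p = gr.IntensityProfile(np.arange(61), np.full(61, 9.0), np.full(61, 50))
        assert gr.profile_summary(p).ratio_60_0 == 1.0

    def test_closed_form_exponential_ratio(self):
        p = self._exp_profile(1000, 15, 0)
        assert gr.profile_summary(p).ratio_60_0 == pytest.approx(np.exp(-4), abs=1e-12)

    def test_missing_far_bin_gives_undefined_ratio(self):
        p = self._exp_profile(100, 15, 0, d_max=40)
        s = gr.profile_summary(p)
        assert np.isnan(s.i60) and np.isnan(s.ratio_60_0)
        assert s.i30 == pytest.approx(100 * np.exp(-2))

    def test_background_subtracted_ratio(self):
        p = self._exp_profile(1000, 15, 100)
        s = gr.profile_summary(p, background=100, subtract_background=True)
        assert s.ratio_60_0 == pytest.approx(np.exp(-4), abs=1e-12)

    def test_fit_recovers_noiseless_parameters(self):
        fit = gr.fit_decay(self._exp_profile(1000, 15, 100), background=100)
        assert fit.amplitude == pytest.approx(1000, rel=1e-3)
        assert fit.decay_length_um == pytest.approx(15, rel=1e-3)

    def test_constant_profile_has_no_decay(self):
        p = gr.IntensityProfile(np.arange(30), np.full(30, 100.0), np.full(30, 50))
        with pytest.raises(ValueError, match="background"):
            gr.fit_decay(p, background=100)


class TestGradientAnalysisEndToEnd:
    def test_noiseless_pipeline_within_two_percent_of_truth(self, straight_tube_2d):
        a, lam, b = 1000.0, 15.0, 100.0
        img = sim.make_gradient_image(
            straight_tube_2d,
            sim.GradientFieldParams(amplitude=a, background=b, decay_length_um=lam, noise_sd=0),
        )
        grouping = pd.DataFrame(
            [{"image_id": "i0", "mouse_id": "m0", "condition": "WT"}]
        )
        res = pl.GradientAnalysis(
            [img], straight_tube_2d, grouping, include_vessel_as_zero=True, min_count=50
        ).fit()
        prof = res.condition_profiles["WT"]
        for d, v, n in zip(prof.distance_um, prof.mean_intensity, prof.n_pixels):
            if n >= 50 and not np.isnan(v):
                assert abs(v - (b + a * np.exp(-d / lam))) < 0.02 * a

    def test_mouse_not_image_is_the_replicate(self):
        imgs, masks, grouping, _ = sim.make_gradient_study(
            seed=0, n_mice=2, images_per_mouse=3
        )
        res = pl.GradientAnalysis(
            imgs, masks[0], grouping, include_vessel_as_zero=True
        ).fit()
        vals = res.values_at(0)
        # one row per mouse per condition, not per image
        assert len(vals) == 4
        assert set(vals["condition"]) == {"WT", "uPAmut"}

    def test_normalized_reference_reads_one_at_vessel(self):
        imgs, masks, grouping, _ = sim.make_gradient_study(seed=1, n_mice=2)
        res = pl.GradientAnalysis(
            imgs, masks[0], grouping, include_vessel_as_zero=True, reference="WT"
        ).fit()
        assert res.normalized_profiles["WT"].mean_intensity[0] == pytest.approx(1.0)
        summary = res.summary(normalized=True)
        assert summary.loc[summary["condition"] == "WT", "I0"].iloc[0] == pytest.approx(1.0)
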