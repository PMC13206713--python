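import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choromap import analysis, synthetic, templates
from choromap.analysis import (
    DifferenceMap,
    fit_eccentricity_model,
    model_features,
    symmetric_percent_change,
)

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


def map_from_values(values, valid=None, metric="CVI"):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return DifferenceMap(values=values, metric=metric, n_iamd=10,
                         n_control=10, valid_mask=valid)


class TestSymmetricPercentChange:
    @pytest.mark.parametrize(
        "x,c,mode,expected",
        [
            (100.0, 100.0, "symmetric", 0.0),
            (1.0, 0.0, "symmetric", 200.0),
            (90.0, 110.0, "symmetric", -20.0),
            (90.0, 110.0, "raw", -200.0 / 9.0),  # -22.22
        ],
    )
    def test_examples(self, x, c, mode, expected):
        assert symmetric_percent_change(x, c, mode) == pytest.approx(expected)

    def test_nonpositive_denominator_is_nan(self):
        assert np.isnan(symmetric_percent_change(0.0, 0.0))
        assert np.isnan(symmetric_percent_change(0.0, 5.0, "raw"))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(a=positive, b=positive)
    def test_antisymmetric_and_bounded(self, a, b):
        v = symmetric_percent_change(a, b)
        assert v == -symmetric_percent_change(b, a)
        assert abs(v) < 200.0

    def test_raw_mode_is_unbounded(self):
        # the stated rationale for the symmetric form
        assert symmetric_percent_change(1e-6, 1.0, "raw") < -1e6


class TestDifferenceMap:
    def test_identical_cohorts_give_zero_map(self):
        spec = synthetic.CohortSpec(n_per_group=3, between_eye_sd=0.0,
                                    cell_sd_pct=0.0, seed=0)
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        d = analysis.difference_map(iamd, ctrl, "LA")
        assert d.valid_mask.all()
        assert np.all(d.values == 0.0)

    def test_antisymmetric_under_group_swap(self):
        spec = synthetic.CohortSpec(
            n_per_group=5, seed=3,
            effect_profile={"CVI": synthetic.linear_profile(2.0, -3.0)})
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        d1 = analysis.difference_map(iamd, ctrl, "CVI")
        d2 = analysis.difference_map(ctrl, iamd, "CVI")
        np.testing.assert_allclose(d1.values, -d2.values, atol=1e-9)

    def test_embedded_profile_tracked_within_noise(self):
        prof = synthetic.quadratic_profile(4.0, -20.0, 16.0)
        spec = synthetic.CohortSpec(n_per_group=40, seed=21,
                                    effect_profile={"CVI": prof})
        iamd, ctrl, truth = synthetic.generate_cohort(spec)
        d = analysis.difference_map(iamd, ctrl, "CVI")
        bins = templates.eccentricity_bin_grid()
        for b in (10, 30, 50):
            sel = (bins == b) & d.valid_mask
            med = np.median(d.values[sel])
            assert med == pytest.approx(
                truth.true_pct["CVI"][sel].mean(), abs=2.0)

    def test_all_invalid_group_gives_invalid_map(self):
        spec = synthetic.CohortSpec(n_per_group=2, seed=1)
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        for g in iamd:
            g.valid_mask[:] = False
        with pytest.warns(UserWarning, match="no valid cells"):
            d = analysis.difference_map(iamd, ctrl, "CT")
        assert not d.valid_mask.any()

    def test_requires_two_eyes(self):
        spec = synthetic.CohortSpec(n_per_group=2, seed=1)
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        with pytest.raises(ValueError, match="two eyes"):
            analysis.difference_map(iamd[:1], ctrl, "CT")


class TestGlobalCompare:
    def test_identical_groups(self):
        spec = synthetic.CohortSpec(n_per_group=4, between_eye_sd=0.0,
                                    cell_sd_pct=0.0, seed=0)
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        res = analysis.global_compare(iamd, ctrl, "CVI")
        assert res.p_value == 1.0
        assert res.median_pct_change == 0.0

    def test_uniform_negative_effect_detected(self):
        spec = synthetic.CohortSpec(
            n_per_group=40, between_eye_sd=1.0, cell_sd_pct=1.0, seed=17,
            effect_profile={"CVI": synthetic.EffectProfile((-5.0,))})
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        res = analysis.global_compare(iamd, ctrl, "CVI")
        assert res.p_value < 0.01
        assert res.median_pct_change == pytest.approx(-5.0, abs=1.0)
        assert res.iqr_pct_change[0] < res.median_pct_change < res.iqr_pct_change[1]

    def test_small_sample_exact_path(self):
        spec = synthetic.CohortSpec(
            n_per_group=2, seed=5,
            effect_profile={"CVI": synthetic.EffectProfile((-5.0,))})
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        res = analysis.global_compare(iamd, ctrl, "CVI")
        assert res.test == "wilcoxon"
        assert 0.0 < res.p_value <= 1.0

    def test_unmatched_sizes_fall_back_to_ranksum(self):
        spec = synthetic.CohortSpec(n_per_group=5, seed=5)
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        with pytest.warns(UserWarning, match="rank-sum"):
            res = analysis.global_compare(iamd[:4], ctrl, "CVI")
        assert res.test == "ranksums"


class TestSectorCompare:
    def test_all_zero_map(self):
        d = map_from_values(np.zeros((60, 60)), np.ones((60, 60), bool))
        res = analysis.sector_compare(d)
        assert res.kruskal_p == 1.0
        assert not res.sectors["significant"].any()

    def test_radially_decreasing_map_separates_rings(self):
        r = templates.cell_eccentricity_mm()
        d = map_from_values(10.0 - 4.0 * r, np.ones((60, 60), bool))
        res = analysis.sector_compare(d)
        assert res.kruskal_p < 1e-10

    def test_effect_only_in_outer_ring(self):
        labels = templates.sector_label_grid("OD")
        alt = np.indices((60, 60)).sum(axis=0) % 2 * 1.0 - 0.5  # exact +-0.5
        values = alt.copy()
        outer = np.char.startswith(labels.astype(str), "outer")
        values[outer] = -5.0 + alt[outer]
        res = analysis.sector_compare(map_from_values(values))
        sig = set(res.sectors.loc[res.sectors["significant"], "sector"])
        assert sig == {"outer_temporal", "outer_superior",
                       "outer_nasal", "outer_inferior"}

    def test_small_sectors_excluded(self):
        values = np.full((60, 60), np.nan)
        valid = np.zeros((60, 60), bool)
        # populate only the central disc
        labels = templates.sector_label_grid("OD")
        central = labels == "central"
        values[central] = 1.0
        valid[central] = True
        res = analysis.sector_compare(map_from_values(values, valid))
        assert "outer_temporal" in res.excluded_sectors
        assert len(res.sectors) == 1


class TestEccentricityFit:
    def test_exact_quadratic_interpolation(self):
        # bins sampled exactly from the printed-style quadratic are
        # reproduced to numerical precision and the quadratic is chosen
        rbin = templates.bin_center_mm(templates.eccentricity_bin_grid())
        vals = 3.75 * rbin**2 - 19.67 * rbin + 16.44
        fit = fit_eccentricity_model(map_from_values(vals))
        a, b, c, r2 = fit.quadratic
        assert abs(a - 3.75) < 1e-9 and abs(b + 19.67) < 1e-9
        assert abs(c - 16.44) < 1e-9
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.chosen == "quadratic"

    def test_noiseless_linear_data_prefers_linear(self):
        rbin = templates.bin_center_mm(templates.eccentricity_bin_grid())
        fit = fit_eccentricity_model(map_from_values(1.16 * rbin - 1.79))
        assert fit.chosen == "linear"
        m, k, r2 = fit.linear
        assert m == pytest.approx(1.16, abs=1e-9)
        assert k == pytest.approx(-1.79, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        # nested quadratic has a ~ 0, not a better R^2 beyond tolerance
        assert abs(fit.quadratic[0]) < 1e-9

    def test_constant_bins_degenerate_convention(self):
        fit = fit_eccentricity_model(map_from_values(np.full((60, 60), 7.0)))
        assert fit.chosen == "linear"
        assert fit.linear[0] == 0.0
        assert fit.linear[2] == 0.0  # R^2 defined as 0

    def test_nestedness_quadratic_never_worse(self, rng):
        for _ in range(10):
            vals = rng.normal(0, 5, (60, 60))
            fit = fit_eccentricity_model(map_from_values(vals))
            assert fit.quadratic[3] >= fit.linear[2] - 1e-12

    def test_too_few_bins_raises(self):
        values = np.full((60, 60), np.nan)
        valid = np.zeros((60, 60), bool)
        values[30, 30] = 1.0
        valid[30, 30] = True
        with pytest.raises(ValueError, match="bins"):
            fit_eccentricity_model(map_from_values(values, valid))


class TestModelFeatures:
    def test_linear_crossover_from_reported_ct_model(self):
        rbin = templates.bin_center_mm(templates.eccentricity_bin_grid())
        fit = fit_eccentricity_model(map_from_values(1.16 * rbin - 1.79))
        feats = model_features(fit)
        assert feats.crossover_mm[0] == pytest.approx(1.543, abs=1e-3)
        assert feats.report()["crossover_mm"] == (1.5,)

    def test_quadratic_vertex_from_reported_cvi_model(self):
        rbin = templates.bin_center_mm(templates.eccentricity_bin_grid())
        vals = 3.75 * rbin**2 - 19.67 * rbin + 16.44
        feats = model_features(fit_eccentricity_model(map_from_values(vals)))
        assert feats.vertex_mm == pytest.approx(2.623, abs=1e-3)
        assert feats.report()["vertex_mm"] == 2.6

    def test_symmetric_quadratic_vertex_at_zero(self):
        rbin = templates.bin_center_mm(templates.eccentricity_bin_grid())
        feats = model_features(
            fit_eccentricity_model(map_from_values(2.0 * rbin**2 - 1.0)))
        assert feats.vertex_mm == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_has_no_crossover(self):
        fit = analysis.EccentricityModelFit(
            linear=(0.0, 1.0, 0.0), quadratic=None, chosen="linear",
            p_value=1.0, fit_range_mm=(0.0, 3.0), n_bins=10)
        feats = model_features(fit)
        assert feats.crossover_mm == ()


class TestCorrelateMetrics:
    def test_self_correlation_is_one(self, rng):
        vals = rng.normal(0, 3, (60, 60))
        d = map_from_values(vals)
        r, _ = analysis.correlate_metrics(d, d)
        assert r == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self, rng):
        vals = rng.normal(0, 3, (60, 60))
        r, _ = analysis.correlate_metrics(
            map_from_values(vals), map_from_values(-vals))
        assert r == pytest.approx(-1.0)

    def test_shared_luminal_driver_correlates_cvi_and_la(self):
        prof = synthetic.quadratic_profile(4.0, -20.0, 16.0)
        spec = synthetic.CohortSpec(n_per_group=40, seed=13,
                                    effect_profile={"CVI": prof, "LA": prof})
        iamd, ctrl, _ = synthetic.generate_cohort(spec)
        d_cvi = analysis.difference_map(iamd, ctrl, "CVI")
        d_la = analysis.difference_map(iamd, ctrl, "LA")
        r, p = analysis.correlate_metrics(d_cvi, d_la, level="bin")
        assert r > 0.8
        assert p < 1e-6

    def test_too_few_points_raises(self):
        values = np.full((60, 60), np.nan)
        valid = np.zeros((60, 60), bool)
        values[0, 0] = 1.0
        valid[0, 0] = True
        d = map_from_values(values, valid)
        with pytest.raises(ValueError, match="3"):
            analysis.correlate_metrics(d, d, level="cell")


class TestNormalityCheck:
    def test_uniform_samples_usually_rejected(self):
        rng = np.random.default_rng(99)
        rejections = sum(
            analysis.normality_check(rng.uniform(0, 1, 50))[1] < 0.05
            for _ in range(100))
        assert rejections > 50

    def test_normal_null_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            analysis.normality_check(rng.standard_normal(500))[1] < 0.05
            for _ in range(100))
        assert rejections <= 12

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            analysis.normality_check(np.ones(10))

    def test_out_of_range_n_raises(self):
        with pytest.raises(ValueError, match="n="):
            analysis.normality_check([1.0, 2.0])
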