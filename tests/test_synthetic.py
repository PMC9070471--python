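"""Generator contracts: determinism, ground-truth exactness, planted structure."""

import numpy as np
import pytest

from aadkit import histology, synthetic
from aadkit.synthetic import CohortConfig


class TestCohortConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_fl": 0},
            {"n_tl": -1},
            {"class_effect": -0.1},
            {"noise_cv": -1.0},
            {"n_subclusters": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestFeatureTable:
    def test_fl_is_mechanically_softer_and_gag_depleted(self):
        table, _ = synthetic.generate_feature_table(CohortConfig(seed=3))
        med = table.groupby("tissue_type")[["g_prime_kpa", "g_double_prime_kpa", "gag_ug_mg"]].median()
        for var in med.columns:
            assert med.loc["FL", var] < med.loc["TL", var]
            assert med.loc["FL", var] < med.loc["FP", var]

    def test_minimal_cohort_rows_finite_positive(self):
        table, truths = synthetic.generate_feature_table(
            CohortConfig(n_fl=1, n_fp=1, n_tl=1, seed=0)
        )
        assert len(table) == 3
        values = table.drop(columns=["sample_id", "tissue_type", "patient_id"])
        assert np.isfinite(values.to_numpy()).all()
        assert (values.to_numpy() > 0).all()

    def test_zero_class_effect_removes_group_shift(self):
        # with no effect the FL rows come from the same distribution:
        # a rank test on G' should not reject at a fixed benign seed
        from aadkit.npstats import kruskal_wallis

        table, _ = synthetic.generate_feature_table(
            CohortConfig(seed=12, class_effect=0.0)
        )
        res = kruskal_wallis(table["g_prime_kpa"], table["tissue_type"])
        assert res.p_raw > 0.05

    def test_determinism(self):
        t1, _ = synthetic.generate_feature_table(CohortConfig(seed=9))
        t2, _ = synthetic.generate_feature_table(CohortConfig(seed=9))
        assert t1.equals(t2)


class TestSpectrumSet:
    def test_rows_are_tic_normalized_and_nonnegative(self, spectrum_set):
        X = spectrum_set.X
        assert (X >= 0).all()
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_effects_zero_noise_gives_identical_samples(self):
        cfg = CohortConfig(seed=4, class_effect=0.0, subcluster_effect=0.0, noise_cv=0.0)
        sset, _ = synthetic.generate_spectrum_set(cfg, n_bins=200)
        X = sset.X
        assert np.ptp(X, axis=0).max() == 0.0

    def test_noise_free_classes_are_three_distinct_templates(self):
        cfg = CohortConfig(n_fl=1, n_fp=1, n_tl=1, noise_cv=0.0, seed=4)
        sset, _ = synthetic.generate_spectrum_set(cfg, n_bins=400)
        X = sset.X
        assert not np.allclose(X[0], X[1])
        assert not np.allclose(X[0], X[2])
        assert not np.allclose(X[1], X[2])

    def test_subcluster_labels_only_for_fl(self, spectrum_set):
        lab = spectrum_set.labels
        assert lab.loc[lab.tissue_type == "FL", "subcluster"].notna().all()
        assert lab.loc[lab.tissue_type != "FL", "subcluster"].isna().all()

    def test_marker_bookkeeping_covers_all_groups(self, spectrum_set):
        assert set(spectrum_set.class_marker_bins) == {"FL", "FP", "TL"}
        assert set(spectrum_set.subcluster_marker_bins) == {0, 1, 2}

    def test_determinism(self, default_config):
        a, _ = synthetic.generate_spectrum_set(default_config, n_bins=300)
        b, _ = synthetic.generate_spectrum_set(default_config, n_bins=300)
        np.testing.assert_array_equal(a.X, b.X)


class TestBurnEvent:
    def test_event_scan_count_matches_duration(self):
        run = synthetic.generate_burn_event(12.0, scan_rate_hz=1.0, seed=1)
        tic = run.tic
        elevated = tic > 3 * np.median(tic)
        assert elevated.sum() == 12

    def test_zero_baseline_noise_gives_exact_baseline(self):
        run = synthetic.generate_burn_event(
            10.0, seed=2, baseline_noise_cv=0.0, baseline_tic=500.0
        )
        tic = run.tic
        outside = np.r_[tic[:10], tic[-10:]]
        np.testing.assert_allclose(outside, 500.0, rtol=1e-12)

    def test_same_seed_identical_runs(self):
        r1 = synthetic.generate_burn_event(15.0, seed=3)
        r2 = synthetic.generate_burn_event(15.0, seed=3)
        for (m1, i1), (m2, i2) in zip(r1.scans, r2.scans):
            np.testing.assert_array_equal(m1, m2)
            np.testing.assert_array_equal(i1, i2)

    def test_atypical_duration_warns_but_generates(self):
        with pytest.warns(UserWarning, match="10-30"):
            run = synthetic.generate_burn_event(5.0, seed=0)
        assert run.n_scans > 0


class TestStainedImages:
    def test_painted_fractions_are_pixel_exact(self, vvg_pair):
        img, truth = vvg_pair
        foot = synthetic._tissue_footprint(128, 128)
        n_tissue = foot.sum()
        col_map = histology.collagen_index_map(img)
        el_map = histology.elastin_index_map(img)
        n_col = np.count_nonzero((col_map > 1.0) & foot)
        n_el = np.count_nonzero((el_map > 0.5) & foot)
        assert n_col / n_tissue == pytest.approx(truth.true_collagen_fraction, abs=1e-12)
        assert n_el / n_tissue == pytest.approx(truth.true_elastin_fraction, abs=1e-12)

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_vvg_image(64, 64, 0.7, 0.5, seed=0)

    def test_minimal_image_valid(self):
        img, truth = synthetic.generate_vvg_image(64, 64, 0.2, 0.2, seed=0)
        assert img.shape == (64, 64, 3)
        mask = histology.tissue_mask(img)
        assert mask.any()

    def test_zero_fractions_quantify_to_zero(self):
        img, _ = synthetic.generate_vvg_image(96, 96, 0.0, 0.0, seed=1)
        mask = histology.tissue_mask(img)
        col = histology.quantify_stain(histology.collagen_index_map(img), mask, 1.0)
        el = histology.quantify_stain(histology.elastin_index_map(img), mask, 0.5)
        assert col.fraction == 0.0
        assert el.fraction == 0.0

    def test_psr_zero_jitter_matches_vvg_truth(self, vvg_pair):
        _, truth = vvg_pair
        psr = synthetic.generate_psr_image(truth, 128, 128, seed=9, jitter=0.0)
        mask = histology.tissue_mask(psr)
        frac = histology.psr_collagen_fraction(psr, mask)
        assert frac == pytest.approx(truth.true_collagen_fraction, abs=0.005)

    def test_psr_zero_collagen_has_no_red(self):
        _, truth = synthetic.generate_vvg_image(96, 96, 0.0, 0.3, seed=2)
        psr = synthetic.generate_psr_image(truth, 96, 96, seed=3, jitter=0.0)
        mask = histology.tissue_mask(psr)
        assert histology.psr_collagen_fraction(psr, mask) == 0.0

    def test_psr_default_jitter_bounded(self, vvg_pair):
        _, truth = vvg_pair
        psr = synthetic.generate_psr_image(truth, 128, 128, seed=11, jitter=0.01)
        mask = histology.tissue_mask(psr)
        frac = histology.psr_collagen_fraction(psr, mask)
        assert abs(frac - truth.true_collagen_fraction) <= 0.01 + 0.005

    def test_tissue_mask_matches_footprint(self):
        img, _ = synthetic.generate_vvg_image(128, 128, 0.3, 0.3, seed=6)
        foot = synthetic._tissue_footprint(128, 128)
        mask = histology.tissue_mask(img)
        jaccard = (mask & foot).sum() / (mask | foot).sum()
        assert jaccard >= 0.98
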