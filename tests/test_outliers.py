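import numpy as np
import pytest

import spadspec as sp
from spadspec.outliers import (
    paired_exclude,
    spad_outliers_kmeans,
    spectral_outliers_mcplsr,
)


class TestKmeansRule:
    def test_hand_computed_single_cluster_example(self):
        # centre = 55; distances {5,4,6,3,7,35}; mean 10, sd 12.33 (n-1)
        # threshold 34.66 -> only the 90 exceeds it
        flags = spad_outliers_kmeans([50, 51, 49, 52, 48, 90])
        assert flags == [5]

    def test_all_equal_values_flag_nothing(self):
        assert spad_outliers_kmeans([50.0] * 10) == []

    def test_k1_equals_direct_mean_sd_rule(self):
        rng = np.random.default_rng(0)
        spad = rng.normal(55, 4, 60)
        dist = np.abs(spad - spad.mean())
        thr = dist.mean() + 2 * np.std(dist, ddof=1)
        expected = np.flatnonzero(dist > thr).tolist()
        assert spad_outliers_kmeans(spad) == expected

    def test_returns_sample_ids_when_given(self):
        ids = list("abcdef")
        assert spad_outliers_kmeans([50, 51, 49, 52, 48, 90], ids) == ["f"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spad_outliers_kmeans([1, 2, 3, 4, 5], k=2)

    def test_two_cluster_variant_runs(self):
        rng = np.random.default_rng(1)
        spad = np.r_[rng.normal(45, 1, 30), rng.normal(60, 1, 30), 95.0]
        flags = spad_outliers_kmeans(spad, k=2)
        assert 60 in flags


class TestMcPlsr:
    def test_deterministic_under_fixed_seed(self):
        g = sp.GroupSpec("V12", "apical", 80, 50.6, 4.3)
        cfg = sp.GeneratorConfig(groups=(g,), spectral_outlier_fraction=0.1, seed=3)
        samples, _ = sp.generate_dataset(cfg)
        a = spectral_outliers_mcplsr(
            samples.reflectance, samples.spad, samples.sample_ids, n_iter=30, seed=5
        )
        b = spectral_outliers_mcplsr(
            samples.reflectance, samples.spad, samples.sample_ids, n_iter=30, seed=5
        )
        assert a == b

    def test_clean_linear_data_unflagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 30))
        y = X[:, 0] * 2.0 + 1.0  # exact low-rank relation, residuals ~ 0
        flags = spectral_outliers_mcplsr(X, y, n_iter=20, sd_multiplier=3, seed=0)
        assert flags == []

    def test_monotone_in_sd_multiplier(self):
        g = sp.GroupSpec("V12", "apical", 90, 50.6, 4.3)
        cfg = sp.GeneratorConfig(groups=(g,), spectral_outlier_fraction=0.1, seed=6)
        samples, _ = sp.generate_dataset(cfg)
        sets = [
            set(
                spectral_outliers_mcplsr(
                    samples.reflectance,
                    samples.spad,
                    samples.sample_ids,
                    n_iter=25,
                    sd_multiplier=m,
                    seed=1,
                )
            )
            for m in (1.0, 2.0, 3.0)
        ]
        assert sets[2] <= sets[1] <= sets[0]

    def test_degenerate_constant_spectra_rejected(self):
        X = np.ones((30, 20))
        with pytest.raises(ValueError, match="degenerate"):
            spectral_outliers_mcplsr(X, np.arange(30.0), n_iter=5)


class TestPairedExclusion:
    def test_disjoint_lists_remove_sum(self, default_group_set):
        samples, _ = default_group_set
        ids = samples.sample_ids
        cleaned, report = paired_exclude(samples, ids[:2], ids[2:5])
        assert report.n_before == samples.n
        assert report.n_after == cleaned.n == samples.n - 5
        assert sorted(report.removed_ids) == sorted(ids[:5])

    def test_overlapping_lists_remove_union(self, default_group_set):
        samples, _ = default_group_set
        a, b, c = samples.sample_ids[:3]
        cleaned, report = paired_exclude(samples, [a, b], [b, c])
        assert len(report.removed_ids) == 3
        assert cleaned.n == samples.n - 3

    def test_empty_lists_identity(self, default_group_set):
        samples, _ = default_group_set
        cleaned, report = paired_exclude(samples, [], [])
        assert cleaned.n == samples.n
        assert report.removed_ids == []

    def test_unknown_id_rejected(self, default_group_set):
        samples, _ = default_group_set
        with pytest.raises(KeyError, match="nope"):
            paired_exclude(samples, ["nope"], [])


class TestGroupwiseScreen:
    def test_both_rules_combined_on_contaminated_data(self):
        g = sp.GroupSpec("V12", "apical", 120, 50.6, 4.3)
        cfg = sp.GeneratorConfig(groups=(g,), spad_outlier_fraction=0.05, seed=8)
        samples, truth = sp.generate_dataset(cfg)
        cleaned, report = sp.screen_sample_set(samples, n_iter=25, seed=2)
        assert set(truth.spad_outlier_ids) <= set(report.spad_outlier_ids)
        assert cleaned.n == report.n_after
        assert report.thresholds_used["mcplsr_n_iter"] == 25
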