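"""Random-pairing null: oracle equivalence, sampling consistency, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clckit import null_model
from clckit.config import AnalysisConfig, independent_pairing_config
from clckit.experiments import analyze_synthetic_cohort, analyze_synthetic_subject
from clckit.config import CohortConfig
from tests.conftest import make_records


def brute_force_null(hr, sr, config=AnalysisConfig()):
    """Independent oracle: enumerate all N*M pairs literally."""
    hr = np.asarray(hr, float)
    sr = np.asarray(sr, float)
    h = np.repeat(hr, sr.size)
    s = np.tile(sr, hr.size)
    ratios = s / h
    dev = np.abs(s - h) / h
    edges = null_model.ratio_bin_edges(config)
    counts, _ = np.histogram(ratios, bins=np.concatenate(([-np.inf], edges, [np.inf])))
    return {
        "probs": counts / ratios.size,
        "p_clc": np.mean(dev <= config.clc_threshold),
        "p_weak": np.mean(dev <= config.weak_threshold),
        "median": np.quantile(ratios, 0.5, method="inverted_cdf"),
        "iqr": (np.quantile(ratios, 0.75, method="inverted_cdf")
                - np.quantile(ratios, 0.25, method="inverted_cdf")),
        "skew": sps.skew(ratios, bias=False),
        "ratios": ratios,
    }


class TestNullExact:
    def test_single_pair(self):
        null = null_model.null_exact([100.0], [100.0])
        assert null.p_clc == 1.0
        hist = null.histogram()
        row = hist[(hist["bin_left"] <= 1.0) & (1.0 < hist["bin_right"])]
        assert row["probability"].iloc[0] == 1.0
        assert row["bin_left"].iloc[0] == 1.0  # R=1 sits in [1.00, 1.01)

    def test_two_by_two_enumerable_by_hand(self):
        # pairs: 100/100, 200/100, 100/100, 200/100 -> ratios {1,1,2,2}
        null = null_model.null_exact([100.0, 100.0], [100.0, 200.0])
        assert null.p_clc == 0.5
        assert null.p_weak_or_clc == 0.5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            null_model.null_exact([], [100.0])

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 80))
        hr = rng.uniform(60, 180, size=n)
        sr = rng.uniform(60, 190, size=n)
        null = null_model.null_exact(hr, sr)
        oracle = brute_force_null(hr, sr)
        np.testing.assert_allclose(null.probabilities, oracle["probs"], atol=1e-12)
        assert abs(null.p_clc - oracle["p_clc"]) <= 1e-12
        assert abs(null.p_weak_or_clc - oracle["p_weak"]) <= 1e-12
        assert abs(null.median - oracle["median"]) <= 1e-9
        assert abs(null.iqr - oracle["iqr"]) <= 1e-9
        assert abs(null.skewness - oracle["skew"]) <= 1e-9
        # CDF agrees with the empirical CDF of the enumerated ratios
        grid = np.linspace(0.4, 2.5, 31)
        ecdf = np.searchsorted(np.sort(oracle["ratios"]), grid, side="right") / oracle["ratios"].size
        np.testing.assert_allclose(null.cdf(grid), ecdf, atol=1e-12)

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(5)
        hr = rng.uniform(70, 160, size=50)
        sr = rng.uniform(60, 180, size=50)
        a = null_model.null_exact(hr, sr)
        b = null_model.null_exact(rng.permutation(hr), rng.permutation(sr))
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=0)
        assert a.p_clc == b.p_clc and a.median == b.median

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(8)
        null = null_model.null_exact(rng.uniform(60, 200, 40), rng.uniform(50, 250, 40))
        assert null.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert null.p_clc <= null.p_weak_or_clc


class TestNullSampled:
    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        hr, sr = rng.uniform(70, 150, 30), rng.uniform(60, 180, 30)
        a = null_model.null_sampled(hr, sr, 20_000, seed=9)
        b = null_model.null_sampled(hr, sr, 20_000, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.p_clc == b.p_clc

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            null_model.null_sampled([100.0, 110.0], [100.0, 90.0], 100, seed=0)

    def test_converges_to_exact(self):
        rng = np.random.default_rng(3)
        hr, sr = rng.uniform(70, 150, 60), rng.uniform(60, 180, 60)
        exact = null_model.null_exact(hr, sr)
        n = 200_000
        sampled = null_model.null_sampled(hr, sr, n, seed=1)
        for attr in ("p_clc", "p_weak_or_clc"):
            p = getattr(exact, attr)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(getattr(sampled, attr) - p) <= 3 * se + 1e-12

    def test_degenerate_single_values(self):
        sampled = null_model.null_sampled([100.0], [100.0], 10_000, seed=0)
        assert np.all(sampled.draws == 1.0)


class TestObserved:
    def test_constant_ratio_peak(self):
        obs = null_model.observed_distribution(make_records([(100, 100)] * 5))
        assert obs.peak_bin == (1.0, 1.01)
        assert obs.peak_probability == 1.0
        assert obs.skewness == 0.0

    def test_p_clc_direct_count(self):
        obs = null_model.observed_distribution(
            make_records([(90, 100), (100, 100), (110, 100)]))
        assert obs.p_clc == pytest.approx(1 / 3)
        assert obs.p_weak_or_clc == pytest.approx(1.0)

    def test_requires_two_instances(self):
        with pytest.raises(ValueError):
            null_model.observed_distribution(make_records([(100, 100)]))


class TestCompare:
    def test_identity_comparison(self):
        # constant HR makes observed ratios and null pairings identical sets
        rng = np.random.default_rng(4)
        sr = rng.integers(80, 140, size=300)
        records = make_records([(s, 100.0) for s in sr])
        obs = null_model.observed_distribution(records)
        null = null_model.null_exact(records["hr"], records["sr"])
        cmp = null_model.compare(obs, null)
        assert cmp.delta_p == pytest.approx(0.0, abs=1e-12)
        assert cmp.ks_statistic <= 1.0 / np.sqrt(len(records))
        assert cmp.ks_p > 0.05

    def test_grid_mismatch_is_an_error(self):
        records = make_records([(100, 100), (90, 100), (110, 100)])
        obs = null_model.observed_distribution(records)
        other = null_model.null_exact(records["hr"], records["sr"],
                                      AnalysisConfig(r_support=(0.5, 2.0)))
        with pytest.raises(ValueError):
            null_model.compare(obs, other)

    def test_entrained_cohort_beats_null(self):
        """Perfect noiseless entrainment: observed p_clc is 1, null's is below."""
        config = CohortConfig(n_subjects=1, days=7, seed=17,
                              couple_fraction=1.0).noiseless()
        rep, _ = analyze_synthetic_subject(config, 0)
        assert rep.observed.p_clc == 1.0
        assert rep.null.p_clc < 1.0
        assert rep.comparison.delta_p > 0


class TestCalibrationUnderIndependence:
    """With HR independent of cadence, observed and null must agree."""

    def test_band_probability_delta_is_small(self):
        config = independent_pairing_config(31, n_subjects=3, days=14)
        reports, _ = analyze_synthetic_cohort(config)
        for rep in reports:
            assert abs(rep.comparison.delta_p) < 0.01

    def test_ks_false_positive_rate(self):
        # 2 subjects x 20 seeds of independent pairing; KS at alpha=0.05
        rejections = trials = 0
        for seed in range(20):
            config = independent_pairing_config(seed, n_subjects=2, days=7)
            reports, _ = analyze_synthetic_cohort(config)
            rejections += sum(r.comparison.ks_p < 0.05 for r in reports)
            trials += len(reports)
        assert rejections / trials <= 0.10
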