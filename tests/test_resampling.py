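"""Bootstrap count nulls, orientation-shuffle test, CDF distance test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthillusion import (
    bootstrap_error_counts,
    cdf_distance_test,
    shuffle_orientation_test,
)
from orthillusion.exceptions import InsufficientDataError


def _adapted(trials, cond, design):
    return trials[
        (trials["condition"] == cond)
        & trials["probe_deg"].isin(set(design.adapted_labels))
    ]


class TestBootstrapErrorCounts:
    @pytest.mark.parametrize("unit", ["trial", "participant"])
    def test_mean_count_matches_observed(self, recon_cohort, recon_reference, design, unit):
        """The bootstrap mean reproduces the observed error count (both units)."""
        for cond, expected in (("test_200", 20), ("test_33", 8)):
            null = bootstrap_error_counts(
                _adapted(recon_cohort, cond, design),
                recon_reference,
                n_iterations=20_000,
                unit=unit,
                seed=2,
            )
            assert null.observed_count == expected
            assert abs(null.mean_count - expected) < 3 * null.mc_se_of_mean
            assert null.pct5 <= null.mean_count <= null.pct95

    def test_trial_unit_matches_binomial_oracle(self, recon_cohort, recon_reference, design):
        """i.i.d. trial resampling is exactly Binomial(240, k/240)."""
        null = bootstrap_error_counts(
            _adapted(recon_cohort, "test_200", design),
            recon_reference,
            n_iterations=100_000,
            unit="trial",
            seed=3,
        )
        n = design.n_adapted_trials_per_test_condition
        support = np.arange(n + 1)
        empirical = np.bincount(null.counts, minlength=n + 1) / null.n_iterations
        oracle = stats.binom.pmf(support, n, null.observed_count / n)
        tv = 0.5 * np.abs(empirical - oracle).sum()
        assert tv < 0.01

    def test_probability_conventions(self, recon_cohort, recon_reference, design):
        null = bootstrap_error_counts(
            _adapted(recon_cohort, "test_200", design),
            recon_reference,
            n_iterations=5_000,
            seed=4,
        )
        for k in (8, 20, 35):
            assert null.p_exact(k) >= 1.0 / (1 + null.n_iterations)
            assert 0 <= null.p_exact(k, "raw") <= 1
            assert null.p_le(k) + null.p_ge(k) >= 1.0  # overlap at k
        # extreme low count: binomial oracle for P(X <= 8 | mean 20)
        assert null.p_le(8, "raw") == pytest.approx(
            stats.binom.cdf(8, 240, 20 / 240), abs=0.005
        )

    def test_reproducible_and_order_invariant(self, recon_cohort, recon_reference, design):
        sub = _adapted(recon_cohort, "test_200", design)
        shuffled = sub.sample(frac=1.0, random_state=9)
        a = bootstrap_error_counts(sub, recon_reference, 2_000, seed=7)
        b = bootstrap_error_counts(shuffled, recon_reference, 2_000, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_empty_input_rejected(self, recon_cohort, recon_reference):
        with pytest.raises(ValueError):
            bootstrap_error_counts(recon_cohort.iloc[:0], recon_reference, 100)


def _panel(n_trials, error_rows, labels, rng):
    """Labeled panel with errors planted at the given row indices."""
    probe = np.resize(np.repeat(labels, 8), n_trials)
    is_error = np.zeros(n_trials, dtype=bool)
    is_error[list(error_rows)] = True
    return pd.DataFrame(
        {
            "participant": "P01",
            "condition": "test_200",
            "probe_deg": probe,
            "repeat": np.resize(np.arange(1, 9), n_trials),
            "is_error": is_error,
        }
    )


class TestShuffleOrientationTest:
    labels = np.arange(-90, 91, 15)

    def test_single_error_matches_exchangeability_oracle(self, rng):
        """One error lands on the 2 adapted of 13 equally frequent labels w.p. 2/13."""
        panel = _panel(104, [0], self.labels, rng)
        n_shuffles = 20_000
        res = shuffle_orientation_test([panel], n_shuffles=n_shuffles, seed=5)
        p0 = 2 / 13
        se = np.sqrt(p0 * (1 - p0) / n_shuffles)
        # row 0 has probe -90 (not adapted) -> observed 0... place error at an
        # adapted label instead so observed = 1 and p = P(shuffled >= 1)
        adapted_row = int(np.flatnonzero(np.isin(panel["probe_deg"], [-45, 45]))[0])
        panel2 = _panel(104, [adapted_row], self.labels, rng)
        res2 = shuffle_orientation_test([panel2], n_shuffles=n_shuffles, seed=5)
        assert res2.observed_statistic == 1
        assert abs(res2.p_value_raw - p0) < 3 * se
        # with the error off the adapted labels the observed statistic is 0
        assert res.observed_statistic == 0
        assert res.p_value_raw == 1.0

    def test_full_concentration_saturates_floor(self, rng):
        """Many errors all at adapted labels: no shuffle matches, p = 1/(1+n)."""
        adapted_rows = np.flatnonzero(np.isin(np.resize(np.repeat(self.labels, 8), 104), [-45, 45]))
        panels = [_panel(104, adapted_rows[:10], self.labels, rng) for _ in range(4)]
        n_shuffles = 100_000
        res = shuffle_orientation_test(panels, n_shuffles=n_shuffles, seed=6)
        assert res.observed_statistic == 40
        assert res.n_extreme == 0
        assert res.p_value == pytest.approx(1.0 / (1 + n_shuffles))

    def test_zero_errors_p_one(self, rng):
        panel = _panel(104, [], self.labels, rng)
        res = shuffle_orientation_test([panel], n_shuffles=1_000, seed=1)
        assert res.observed_statistic == 0
        assert res.p_value_raw == 1.0

    def test_matches_hypergeometric_oracle(self, rng):
        """Shuffled statistic distribution equals the hypergeometric law."""
        m_errors = 5
        adapted_rows = np.flatnonzero(np.isin(np.resize(np.repeat(self.labels, 8), 104), [-45, 45]))
        panel = _panel(104, list(adapted_rows[:3]) + [0, 1], self.labels, rng)
        res = shuffle_orientation_test([panel], n_shuffles=50_000, seed=8)
        # oracle: 16 adapted slots among 104, 5 errors
        oracle = stats.hypergeom(104, 16, m_errors)
        assert res.shuffled_mean == pytest.approx(oracle.mean(), abs=0.02)
        p_ge_3 = oracle.sf(2)
        assert res.p_value_raw == pytest.approx(p_ge_3, abs=3 * np.sqrt(p_ge_3 / 50_000))

    def test_reproducible(self, rng):
        panel = _panel(104, [3, 20], self.labels, rng)
        a = shuffle_orientation_test([panel], 3_000, seed=12)
        b = shuffle_orientation_test([panel], 3_000, seed=12)
        assert a.n_extreme == b.n_extreme and a.p_value == b.p_value


class TestCdfDistanceTest:
    def test_identical_sample_distance_zero_p_one(self, rng):
        ctrl = rng.normal(0, 5, 400)
        # error offsets equal to (90 + the centered control pool) reproduce
        # the reference CDF exactly
        res = cdf_distance_test(ctrl - ctrl.mean() + 90.0, ctrl, n_resamples=500,
                                seed=1, recenter_per_resample=False)
        assert res.observed_distance == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_type_i_error_calibrated(self, rng):
        """Null errors drawn from the control pool reject at ~alpha."""
        n_reps, n_cases, alpha = 500, 18, 0.05
        rejections = 0
        for rep in range(n_reps):
            ctrl = rng.normal(0, 5, 300)
            err = rng.choice(ctrl, n_cases, replace=True) + 90.0
            res = cdf_distance_test(err, ctrl, n_resamples=400, seed=rep)
            if res.p_value < alpha:
                rejections += 1
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.09

    def test_power_against_gross_shift(self, rng):
        """A 3-SD location shift of the error offsets is essentially always detected."""
        detected = 0
        n_reps = 100
        for rep in range(n_reps):
            ctrl = rng.normal(0, 5, 300)
            err = rng.normal(3 * 5.0, 5.0, 18) + 90.0
            # global centering mode: a pure location shift must be visible
            res = cdf_distance_test(err, ctrl, n_resamples=1_000, seed=rep,
                                    recenter_per_resample=False)
            if res.p_value < 0.01:
                detected += 1
        assert detected / n_reps > 0.99

    def test_insufficient_errors(self, rng):
        with pytest.raises(InsufficientDataError):
            cdf_distance_test([90.0], rng.normal(0, 5, 100), n_resamples=10)

    def test_envelope_and_band_shapes(self, rng):
        ctrl = rng.normal(0, 5, 500)
        err = rng.normal(0, 5, 18) + 90.0
        res = cdf_distance_test(err, ctrl, n_resamples=300, seed=3)
        assert res.grid.shape == res.reference_cdf.shape == (201,)
        assert np.all(res.band5 <= res.band95)
        assert np.all(np.diff(res.reference_cdf) >= 0)
        assert res.n_cases == 18
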