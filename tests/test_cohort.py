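"""Synthetic-cohort generator: mixture structure, determinism, planted rates."""

import numpy as np
import pandas as pd
import pytest

from orthillusion import (
    GeneratorParams,
    StudyDesign,
    bias_function,
    classify_errors,
    compute_offsets,
    count_errors_at_adapted,
    fit_control_reference,
    generate_cohort,
    reconstruct_reported_counts,
)
from orthillusion.exceptions import ConfigurationError

from conftest import REPORTED_COUNTS


class TestBiasFunction:
    def test_fixed_points_at_cardinal_and_oblique(self):
        for theta in (0.0, 45.0, -45.0, 90.0, -90.0):
            assert bias_function(theta, 6.8) == pytest.approx(0.0, abs=1e-12)

    def test_repulsion_signs(self):
        assert bias_function(10.0, 6.8) > 0  # pushed away from horizontal
        assert bias_function(80.0, 6.8) < 0  # pushed away from vertical

    def test_bounded_by_amplitude(self, rng):
        theta = rng.uniform(-90, 90, 1000)
        assert np.all(np.abs(bias_function(theta, 6.8)) <= 6.8 + 1e-12)


class TestGenerateCohort:
    def test_same_seed_identical_tables(self, design):
        a = generate_cohort(design, seed=42)
        b = generate_cohort(design, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(design, seed=43)
        assert not a["response_deg"].equals(c["response_deg"])

    def test_zero_rates_yield_no_orthogonal_responses(self, design):
        params = GeneratorParams(
            illusion_rate_200=0.0, illusion_rate_33=0.0, control_illusion_rate=0.0
        )
        trials = generate_cohort(design, params, seed=5)
        offsets = compute_offsets(trials)
        # all offsets stay within bias amplitude + heterogeneity + a few noise SDs
        assert np.max(np.abs(offsets)) < params.bias_amplitude + 6 * (
            params.bias_heterogeneity_sd + params.response_noise_sd
        )
        assert np.sum(np.abs(np.abs(offsets) - 90) < 25) == 0

    def test_susceptible_subset_size_and_clustering(self, design):
        params = GeneratorParams(control_illusion_rate=0.0)  # isolate planted component
        trials, info = generate_cohort(design, params, seed=11, return_info=True)
        assert len(info["susceptible_participants"]) == round(7 / 15 * 15)
        illusory = trials[info["illusory_mask"]]
        test_illusory = illusory[illusory["condition"].isin(["test_200", "test_33"])]
        # planted test-condition illusions only in susceptible participants,
        # at adapted probes, with the sustained grating parallel to the probe
        assert set(test_illusory["participant"]) <= set(info["susceptible_participants"])
        assert set(test_illusory["probe_deg"]) <= set(design.adapted_labels)
        assert (test_illusory["single_grating_deg"] == test_illusory["probe_deg"]).all()

    def test_unreachable_rate_raises(self, design):
        params = GeneratorParams(illusion_rate_200=0.9, susceptible_fraction=0.2)
        with pytest.raises(ConfigurationError):
            generate_cohort(design, params, seed=0)

    def test_invalid_params_raise(self):
        with pytest.raises(ConfigurationError):
            GeneratorParams(illusion_rate_200=1.5).validate()
        with pytest.raises(ConfigurationError):
            GeneratorParams(response_noise_sd=0.0).validate()

    def test_planted_and_veridical_scatter_match(self, design):
        """The orthogonal mixture component scatters like veridical responses."""
        from orthillusion import canonicalize_orientation

        params = GeneratorParams(illusion_rate_200=0.3, illusion_rate_33=0.3)
        jitters = []
        for seed in range(8):
            trials, info = generate_cohort(design, params, seed=seed, return_info=True)
            offsets = compute_offsets(trials)
            planted = info["illusory_mask"] & trials["condition"].isin(
                ["test_200", "test_33"]
            ).to_numpy()
            # scatter of the orthogonal component around the +90 offset
            jitters.append(canonicalize_orientation(offsets[planted] - 90.0))
        jitter_sd = np.std(np.concatenate(jitters), ddof=1)
        # compare against the nominal noise SD; veridical offsets also carry
        # bias/heterogeneity, so use the parameter as the yardstick
        assert jitter_sd == pytest.approx(params.response_noise_sd, rel=0.1)


class TestPlantedRateRecovery:
    def test_marginal_rates_recovered_over_cohorts(self, design):
        """Mean recovered error rate matches the planted marginal rates."""
        n_cohorts = 50
        rates = {"test_200": [], "test_33": []}
        for seed in range(n_cohorts):
            trials = generate_cohort(design, seed=seed)
            ref = fit_control_reference(trials)
            labeled = classify_errors(trials, ref)
            for cond in rates:
                rates[cond].append(count_errors_at_adapted(labeled, cond, design).fraction)
        params = GeneratorParams()
        for cond, planted in (
            ("test_200", params.illusion_rate_200),
            ("test_33", params.illusion_rate_33),
        ):
            sample = np.asarray(rates[cond])
            se = sample.std(ddof=1) / np.sqrt(n_cohorts)
            assert abs(sample.mean() - planted) < 3 * se, (cond, sample.mean(), se)

    def test_null_cohorts_rarely_produce_control_errors(self, design):
        """With no planted illusions, 4-SD control errors are < 1 per cohort."""
        params = GeneratorParams(
            illusion_rate_200=0.0, illusion_rate_33=0.0, control_illusion_rate=0.0
        )
        counts = []
        for seed in range(20):
            trials = generate_cohort(design, params, seed=1000 + seed)
            ref = fit_control_reference(trials)
            labeled = classify_errors(trials, ref)
            controls = labeled[
                labeled["condition"].str.startswith("control")
            ]
            counts.append(int(controls["is_error"].sum()))
        assert np.mean(counts) < 1.0


class TestReconstructReportedCounts:
    def test_exact_requested_counts(self, recon_labeled, design):
        for cond, expected in REPORTED_COUNTS.items():
            assert count_errors_at_adapted(recon_labeled, cond, design).count == expected

    def test_zero_count_cohort(self, design):
        trials = reconstruct_reported_counts(design, {"test_200": 0, "test_33": 0}, seed=7)
        ref = fit_control_reference(trials)
        labeled = classify_errors(trials, ref)
        for cond in REPORTED_COUNTS:
            assert count_errors_at_adapted(labeled, cond, design).count == 0

    def test_capacity_bound(self, design):
        with pytest.raises(ValueError):
            reconstruct_reported_counts(design, {"test_200": 241}, seed=0)

    def test_determinism(self, design):
        a = reconstruct_reported_counts(design, REPORTED_COUNTS, seed=55)
        b = reconstruct_reported_counts(design, REPORTED_COUNTS, seed=55)
        pd.testing.assert_frame_equal(a, b)
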