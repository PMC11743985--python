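"""Synthetic cohort generator: spectral shape, behavioral links, determinism."""

import numpy as np
import pytest

from painattn.behavior import compute_ap_type, compute_iap_score, filter_ni_trials
from painattn.behavior import EmptyAfterFilterError
from painattn.simulate import (
    CohortConfig,
    GroundTruth,
    InvalidConfigError,
    simulate_cohort,
    simulate_experience_sampling,
    simulate_ground_truth,
    simulate_ni_trials,
    simulate_roi_timeseries,
    synthesize_series,
    target_psd,
)
from painattn.spectral import compute_band_metrics, welch_psd, znormalize
from painattn.stats import cohens_d


def one_roi_config(**kw):
    defaults = dict(
        n_subjects_per_group=2, seed=1, duration_s=60.0, roi_list=("PCC",)
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


def truth_for(config, alpha_center=10.0, theta=0.2, idx=0):
    return GroundTruth(
        subject_id="sub-001",
        subject_idx=idx,
        group="low",
        ap_type="A",
        latent_p=0.3,
        rt_shift_ms=-75.0,
        alpha_center_by_roi={r: alpha_center for r in config.roi_list},
        theta_power_by_roi={r: theta for r in config.roi_list},
    )


class TestROITimeSeries:
    def test_length_and_fs_match_config(self):
        config = one_roi_config(duration_s=10.0)
        s = simulate_roi_timeseries(config, truth_for(config), "PCC")
        assert s.n_samples == 10_000
        assert s.fs == 1000.0

    def test_degenerate_config_gives_flat_spectrum(self):
        """Zero bumps and exponent 0 yield white noise: the Welch PSD is
        flat within sampling error across widely separated bands."""
        config = one_roi_config(
            duration_s=120.0,
            aperiodic_exponent=0.0,
            alpha_bump_power_by_group=(0.0, 0.0),
            theta_power_by_group=(0.0, 0.0),
            theta_effect_d=0.0,
            noise_sd=0.0,
        )
        s = simulate_roi_timeseries(config, truth_for(config, theta=0.0), "PCC")
        spec = welch_psd(znormalize(s))
        bands = [(5, 15), (50, 60), (150, 160), (300, 310)]
        means = [
            np.mean(spec.power[(spec.freqs >= lo) & (spec.freqs < hi)])
            for lo, hi in bands
        ]
        assert max(means) / min(means) == pytest.approx(1.0, rel=0.1)

    def test_paf_recovery_at_configured_center(self):
        config = one_roi_config(
            alpha_bump_power_by_group=(2.0, 2.0), noise_sd=0.01
        )
        s = simulate_roi_timeseries(config, truth_for(config, 10.0), "PCC")
        m = compute_band_metrics(s)
        assert m.paf_speed == pytest.approx(10.0, abs=0.1)  # one grid bin

    def test_aperiodic_loglog_slope_matches_exponent(self):
        """Log-log linear fit over 20-80 Hz recovers -aperiodic_exponent."""
        config = one_roi_config(
            duration_s=120.0,
            aperiodic_exponent=1.5,
            alpha_bump_power_by_group=(0.0, 0.0),
            theta_power_by_group=(0.0, 0.0),
            theta_effect_d=0.0,
            noise_sd=0.01,
        )
        s = simulate_roi_timeseries(config, truth_for(config, theta=0.0), "PCC")
        spec = welch_psd(s)
        mask = (spec.freqs >= 20) & (spec.freqs <= 80)
        slope = np.polyfit(
            np.log10(spec.freqs[mask]), np.log10(spec.power[mask]), 1
        )[0]
        assert slope == pytest.approx(-1.5, abs=0.1)

    def test_invalid_config_raises(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(duration_s=-1)
        with pytest.raises(InvalidConfigError):
            CohortConfig(fs=0)
        with pytest.raises(InvalidConfigError):
            CohortConfig(alpha_center_by_group=(7.0, 10.0))
        with pytest.raises(InvalidConfigError):
            CohortConfig(n_subjects_per_group=1)

    def test_synthesis_psd_proportional_to_target(self, rng):
        freqs = np.fft.rfftfreq(60_000, 1 / 1000)
        psd = target_psd(freqs, 1.0, 10.0, 0.5, 1.0, 0.2, 0.05)
        x = synthesize_series(psd, 60_000, rng)
        spec = welch_psd(znormalize(ROITimeSeriesWrap(x)))
        # ratio of alpha-peak to 30 Hz background should match the target
        tgt_ratio = psd[np.argmin(abs(freqs - 10))] / psd[np.argmin(abs(freqs - 30))]
        est_ratio = (
            spec.power[np.argmin(abs(spec.freqs - 10))]
            / spec.power[np.argmin(abs(spec.freqs - 30))]
        )
        assert est_ratio == pytest.approx(tgt_ratio, rel=0.35)


def ROITimeSeriesWrap(x):
    from painattn.spectral import ROITimeSeries

    return ROITimeSeries("w", "PCC", 1000.0, x)


class TestExperienceSamplingLink:
    def test_endpoints_are_deterministic(self, rng):
        all_pain = simulate_experience_sampling(1.0, 20, rng)
        assert {r.response for r in all_pain} == {"only_pain"}
        assert compute_iap_score(all_pain).iap_score == 2.0
        all_else = simulate_experience_sampling(0.0, 20, rng)
        assert {r.response for r in all_else} == {"only_else"}
        assert compute_iap_score(all_else).iap_score == -2.0

    def test_symmetric_latent_gives_zero_mean_score(self, rng):
        scores = [
            compute_iap_score(simulate_experience_sampling(0.5, 20, rng)).iap_score
            for _ in range(1000)
        ]
        # per-trial score variance is ~1.5, so the MC mean has SD ~ 0.009
        assert np.mean(scores) == pytest.approx(0.0, abs=0.04)

    def test_monotone_in_latent_p(self, rng):
        means = [
            np.mean(
                [
                    compute_iap_score(
                        simulate_experience_sampling(p, 20, rng)
                    ).iap_score
                    for _ in range(300)
                ]
            )
            for p in (0.2, 0.5, 0.8)
        ]
        assert means[0] < means[1] < means[2]

    def test_invalid_latent_p_raises(self):
        with pytest.raises(InvalidConfigError):
            simulate_experience_sampling(1.5, 20)


class TestNITrials:
    def test_noise_free_shift_recovers_exactly(self, rng):
        trials = simulate_ni_trials(1216.0, 48.0, rt_sigma=0.0, rng=rng)
        result = compute_ap_type(filter_ni_trials(trials))
        assert result.delta_rt_mean == pytest.approx(48.0)
        assert result.ap_type == "P"
        trials = simulate_ni_trials(1344.0, -75.0, rt_sigma=0.0, rng=rng)
        result = compute_ap_type(filter_ni_trials(trials))
        assert result.delta_rt_mean == pytest.approx(-75.0)
        assert result.ap_type == "A"

    def test_block_structure(self, rng):
        trials = simulate_ni_trials(1300.0, 50.0, rng=rng)
        assert len(trials) == 6 * 24
        by_block = {b: {t.condition for t in trials if t.block_index == b} for b in range(1, 7)}
        assert by_block == {
            1: {"no_pain"}, 2: {"pain"}, 3: {"no_pain"},
            4: {"pain"}, 5: {"no_pain"}, 6: {"pain"},
        }

    def test_all_outliers_empty_after_filter(self, rng):
        trials = simulate_ni_trials(1300.0, 50.0, outlier_rate=1.0, rng=rng)
        surviving = filter_ni_trials(trials)
        assert surviving == []
        with pytest.raises(EmptyAfterFilterError):
            compute_ap_type(surviving)

    def test_invalid_params_raise(self):
        with pytest.raises(InvalidConfigError):
            simulate_ni_trials(1300.0, 0.0, trials_per_block=0)
        with pytest.raises(InvalidConfigError):
            simulate_ni_trials(1300.0, 0.0, n_blocks=5)


class TestCohort:
    def test_seed_reproducibility_bit_identical(self, tiny_cohort_config):
        a = simulate_cohort(tiny_cohort_config)
        b = simulate_cohort(tiny_cohort_config)
        assert a.es_table.equals(b.es_table)
        assert a.ni_table.equals(b.ni_table)
        assert a.truth_table.equals(b.truth_table)
        sa = a.roi_series("sub-001", "PCC")
        sb = b.roi_series("sub-001", "PCC")
        np.testing.assert_array_equal(sa.samples, sb.samples)

    def test_different_seeds_differ(self, tiny_cohort_config):
        from dataclasses import replace

        a = simulate_cohort(tiny_cohort_config)
        b = simulate_cohort(replace(tiny_cohort_config, seed=99))
        assert not a.ni_table.equals(b.ni_table)

    def test_substreams_independent_of_regeneration_order(self, tiny_cohort_config):
        cohort = simulate_cohort(tiny_cohort_config)
        first = cohort.roi_series("sub-002", "precuneus")
        # regenerate other series in between; the substream must not shift
        cohort.roi_series("sub-001", "PCC")
        second = cohort.roi_series("sub-002", "precuneus")
        np.testing.assert_array_equal(first.samples, second.samples)

    def test_ground_truth_labels_and_propensities(self):
        config = CohortConfig(n_subjects_per_group=(5, 4), duration_s=5)
        truths = simulate_ground_truth(config)
        assert [t.group for t in truths] == ["low"] * 5 + ["high"] * 4
        assert all(0 <= t.latent_p <= 1 for t in truths)
        assert all(np.isfinite(t.rt_shift_ms) for t in truths)
        assert all(t.ap_type in ("A", "P") for t in truths)


class TestEffectSizeRecovery:
    def test_theta_d_recovered_through_spectral_pipeline(self):
        """Ground-truth theta effect (d = 0.93) survives synthesis, Welch
        estimation and z-normalization to within +/-0.15 at n = 200/group.

        Wide group separation keeps subject-level variance dominant over
        spectral estimation noise; d is averaged over 4 ROIs to tame the
        sampling error of the d estimator itself.
        """
        config = CohortConfig(
            n_subjects_per_group=200,
            seed=0,
            duration_s=30.0,
            theta_power_by_group=(0.35, 0.20),
            theta_effect_d=0.93,
            roi_list=("PCC", "precuneus", "left_S1", "right_TPJ"),
        )
        truths = simulate_ground_truth(config)
        ds = []
        for roi in config.roi_list:
            theta = {"low": [], "high": []}
            for t in truths:
                m = compute_band_metrics(
                    simulate_roi_timeseries(config, t, roi)
                )
                theta[t.group].append(m.total_theta_power)
            ds.append(cohens_d(theta["low"], theta["high"]))
        assert np.mean(ds) == pytest.approx(0.93, abs=0.15)
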