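"""Generator contracts: paradigm timing, planted-truth self-consistency,
IPFM beat placement and determinism."""

from __future__ import annotations

import numpy as np
import pytest

import micardia as mc
from micardia.errors import ParameterError
from micardia.synthetic import perturb_effects

FS = 250.0


class TestEvents:
    def test_default_paradigm_has_three_runs_of_forty(self):
        ev = mc.generate_events(mc.ParadigmSpec(), seed=0)
        assert len(ev) == 120
        assert set(ev["label"]) <= {"go", "nogo"}
        assert ev["onset_sample"].is_monotonic_increasing

    def test_gaps_uniform_on_11_14_seconds(self):
        # Monte-Carlo check of the uniform inter-cue law on 10k events
        p = mc.ParadigmSpec(n_runs=100, trials_per_run=100)
        ev = mc.generate_events(p, seed=1)
        gaps = np.diff(ev["onset_sample"].to_numpy()) / FS
        assert gaps.min() >= 11.0 - 1 / FS and gaps.max() <= 14.0 + 1 / FS
        assert abs(gaps.mean() - 12.5) < 0.1

    def test_degenerate_go_probability(self):
        ev = mc.generate_events(mc.ParadigmSpec(p_go=1.0), seed=2)
        assert (ev["label"] == "go").all()

    def test_invalid_paradigm_rejected(self):
        with pytest.raises(ParameterError):
            mc.ParadigmSpec(inter_cue_min_s=15.0, inter_cue_max_s=14.0)
        with pytest.raises(ParameterError):
            mc.ParadigmSpec(sample_rate_hz=0.0)
        with pytest.raises(ParameterError):
            mc.ParadigmSpec(p_go=1.5)


class TestTruthModels:
    def test_erd_truth_hits_planted_depth_at_planted_latency(self):
        eff = mc.EffectSpec()
        for cond, lat, depth in (
            ("go", eff.erd_early_latency_go_s, eff.erd_early_depth_go),
            ("nogo", eff.erd_early_latency_nogo_s, eff.erd_early_depth_nogo),
        ):
            val = mc.erd_truth_curve(eff, cond, np.array([lat]))[0]
            assert val == pytest.approx(depth, abs=1e-9)

    def test_nogo_envelope_power_ratio_in_dip(self):
        # -32.00 % at 397 ms => band-power ratio 0.68 by construction
        eff = mc.EffectSpec()
        g = mc.erd_truth_curve(eff, "nogo", np.array([0.397]))[0]
        assert 1.0 + g / 100.0 == pytest.approx(0.68, abs=1e-9)

    def test_null_effect_truth_is_flat(self):
        eff = mc.EffectSpec(
            erd_early_depth_go=0.0,
            erd_early_depth_nogo=0.0,
            peri_imagery_depth=0.0,
            rebound_gain=0.0,
        )
        t = np.linspace(-5, 6, 500)
        for cond in ("go", "nogo"):
            assert np.allclose(mc.erd_truth_curve(eff, cond, t), 0.0)

    def test_hr_truth_minimum_matches_planted_dip(self):
        eff = mc.EffectSpec()
        t = np.linspace(-5, 6, 11001)
        for cond, lat, depth in (
            ("go", eff.hr_decel_latency_go_s, eff.hr_decel_go),
            ("nogo", eff.hr_decel_latency_nogo_s, eff.hr_decel_nogo),
        ):
            h = mc.hr_truth_curve(eff, cond, t)
            # the go acceleration bump's tail shifts the exact minimum by a
            # hair; the curve still passes through the planted depth at the
            # planted latency (asserted exactly below)
            assert h.min() == pytest.approx(depth, abs=0.02)
            # flat-bottomed dip: the argmin is diffuse within the bottom
            assert t[np.argmin(h)] == pytest.approx(lat, abs=0.2)
            at_lat = mc.hr_truth_curve(eff, cond, np.array([lat]))[0]
            assert at_lat == pytest.approx(depth, abs=1e-9)


class TestEcg:
    def test_constant_rate_beats_exactly_one_second_apart(self):
        eff = mc.EffectSpec(
            hr_baseline_bpm=60.0, slow_hr_amp=0.0,
            hr_decel_go=0.0, hr_decel_nogo=0.0, hr_accel_go=0.0,
        )
        ev = mc.generate_events(mc.ParadigmSpec(n_runs=1, trials_per_run=5), seed=0)
        n = int(ev["onset_sample"].max() + 8 * FS)
        _, beats, rate = mc.generate_ecg(ev, eff, seed=0, n_samples=n)
        assert np.allclose(rate, 60.0)
        assert np.allclose(np.diff(beats), 1.0, atol=1e-9)

    def test_planted_nogo_dip_gives_rate_minimum_0_9806(self):
        eff = mc.EffectSpec(slow_hr_amp=0.0, hr_decel_go=0.0, hr_accel_go=0.0)
        ev = mc.generate_events(mc.ParadigmSpec(p_go=1e-12), seed=3)  # all nogo
        n = int(ev["onset_sample"].max() + 8 * FS)
        _, _, rate = mc.generate_ecg(ev, eff, seed=0, n_samples=n)
        assert rate.min() / eff.hr_baseline_bpm == pytest.approx(0.9806, abs=1e-4)

    def test_zero_amplitude_template_keeps_truth_but_breaks_detector(self):
        eff = mc.EffectSpec()
        ev = mc.generate_events(mc.ParadigmSpec(n_runs=1, trials_per_run=4), seed=1)
        ecg, beats, _ = mc.generate_ecg(
            ev, eff, seed=0, template_amplitude_mv=0.0
        )
        assert np.all(ecg == 0.0)
        assert beats.size > 10
        with pytest.raises(mc.errors.NoBeatsDetectedError):
            mc.detect_qrs(ecg, FS)

    def test_nonpositive_rate_rejected(self):
        eff = mc.EffectSpec(hr_baseline_bpm=40.0, slow_hr_amp=120.0)
        ev = mc.generate_events(mc.ParadigmSpec(n_runs=1, trials_per_run=4), seed=1)
        with pytest.raises(ParameterError):
            mc.generate_ecg(ev, eff, seed=0)


class TestEmg:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 120)])
    def test_degenerate_fractions(self, fraction, expected):
        ev = mc.generate_events(mc.ParadigmSpec(), seed=4)
        _, flags = mc.generate_emg(ev, fraction, seed=0)
        assert flags.sum() == expected

    def test_flag_count_follows_binomial_law(self):
        ev = mc.generate_events(mc.ParadigmSpec(), seed=5)
        counts = [
            mc.generate_emg(ev, 0.2, seed=s)[1].sum() for s in range(25)
        ]
        # mean 24, SD sqrt(120*.2*.8)=4.38; CI for the mean of 25 draws
        assert abs(np.mean(counts) - 24.0) < 3 * 4.38 / np.sqrt(25)

    def test_burst_exceeds_six_sd_of_trial_rest_window(self):
        ev = mc.generate_events(mc.ParadigmSpec(n_runs=1, trials_per_run=10), seed=6)
        emg, flags = mc.generate_emg(ev, 1.0, seed=6)
        rest = int(5 * FS)
        for onset in ev["onset_sample"]:
            r = emg[0, onset - rest : onset]
            post = emg[0, onset : onset + int(2 * FS)]
            assert post.max() >= r.mean() + 6 * r.std() - 1e-9


class TestSessionAndCohort:
    def test_same_seed_bitwise_identical(self, small_paradigm):
        s1, t1 = mc.generate_session(small_paradigm, seed=9)
        s2, t2 = mc.generate_session(small_paradigm, seed=9)
        assert np.array_equal(s1.eeg, s2.eeg)
        assert np.array_equal(s1.ecg, s2.ecg)
        assert np.array_equal(s1.emg, s2.emg)
        assert s1.events.equals(s2.events)
        assert np.array_equal(t1.beat_times, t2.beat_times)

    def test_different_seed_different_noise_same_truth(self, small_paradigm):
        eff = mc.EffectSpec()
        s1, t1 = mc.generate_session(small_paradigm, eff, seed=1)
        s2, t2 = mc.generate_session(small_paradigm, eff, seed=2)
        assert not np.array_equal(s1.eeg, s2.eeg)
        for cond in ("go", "nogo"):
            assert np.array_equal(t1.erd_truth[cond], t2.erd_truth[cond])
            assert np.array_equal(t1.hr_truth[cond], t2.hr_truth[cond])

    def test_zero_spread_cohort_inherits_population_effects(self, small_paradigm):
        eff = mc.EffectSpec(subject_sd_scale=0.0)
        [(_, truth)] = mc.generate_cohort(1, small_paradigm, eff, seed=0)
        assert truth.effects == eff

    def test_cohort_size_and_validation(self, small_paradigm):
        cohort = mc.generate_cohort(3, small_paradigm, seed=0, modalities=("emg",))
        assert len(cohort) == 3
        with pytest.raises(ParameterError):
            mc.generate_cohort(0, small_paradigm)

    def test_subject_effects_unbiased_around_population(self):
        # law of large numbers on the perturbation alone (no signal synthesis)
        eff = mc.EffectSpec()
        rng = np.random.default_rng(0)
        draws = [perturb_effects(eff, rng) for _ in range(400)]
        depths = np.array([d.erd_early_depth_nogo for d in draws])
        hr = np.array([d.hr_decel_nogo for d in draws])
        assert abs(depths.mean() - eff.erd_early_depth_nogo) < 4 * 4.0 / 20.0
        assert abs(hr.mean() - eff.hr_decel_nogo) < 4 * 0.15 / 20.0

    def test_carrier_outside_passband_rejected(self):
        with pytest.raises(ParameterError):
            mc.EffectSpec(beta_band_hz=(50.0, 90.0))
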