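"""Generator contracts: study structure, bivariate ratings, epochs, artifacts."""

import numpy as np
import pandas as pd
import pytest

from emopower.montage import LPP_CLUSTER, OCCIPITAL_CLUSTER, default_montage
from emopower.synthgen import (SimulationConfig, frame_brightness,
                               frame_motion_metric, inject_artifacts,
                               simulate_epochs, simulate_study)

from conftest import SMALL


class TestStudyStructure:
    def test_default_stimulus_partition(self, small_study):
        stimuli = small_study[0]
        counts = stimuli["category"].value_counts()
        assert set(counts.index) == {"pleasant", "neutral", "unpleasant"}
        assert counts.nunique() == 1
        ero = stimuli[stimuli["content_tag"] == "erotica"]
        sur = stimuli[stimuli["content_tag"] == "surgery"]
        assert (ero["category"] == "pleasant").all()
        assert (sur["category"] == "unpleasant").all()

    def test_full_scale_study_is_90_stimuli_45_participants(self):
        stimuli, profiles, ratings, _ = simulate_study(SimulationConfig(), 1)
        assert len(stimuli) == 90
        assert (stimuli["category"].value_counts() == 30).all()
        assert (stimuli["content_tag"] == "erotica").sum() == 8
        assert (stimuli["content_tag"] == "surgery").sum() == 5
        assert len(profiles) == 45
        assert len(ratings) == 45 * 90

    def test_ratings_are_integers_on_scale(self, small_study):
        ratings = small_study[2]
        for col in ("arousal", "valence"):
            assert ratings[col].between(1, 9).all()
            assert (ratings[col] == ratings[col].astype(int)).all()

    def test_identical_seed_bit_identical(self, small_config):
        a = simulate_study(small_config, 5)
        b = simulate_study(small_config, 5)
        pd.testing.assert_frame_equal(a[2], b[2])
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(par_sd=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(resid_sd_mean=-1.0)


class TestBivariateStructure:
    def test_degenerate_stimulus_prior_gives_zero_effects(self):
        cfg = SimulationConfig(**{**SMALL, "stim_effect_sd": 1e-12,
                                  "content_amp_scale": 0.0})
        stimuli, _, _, _ = simulate_study(cfg, 3)
        assert np.abs(stimuli["true_effect"]).max() < 1e-6

    def test_zero_covariance_gives_uncorrelated_samples(self):
        cfg = SimulationConfig(n_participants=2, n_stimuli=90, rho_mean=0.0,
                               rho_sd=0.0, stim_effect_sd=1e-9)
        rows = []
        for seed in range(30):  # ~5.4e3 trials per participant total
            _, _, ratings, _ = simulate_study(cfg, 100 + seed)
            rows.append(ratings)
        r = pd.concat(rows)
        for _, sub in r.groupby("participant_id"):
            resid_a = sub["amplitude"] - sub.groupby("stimulus_id")[
                "amplitude"].transform("mean")
            resid_r = sub["arousal_raw"] - sub.groupby("stimulus_id")[
                "arousal_raw"].transform("mean")
            assert abs(np.corrcoef(resid_a, resid_r)[0, 1]) < 0.05

    def test_sample_correlation_matches_implied_rho(self):
        """Residual sample correlations sit within 3 SE of each profile's
        implied rho = cov / (sd_amp * sd_aro) under a flat stimulus design."""
        cfg = SimulationConfig(n_participants=8, n_stimuli=90,
                               stim_effect_sd=1e-9, aro_stim_sd=1e-9,
                               rho_mean=0.3, rho_sd=0.15)
        stimuli, profiles, ratings, _ = simulate_study(cfg, 1)
        # flat structural means within category; remove them exactly
        for _, sub in ratings.groupby("participant_id"):
            pid = sub["participant_id"].iloc[0]
            prof = profiles[profiles["participant_id"] == pid].iloc[0]
            rho = prof["amp_aro_cov"] / (prof["resid_sd"] * prof["aro_sd"])
            a = sub["amplitude"] - sub.groupby("category")["amplitude"].transform("mean")
            b = sub["arousal_raw"] - sub.groupby("category")["arousal_raw"].transform("mean")
            r = np.corrcoef(a, b)[0, 1]
            se = (1 - rho ** 2) / np.sqrt(len(sub) - 3)
            assert abs(r - rho) < 3 * se + 0.02


class TestEpochSynthesis:
    def test_noise_free_video_is_pure_tone_on_occipital(self):
        cfg = SimulationConfig(n_participants=2, n_stimuli=3, n_erotica=0,
                               n_surgery=0, n_channels=20, background_sd=1e-9,
                               bb_base_sd=1e-9, bb_arousal_slope=0.0,
                               bb_floor_sd=1e-9, tone_amp_cv=0.0,
                               tone_gain_par_sd=0.0, baseline_noise_mult=1.0)
        stimuli, profiles, _, _ = simulate_study(cfg, 2)
        ep, _ = simulate_epochs(stimuli, profiles, "video", cfg, 3)
        occ = ep.channel_indices(OCCIPITAL_CLUSTER)
        other = [i for i in range(ep.n_channels) if i not in occ]
        assert np.abs(ep.data[:, other, :]).max() < 1e-6
        t = ep.times
        expected = cfg.tone_amp_uv * np.sin(2 * np.pi * 7.5 * t)
        assert np.abs(ep.data[0, occ[0]] - expected).max() < 1e-6

    def test_scene_window_and_onset_sample(self, scene_epochs):
        ep, _ = scene_epochs
        assert ep.times[0] == pytest.approx(-0.125)
        assert ep.times[-1] == pytest.approx(2.0, abs=1.0 / ep.srate)
        assert ep.times[ep.t0] == 0.0

    def test_scene_mean_recovers_injected_amplitude(self, small_config,
                                                    small_study, scene_epochs):
        """Cluster/window mean equals the injected per-trial amplitude up to
        background-noise error."""
        ep, truth = scene_epochs
        ch = ep.channel_indices(LPP_CLUSTER)
        sl = ep.time_slice(0.4, 0.9)
        measured = ep.data[:, ch, sl.start:sl.stop].mean(axis=(1, 2))
        resid = measured - truth.trial_amplitude
        # noise SE of the window/cluster mean of unit-SD 1/f background
        assert np.abs(resid).mean() < 0.5
        assert np.corrcoef(measured, truth.trial_amplitude)[0, 1] > 0.98

    def test_video_emotional_has_equal_75_bin_but_less_broadband(self):
        """Construction check for the driven-frequency confound: the 7.5 Hz
        bin is category-invariant while 3-10 Hz power drops for emotional."""
        from emopower.sigproc import band_power, fft_spectrum

        cfg = SimulationConfig(n_participants=4, n_stimuli=30, n_erotica=0,
                               n_surgery=0, n_channels=20, tone_amp_cv=0.0,
                               tone_gain_par_sd=0.0, background_sd=0.05)
        stimuli, profiles, _, _ = simulate_study(cfg, 4)
        ep, _ = simulate_epochs(stimuli, profiles, "video", cfg, 5)
        spec = fft_spectrum(ep, (1.0, 9.0), OCCIPITAL_CLUSTER,
                            groupby=["category"])
        by_cat = dict(zip(spec.groups, np.atleast_2d(spec.power)))
        bin75 = {c: band_power(
            type(spec)(spec.freqs, p, spec.bin_width, spec.window), 7.5, 7.5)
            for c, p in by_cat.items()}
        bb = {c: band_power(
            type(spec)(spec.freqs, p, spec.bin_width, spec.window), 3.0, 10.0)
            for c, p in by_cat.items()}
        tone_power = cfg.tone_amp_uv ** 2 / 2
        for c in bin75:
            assert abs(bin75[c] - tone_power) / tone_power < 0.25
        assert bb["pleasant"] < bb["neutral"]
        assert bb["unpleasant"] < bb["neutral"]

    def test_unknown_mode_rejected(self, small_config, small_study):
        stimuli, profiles, _, _ = small_study
        with pytest.raises(ValueError):
            simulate_epochs(stimuli, profiles, "movie", small_config, 1)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(srate=16.0)

    def test_seed_determinism(self, small_config, small_study):
        stimuli, profiles, ratings, _ = small_study
        a, _ = simulate_epochs(stimuli, profiles, "scene", small_config, 9,
                               trial_effects=ratings)
        b, _ = simulate_epochs(stimuli, profiles, "scene", small_config, 9,
                               trial_effects=ratings)
        assert np.array_equal(a.data, b.data)


class TestArtifacts:
    def test_zero_rate_is_identity(self, scene_epochs):
        ep, _ = scene_epochs
        out, truth = inject_artifacts(ep, 0.0, 0.0, seed=7)
        assert np.array_equal(out.data, ep.data)
        assert not truth.artifact_mask.any()

    def test_masked_cells_exceed_clean_amplitudes(self, scene_epochs):
        ep, _ = scene_epochs
        out, truth = inject_artifacts(ep, 0.1, 0.1, seed=7)
        mask = truth.artifact_mask
        assert mask.any()
        clean_q = np.percentile(np.abs(ep.data), 99.9)
        bad_max = np.abs(out.data[mask]).reshape(mask.sum(), -1).max(axis=1)
        assert (bad_max > clean_q).all()

    def test_rate_one_rejected(self, scene_epochs):
        ep, _ = scene_epochs
        with pytest.raises(ValueError):
            inject_artifacts(ep, 1.0, 0.1, seed=1)


class TestStimulusFeatures:
    @pytest.mark.parametrize("frames, expected", [
        (np.full((3, 4, 4), 128.0), 0.0),                       # identical
        (np.array([[[100.0]], [[130.0]]]), 30.0),               # two pixels
        (np.stack([np.zeros((2, 2)), np.full((2, 2), 255.0),
                   np.zeros((2, 2))]), 255.0),                  # alternating
    ])
    def test_motion_metric_hand_values(self, frames, expected):
        assert frame_motion_metric(frames) == pytest.approx(expected)

    def test_motion_metric_input_validation(self):
        with pytest.raises(ValueError):
            frame_motion_metric(np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            frame_motion_metric(np.full((2, 2, 2), 300.0))

    def test_brightness_is_mean_gray_value(self):
        frames = np.stack([np.zeros((2, 2)), np.full((2, 2), 255.0)])
        assert frame_brightness(frames) == pytest.approx(127.5)


def test_montage_contains_both_clusters():
    names, pos = default_montage()
    assert len(names) == 128
    assert set(LPP_CLUSTER) <= set(names)
    assert set(OCCIPITAL_CLUSTER) <= set(names)
    assert np.allclose(np.linalg.norm(pos, axis=1), 1.0)
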