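"""Synthetic emotional scene/video EEG study generator.

Emulates the statistical structure the downstream analysis assumes:

* a stimulus set of 90 items (30 pleasant / 30 neutral / 30 unpleasant, with
  8 erotica items inside pleasant and 5 surgery items inside unpleasant),
  each carrying a ground-truth amplitude deviation and a normative arousal;
* per-participant bivariate (amplitude, arousal) structure: each trial's
  latent amplitude deviation and experienced arousal are drawn jointly from
  the participant's 2x2 covariance, so both hierarchical models downstream
  are literally true of the generated data;
* scene epochs with a centro-parietal slow positivity at 400-900 ms whose
  per-trial amplitude is participant-mean + stimulus-effect + residual noise;
* video epochs with a fixed-amplitude 7.5 Hz driven oscillation at occipital
  sensors (never modulated by content) plus band-limited 3-10 Hz stochastic
  power whose standard deviation decreases with experienced arousal — the
  mechanism by which a narrow-band 7-8 Hz envelope measure picks up a
  broadband emotion effect;
* 1/f-shaped background noise everywhere, elevated during the scrambled
  video baseline;
* optional step/drift/spike artifact contamination with a ground-truth mask.

All randomness flows from a single integer seed; identical seed and config
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet
from .montage import LPP_CLUSTER, OCCIPITAL_CLUSTER, default_montage

CATEGORIES = ("pleasant", "neutral", "unpleasant")

# Ground-truth content-mean amplitude deviations (microvolts) and normative
# arousal (1-9) per content tag.  Amplitude deviations follow the qualitative
# pattern of emotional-scene ERP research: erotica and surgery/gore produce
# the largest slow positivities, neutral the smallest.
_CONTENT_AMP = {
    "erotica": 2.6, "pleasant-other": -0.1, "neutral": -1.05,
    "unpleasant-other": 0.2, "surgery": 1.6,
}
_CONTENT_ARO = {
    "erotica": 6.5, "pleasant-other": 5.8, "neutral": 4.2,
    "unpleasant-other": 6.8, "surgery": 6.7,
}
_CONTENT_VAL = {
    "erotica": 5.4, "pleasant-other": 7.1, "neutral": 5.3,
    "unpleasant-other": 3.3, "surgery": 3.3,
}


@dataclass
class SimulationConfig:
    """Generator parameters.  Defaults are the study conditions.

    Amplitude hyperparameters are on the scene-LPP microvolt scale; the
    video measure reuses the same latent structure through the broadband
    suppression mapping below.
    """

    n_participants: int = 45
    n_stimuli: int = 90
    n_erotica: int = 8
    n_surgery: int = 5

    # Model-1 hyperparameters (microvolts)
    par_mean: float = 5.0          # grand mean of participant means (ParBar)
    par_sd: float = 3.0            # SD of participant means (sigmaPar)
    stim_effect_sd: float = 0.8    # within-content-tag stimulus jitter (sigmaStim)
    content_amp_scale: float = 1.0  # multiplier on content-mean amplitude effects
    resid_sd_mean: float = 5.0     # mean per-trial residual SD (sigmaBar)
    resid_sd_sd: float = 1.5       # SD of residual SDs (tau)

    # Model-2 / ratings hyperparameters (scale units 1-9)
    aro_stim_sd: float = 0.5       # per-stimulus arousal jitter around content mean
    aro_par_sd: float = 0.6        # SD of participant mean-arousal offsets
    aro_sd_mean: float = 1.6       # mean within-participant arousal SD
    aro_sd_sd: float = 0.3
    val_noise_sd: float = 1.0      # residual valence-rating noise
    rho_mean: float = 0.15         # mean per-participant amplitude-arousal correlation
    rho_sd: float = 0.10

    # Epoch synthesis
    srate: float = 256.0           # 512 Hz available via config; 256 keeps tests fast
    n_channels: int = 128
    scene_window: tuple = (-0.125, 2.0)   # seconds around scene onset
    video_window: tuple = (-2.0, 10.0)    # seconds around video onset
    lpp_window: tuple = (0.4, 0.9)        # injected positivity extent
    tone_freq: float = 7.5         # driven flicker frequency (60 Hz / 8)
    tone_amp_uv: float = 1.0       # driven amplitude, identical for all categories
    tone_amp_cv: float = 0.25      # trial-level lognormal amplitude jitter
    tone_gain_par_sd: float = 0.3  # between-participant lognormal gain spread
    bb_notch_halfwidth: float = 0.3  # endogenous-noise notch around tone_freq
    bb_band: tuple = (3.0, 10.0)   # broadband stochastic band
    bb_base_sd: float = 1.1        # broadband SD at arousal 5
    bb_arousal_slope: float = -0.3   # d(SD)/d(arousal): suppression with arousal
    bb_floor_sd: float = 0.1
    background_sd: float = 1.0     # 1/f background SD (microvolts)
    oneoverf_exponent: float = 1.0
    baseline_noise_mult: float = 1.5  # scrambled-baseline noise elevation

    # Artifact injection
    artifact_amp_uv: float = 250.0

    def __post_init__(self):
        for name in ("par_sd", "stim_effect_sd", "resid_sd_mean", "aro_sd_mean",
                     "background_sd", "srate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("resid_sd_sd", "aro_stim_sd", "aro_par_sd", "aro_sd_sd",
                     "rho_sd", "val_noise_sd", "bb_base_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_stimuli % len(CATEGORIES):
            raise ValueError("n_stimuli must divide evenly into 3 categories")
        if self.n_erotica > self.n_stimuli // 3 or self.n_surgery > self.n_stimuli // 3:
            raise ValueError("content subsets exceed category size")
        if self.srate <= 2 * self.bb_band[1]:
            raise ValueError("srate violates Nyquist for broadband content")


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    rng_seed: int
    stimuli: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    artifact_mask: np.ndarray | None = None
    trial_amplitude: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def clip_rating(x: np.ndarray) -> np.ndarray:
    """Round-half-away-from-zero then clip to the integer 1-9 rating scale."""
    return np.clip(_round_half_away(np.asarray(x, float)), 1, 9).astype(int)


def make_stimulus_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stimulus set with ground-truth amplitude effects and normative arousal."""
    per_cat = config.n_stimuli // 3
    rows = []
    sid = 1
    for cat in CATEGORIES:
        for i in range(per_cat):
            if cat == "pleasant" and i < config.n_erotica:
                tag = "erotica"
            elif cat == "unpleasant" and i < config.n_surgery:
                tag = "surgery"
            else:
                tag = "other"
            key = cat if tag == "other" else tag
            key = {"pleasant": "pleasant-other", "unpleasant": "unpleasant-other",
                   "neutral": "neutral"}.get(key, key)
            rows.append((sid, cat, tag, _CONTENT_AMP[key], _CONTENT_ARO[key],
                         _CONTENT_VAL[key]))
            sid += 1
    df = pd.DataFrame(rows, columns=["stimulus_id", "category", "content_tag",
                                     "true_effect", "true_arousal", "true_valence"])
    df["true_effect"] = (config.content_amp_scale * df["true_effect"]
                         + rng.normal(0, config.stim_effect_sd, len(df)))
    # Center stimulus effects: the model identifies them as deviations from 0.
    df["true_effect"] -= df["true_effect"].mean()
    df["true_arousal"] = np.clip(
        df["true_arousal"] + rng.normal(0, config.aro_stim_sd, len(df)), 1, 9)
    return df


def make_participant_profiles(config: SimulationConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Per-participant means, residual SDs, and amplitude-arousal covariance."""
    J = config.n_participants
    mean_amp = rng.normal(config.par_mean, config.par_sd, J)
    resid_sd = np.abs(rng.normal(config.resid_sd_mean, config.resid_sd_sd, J))
    resid_sd = np.maximum(resid_sd, 0.1 * config.resid_sd_mean)
    mean_aro = 5.0 + rng.normal(0, config.aro_par_sd, J)
    aro_sd = np.maximum(np.abs(rng.normal(config.aro_sd_mean, config.aro_sd_sd, J)), 0.2)
    rho = np.clip(rng.normal(config.rho_mean, config.rho_sd, J), -0.95, 0.95)
    cov = rho * resid_sd * aro_sd
    return pd.DataFrame({
        "participant_id": np.arange(1, J + 1),
        "mean_amp": mean_amp, "resid_sd": resid_sd,
        "mean_aro": mean_aro, "aro_sd": aro_sd, "amp_aro_cov": cov,
    })


def simulate_study(config: SimulationConfig, seed: int):
    """Generate stimuli, participant profiles, and per-trial latent ratings.

    Each trial's (amplitude deviation, arousal) pair is a single draw from
    the participant's bivariate normal centered at the trial's structural
    means, so the implied residual correlation is exactly the profile's
    ``amp_aro_cov / (resid_sd * aro_sd)``.

    Returns ``(stimuli, profiles, ratings, truth)`` where ``ratings`` has one
    row per participant x stimulus with integer SAM ratings (already on the
    analysis orientation: higher = more arousing / more pleasant) alongside
    the latent continuous draws.
    """
    rng = np.random.default_rng(seed)
    stimuli = make_stimulus_table(config, rng)
    profiles = make_participant_profiles(config, rng)

    J, S = len(profiles), len(stimuli)
    par_idx = np.repeat(np.arange(J), S)
    stim_idx = np.tile(np.arange(S), J)

    mu_amp = profiles["mean_amp"].to_numpy()[par_idx] + \
        stimuli["true_effect"].to_numpy()[stim_idx]
    mu_aro = (profiles["mean_aro"].to_numpy()[par_idx] - 5.0) + \
        stimuli["true_arousal"].to_numpy()[stim_idx]

    sd_a = profiles["resid_sd"].to_numpy()[par_idx]
    sd_r = profiles["aro_sd"].to_numpy()[par_idx]
    cov = profiles["amp_aro_cov"].to_numpy()[par_idx]
    # Draw correlated pair via Cholesky of each 2x2 covariance.
    z1 = rng.standard_normal(J * S)
    z2 = rng.standard_normal(J * S)
    rho = np.clip(cov / (sd_a * sd_r), -0.999, 0.999)
    amp = mu_amp + sd_a * z1
    aro_raw = mu_aro + sd_r * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)

    val_raw = stimuli["true_valence"].to_numpy()[stim_idx] + \
        rng.normal(0, config.val_noise_sd, J * S)

    ratings = pd.DataFrame({
        "participant_id": profiles["participant_id"].to_numpy()[par_idx],
        "stimulus_id": stimuli["stimulus_id"].to_numpy()[stim_idx],
        "category": stimuli["category"].to_numpy()[stim_idx],
        "content_tag": stimuli["content_tag"].to_numpy()[stim_idx],
        "amplitude": amp,
        "arousal_raw": aro_raw,
        "arousal": clip_rating(aro_raw),
        "valence": clip_rating(val_raw),
    })
    truth = GroundTruth(rng_seed=seed, stimuli=stimuli, profiles=profiles)
    return stimuli, profiles, ratings, truth


# ---------------------------------------------------------------------------
# epoch synthesis


def _oneoverf_noise(rng, shape, n_samples, srate, exponent, sd):
    """Spectrally shaped Gaussian noise, unit-variance scaled to ``sd``."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1 / srate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    scale = out.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return out / scale * sd


def _bandlimited_noise(rng, shape, n_samples, srate, band, notch=None):
    """Unit-SD Gaussian noise band-limited to ``band`` (Hz) by spectral
    masking, with an optional ``(lo, hi)`` notch.

    The notch carves the driven-frequency bin out of the endogenous
    broadband process: entrainment replaces, rather than adds to, ongoing
    activity at the flicker frequency, so category-dependent broadband
    suppression never touches the driven bin itself.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1 / srate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if notch is not None:
        mask &= ~((freqs >= notch[0]) & (freqs <= notch[1]))
    x = np.fft.irfft(spec * mask, n=n_samples, axis=-1)
    scale = x.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return x / scale


def simulate_epochs(stimuli: pd.DataFrame, profiles: pd.DataFrame, mode: str,
                    config: SimulationConfig, seed: int,
                    trial_effects: pd.DataFrame | None = None):
    """Synthesize raw multichannel epochs for every participant x stimulus.

    ``mode="scene"`` injects the centro-parietal positivity; ``mode="video"``
    injects the occipital driven tone plus arousal-suppressed broadband
    noise.  If ``trial_effects`` (the ratings table from
    :func:`simulate_study`) is given, its latent per-trial ``amplitude`` and
    ``arousal_raw`` columns drive the injected signal so measured amplitudes
    share the ratings' bivariate structure; otherwise fresh residual draws
    are used.

    Returns ``(EpochSet, GroundTruth)``.
    """
    if mode not in ("scene", "video"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    names, pos = default_montage(config.n_channels)
    srate = config.srate
    t_lo, t_hi = config.scene_window if mode == "scene" else config.video_window
    n_samples = int(round((t_hi - t_lo) * srate))
    t0 = int(round(-t_lo * srate))
    times = (np.arange(n_samples) - t0) / srate

    J, S = len(profiles), len(stimuli)
    n_trials = J * S
    par_idx = np.repeat(np.arange(J), S)
    stim_idx = np.tile(np.arange(S), J)

    meta = pd.DataFrame({
        "participant_id": profiles["participant_id"].to_numpy()[par_idx],
        "stimulus_id": stimuli["stimulus_id"].to_numpy()[stim_idx],
        "category": stimuli["category"].to_numpy()[stim_idx],
        "stimulus_type": mode,
    })

    if trial_effects is not None:
        key = meta[["participant_id", "stimulus_id"]].merge(
            trial_effects, on=["participant_id", "stimulus_id"], how="left",
            validate="one_to_one")
        if key["amplitude"].isna().any():
            raise ValueError("trial_effects missing rows for some trials")
        trial_amp = key["amplitude"].to_numpy()
        trial_aro = key["arousal_raw"].to_numpy()
    else:
        mu = profiles["mean_amp"].to_numpy()[par_idx] + \
            stimuli["true_effect"].to_numpy()[stim_idx]
        sd = profiles["resid_sd"].to_numpy()[par_idx]
        trial_amp = mu + sd * rng.standard_normal(n_trials)
        trial_aro = stimuli["true_arousal"].to_numpy()[stim_idx]

    data = _oneoverf_noise(rng, (n_trials, config.n_channels), n_samples, srate,
                           config.oneoverf_exponent, config.background_sd)
    if mode == "video" and config.baseline_noise_mult != 1.0:
        data[..., times < 0] *= config.baseline_noise_mult

    idx_lookup = {n: i for i, n in enumerate(names)}
    if mode == "scene":
        ch = np.array([idx_lookup[c] for c in LPP_CLUSTER])
        win = (times >= config.lpp_window[0] - 1e-9) & \
              (times <= config.lpp_window[1] + 1e-9)
        pulse = np.zeros(n_samples)
        pulse[win] = 1.0
        data[np.ix_(np.arange(n_trials), ch)] += \
            trial_amp[:, None, None] * pulse[None, None, :]
    else:
        ch = np.array([idx_lookup[c] for c in OCCIPITAL_CLUSTER])
        # driven-amplitude variability is attentional/anatomical, never
        # content-driven: a per-participant gain plus trial-level jitter
        par_gain = np.exp(config.tone_gain_par_sd * rng.standard_normal(J))
        trial_jitter = np.exp(config.tone_amp_cv * rng.standard_normal(n_trials)
                              - 0.5 * config.tone_amp_cv ** 2)
        tone_amp = config.tone_amp_uv * par_gain[par_idx] * trial_jitter
        tone = np.sin(2 * np.pi * config.tone_freq * times)
        bb_sd = np.maximum(
            config.bb_base_sd + config.bb_arousal_slope * (trial_aro - 5.0),
            config.bb_floor_sd)
        notch = (config.tone_freq - config.bb_notch_halfwidth,
                 config.tone_freq + config.bb_notch_halfwidth)
        bb = _bandlimited_noise(rng, (n_trials, len(ch)), n_samples, srate,
                                config.bb_band, notch=notch)
        data[np.ix_(np.arange(n_trials), ch)] += \
            tone_amp[:, None, None] * tone[None, None, :] + \
            bb_sd[:, None, None] * bb

    epochs = EpochSet(data=data, srate=srate, t0=t0, channel_names=names,
                      channel_positions=pos, trial_meta=meta)
    truth = GroundTruth(rng_seed=seed, stimuli=stimuli, profiles=profiles,
                        trial_amplitude=trial_amp,
                        extras={"trial_arousal": trial_aro, "mode": mode})
    return epochs, truth


def inject_artifacts(epochs: EpochSet, trial_rate: float, sensor_rate: float,
                     seed: int, config: SimulationConfig | None = None):
    """Contaminate a fraction of trial x channel cells with step+drift+spikes.

    ``trial_rate`` is the fraction of trials affected; within each affected
    trial, ``sensor_rate`` of channels are contaminated.  Returns a new
    :class:`EpochSet` and a :class:`GroundTruth` carrying the boolean
    ``artifact_mask`` of shape ``(n_trials, n_channels)``.
    """
    for r in (trial_rate, sensor_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    amp = (config or SimulationConfig()).artifact_amp_uv
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    mask = np.zeros((epochs.n_trials, epochs.n_channels), dtype=bool)
    n_bad_trials = int(round(trial_rate * epochs.n_trials))
    n_bad_ch = max(1, int(round(sensor_rate * epochs.n_channels))) \
        if n_bad_trials else 0
    bad_trials = rng.choice(epochs.n_trials, n_bad_trials, replace=False)
    n = epochs.n_samples
    for tr in bad_trials:
        chans = rng.choice(epochs.n_channels, n_bad_ch, replace=False)
        for c in chans:
            contam = np.zeros(n)
            step_at = rng.integers(n // 8, 7 * n // 8)
            contam[step_at:] += rng.choice([-1, 1]) * amp * 0.5
            contam += np.linspace(0, rng.choice([-1, 1]) * amp, n)
            for _ in range(3):
                s = rng.integers(0, n)
                contam[s] += rng.choice([-1, 1]) * amp
            out.data[tr, c] += contam
            mask[tr, c] = True
    truth = GroundTruth(rng_seed=seed, artifact_mask=mask)
    return out, truth


# ---------------------------------------------------------------------------
# stimulus low-level features


def frame_motion_metric(frames: np.ndarray) -> float:
    """Mean absolute frame-to-frame change in grayscale pixel brightness.

    ``frames`` is ``(n_frames, height, width)`` with values in [0, 255]; the
    result is the average over all consecutive-frame pairs and pixels of
    ``|brightness(t+1) - brightness(t)|``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least 2 frames of shape (frame, h, w)")
    if frames.min() < 0 or frames.max() > 255:
        raise ValueError("grayscale values must lie in [0, 255]")
    return float(np.abs(np.diff(frames, axis=0)).mean())


def frame_brightness(frames: np.ndarray) -> float:
    """Average grayscale pixel value (0 = black, 255 = white) over all frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.min() < 0 or frames.max() > 255:
        raise ValueError("grayscale values must lie in [0, 255]")
    return float(frames.mean())
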