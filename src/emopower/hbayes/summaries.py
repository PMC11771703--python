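"""Posterior summaries, contrasts, SNR, log-likelihoods, and R-squared.

All derived quantities are computed draw-wise, so every summary is a full
posterior (median and inner-95% credibility interval) rather than a point
estimate with a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model1 import Model1Posterior
from .model2 import Model2Posterior, conditional_params

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PosteriorSummary:
    median: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("inconsistent summary ordering")

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def summarize(draws: np.ndarray) -> PosteriorSummary:
    """Median and inner 95% of a draw array (any shape, flattened)."""
    x = np.ravel(draws)
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return PosteriorSummary(median=float(med), ci_low=float(lo), ci_high=float(hi))


def _stim_columns(post: Model1Posterior, stimulus_ids) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(post.stimuli)}
    missing = [s for s in stimulus_ids if s not in lookup]
    if missing:
        raise KeyError(f"stimuli not in posterior: {missing}")
    return np.array([lookup[s] for s in stimulus_ids])


def group_beta2_draws(post: Model1Posterior, groups: dict) -> dict:
    """Draw-wise mean stimulus effect per named group of stimulus ids."""
    out = {}
    for name, ids in groups.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"empty group {name!r}")
        out[name] = post.beta2[..., _stim_columns(post, ids)].mean(axis=-1)
    return out


def contrast_categories(post: Model1Posterior, stimuli: pd.DataFrame,
                        emotional=("pleasant", "unpleasant"),
                        neutral: str = "neutral"):
    """Category-mean posteriors and the emotional-minus-neutral difference.

    ``stimuli`` maps ``stimulus_id`` to ``category``.  Returns
    ``(summaries, diff_draws)`` where ``summaries`` has one
    :class:`PosteriorSummary` per category plus ``"emotional-neutral"`` and
    ``diff_draws`` is the draw-wise difference array.
    """
    groups = {cat: stimuli.loc[stimuli["category"] == cat, "stimulus_id"].tolist()
              for cat in stimuli["category"].unique()}
    draws = group_beta2_draws(post, groups)
    emo_ids = [sid for cat in emotional for sid in groups[cat]]
    emo = group_beta2_draws(post, {"emotional": emo_ids})["emotional"]
    diff = emo - draws[neutral]
    summaries = {k: summarize(v) for k, v in draws.items()}
    summaries["emotional-neutral"] = summarize(diff)
    return summaries, diff


def snr_posterior(post: Model1Posterior, stimuli: pd.DataFrame,
                  emotional=("pleasant", "unpleasant"), neutral: str = "neutral",
                  absolute: bool = False):
    """Per-trial signal-to-noise posterior for the emotional-neutral contrast.

    Signal is the draw-wise difference of mean stimulus effects; noise is the
    draw-wise mean single-trial residual SD (sigmaBar).  ``absolute=True``
    takes |SNR| draw-wise for cross-measure comparison when the two
    measures' effects have opposite signs.

    Returns ``(PosteriorSummary, draws)``.
    """
    _, diff = contrast_categories(post, stimuli, emotional, neutral)
    snr = diff / post.sigma_bar
    if absolute:
        snr = np.abs(snr)
    return summarize(snr), snr


def posthoc_content_split(post: Model1Posterior, stimuli: pd.DataFrame):
    """Five content-group posteriors: erotica / pleasant-other / neutral /
    unpleasant-other / surgery.  Unequal group sizes are fine; smaller groups
    simply yield wider intervals."""
    tags = set(stimuli["content_tag"].unique()) - {"other"}
    if not tags <= {"erotica", "surgery"}:
        raise ValueError(f"unknown content tags: {tags - {'erotica', 'surgery'}}")
    groups = {}
    for name, sel in (
        ("erotica", (stimuli["content_tag"] == "erotica")),
        ("pleasant-other", (stimuli["category"] == "pleasant")
         & (stimuli["content_tag"] == "other")),
        ("neutral", stimuli["category"] == "neutral"),
        ("unpleasant-other", (stimuli["category"] == "unpleasant")
         & (stimuli["content_tag"] == "other")),
        ("surgery", stimuli["content_tag"] == "surgery"),
    ):
        ids = stimuli.loc[sel, "stimulus_id"].tolist()
        if ids:
            groups[name] = ids
    draws = group_beta2_draws(post, groups)
    return {k: summarize(v) for k, v in draws.items()}, draws


def participant_distribution_draws(post: Model1Posterior,
                                   seed: int = 0) -> np.ndarray:
    """Simulated new-participant means: one Normal(ParBar, sigmaPar) draw per
    posterior draw — the estimated distribution of participants."""
    rng = np.random.default_rng(seed)
    pb = post.flat("par_bar")
    sp = post.flat("sigma_par")
    return pb + sp * rng.standard_normal(pb.shape)


# ---------------------------------------------------------------------------
# pointwise log-likelihood and R-squared


def _unit_index(values, labels) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(labels)}
    missing = sorted(set(values) - set(lookup))
    if missing:
        raise KeyError(f"trials reference unknown units: {missing[:5]}")
    return np.array([lookup[v] for v in values])


def pointwise_loglik(post, trials: pd.DataFrame) -> np.ndarray:
    """Log-likelihood of each trial under each posterior draw.

    Model 1: normal density at beta1_j + beta2_k with the participant's
    sigma_j.  Model 2: normal density at the conditional mean/variance of
    amplitude given the trial's arousal.  Returns (chain, draw, trial).
    """
    y = trials["amplitude"].to_numpy(float)
    par = _unit_index(trials["participant_id"].to_numpy(), post.participants)
    if isinstance(post, Model1Posterior):
        stim = _unit_index(trials["stimulus_id"].to_numpy(), post.stimuli)
        mu = post.beta1[..., par] + post.beta2[..., stim]
        sd = post.sigma[..., par]
        return -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - mu) / sd) ** 2
    if isinstance(post, Model2Posterior):
        aro = trials["arousal"].to_numpy(float)
        mean, var = conditional_params(
            post.mu_amp[..., par], post.mu_aro[..., par], post.s_amp[..., par],
            post.s_aro[..., par], post.s_ampaaro[..., par], aro)
        return -0.5 * _LOG2PI - 0.5 * np.log(var) - 0.5 * (y - mean) ** 2 / var
    raise TypeError(f"unsupported posterior type {type(post).__name__}")


def r2_posterior(post, trials: pd.DataFrame, predictor_only: bool = False):
    """Draw-wise per-trial variance explained.

    R^2 = var(predicted) / (var(predicted) + residual variance), where the
    residual variance is the draw-wise mean modeled trial variance.  With
    ``predictor_only`` the participant effect is removed first, leaving the
    variance explained by the predictor of interest alone (stimulus effects
    for Model 1, arousal for Model 2).

    Returns ``(PosteriorSummary, draws)``; draws have shape (chain, draw).
    """
    y = trials["amplitude"].to_numpy(float)
    if y.var() == 0:
        raise ValueError("zero total variance")
    par = _unit_index(trials["participant_id"].to_numpy(), post.participants)
    if isinstance(post, Model1Posterior):
        stim = _unit_index(trials["stimulus_id"].to_numpy(), post.stimuli)
        pred = post.beta2[..., stim] if predictor_only \
            else post.beta1[..., par] + post.beta2[..., stim]
        resid_var = (post.sigma[..., par] ** 2).mean(axis=-1)
    elif isinstance(post, Model2Posterior):
        aro = trials["arousal"].to_numpy(float)
        mean, var = conditional_params(
            post.mu_amp[..., par], post.mu_aro[..., par], post.s_amp[..., par],
            post.s_aro[..., par], post.s_ampaaro[..., par], aro)
        pred = mean - post.mu_amp[..., par] if predictor_only else mean
        resid_var = var.mean(axis=-1)
    else:
        raise TypeError(f"unsupported posterior type {type(post).__name__}")
    pred_var = pred.var(axis=-1)
    r2 = pred_var / (pred_var + resid_var)
    return summarize(r2), r2
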