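"""Multilevel participant + stimulus model of single-trial amplitudes.

Likelihood and priors::

    Amplitude_i ~ Normal(mu_i, sigma_{Par_i})
    mu_i        = beta1_{Par_i} + beta2_{Stim_i}
    beta1_j     ~ Normal(ParBar, sigmaPar)
    beta2_k     ~ Normal(0, sigmaStim)
    sigma_j     ~ Normal(sigmaBar, tau)        constrained positive
    ParBar      ~ Normal(mean(y), 2 SD(y))
    sigmaPar, sigmaStim, sigmaBar, tau ~ HalfNormal(0, 2 SD(y))

Every participant gets their own residual SD; stimulus effects are
deviations from the participant mean, partially pooled toward zero.  The
sampler Gibbs-updates all location parameters (conjugate normals) and uses
adaptive log-scale random-walk Metropolis for the five scale parameters,
including the positivity-truncation constant of the sigma_j prior in the
(sigmaBar, tau) conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mh import (ConvergenceError, StepAdapter, group_scale_move,
                  group_translate_move, halfnormal_logpdf, mh_update,
                  normal_logpdf, truncnorm_pos_lognorm)


@dataclass
class SamplerConfig:
    """MCMC settings.  The convergence contract, not the sampler, is fixed:
    any configuration passing R-hat < ``rhat_limit`` is acceptable."""

    n_chains: int = 4
    n_warmup: int = 600
    n_draws: int = 1500
    thin: int = 1              # keep every thin-th post-warmup iteration
    seed: int = 0
    check_rhat: bool = True
    rhat_limit: float = 1.01
    auto_extend: int = 2       # refits with doubled length on a failed R-hat check
    prior_mean: float | None = None    # overrides mean(amplitude)
    prior_scale: float | None = None   # overrides 2 * SD(amplitude)


@dataclass
class Model1Posterior:
    """Posterior draws, shaped ``(chain, draw[, unit])``."""

    beta1: np.ndarray          # (C, D, J) participant means, uV
    beta2: np.ndarray          # (C, D, S) stimulus deviations, uV
    sigma: np.ndarray          # (C, D, J) per-participant residual SD, uV
    par_bar: np.ndarray        # (C, D)
    sigma_par: np.ndarray
    sigma_stim: np.ndarray
    sigma_bar: np.ndarray
    tau: np.ndarray
    participants: np.ndarray   # participant_id per beta1 column
    stimuli: np.ndarray        # stimulus_id per beta2 column
    rhat_max: float | None = None
    meta: dict = field(default_factory=dict)

    def to_draw_dict(self) -> dict:
        return {
            "beta1": self.beta1, "beta2": self.beta2, "sigma": self.sigma,
            "par_bar": self.par_bar, "sigma_par": self.sigma_par,
            "sigma_stim": self.sigma_stim, "sigma_bar": self.sigma_bar,
            "tau": self.tau,
        }

    def flat(self, name: str) -> np.ndarray:
        """Draws with chains stacked: (C*D, ...)."""
        x = getattr(self, name)
        return x.reshape((-1,) + x.shape[2:])


def _prepare(trials: pd.DataFrame):
    req = {"participant_id", "stimulus_id", "amplitude"}
    if not req <= set(trials.columns):
        raise ValueError(f"trials missing columns {req - set(trials.columns)}")
    y = trials["amplitude"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite amplitudes")
    participants, par = np.unique(trials["participant_id"].to_numpy(), return_inverse=True)
    stimuli, stim = np.unique(trials["stimulus_id"].to_numpy(), return_inverse=True)
    if len(participants) < 2 or len(stimuli) < 2 or y.size < max(len(participants),
                                                                 len(stimuli)) + 1:
        raise ValueError("degenerate data: need >=2 participants, >=2 stimuli")
    return y, par, stim, participants, stimuli


def fit_model1(trials: pd.DataFrame, config: SamplerConfig | None = None) -> Model1Posterior:
    """Fit the participant + stimulus model to single-trial amplitudes.

    ``trials`` needs ``participant_id``, ``stimulus_id``, ``amplitude``
    columns.  If the R-hat convergence check fails, the fit is repeated with
    doubled warmup and draws (up to ``auto_extend`` times); a fit that still
    fails raises :class:`ConvergenceError` rather than returning silently.
    """
    from dataclasses import replace

    cfg = config or SamplerConfig()
    current = cfg
    for attempt in range(max(0, cfg.auto_extend) + 1):
        post = _sample_model1(trials, current, attempt)
        if not cfg.check_rhat:
            return post
        from ..modelcmp import rhat_max
        post.rhat_max = rhat_max(post.to_draw_dict())
        if post.rhat_max < cfg.rhat_limit:
            return post
        current = replace(current, n_warmup=2 * current.n_warmup,
                          n_draws=2 * current.n_draws)
    raise ConvergenceError(
        f"R-hat {post.rhat_max:.4f} >= {cfg.rhat_limit} after "
        f"{cfg.auto_extend + 1} attempts: chains did not converge")


def _sample_model1(trials: pd.DataFrame, cfg: SamplerConfig,
                   attempt: int = 0) -> Model1Posterior:
    y, par, stim, participants, stimuli = _prepare(trials)
    J, S, n = len(participants), len(stimuli), y.size
    n_j = np.bincount(par, minlength=J).astype(float)

    m0 = cfg.prior_mean if cfg.prior_mean is not None else float(y.mean())
    s0 = cfg.prior_scale if cfg.prior_scale is not None else 2.0 * float(y.std())
    if s0 <= 0:
        raise ValueError("prior scale must be positive (constant data?)")

    C, W, D = cfg.n_chains, cfg.n_warmup, cfg.n_draws
    store = {k: np.empty((C, D) + s) for k, s in {
        "beta1": (J,), "beta2": (S,), "sigma": (J,), "par_bar": (),
        "sigma_par": (), "sigma_stim": (), "sigma_bar": (), "tau": ()}.items()}

    emp_b1 = np.bincount(par, y, minlength=J) / np.maximum(n_j, 1)
    emp_sd = np.sqrt(np.maximum(
        np.bincount(par, (y - emp_b1[par]) ** 2, minlength=J) / np.maximum(n_j, 1),
        1e-3 * y.var() + 1e-12))

    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, c, attempt]))
        b1 = emp_b1 + 0.1 * s0 * rng.standard_normal(J)
        b2 = np.zeros(S)
        sig = emp_sd * np.exp(0.1 * rng.standard_normal(J))
        par_bar = float(b1.mean())
        sigma_par = max(float(b1.std()), 0.05 * s0)
        sigma_stim = 0.25 * s0
        sigma_bar = float(sig.mean())
        tau = max(float(sig.std()), 0.05 * sigma_bar)

        ad_sig = StepAdapter((J,), 0.3)
        ad_hyper = {k: StepAdapter((), 0.3)
                    for k in ("sigma_par", "sigma_stim", "sigma_bar", "tau",
                              "tau_group", "bar_group")}

        def collapsed_scale_lp(x, W_grp, m_grp, s2_grp, prior_scale):
            """Marginal log-posterior of a group-SD hyperparameter with the
            group effects integrated out (breaks the Gibbs funnel).

            Group g contributes residuals with precision-weighted count
            ``W_grp``, weighted sum ``m_grp`` and weighted sum of squares
            ``s2_grp``; effects are N(0, s^2) a priori.
            """
            s2 = np.exp(2 * x)
            denom = 1.0 + s2 * W_grp
            ll = -0.5 * np.log(denom) - 0.5 * (s2_grp - s2 * m_grp ** 2 / denom)
            return ll.sum() + halfnormal_logpdf(np.exp(x), prior_scale) + x

        for it in range(W + D * cfg.thin):
            warm = it < W
            w = 1.0 / sig[par] ** 2

            # stimulus-SD hyperparameter (collapsed MH: beta2 integrated out)
            r = y - b1[par]
            W_k = np.bincount(stim, w, minlength=S)
            m_k = np.bincount(stim, w * r, minlength=S)
            s2_k = np.bincount(stim, w * r * r, minlength=S)
            for _ in range(3):
                x, acc = mh_update(
                    rng, np.log(sigma_stim),
                    lambda xx: collapsed_scale_lp(xx, W_k, m_k, s2_k, s0),
                    ad_hyper["sigma_stim"].step)
                sigma_stim = float(np.exp(x))
                if warm:
                    ad_hyper["sigma_stim"].adapt(acc)

            # stimulus deviations (conjugate)
            prec_k = W_k + 1.0 / sigma_stim ** 2
            mean_k = m_k / prec_k
            b2 = mean_k + rng.standard_normal(S) / np.sqrt(prec_k)

            # participant-SD hyperparameter (collapsed MH: beta1 integrated out)
            r = y - b2[stim] - par_bar
            W_j = np.bincount(par, w, minlength=J)
            m_j = np.bincount(par, w * r, minlength=J)
            s2_j = np.bincount(par, w * r * r, minlength=J)
            for _ in range(3):
                x, acc = mh_update(
                    rng, np.log(sigma_par),
                    lambda xx: collapsed_scale_lp(xx, W_j, m_j, s2_j, s0),
                    ad_hyper["sigma_par"].step)
                sigma_par = float(np.exp(x))
                if warm:
                    ad_hyper["sigma_par"].adapt(acc)

            # participant means (conjugate)
            r = y - b2[stim]
            prec_j = W_j + 1.0 / sigma_par ** 2
            mean_j = (np.bincount(par, w * r, minlength=J)
                      + par_bar / sigma_par ** 2) / prec_j
            b1 = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)

            # grand participant mean (conjugate)
            prec = J / sigma_par ** 2 + 1.0 / s0 ** 2
            mean = (b1.sum() / sigma_par ** 2 + m0 / s0 ** 2) / prec
            par_bar = mean + rng.standard_normal() / np.sqrt(prec)

            # per-participant residual SDs (MH on log sigma_j)
            sse = np.bincount(par, (y - b1[par] - b2[stim]) ** 2, minlength=J)

            def lp_sig(x):
                s = np.exp(x)
                return (-n_j * x - sse / (2 * s ** 2)
                        + normal_logpdf(s, sigma_bar, tau) + x)

            for _ in range(2):
                x, acc = mh_update(rng, np.log(sig), lp_sig, ad_sig.step)
                sig = np.exp(x)
                if warm:
                    ad_sig.adapt(acc)

            # residual-SD hyperparameters (MH on log scale, several sweeps)
            def lp_sigma_bar(x):
                m = np.exp(x)
                return (normal_logpdf(sig, m, tau).sum()
                        - J * truncnorm_pos_lognorm(m, tau)
                        + halfnormal_logpdf(m, s0) + x)

            def lp_tau(x):
                t = np.exp(x)
                return (normal_logpdf(sig, sigma_bar, t).sum()
                        - J * truncnorm_pos_lognorm(sigma_bar, t)
                        + halfnormal_logpdf(t, s0) + x)

            for _ in range(3):
                x, acc = mh_update(rng, np.log(sigma_bar), lp_sigma_bar,
                                   ad_hyper["sigma_bar"].step)
                sigma_bar = float(np.exp(x))
                if warm:
                    ad_hyper["sigma_bar"].adapt(acc)
                x, acc = mh_update(rng, np.log(tau), lp_tau,
                                   ad_hyper["tau"].step)
                tau = float(np.exp(x))
                if warm:
                    ad_hyper["tau"].adapt(acc)

            # joint funnel moves: rescale / translate all sigma_j with their
            # hyperparameters so the sampler can traverse small-tau regions
            def sig_data_loglik(s):
                if np.any(s <= 0):
                    return -np.inf
                return float((-n_j * np.log(s) - sse / (2 * s ** 2)).sum())

            for _ in range(3):
                tau, sig, acc = group_scale_move(
                    rng, tau, sigma_bar, sig, sig_data_loglik,
                    lambda t: float(halfnormal_logpdf(t, s0)
                                    - J * truncnorm_pos_lognorm(sigma_bar, t)
                                    + np.log(t)),
                    ad_hyper["tau_group"].step)
                if warm:
                    ad_hyper["tau_group"].adapt(acc)
            sigma_bar, sig, acc = group_translate_move(
                rng, sigma_bar, sig, sig_data_loglik,
                lambda m: float(halfnormal_logpdf(m, s0)
                                - J * truncnorm_pos_lognorm(m, tau)),
                ad_hyper["bar_group"].step * max(sigma_bar, 1e-12))
            if warm:
                ad_hyper["bar_group"].adapt(acc)

            if not warm and (it - W) % cfg.thin == cfg.thin - 1:
                d = (it - W) // cfg.thin
                store["beta1"][c, d] = b1
                store["beta2"][c, d] = b2
                store["sigma"][c, d] = sig
                store["par_bar"][c, d] = par_bar
                store["sigma_par"][c, d] = sigma_par
                store["sigma_stim"][c, d] = sigma_stim
                store["sigma_bar"][c, d] = sigma_bar
                store["tau"][c, d] = tau

    return Model1Posterior(participants=participants, stimuli=stimuli,
                           meta={"prior_mean": m0, "prior_scale": s0}, **store)
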