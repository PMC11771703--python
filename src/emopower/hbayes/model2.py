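"""Multilevel bivariate amplitude-arousal model.

Each trial's (amplitude, arousal) pair comes from the participant's own
bivariate normal::

    (Amp_i, Aro_i) ~ MVNormal((muAmp_j, muAro_j), Sigma_j)
    Sigma_j = [[sAmp_j^2, sAmpAro_j], [sAmpAro_j, sAro_j^2]]

with every participant-level parameter partially pooled through normal
hyper-distributions (SDs constrained positive), the grand arousal mean given
a scaled Beta(1.1, 1.1) prior supported on the 1-9 rating range, and
amplitude-scale hyperpriors set to HalfNormal(0, 2 SD(amplitude)) /
HalfNormal(0, 4) for arousal scales.  Positive-definiteness of each
Sigma_j is enforced by rejecting proposals with non-positive determinant.

The model's predictive use is conditional: amplitude given arousal, via

    mean = muAmp + (sAmpAro / sAro^2) (aro - muAro)
    var  = sAmp^2 - sAmpAro^2 / sAro^2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mh import (ConvergenceError, StepAdapter, group_scale_move,
                  group_translate_move, halfnormal_logpdf, mh_update,
                  normal_logpdf, truncnorm_pos_lognorm)
from .model1 import SamplerConfig

_HYPERS = ("mu_amp_bar", "sigma_par_amp", "mu_aro_bar", "sigma_par_aro",
           "s_amp_bar", "tau_par_amp", "s_aro_bar", "tau_par_aro",
           "s_ampaaro_bar", "tau_ampaaro")


@dataclass
class Model2Posterior:
    """Posterior draws, shaped ``(chain, draw[, participant])``."""

    mu_amp: np.ndarray         # (C, D, J)
    mu_aro: np.ndarray         # (C, D, J)
    s_amp: np.ndarray          # (C, D, J)
    s_aro: np.ndarray          # (C, D, J)
    s_ampaaro: np.ndarray      # (C, D, J) covariance term
    hypers: dict               # name -> (C, D)
    participants: np.ndarray
    rhat_max: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        """Per-participant correlation draws, (C, D, J)."""
        return self.s_ampaaro / (self.s_amp * self.s_aro)

    def to_draw_dict(self) -> dict:
        d = {"mu_amp": self.mu_amp, "mu_aro": self.mu_aro, "s_amp": self.s_amp,
             "s_aro": self.s_aro, "s_ampaaro": self.s_ampaaro}
        d.update(self.hypers)
        return d

    def flat(self, name: str) -> np.ndarray:
        x = self.to_draw_dict()[name] if name != "rho" else self.rho
        return x.reshape((-1,) + x.shape[2:])


def _beta_arousal_logpdf(x):
    """Log-density of 1 + 8*Beta(1.1, 1.1): the grand-arousal-mean prior."""
    return stats.beta.logpdf((x - 1.0) / 8.0, 1.1, 1.1) - np.log(8.0)


def fit_model2(trials: pd.DataFrame, config: SamplerConfig | None = None) -> Model2Posterior:
    """Fit the bivariate amplitude-arousal model to single-trial data.

    ``trials`` needs ``participant_id``, ``amplitude``, ``arousal``.  On a
    failed R-hat check the fit is repeated with doubled warmup/draws (up to
    ``auto_extend`` times) before raising :class:`ConvergenceError`.
    """
    from dataclasses import replace

    cfg = config or SamplerConfig()
    current = cfg
    for attempt in range(max(0, cfg.auto_extend) + 1):
        post = _sample_model2(trials, current, attempt)
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


def _sample_model2(trials: pd.DataFrame, cfg: SamplerConfig,
                   attempt: int = 0) -> Model2Posterior:
    req = {"participant_id", "amplitude", "arousal"}
    if not req <= set(trials.columns):
        raise ValueError(f"trials missing columns {req - set(trials.columns)}")
    amp = trials["amplitude"].to_numpy(float)
    aro = trials["arousal"].to_numpy(float)
    if np.isnan(aro).any():
        raise ValueError("arousal must be present for every trial")
    participants, par = np.unique(trials["participant_id"].to_numpy(),
                                  return_inverse=True)
    J, n = len(participants), amp.size
    n_j = np.bincount(par, minlength=J).astype(float)
    if (n_j < 2).any():
        raise ValueError("every participant needs at least 2 trials")

    m0a = float(amp.mean())
    s0a = cfg.prior_scale if cfg.prior_scale is not None else 2.0 * float(amp.std())
    s0r = 4.0

    C, W, D = cfg.n_chains, cfg.n_warmup, cfg.n_draws
    store = {k: np.empty((C, D, J)) for k in
             ("mu_amp", "mu_aro", "s_amp", "s_aro", "s_ampaaro")}
    hstore = {k: np.empty((C, D)) for k in _HYPERS}

    emp_mu_a = np.bincount(par, amp, minlength=J) / n_j
    emp_mu_r = np.bincount(par, aro, minlength=J) / n_j
    emp_sa = np.sqrt(np.bincount(par, (amp - emp_mu_a[par]) ** 2, minlength=J) / n_j)
    emp_sr = np.sqrt(np.bincount(par, (aro - emp_mu_r[par]) ** 2, minlength=J) / n_j)
    emp_sa = np.maximum(emp_sa, 0.05 * amp.std() + 1e-9)
    emp_sr = np.maximum(emp_sr, 0.2)

    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, c, attempt]))
        mu_a = emp_mu_a + 0.05 * s0a * rng.standard_normal(J)
        mu_r = np.clip(emp_mu_r + 0.1 * rng.standard_normal(J), 1.0, 9.0)
        sa = emp_sa * np.exp(0.1 * rng.standard_normal(J))
        sr = emp_sr * np.exp(0.1 * rng.standard_normal(J))
        sar = np.zeros(J)
        h = {
            "mu_amp_bar": float(mu_a.mean()),
            "sigma_par_amp": max(float(mu_a.std()), 0.05 * s0a),
            "mu_aro_bar": float(np.clip(mu_r.mean(), 1.5, 8.5)),
            "sigma_par_aro": max(float(mu_r.std()), 0.1),
            "s_amp_bar": float(sa.mean()),
            "tau_par_amp": max(float(sa.std()), 0.05 * float(sa.mean())),
            "s_aro_bar": float(sr.mean()),
            "tau_par_aro": max(float(sr.std()), 0.05 * float(sr.mean())),
            "s_ampaaro_bar": 0.0,
            "tau_ampaaro": 0.1 * s0a,
        }

        ad = {k: StepAdapter((J,), 0.2) for k in ("sa", "sr", "sar",
                                                  "sa_rho", "sr_rho")}
        ad_h = {k: StepAdapter((), 0.3) for k in _HYPERS if k not in
                ("mu_amp_bar", "s_ampaaro_bar")}
        ad_g = {k: StepAdapter((), 0.3) for k in
                ("sa_scale", "sr_scale", "sar_scale", "sa_shift", "sr_shift",
                 "sar_shift", "mua_shift", "mur_shift", "mua_scale",
                 "mur_scale")}

        # fixed per-participant data sufficient statistics
        d_sa = np.bincount(par, amp, minlength=J)
        d_sr = np.bincount(par, aro, minlength=J)
        d_saa = np.bincount(par, amp * amp, minlength=J)
        d_srr = np.bincount(par, aro * aro, minlength=J)
        d_sar = np.bincount(par, amp * aro, minlength=J)

        for it in range(W + D * cfg.thin):
            warm = it < W

            # --- participant means (conjugate bivariate normal), 2x2 algebra
            det = sa ** 2 * sr ** 2 - sar ** 2
            iaa, irr, iar = sr ** 2 / det, sa ** 2 / det, -sar / det
            sum_a = np.bincount(par, amp, minlength=J)
            sum_r = np.bincount(par, aro, minlength=J)
            # precision = n_j * Sigma^-1 + diag(prior precisions)
            paa = n_j * iaa + 1.0 / h["sigma_par_amp"] ** 2
            prr = n_j * irr + 1.0 / h["sigma_par_aro"] ** 2
            par_ = n_j * iar
            ba = iaa * sum_a + iar * sum_r + h["mu_amp_bar"] / h["sigma_par_amp"] ** 2
            br = iar * sum_a + irr * sum_r + h["mu_aro_bar"] / h["sigma_par_aro"] ** 2
            pdet = paa * prr - par_ ** 2
            mean_a = (prr * ba - par_ * br) / pdet
            mean_r = (paa * br - par_ * ba) / pdet
            # sample MVN(mean, P^-1) via Cholesky of the covariance
            caa = prr / pdet
            crr = paa / pdet
            car = -par_ / pdet
            l11 = np.sqrt(caa)
            l21 = car / l11
            l22 = np.sqrt(np.maximum(crr - l21 ** 2, 1e-300))
            z1, z2 = rng.standard_normal(J), rng.standard_normal(J)
            mu_a = mean_a + l11 * z1
            mu_r = mean_r + l21 * z1 + l22 * z2

            # --- per-participant covariance components (MH)
            da = amp - mu_a[par]
            dr = aro - mu_r[par]
            s_aa = np.bincount(par, da * da, minlength=J)
            s_rr = np.bincount(par, dr * dr, minlength=J)
            s_ar = np.bincount(par, da * dr, minlength=J)

            def mvn_loglik(sa_, sr_, sar_):
                det_ = sa_ ** 2 * sr_ ** 2 - sar_ ** 2
                bad = det_ <= 0
                det_ = np.where(bad, 1.0, det_)
                ll = (-0.5 * n_j * np.log(det_)
                      - 0.5 * (sr_ ** 2 * s_aa - 2 * sar_ * s_ar
                               + sa_ ** 2 * s_rr) / det_)
                return np.where(bad, -np.inf, ll)

            def lp_sa(x):
                s = np.exp(x)
                return (mvn_loglik(s, sr, sar)
                        + normal_logpdf(s, h["s_amp_bar"], h["tau_par_amp"]) + x)

            def lp_sr(x):
                s = np.exp(x)
                return (mvn_loglik(sa, s, sar)
                        + normal_logpdf(s, h["s_aro_bar"], h["tau_par_aro"]) + x)

            def lp_sar(x):
                return (mvn_loglik(sa, sr, x)
                        + normal_logpdf(x, h["s_ampaaro_bar"], h["tau_ampaaro"]))

            for _ in range(3):
                x, acc = mh_update(rng, np.log(sa), lp_sa, ad["sa"].step)
                sa = np.exp(x)
                if warm:
                    ad["sa"].adapt(acc)
                x, acc = mh_update(rng, np.log(sr), lp_sr, ad["sr"].step)
                sr = np.exp(x)
                if warm:
                    ad["sr"].adapt(acc)
                for _ in range(2):
                    sar, acc = mh_update(rng, sar, lp_sar,
                                         ad["sar"].step * np.maximum(sa * sr, 1e-12))
                    if warm:
                        ad["sar"].adapt(acc)

                # correlation-preserving joint moves: rescale one SD together
                # with the covariance so each rho_j is invariant
                def rho_move(scale_vals, other_prior_mu, other_prior_sd,
                             which, adapter):
                    eps = adapter.step * rng.standard_normal(J)
                    new_s = scale_vals * np.exp(eps)
                    new_sar = sar * np.exp(eps)
                    if which == "sa":
                        lp0 = mvn_loglik(scale_vals, sr, sar)
                        lp1 = mvn_loglik(new_s, sr, new_sar)
                    else:
                        lp0 = mvn_loglik(sa, scale_vals, sar)
                        lp1 = mvn_loglik(sa, new_s, new_sar)
                    dprior = (normal_logpdf(new_s, other_prior_mu, other_prior_sd)
                              - normal_logpdf(scale_vals, other_prior_mu,
                                              other_prior_sd)
                              + normal_logpdf(new_sar, h["s_ampaaro_bar"],
                                              h["tau_ampaaro"])
                              - normal_logpdf(sar, h["s_ampaaro_bar"],
                                              h["tau_ampaaro"]))
                    logr = lp1 - lp0 + dprior + 2 * eps  # two log-Jacobians
                    acc_ = np.log(rng.uniform(size=J)) < logr
                    acc_ &= np.isfinite(logr)
                    return (np.where(acc_, new_s, scale_vals),
                            np.where(acc_, new_sar, sar), acc_)

                sa, sar, acc = rho_move(sa, h["s_amp_bar"], h["tau_par_amp"],
                                        "sa", ad["sa_rho"])
                if warm:
                    ad["sa_rho"].adapt(acc)
                sr, sar, acc = rho_move(sr, h["s_aro_bar"], h["tau_par_aro"],
                                        "sr", ad["sr_rho"])
                if warm:
                    ad["sr_rho"].adapt(acc)

            # --- hyperparameters
            # grand amplitude mean (conjugate)
            prec = J / h["sigma_par_amp"] ** 2 + 1.0 / s0a ** 2
            mean = (mu_a.sum() / h["sigma_par_amp"] ** 2 + m0a / s0a ** 2) / prec
            h["mu_amp_bar"] = mean + rng.standard_normal() / np.sqrt(prec)

            # grand covariance mean (conjugate: normal prior, normal likelihood)
            prec = J / h["tau_ampaaro"] ** 2 + 1.0 / s0a ** 2
            mean = (sar.sum() / h["tau_ampaaro"] ** 2) / prec
            h["s_ampaaro_bar"] = mean + rng.standard_normal() / np.sqrt(prec)

            # grand arousal mean (MH, Beta-scaled prior on (1, 9))
            def lp_mu_aro_bar(x):
                if not 1.0 < x < 9.0:
                    return -np.inf
                return (normal_logpdf(mu_r, x, h["sigma_par_aro"]).sum()
                        + _beta_arousal_logpdf(x))

            h["mu_aro_bar"], acc = mh_update(rng, h["mu_aro_bar"], lp_mu_aro_bar,
                                             ad_h["mu_aro_bar"].step)
            h["mu_aro_bar"] = float(h["mu_aro_bar"])
            if warm:
                ad_h["mu_aro_bar"].adapt(acc)

            # scale hyperparameters (MH on log scale)
            def lp_scale(x, values, center_key, prior_scale, truncated,
                         is_mean_param, other):
                s = np.exp(x)
                if is_mean_param:
                    ll = normal_logpdf(values, s, other).sum()
                    if truncated:
                        ll -= len(values) * truncnorm_pos_lognorm(s, other)
                else:
                    ll = normal_logpdf(values, other, s).sum()
                    if truncated:
                        ll -= len(values) * truncnorm_pos_lognorm(other, s)
                return ll + halfnormal_logpdf(s, prior_scale) + x

            updates = (
                ("sigma_par_amp", mu_a, s0a, False, False, h["mu_amp_bar"]),
                ("sigma_par_aro", mu_r, s0r, False, False, h["mu_aro_bar"]),
                ("s_amp_bar", sa, s0a, True, True, h["tau_par_amp"]),
                ("tau_par_amp", sa, s0a, True, False, h["s_amp_bar"]),
                ("s_aro_bar", sr, s0r, True, True, h["tau_par_aro"]),
                ("tau_par_aro", sr, s0r, True, False, h["s_aro_bar"]),
                ("tau_ampaaro", sar, s0a, False, False, h["s_ampaaro_bar"]),
            )
            for name, values, pscale, trunc, is_mean, other in updates:
                x, acc = mh_update(
                    rng, np.log(h[name]),
                    lambda xx, v=values, ps=pscale, tr=trunc, im=is_mean, ot=other:
                        lp_scale(xx, v, name, ps, tr, im, ot),
                    ad_h[name].step)
                h[name] = float(np.exp(x))
                if warm:
                    ad_h[name].adapt(acc)

            # joint funnel moves: covariance components move with their hypers
            def ll_sa(v):
                if np.any(v <= 0):
                    return -np.inf
                return float(mvn_loglik(v, sr, sar).sum())

            def ll_sr(v):
                if np.any(v <= 0):
                    return -np.inf
                return float(mvn_loglik(sa, v, sar).sum())

            def ll_sar(v):
                return float(mvn_loglik(sa, sr, v).sum())

            for _ in range(2):
                h["tau_par_amp"], sa, acc = group_scale_move(
                    rng, h["tau_par_amp"], h["s_amp_bar"], sa, ll_sa,
                    lambda t: float(halfnormal_logpdf(t, s0a)
                                    - J * truncnorm_pos_lognorm(h["s_amp_bar"], t)
                                    + np.log(t)), ad_g["sa_scale"].step)
                if warm:
                    ad_g["sa_scale"].adapt(acc)
                h["s_amp_bar"], sa, acc = group_translate_move(
                    rng, h["s_amp_bar"], sa, ll_sa,
                    lambda m: float(halfnormal_logpdf(m, s0a)
                                    - J * truncnorm_pos_lognorm(m, h["tau_par_amp"])),
                    ad_g["sa_shift"].step * max(h["s_amp_bar"], 1e-12))
                if warm:
                    ad_g["sa_shift"].adapt(acc)

                h["tau_par_aro"], sr, acc = group_scale_move(
                    rng, h["tau_par_aro"], h["s_aro_bar"], sr, ll_sr,
                    lambda t: float(halfnormal_logpdf(t, s0r)
                                    - J * truncnorm_pos_lognorm(h["s_aro_bar"], t)
                                    + np.log(t)), ad_g["sr_scale"].step)
                if warm:
                    ad_g["sr_scale"].adapt(acc)
                h["s_aro_bar"], sr, acc = group_translate_move(
                    rng, h["s_aro_bar"], sr, ll_sr,
                    lambda m: float(halfnormal_logpdf(m, s0r)
                                    - J * truncnorm_pos_lognorm(m, h["tau_par_aro"])),
                    ad_g["sr_shift"].step * max(h["s_aro_bar"], 1e-12))
                if warm:
                    ad_g["sr_shift"].adapt(acc)

            # mean-family funnel moves: grand means / spreads with mu vectors
            def ll_means(mu_a_v, mu_r_v):
                det_ = sa ** 2 * sr ** 2 - sar ** 2
                iaa_ = sr ** 2 / det_
                irr_ = sa ** 2 / det_
                iar_ = -sar / det_
                qa = d_saa - 2 * mu_a_v * d_sa + n_j * mu_a_v ** 2
                qr = d_srr - 2 * mu_r_v * d_sr + n_j * mu_r_v ** 2
                qx = d_sar - mu_a_v * d_sr - mu_r_v * d_sa + n_j * mu_a_v * mu_r_v
                return float((-0.5 * (iaa_ * qa + 2 * iar_ * qx + irr_ * qr)).sum())

            h["mu_amp_bar"], mu_a, acc = group_translate_move(
                rng, h["mu_amp_bar"], mu_a, lambda v: ll_means(v, mu_r),
                lambda m: float(normal_logpdf(m, m0a, s0a)),
                ad_g["mua_shift"].step * max(h["sigma_par_amp"], 1e-12))
            if warm:
                ad_g["mua_shift"].adapt(acc)
            h["mu_aro_bar"], mu_r, acc = group_translate_move(
                rng, h["mu_aro_bar"], mu_r, lambda v: ll_means(mu_a, v),
                lambda m: float(_beta_arousal_logpdf(m))
                if 1.0 < m < 9.0 else -np.inf,
                ad_g["mur_shift"].step * max(h["sigma_par_aro"], 1e-12))
            if warm:
                ad_g["mur_shift"].adapt(acc)
            h["sigma_par_amp"], mu_a, acc = group_scale_move(
                rng, h["sigma_par_amp"], h["mu_amp_bar"], mu_a,
                lambda v: ll_means(v, mu_r),
                lambda t: float(halfnormal_logpdf(t, s0a) + np.log(t)),
                ad_g["mua_scale"].step)
            if warm:
                ad_g["mua_scale"].adapt(acc)
            h["sigma_par_aro"], mu_r, acc = group_scale_move(
                rng, h["sigma_par_aro"], h["mu_aro_bar"], mu_r,
                lambda v: ll_means(mu_a, v),
                lambda t: float(halfnormal_logpdf(t, s0r) + np.log(t)),
                ad_g["mur_scale"].step)
            if warm:
                ad_g["mur_scale"].adapt(acc)

            for _ in range(3):
                h["tau_ampaaro"], sar, acc = group_scale_move(
                    rng, h["tau_ampaaro"], h["s_ampaaro_bar"], sar, ll_sar,
                    lambda t: float(halfnormal_logpdf(t, s0a) + np.log(t)),
                    ad_g["sar_scale"].step)
                if warm:
                    ad_g["sar_scale"].adapt(acc)
                h["s_ampaaro_bar"], sar, acc = group_translate_move(
                    rng, h["s_ampaaro_bar"], sar, ll_sar,
                    lambda m: float(normal_logpdf(m, 0.0, s0a)),
                    ad_g["sar_shift"].step * max(abs(h["s_ampaaro_bar"]),
                                                 0.1 * h["tau_ampaaro"], 1e-12))
                if warm:
                    ad_g["sar_shift"].adapt(acc)
                # conjugate refresh of the covariance-mean hyper between moves
                prec = J / h["tau_ampaaro"] ** 2 + 1.0 / s0a ** 2
                mean = (sar.sum() / h["tau_ampaaro"] ** 2) / prec
                h["s_ampaaro_bar"] = mean + rng.standard_normal() / np.sqrt(prec)

            if not warm and (it - W) % cfg.thin == cfg.thin - 1:
                d = (it - W) // cfg.thin
                store["mu_amp"][c, d] = mu_a
                store["mu_aro"][c, d] = mu_r
                store["s_amp"][c, d] = sa
                store["s_aro"][c, d] = sr
                store["s_ampaaro"][c, d] = sar
                for k in _HYPERS:
                    hstore[k][c, d] = h[k]

    return Model2Posterior(participants=participants, hypers=hstore,
                           meta={"prior_scale_amp": s0a}, **store)


def conditional_params(mu_amp, mu_aro, s_amp, s_aro, s_ampaaro, arousal):
    """Conditional mean and variance of amplitude given an arousal value.

    Implements the bivariate-normal conditioning formulas; inputs may be
    scalars or broadcastable draw arrays.
    """
    mean = mu_amp + s_ampaaro / s_aro ** 2 * (arousal - mu_aro)
    var = s_amp ** 2 - s_ampaaro ** 2 / s_aro ** 2
    return mean, var


def conditional_amplitude(post: Model2Posterior, arousal: float, participant):
    """Draw-wise conditional (mean, var) of amplitude at ``arousal``.

    Returns two arrays of shape (chain, draw) for the given participant id.
    """
    if not 1.0 <= arousal <= 9.0:
        raise ValueError("arousal must be in [1, 9]")
    j = int(np.flatnonzero(post.participants == participant)[0])
    return conditional_params(
        post.mu_amp[..., j], post.mu_aro[..., j], post.s_amp[..., j],
        post.s_aro[..., j], post.s_ampaaro[..., j], arousal)
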