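"""Shared Metropolis-within-Gibbs machinery.

Location parameters in both hierarchical models have conjugate normal full
conditionals and are Gibbs-sampled exactly; scale parameters use adaptive
random-walk Metropolis on the log scale (with the log-Jacobian folded into
the target), adapted toward a 0.44 acceptance rate during warmup only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

_TARGET_ACCEPT = 0.44


def halfnormal_logpdf(x, scale):
    """Log-density of HalfNormal(0, scale), up to a constant in ``scale``.

    The scale never varies within a single MH update that uses this prior,
    so constants in ``scale`` are kept for clarity but not required.
    """
    x = np.asarray(x, float)
    out = np.where(x > 0, -0.5 * (x / scale) ** 2 - np.log(scale), -np.inf)
    return out


def normal_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def truncnorm_pos_lognorm(mu, sd):
    """log P(X > 0) for X ~ Normal(mu, sd): the positivity-truncation constant."""
    return log_ndtr(mu / sd)


def mh_update(rng, x, logpost, step):
    """One vectorized random-walk MH move.

    ``logpost`` must evaluate elementwise (each component's full conditional
    independent of the others' proposals).  Returns ``(new_x, accepted)``.
    """
    x = np.asarray(x, float)
    prop = x + step * rng.standard_normal(x.shape if x.shape else None)
    lp0 = np.asarray(logpost(x), float)
    lp1 = np.asarray(logpost(prop), float)
    with np.errstate(invalid="ignore"):
        accept = np.log(rng.uniform(size=x.shape if x.shape else None)) < lp1 - lp0
    accept = np.asarray(accept) & np.isfinite(lp1)
    return np.where(accept, prop, x), accept


class StepAdapter:
    """Robbins-Monro step-size adaptation toward 0.44 acceptance."""

    def __init__(self, shape=(), init: float = 0.5):
        self.log_step = np.full(shape, np.log(init))
        self.t = 0

    @property
    def step(self):
        return np.exp(self.log_step)

    def adapt(self, accepted):
        self.t += 1
        gamma = min(0.5, 2.0 / np.sqrt(self.t))
        self.log_step = self.log_step + gamma * (
            np.asarray(accepted, float) - _TARGET_ACCEPT)


def group_scale_move(rng, tau, center, values, data_loglik, log_prior_extra, step):
    """Joint funnel move: rescale group deviations together with their SD.

    Proposes ``tau' = tau * e^eps`` and ``values' = center + (values -
    center) * e^eps``.  The group-prior standardized residuals are invariant
    and the ``-n log tau`` prior term cancels against the Jacobian, so the
    acceptance ratio only involves the data log-likelihood of the rescaled
    values plus ``log_prior_extra`` (hyperprior on tau, truncation constants,
    and the log-Jacobian of the log-tau parameterization).
    """
    eps = step * rng.standard_normal()
    new_tau = tau * np.exp(eps)
    new_values = center + (values - center) * np.exp(eps)
    lp0 = data_loglik(values) + log_prior_extra(tau)
    lp1 = data_loglik(new_values) + log_prior_extra(new_tau)
    if np.isfinite(lp1) and np.log(rng.uniform()) < lp1 - lp0:
        return new_tau, new_values, True
    return tau, values, False


def group_translate_move(rng, center, values, data_loglik, log_prior_extra, step):
    """Joint funnel move: shift group values together with their mean.

    Proposes ``center' = center + delta`` and ``values' = values + delta``;
    standardized deviations are invariant, so only the data log-likelihood
    and ``log_prior_extra`` (hyperprior on center plus truncation constants)
    enter the ratio.
    """
    delta = step * rng.standard_normal()
    lp0 = data_loglik(values) + log_prior_extra(center)
    lp1 = data_loglik(values + delta) + log_prior_extra(center + delta)
    if np.isfinite(lp1) and np.log(rng.uniform()) < lp1 - lp0:
        return center + delta, values + delta, True
    return center, values, False


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat convergence contract."""
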