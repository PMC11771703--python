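"""Convergence diagnostics and cross-validation model comparison.

R-hat (rank-normalized split between/within-chain variance ratio) and
PSIS-LOO (Pareto-smoothed importance-sampling leave-one-out, 20% tail
generalized-Pareto smoothing) are delegated to arviz — the reference
implementations of both.  Expected log pointwise predictive density (ELPD)
differences and cross-validation stacking weights are computed here; the
stacking weights maximize the combined leave-one-out predictive density
over the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az


@dataclass
class LooResult:
    elpd: float                 # sum of pointwise elpd
    se: float                   # sqrt(n * var(pointwise))
    pointwise_elpd: np.ndarray  # per trial
    pareto_k: np.ndarray        # per trial

    @property
    def n(self) -> int:
        return self.pointwise_elpd.size


@dataclass
class StackingWeights:
    weights: np.ndarray
    degenerate: bool = False    # models indistinguishable; uniform returned


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of one parameter's (chain, draw) draws.

    Chains that are all identical and constant carry no mixing information
    and are treated as converged (R-hat 1).
    """
    x = np.asarray(draws, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chain, draw) with >=2 chains and >=4 draws")
    if np.ptp(x) == 0:
        return 1.0
    return float(az.rhat(x))


def rhat_max(draw_dict: dict) -> float:
    """Largest R-hat over every scalar component of a dict of (chain, draw[, unit])
    draw arrays (the convergence gate for a whole fit)."""
    worst = 1.0
    for name, x in draw_dict.items():
        x = np.asarray(x, float)
        if x.ndim == 2:
            x = x[..., None]
        for idx in range(x.shape[-1]):
            worst = max(worst, rhat(x[..., idx]))
    return worst


def psis_loo(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    ``loglik`` is (chain, draw, trial) or (draw, trial) (treated as one
    chain).  Importance ratios per trial are smoothed by a generalized
    Pareto fit to the upper 20% tail; the Pareto shape k is reported per
    trial.  Degenerate trials whose log-likelihood is constant across draws
    are exact: their pointwise elpd is that constant.
    """
    ll = np.asarray(loglik, float)
    if ll.ndim == 2:
        ll = ll[None]
    if ll.ndim != 3:
        raise ValueError("loglik must be (chain, draw, trial) or (draw, trial)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihoods")
    n_draws_total = ll.shape[0] * ll.shape[1]
    flat = ll.reshape(n_draws_total, -1)
    const = np.ptp(flat, axis=0) == 0
    if const.all():
        pointwise = flat[0]
        return LooResult(elpd=float(pointwise.sum()),
                         se=float(np.sqrt(pointwise.size * pointwise.var())),
                         pointwise_elpd=pointwise,
                         pareto_k=np.zeros(pointwise.size))
    idata = az.from_dict(posterior={"_": np.zeros(ll.shape[:2])},
                         log_likelihood={"y": ll})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pointwise = np.asarray(res.loo_i.values, float)
    k = np.asarray(res.pareto_k.values, float)
    # exact-case trials: importance weights are uniform
    if const.any():
        pointwise = pointwise.copy()
        pointwise[const] = flat[0, const]
        k[const] = 0.0
    return LooResult(elpd=float(pointwise.sum()),
                     se=float(np.sqrt(pointwise.size * pointwise.var())),
                     pointwise_elpd=pointwise, pareto_k=k)


def elpd_diff(a: LooResult, b: LooResult):
    """Pairwise ELPD difference (a - b) with its pointwise-based SE."""
    if a.n != b.n:
        raise ValueError("LooResults cover different numbers of trials")
    d = a.pointwise_elpd - b.pointwise_elpd
    return float(d.sum()), float(np.sqrt(d.size * d.var()))


def stacking_weights(loo_results: list, tol: float = 1e-6) -> StackingWeights:
    """Cross-validation stacking weights over >=2 models.

    Maximizes ``sum_i log sum_m w_m exp(elpd_i,m)`` over the simplex via an
    unconstrained softmax parameterization.  If the models' pointwise elpds
    are indistinguishable the objective is flat: uniform weights are
    returned with ``degenerate=True``.
    """
    if len(loo_results) < 2:
        raise ValueError("need at least 2 models")
    n = loo_results[0].n
    if any(r.n != n for r in loo_results):
        raise ValueError("models evaluated on different trials")
    L = np.stack([r.pointwise_elpd for r in loo_results], axis=1)  # (n, M)
    M = L.shape[1]
    if np.ptp(L - L[:, :1], axis=1).max() < tol:
        return StackingWeights(weights=np.full(M, 1.0 / M), degenerate=True)

    Lc = L - L.max(axis=1, keepdims=True)  # stabilize

    def neg_obj(theta):
        w_log = np.concatenate([theta, [0.0]])
        w_log = w_log - logsumexp(w_log)
        return -np.sum(logsumexp(Lc + w_log, axis=1))

    best = None
    for x0 in (np.zeros(M - 1), np.full(M - 1, 2.0), np.full(M - 1, -2.0)):
        res = minimize(neg_obj, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    w_log = np.concatenate([best.x, [0.0]])
    w = np.exp(w_log - logsumexp(w_log))
    w = np.maximum(w, 0)
    w /= w.sum()
    return StackingWeights(weights=w)
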