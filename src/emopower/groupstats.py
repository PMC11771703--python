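"""Frequentist group-level statistics.

Repeated-measures ANOVAs (sphericity assumed, uncorrected degrees of
freedom), paired t-tests with Cohen's D, by-stimulus Pearson correlations,
and the stimulus-type x arousal interaction regression.  Partial eta squared
is derived from the F statistic as ``F * df_num / (F * df_num + df_den)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
import statsmodels.formula.api as smf


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


def _partial_eta_sq(F: float, df_num: float, df_den: float) -> float:
    return F * df_num / (F * df_num + df_den)


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> list[AnovaResult]:
    """Repeated-measures ANOVA with one or two within-participant factors.

    ``data`` is long-format with one row per subject x cell (a complete,
    balanced design).  Returns main effects and, for two factors, the
    interaction, with uncorrected (sphericity-assumed) dfs.
    """
    if len(within) not in (1, 2):
        raise ValueError("design must have 1 or 2 within factors")
    cells = data.groupby([subject] + within).size()
    if (cells != 1).any():
        raise ValueError("design must have exactly one value per subject x cell")
    res = AnovaRM(data, depvar=dv, subject=subject, within=within).fit()
    tbl = res.anova_table
    out = []
    for effect, row in tbl.iterrows():
        F, dfn, dfd = row["F Value"], row["Num DF"], row["Den DF"]
        p = row["Pr > F"]
        # a degenerate cell (zero effect and zero error variance) can yield
        # numerical junk; F is non-negative by definition
        if not np.isfinite(F) or F < 0:
            F, p = 0.0, 1.0
        out.append(AnovaResult(effect=effect, F=float(F), df_num=float(dfn),
                               df_den=float(dfd), p=float(p),
                               partial_eta_sq=_partial_eta_sq(F, dfn, dfd)))
    return out


def paired_t(x, y):
    """Two-sided paired t-test with Cohen's D = mean(diff)/SD(diff).

    Returns ``(t, df, p, cohens_d)``.  With this D convention and n pairs,
    ``D == t / sqrt(n)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length paired vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    cohens_d = d.mean() / sd
    return float(res.statistic), int(x.size - 1), float(res.pvalue), float(cohens_d)


def stimulus_correlation(stim_z, arousal_means):
    """Pearson correlation (r, two-sided p) of per-stimulus z vs mean arousal."""
    x = np.asarray(arousal_means, float)
    y = np.asarray(stim_z, float)
    if x.size < 3:
        raise ValueError("need at least 3 stimuli")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def arousal_interaction_model(stim_table: pd.DataFrame) -> AnovaResult:
    """Test whether the arousal slope differs between the two EEG measures.

    ``stim_table`` has one row per stimulus x measure with columns ``z``
    (per-stimulus participant-averaged z-score, sign-aligned so that higher
    means larger response), ``arousal`` and ``measure``.  Fits
    ``z ~ arousal * measure`` by OLS and returns the interaction F-test.
    """
    counts = stim_table["measure"].value_counts()
    if len(counts) != 2 or counts.nunique() != 1:
        raise ValueError("need two measures with equal stimulus counts")
    fit = smf.ols("z ~ arousal * C(measure)", data=stim_table).fit()
    name = [t for t in fit.params.index if t.startswith("arousal:")][0]
    dfn, dfd = 1.0, float(fit.df_resid)
    if fit.ssr <= 1e-12 * max(float(stim_table["z"].var()), 1e-30) * len(stim_table):
        # perfect deterministic fit: no residual variance, no interaction test
        F = 0.0
        return AnovaResult(effect="arousal x measure", F=F, df_num=dfn,
                           df_den=dfd, p=1.0, partial_eta_sq=0.0)
    t_val = fit.tvalues[name]
    F = float(t_val ** 2)
    return AnovaResult(effect="arousal x measure", F=F, df_num=dfn, df_den=dfd,
                       p=float(fit.pvalues[name]),
                       partial_eta_sq=_partial_eta_sq(F, dfn, dfd))
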