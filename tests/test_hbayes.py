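"""Hierarchical model fits, posterior operations, and calibration checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emopower.hbayes import (ConvergenceError, SamplerConfig,
                             conditional_amplitude, conditional_params,
                             contrast_categories, fit_model1, fit_model2,
                             participant_distribution_draws, pointwise_loglik,
                             posthoc_content_split, r2_posterior, snr_posterior,
                             summarize)

from conftest import model1_dataset, model2_dataset

FAST = dict(n_chains=2, n_warmup=300, n_draws=400, check_rhat=False)


@pytest.fixture(scope="module")
def fitted_model1():
    trials, truth = model1_dataset(seed=1)
    post = fit_model1(trials, SamplerConfig(seed=1, **FAST))
    return trials, truth, post


@pytest.fixture(scope="module")
def fitted_model2():
    trials = model2_dataset(seed=1)
    post = fit_model2(trials, SamplerConfig(seed=1, **FAST))
    return trials, post


def _stim_table(S):
    cats = np.array(["pleasant"] * (S // 3) + ["neutral"] * (S // 3)
                    + ["unpleasant"] * (S - 2 * (S // 3)))
    return pd.DataFrame({"stimulus_id": np.arange(1, S + 1), "category": cats,
                         "content_tag": ["other"] * S})


class TestModel1Fit:
    def test_recovers_stimulus_effects(self, fitted_model1):
        trials, truth, post = fitted_model1
        med = np.median(post.flat("beta2"), axis=0)
        assert np.corrcoef(med, truth["beta2"])[0, 1] > 0.8

    def test_shrinkage_of_extreme_stimulus(self, fitted_model1):
        """Partial pooling pulls raw stimulus means toward zero."""
        trials, truth, post = fitted_model1
        raw_dev = (trials.groupby("stimulus_id")["amplitude"].mean()
                   - trials["amplitude"].mean()).loc[post.stimuli].to_numpy()
        med = np.median(post.flat("beta2"), axis=0)
        extreme = np.argmax(np.abs(raw_dev))
        assert abs(med[extreme]) < abs(raw_dev[extreme])

    def test_null_effects_covered_by_intervals(self):
        """With no true stimulus effects, at least 90% of the 95% intervals
        contain zero."""
        trials, truth = model1_dataset(seed=3, sigma_stim=1e-6, sigma_bar=1.0,
                                       tau=0.2)
        post = fit_model1(trials, SamplerConfig(seed=3, **FAST))
        b2 = post.flat("beta2")
        lo, hi = np.percentile(b2, [2.5, 97.5], axis=0)
        assert ((lo <= 0) & (0 <= hi)).mean() >= 0.9

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_model1(pd.DataFrame({"participant_id": [1], "stimulus_id": [1],
                                     "amplitude": [1.0]}))

    def test_convergence_contract_enforced(self):
        """An absurdly short run must raise rather than return silently."""
        trials, _ = model1_dataset(seed=4)
        with pytest.raises(ConvergenceError):
            fit_model1(trials, SamplerConfig(seed=4, n_chains=2, n_warmup=3,
                                             n_draws=8, auto_extend=0))

    def test_simulation_based_calibration_of_grand_mean(self):
        """Rank of the true grand participant mean among posterior draws is
        uniform when data are generated from the model's own prior draw."""
        n_rep, n_ranks = 60, 10
        ranks = np.zeros(n_rep, dtype=int)
        rng = np.random.default_rng(99)
        for rep in range(n_rep):
            # prior draw with fixed hyper-prior scales
            par_bar = rng.normal(0.0, 2.0)
            sigma_par = abs(rng.normal(0.0, 2.0))
            sigma_stim = abs(rng.normal(0.0, 2.0))
            sigma_bar = abs(rng.normal(0.0, 2.0))
            tau = abs(rng.normal(0.0, 2.0))
            J, S = 5, 6
            b1 = rng.normal(par_bar, sigma_par, J)
            b2 = rng.normal(0, sigma_stim, S)
            sig = np.abs(stats.truncnorm.rvs(-sigma_bar / max(tau, 1e-9), np.inf,
                                             loc=sigma_bar, scale=max(tau, 1e-9),
                                             size=J, random_state=rng))
            par = np.repeat(np.arange(J), S)
            stim = np.tile(np.arange(S), J)
            y = b1[par] + b2[stim] + sig[par] * rng.standard_normal(J * S)
            trials = pd.DataFrame({"participant_id": par + 1,
                                   "stimulus_id": stim + 1, "amplitude": y})
            post = fit_model1(trials, SamplerConfig(
                seed=1000 + rep, n_chains=1, n_warmup=250, n_draws=270,
                check_rhat=False, prior_mean=0.0, prior_scale=4.0))
            draws = post.flat("par_bar")[::30][:n_ranks - 1]  # thinned draws
            ranks[rep] = int((draws < par_bar).sum())
        counts = np.bincount(ranks, minlength=n_ranks)
        chi2 = ((counts - n_rep / n_ranks) ** 2 / (n_rep / n_ranks)).sum()
        assert stats.chi2.sf(chi2, n_ranks - 1) > 0.01


class TestContrasts:
    def test_identical_groups_center_difference_at_zero(self):
        trials, truth = model1_dataset(seed=5, sigma_stim=1e-6)
        post = fit_model1(trials, SamplerConfig(seed=5, **FAST))
        stim = _stim_table(len(post.stimuli))
        summaries, diff = contrast_categories(post, stim)
        assert summaries["emotional-neutral"].contains(0.0)

    def test_injected_group_difference_recovered(self):
        trials, truth = model1_dataset(seed=6, sigma_stim=1e-6, sigma_bar=1.0,
                                       tau=0.1)
        stim = _stim_table(30)
        shift = trials["stimulus_id"].map(
            dict(zip(stim["stimulus_id"],
                     stim["category"].map({"pleasant": 1.0, "neutral": -1.0,
                                           "unpleasant": 1.0}))))
        trials = trials.assign(amplitude=trials["amplitude"] + shift)
        post = fit_model1(trials, SamplerConfig(seed=6, **FAST))
        summaries, diff = contrast_categories(post, stim)
        assert summaries["emotional-neutral"].median == pytest.approx(2.0, abs=0.5)
        assert not summaries["emotional-neutral"].contains(0.0)

    def test_contrast_antisymmetry(self, fitted_model1):
        trials, truth, post = fitted_model1
        stim = _stim_table(len(post.stimuli))
        _, ab = contrast_categories(post, stim, emotional=("pleasant",),
                                    neutral="neutral")
        _, ba = contrast_categories(post, stim, emotional=("neutral",),
                                    neutral="pleasant")
        assert np.allclose(ab, -ba)


class TestSnr:
    def test_signal_over_noise_ratio_of_knowns(self):
        """Injected 2 uV contrast over 8 uV residual noise gives |SNR| about
        0.25.  Effects follow a deterministic pattern so the true contrast is
        exactly 2, and the cohort is large enough that stimulus-mean
        shrinkage is mild."""
        rng = np.random.default_rng(7)
        J, S = 150, 30
        stim = _stim_table(S)
        cat_shift = stim["category"].map({"pleasant": 1.0, "neutral": -1.0,
                                          "unpleasant": 1.0}).to_numpy()
        pattern = np.tile(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), S // 5)
        b2 = cat_shift + 2.0 * pattern / pattern.std()   # spread 2, known means
        par = np.repeat(np.arange(J), S)
        stim_idx = np.tile(np.arange(S), J)
        y = b2[stim_idx] + 8.0 * rng.standard_normal(J * S)
        trials = pd.DataFrame({"participant_id": par + 1,
                               "stimulus_id": stim_idx + 1, "amplitude": y})
        post = fit_model1(trials, SamplerConfig(seed=7, **FAST))
        summ, _ = snr_posterior(post, stim, absolute=True)
        assert summ.median == pytest.approx(0.25, abs=0.05)

    def test_self_contrast_is_exactly_zero(self, fitted_model1):
        trials, truth, post = fitted_model1
        stim = _stim_table(len(post.stimuli))
        _, snr = snr_posterior(post, stim, emotional=("neutral",),
                               neutral="neutral")
        assert np.all(snr == 0.0)


class TestPosthocSplit:
    def test_all_other_tags_reduce_to_three_groups(self, fitted_model1):
        trials, truth, post = fitted_model1
        stim = _stim_table(len(post.stimuli))
        summaries, draws = posthoc_content_split(post, stim)
        assert set(summaries) == {"pleasant-other", "neutral", "unpleasant-other"}

    def test_erotica_boost_separates_from_other_pleasant(self):
        trials, truth = model1_dataset(seed=8, sigma_stim=0.3, sigma_bar=1.0,
                                       tau=0.1)
        stim = _stim_table(30)
        stim.loc[:3, "content_tag"] = "erotica"  # 4 pleasant stimuli boosted
        boost = trials["stimulus_id"].map(
            dict(zip(stim["stimulus_id"],
                     np.where(stim["content_tag"] == "erotica", 3.0, 0.0))))
        trials = trials.assign(amplitude=trials["amplitude"] + boost)
        post = fit_model1(trials, SamplerConfig(seed=8, **FAST))
        summaries, _ = posthoc_content_split(post, stim)
        assert summaries["erotica"].ci_low > summaries["pleasant-other"].ci_high

    def test_smaller_group_wider_interval(self):
        trials, truth = model1_dataset(seed=9, sigma_stim=1e-6, sigma_bar=2.0,
                                       tau=0.2)
        stim = _stim_table(30)
        stim.loc[:1, "content_tag"] = "erotica"     # 2 stimuli
        post = fit_model1(trials, SamplerConfig(seed=9, **FAST))
        summaries, _ = posthoc_content_split(post, stim)
        width = lambda s: s.ci_high - s.ci_low  # noqa: E731
        assert width(summaries["erotica"]) > width(summaries["neutral"])


class TestModel2:
    def test_null_covariance_recovered(self):
        trials = model2_dataset(seed=2, rho=0.0)
        post = fit_model2(trials, SamplerConfig(seed=2, **FAST))
        hyper = post.flat("s_ampaaro_bar")
        lo, hi = np.percentile(hyper, [2.5, 97.5])
        assert lo <= 0.0 <= hi

    def test_common_correlation_recovered_with_shrinkage(self, fitted_model2):
        trials, post = fitted_model2
        med = np.median(post.flat("rho"), axis=0)
        assert (np.abs(med - (-0.5)) <= 0.15).mean() >= 0.8

    def test_fewer_trials_widen_correlation_interval(self):
        trials = model2_dataset(seed=4, J=8, n_per=90)
        few = trials[trials["participant_id"] == 1].iloc[:3]
        trials = pd.concat([trials[trials["participant_id"] != 1], few])
        post = fit_model2(trials, SamplerConfig(seed=4, **FAST))
        rho = post.flat("rho")
        widths = np.percentile(rho, 97.5, axis=0) - np.percentile(rho, 2.5, axis=0)
        j_few = int(np.flatnonzero(post.participants == 1)[0])
        assert widths[j_few] > np.delete(widths, j_few).max() * 0.99

    def test_missing_arousal_rejected(self):
        trials = model2_dataset(seed=5).astype({"arousal": float})
        trials.loc[trials.index[0], "arousal"] = np.nan
        with pytest.raises(ValueError):
            fit_model2(trials, SamplerConfig(**FAST))


class TestConditionalFormulas:
    def test_independence_limit(self):
        mean, var = conditional_params(2.0, 5.0, 3.0, 1.5, 0.0, arousal=8.0)
        assert mean == 2.0
        assert var == 9.0

    def test_perfect_correlation_limit(self):
        sd_a, sd_r = 3.0, 1.5
        cov = sd_a * sd_r * 0.9999
        _, var = conditional_params(0.0, 5.0, sd_a, sd_r, cov, arousal=6.0)
        assert var < 0.01 * sd_a ** 2

    def test_matches_grid_conditioning_oracle(self):
        """Brute-force numerical conditioning of a discretized bivariate
        normal agrees with the closed-form conditional mean and variance."""
        mu = np.array([1.3, 4.2])
        sd_a, sd_r, rho = 2.0, 1.4, -0.55
        cov = rho * sd_a * sd_r
        Sigma = np.array([[sd_a ** 2, cov], [cov, sd_r ** 2]])
        a_grid = np.linspace(mu[0] - 8 * sd_a, mu[0] + 8 * sd_a, 4001)
        for aro in (2.0, 4.5, 7.0):
            x = np.stack([a_grid, np.full_like(a_grid, aro)], axis=1)
            dens = stats.multivariate_normal(mu, Sigma).pdf(x)
            dens /= dens.sum()
            grid_mean = (a_grid * dens).sum()
            grid_var = ((a_grid - grid_mean) ** 2 * dens).sum()
            mean, var = conditional_params(mu[0], mu[1], sd_a, sd_r, cov, aro)
            assert abs(mean - grid_mean) < 1e-3
            assert abs(var - grid_var) < 1e-3

    def test_conditional_amplitude_validates_scale(self, fitted_model2):
        trials, post = fitted_model2
        with pytest.raises(ValueError):
            conditional_amplitude(post, 12.0, participant=1)
        mean, var = conditional_amplitude(post, 6.0, participant=1)
        assert mean.shape == post.mu_amp.shape[:2]
        assert np.all(var > 0)


class TestPointwiseLoglik:
    def test_closed_form_at_the_mode(self, fitted_model1):
        trials, truth, post = fitted_model1
        ll = pointwise_loglik(post, trials)
        # place one synthetic trial exactly at a draw's predicted mean
        c, d, i = 0, 0, 0
        pid = trials["participant_id"].iloc[i]
        sid = trials["stimulus_id"].iloc[i]
        j = int(np.flatnonzero(post.participants == pid)[0])
        k = int(np.flatnonzero(post.stimuli == sid)[0])
        mu = post.beta1[c, d, j] + post.beta2[c, d, k]
        sd = post.sigma[c, d, j]
        t_at_mode = trials.iloc[[i]].assign(amplitude=mu)
        ll_mode = pointwise_loglik(post, t_at_mode)[c, d, 0]
        assert ll_mode == pytest.approx(-np.log(sd * np.sqrt(2 * np.pi)))
        assert ll[c, d, i] <= ll_mode + 1e-12

    def test_additivity_against_whole_dataset_evaluation(self, fitted_model1):
        trials, truth, post = fitted_model1
        ll = pointwise_loglik(post, trials)
        c, d = 1, 5
        pid = {p: i for i, p in enumerate(post.participants)}
        sid = {s: i for i, s in enumerate(post.stimuli)}
        total = 0.0
        for _, row in trials.iterrows():
            mu = post.beta1[c, d, pid[row.participant_id]] + \
                post.beta2[c, d, sid[row.stimulus_id]]
            sd = post.sigma[c, d, pid[row.participant_id]]
            total += stats.norm.logpdf(row.amplitude, mu, sd)
        assert abs(ll[c, d].sum() - total) < 1e-8

    def test_unknown_participant_rejected(self, fitted_model1):
        trials, truth, post = fitted_model1
        bad = trials.iloc[[0]].assign(participant_id=999)
        with pytest.raises(KeyError):
            pointwise_loglik(post, bad)


class TestR2:
    def test_draws_bounded_in_unit_interval(self, fitted_model1):
        trials, truth, post = fitted_model1
        _, r2 = r2_posterior(post, trials)
        assert np.all((r2 >= 0) & (r2 <= 1))

    def test_pure_noise_fit_near_zero(self):
        rng = np.random.default_rng(12)
        J, S = 10, 30
        par = np.repeat(np.arange(J), S)
        stim = np.tile(np.arange(S), J)
        trials = pd.DataFrame({"participant_id": par + 1, "stimulus_id": stim + 1,
                               "amplitude": rng.standard_normal(J * S)})
        post = fit_model1(trials, SamplerConfig(seed=12, **FAST))
        summ, _ = r2_posterior(post, trials)
        assert summ.median < 0.05

    def test_low_noise_fit_near_one(self):
        trials, truth = model1_dataset(seed=13, sigma_bar=0.1, tau=0.01)
        post = fit_model1(trials, SamplerConfig(seed=13, **FAST))
        summ, _ = r2_posterior(post, trials)
        assert summ.median > 0.95

    def test_predictor_only_is_smaller_than_full(self, fitted_model1):
        trials, truth, post = fitted_model1
        full, _ = r2_posterior(post, trials)
        pred, _ = r2_posterior(post, trials, predictor_only=True)
        assert pred.median < full.median

    def test_model2_r2_defined(self, fitted_model2):
        trials, post = fitted_model2
        summ, r2 = r2_posterior(post, trials)
        assert np.all((r2 >= 0) & (r2 <= 1))


class TestParticipantDistribution:
    def test_law_of_total_variance(self, fitted_model1):
        trials, truth, post = fitted_model1
        draws = participant_distribution_draws(post, seed=3)
        pb = post.flat("par_bar")
        sp = post.flat("sigma_par")
        expected_var = (sp ** 2).mean() + pb.var()
        assert draws.var() == pytest.approx(expected_var, rel=0.05)
        assert draws.mean() == pytest.approx(
            pb.mean(), abs=2 * draws.std() / np.sqrt(draws.size) + 0.05)


def test_summary_ordering_invariant(fitted_model1):
    _, _, post = fitted_model1
    s = summarize(post.flat("par_bar"))
    assert s.ci_low <= s.median <= s.ci_high
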