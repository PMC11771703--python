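"""End-to-end pipeline: simulate -> screen -> measure -> stats -> models.

A :class:`PipelineConfig` (optionally loaded from YAML; unknown keys are
rejected) drives every stage.  Outputs are CSV tables plus a line-oriented
log; every table carries the config hash and master seed, so a re-run with
the same config reproduces every deterministic artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import artifacts as art
from . import groupstats, hbayes, measures, modelcmp, sigproc, synthgen
from .synthgen import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    artifact_trial_rate: float = 0.05
    artifact_sensor_rate: float = 0.05
    screening: dict = field(default_factory=dict)    # ScadsThresholds overrides
    sampler: dict = field(default_factory=dict)      # hbayes.SamplerConfig overrides
    skip_bayes: bool = False
    bands: dict = field(default_factory=lambda: {
        "7.5_bin": (7.5, 7.5), "7-8": (7.0, 8.0), "3-10": (3.0, 10.0)})

    # Desk-scale defaults: the full study geometry (45 participants x 90
    # stimuli x 128 channels) is available by overriding `simulation`.
    _SIM_DEFAULTS = {"n_participants": 12, "n_stimuli": 30, "n_erotica": 3,
                     "n_surgery": 2, "n_channels": 24}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        params = {**self._SIM_DEFAULTS, **self.simulation}
        return SimulationConfig(**params)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int):
    out = df.copy()
    out["config_hash"] = cfg_hash
    out["seed"] = seed
    out.to_csv(path, index=False)


def _preprocess(epochs, mode, thresholds):
    scores = art.scads_scores(epochs)
    clean, rejection = art.reject_and_interpolate(epochs, scores, thresholds)
    clean = sigproc.filter_epochs(clean, sigproc.LOWPASS_30)
    if mode == "scene":
        clean = sigproc.filter_epochs(clean, sigproc.HIGHPASS_LPP)
    else:
        clean = sigproc.filter_epochs(clean, sigproc.HIGHPASS_VIDEO)
    clean = art.average_reference(clean)
    if mode == "scene":
        clean = art.baseline_correct(clean, (-0.1, 0.0))
    return clean, rejection


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full chain and write the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seed = config.seed
    log_path = out / "log.txt"
    log_lines = []
    t_start = time.monotonic()

    def log(msg):
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        log_lines.append(f"{stamp} [{time.monotonic() - t_start:8.2f}s] {msg}")

    def run_stage(name, fn):
        log(f"stage {name}: start")
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - report stage and cause
            log(f"stage {name}: FAILED: {e}")
            log_path.write_text("\n".join(log_lines) + "\n")
            raise StageError(name, e) from e
        log(f"stage {name}: done")
        return result

    log(f"config hash {cfg_hash}, seed {seed}")
    sim = config.sim_config()
    th = art.ScadsThresholds(**config.screening)

    stimuli, profiles, ratings, _ = run_stage(
        "simulate", lambda: synthgen.simulate_study(sim, seed))
    _write(stimuli, out / "stimuli.csv", cfg_hash, seed)
    _write(ratings, out / "ratings.csv", cfg_hash, seed)

    trial_tables = {}
    rejections = {}
    spectra = None
    for mode in ("scene", "video"):
        ep, _ = run_stage(f"epochs-{mode}", lambda m=mode: synthgen.simulate_epochs(
            stimuli, profiles, m, sim, seed + (10 if m == "video" else 0),
            trial_effects=ratings))
        if config.artifact_trial_rate > 0:
            ep, _ = run_stage(f"artifacts-{mode}", lambda e=ep, m=mode:
                              synthgen.inject_artifacts(
                                  e, config.artifact_trial_rate,
                                  config.artifact_sensor_rate,
                                  seed + (20 if m == "video" else 30), sim))
        clean, rejection = run_stage(f"preprocess-{mode}",
                                     lambda e=ep: _preprocess(e, mode, th))
        rejections[mode] = rejection
        if mode == "scene":
            tt = run_stage("measure-scene", lambda: measures.lpp_per_trial(clean))
        else:
            tt = run_stage("measure-video",
                           lambda: measures.oscillation_power_per_trial(clean))
            spectra = run_stage("spectra", lambda: {
                pid: sigproc.fft_spectrum(
                    _subset(clean, pid), measures.VIDEO_WINDOW,
                    measures.OCCIPITAL_CLUSTER, groupby=["category"])
                for pid in clean.trial_meta["participant_id"].unique()})
        tt = measures.attach_ratings(tt, ratings)
        trial_tables[mode] = tt
        _write(tt, out / f"trials_{mode}.csv", cfg_hash, seed)

    counts = pd.concat([rejections[m].retained_counts for m in rejections])
    exclusions = run_stage("exclusion", lambda: art.apply_exclusion(counts))
    _write(exclusions, out / "exclusions.csv", cfg_hash, seed)
    kept = set(exclusions.loc[~exclusions["excluded"], "participant_id"])
    for mode in trial_tables:
        trial_tables[mode] = trial_tables[mode][
            trial_tables[mode]["participant_id"].isin(kept)]

    stats_rows = run_stage("groupstats",
                           lambda: _group_statistics(trial_tables))
    _write(pd.DataFrame(stats_rows), out / "groupstats.csv", cfg_hash, seed)

    bandz = run_stage("band-zscores", lambda: measures.category_band_zscores(
        {p: s for p, s in spectra.items() if p in kept}, config.bands))
    _write(bandz, out / "band_zscores.csv", cfg_hash, seed)
    band_stats = []
    for band, sub in bandz.groupby("band", sort=False):
        res = groupstats.rm_anova(sub, dv="z", subject="participant_id",
                                  within=["category"])[0]
        band_stats.append({"band": band, "F": res.F, "df_num": res.df_num,
                           "df_den": res.df_den, "p": res.p,
                           "partial_eta_sq": res.partial_eta_sq})
    _write(pd.DataFrame(band_stats), out / "band_anova.csv", cfg_hash, seed)

    if config.skip_bayes:
        log("skip_bayes set: stopping after group statistics")
        log_path.write_text("\n".join(log_lines) + "\n")
        return out

    summary_rows = []
    for mode, tt in trial_tables.items():
        scfg = hbayes.SamplerConfig(seed=seed, **config.sampler)
        m1 = run_stage(f"fit-model1-{mode}", lambda t=tt, c=scfg:
                       hbayes.fit_model1(t, c))
        m2 = run_stage(f"fit-model2-{mode}", lambda t=tt, c=scfg:
                       hbayes.fit_model2(t, c))
        ll1 = hbayes.pointwise_loglik(m1, tt)
        ll2 = hbayes.pointwise_loglik(m2, tt)
        loo1, loo2 = modelcmp.psis_loo(ll1), modelcmp.psis_loo(ll2)
        diff, se = modelcmp.elpd_diff(loo2, loo1)
        w = modelcmp.stacking_weights([loo1, loo2])
        for label, post, loo, weight in (("model1", m1, loo1, w.weights[0]),
                                         ("model2", m2, loo2, w.weights[1])):
            r2, _ = hbayes.r2_posterior(post, tt)
            pr2, _ = hbayes.r2_posterior(post, tt, predictor_only=True)
            summary_rows.append({
                "measure": mode, "model": label,
                "r2_median": r2.median, "r2_lo": r2.ci_low, "r2_hi": r2.ci_high,
                "predictor_r2_median": pr2.median, "predictor_r2_lo": pr2.ci_low,
                "predictor_r2_hi": pr2.ci_high,
                "elpd": loo.elpd, "elpd_diff_vs_model1": 0.0 if label == "model1"
                else diff, "elpd_diff_se": 0.0 if label == "model1" else se,
                "stacking_weight": weight, "rhat_max": post.rhat_max,
            })
        np.savez(out / f"posterior_model1_{mode}.npz", **m1.to_draw_dict())
        np.savez(out / f"posterior_model2_{mode}.npz", **m2.to_draw_dict())
        hyper_draws = pd.DataFrame({
            "par_bar": m1.flat("par_bar"), "sigma_par": m1.flat("sigma_par"),
            "sigma_stim": m1.flat("sigma_stim"), "sigma_bar": m1.flat("sigma_bar"),
            "tau": m1.flat("tau")})
        _write(hyper_draws, out / f"posterior_model1_hypers_{mode}.csv",
               cfg_hash, seed)
    _write(pd.DataFrame(summary_rows), out / "model_summary.csv", cfg_hash, seed)

    log("pipeline complete")
    log_path.write_text("\n".join(log_lines) + "\n")
    return out


def _subset(epochs, participant_id):
    mask = (epochs.trial_meta["participant_id"] == participant_id).to_numpy()
    from .epochs import EpochSet
    return EpochSet(data=epochs.data[mask], srate=epochs.srate, t0=epochs.t0,
                    channel_names=list(epochs.channel_names),
                    channel_positions=epochs.channel_positions,
                    trial_meta=epochs.trial_meta[mask].reset_index(drop=True))


def _group_statistics(trial_tables: dict) -> list[dict]:
    """Category z-score ANOVAs per measure plus the factorial interaction."""
    rows = []
    zs = {}
    for mode, tt in trial_tables.items():
        cm = measures.category_means(tt)
        z = measures.category_zscore(cm)
        z["stimulus_type"] = mode
        zs[mode] = z
        res = groupstats.rm_anova(z, dv="z", subject="participant_id",
                                  within=["category"])[0]
        rows.append({"analysis": f"category-{mode}", "effect": res.effect,
                     "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                     "p": res.p, "partial_eta_sq": res.partial_eta_sq})
    both = pd.concat(zs.values(), ignore_index=True)
    common = set.intersection(*[set(z["participant_id"]) for z in zs.values()])
    both = both[both["participant_id"].isin(common)]
    for res in groupstats.rm_anova(both, dv="z", subject="participant_id",
                                   within=["category", "stimulus_type"]):
        rows.append({"analysis": "factorial", "effect": res.effect, "F": res.F,
                     "df_num": res.df_num, "df_den": res.df_den, "p": res.p,
                     "partial_eta_sq": res.partial_eta_sq})
    for mode, tt in trial_tables.items():
        sz = measures.stimulus_zscore(tt)
        aro = tt.groupby("stimulus_id", sort=True)["arousal"].mean()
        r, p = groupstats.stimulus_correlation(sz["z"], aro.loc[sz["stimulus_id"]])
        rows.append({"analysis": f"arousal-correlation-{mode}", "effect": "pearson",
                     "F": np.nan, "df_num": np.nan, "df_den": np.nan, "p": p,
                     "partial_eta_sq": np.nan, "r": r})
    return rows
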