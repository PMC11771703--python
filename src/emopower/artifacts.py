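"""Statistical screening of trial x sensor cells, dense-array style.

The screening follows the SCADS recipe: for every trial x channel cell,
compute maximum absolute amplitude, maximum absolute first derivative, and
standard deviation; robust-standardize each index (median/IQR across all
cells) and average them into a composite score.  Cells beyond a composite
threshold are marked bad; trials with too many bad channels are rejected;
surviving bad channels are replaced by an inverse-great-circle-distance
weighted average of the nearest clean channels (an explicit approximation of
spherical-spline interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import great_circle_distances


@dataclass
class ScadsScores:
    max_amp: np.ndarray        # (trial, channel) uV
    max_deriv: np.ndarray      # (trial, channel) uV/sample
    sd: np.ndarray             # (trial, channel) uV
    composite: np.ndarray      # (trial, channel) robust-z units


@dataclass
class ScadsThresholds:
    """Distribution-based cutoffs (robust-SD units) and structural limits."""

    cell_composite: float = 3.0        # cell bad if composite exceeds this
    trial_bad_fraction: float = 0.10   # trial rejected if > this fraction bad
    n_neighbors: int = 6               # interpolation neighbors


@dataclass
class RejectionResult:
    bad_cells: np.ndarray              # (trial, channel) bool, pre-rejection
    rejected_trials: np.ndarray        # (trial,) bool
    interpolated: np.ndarray           # (trial, channel) bool
    retained_counts: pd.DataFrame = field(default=None, repr=False)


def _robust_z(x: np.ndarray) -> np.ndarray:
    """Robust standardization per channel (median/IQR across trials).

    Standardizing within channel keeps channels that legitimately carry
    large signal (e.g. the occipital sensors during flicker) from being
    flagged wholesale; a cell is suspect relative to its own sensor's
    across-trial distribution.
    """
    med = np.median(x, axis=0, keepdims=True)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = (q75 - q25)[None]
    out = np.zeros_like(x, dtype=float)
    ok = np.broadcast_to(iqr > 0, x.shape)
    # 1.349 converts IQR to an SD-equivalent under normality.
    scaled = (x - med) / np.where(iqr > 0, iqr / 1.349, 1.0)
    out[ok] = scaled[ok]
    return out


def scads_scores(epochs: EpochSet) -> ScadsScores:
    """Per-cell amplitude / derivative / SD indices and their composite."""
    if epochs.n_samples < 2:
        raise ValueError("need at least 2 samples per trial")
    d = epochs.data
    max_amp = np.abs(d).max(axis=-1)
    max_deriv = np.abs(np.diff(d, axis=-1)).max(axis=-1)
    sd = d.std(axis=-1)
    parts = []
    for index in (max_amp, max_deriv, sd):
        z = _robust_z(index)
        if np.any(z):  # constant-zero index carries no information
            parts.append(z)
    composite = np.mean(parts, axis=0) if parts else np.zeros_like(max_amp)
    return ScadsScores(max_amp=max_amp, max_deriv=max_deriv, sd=sd,
                       composite=composite)


def reject_and_interpolate(epochs: EpochSet, scores: ScadsScores,
                           thresholds: ScadsThresholds | None = None):
    """Mark bad cells, drop bad trials, interpolate surviving bad channels.

    Returns ``(clean EpochSet, RejectionResult)``.  The returned epochs
    contain only retained trials, in original order.
    """
    th = thresholds or ScadsThresholds()
    bad = scores.composite > th.cell_composite
    bad_frac = bad.mean(axis=1)
    rejected = bad_frac > th.trial_bad_fraction

    keep = ~rejected
    interp_mask = np.zeros_like(bad)
    out = epochs.copy()
    dist = great_circle_distances(epochs.channel_positions)
    for tr in np.flatnonzero(keep):
        bad_ch = np.flatnonzero(bad[tr])
        if bad_ch.size == 0:
            continue
        clean_ch = np.flatnonzero(~bad[tr])
        if clean_ch.size == 0:
            raise ValueError(f"all channels bad in retained trial {tr}")
        for c in bad_ch:
            d = dist[c, clean_ch]
            order = np.argsort(d)[: th.n_neighbors]
            w = 1.0 / np.maximum(d[order], 1e-6)
            w /= w.sum()
            out.data[tr, c] = w @ epochs.data[tr, clean_ch[order]]
            interp_mask[tr, c] = True

    meta = epochs.trial_meta.reset_index(drop=True)
    retained = meta[keep].groupby(
        ["participant_id", "category", "stimulus_type"], sort=True
    ).size().rename("retained").reset_index()
    total = meta.groupby(
        ["participant_id", "category", "stimulus_type"], sort=True
    ).size().rename("total").reset_index()
    counts = total.merge(retained, how="left",
                         on=["participant_id", "category", "stimulus_type"])
    counts["retained"] = counts["retained"].fillna(0).astype(int)

    clean = EpochSet(
        data=out.data[keep], srate=epochs.srate, t0=epochs.t0,
        channel_names=list(epochs.channel_names),
        channel_positions=epochs.channel_positions,
        trial_meta=meta[keep].reset_index(drop=True),
    )
    return clean, RejectionResult(bad_cells=bad, rejected_trials=rejected,
                                  interpolated=interp_mask,
                                  retained_counts=counts)


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the across-channel mean at every sample of every trial."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return epochs.copy(data=epochs.data - epochs.data.mean(axis=1, keepdims=True))


def baseline_correct(epochs: EpochSet, window: tuple = (-0.1, 0.0)) -> EpochSet:
    """Subtract each trial x channel's mean over the pre-onset ``window``.

    The window is half-open, ``[t_start, t_end)``, so the default 100 ms
    pre-onset baseline never includes the onset sample itself.
    """
    t = epochs.times
    mask = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
    if not mask.any():
        raise ValueError("empty baseline window")
    base = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return epochs.copy(data=epochs.data - base)


def apply_exclusion(counts: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Apply the participant-exclusion rule on retained-trial counts.

    A participant is excluded iff the pipeline removed *over* half of the
    trials from any valence category within either stimulus series —
    i.e. retained < 50% in some (category, series) cell; retaining exactly
    half keeps the participant.

    ``counts`` needs columns participant_id, category, stimulus_type,
    retained, total.  Returns a per-participant frame with an ``excluded``
    flag and the worst retained fraction.
    """
    required = {"participant_id", "category", "stimulus_type", "retained", "total"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts missing columns {required - set(counts.columns)}")
    c = counts.copy()
    c["fraction"] = c["retained"] / c["total"]
    per_par = c.groupby("participant_id")["fraction"].min().rename("worst_fraction")
    out = per_par.reset_index()
    out["excluded"] = out["worst_fraction"] < min_fraction
    return out
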