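"""Per-trial dependent measures and within-participant Z-scorings.

Two single-trial amplitudes drive the whole analysis:

* **scene-LPP** — mean voltage over a 9-sensor centro-parietal cluster in
  the 400-900 ms post-onset window of baseline-corrected scene epochs;
* **video oscillation-power** — mean Hilbert envelope of the 7-8 Hz
  band-passed signal over a 9-sensor occipital cluster in the 1-9 s window
  of video epochs.  Because a narrow-band envelope integrates whatever power
  sits inside its pass band, this measure responds to broadband 3-10 Hz
  shifts as well as to the driven 7.5 Hz oscillation — the confound the
  Fourier band analyses expose.

Z-scoring is always within participant; the default SD convention is the
sample (n-1 denominator) one, so three category values (1, 2, 3) map to
(-1, 0, 1).  The convention is configurable via ``ddof``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import LPP_CLUSTER, OCCIPITAL_CLUSTER
from .sigproc import band_power, bandpass_spec, filter_epochs, \
    hilbert_envelope

LPP_WINDOW = (0.4, 0.9)
VIDEO_WINDOW = (1.0, 9.0)


def _trial_rows(epochs: EpochSet, amplitude: np.ndarray) -> pd.DataFrame:
    out = epochs.trial_meta.copy().reset_index(drop=True)
    out["amplitude"] = amplitude
    return out


def lpp_per_trial(epochs: EpochSet, cluster=None, window=LPP_WINDOW) -> pd.DataFrame:
    """Scene-LPP per trial: cluster/window mean voltage in microvolts.

    Expects baseline-corrected (and typically average-referenced) scene
    epochs.  Returns the trial metadata with an ``amplitude`` column.
    """
    ch = epochs.channel_indices(cluster or LPP_CLUSTER)
    sl = epochs.time_slice(*window)
    amp = epochs.data[:, ch, sl.start:sl.stop].mean(axis=(1, 2))
    return _trial_rows(epochs, amp)


def oscillation_power_per_trial(epochs: EpochSet, cluster=None,
                                center_hz: float = 7.5, halfwidth_hz: float = 0.5,
                                window=VIDEO_WINDOW) -> pd.DataFrame:
    """Video oscillation-power per trial: mean 7-8 Hz Hilbert envelope (uV).

    The signal is band-passed ``center_hz +- halfwidth_hz``, the analytic
    envelope taken per channel, then averaged over cluster channels and the
    1-9 s window (which already excludes onset/offset transients, so no
    extra edge trimming is applied).
    """
    ch = epochs.channel_indices(cluster or OCCIPITAL_CLUSTER)
    filtered = filter_epochs(epochs, bandpass_spec(center_hz, halfwidth_hz))
    env = hilbert_envelope(filtered.data[:, ch, :], axis=-1)
    sl = epochs.time_slice(*window)
    amp = env[..., sl.start:sl.stop].mean(axis=(1, 2))
    return _trial_rows(epochs, amp)


def attach_ratings(trials: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    """Merge per-trial SAM ratings into a trial table by participant+stimulus."""
    cols = ["participant_id", "stimulus_id", "arousal", "valence"]
    merged = trials.merge(ratings[cols], on=["participant_id", "stimulus_id"],
                          how="left", validate="many_to_one")
    if merged["arousal"].isna().any():
        raise ValueError("ratings missing for some trials")
    return merged


def category_zscore(values: pd.DataFrame, value_col: str = "amplitude",
                    ddof: int = 1) -> pd.DataFrame:
    """Z-score per-participant category means within participant.

    ``values`` has one row per participant x category (optionally per
    measure via extra grouping columns already split out by the caller).
    Raises on zero spread, which would make the z-scores undefined.
    """
    def _z(x):
        sd = x.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("zero SD within participant; z-score undefined")
        return (x - x.mean()) / sd

    out = values.copy()
    out["z"] = values.groupby("participant_id")[value_col].transform(_z)
    return out


def category_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean amplitude per participant x category (input to z-scoring)."""
    return trials.groupby(["participant_id", "category"], sort=True)[
        "amplitude"].mean().reset_index()


def stimulus_zscore(trials: pd.DataFrame, value_col: str = "amplitude",
                    ddof: int = 1) -> pd.DataFrame:
    """Participant-averaged per-stimulus z-scores.

    Each participant's single-trial amplitudes are z-scored across all their
    trials (no category averaging), then averaged per stimulus across
    participants: one value per stimulus, the basis of the by-stimulus
    arousal correlations.  Stimuli with no retained trials are absent from
    the output (flagged via the ``n`` column of present ones).
    """

    def _z(x):
        sd = x.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("zero SD within participant; z-score undefined")
        return (x - x.mean()) / sd

    t = trials.copy()
    t["z"] = t.groupby("participant_id")[value_col].transform(_z)
    agg = t.groupby("stimulus_id", sort=True).agg(
        z=("z", "mean"), n=("z", "size"),
        category=("category", "first")).reset_index()
    return agg


def category_band_zscores(spectra: dict, bands: dict) -> pd.DataFrame:
    """Within-participant z of per-category band power, per frequency band.

    ``spectra`` maps participant_id -> :class:`SpectrumResult` whose rows are
    the three valence categories (``groups`` attribute); ``bands`` maps a
    band label to ``(lo_hz, hi_hz)`` (a single 7.5 Hz bin is ``(7.5, 7.5)``).
    Returns rows of (participant_id, band, category, power, z).
    """
    rows = []
    for pid, spec in spectra.items():
        if spec.groups is None:
            raise ValueError("spectrum must be grouped by category")
        for label, (lo, hi) in bands.items():
            bp = band_power(spec, lo, hi)
            for cat, p in zip(spec.groups, np.atleast_1d(bp)):
                rows.append((pid, label, cat, p))
    df = pd.DataFrame(rows, columns=["participant_id", "band", "category", "power"])
    out = []
    for label, sub in df.groupby("band", sort=False):
        out.append(category_zscore(sub, value_col="power"))
    return pd.concat(out, ignore_index=True)
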