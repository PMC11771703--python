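"""Single-trial epoch container and its on-disk (NPZ) layout.

An :class:`EpochSet` is the pipeline's raw currency: a dense
``(trial, channel, sample)`` array in microvolts plus the sampling rate, the
stimulus-onset sample, the montage, and one metadata row per trial.  Time is
expressed in seconds relative to stimulus onset; sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_SCHEMA_VERSION = 1
_META_COLUMNS = ["participant_id", "stimulus_id", "category", "stimulus_type"]


@dataclass
class EpochSet:
    """Multichannel single-trial EEG epochs with metadata.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` float array, microvolts.
    srate
        Sampling rate in Hz.
    t0
        Sample index of stimulus onset (0-based), so the time of sample ``s``
        is ``(s - t0) / srate`` seconds.
    channel_names, channel_positions
        Montage labels and unit-sphere coordinates, ``(n_channels, 3)``.
    trial_meta
        One row per trial with at least ``participant_id``, ``stimulus_id``,
        ``category`` and ``stimulus_type`` columns.
    """

    data: np.ndarray
    srate: float
    t0: int
    channel_names: list[str]
    channel_positions: np.ndarray
    trial_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, sample)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        n_tr, n_ch, _ = self.data.shape
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length mismatch")
        if len(self.trial_meta) != n_tr:
            raise ValueError("trial_meta length mismatch")
        missing = [c for c in _META_COLUMNS if c not in self.trial_meta.columns]
        if missing:
            raise ValueError(f"trial_meta missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.t0) / self.srate

    def time_slice(self, t_start: float, t_end: float) -> slice:
        """Sample slice covering ``t_start <= t <= t_end`` (seconds).

        The window must lie entirely within the epoch.
        """
        t = self.times
        # allow the end point to fall within one sample past the last sample
        # (an exclusive-end window like [0, 8) s on an 8 s epoch is valid)
        if t_start < t[0] - 1e-9 or t_end > t[-1] + 1.0 / self.srate + 1e-9:
            raise ValueError(f"window [{t_start}, {t_end}] s outside epoch "
                             f"[{t[0]:.3f}, {t[-1]:.3f}] s")
        idx = np.flatnonzero((t >= t_start - 1e-9) & (t <= t_end + 1e-9))
        if idx.size == 0:
            raise ValueError(f"empty window [{t_start}, {t_end}] s")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def channel_indices(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return np.array([lookup[n] for n in names])

    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            trial_meta=self.trial_meta.copy(),
        )


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to ``path`` as NPZ (lossless round-trip)."""
    meta = epochs.trial_meta
    np.savez(
        path,
        schema_version=np.array(_SCHEMA_VERSION),
        data=epochs.data,
        srate=np.array(epochs.srate),
        t0=np.array(epochs.t0),
        channel_names=np.array(epochs.channel_names, dtype=object),
        channel_positions=epochs.channel_positions,
        meta_columns=np.array(list(meta.columns), dtype=object),
        **{f"meta_{c}": meta[c].to_numpy() for c in meta.columns},
    )


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    with np.load(path, allow_pickle=True) as f:
        keys = set(f.files)
        required = {"schema_version", "data", "srate", "t0", "channel_names",
                    "channel_positions", "meta_columns"}
        if not required <= keys:
            raise ValueError(f"epoch file schema mismatch; missing {required - keys}")
        version = int(f["schema_version"])
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported epoch schema version {version}")
        cols = list(f["meta_columns"])
        meta = pd.DataFrame({c: f[f"meta_{c}"] for c in cols})
        return EpochSet(
            data=f["data"],
            srate=float(f["srate"]),
            t0=int(f["t0"]),
            channel_names=list(f["channel_names"]),
            channel_positions=f["channel_positions"],
            trial_meta=meta,
        )
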