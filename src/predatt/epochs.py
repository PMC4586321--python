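"""Epoched-EEG container and its on-disk representation.

An :class:`EpochSet` holds trials x channels x samples of voltage (µV) cut
around stimulus onset, together with per-trial metadata (category, block,
position, neighbours, press adjacency) needed by the trial-exclusion rules.
On disk it is an HDF5 array plus a JSON sidecar carrying channel labels,
sampling rate, epoch window and the metadata table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Metadata columns every EpochSet carries.
META_COLUMNS = (
    "category", "block", "position", "onset_ms",
    "preceding_category", "following_category",
    "followed_by_press", "preceded_by_press",
)


def sample_indices(window_ms: tuple[float, float], sfreq: float) -> np.ndarray:
    """Sample indices k (time = k / sfreq) covering ``window_ms`` around onset.

    The first index is round(start * sfreq) and the count is
    round((end - start) * sfreq), so a (-700, 800) ms window at 512 Hz yields
    768 samples at indices -358 .. 409.
    """
    start_s, end_s = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    first = round(start_s * sfreq)
    n = round((end_s - start_s) * sfreq)
    return np.arange(first, first + n)


@dataclass
class EpochSet:
    """Trials x channels x samples of epoched EEG with trial metadata."""

    data: np.ndarray                 # (n_trials, n_channels, n_samples), µV
    trial_meta: pd.DataFrame
    channel_labels: tuple[str, ...]
    sfreq: float
    window_ms: tuple[float, float]
    baseline_applied: bool = False
    exclusions: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        n_trials, n_channels, n_samples = self.data.shape
        expected = len(sample_indices(self.window_ms, self.sfreq))
        if n_samples != expected:
            raise ValueError(
                f"data has {n_samples} samples; window/sfreq imply {expected}"
            )
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta length must equal trial count")
        if n_channels != len(self.channel_labels):
            raise ValueError("channel_labels length must equal channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset (k / sfreq)."""
        return sample_indices(self.window_ms, self.sfreq) / self.sfreq * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def clean_mask(self) -> np.ndarray:
        """Boolean mask of trials not flagged by any exclusion rule."""
        if self.exclusions is None:
            return np.ones(self.n_trials, dtype=bool)
        return ~self.exclusions.to_numpy().any(axis=1)

    def subset(self, mask_or_index) -> "EpochSet":
        """New EpochSet restricted to the given trials (metadata kept aligned)."""
        idx = np.asarray(mask_or_index)
        excl = None
        if self.exclusions is not None:
            excl = self.exclusions.iloc[idx].reset_index(drop=True) \
                if idx.dtype != bool else self.exclusions.loc[idx].reset_index(drop=True)
        meta = self.trial_meta.iloc[idx] if idx.dtype != bool \
            else self.trial_meta.loc[idx]
        return replace(
            self,
            data=self.data[idx],
            trial_meta=meta.reset_index(drop=True),
            exclusions=excl,
        )


def write_epochs(epochs: EpochSet, h5_path) -> None:
    """Write an EpochSet as HDF5 (`epochs` dataset) + JSON sidecar (.json)."""
    import h5py

    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
    sidecar = {
        "channel_labels": list(epochs.channel_labels),
        "sfreq": epochs.sfreq,
        "window_ms": list(epochs.window_ms),
        "baseline_applied": epochs.baseline_applied,
        "trial_meta": epochs.trial_meta.to_dict(orient="list"),
    }
    h5_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_epochs(h5_path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    import h5py

    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as f:
        data = f["epochs"][()]
    sidecar = json.loads(h5_path.with_suffix(".json").read_text())
    meta = pd.DataFrame(sidecar["trial_meta"])
    return EpochSet(
        data=data,
        trial_meta=meta,
        channel_labels=tuple(sidecar["channel_labels"]),
        sfreq=sidecar["sfreq"],
        window_ms=tuple(sidecar["window_ms"]),
        baseline_applied=sidecar["baseline_applied"],
    )
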