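"""Electrode montage: 64-channel 10-10 labels on the unit sphere.

Coordinates come from mne's bundled BioSemi-64 standard montage and are
re-normalized to unit radius, which is the convention the spherical-spline
interpolation assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Electrodes used in the scalp-distribution ANOVAs.
MIDLINE_SET = ("Fz", "Cz", "Pz")
#: Electrode used for the predictive-processing P3 measures.
CENTROPARIETAL = "CPz"


@dataclass(frozen=True)
class Montage:
    """Electrode label -> unit-sphere 3D coordinate."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit radius

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        r = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(r, 1.0, atol=1e-6):
            raise ValueError("montage positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        idx = [self.index(lb) for lb in labels]
        return Montage(tuple(labels), self.positions[idx])


def standard_64_montage() -> Montage:
    """Full 64-channel montage with 10-10 labels (includes Fz, Cz, CPz, Pz)."""
    import mne

    m = mne.channels.make_standard_montage("biosemi64")
    pos = m.get_positions()["ch_pos"]
    labels = tuple(m.ch_names)
    xyz = np.array([pos[lb] for lb in labels], dtype=float)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return Montage(labels, xyz)


def reduced_montage(labels=("Fz", "FCz", "Cz", "CPz", "Pz", "POz", "C3", "C4")) -> Montage:
    """Subset of the 64-channel montage; handy for fast simulations."""
    return standard_64_montage().subset(labels)
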