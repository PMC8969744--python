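"""In-memory containers for continuous and epoched EEG.

Voltages are in microvolts throughout; times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage

__all__ = ["ContinuousEEG", "EpochSet"]

#: epoch alignment origins
ALIGN_FIRST = "first_sound"
ALIGN_FIFTH = "fifth_sound"


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording: (n_channels, n_samples) in uV."""

    data: np.ndarray
    sfreq: float
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_sensors:
            raise ValueError(
                f"{self.data.shape[0]} data channels but montage has "
                f"{self.montage.n_sensors} sensors"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(self.data.copy(), self.sfreq, self.montage)


@dataclass
class EpochSet:
    """Epoched EEG: (n_trials, n_channels, n_samples) in uV.

    ``times`` is the common time axis in seconds relative to the alignment
    origin (onset of the first or of the fifth sound of a series).
    ``metadata`` carries one row per trial with at least the columns
    ``state`` (PRE/HYP), ``stimulus`` (standard/deviant) and ``block_type``.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    metadata: pd.DataFrame
    montage: Montage
    alignment: str = ALIGN_FIRST

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x time)")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != self.montage.n_sensors:
            raise ValueError("channel count does not match montage")
        if len(self.times) != n_t:
            raise ValueError("times length does not match data")
        if len(self.metadata) != n_tr:
            raise ValueError("metadata rows must equal trial count")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.sfreq,
            self.times.copy(),
            self.metadata.copy(),
            self.montage,
            self.alignment,
        )

    def time_mask(self, window) -> np.ndarray:
        """Boolean mask over the time axis for ``window=(lo, hi)``, inclusive."""
        lo, hi = window
        return (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EpochSet(
            self.data[idx],
            self.sfreq,
            self.times.copy(),
            self.metadata.iloc[idx],
            self.montage,
            self.alignment,
        )

    def crop(self, window) -> "EpochSet":
        """Restrict the time axis to ``window=(lo, hi)`` seconds, inclusive."""
        mask = self.time_mask(window)
        if not mask.any():
            raise ValueError(f"window {window} outside the epoch span")
        out = self.copy()
        out.data = out.data[:, :, mask]
        out.times = out.times[mask]
        return out

    def select_channels(self, idx) -> np.ndarray:
        """Raw data for the given channel indices (no container rebuild)."""
        return self.data[:, np.asarray(idx), :]


def concatenate_epochs(epoch_sets) -> EpochSet:
    """Stack several EpochSets sharing montage / time axis / alignment."""
    epoch_sets = list(epoch_sets)
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.alignment != first.alignment or not np.allclose(es.times, first.times):
            raise ValueError("epoch sets are not alignment-compatible")
        if es.montage is not first.montage and es.montage.names != first.montage.names:
            raise ValueError("epoch sets use different montages")
    return EpochSet(
        np.concatenate([es.data for es in epoch_sets], axis=0),
        first.sfreq,
        first.times.copy(),
        pd.concat([es.metadata for es in epoch_sets], ignore_index=True),
        first.montage,
        first.alignment,
    )
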