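"""File I/O: TSV event tables, HDF5 epoch/continuous containers, WAV, JSON.

Continuous recordings and epoch sets round-trip through HDF5 (h5py) with
the montage and trial metadata embedded.  Event timelines round-trip
through tab-separated tables.  User-supplied recordings in standard
interchange formats (EDF+, BrainVision) can be loaded through MNE when it
is installed (optional dependency).
"""

from __future__ import annotations

import io as _stdlib_io
import json

import h5py
import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet
from .montage import Montage
from .paradigm import EventTimeline

__all__ = [
    "save_continuous_h5",
    "load_continuous_h5",
    "save_epochs_h5",
    "load_epochs_h5",
    "write_events_tsv",
    "read_events_tsv",
    "write_wav",
    "write_json",
    "load_raw_mne",
]

def _write_montage(grp, montage: Montage) -> None:
    grp.create_dataset("positions", data=montage.positions)
    grp.create_dataset("adjacency", data=montage.adjacency.astype(np.uint8))
    grp.attrs["names"] = json.dumps(list(montage.names))


def _read_montage(grp) -> Montage:
    return Montage(
        names=tuple(json.loads(grp.attrs["names"])),
        positions=grp["positions"][()],
        adjacency=grp["adjacency"][()].astype(bool),
    )


def save_continuous_h5(path, continuous: ContinuousEEG) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=continuous.data, compression="gzip")
        f.attrs["sfreq"] = continuous.sfreq
        f.attrs["kind"] = "continuous"
        _write_montage(f.create_group("montage"), continuous.montage)


def load_continuous_h5(path) -> ContinuousEEG:
    with h5py.File(path, "r") as f:
        return ContinuousEEG(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            montage=_read_montage(f["montage"]),
        )


def save_epochs_h5(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["alignment"] = epochs.alignment
        f.attrs["kind"] = "epochs"
        f.attrs["metadata"] = epochs.metadata.to_json(orient="split")
        _write_montage(f.create_group("montage"), epochs.montage)


def load_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = pd.read_json(_stdlib_io.StringIO(f.attrs["metadata"]), orient="split")
        return EpochSet(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            times=f["times"][()],
            metadata=meta,
            montage=_read_montage(f["montage"]),
            alignment=str(f.attrs["alignment"]),
        )


def write_events_tsv(path, timeline: EventTimeline) -> None:
    timeline.to_tsv(path)


def read_events_tsv(path, soa: float | None = None) -> EventTimeline:
    """Rebuild an EventTimeline from a per-sound TSV event table."""
    df = pd.read_csv(path, sep="\t")
    groups = df.sort_values(["series_index", "sound_index"]).groupby("series_index")
    onsets, kinds, blocks, states = [], [], [], []
    for _, g in groups:
        onsets.append(g["onset_s"].to_numpy())
        kinds.append(g["trial_type"].iloc[0])
        blocks.append(g["block_type"].iloc[0])
        states.append(g["state"].iloc[0] if "state" in g and pd.notna(g["state"].iloc[0]) and g["state"].iloc[0] != "" else None)
    onsets = np.asarray(onsets)
    if soa is None:
        soa = float(np.median(np.diff(onsets, axis=1)))
    dur = float(df["duration_s"].iloc[0])
    fifth_end = onsets[:, 4] + dur
    isi = onsets[1:, 0] - fifth_end[:-1]
    state = None if any(s is None for s in states) else np.asarray(states, dtype=object)
    return EventTimeline(
        sound_onsets=onsets,
        kind=np.asarray(kinds, dtype=object),
        block_type=np.asarray(blocks, dtype=object),
        isi=isi,
        soa=soa,
        sound_duration=dur,
        state=state,
    )


def write_wav(path, waveform: np.ndarray, rate: int = 44100) -> None:
    """Write a peak-normalized waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    w = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(w)) if w.size else 0.0
    if peak > 0:
        w = w / peak
    wavfile.write(path, int(rate), (w * 32767).astype(np.int16))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, cls=_NumpyEncoder)


def load_raw_mne(path, montage: Montage | None = None) -> ContinuousEEG:
    """Load a continuous EEG file (EDF+, BrainVision, FIF...) via MNE.

    Voltages are converted from volts to microvolts.  If no montage is
    given, sensor positions are taken from the file when available,
    otherwise a generic disc layout of matching size is used.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "reading standard EEG interchange formats requires the optional "
            "'mne' dependency (pip install oddball-eeg[eeg-io])"
        ) from err

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    raw.pick(picks="eeg", verbose="error")
    data = raw.get_data() * 1e6
    if montage is None:
        from .montage import disc_montage

        montage = disc_montage(data.shape[0])
    return ContinuousEEG(data=data, sfreq=float(raw.info["sfreq"]), montage=montage)
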