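"""Filtering, epoching, artifact rejection, re-referencing and baselining.

The preprocessing chain mirrors a conventional high-density EEG pipeline:

1. zero-phase band-pass (0.5-10 Hz for ERP/decoding, 0.5-45 Hz for
   spectral/connectivity analyses) with 50 and 100 Hz notches;
2. segmentation from -200 to +1400 ms around the first sound of each
   series;
3. automated artifact rejection: channels whose peak-to-peak amplitude
   exceeds 100 uV in more than 50% of epochs are rejected; channels whose
   mean variance z-scores above 4 across channels are rejected (rule run
   twice, statistics recomputed over survivors); epochs exceeding 100 uV
   peak-to-peak on more than 10% of the surviving channels are rejected;
   rejected channels are interpolated from their neighbours.  A recording
   passes if at least 70% of channels and 70% of epochs survive;
4. average reference;
5. realignment to the fifth-sound onset (-800 to +800 ms) and baseline
   correction (ERP mode: the 800 ms before the fifth sound; spectral
   mode: the 200 ms before the first sound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ALIGN_FIFTH, ALIGN_FIRST, ContinuousEEG, EpochSet
from .paradigm import EventTimeline

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "RejectionReport",
    "RejectionError",
    "bandpass",
    "epoch_and_align",
    "realign_to_fifth",
    "reject_artifacts",
    "rereference_average",
    "baseline_correct",
]


class RejectionError(RuntimeError):
    """Raised when rejection leaves no usable data."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch specification."""

    band_low: float
    band_high: float
    notches: tuple = (50.0, 100.0)
    purpose: str = "erp"

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")

    @staticmethod
    def erp() -> "FilterSpec":
        return FilterSpec(0.5, 10.0, purpose="erp")

    @staticmethod
    def spectral() -> "FilterSpec":
        return FilterSpec(0.5, 45.0, purpose="spectral")


def _filter_array(data: np.ndarray, sfreq: float, spec: FilterSpec) -> np.ndarray:
    from scipy import signal

    nyq = sfreq / 2.0
    if spec.band_high >= nyq:
        raise ValueError(
            f"band_high {spec.band_high} Hz at or above Nyquist ({nyq} Hz)"
        )
    out = data - data.mean(axis=-1, keepdims=True)
    sos = signal.butter(
        4, [spec.band_low, spec.band_high], btype="bandpass", fs=sfreq, output="sos"
    )
    out = signal.sosfiltfilt(sos, out, axis=-1)
    for f0 in spec.notches:
        if f0 >= nyq:
            continue
        b, a = signal.iirnotch(f0, Q=30.0, fs=sfreq)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def bandpass(continuous: ContinuousEEG, spec: FilterSpec) -> ContinuousEEG:
    """Zero-phase 4th-order Butterworth band-pass + notch, per channel.

    Forward-backward application preserves component latencies; the DC
    component is removed before filtering.
    """
    return ContinuousEEG(
        _filter_array(continuous.data, continuous.sfreq, spec),
        continuous.sfreq,
        continuous.montage,
    )


def epoch_and_align(
    continuous: ContinuousEEG,
    timeline: EventTimeline,
    tmin: float = -0.2,
    tmax: float = 1.4,
) -> EpochSet:
    """One epoch per series, time-locked to the first sound onset.

    Epochs whose span falls outside the recording are dropped with a
    logged warning.  The sample grid is [round(tmin*fs), round(tmax*fs)),
    i.e. 400 samples for the default -0.2..+1.4 s span at 250 Hz.
    """
    fs = continuous.sfreq
    rel = np.arange(int(round(tmin * fs)), int(round(tmax * fs)))
    times = rel / fs
    meta = timeline.metadata()
    keep, chunks = [], []
    for i in range(timeline.n_series):
        s0 = int(round(timeline.series_onset[i] * fs))
        idx = s0 + rel
        if idx[0] < 0 or idx[-1] >= continuous.n_samples:
            logger.warning("series %d too close to the recording edge; dropped", i)
            continue
        keep.append(i)
        chunks.append(continuous.data[:, idx])
    if not chunks:
        raise ValueError("no series fits inside the recording")
    data = np.stack(chunks, axis=0)
    return EpochSet(
        data=data,
        sfreq=fs,
        times=times,
        metadata=meta.iloc[keep],
        montage=continuous.montage,
        alignment=ALIGN_FIRST,
    )


def realign_to_fifth(
    epochs: EpochSet,
    soa: float = 0.150,
    tmin: float = -0.8,
    tmax: float = 0.8,
) -> EpochSet:
    """Re-express epochs relative to the fifth-sound onset and crop.

    The fifth sound starts 4*soa after the first, so realignment shifts
    the time axis by -4*soa (0.6 s at the 150-ms SOA) and crops to
    [tmin, tmax).  With the default spans this is a pure relabelling:
    -0.2..+1.4 s around the first sound is exactly -0.8..+0.8 s around
    the fifth.
    """
    if epochs.alignment != ALIGN_FIRST:
        raise ValueError("epochs are not first-sound aligned")
    shift = 4.0 * soa
    new_times = epochs.times - shift
    mask = (new_times >= tmin - 1e-9) & (new_times < tmax - 1e-9)
    out = epochs.copy()
    out.data = out.data[:, :, mask]
    out.times = new_times[mask]
    out.alignment = ALIGN_FIFTH
    return out


@dataclass
class RejectionReport:
    """Outcome of the automated artifact-rejection procedure."""

    channels_rejected_rule1: list
    channels_rejected_rule2: list
    epochs_rejected: list
    channels_interpolated: list
    kept_channel_fraction: float
    kept_epoch_fraction: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "channels_rejected_rule1": [int(c) for c in self.channels_rejected_rule1],
            "channels_rejected_rule2": [int(c) for c in self.channels_rejected_rule2],
            "epochs_rejected": [int(e) for e in self.epochs_rejected],
            "channels_interpolated": [int(c) for c in self.channels_interpolated],
            "kept_channel_fraction": float(self.kept_channel_fraction),
            "kept_epoch_fraction": float(self.kept_epoch_fraction),
            "passed": bool(self.passed),
        }


def _interpolate_channels(epochs: EpochSet, bad: np.ndarray, good: np.ndarray) -> None:
    """Replace bad channels by a distance-weighted average of good neighbours."""
    pos = epochs.montage.positions
    adj = epochs.montage.adjacency
    for ch in bad:
        donors = np.intersect1d(np.flatnonzero(adj[ch]), good)
        if len(donors) == 0:
            donors = good
        d = np.linalg.norm(pos[donors] - pos[ch], axis=1)
        w = 1.0 / np.maximum(d, 1e-6)
        w = w / w.sum()
        epochs.data[:, ch, :] = np.tensordot(w, epochs.data[:, donors, :], axes=(0, 1))


def reject_artifacts(
    epochs: EpochSet,
    ptp_threshold: float = 100.0,
    chan_epoch_frac: float = 0.5,
    z_thresh: float = 4.0,
    z_repeats: int = 2,
    epoch_chan_frac: float = 0.1,
    min_kept_fraction: float = 0.70,
):
    """Automated peak-to-peak / variance rejection with the 70%/70% pass rule.

    Rules, in order:

    1. reject channels whose peak-to-peak amplitude exceeds
       ``ptp_threshold`` in more than ``chan_epoch_frac`` of the epochs;
    2. reject channels whose mean variance (across epochs) z-scores above
       ``z_thresh`` over the surviving channels; run ``z_repeats`` times,
       recomputing the statistics over survivors each pass;
    3. reject epochs whose peak-to-peak exceeds the threshold on more
       than ``epoch_chan_frac`` of the surviving channels;
    4. interpolate rejected channels from neighbouring kept channels.

    Returns ``(clean_epochs, RejectionReport)``; the report's ``passed``
    flag requires at least ``min_kept_fraction`` of channels *and* epochs
    to survive.
    """
    n_tr, n_ch, _ = epochs.data.shape
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    exceeded = ptp > ptp_threshold

    # rule 1: channel bad in too many epochs
    rule1 = np.flatnonzero(exceeded.mean(axis=0) > chan_epoch_frac)
    alive = np.setdiff1d(np.arange(n_ch), rule1)

    # rule 2: variance z-score across surviving channels, repeated
    rule2 = []
    variances = epochs.data.var(axis=2).mean(axis=0)  # mean variance per channel
    for _ in range(z_repeats):
        if len(alive) < 2:
            break
        v = variances[alive]
        sd = v.std()
        if sd == 0:
            break
        z = (v - v.mean()) / sd
        bad = alive[z > z_thresh]
        if len(bad) == 0:
            break
        rule2.extend(bad.tolist())
        alive = np.setdiff1d(alive, bad)
    rule2 = sorted(rule2)

    if len(alive) == 0:
        report = RejectionReport(
            channels_rejected_rule1=rule1.tolist(),
            channels_rejected_rule2=rule2,
            epochs_rejected=[],
            channels_interpolated=[],
            kept_channel_fraction=0.0,
            kept_epoch_fraction=0.0,
            passed=False,
        )
        raise RejectionError("all channels rejected", report=report)

    # rule 3: epoch bad on too many surviving channels
    bad_epochs = np.flatnonzero(exceeded[:, alive].mean(axis=1) > epoch_chan_frac)
    kept_epochs = np.setdiff1d(np.arange(n_tr), bad_epochs)
    if len(kept_epochs) == 0:
        report = RejectionReport(
            channels_rejected_rule1=rule1.tolist(),
            channels_rejected_rule2=rule2,
            epochs_rejected=bad_epochs.tolist(),
            channels_interpolated=[],
            kept_channel_fraction=len(alive) / n_ch,
            kept_epoch_fraction=0.0,
            passed=False,
        )
        raise RejectionError("all epochs rejected", report=report)

    out = epochs.select_trials(kept_epochs)
    rejected_channels = np.setdiff1d(np.arange(n_ch), alive)
    _interpolate_channels(out, rejected_channels, alive)

    kept_ch_frac = len(alive) / n_ch
    kept_ep_frac = len(kept_epochs) / n_tr
    report = RejectionReport(
        channels_rejected_rule1=rule1.tolist(),
        channels_rejected_rule2=rule2,
        epochs_rejected=bad_epochs.tolist(),
        channels_interpolated=rejected_channels.tolist(),
        kept_channel_fraction=kept_ch_frac,
        kept_epoch_fraction=kept_ep_frac,
        passed=(kept_ch_frac >= min_kept_fraction) and (kept_ep_frac >= min_kept_fraction),
    )
    logger.info(
        "rejection: %d/%d channels kept, %d/%d epochs kept, passed=%s",
        len(alive), n_ch, len(kept_epochs), n_tr, report.passed,
    )
    return out, report


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (average reference)."""
    if epochs.n_channels < 2:
        raise ValueError("average reference is undefined for a single channel")
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


def baseline_correct(epochs: EpochSet, window) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window=(lo, hi)`` s."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the epoch span")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


#: ERP-mode baseline: the 800 ms before the fifth sound (fifth-aligned epochs)
BASELINE_ERP = (-0.8, 0.0)
#: spectral-mode baseline: the 200 ms before the first sound
BASELINE_SPECTRAL = (-0.8, -0.6)
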