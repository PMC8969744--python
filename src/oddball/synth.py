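"""Synthetic EEG generator with ground-truth evoked components.

Stands in for a real subject recording: continuous multichannel EEG is
assembled from (i) evoked component kernels time-locked to the paradigm's
sound onsets, with amplitudes that may differ by condition (PRE/HYP) and
stimulus class (standard/deviant); (ii) 1/f background noise plus band
oscillations; (iii) optional lagged linear coupling between sensor pairs
(a fixture for connectivity measures); and (iv) optional planted
high-amplitude artifacts (a fixture for the rejection rules).

Component kernels are Hanning bumps spanning the component's latency
window, scaled so that the *mean* voltage over the window equals the
configured amplitude in uV -- i.e. the injected amplitude is directly the
quantity the window-average ERP measurement recovers.  Topography weight
vectors are zero-mean across the montage so that average referencing
leaves injected effects untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet
from .montage import Montage, default_rois
from .paradigm import EventTimeline

__all__ = [
    "ComponentSpec",
    "SimulationConfig",
    "GroundTruth",
    "ArtifactPlan",
    "default_components",
    "simulate_recording",
    "inject_artifacts",
    "couple_sensors",
    "zero_mean_topography",
]

ALIGN_EACH_SOUND = "each_sound"
ALIGN_FIFTH_SOUND = "fifth_sound"

STATES = ("PRE", "HYP")
STIMULI = ("standard", "deviant")


class SimulationError(ValueError):
    pass


def zero_mean_topography(montage: Montage, sensors, counter_sensors=None) -> np.ndarray:
    """Weight +1 on ``sensors``, negative counterweight on ``counter_sensors``.

    Zero-mean weights make injected effects invariant under average
    referencing.  When ``counter_sensors`` is None the counterweight is
    spread over all remaining sensors; placing it on a distant sensor
    group instead keeps other components' measurement ROIs free of
    cross-talk.
    """
    w = np.zeros(montage.n_sensors)
    sensors = np.asarray(sensors)
    w[sensors] = 1.0
    if counter_sensors is None:
        counter_sensors = np.setdiff1d(np.arange(montage.n_sensors), sensors)
    counter_sensors = np.asarray(counter_sensors)
    if len(counter_sensors):
        w[counter_sensors] = -len(sensors) / len(counter_sensors)
    return w


@dataclass
class ComponentSpec:
    """One evoked component.

    ``window`` is the latency window in seconds relative to the eliciting
    sound onset; ``amplitudes`` maps (state, stimulus) to the mean voltage
    in uV that the component contributes over its window on its
    positively-weighted sensors.
    """

    name: str
    window: tuple  # (start, end) s relative to eliciting onset
    amplitudes: dict  # {(state, stimulus): uV}
    topography: np.ndarray  # (n_sensors,)
    align: str = ALIGN_FIFTH_SOUND

    def __post_init__(self):
        lo, hi = self.window
        if not hi > lo:
            raise SimulationError(f"{self.name}: empty latency window")
        self.topography = np.asarray(self.topography, dtype=float)
        if not np.all(np.isfinite(self.topography)):
            raise SimulationError(f"{self.name}: non-finite topography")
        for st in STATES:
            for sm in STIMULI:
                self.amplitudes.setdefault((st, sm), 0.0)

    def kernel(self, sfreq: float) -> np.ndarray:
        """Hanning bump over the window, scaled to unit window mean."""
        n = int(round((self.window[1] - self.window[0]) * sfreq))
        if n < 2:
            raise SimulationError(f"{self.name}: window too short at {sfreq} Hz")
        k = np.hanning(n)
        return k / k.mean()


def default_components(
    montage: Montage,
    p1: float = 1.0,
    mmn: float = 0.0,
    p3a: dict | None = None,
    p3b: dict | None = None,
    rois: dict | None = None,
) -> list:
    """Construct the standard component set for a montage.

    ``p1`` is an unconditional response to every sound onset (same for all
    trials); ``mmn`` a deviant-minus-standard effect present in both
    states; ``p3a``/``p3b`` map state -> deviant-minus-standard effect in
    uV (e.g. ``{"PRE": 1.36}``).  Latency windows are expressed relative
    to the eliciting sound onset; relative to the fifth sound they are the
    conventional MMN 140-192 ms, P3a 280-340 ms and P3b 400-800 ms
    windows, and the P1 window 68-116 ms after each sound onset.
    """
    rois = rois if rois is not None else default_rois(montage)
    p3a = p3a or {}
    p3b = p3b or {}
    # counterweights sit on the anterior (P1) group for the deviant-related
    # components, and vice versa, so that each component's measurement ROI
    # sees no cross-talk from the others (filters smear components in time,
    # so sharing ROI sensors between a component and another component's
    # counterweight would bias nearby windows)
    topo_p1 = zero_mean_topography(
        montage, rois["P1"], np.concatenate([rois["MMN_P3a"], rois["P3b"]])
    )
    topo_mid = zero_mean_topography(montage, rois["MMN_P3a"], rois["P1"])
    topo_post = zero_mean_topography(montage, rois["P3b"], rois["P1"])

    def cells(per_state: dict) -> dict:
        amp = {}
        for st in STATES:
            amp[(st, "deviant")] = float(per_state.get(st, 0.0))
            amp[(st, "standard")] = 0.0
        return amp

    comps = [
        ComponentSpec(
            name="P1",
            window=(0.068, 0.116),
            amplitudes={(st, sm): p1 for st in STATES for sm in STIMULI},
            topography=topo_p1,
            align=ALIGN_EACH_SOUND,
        ),
        ComponentSpec(
            name="MMN",
            window=(0.140, 0.192),
            amplitudes=cells({"PRE": mmn, "HYP": mmn}),
            topography=topo_mid,
            align=ALIGN_FIFTH_SOUND,
        ),
        ComponentSpec(
            name="P3a",
            window=(0.280, 0.340),
            amplitudes=cells(p3a),
            topography=topo_mid,
            align=ALIGN_FIFTH_SOUND,
        ),
        ComponentSpec(
            name="P3b",
            window=(0.400, 0.800),
            amplitudes=cells(p3b),
            topography=topo_post,
            align=ALIGN_FIFTH_SOUND,
        ),
    ]
    return comps


@dataclass
class SimulationConfig:
    """Everything needed to render a continuous synthetic recording."""

    montage: Montage
    components: list
    eeg_rate: float = 250.0
    noise_std: float = 1.0  # uV, std of the 1/f background per channel
    one_over_f_alpha: float = 1.0
    spatial_mixing: float = 0.0  # fraction of noise variance shared across sensors
    n_noise_sources: int = 8
    #: std (uV) of 1/f background projected through each component's own
    #: topography: ongoing activity of the same generators that produce the
    #: evoked components.  It makes multivariate pooling across sensors no
    #: more sensitive than ROI averaging, as in real recordings, instead of
    #: letting a decoder average sensor-private noise away.
    topo_noise_std: float = 0.0
    oscillations: dict = field(default_factory=lambda: {10.0: 0.5})  # Hz -> uV
    coupling: list = field(default_factory=list)  # (src, dst, lag_samples, strength)
    rng_seed: int = 0
    pad: float = 1.0  # silence appended after the last sound, s

    def __post_init__(self):
        if self.eeg_rate <= 2 * 45.0:
            raise SimulationError("eeg_rate must exceed twice the highest analyzed frequency (45 Hz)")
        for src, dst, lag, strength in self.coupling:
            if int(lag) != lag:
                raise SimulationError("coupling lags must be whole samples")


@dataclass
class GroundTruth:
    """What was actually put into a simulated recording."""

    metadata: pd.DataFrame  # per-series state/stimulus/onsets
    injected: dict  # component name -> {(state, stimulus): uV}
    coupling: list
    rng_seed: int


def _one_over_f_noise(rng, n_channels, n_samples, sfreq, alpha):
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = noise.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def _narrowband_noise(rng, n_channels, n_samples, sfreq, center, rel_bw=0.15):
    """Stochastic band-limited oscillation (unit variance per channel).

    White noise spectrally shaped by a Gaussian bump at ``center`` Hz
    (relative bandwidth ``rel_bw``): an oscillation with naturally
    drifting amplitude and phase, as scalp rhythms have -- a pure
    deterministic sinusoid would be phase-locked to the discrete event
    grid and bias event-locked averages.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    bw = max(rel_bw * center, 0.5)
    shaping = np.exp(-0.5 * ((freqs - center) / bw) ** 2)
    shaping[0] = 0.0
    osc = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = osc.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return osc / sd


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """x delayed by ``lag`` samples along the last axis, zero-filled."""
    if lag == 0:
        return x.copy()
    out = np.zeros_like(x)
    if lag > 0:
        out[..., lag:] = x[..., :-lag]
    else:
        out[..., :lag] = x[..., -lag:]
    return out


def simulate_recording(config: SimulationConfig, timeline: EventTimeline):
    """Render the continuous recording for a state-labelled timeline.

    Returns ``(ContinuousEEG, GroundTruth)``.  The timeline must carry
    per-series ``state`` labels (use ``EventTimeline.with_state``).
    """
    if timeline.state is None:
        raise SimulationError("timeline must carry state labels (use with_state)")
    fs = config.eeg_rate
    n_samples = int(np.ceil((timeline.end_time + config.pad) * fs))
    n_ch = config.montage.n_sensors
    data = np.zeros((n_ch, n_samples))

    for comp in config.components:
        kern = comp.kernel(fs)
        start_offset = int(round(comp.window[0] * fs))
        if comp.align == ALIGN_EACH_SOUND:
            onset_cols = range(5)
        else:
            onset_cols = (4,)
        for i in range(timeline.n_series):
            amp = comp.amplitudes.get((timeline.state[i], timeline.kind[i]), 0.0)
            if amp == 0.0:
                continue
            for j in onset_cols:
                s0 = int(round(timeline.sound_onsets[i, j] * fs)) + start_offset
                s1 = s0 + len(kern)
                if s0 < 0 or s1 > n_samples:
                    raise SimulationError(
                        f"component {comp.name} extends beyond the recording"
                    )
                data[:, s0:s1] += amp * np.outer(comp.topography, kern)

    rng = np.random.default_rng(config.rng_seed)
    if config.noise_std > 0:
        noise = _one_over_f_noise(rng, n_ch, n_samples, fs, config.one_over_f_alpha)
        if config.spatial_mixing > 0:
            # spatially coherent background: a few 1/f sources mixed into all
            # sensors (volume-conduction-like), blended with private noise
            sources = _one_over_f_noise(
                rng, config.n_noise_sources, n_samples, fs, config.one_over_f_alpha
            )
            mix = rng.standard_normal((n_ch, config.n_noise_sources))
            mix /= np.linalg.norm(mix, axis=1, keepdims=True)
            shared = mix @ sources
            sd = shared.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            shared /= sd
            lam = config.spatial_mixing
            noise = np.sqrt(lam) * shared + np.sqrt(1.0 - lam) * noise
        data += config.noise_std * noise
    if config.topo_noise_std > 0:
        for comp in config.components:
            src = _one_over_f_noise(rng, 1, n_samples, fs, config.one_over_f_alpha)[0]
            data += config.topo_noise_std * np.outer(comp.topography, src)
    for freq, amp in config.oscillations.items():
        if amp <= 0:
            continue
        data += amp * _narrowband_noise(rng, n_ch, n_samples, fs, freq)

    if config.coupling:
        base = data.copy()
        for src, dst, lag, strength in config.coupling:
            data[dst] += strength * _lagged(base[src], int(lag))

    gt = GroundTruth(
        metadata=timeline.metadata(),
        injected={c.name: dict(c.amplitudes) for c in config.components},
        coupling=list(config.coupling),
        rng_seed=config.rng_seed,
    )
    return ContinuousEEG(data, fs, config.montage), gt


@dataclass
class ArtifactPlan:
    """Planted high-amplitude artifacts, addressed by explicit indices.

    ``bad_channels`` maps channel -> epoch indices in which that channel is
    contaminated; ``bad_epochs`` maps epoch -> channel indices contaminated
    within that epoch.  ``amplitude`` is the planted step size in uV
    (peak-to-peak of the artifact), chosen well above the 100-uV rejection
    threshold by default.
    """

    bad_channels: dict = field(default_factory=dict)
    bad_epochs: dict = field(default_factory=dict)
    amplitude: float = 1000.0

    @staticmethod
    def for_channel_fraction(channel: int, fraction: float, n_epochs: int, rng_seed: int = 0,
                             amplitude: float = 1000.0) -> "ArtifactPlan":
        """Contaminate ``channel`` in round(fraction * n_epochs) epochs."""
        rng = np.random.default_rng(rng_seed)
        k = int(round(fraction * n_epochs))
        eps = np.sort(rng.choice(n_epochs, size=k, replace=False))
        return ArtifactPlan(bad_channels={channel: eps}, amplitude=amplitude)

    @staticmethod
    def for_epoch_fraction(epoch: int, fraction: float, n_channels: int, rng_seed: int = 0,
                           amplitude: float = 1000.0) -> "ArtifactPlan":
        """Contaminate ``epoch`` on round(fraction * n_channels) channels."""
        rng = np.random.default_rng(rng_seed)
        k = int(round(fraction * n_channels))
        chs = np.sort(rng.choice(n_channels, size=k, replace=False))
        return ArtifactPlan(bad_epochs={epoch: chs}, amplitude=amplitude)

    def merged(self, other: "ArtifactPlan") -> "ArtifactPlan":
        bc = {k: np.asarray(v) for k, v in self.bad_channels.items()}
        for k, v in other.bad_channels.items():
            bc[k] = np.union1d(bc.get(k, np.empty(0, int)), v)
        be = {k: np.asarray(v) for k, v in self.bad_epochs.items()}
        for k, v in other.bad_epochs.items():
            be[k] = np.union1d(be.get(k, np.empty(0, int)), v)
        return ArtifactPlan(bad_channels=bc, bad_epochs=be, amplitude=self.amplitude)


def _step_artifact(n_times: int, amplitude: float) -> np.ndarray:
    """Step waveform with peak-to-peak exactly ``amplitude``."""
    half = n_times // 2
    art = np.full(n_times, amplitude / 2.0)
    art[half:] = -amplitude / 2.0
    return art


def inject_artifacts(epochs: EpochSet, plan: ArtifactPlan) -> EpochSet:
    """Add planted step artifacts to an epoch set (returns a copy)."""
    out = epochs.copy()
    art = _step_artifact(out.n_times, plan.amplitude)
    for ch, eps in plan.bad_channels.items():
        eps = np.asarray(eps, dtype=int)
        if len(eps) and (eps.min() < 0 or eps.max() >= out.n_trials):
            raise IndexError("artifact plan epoch index out of bounds")
        out.data[eps, ch, :] += art
    for ep, chs in plan.bad_epochs.items():
        chs = np.asarray(chs, dtype=int)
        if len(chs) and (chs.min() < 0 or chs.max() >= out.n_channels):
            raise IndexError("artifact plan channel index out of bounds")
        out.data[ep, chs, :] += art
    return out


def couple_sensors(epochs: EpochSet, pairs, lag: int, strength: float) -> EpochSet:
    """Add a delayed, scaled copy of each source channel onto its target.

    ``pairs`` is a list of (source, target) channel indices; ``lag`` is in
    whole samples.  Coupling reads from the *input* data, so the order of
    pairs does not matter.
    """
    if int(lag) != lag:
        raise ValueError("lag must be a whole number of samples")
    out = epochs.copy()
    base = epochs.data
    for src, dst in pairs:
        out.data[:, dst, :] += strength * _lagged(base[:, src, :], int(lag))
    return out
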