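"""Auditory odd-ball paradigm: stimuli, block composition and event timing.

The paradigm presents series of five 50-ms complex sounds at a 150-ms
stimulus onset asynchrony (SOA).  A series is *standard* when all five
sounds are identical (AAAAA / BBBBB) and *deviant* when the fifth sound
differs (AAAAB / BBBBA).  Blocks of type ``a`` contain only A-based series
(67% AAAAA / 33% AAAAB) and blocks of type ``b`` only B-based ones.
Consecutive series are separated by a variable silent interval drawn from
a discrete uniform grid (1.350-1.650 s in 50-ms steps).

Each sound is the sum of three equal-amplitude sinusoids (sound A:
350/700/1400 Hz; sound B: 500/1000/2000 Hz) with 7-ms linear rise and
fall ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SoundSpec",
    "SOUND_A",
    "SOUND_B",
    "SeriesSpec",
    "BlockPlan",
    "EventTimeline",
    "synthesize_sound",
    "build_block",
    "schedule_events",
]

STANDARD = "standard"
DEVIANT = "deviant"


class ParadigmError(ValueError):
    """Invalid stimulus or schedule specification."""


@dataclass(frozen=True)
class SoundSpec:
    """Three-tone complex sound.

    Parameters
    ----------
    tone_frequencies : tuple of 3 floats
        Frequencies of the sinusoidal components, Hz.
    duration : float
        Total sound duration, s.
    ramp : float
        Linear rise and fall time, s.
    audio_rate : float
        Audio sampling rate, samples/s.
    label : str
        "A" or "B".
    amplitudes : tuple of 3 floats
        Relative amplitude of each tone before peak normalization.
    """

    tone_frequencies: tuple
    duration: float = 0.050
    ramp: float = 0.007
    audio_rate: float = 44100.0
    label: str = "A"
    amplitudes: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.tone_frequencies) != 3 or len(self.amplitudes) != 3:
            raise ParadigmError("a sound is composed of exactly three tones")
        if not self.duration > 2 * self.ramp:
            raise ParadigmError("duration must exceed twice the ramp time")
        nyquist = self.audio_rate / 2.0
        if any(f >= nyquist for f in self.tone_frequencies):
            raise ParadigmError("tone frequency at or above Nyquist")


SOUND_A = SoundSpec(tone_frequencies=(350.0, 700.0, 1400.0), label="A")
SOUND_B = SoundSpec(tone_frequencies=(500.0, 1000.0, 2000.0), label="B")


def synthesize_sound(spec: SoundSpec) -> np.ndarray:
    """Render a SoundSpec to a waveform (float array, peak <= 1).

    Sum of three equal-amplitude sinusoids over the full duration, with a
    linear amplitude ramp over the first and last ``ramp`` seconds, peak
    normalized.
    """
    n = int(round(spec.duration * spec.audio_rate))
    t = np.arange(n) / spec.audio_rate
    wave = np.zeros(n)
    for f, a in zip(spec.tone_frequencies, spec.amplitudes):
        wave += a * np.sin(2.0 * np.pi * f * t)
    n_ramp = int(round(spec.ramp * spec.audio_rate))
    if n_ramp > 0:
        env = np.ones(n)
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[n - n_ramp:] = ramp[::-1]
        wave = wave * env
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak
    return wave


@dataclass(frozen=True)
class SeriesSpec:
    """One series of five sounds."""

    sounds: tuple  # five labels from {"A", "B"}
    soa: float = 0.150

    def __post_init__(self):
        if len(self.sounds) != 5:
            raise ParadigmError("a series contains exactly five sounds")
        if any(s not in ("A", "B") for s in self.sounds):
            raise ParadigmError("sound labels must be 'A' or 'B'")
        first_four = set(self.sounds[:4])
        if len(first_four) != 1:
            raise ParadigmError("the first four sounds must be identical")

    @property
    def kind(self) -> str:
        return STANDARD if self.sounds[4] == self.sounds[0] else DEVIANT


@dataclass(frozen=True)
class BlockPlan:
    """Ordered series composition of one stimulation block."""

    block_type: str  # "a" or "b"
    series: tuple  # of SeriesSpec

    def __post_init__(self):
        base = "A" if self.block_type == "a" else "B"
        for s in self.series:
            if s.sounds[0] != base:
                raise ParadigmError(
                    f"block type {self.block_type} may only contain {base}-based series"
                )

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def deviant_count(self) -> int:
        return sum(1 for s in self.series if s.kind == DEVIANT)


def build_block(
    block_type: str,
    n_series: int = 78,
    deviant_fraction: float = 0.33,
    rng_seed: int = 0,
    soa: float = 0.150,
) -> BlockPlan:
    """Compose a block with round(deviant_fraction * n_series) deviants,
    uniformly shuffled by the seeded generator.

    Rounding is half-away-from-zero, so the printed 67%/33% split of a
    78-series block yields 52 standards and 26 deviants.
    """
    if block_type not in ("a", "b"):
        raise ParadigmError("block_type must be 'a' or 'b'")
    if not (0.0 < deviant_fraction < 1.0):
        raise ParadigmError("deviant_fraction must lie strictly between 0 and 1")
    if n_series < 1:
        raise ParadigmError("n_series must be >= 1")
    base = "A" if block_type == "a" else "B"
    other = "B" if base == "A" else "A"
    n_dev = int(np.floor(deviant_fraction * n_series + 0.5))
    std = SeriesSpec(sounds=(base,) * 5, soa=soa)
    dev = SeriesSpec(sounds=(base,) * 4 + (other,), soa=soa)
    series = [std] * (n_series - n_dev) + [dev] * n_dev
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_series)
    return BlockPlan(block_type=block_type, series=tuple(series[i] for i in order))


@dataclass
class EventTimeline:
    """Absolute event times of a scheduled sequence of series.

    ``sound_onsets`` has shape (n_series, 5); ``series_onset`` is its first
    column.  ``state`` is an optional per-series condition label (PRE/HYP)
    attached when sessions are assembled.
    """

    sound_onsets: np.ndarray
    kind: np.ndarray  # "standard" / "deviant" per series
    block_type: np.ndarray  # per series
    isi: np.ndarray  # (n_series - 1,), gap after each series' fifth sound
    soa: float
    sound_duration: float
    state: np.ndarray | None = None

    def __post_init__(self):
        self.sound_onsets = np.asarray(self.sound_onsets, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.block_type = np.asarray(self.block_type, dtype=object)
        self.isi = np.asarray(self.isi, dtype=float)
        if self.sound_onsets.ndim != 2 or self.sound_onsets.shape[1] != 5:
            raise ParadigmError("sound_onsets must be (n_series, 5)")
        if self.state is not None:
            self.state = np.asarray(self.state, dtype=object)

    @property
    def n_series(self) -> int:
        return self.sound_onsets.shape[0]

    @property
    def series_onset(self) -> np.ndarray:
        return self.sound_onsets[:, 0]

    @property
    def fifth_onset(self) -> np.ndarray:
        return self.sound_onsets[:, 4]

    @property
    def end_time(self) -> float:
        return float(self.fifth_onset[-1] + self.sound_duration)

    def with_state(self, state: str) -> "EventTimeline":
        out = replace(self)
        out.state = np.asarray([state] * self.n_series, dtype=object)
        return out

    def shifted(self, offset: float) -> "EventTimeline":
        out = replace(self)
        out.sound_onsets = self.sound_onsets + offset
        return out

    def metadata(self) -> pd.DataFrame:
        """One row per series: onset, stimulus kind, block type, state."""
        return pd.DataFrame(
            {
                "series_index": np.arange(self.n_series),
                "onset": self.series_onset,
                "fifth_onset": self.fifth_onset,
                "stimulus": self.kind,
                "block_type": self.block_type,
                "state": self.state if self.state is not None else [None] * self.n_series,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-sound event table (onset_s, duration_s, trial_type, ...)."""
        rows = []
        for i in range(self.n_series):
            for j in range(5):
                rows.append(
                    {
                        "onset_s": self.sound_onsets[i, j],
                        "duration_s": self.sound_duration,
                        "trial_type": self.kind[i],
                        "block_type": self.block_type[i],
                        "series_index": i,
                        "sound_index": j,
                        "state": self.state[i] if self.state is not None else "",
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def concatenate(timelines) -> "EventTimeline":
        """Join timelines (already shifted to absolute time, states attached)."""
        timelines = list(timelines)
        soa = timelines[0].soa
        dur = timelines[0].sound_duration
        states = [
            tl.state if tl.state is not None else np.asarray([None] * tl.n_series)
            for tl in timelines
        ]
        return EventTimeline(
            sound_onsets=np.concatenate([tl.sound_onsets for tl in timelines]),
            kind=np.concatenate([tl.kind for tl in timelines]),
            block_type=np.concatenate([tl.block_type for tl in timelines]),
            isi=np.concatenate([tl.isi for tl in timelines] or [np.empty(0)]),
            soa=soa,
            sound_duration=dur,
            state=np.concatenate(states),
        )


def schedule_events(
    block: BlockPlan,
    soa: float = 0.150,
    isi_min: float = 1.350,
    isi_max: float = 1.650,
    isi_step: float = 0.050,
    rng_seed: int = 0,
    t_start: float = 1.0,
    sound_duration: float = 0.050,
) -> EventTimeline:
    """Lay the block's series out in time.

    Within a series, consecutive sound onsets are exactly ``soa`` apart.
    The gap between the *end* of a series' fifth sound and the next
    series' first sound is drawn uniformly from the discrete grid
    ``isi_min, isi_min + isi_step, ..., isi_max``.
    """
    if isi_min > isi_max:
        raise ParadigmError("isi_min must not exceed isi_max")
    span = isi_max - isi_min
    if isi_step <= 0:
        raise ParadigmError("isi_step must be positive")
    n_steps = span / isi_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParadigmError("isi_step must divide the ISI range exactly")
    choices = isi_min + isi_step * np.arange(int(round(n_steps)) + 1)

    rng = np.random.default_rng(rng_seed)
    n = block.n_series
    isi = choices[rng.integers(0, len(choices), size=max(n - 1, 0))]

    onsets = np.empty((n, 5))
    t = t_start
    for i in range(n):
        onsets[i] = t + soa * np.arange(5)
        if i < n - 1:
            t = onsets[i, 4] + sound_duration + isi[i]
    return EventTimeline(
        sound_onsets=onsets,
        kind=np.asarray([s.kind for s in block.series], dtype=object),
        block_type=np.asarray([block.block_type] * n, dtype=object),
        isi=isi,
        soa=soa,
        sound_duration=sound_duration,
    )
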