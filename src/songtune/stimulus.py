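"""Synthetic courtship-song stimuli.

Drosophila melanogaster pulse song is a train of brief Gaussian-enveloped
sinusoidal pulses (~220 Hz carrier) separated by the inter-pulse interval
(IPI, ~35 ms in conspecific song); sine song is a continuous low-frequency
hum.  This module synthesizes calibrated waveforms for these stimuli plus
band-limited white noise, and assembles them into playback protocols
(intensity ramps, intermittent trains) on a shared time grid.

Calibration is relative: amplitude 1.0 corresponds to the reference level
``REF_DB`` (80 dB SPL) and scales by ``10**((level - REF_DB)/20)``.  Mapping
dB SPL to absolute particle velocity is a property of the playback hardware
and is not modelled here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "REF_DB",
    "db_to_amplitude",
    "PulseTrainSpec",
    "SineSpec",
    "NoiseSpec",
    "Waveform",
    "ProtocolSegment",
    "StimulusProtocol",
    "make_pulse",
    "make_pulse_train",
    "make_sine",
    "make_noise",
    "make_ramp_protocol",
    "make_intermittent_protocol",
]

#: Reference level (dB SPL) at which waveform amplitude is 1.0.
REF_DB = 80.0

#: Default sampling rate for synthesized stimuli (samples/s).
DEFAULT_SAMPLE_RATE = 10_000.0

#: Pulse envelopes are truncated at +/- this many standard deviations.
ENVELOPE_TRUNC_SD = 3.0


def db_to_amplitude(level_db: float, ref_db: float = REF_DB) -> float:
    """Peak-amplitude scale factor for a sound level in dB re ``ref_db``."""
    return float(10.0 ** ((level_db - ref_db) / 20.0))


def _read_source(source) -> str:
    """Accept either a path to a JSON file or a JSON string."""
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "{" not in source:
        return Path(source).read_text()
    return str(source)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of a pulse-song train.

    ``ipi_ms`` is the peak-to-peak interval between successive pulse
    envelope maxima; ``envelope_sigma_ms`` the Gaussian envelope SD.
    """

    carrier_freq: float = 220.0
    ipi_ms: float = 35.0
    n_pulses: int = 40
    envelope_sigma_ms: float = 2.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    level_db: float = REF_DB

    def __post_init__(self) -> None:
        if self.ipi_ms <= 0:
            raise ValueError(f"ipi_ms must be positive, got {self.ipi_ms}")
        if self.n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if self.envelope_sigma_ms <= 0:
            raise ValueError("envelope_sigma_ms must be positive")
        if self.carrier_freq <= 0:
            raise ValueError("carrier_freq must be positive")
        if self.sample_rate < 4.0 * self.carrier_freq:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz is too low for a "
                f"{self.carrier_freq} Hz carrier; need >= 4x the carrier "
                "frequency to represent the pulse faithfully"
            )

    @property
    def pulse_support_ms(self) -> float:
        """Total truncated envelope support (ms)."""
        return 2.0 * ENVELOPE_TRUNC_SD * self.envelope_sigma_ms

    @property
    def span_s(self) -> float:
        """Peak-to-peak span of the train plus envelope tails (s)."""
        return ((self.n_pulses - 1) * self.ipi_ms + self.pulse_support_ms) / 1000.0


@dataclass(frozen=True)
class SineSpec:
    """Sine-song stimulus: a pure tone (default 140 Hz, 1.4 s)."""

    freq: float = 140.0
    duration: float = 1.4
    level_db: float = REF_DB
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        if self.sample_rate < 4.0 * self.freq:
            raise ValueError("sample_rate too low for sine frequency")


@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited white-noise stimulus (default 1.4 s), seeded."""

    duration: float = 1.4
    level_db: float = REF_DB
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


# ---------------------------------------------------------------------------
# Waveform container
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """A sampled pressure signal with its sample rate and dB calibration tag."""

    samples: np.ndarray
    sample_rate: float
    level_db: float = REF_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def to_wav(self, path: str | Path) -> None:
        wavfile.write(str(path), int(round(self.sample_rate)),
                      self.samples.astype(np.float32))

    @classmethod
    def from_wav(cls, path: str | Path, level_db: float = REF_DB) -> "Waveform":
        rate, data = wavfile.read(str(path))
        return cls(np.asarray(data, dtype=np.float64), float(rate), level_db)

    def spectral_argmax(self, min_duration_s: float = 1.0) -> float:
        """Frequency (Hz) of the magnitude-spectrum maximum.

        Zero-pads to at least ``min_duration_s`` so the FFT resolution is
        at most ``1/min_duration_s`` Hz.
        """
        n = max(len(self.samples), int(round(min_duration_s * self.sample_rate)))
        spectrum = np.abs(np.fft.rfft(self.samples, n=n))
        freqs = np.fft.rfftfreq(n, d=1.0 / self.sample_rate)
        return float(freqs[int(np.argmax(spectrum))])


# ---------------------------------------------------------------------------
# Elementary stimuli
# ---------------------------------------------------------------------------

def make_pulse(spec: PulseTrainSpec) -> Waveform:
    """One Gaussian-enveloped sinusoidal pulse.

    s(t) = A * exp(-t^2 / 2 sigma^2) * sin(2 pi f_c t) on t in
    [-3 sigma, +3 sigma], envelope peak at t = 0.
    """
    sigma = spec.envelope_sigma_ms / 1000.0
    half = int(round(ENVELOPE_TRUNC_SD * sigma * spec.sample_rate))
    t = np.arange(-half, half + 1) / spec.sample_rate
    amp = db_to_amplitude(spec.level_db)
    samples = amp * np.exp(-t ** 2 / (2.0 * sigma ** 2)) * np.sin(
        2.0 * np.pi * spec.carrier_freq * t)
    return Waveform(samples, spec.sample_rate, spec.level_db)


def make_pulse_train(spec: PulseTrainSpec) -> Waveform:
    """``n_pulses`` copies of :func:`make_pulse` at peak-to-peak IPI spacing."""
    if spec.ipi_ms <= spec.pulse_support_ms and spec.n_pulses > 1:
        raise ValueError(
            f"IPI {spec.ipi_ms} ms <= pulse support {spec.pulse_support_ms} ms: "
            "pulses would overlap; increase ipi_ms or narrow the envelope"
        )
    pulse = make_pulse(spec).samples
    ipi_samp = spec.ipi_ms / 1000.0 * spec.sample_rate
    n_total = int(round((spec.n_pulses - 1) * ipi_samp)) + len(pulse)
    out = np.zeros(n_total)
    for i in range(spec.n_pulses):
        start = int(round(i * ipi_samp))
        out[start:start + len(pulse)] += pulse
    return Waveform(out, spec.sample_rate, spec.level_db)


def make_sine(spec: SineSpec) -> Waveform:
    """Sine song: A * sin(2 pi f t) for the given duration."""
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    amp = db_to_amplitude(spec.level_db)
    return Waveform(amp * np.sin(2.0 * np.pi * spec.freq * t),
                    spec.sample_rate, spec.level_db)


def make_noise(spec: NoiseSpec) -> Waveform:
    """Seeded Gaussian white noise, band-limited to Nyquist by sampling.

    Scaled so the RMS equals the calibrated amplitude A(level_db); with the
    same seed the samples are bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    samples = rng.standard_normal(n)
    rms = np.sqrt(np.mean(samples ** 2))
    samples *= db_to_amplitude(spec.level_db) / rms
    return Waveform(samples, spec.sample_rate, spec.level_db)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

_SPEC_TYPES = {"pulse_train": PulseTrainSpec, "sine": SineSpec, "noise": NoiseSpec}


@dataclass(frozen=True)
class ProtocolSegment:
    """One stimulus epoch within a protocol (silence between segments is
    implicit)."""

    start_s: float
    kind: str                    # 'pulse_train' | 'sine' | 'noise'
    spec: PulseTrainSpec | SineSpec | NoiseSpec

    @property
    def duration_s(self) -> float:
        if isinstance(self.spec, PulseTrainSpec):
            return self.spec.span_s
        return self.spec.duration

    @property
    def level_db(self) -> float:
        return self.spec.level_db


@dataclass
class StimulusProtocol:
    """Ordered, non-overlapping stimulus segments on a common timeline."""

    segments: list[ProtocolSegment]
    total_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        starts = [s.start_s for s in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.start_s + a.duration_s > b.start_s + 1e-9:
                raise ValueError(
                    f"segments overlap at t={b.start_s:.3f}s: previous segment "
                    f"ends at {a.start_s + a.duration_s:.3f}s"
                )

    # -- event view (consumed by trace_metrics / synthetic_data) ------------

    def events(self) -> list[dict]:
        """Stimulus-onset table: one dict per segment with onset/kind/ipi/dB."""
        out = []
        for seg in self.segments:
            ev = {"onset": seg.start_s, "kind": seg.kind,
                  "level_db": seg.level_db, "duration": seg.duration_s}
            if isinstance(seg.spec, PulseTrainSpec):
                ev["ipi_ms"] = seg.spec.ipi_ms
            out.append(ev)
        return out

    # -- rendering -----------------------------------------------------------

    def render(self, sample_rate: float = DEFAULT_SAMPLE_RATE) -> Waveform:
        """Concatenate all segments (with silences) into one waveform."""
        n = int(round(self.total_s * sample_rate))
        out = np.zeros(n)
        for seg in self.segments:
            spec = seg.spec
            if spec.sample_rate != sample_rate:
                spec = type(spec)(**{**asdict(spec), "sample_rate": sample_rate})
            wf = _RENDERERS[seg.kind](spec)
            start = int(round(seg.start_s * sample_rate))
            stop = min(start + len(wf.samples), n)
            out[start:stop] += wf.samples[: stop - start]
        return Waveform(out, sample_rate, REF_DB)

    # -- serialization --------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "total_s": self.total_s,
            "metadata": self.metadata,
            "segments": [
                {"start_s": s.start_s, "kind": s.kind, "spec": asdict(s.spec)}
                for s in self.segments
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StimulusProtocol":
        doc = json.loads(_read_source(source))
        segments = [
            ProtocolSegment(d["start_s"], d["kind"],
                            _SPEC_TYPES[d["kind"]](**d["spec"]))
            for d in doc["segments"]
        ]
        return cls(segments, doc["total_s"], doc.get("metadata", {}))


_RENDERERS = {"pulse_train": make_pulse_train, "sine": make_sine, "noise": make_noise}


def make_ramp_protocol(train: PulseTrainSpec,
                       levels_db: list[float] | np.ndarray | None = None,
                       block_s: float = 30.0,
                       lead_silence_s: float = 60.0) -> StimulusProtocol:
    """Intensity-ramp protocol: lead silence, then one continuous pulse-song
    block per level, each ``block_s`` long with level increasing block by
    block (default 60 to 90 dB in 2.5 dB steps after 60 s of silence).

    Within a block the train is continuous: pulses at the spec IPI fill the
    whole block, so the pulse count per block depends on IPI.
    """
    if levels_db is None:
        levels_db = np.arange(60.0, 90.0 + 1e-9, 2.5)
    levels_db = list(np.asarray(levels_db, dtype=float))
    if len(levels_db) == 0:
        raise ValueError("levels_db must contain at least one level")
    if any(b < a for a, b in zip(levels_db, levels_db[1:])):
        raise ValueError("levels_db must be non-decreasing (a ramp)")

    segments = []
    for i, level in enumerate(levels_db):
        start = lead_silence_s + i * block_s
        # continuous train filling the block: last peak at most block end
        n_pulses = int(np.floor((block_s * 1000.0 - train.pulse_support_ms)
                                / train.ipi_ms)) + 1
        spec = PulseTrainSpec(
            carrier_freq=train.carrier_freq, ipi_ms=train.ipi_ms,
            n_pulses=n_pulses, envelope_sigma_ms=train.envelope_sigma_ms,
            sample_rate=train.sample_rate, level_db=level)
        segments.append(ProtocolSegment(start, "pulse_train", spec))
    total = lead_silence_s + len(levels_db) * block_s
    return StimulusProtocol(segments, total, metadata={
        "protocol": "ramp", "levels_db": levels_db, "block_s": block_s,
        "lead_silence_s": lead_silence_s, "ipi_ms": train.ipi_ms})


def make_intermittent_protocol(train: PulseTrainSpec,
                               period_s: float = 5.0,
                               total_song_s: float = 120.0,
                               lead_s: float = 60.0,
                               tail_s: float = 120.0) -> StimulusProtocol:
    """Intermittent protocol: a fixed-length train every ``period_s`` during
    the song window, flanked by silences (default 1 min silence, 2 min of
    40-pulse trains every 5 s, 2 min silence).  Pulse count per window is
    IPI-independent by construction.
    """
    if period_s < train.span_s:
        raise ValueError(
            f"train span {train.span_s:.3f}s exceeds period {period_s}s: "
            "trains would overlap")
    n_trains = int(np.floor(total_song_s / period_s + 1e-9))
    segments = [
        ProtocolSegment(lead_s + i * period_s, "pulse_train", train)
        for i in range(n_trains)
    ]
    total = lead_s + total_song_s + tail_s
    return StimulusProtocol(segments, total, metadata={
        "protocol": "intermittent", "period_s": period_s,
        "song_window": [lead_s, lead_s + total_song_s],
        "ipi_ms": train.ipi_ms, "level_db": train.level_db})
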