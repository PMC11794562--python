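"""Synthetic annotated single-lead ECG with labelled N/S/V beats.

Each beat is a sum of Gaussian bumps, one per wave (P, Q, R, S, T), with
textbook lead-II proportions as defaults.  The class contrasts give both
classifier branches learnable signal and mirror how cardiologists read
the real classes:

* **S** (supraventricular ectopic): the P wave is absent (overlapped with
  the previous T), and the preceding RR interval is shortened by 30%, so
  ratio-RR < 1 by construction.
* **V** (ventricular ectopic): a broad QRS — the Q/R/S widths are scaled
  by at least 1.8x — and no P wave.

A record concatenates beats at jittered RR intervals on top of a
sinusoidal baseline drift plus white noise, and can be written as a WFDB
triplet so the whole file-reading pipeline is testable offline.  The
morphology is deliberately schematic: it does not emulate inter-patient
variability, electrode noise types, or real arrhythmia diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pmat import wfdb_io
from pmat.preprocessing import AnnotatedSignal

#: AAMI class -> annotation symbol used in fixtures (round-trips via map_aami)
CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V"}


@dataclass
class WaveSpec:
    """One Gaussian bump: amplitude (dimensionless), center and width (s)."""

    amplitude: float
    center: float
    width: float


@dataclass
class BeatTemplateParams:
    """Per-wave parameters of the beat template (centers relative to R)."""

    p: WaveSpec = field(default_factory=lambda: WaveSpec(0.15, -0.17, 0.025))
    q: WaveSpec = field(default_factory=lambda: WaveSpec(-0.10, -0.035, 0.010))
    r: WaveSpec = field(default_factory=lambda: WaveSpec(1.00, 0.0, 0.012))
    s: WaveSpec = field(default_factory=lambda: WaveSpec(-0.20, 0.035, 0.012))
    t: WaveSpec = field(default_factory=lambda: WaveSpec(0.30, 0.22, 0.050))
    v_width_factor: float = 1.9  # QRS widening for class V (>= 1.8)

    def waves_for_class(self, cls: str) -> list[WaveSpec]:
        if cls == "N":
            return [self.p, self.q, self.r, self.s, self.t]
        if cls == "S":
            return [self.q, self.r, self.s, self.t]
        if cls == "V":
            f = self.v_width_factor
            widen = [replace(w, width=w.width * f) for w in (self.q, self.r,
                                                             self.s)]
            return widen + [self.t]
        raise ValueError(f"class must be one of N/S/V, got {cls!r}")


@dataclass
class RhythmSpec:
    """Generation parameters of one synthetic record."""

    n_beats: int = 100
    class_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # P(N), P(S), P(V)
    base_rr: float = 0.8          # seconds
    rr_jitter: float = 0.05       # fractional s.d. of RR intervals
    s_rr_shortening: float = 0.3  # fraction removed from the RR before an S beat
    baseline_amp: float = 0.15    # baseline drift amplitude (signal units)
    baseline_freq: float = 0.3    # Hz
    noise_sd: float = 0.02        # white noise s.d.
    fs: float = 360.0             # Hz (MIT-BIH rate)
    seed: int = 0
    template: BeatTemplateParams = field(default_factory=BeatTemplateParams)

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.base_rr <= 0 or self.fs <= 0:
            raise ValueError("base_rr and fs must be positive")


def synth_beat(cls: str, fs: float = 360.0,
               template: BeatTemplateParams | None = None,
               pre: float = 0.25, post: float = 0.45) -> np.ndarray:
    """One noiseless beat of class ``cls`` on a [-pre, post) grid around R."""
    template = template or BeatTemplateParams()
    t = np.arange(-int(pre * fs), int(post * fs)) / fs
    out = np.zeros_like(t)
    for wave in template.waves_for_class(cls):
        out += wave.amplitude * np.exp(-0.5 * ((t - wave.center) / wave.width) ** 2)
    return out


def synth_record(spec: RhythmSpec) -> tuple[AnnotatedSignal, list[str]]:
    """Generate an annotated record; returns (signal, per-beat class labels).

    R-peak sample indices and labels are exact by construction; the RR
    interval preceding each S beat is shortened by ``s_rr_shortening``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(rng.choice(["N", "S", "V"], size=spec.n_beats,
                             p=spec.class_mix))
    rr = spec.base_rr * (1.0 + spec.rr_jitter * rng.standard_normal(spec.n_beats))
    rr = np.clip(rr, 0.3 * spec.base_rr, None)
    for i, cls in enumerate(labels):
        if cls == "S":
            rr[i] *= 1.0 - spec.s_rr_shortening
    peak_times = 0.5 + np.cumsum(rr)  # first peak 0.5 s + rr[0] into the record
    duration = peak_times[-1] + 0.6
    n = int(duration * spec.fs)
    t = np.arange(n) / spec.fs
    signal = np.zeros(n)
    half = 0.5  # beat support half-width in seconds
    for pt, cls in zip(peak_times, labels):
        lo = max(0, int((pt - half) * spec.fs))
        hi = min(n, int((pt + half) * spec.fs))
        tt = t[lo:hi] - pt
        for wave in spec.template.waves_for_class(cls):
            signal[lo:hi] += wave.amplitude * np.exp(
                -0.5 * ((tt - wave.center) / wave.width) ** 2)
    if spec.baseline_amp:
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.baseline_amp * np.sin(
            2 * np.pi * spec.baseline_freq * t + phase)
    if spec.noise_sd:
        signal += spec.noise_sd * rng.standard_normal(n)
    r_peaks = np.round(peak_times * spec.fs).astype(np.int64)
    symbols = np.array([CLASS_SYMBOL[c] for c in labels])
    annotated = AnnotatedSignal(samples=signal, sampling_rate=spec.fs,
                                r_peaks=r_peaks, beat_symbols=symbols)
    return annotated, labels


def write_wfdb_fixture(record: AnnotatedSignal, labels: list[str],
                       directory, name: str = "synth",
                       gain: float = 1000.0) -> None:
    """Write the record as a WFDB triplet readable by datasets.read_record.

    The 16-bit quantization at the default gain keeps the round-trip error
    below 1e-3 of the signal range; peak positions round-trip exactly.
    """
    annotations = [(int(s), CLASS_SYMBOL[c])
                   for s, c in zip(record.r_peaks, labels)]
    wfdb_io.write_record(directory, name, record.samples,
                         record.sampling_rate, annotations=annotations,
                         lead_names=("MLII",), gain=gain)
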