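"""ECG preprocessing: baseline removal, scaling, segmentation, RR features.

Baseline wander (respiration/motion drift below ~1 Hz) is estimated with
a cascade of two median filters of 200 ms and 600 ms width and subtracted
from the raw signal; QRS complexes are too narrow to survive the medians,
so the estimate tracks only the drift.  Each heartbeat is then cut around
its annotated R-peak with a duration-based window, min-max scaled to
[0, 1], transformed with the left-variant PMAT and resized to 120x120.
Four timing features accompany each beat, all in seconds (the ratio is
dimensionless): pre-RR, post-RR, local-RR (mean of up to the ten
preceding RR intervals) and ratio-RR = pre/post.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

from pmat.core import pmat, resize_image

logger = logging.getLogger(__name__)


@dataclass
class AnnotatedSignal:
    """Single-lead signal with annotated R-peak positions and beat symbols."""

    samples: np.ndarray
    sampling_rate: float
    r_peaks: np.ndarray
    beat_symbols: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.beat_symbols = np.asarray(self.beat_symbols)
        if len(self.r_peaks) != len(self.beat_symbols):
            raise ValueError("r_peaks and beat_symbols lengths differ")
        if self.r_peaks.size and (np.any(np.diff(self.r_peaks) <= 0)
                                  or self.r_peaks[0] < 0
                                  or self.r_peaks[-1] >= self.samples.size):
            raise ValueError("r_peaks must be strictly increasing and in range")


@dataclass
class RRFeatures:
    """Four handcrafted timing features of one heartbeat (seconds; ratio unitless)."""

    pre_rr: float
    post_rr: float
    local_rr: float
    ratio_rr: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pre_rr, self.post_rr, self.local_rr,
                         self.ratio_rr], dtype=np.float32)


@dataclass
class HeartbeatRecord:
    """One classified unit: segment, 120x120 image, RR features, label, provenance."""

    segment: np.ndarray
    image: np.ndarray
    features: RRFeatures
    label: str
    source: tuple[str, str, int]  # (database, record id, r-peak sample)


@dataclass
class PipelineConfig:
    """Tunables of the per-beat pipeline.

    Durations are seconds; the segmentation window runs from ``pre_dur``
    before the R-peak to ``post_dur`` after it.  ``w_max=None`` uses the
    segment length (a square matrix before resizing).
    """

    pre_dur: float = 0.25
    post_dur: float = 0.45
    image_height: int = 120
    image_width: int = 120
    variant: str = "left"
    w_max: int | None = None
    local_rr_window: int = 10
    baseline_widths_ms: tuple[float, float] = (200.0, 600.0)


def _odd_kernel(duration_ms: float, fs: float) -> int:
    size = int(round(duration_ms * 1e-3 * fs))
    return size + 1 if size % 2 == 0 else size


def remove_baseline(x: AnnotatedSignal,
                    widths_ms: tuple[float, float] = (200.0, 600.0)) -> AnnotatedSignal:
    """Subtract the two-stage median-filter baseline estimate.

    Kernel sizes are ``round(width * fs)`` forced odd; edges use reflect
    padding.  R-peaks and symbols pass through unchanged.
    """
    if not x.sampling_rate or x.sampling_rate <= 0:
        raise ValueError("sampling rate must be known and positive")
    k1 = _odd_kernel(widths_ms[0], x.sampling_rate)
    k2 = _odd_kernel(widths_ms[1], x.sampling_rate)
    baseline = median_filter(x.samples, size=k1, mode="reflect")
    baseline = median_filter(baseline, size=k2, mode="reflect")
    return replace(x, samples=x.samples - baseline)


def scale_unit(segment: np.ndarray) -> np.ndarray:
    """Min-max scale a segment to [0, 1]; constant segments map to zeros."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise ValueError("segment must have length >= 2")
    lo, hi = seg.min(), seg.max()
    if hi == lo:
        warnings.warn("constant segment scaled to all zeros", stacklevel=2)
        return np.zeros_like(seg)
    return (seg - lo) / (hi - lo)


def segment_heartbeat(x: AnnotatedSignal, peak_index: int,
                      pre_dur: float = 0.25, post_dur: float = 0.45) -> np.ndarray:
    """Samples in ``[peak - pre_dur*fs, peak + post_dur*fs)``.

    Duration-based, so differing sampling rates yield differing sample
    counts for the same time span.  Raises if the window overflows the
    record; callers exclude such beats.
    """
    if pre_dur <= 0 or post_dur <= 0:
        raise ValueError("pre_dur and post_dur must be positive")
    fs = x.sampling_rate
    # integer samples within the real interval [peak - pre*fs, peak + post*fs)
    start = int(np.ceil(peak_index - pre_dur * fs))
    stop = int(np.ceil(peak_index + post_dur * fs))
    if start < 0 or stop > x.samples.size:
        raise ValueError(
            f"window [{start}, {stop}) exceeds record bounds "
            f"[0, {x.samples.size})")
    return x.samples[start:stop]


def rr_features(r_peaks, fs: float, beat_index: int,
                local_window: int = 10) -> RRFeatures:
    """RR features of the beat at ``beat_index`` within the peak list.

    Requires at least one preceding and one following peak.  local-RR
    averages up to ``local_window`` preceding intervals (all available if
    fewer).
    """
    peaks = np.asarray(r_peaks, dtype=np.int64)
    if not (1 <= beat_index <= peaks.size - 2):
        raise ValueError(
            f"beat {beat_index} lacks a preceding or following R-peak")
    intervals = np.diff(peaks) / fs
    pre = float(intervals[beat_index - 1])
    post = float(intervals[beat_index])
    local = float(intervals[max(0, beat_index - local_window):beat_index].mean())
    return RRFeatures(pre_rr=pre, post_rr=post, local_rr=local,
                      ratio_rr=pre / post)


def beat_to_record(x: AnnotatedSignal, beat_index: int, label: str,
                   config: PipelineConfig | None = None,
                   database: str = "", record_id: str = "") -> HeartbeatRecord:
    """Full per-beat pipeline: segment -> scale -> PMAT -> resize + features.

    ``x`` should already be baseline-filtered.  Raises (propagated from the
    components) when the beat fails boundary or neighbour checks.
    """
    cfg = config or PipelineConfig()
    peak = int(x.r_peaks[beat_index])
    segment = segment_heartbeat(x, peak, cfg.pre_dur, cfg.post_dur)
    scaled = scale_unit(segment)
    matrix = pmat(scaled, w_max=cfg.w_max, variant=cfg.variant)
    image = resize_image(matrix, cfg.image_height, cfg.image_width)
    feats = rr_features(x.r_peaks, x.sampling_rate, beat_index,
                        cfg.local_rr_window)
    return HeartbeatRecord(segment=scaled, image=image.astype(np.float32),
                           features=feats, label=label,
                           source=(database, record_id, peak))


def extract_beats(x: AnnotatedSignal, labels, config: PipelineConfig | None = None,
                  database: str = "", record_id: str = ""):
    """Run :func:`beat_to_record` over every annotated beat of a record.

    ``labels`` gives the AAMI class per R-peak (None entries are skipped as
    non-beats).  Returns ``(records, exclusions)`` where ``exclusions``
    counts skipped beats by reason.
    """
    cfg = config or PipelineConfig()
    records: list[HeartbeatRecord] = []
    exclusions: Counter[str] = Counter()
    for i in range(len(x.r_peaks)):
        label = labels[i]
        if label is None:
            exclusions["non-beat"] += 1
            continue
        if i == 0 or i == len(x.r_peaks) - 1:
            exclusions["missing-neighbor"] += 1
            continue
        try:
            records.append(beat_to_record(x, i, label, cfg, database, record_id))
        except ValueError as exc:
            logger.debug("beat %d skipped: %s", i, exc)
            exclusions["window-overflow"] += 1
    return records, dict(exclusions)
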