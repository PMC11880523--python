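"""Ripple detection and RCI extraction from raw LFP traces.

Implements the standard preprocessing chain for hippocampal sharp-wave
ripples: decimate the wideband recording to 2 kHz, band-pass in the ripple
band with a zero-phase Chebyshev type-II filter, take the Hilbert envelope,
threshold it in units of its own standard deviation, and cut non-overlapping
512-sample windows centered on each detected event.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .simulate import LabeledDataset, ObservedLabel, SimConfig

__all__ = [
    "LFPTrace",
    "RippleEvent",
    "downsample",
    "ripple_bandpass",
    "envelope",
    "detect_events",
    "segment_rcis",
    "balance_classes",
]


@dataclass(frozen=True)
class LFPTrace:
    """A single-channel local field potential recording."""

    samples: np.ndarray  # amplitude (mV)
    sampling_rate: float  # Hz

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class RippleEvent:
    """One detected ripple: onset/offset sample indices and envelope peak."""

    onset: int
    offset: int
    peak_envelope: float

    def __post_init__(self):
        if not 0 <= self.onset < self.offset:
            raise ValueError("need 0 <= onset < offset")

    @property
    def center(self) -> int:
        return (self.onset + self.offset) // 2


def downsample(trace: LFPTrace, target_rate: float) -> LFPTrace:
    """Anti-alias filter and decimate to ``target_rate`` (e.g. 40 kHz -> 2 kHz)."""
    if target_rate > trace.sampling_rate:
        raise ValueError("cannot downsample to a higher rate")
    if target_rate == trace.sampling_rate:
        return trace
    ratio = Fraction(trace.sampling_rate / target_rate).limit_denominator(1000)
    if ratio.denominator == 1:
        out = signal.decimate(trace.samples, ratio.numerator, ftype="fir", zero_phase=True)
    else:
        out = signal.resample_poly(trace.samples, ratio.denominator, ratio.numerator)
    return LFPTrace(out.astype(np.float64), target_rate)


def ripple_bandpass(
    trace: LFPTrace,
    band: tuple[float, float] = (120.0, 200.0),
    order: int = 4,
    stop_atten_db: float = 40.0,
    transition: float = 0.25,
) -> LFPTrace:
    """Zero-phase Chebyshev type-II band-pass in the ripple band.

    ``band`` gives the passband edges; the stopband edges sit a fractional
    ``transition`` outside it.  The filter is applied forward-backward
    (``sosfiltfilt``) so event onsets and offsets are not delayed.
    """
    lo, hi = band
    nyq = trace.sampling_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    ws = (lo * (1.0 - transition), min(hi * (1.0 + transition), 0.99 * nyq))
    sos = signal.cheby2(
        order, stop_atten_db, ws, btype="bandpass", fs=trace.sampling_rate, output="sos"
    )
    return LFPTrace(signal.sosfiltfilt(sos, trace.samples), trace.sampling_rate)


def envelope(filtered: LFPTrace) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal; >= |signal| everywhere."""
    return np.abs(signal.hilbert(filtered.samples))


def detect_events(
    env: np.ndarray,
    sampling_rate: float,
    detect_k: float = 3.0,
    bound_k: float = 1.0,
    min_dur_ms: float = 20.0,
) -> list[RippleEvent]:
    """Threshold the envelope into discrete ripple events.

    An event is seeded wherever the envelope exceeds mean + detect_k * sd;
    its onset/offset extend outward to the crossings of mean + bound_k * sd.
    Events sharing the same boundary interval merge, so the result is an
    ordered, non-overlapping list.  Events shorter than ``min_dur_ms`` are
    discarded.  A constant envelope (sd == 0) yields no events.
    """
    if detect_k <= bound_k or bound_k < 0:
        raise ValueError("need detect_k > bound_k >= 0")
    env = np.asarray(env, dtype=np.float64)
    sd = env.std()
    if sd == 0.0:
        return []
    mean = env.mean()
    above_bound = env > mean + bound_k * sd
    above_detect = env > mean + detect_k * sd
    # label contiguous bound-level segments, keep those reaching detect level
    edges = np.diff(above_bound.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_bound[0]:
        starts = np.r_[0, starts]
    if above_bound[-1]:
        ends = np.r_[ends, len(env)]
    min_samples = min_dur_ms * sampling_rate / 1000.0
    events = []
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        if not above_detect[s:e].any():
            continue
        events.append(RippleEvent(int(s), int(e - 1), float(env[s:e].max())))
    return events


def segment_rcis(
    trace: LFPTrace, events: list[RippleEvent], rci_length: int = 512
) -> np.ndarray:
    """Cut one ``rci_length`` window centered on each event midpoint.

    Windows that would overlap an already emitted window, or run past either
    end of the trace, are dropped; the emitted rows are disjoint in source
    coordinates.
    """
    half = rci_length // 2
    rows = []
    last_end = 0
    for ev in sorted(events, key=lambda ev: ev.onset):
        start = ev.center - half
        end = start + rci_length
        if start < last_end or end > len(trace):
            continue
        rows.append(trace.samples[start:end])
        last_end = end
    if not rows:
        return np.empty((0, rci_length), dtype=np.float32)
    return np.asarray(rows, dtype=np.float32)


def balance_classes(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
    config: SimConfig = SimConfig(),
) -> LabeledDataset:
    """Combine two RCI matrices into a balanced BL/AL dataset.

    The larger set is subsampled uniformly without replacement to the size
    of the smaller.  For recorded data the true class is unknown, so the
    ``true_class`` field simply mirrors the observed label and the noise
    proportion is recorded as NaN.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be nonempty")
    n = min(len(a), len(b))
    if len(a) > n:
        a = a[rng.choice(len(a), size=n, replace=False)]
    if len(b) > n:
        b = b[rng.choice(len(b), size=n, replace=False)]
    signals = np.concatenate([a, b]).astype(np.float32)
    observed = np.r_[
        np.full(n, int(ObservedLabel.BL)), np.full(n, int(ObservedLabel.AL))
    ]
    return LabeledDataset(signals, observed.copy(), observed, float("nan"), config)
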