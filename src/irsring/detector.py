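"""Bit-faithful emulation of the embedded fall-detection algorithm.

The firmware samples each of the 16 channels at 3.2 kHz and maintains a
32-sample moving-average baseline per channel in integer fixed point (5
fractional bits).  When the deviation of a sample from its channel baseline
exceeds the detection threshold ST, a detection opens; while open, every
above-threshold deviation is added to an amplitude sum; the detection
closes once the deviation has stayed at or below ST for ``holdoff_samples``
consecutive samples.  The summed amplitude is then normalised by dividing
by the power of two nearest to the number of contributing samples — an
integer shift instead of a division, at the price of a relative error of up
to 50% versus the exact mean.

Two baseline flavours are provided because the firmware description reads
both ways: a recursive exponentially weighted average with alpha = 1/32
(``"ema"``, the default: the most recent samples carry the highest weight)
and a true 32-sample sliding mean (``"sma"``).  While a channel has an open
detection its baseline is frozen by default so a long occlusion is not
absorbed into the baseline.

All arithmetic on the detection path is integer arithmetic on ADC counts,
mirroring what a small microcontroller would execute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fall import ChannelSignal

__all__ = [
    "DetectorConfig",
    "BaselineState",
    "DetectionEvent",
    "ST40",
    "ST100",
    "nearest_power_of_two",
    "normalize_amplitude",
    "update_baseline",
    "detect_stream",
    "events_to_frame",
]

N_CHANNELS = 16
_FRAC_BITS = 5  # fixed-point fractional bits of the baseline accumulator


@dataclass(frozen=True)
class DetectorConfig:
    threshold: int = 100  # ST, ADC counts of baseline deviation
    window_samples: int = 32
    holdoff_samples: int = 8
    baseline_mode: str = "ema"  # "ema" or "sma"
    freeze_baseline_during_event: bool = True
    sample_rate: float = 3200.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.window_samples != 32:
            raise ValueError("the firmware averages exactly 32 samples")
        if self.holdoff_samples < 1:
            raise ValueError("holdoff_samples must be >= 1")
        if self.baseline_mode not in ("ema", "sma"):
            raise ValueError("baseline_mode must be 'ema' or 'sma'")


#: Sensitive laboratory setting used for tiny arthropods.
ST40 = DetectorConfig(threshold=40)
#: Robust field setting used for arthropods larger than ~1 mm.
ST100 = DetectorConfig(threshold=100)


def nearest_power_of_two(n: int) -> int:
    """Power of two nearest to ``n`` (ties round down), ``n >= 1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = 1 << (int(n).bit_length() - 1)
    hi = lo << 1
    return lo if n - lo <= hi - n else hi


def normalize_amplitude(raw_sum: int, n_samples: int) -> int:
    """Shift-based average: ``raw_sum`` divided by the power of two nearest
    to ``n_samples``.  Relative error versus the exact mean is at most 50%,
    attained at ties (e.g. n = 6 -> divisor 4)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    divisor = nearest_power_of_two(n_samples)
    return int(raw_sum) >> (divisor.bit_length() - 1)


@dataclass
class BaselineState:
    """Per-channel running baseline in integer fixed point.

    ``fp[c]`` holds baseline * 32.  In SMA mode ``window[c]`` is the
    32-sample history and ``fp[c]`` its running sum (which is exactly the
    mean in 5-bit fixed point).
    """

    mode: str = "ema"
    fp: list = field(default_factory=lambda: [0] * N_CHANNELS)
    window: list = field(default_factory=list)
    pos: list = field(default_factory=lambda: [0] * N_CHANNELS)
    initialized: list = field(default_factory=lambda: [False] * N_CHANNELS)

    def value(self, channel: int) -> int:
        """Baseline in whole counts (fixed point truncated)."""
        return self.fp[channel] >> _FRAC_BITS


def update_baseline(state: BaselineState, sample: int, channel: int,
                    cfg: DetectorConfig) -> BaselineState:
    """Advance one channel's baseline by one sample (in place).

    EMA: ``fp += (sample*32 - fp) >> 5`` (floor shift, like the firmware's
    arithmetic right shift).  SMA: replace the oldest window sample.
    A constant input is a fixed point of both updates.
    """
    if not 0 <= channel < N_CHANNELS:
        raise ValueError("channel out of range")
    sample = int(sample)
    if cfg.baseline_mode == "ema":
        if not state.initialized[channel]:
            state.fp[channel] = sample << _FRAC_BITS
            state.initialized[channel] = True
        else:
            state.fp[channel] += (sample * 32 - state.fp[channel]) >> _FRAC_BITS
    else:
        if not state.window:
            state.window = [[0] * cfg.window_samples for _ in range(N_CHANNELS)]
        if not state.initialized[channel]:
            state.window[channel] = [sample] * cfg.window_samples
            state.fp[channel] = sample * cfg.window_samples
            state.initialized[channel] = True
        else:
            w = state.window[channel]
            p = state.pos[channel]
            state.fp[channel] += sample - w[p]
            w[p] = sample
            state.pos[channel] = (p + 1) % cfg.window_samples
    return state


@dataclass(frozen=True)
class DetectionEvent:
    """One closed detection (possibly spanning several channels).

    ``n_samples`` counts the above-threshold samples that contributed to
    ``raw_sum``; ``span_samples`` is the first-to-last extent.  For events
    merged across channels the amplitude fields are those of the dominant
    channel (the one with the largest normalised amplitude) so that
    ``normalized_amplitude = raw_sum >> log2(nearest_power_of_two(n_samples))``
    always holds.
    """

    channel_mask: int
    start_index: int
    n_samples: int
    span_samples: int
    raw_sum: int
    normalized_amplitude: int
    threshold_used: int

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(c for c in range(N_CHANNELS) if self.channel_mask >> c & 1)


@dataclass
class _OpenEvent:
    start: int
    last_above: int
    n: int = 0
    raw: int = 0
    below: int = 0


def _detect_channel(x: Sequence[int], cfg: DetectorConfig) -> list[_OpenEvent]:
    """Run the single-channel state machine over one sample stream."""
    st = cfg.threshold
    freeze = cfg.freeze_baseline_during_event
    state = BaselineState(mode=cfg.baseline_mode)
    closed: list[_OpenEvent] = []
    open_ev: _OpenEvent | None = None
    for i, sample in enumerate(x):
        sample = int(sample)
        dev = sample - state.value(0)
        if open_ev is None:
            if state.initialized[0] and dev > st:
                open_ev = _OpenEvent(start=i, last_above=i, n=1, raw=dev)
            else:
                update_baseline(state, sample, 0, cfg)
        else:
            if dev > st:
                open_ev.n += 1
                open_ev.raw += dev
                open_ev.last_above = i
                open_ev.below = 0
            else:
                open_ev.below += 1
                if open_ev.below >= cfg.holdoff_samples:
                    closed.append(open_ev)
                    open_ev = None
                    update_baseline(state, sample, 0, cfg)
                    continue
            if not freeze:
                update_baseline(state, sample, 0, cfg)
    if open_ev is not None:  # stream ended with an open detection
        closed.append(open_ev)
    return closed


def detect_stream(signal: ChannelSignal | np.ndarray,
                  cfg: DetectorConfig = ST100) -> list[DetectionEvent]:
    """Detect events in a 16-channel count stream.

    Per channel the embedded state machine produces candidate events;
    candidates whose sample spans overlap in time across channels are
    merged into one :class:`DetectionEvent` with the union channel mask and
    the dominant channel's amplitude statistics.  Events are returned in
    order of their start sample.
    """
    counts = signal.counts if isinstance(signal, ChannelSignal) else np.asarray(signal)
    if counts.ndim != 2 or counts.shape[0] != N_CHANNELS or counts.shape[1] < 1:
        raise ValueError("signal must be a non-empty 16 x T count array")
    per_channel: list[tuple[int, _OpenEvent]] = []
    for c in range(N_CHANNELS):
        col = counts[c]
        # cheap reject: a channel whose total range cannot exceed ST is flat
        if int(col.max()) - int(col.min()) > cfg.threshold:
            for ev in _detect_channel(col.tolist(), cfg):
                per_channel.append((c, ev))
    per_channel.sort(key=lambda ce: (ce[1].start, ce[0]))

    merged: list[DetectionEvent] = []
    cluster: list[tuple[int, _OpenEvent]] = []
    cluster_end = -1
    for c, ev in per_channel:
        if cluster and ev.start > cluster_end:
            merged.append(_finalize(cluster, cfg))
            cluster = []
            cluster_end = -1
        cluster.append((c, ev))
        cluster_end = max(cluster_end, ev.last_above)
    if cluster:
        merged.append(_finalize(cluster, cfg))
    return merged


def _finalize(cluster: list[tuple[int, _OpenEvent]], cfg: DetectorConfig) -> DetectionEvent:
    mask = 0
    for c, _ in cluster:
        mask |= 1 << c
    start = min(ev.start for _, ev in cluster)
    end = max(ev.last_above for _, ev in cluster)
    dominant = max(cluster, key=lambda ce: (normalize_amplitude(ce[1].raw, ce[1].n), ce[1].raw))[1]
    return DetectionEvent(
        channel_mask=mask,
        start_index=start,
        n_samples=dominant.n,
        span_samples=end - start + 1,
        raw_sum=dominant.raw,
        normalized_amplitude=normalize_amplitude(dominant.raw, dominant.n),
        threshold_used=cfg.threshold,
    )


def events_to_frame(events: Iterable[DetectionEvent],
                    sample_rate: float = 3200.0) -> "pd.DataFrame":
    """Tabulate events for CSV export (times in ms, mask in hex)."""
    import pandas as pd

    rows = [{
        "start_time_ms": ev.start_index / sample_rate * 1e3,
        "duration_samples": ev.span_samples,
        "n_samples": ev.n_samples,
        "channel_mask_hex": f"{ev.channel_mask:04x}",
        "raw_sum": ev.raw_sum,
        "normalized_amplitude": ev.normalized_amplitude,
        "ST": ev.threshold_used,
    } for ev in events]
    return pd.DataFrame(rows, columns=["start_time_ms", "duration_samples", "n_samples",
                                       "channel_mask_hex", "raw_sum",
                                       "normalized_amplitude", "ST"])
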