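"""Embedded detection algorithm: baseline, events, shift normalisation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from irsring import (
    BaselineState,
    DetectorConfig,
    detect_stream,
    nearest_power_of_two,
    normalize_amplitude,
    update_baseline,
)
from conftest import add_pulse, flat_signal


# -- baseline ----------------------------------------------------------

@pytest.mark.parametrize("mode", ["ema", "sma"])
def test_constant_input_is_a_fixed_point(mode):
    cfg = DetectorConfig(baseline_mode=mode)
    state = BaselineState(mode=mode)
    for _ in range(100):
        update_baseline(state, 700, 0, cfg)
        assert state.value(0) == 700


def test_ema_step_response_matches_geometric_sum():
    """0 -> c step: after 32 updates the EMA holds c*(1 - (31/32)^32)."""
    cfg = DetectorConfig(baseline_mode="ema")
    state = BaselineState(mode="ema")
    update_baseline(state, 0, 0, cfg)  # initialise at 0
    c = 512
    for _ in range(32):
        update_baseline(state, c, 0, cfg)
    expected = c * (1.0 - (31.0 / 32.0) ** 32)
    assert state.value(0) == pytest.approx(expected, abs=2.0)  # fixed-point floor


def test_sma_window_fully_replaced_after_32_samples():
    cfg = DetectorConfig(baseline_mode="sma")
    state = BaselineState(mode="sma")
    update_baseline(state, 0, 0, cfg)
    for _ in range(32):
        update_baseline(state, 480, 0, cfg)
    assert state.value(0) == 480


# -- power-of-two normalisation ---------------------------------------

@pytest.mark.parametrize("n, divisor", [(1, 1), (3, 2), (5, 4), (6, 4), (8, 8),
                                        (12, 8), (13, 16), (96, 64), (97, 128)])
def test_nearest_power_of_two_ties_round_down(n, divisor):
    assert nearest_power_of_two(n) == divisor


def test_normalize_amplitude_examples():
    assert normalize_amplitude(3200, 16) == 200          # power-of-two n: exact
    assert normalize_amplitude(1200, 6) == 300           # exact mean 200: 50% error
    assert normalize_amplitude(400, 5) == 100            # divisor 4
    with pytest.raises(ValueError):
        normalize_amplitude(100, 0)


def test_shift_normalisation_error_bound_brute_force():
    """Max relative error vs the exact mean over n in [1, 4096] is exactly 50%."""
    def oracle_npo2(n):  # exhaustive search, independent of the bit trickery
        powers = [1 << k for k in range(14)]
        best = min(powers, key=lambda p: (abs(n - p), p))
        return best

    errors = {}
    for n in range(1, 4097):
        d = oracle_npo2(n)
        assert nearest_power_of_two(n) == d
        errors[n] = abs(n / d - 1.0)
    assert max(errors.values()) == pytest.approx(0.5, abs=1e-12)
    assert errors[6] == pytest.approx(0.5, abs=1e-12)  # tie rounded down: 6 -> 4


# -- event building ----------------------------------------------------

def test_flat_signal_yields_no_events(st100):
    assert detect_stream(flat_signal(), st100) == []


def test_empty_signal_rejected(st100):
    with pytest.raises(ValueError):
        detect_stream(np.empty((16, 0), dtype=np.uint16), st100)


def test_rectangular_pulse_hand_trace(st100):
    """Height 200, 16 samples, ST 100, holdoff 8: one event, sum 3200."""
    counts = add_pulse(flat_signal(), channel=4, start=100, length=16, height=200)
    events = detect_stream(counts, st100)
    assert len(events) == 1
    ev = events[0]
    assert ev.channel_mask == 1 << 4
    assert ev.start_index == 100
    assert ev.n_samples == 16
    assert ev.raw_sum == 3200
    assert ev.normalized_amplitude == 200
    assert ev.threshold_used == 100


@pytest.mark.parametrize("gap, n_events", [(12, 2), (9, 2), (8, 2), (5, 1), (2, 1)])
def test_pulse_pair_respects_the_closing_rule(st100, gap, n_events):
    """Pulses separated by >= holdoff samples split; shorter gaps merge."""
    counts = add_pulse(flat_signal(), 4, 100, 16, 200)
    counts = add_pulse(counts, 4, 116 + gap, 16, 200)
    events = detect_stream(counts, st100)
    assert len(events) == n_events
    if n_events == 1:
        assert events[0].n_samples == 32
        assert events[0].raw_sum == 6400


def test_overlapping_channels_merge_into_one_event(st100):
    counts = add_pulse(flat_signal(), 3, 100, 16, 150)
    counts = add_pulse(counts, 5, 108, 16, 300)
    events = detect_stream(counts, st100)
    assert len(events) == 1
    ev = events[0]
    assert ev.channel_mask == (1 << 3) | (1 << 5)
    assert ev.start_index == 100
    # dominant channel (5) supplies the amplitude statistics
    assert ev.normalized_amplitude == normalize_amplitude(16 * 300, 16)


def test_raising_threshold_never_adds_events():
    """Single-channel property: a higher ST can only drop events.

    (Across channels the count is not monotone because a low threshold can
    merge overlapping per-channel detections into fewer records.)
    """
    rng = np.random.default_rng(0)
    counts = flat_signal(n=1500).astype(np.int64)
    counts[9] += rng.normal(0, 30, size=1500).astype(np.int64)
    for start in (200, 700, 1200):
        counts[9, start:start + 12] += 250
    counts = np.clip(counts, 0, 1023).astype(np.uint16)
    n_prev = None
    for thr in (40, 80, 120, 200, 400):
        n = len(detect_stream(counts, DetectorConfig(threshold=thr)))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_window_matches_10ms_at_the_adc_rate():
    cfg = DetectorConfig()
    assert cfg.window_samples / cfg.sample_rate == pytest.approx(10e-3)


@given(st.data())
def test_agrees_with_brute_force_segmenter(data):
    """Well-separated rectangular pulses: the state machine matches an
    independent run-scanner with gap tolerance = holdoff."""
    cfg = DetectorConfig(threshold=100, holdoff_samples=8)
    n_pulses = data.draw(st.integers(1, 4))
    counts = flat_signal(n=120 * n_pulses + 200)
    pos = 60
    placed = []
    for _ in range(n_pulses):
        length = data.draw(st.integers(1, 20))
        height = data.draw(st.integers(120, 400))
        placed.append((pos, length, height))
        counts = add_pulse(counts, 7, pos, length, height)
        pos += length + data.draw(st.integers(30, 60))  # >> holdoff: separate events

    # independent oracle on the known flat baseline
    dev = counts[7].astype(int) - 512
    above = dev > cfg.threshold
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            last = i
            while j < len(above) and (above[j] or j - last < cfg.holdoff_samples):
                if above[j]:
                    last = j
                j += 1
            runs.append((i, sum(dev[k] for k in range(i, last + 1) if above[k]),
                         sum(above[i:last + 1])))
            i = j
        else:
            i += 1

    events = detect_stream(counts, cfg)
    assert len(events) == len(runs)
    for ev, (start, raw, n) in zip(events, runs):
        assert ev.start_index == start
        assert ev.raw_sum == raw
        assert ev.n_samples == n
        assert ev.normalized_amplitude == normalize_amplitude(raw, n)


def test_identical_input_gives_identical_events(st100):
    counts = add_pulse(flat_signal(), 11, 150, 10, 220)
    assert detect_stream(counts, st100) == detect_stream(counts, st100)
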