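"""Synthetic per-channel sensor signals for objects falling through the ring.

Pipeline (per drop): constant-acceleration free-fall kinematics through the
two sensed sheets -> per-channel fractional occlusion (flutter modulates the
projected outline sinusoidally) -> light-level dip -> two-stage amplifier
emulation (stage-1 gain with its gain-bandwidth-limited one-pole low-pass,
5 Hz one-pole high-pass, stage-2 gain) -> additive white Gaussian noise ->
decimation from the internally oversampled rate to the 3.2 kHz per-channel
A/D rate -> offset, rounding and clamping to the ADC count range.

The simulation runs internally at ``internal_oversample`` x 3.2 kHz because
the analog bandwidth (~6.7 kHz) exceeds the ADC Nyquist rate; decimation is
plain subsampling, reproducing the hardware's accepted aliasing rather than
adding an anti-aliasing filter it does not have.  The internal grid is
phase-locked to the ADC clock (decimated sample k always falls at k/3200 s
relative to ring-top entry) and the analog filters use first-order-hold
discretisation, so the digitised output is insensitive to the oversample
factor.

The mapping from physical light change to ADC counts is a calibration, not
a derivation: ``light_scale`` is the mid-band count amplitude of a full
occlusion of a fully lit channel, and ``noise_sigma`` is the one free noise
parameter that the detectability analysis calibrates against the reported
sensitivity of the physical instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geometry import (
    ObjectDescriptor,
    OutOfFieldError,
    RingGeometry,
    channel_illumination,
    occlusion_profile,
)

__all__ = [
    "FrontEndConfig",
    "ChannelSignal",
    "DropParams",
    "SimulationFaultError",
    "trajectory",
    "simulate_signal",
    "amplifier_response",
]

G_MM_S2 = 9810.0  # gravitational acceleration, mm/s^2


class SimulationFaultError(RuntimeError):
    """A non-finite value appeared inside the simulation pipeline."""


@dataclass(frozen=True)
class FrontEndConfig:
    """Analog front end, ADC, and noise model of one photodiode channel.

    ``gain_stage1`` (15x, micropower op-amp) is bandwidth-limited by the
    amplifier's 100 kHz gain-bandwidth product, giving a one-pole low-pass
    at ``gbw_stage1 / gain_stage1`` ~ 6.7 kHz.  ``gain_stage2`` (30x) is
    AC-coupled through a ~5 Hz high-pass.  ``light_scale`` and
    ``noise_sigma`` are in ADC counts (see module docstring).
    """

    gain_stage1: float = 15.0
    gain_stage2: float = 30.0
    hpf_corner: float = 5.0
    gbw_stage1: float = 100e3
    sample_rate: float = 3200.0
    adc_bits: int = 10
    noise_sigma: float = 8.0
    internal_oversample: int = 10
    light_scale: float = 760.0

    @property
    def stage1_bandwidth(self) -> float:
        return self.gbw_stage1 / self.gain_stage1

    @property
    def adc_max(self) -> int:
        return (1 << self.adc_bits) - 1

    @property
    def adc_offset(self) -> int:
        """Quiescent mid-rail level of the digitised signal, counts."""
        return 1 << (self.adc_bits - 1)


@dataclass
class ChannelSignal:
    """Sampled 16-channel signal in ADC counts at the per-channel A/D rate."""

    counts: np.ndarray  # (16, T) unsigned integers
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 16 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 16 x T array with T >= 1")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """One column per channel; metadata in '#'-prefixed header lines."""
        with open(path, "w") as fh:
            fh.write(f"# sample_rate={self.sample_rate}\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            pd.DataFrame(self.counts.T,
                         columns=[f"ch{i}" for i in range(16)]).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelSignal":
        meta: dict = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        body = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        rate = float(meta.pop("sample_rate", 3200.0))
        df = pd.read_csv(StringIO("".join(lines[body:])))
        return cls(counts=df.to_numpy().T.astype(np.uint16), sample_rate=rate, meta=meta)


@dataclass(frozen=True)
class DropParams:
    """How one object enters the ring: lateral entry point and fall height.

    ``drop_height`` is measured from the release point to the top of the
    ring; the default is the 38 mm glass tube sitting above it.
    """

    entry: tuple[float, float] = (0.0, 0.0)
    drop_height: float = 38.0
    orientation_phase: float | None = None  # None: drawn from the trial RNG
    flutter_phase: float | None = None


def _time_grid(
    obj: ObjectDescriptor,
    drop_height: float,
    geom: RingGeometry,
    fe: FrontEndConfig,
    pre_roll: float,
    tail: float,
) -> tuple[np.ndarray, int]:
    """Oversampled time axis phase-locked to the ADC clock.

    Returns ``(t, n_pre_os)``; t=0 is ring-top entry, decimated samples sit
    at integer multiples of 1/sample_rate regardless of the oversample
    factor.
    """
    m = fe.internal_oversample
    v0 = math.sqrt(2.0 * G_MM_S2 * drop_height)
    sigma_z = geom.beam_vertical_extent / (2.0 * math.sqrt(2.0))
    sigma_eff = math.hypot(sigma_z, obj.size / 4.0)
    z_end = geom.sheet_depths()[-1] + 4.0 * sigma_eff
    t_end = (-v0 + math.sqrt(v0 ** 2 + 2.0 * G_MM_S2 * z_end)) / G_MM_S2
    n_pre = int(round(pre_roll * fe.sample_rate))
    n_dec = n_pre + int(math.ceil((t_end + tail) * fe.sample_rate))
    fs = fe.sample_rate * m
    t = (np.arange(n_dec * m) - n_pre * m) / fs
    return t, n_pre * m


def trajectory(
    obj: ObjectDescriptor,
    drop_height: float,
    lateral_entry: Sequence[float],
    geom: RingGeometry,
    fe: FrontEndConfig | None = None,
    pre_roll: float = 0.012,
    tail: float = 0.008,
) -> tuple[np.ndarray, np.ndarray]:
    """Free-fall depth profile through the sensed sheets.

    Returns ``(t, z)`` at the internal oversampled rate: time in seconds
    (t=0 at ring-top entry, negative during the pre-roll the detector needs
    to settle its baseline) and depth below the ring top in mm.  Entries
    with ``z < 0`` are above the ring.  The trace ends once the object has
    fallen clear of the lower sensed sheet.
    """
    if drop_height < 0:
        raise ValueError("drop_height must be >= 0")
    lateral_entry = np.asarray(lateral_entry, dtype=float)
    if math.hypot(*lateral_entry) > geom.tube_diameter / 2.0:
        raise OutOfFieldError(f"lateral entry {tuple(lateral_entry)} outside the tube")
    fe = fe or FrontEndConfig()
    v0 = math.sqrt(2.0 * G_MM_S2 * drop_height)
    t, _ = _time_grid(obj, drop_height, geom, fe, pre_roll, tail)
    z = np.where(t >= 0.0, v0 * t + 0.5 * G_MM_S2 * t ** 2, -1.0)
    return t, z


def _foh_one_pole_lowpass(x: np.ndarray, corner: float, fs: float) -> np.ndarray:
    """First-order RC low-pass, exact for piecewise-linear input.

    First-order-hold discretisation keeps the output essentially
    independent of the internal oversampling factor.
    """
    a_t = 2.0 * math.pi * corner / fs
    e = math.exp(-a_t)
    s = (1.0 - e) / a_t
    # y[n] = e*y[n-1] + (1-s)*x[n] + (s-e)*x[n-1]
    return lfilter([1.0 - s, s - e], [1.0, -e], x, axis=-1)


def simulate_signal(
    geom: RingGeometry,
    obj: ObjectDescriptor,
    fe: FrontEndConfig,
    drop: DropParams | None = None,
    seed: int = 0,
) -> ChannelSignal:
    """Simulate the digitised 16-channel response to one falling object.

    Deterministic for a fixed seed: the seed drives the noise stream and,
    when :class:`DropParams` leaves them unset, the orientation and flutter
    phases.
    """
    drop = drop or DropParams()
    rng = np.random.default_rng(seed)
    ori = drop.orientation_phase
    if ori is None:
        ori = float(rng.uniform(0.0, 2.0 * math.pi))
    fphase = drop.flutter_phase
    if fphase is None:
        fphase = float(rng.uniform(0.0, 2.0 * math.pi))

    t, z = trajectory(obj, drop.drop_height, drop.entry, geom, fe)
    fs = fe.sample_rate * fe.internal_oversample

    # outline scale over time (flutter shrinks the projected outline)
    fa = obj.flutter_amplitude
    if fa > 0.0:
        scale_t = 1.0 - fa * 0.5 * (1.0 + np.sin(
            2.0 * math.pi * obj.flutter_frequency * t + fphase))
        grid = np.linspace(1.0 - fa, 1.0, 7)
    else:
        scale_t = np.ones_like(t)
        grid = np.array([1.0])

    occ_grid = occlusion_profile(geom, obj, drop.entry, ori, scales=grid)  # (16, S)
    if grid.size == 1:
        occ_t = np.repeat(occ_grid, t.size, axis=1)
    else:
        occ_t = np.stack([np.interp(scale_t, grid, occ_grid[c]) for c in range(16)])

    # vertical envelope per sensed sheet
    sigma_z = geom.beam_vertical_extent / (2.0 * math.sqrt(2.0))
    sigma_eff = math.hypot(sigma_z, obj.size / 4.0)
    depths = geom.sheet_depths()
    env = np.exp(-0.5 * ((z[None, :] - depths[:, None]) / sigma_eff) ** 2)
    env *= (z >= 0.0)[None, :]  # above the ring nothing is shaded

    illum = channel_illumination(geom)
    u = illum[:, None] * occ_t * env[geom.channel_rows()]  # physical dip, 0..1

    # amplifier chain; occlusion maps to a positive processed deviation
    x1 = _foh_one_pole_lowpass(fe.gain_stage1 * u, fe.stage1_bandwidth, fs)
    x2 = fe.gain_stage2 * (x1 - _foh_one_pole_lowpass(x1, fe.hpf_corner, fs))
    y = x2 * (fe.light_scale / (fe.gain_stage1 * fe.gain_stage2))
    if not np.all(np.isfinite(y)):
        raise SimulationFaultError("non-finite value in the amplifier chain")
    if fe.noise_sigma > 0:
        y = y + rng.normal(0.0, fe.noise_sigma, size=y.shape)

    y = y[:, :: fe.internal_oversample]  # ADC-clock-aligned subsampling
    counts = np.clip(np.rint(fe.adc_offset + y), 0, fe.adc_max).astype(np.uint16)
    meta = {"variant": geom.variant.value, "seed": seed, "size_mm": obj.size,
            "group": obj.group_label, "entry": tuple(drop.entry)}
    return ChannelSignal(counts=counts, sample_rate=fe.sample_rate, meta=meta)


def amplifier_response(fe: FrontEndConfig, frequency: float | np.ndarray) -> np.ndarray | float:
    """Cascaded magnitude response of both gain stages, the stage-1
    bandwidth limit and the AC-coupling high-pass."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    hp = (f / fe.hpf_corner) / np.sqrt(1.0 + (f / fe.hpf_corner) ** 2)
    lp = 1.0 / np.sqrt(1.0 + (f / fe.stage1_bandwidth) ** 2)
    out = fe.gain_stage1 * fe.gain_stage2 * hp * lp
    return float(out) if np.isscalar(frequency) else out
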