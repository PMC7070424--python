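"""Emitter/detector geometry of the infrared sensor-ring and optical occlusion.

The sensor-ring is a light gate built on the cross-section of a trap tube:
two vertically stacked infrared LEDs face 16 IR photodiodes arranged along
the opposite semicircle, in two vertically offset rows whose angular
positions are staggered by half the inter-diode pitch.  An object falling
through the ring shades part of the LED light reaching each photodiode; the
amount of shading depends on the object's size, shape, transparency,
position and orientation.

Two ring variants are modelled:

``IRSR1``
    wide sensing field (35 mm aperture) for macroarthropods, 2-35 mm.
``IRSR2``
    narrow, denser sensing field (10 mm aperture) for soil microarthropods,
    0.1-2 mm.  Its higher sensitivity comes purely from geometry: emitters
    and detectors sit much closer together, so the same object shades a far
    larger fraction of every LED->diode ray bundle.

The optical model is two-dimensional: each photodiode row is an independent
sensed sheet inside the 15 mm ring height, and within a sheet light
transport is a fan of straight rays from the (point) LED position to points
sampled across each photodiode's aperture arc.  The two stacked LEDs share
the same in-plane position but have their beam axes rotated against each
other by ``led_beam_shift``, which is what homogenises the field; they enter
the model as two angular-intensity lobes weighting the same ray fan.

Units: millimetres and radians internally; the serialisation layer speaks
degrees (keys suffixed ``_deg``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Variant",
    "RingGeometry",
    "ObjectDescriptor",
    "OutOfFieldError",
    "build_ring",
    "occlusion_fraction",
    "occlusion_profile",
    "channel_illumination",
    "geometry_to_dict",
    "geometry_from_dict",
    "geometry_to_yaml",
    "geometry_from_yaml",
]


class Variant(str, enum.Enum):
    """Sensor-ring variant: wide (IRSR1, 35 mm) or narrow (IRSR2, 10 mm)."""

    IRSR1 = "IRSR1"
    IRSR2 = "IRSR2"


class OutOfFieldError(ValueError):
    """A position lies outside the region the ring can sense."""


@dataclass(frozen=True)
class RingGeometry:
    """One sensor variant's emitter/detector layout and sensing aperture.

    Angles are radians, lengths millimetres.  ``ring_radius`` is the radius
    of the circle carrying the LED pair (at angle 0) and the photodiodes
    (equally spaced over the opposite semicircle); it defaults to
    1.4x the aperture radius so every LED->diode ray crosses the sensing
    aperture, which is what makes a centered object as large as the aperture
    block every channel completely.
    """

    variant: Variant
    aperture_diameter: float
    ring_radius: float
    n_photodiodes: int = 16
    n_rows: int = 2
    row_offset_angle: float = math.pi / 16
    n_leds: int = 2
    led_beam_shift: float = math.radians(60.0)
    half_beam_angle: float = math.radians(60.0)
    ring_height: float = 15.0
    tube_diameter: float = 50.0
    tube_length_above: float = 38.0
    beam_vertical_extent: float = 4.9
    row_separation: float = 5.0
    n_rays: int = 4096

    def __post_init__(self) -> None:
        if self.n_photodiodes != 16:
            raise ValueError("the ring carries 16 photodiodes")
        if not 0 < self.aperture_diameter < self.tube_diameter:
            raise ValueError("aperture must be positive and inside the tube")
        if self.half_beam_angle <= 0 or self.beam_vertical_extent <= 0:
            raise ValueError("half_beam_angle and beam_vertical_extent must be > 0")
        if self.n_rays < 8:
            raise ValueError("n_rays too small for a meaningful ray bundle")

    # -- derived layout -------------------------------------------------

    @property
    def diode_pitch(self) -> float:
        """Angular pitch between adjacent photodiodes (both rows combined)."""
        return math.pi / self.n_photodiodes

    @property
    def diode_half_aperture(self) -> float:
        """Angular half-width of one photodiode's sensitive arc.

        Half the pitch, so the 16 apertures tile the semicircle without
        gaps: any ray from the LED into the far semicircle lands on exactly
        one channel.
        """
        return self.diode_pitch / 2.0

    def diode_angles(self) -> np.ndarray:
        """Angular centre of each channel, radians, ascending (length 16).

        Channels alternate between the two rows (channel i sits in row
        ``i % 2``); the stagger between rows is ``row_offset_angle`` = half
        the within-row pitch.
        """
        k = np.arange(self.n_photodiodes)
        return math.pi / 2 + (k + 0.5) * self.diode_pitch

    def channel_rows(self) -> np.ndarray:
        """Row index (0 or 1) of each channel."""
        return np.arange(self.n_photodiodes) % 2

    def sheet_depths(self) -> np.ndarray:
        """Depth of the two sensed sheets below the ring top, mm."""
        mid = self.ring_height / 2.0
        return np.array([mid - self.row_separation / 2.0,
                         mid + self.row_separation / 2.0])

    @property
    def led_position(self) -> np.ndarray:
        return np.array([self.ring_radius, 0.0])


@dataclass(frozen=True)
class ObjectDescriptor:
    """A falling object: grain particle or arthropod.

    ``size`` is the largest body/particle diameter in mm.  ``opacity`` scales
    the shading linearly (1 = fully opaque stone grain; living springtails
    with shimmering cuticle are lower).  ``flutter_amplitude`` is the
    relative shrinkage of the projected outline as appendages bend during
    the fall: the outline scale oscillates in ``[1 - amplitude, 1]`` at
    ``flutter_frequency``.
    """

    size: float
    shape: str = "sphere"
    aspect_ratio: float = 1.0
    opacity: float = 1.0
    flutter_amplitude: float = 0.0
    flutter_frequency: float = 0.0
    group_label: str = "grain"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("size must be > 0")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must lie in [0, 1]")
        if not 0.0 <= self.flutter_amplitude <= 1.0:
            raise ValueError("flutter_amplitude must lie in [0, 1]")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio is length/width, >= 1")


_VARIANT_APERTURE = {Variant.IRSR1: 35.0, Variant.IRSR2: 10.0}


def build_ring(variant: Variant | str, **overrides) -> RingGeometry:
    """Construct the default geometry of one ring variant.

    Parameters the hardware description leaves open (beam angle, ring
    radius, row separation, vertical beam extent, ray count) take documented
    configuration defaults and can be overridden by keyword.
    """
    try:
        variant = Variant(variant)
    except ValueError as exc:
        raise ValueError(f"unknown sensor-ring variant: {variant!r}") from exc
    aperture = overrides.pop("aperture_diameter", _VARIANT_APERTURE[variant])
    ring_radius = overrides.pop("ring_radius", 0.7 * aperture)
    return RingGeometry(variant=variant, aperture_diameter=aperture,
                        ring_radius=ring_radius, **overrides)


# -- ray table ----------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + math.pi) % (2 * math.pi) - math.pi


@lru_cache(maxsize=16)
def _ray_table(geom: RingGeometry):
    """Stratified ray bundle for a geometry: endpoints, weights, weight sums.

    One bundle of ``n_rays`` rays per channel runs from the LED position to
    midpoints of equal sub-arcs of the diode aperture, so occlusion is
    deterministic.  Each ray is weighted by the summed angular intensity of
    the two LED lobes (Gaussian profile, ``half_beam_angle`` = half-width at
    half maximum, axes at +-``led_beam_shift``/2 about the boresight toward
    the ring centre).
    """
    centres = geom.diode_angles()
    u = (np.arange(geom.n_rays) + 0.5) / geom.n_rays  # stratified midpoints
    ang = centres[:, None] + (u[None, :] - 0.5) * 2.0 * geom.diode_half_aperture
    ends = geom.ring_radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    led = geom.led_position
    d = ends - led
    ray_angle = np.arctan2(d[..., 1], d[..., 0])
    off_axis = _wrap_angle(ray_angle - math.pi)  # boresight points at the centre
    sigma = geom.half_beam_angle / math.sqrt(2.0 * math.log(2.0))
    shift = geom.led_beam_shift / 2.0
    w = (np.exp(-0.5 * ((off_axis - shift) / sigma) ** 2)
         + np.exp(-0.5 * ((off_axis + shift) / sigma) ** 2))
    return led, ends, w, w.sum(axis=1)


def channel_illumination(geom: RingGeometry) -> np.ndarray:
    """Relative unobstructed light level per channel, in [0, 1].

    1 would mean every ray of the channel sits on an LED lobe peak.  The
    dip a falling object produces on a channel is proportional to this
    level times the channel's occlusion fraction.
    """
    _, _, w, _ = _ray_table(geom)
    return w.sum(axis=1) / (geom.n_leds * geom.n_rays)


def _segment_distance_to_origin(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Distance from the origin to segments p1->p2 (broadcast over p2)."""
    d = p2 - p1
    denom = np.einsum("...i,...i", d, d)
    t = -np.einsum("...i,...i", np.broadcast_to(p1, p2.shape), d) / np.maximum(denom, 1e-30)
    t = np.clip(t, 0.0, 1.0)
    closest = p1 + t[..., None] * d
    return np.sqrt(np.einsum("...i,...i", closest, closest))


def occlusion_profile(
    geom: RingGeometry,
    obj: ObjectDescriptor,
    position: Sequence[float],
    orientation_phase: float = 0.0,
    scales: Sequence[float] | np.ndarray = (1.0,),
) -> np.ndarray:
    """Per-channel occlusion at several outline scales, shape (16, len(scales)).

    The outline is the object's projected cross-section: a disk of diameter
    ``size * scale`` for spheres, an ellipse with major axis ``size * scale``
    and axis ratio ``aspect_ratio`` (rotated by ``orientation_phase``) for
    ellipsoids.  Occlusion of a channel is the intensity-weighted fraction
    of its ray bundle intersecting the outline, times ``opacity``.

    Evaluating many scales at once is cheap because the ray geometry is
    shared; the fall simulator uses this for flutter.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (2,):
        raise ValueError("position must be a 2D point (x, y) in mm")
    if math.hypot(*position) > geom.tube_diameter / 2.0:
        raise OutOfFieldError(
            f"position {tuple(position)} lies outside the {geom.tube_diameter} mm tube")
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    led, ends, w, wsum = _ray_table(geom)

    a = obj.size / 2.0
    b = a / obj.aspect_ratio
    # Map the outline to the unit circle; ray-outline tests become distance
    # thresholds, and a uniformly scaled outline just rescales the threshold.
    c, s = math.cos(-orientation_phase), math.sin(-orientation_phase)
    rot = np.array([[c, -s], [s, c]])
    scl = np.array([1.0 / a, 1.0 / b])
    p1 = ((led - position) @ rot.T) * scl
    p2 = ((ends - position) @ rot.T) * scl
    dist = _segment_distance_to_origin(p1, p2)  # (16, n_rays)

    blocked = dist[:, :, None] <= scales[None, None, :]
    frac = np.einsum("cr,crs->cs", w, blocked) / wsum[:, None]
    return obj.opacity * frac


def occlusion_fraction(
    geom: RingGeometry,
    obj: ObjectDescriptor,
    position: Sequence[float],
    orientation_phase: float = 0.0,
    outline_scale: float = 1.0,
) -> np.ndarray:
    """Fraction of each channel's light blocked by the object, length 16.

    Values lie in [0, 1]; a transparent object (opacity 0) blocks nothing,
    a centered opaque object at least as large as the sensing aperture
    blocks every channel completely.
    """
    return occlusion_profile(geom, obj, position, orientation_phase,
                             scales=(outline_scale,))[:, 0]


# -- serialisation ------------------------------------------------------

_ANGLE_FIELDS = ("row_offset_angle", "led_beam_shift", "half_beam_angle")


def geometry_to_dict(geom: RingGeometry) -> dict:
    """Plain dict with documented keys; angles in degrees (``*_deg``)."""
    d: dict = {"variant": geom.variant.value}
    for name in ("aperture_diameter", "ring_radius", "n_photodiodes", "n_rows",
                 "n_leds", "ring_height", "tube_diameter", "tube_length_above",
                 "beam_vertical_extent", "row_separation", "n_rays"):
        d[name] = getattr(geom, name)
    for name in _ANGLE_FIELDS:
        d[name + "_deg"] = math.degrees(getattr(geom, name))
    return d


def geometry_from_dict(d: Mapping) -> RingGeometry:
    kw = dict(d)
    variant = Variant(kw.pop("variant"))
    for name in _ANGLE_FIELDS:
        if name + "_deg" in kw:
            kw[name] = math.radians(kw.pop(name + "_deg"))
    return RingGeometry(variant=variant, **kw)


def geometry_to_yaml(geom: RingGeometry) -> str:
    return yaml.safe_dump(geometry_to_dict(geom), sort_keys=True)


def geometry_from_yaml(text: str) -> RingGeometry:
    return geometry_from_dict(yaml.safe_load(text))
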