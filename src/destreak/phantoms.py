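"""Analytic ellipse phantoms and their closed-form sinograms.

The phantoms play two roles: they are the ground-truth objects for the
end-to-end low-dose experiment, and — because the parallel-beam
projection of an ellipse has a closed form — they are the independent
oracle against which the numerical forward projector is validated.

The ``torso`` preset emulates the artifact-provoking geometry of a human
torso scan: a wide body ellipse with two dense "shoulder" disks so that
rays along the shoulder-to-shoulder (horizontal) direction are far more
attenuated than vertical rays.  That direction is where photon
starvation strikes first and where the streak artifacts form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ScanGeometry, Sinogram
from .image import AttenuationImage

__all__ = [
    "EllipseSpec",
    "make_phantom",
    "analytic_ellipse_sinogram",
    "preset_ellipses",
    "PRESETS",
]


@dataclass(frozen=True)
class EllipseSpec:
    """An ellipse in normalized field-of-view coordinates ``[-1, 1]^2``.

    ``additive_attenuation`` is added to every point inside the ellipse;
    overlapping ellipses sum, so low-contrast inserts are written as
    small additive perturbations on top of the body ellipse.
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0  # degrees, counter-clockwise
    additive_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("semi-axes must be strictly positive")

    def bounding_half_widths(self) -> tuple[float, float]:
        """Tight axis-aligned half-widths of the rotated ellipse."""
        phi = math.radians(self.rotation)
        a, b = self.semi_axis_a, self.semi_axis_b
        wx = math.hypot(a * math.cos(phi), b * math.sin(phi))
        wy = math.hypot(a * math.sin(phi), b * math.cos(phi))
        return wx, wy

    def inside_unit_fov(self) -> bool:
        wx, wy = self.bounding_half_widths()
        return abs(self.center_x) + wx <= 1.0 and abs(self.center_y) + wy <= 1.0


# Torso: body ellipse + two dense shoulder disks + low-contrast inserts.
# Attenuations put the widest shoulder-to-shoulder ray at a line integral
# of ~7.4 (attenuation x FOV-length units): at the default low-dose flux
# I0 = 1e3 that leaves well under one transmitted photon on average,
# i.e. genuine photon starvation along that direction.
_TORSO = (
    EllipseSpec(0.0, 0.0, 0.90, 0.55, 0.0, 2.5),            # body (soft tissue)
    EllipseSpec(-0.62, 0.0, 0.18, 0.18, 0.0, 4.0),          # left shoulder (dense)
    EllipseSpec(+0.62, 0.0, 0.18, 0.18, 0.0, 4.0),          # right shoulder (dense)
    EllipseSpec(0.0, 0.28, 0.07, 0.07, 0.0, 0.6),           # low-contrast insert
    EllipseSpec(-0.30, -0.20, 0.09, 0.09, 0.0, -0.6),       # low-contrast void
    EllipseSpec(0.30, -0.18, 0.10, 0.05, 30.0, 0.8),        # tilted insert
    EllipseSpec(0.0, -0.05, 0.04, 0.04, 0.0, 1.0),          # small dense "spine" marker
)

_DISK = (EllipseSpec(0.0, 0.0, 0.4, 0.4, 0.0, 1.0),)

PRESETS: dict[str, tuple[EllipseSpec, ...]] = {"disk": _DISK, "torso": _TORSO}


def preset_ellipses(preset: str) -> list[EllipseSpec]:
    """Return a copy of the ellipse list for a named preset."""
    try:
        return list(PRESETS[preset])
    except KeyError:
        raise ValueError(f"unknown phantom preset {preset!r}; choose from {sorted(PRESETS)}") from None


def make_phantom(
    preset: str = "torso",
    size: int = 256,
    overrides: Sequence[EllipseSpec] | None = None,
) -> AttenuationImage:
    """Rasterize a phantom preset onto an ``size x size`` grid.

    ``overrides``, when given, replaces the preset's ellipse list
    entirely.  Rasterization is centre-of-pixel point sampling: a pixel
    receives the sum of ``additive_attenuation`` over all ellipses whose
    interior contains its centre.
    """
    if size < 16:
        raise ValueError("phantom size must be >= 16")
    ellipses = list(overrides) if overrides is not None else preset_ellipses(preset)
    for e in ellipses:
        if not e.inside_unit_fov():
            raise ValueError(f"ellipse {e} extends outside the unit field of view")

    pixel_size = 2.0 / size
    c = -1.0 + (np.arange(size) + 0.5) * pixel_size
    xg, yg = np.meshgrid(c, c)  # yg varies along rows
    values = np.zeros((size, size))
    for e in ellipses:
        phi = math.radians(e.rotation)
        dx = xg - e.center_x
        dy = yg - e.center_y
        u = (dx * math.cos(phi) + dy * math.sin(phi)) / e.semi_axis_a
        v = (-dx * math.sin(phi) + dy * math.cos(phi)) / e.semi_axis_b
        values += np.where(u * u + v * v <= 1.0, e.additive_attenuation, 0.0)
    return AttenuationImage(values, pixel_size)


def ellipse_chord(e: EllipseSpec, angle_deg: float, offset: float) -> float:
    """Chord length of the ray ``x cos(a) + y sin(a) = offset`` through ``e``.

    Standard closed form: projecting a rotated ellipse onto the detector
    axis gives an effective half-width ``w(a)`` with
    ``w^2 = a^2 cos^2(a - phi) + b^2 sin^2(a - phi)``; the chord is
    ``2ab sqrt(w^2 - t^2) / w^2`` for ``|t| < w``, with ``t`` the offset
    relative to the projected centre.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(e.rotation)
    t = offset - (e.center_x * math.cos(theta) + e.center_y * math.sin(theta))
    a, b = e.semi_axis_a, e.semi_axis_b
    w2 = (a * math.cos(theta - phi)) ** 2 + (b * math.sin(theta - phi)) ** 2
    if t * t >= w2:
        return 0.0
    return 2.0 * a * b * math.sqrt(w2 - t * t) / w2


def analytic_ellipse_sinogram(ellipses: Sequence[EllipseSpec], geometry: ScanGeometry) -> Sinogram:
    """Exact parallel-beam sinogram of a sum of ellipses.

    Each bin is the sum over ellipses of attenuation times chord length —
    the closed-form line integral, with no discretization error.
    """
    angles = np.radians(geometry.view_angles_deg())[:, None]
    offsets = geometry.detector_offsets()[None, :]
    values = np.zeros((geometry.n_views, geometry.n_detectors))
    for e in ellipses:
        phi = math.radians(e.rotation)
        a, b = e.semi_axis_a, e.semi_axis_b
        t = offsets - (e.center_x * np.cos(angles) + e.center_y * np.sin(angles))
        w2 = (a * np.cos(angles - phi)) ** 2 + (b * np.sin(angles - phi)) ** 2
        under = np.maximum(w2 - t * t, 0.0)
        values += e.additive_attenuation * 2.0 * a * b * np.sqrt(under) / w2
    return Sinogram(values, geometry)
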