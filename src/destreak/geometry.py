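"""Parallel-beam scan geometry and sinogram container.

Conventions (shared by the projector and the FBP back end):

* view angles ``theta_v = v * angular_span / n_views`` degrees,
  ``v = 0 .. n_views - 1`` (half-open: the end angle is not repeated);
* at view angle ``theta`` the detector axis is the unit vector
  ``u = (cos theta, sin theta)`` and rays run along
  ``(-sin theta, cos theta)``;
* detector offsets ``s_d = (d - (n_detectors - 1) / 2 +
  detector_center_offset) * detector_spacing`` in the same physical
  units as the image pixel size, so a sinogram bin holds the line
  integral over the ray ``{(x, y) : x cos theta + y sin theta = s_d}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScanGeometry", "Sinogram", "default_geometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition description."""

    n_views: int
    angular_span: float = 360.0
    n_detectors: int = 0
    detector_spacing: float = 1.0
    detector_center_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.angular_span not in (180.0, 360.0, 180, 360):
            raise ValueError("angular_span must be 180 or 360 degrees")
        if self.n_detectors < 2:
            raise ValueError("n_detectors must be >= 2")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    def view_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * (float(self.angular_span) / self.n_views)

    def detector_offsets(self) -> np.ndarray:
        d = np.arange(self.n_detectors, dtype=np.float64)
        return (d - (self.n_detectors - 1) / 2.0 + self.detector_center_offset) * self.detector_spacing

    @property
    def detector_span(self) -> float:
        return self.n_detectors * self.detector_spacing


@dataclass(frozen=True)
class Sinogram:
    """``n_views x n_detectors`` grid of line integrals plus its geometry."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (self.geometry.n_views, self.geometry.n_detectors):
            raise ValueError(
                f"sinogram shape {values.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_detectors})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("sinogram contains non-finite values")
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(values, self.geometry)


def default_geometry(image_size: int, n_views: int = 1200, angular_span: float = 360.0) -> ScanGeometry:
    """Pipeline default: 1200 views over 360 degrees, detector pitch equal
    to the pixel size, and 1.5x the image side of detector channels
    (rounded up to even) so the array covers the field-of-view diagonal.
    """
    n_det = math.ceil(1.5 * image_size)
    n_det += n_det % 2
    return ScanGeometry(
        n_views=n_views,
        angular_span=angular_span,
        n_detectors=n_det,
        detector_spacing=2.0 / image_size,
    )
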