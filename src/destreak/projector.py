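"""Ray-driven parallel-beam forward projector (pseudo projections).

Each sinogram bin is the line integral of the attenuation image along a
parallel ray, evaluated Joseph-style: the ray is sampled at uniform
steps of half a pixel and the image is bilinearly interpolated at each
sample (zero outside the grid), so the bin value is

    p(theta, s) = h * sum_k image(ray point k),   h ~= pixel_size / 2.

The projector is linear in the image and maps non-negative images to
non-negative sinograms.  The geometry of the pseudo projections need
not match whatever scanner produced the input reconstruction; the
parallel-beam choice here is deliberate and self-contained.
"""

from __future__ import annotations

import math

import numba
import numpy as np

from .geometry import ScanGeometry, Sinogram
from .image import AttenuationImage

__all__ = ["forward_project", "ray_integral"]


@numba.njit(cache=True)
def _ray_sums_kernel(values, px, half_side, theta_rad, offsets, t, out):
    """Accumulate bilinear samples along each ray of one view."""
    n = values.shape[0]
    ux = math.cos(theta_rad)
    uy = math.sin(theta_rad)
    vx, vy = -uy, ux
    for d in range(offsets.shape[0]):
        s = offsets[d]
        acc = 0.0
        for k in range(t.shape[0]):
            x = s * ux + t[k] * vx
            y = s * uy + t[k] * vy
            col = (x + half_side) / px - 0.5
            row = (y + half_side) / px - 0.5
            r0 = math.floor(row)
            c0 = math.floor(col)
            fr = row - r0
            fc = col - c0
            ir = int(r0)
            ic = int(c0)
            v = 0.0
            if 0 <= ir < n and 0 <= ic < n:
                v += values[ir, ic] * (1.0 - fr) * (1.0 - fc)
            if 0 <= ir < n and 0 <= ic + 1 < n:
                v += values[ir, ic + 1] * (1.0 - fr) * fc
            if 0 <= ir + 1 < n and 0 <= ic < n:
                v += values[ir + 1, ic] * fr * (1.0 - fc)
            if 0 <= ir + 1 < n and 0 <= ic + 1 < n:
                v += values[ir + 1, ic + 1] * fr * fc
            acc += v
        out[d] = acc


def _ray_sums(image: AttenuationImage, angle_deg: float, offsets: np.ndarray) -> np.ndarray:
    """Line integrals at one view angle for an array of detector offsets."""
    n = image.size
    px = image.pixel_size
    half_side = 0.5 * n * px
    ray_len = 2.0 * math.sqrt(2.0) * half_side  # covers the image diagonal
    step = px / 2.0
    n_steps = int(math.ceil(ray_len / step))
    h = ray_len / n_steps
    t = -0.5 * ray_len + (np.arange(n_steps) + 0.5) * h
    out = np.empty(offsets.shape[0])
    _ray_sums_kernel(
        image.values, px, half_side, math.radians(angle_deg), np.ascontiguousarray(offsets, dtype=np.float64), t, out
    )
    return out * h


def ray_integral(image: AttenuationImage, angle: float, offset: float) -> float:
    """Line integral along the single ray ``x cos(angle) + y sin(angle) = offset``.

    Exactly the per-ray kernel of :func:`forward_project`: the sinogram
    bin at a given (view, detector) equals ``ray_integral`` at that
    ray's angle and offset.
    """
    return float(_ray_sums(image, angle, np.array([offset]))[0])


def forward_project(image: AttenuationImage, geometry: ScanGeometry) -> Sinogram:
    """Forward-project an attenuation image into a sinogram of pseudo projections."""
    offsets = geometry.detector_offsets()
    values = np.empty((geometry.n_views, geometry.n_detectors))
    for v, ang in enumerate(geometry.view_angles_deg()):
        values[v] = _ray_sums(image, ang, offsets)
    return Sinogram(values, geometry)
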