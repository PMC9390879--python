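"""Attenuation images: the reconstruction / phantom domain.

An :class:`AttenuationImage` is a square grid of linear attenuation
coefficients.  The field of view is the square ``[-1, 1] x [-1, 1]`` in
physical units, so ``pixel_size = 2 / N`` and the centre of pixel
``(row, col)`` sits at ``y = -1 + (row + 0.5) * pixel_size``,
``x = -1 + (col + 0.5) * pixel_size``.  Attenuation values are per unit
length in those same physical units, which makes line integrals through
the image dimensionless (attenuation x length).

Phantoms are non-negative by construction.  Reconstructed images may
carry small negative excursions from the ramp filter; they are stored
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttenuationImage"]

MIN_SIZE = 16


@dataclass(frozen=True)
class AttenuationImage:
    """A square 2D attenuation map with its pixel size.

    Parameters
    ----------
    values
        ``(N, N)`` array of attenuation coefficients (per unit length).
    pixel_size
        Physical side length of one pixel; defaults to ``2 / N`` so the
        image spans the canonical ``[-1, 1]^2`` field of view.
    """

    values: np.ndarray
    pixel_size: float = field(default=0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"image must be square 2D, got shape {values.shape}")
        if values.shape[0] < MIN_SIZE:
            raise ValueError(f"image side must be >= {MIN_SIZE}, got {values.shape[0]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "values", values)
        if self.pixel_size == 0.0:
            object.__setattr__(self, "pixel_size", 2.0 / values.shape[0])
        elif self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def physical_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates ``(x, y)``, each of length ``N``."""
        n = self.size
        c = -0.5 * n * self.pixel_size + (np.arange(n) + 0.5) * self.pixel_size
        return c, c.copy()
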