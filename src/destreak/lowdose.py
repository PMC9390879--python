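"""Low-dose transmission noise model.

X-ray flux through an object follows the Beer-Lambert law: with incident
photon count ``I0`` and line integral ``p`` of the attenuation along a
ray, the transmitted count is Poisson distributed with mean
``I0 * exp(-p)``.  The post-log measurement recovers the line integral,

    p_hat = ln(I0) - ln(I),

and first-order error propagation gives its variance

    var(p_hat) ~= exp(p) / I0,

so heavily attenuated rays (large ``p``) are exponentially noisier than
lightly attenuated ones.  That exponential variance law is exactly why a
threshold on the projection value identifies the bins worth smoothing.

When the transmitted count is zero ("photon starvation") the log is
undefined; counts are clamped at ``max(starvation_floor, 1)`` before the
log, which caps the post-log value at ``ln(I0)``.  ``I0`` is treated as
a known noiseless constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Sinogram

__all__ = ["NoiseModel", "simulate_counts", "post_log", "predicted_variance"]


@dataclass(frozen=True)
class NoiseModel:
    """Incident flux, starvation clamp and RNG seed for one acquisition.

    ``incident_counts`` of order 1e3 gives a genuinely starved low-dose
    scan on the torso phantom (peak line integral ~ 7.4 leaves a mean
    transmitted count below one photon); 2e4 serves as the regular dose.
    """

    incident_counts: float = 1000.0
    starvation_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incident_counts <= 0:
            raise ValueError("incident_counts must be positive")
        if self.starvation_floor < 0:
            raise ValueError("starvation_floor must be >= 0")


def simulate_counts(sinogram: Sinogram, model: NoiseModel) -> np.ndarray:
    """Draw transmitted photon counts for every sinogram bin.

    Each bin is an independent ``Poisson(I0 * exp(-p))`` draw.  The RNG
    is constructed from ``model.seed`` on every call, so repeated calls
    with the same model are bit-identical.
    """
    p = sinogram.values
    if np.any(p < 0):
        raise ValueError("sinogram has negative line integrals; cannot simulate transmission")
    rng = np.random.default_rng(model.seed)
    return rng.poisson(model.incident_counts * np.exp(-p))


def post_log(counts: np.ndarray, model: NoiseModel, geometry=None) -> np.ndarray | Sinogram:
    """Convert transmitted counts back to line integrals.

    ``p = ln(I0) - ln(max(counts, clamp))`` with
    ``clamp = max(starvation_floor, 1)``, so starved (zero-count) bins
    come out finite at ``ln(I0)``.  If ``geometry`` is given the result
    is wrapped in a :class:`Sinogram`.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    clamp = max(model.starvation_floor, 1.0)
    p = np.log(model.incident_counts) - np.log(np.maximum(counts, clamp))
    if geometry is not None:
        return Sinogram(p, geometry)
    return p


def predicted_variance(p, incident_counts: float):
    """First-order variance of the post-log measurement: ``exp(p) / I0``.

    Strictly increasing in ``p`` and decreasing in ``I0``; valid before
    the clamp regime, i.e. while ``I0 * exp(-p) >> 1``.
    """
    if incident_counts <= 0:
        raise ValueError("incident_counts must be positive")
    return np.exp(p) / incident_counts


def measure_lowdose(sinogram: Sinogram, model: NoiseModel) -> Sinogram:
    """Simulate one noisy post-log acquisition of a clean sinogram."""
    counts = simulate_counts(sinogram, model)
    return post_log(counts, model, geometry=sinogram.geometry)
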