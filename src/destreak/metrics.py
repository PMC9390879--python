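"""Image-quality evaluation: SSD, NPS, MTF, line profiles, FWHM.

* **SSD** — normalized sum-square difference between a test image and
  the gold standard,

      SSD = sum (X_gold - X)^2 / (sqrt(sum X_gold^2) * sqrt(sum X^2)),

  dimensionless, symmetric, zero iff the images are identical.  (The
  product-of-norms denominator is this package's documented convention.)

* **NPS image** — magnitude of the centred 2D DFT of the difference
  image ``X_gold - X``; identically zero for matching images.  Streak
  artifacts along the horizontal (shoulder-to-shoulder) direction show
  up as energy concentrated along the central *vertical* frequency axis.

* **MTF image** — ``(|FT(X_out)| + eps) / (|FT(X_in)| + eps)`` with
  ``eps = 0.1`` guarding the division; summarized as radial curves by
  averaging 32-degree wedges about the 0, 45 and 90 degree frequency
  directions (each wedge paired with its point reflection, since real
  images have Hermitian spectra), then normalizing to 1 at zero
  frequency.

* **Line profiles / FWHM** — spatial-domain resolution check: the full
  width at half maximum of a profile across a small dense feature, with
  the half-maximum crossings located by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import AttenuationImage

__all__ = [
    "ssd",
    "nps_image",
    "central_vertical_band_energy",
    "mtf_image",
    "mtf_curves",
    "MTFCurves",
    "line_profile",
    "fwhm",
    "MetricReport",
]


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, AttenuationImage) else np.asarray(img, dtype=np.float64)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def ssd(gold, test) -> float:
    """Normalized sum-square difference (0 = identical, smaller = better)."""
    a, b = _values(gold), _values(test)
    _check_same_shape(a, b)
    denom = np.sqrt(np.sum(a * a)) * np.sqrt(np.sum(b * b))
    if denom == 0.0:
        raise ValueError("SSD undefined: both images are all-zero")
    return float(np.sum((a - b) ** 2) / denom)


def nps_image(gold, test) -> np.ndarray:
    """Noise-power-spectrum image: |2D DFT(gold - test)|, zero-frequency centred."""
    a, b = _values(gold), _values(test)
    _check_same_shape(a, b)
    return np.abs(np.fft.fftshift(np.fft.fft2(a - b)))


def central_vertical_band_energy(nps: np.ndarray, half_width: int = 3) -> float:
    """Energy of the NPS in the central vertical frequency band.

    Sums ``|NPS|^2`` over the columns within ``half_width`` bins of the
    zero horizontal frequency — the band where horizontal streak
    artifacts concentrate their spectral signature.
    """
    nps = np.asarray(nps)
    c = nps.shape[1] // 2
    band = nps[:, c - half_width + 1 : c + half_width]  # |fx| < half_width bins
    return float(np.sum(band**2))


def mtf_image(input_img, output_img, epsilon: float = 0.1) -> np.ndarray:
    """Modulation-transfer image ``(|FT(out)| + eps) / (|FT(in)| + eps)``, centred."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a, b = _values(input_img), _values(output_img)
    _check_same_shape(a, b)
    num = np.abs(np.fft.fftshift(np.fft.fft2(b))) + epsilon
    den = np.abs(np.fft.fftshift(np.fft.fft2(a))) + epsilon
    return num / den


@dataclass(frozen=True)
class MTFCurves:
    """Radial MTF curves along the 0, 45 and 90 degree frequency wedges."""

    radial_frequencies: np.ndarray  # cycles/pixel, 0 .. Nyquist
    curve_0deg: np.ndarray
    curve_45deg: np.ndarray
    curve_90deg: np.ndarray
    wedge_half_angle: float = 16.0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "frequency": self.radial_frequencies,
            "mtf_0deg": self.curve_0deg,
            "mtf_45deg": self.curve_45deg,
            "mtf_90deg": self.curve_90deg,
        }


def _wedge_average(mtf: np.ndarray, center_deg: float, half_angle: float) -> np.ndarray:
    """Average the centred MTF image over a wedge of directions.

    Polar resampling at 1-pixel radial and 1-degree angular steps with
    bilinear interpolation; the diametrically opposite wedge is included
    (Hermitian symmetry of real-image spectra doubles the averaging
    count).
    """
    n = mtf.shape[0]
    c = n // 2  # fftshift centre
    radii = np.arange(n // 2, dtype=np.float64)
    angles = np.radians(np.arange(-half_angle, half_angle + 1.0) + center_deg)
    angles = np.concatenate([angles, angles + np.pi])
    rr, aa = np.meshgrid(radii, angles)
    cols = c + rr * np.cos(aa)
    rows = c + rr * np.sin(aa)
    samples = ndimage.map_coordinates(mtf, [rows.ravel(), cols.ravel()], order=1, mode="nearest").reshape(rr.shape)
    return samples.mean(axis=0)


def mtf_curves(mtf: np.ndarray, wedge_half_angle: float = 16.0) -> MTFCurves:
    """Extract the three wedge-averaged radial curves from an MTF image.

    Curves are normalized to 1 at zero frequency so different images are
    directly comparable.
    """
    mtf = np.asarray(mtf)
    if mtf.ndim != 2 or mtf.shape[0] != mtf.shape[1]:
        raise ValueError("MTF image must be square")
    if mtf.shape[0] < 32:
        raise ValueError("MTF image too small for polar binning (need >= 32)")
    n = mtf.shape[0]
    freqs = np.arange(n // 2) / n  # cycles/pixel
    curves = {}
    for ang in (0.0, 45.0, 90.0):
        curve = _wedge_average(mtf, ang, wedge_half_angle)
        curves[ang] = curve / curve[0]
    return MTFCurves(freqs, curves[0.0], curves[45.0], curves[90.0], wedge_half_angle)


def line_profile(image, row: int, col_start: int, col_end: int) -> np.ndarray:
    """Pixel values along the horizontal segment ``[col_start, col_end)`` of one row."""
    values = _values(image)
    n_rows, n_cols = values.shape
    if not 0 <= row < n_rows:
        raise IndexError(f"row {row} out of bounds for {n_rows} rows")
    if not (0 <= col_start < col_end <= n_cols):
        raise IndexError(f"column range [{col_start}, {col_end}) out of bounds for {n_cols} columns")
    return values[row, col_start:col_end].copy()


def fwhm(profile: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked profile, in samples.

    The baseline is the profile minimum; each half-maximum crossing is
    located by linear interpolation between the neighbouring samples on
    either side of the (unique) peak.  Invariant to scaling and baseline
    shifts of the profile.
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    baseline = y.min()
    peak = y.max()
    if peak == baseline:
        raise ValueError("flat profile: FWHM undefined")
    if np.count_nonzero(y == peak) > 1:
        raise ValueError("profile maximum is not unique")
    ip = int(np.argmax(y))
    if ip in (0, y.size - 1):
        raise ValueError("peak at the profile boundary: crossings undefined")
    half = baseline + 0.5 * (peak - baseline)

    def cross(idx_from, idx_to, step):
        i = idx_from
        while i != idx_to and y[i] >= half:
            i += step
        if y[i] >= half:
            raise ValueError("profile never falls below half maximum on one side")
        # linear interpolation between i-step (>= half) and i (< half)
        frac = (y[i - step] - half) / (y[i - step] - y[i])
        return (i - step) + step * frac

    left = cross(ip, 0, -1)
    right = cross(ip, y.size - 1, +1)
    return float(right - left)


@dataclass
class MetricReport:
    """One evaluation of a test image against the gold standard."""

    ssd: float
    fwhm: float | None = None
    altered_bin_fraction: float | None = None
    nps_vertical_band_energy: float | None = None
    files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ssd < 0:
            raise ValueError("ssd must be >= 0")

    def as_row(self) -> dict[str, float | str | None]:
        row: dict[str, float | str | None] = {
            "ssd": self.ssd,
            "fwhm": self.fwhm,
            "altered_bin_fraction": self.altered_bin_fraction,
            "nps_vertical_band_energy": self.nps_vertical_band_energy,
        }
        row.update({f"file_{k}": v for k, v in self.files.items()})
        return row
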