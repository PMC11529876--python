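"""Per-tile illumination correction.

Three interchangeable corrections for smooth intensity gradients in raw
tiles: rolling-ball background subtraction (morphological opening), 2-D
polynomial surface fitting, and frequency-domain Gaussian high-pass.  All
methods work in floating point internally and re-quantize to the input
dtype on return; ``preserve_mean`` restores the input mean exactly so the
grey-level scale of the montage is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import ConfigurationError

_METHODS = ("rolling_ball", "polynomial", "highpass")


@dataclass(frozen=True)
class FlatfieldParams:
    method: str = "rolling_ball"
    radius_px: Optional[int] = None  # rolling_ball; default tile_width // 8
    degree: int = 2  # polynomial
    cutoff_fraction: float = 0.01  # highpass, cycles/px
    preserve_mean: bool = True

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigurationError(f"unknown flatfield method {self.method!r}")
        if self.method == "rolling_ball" and self.radius_px is not None and self.radius_px < 1:
            raise ConfigurationError("radius_px must be >= 1")
        if self.method == "polynomial" and not 0 <= self.degree <= 4:
            raise ConfigurationError("polynomial degree must be in [0, 4]")
        if self.method == "highpass" and not 0.0 < self.cutoff_fraction < 0.5:
            raise ConfigurationError("cutoff_fraction must lie in (0, 0.5)")


def _dtype_range(dtype: np.dtype) -> Optional[Tuple[float, float]]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return None


def _finalize(out: np.ndarray, image: np.ndarray, preserve_mean: bool) -> np.ndarray:
    if preserve_mean:
        out = out + (float(image.mean()) - float(out.mean()))
    rng = _dtype_range(image.dtype)
    if rng is not None:
        out = np.clip(np.rint(out), rng[0], rng[1]).astype(image.dtype)
    else:
        out = out.astype(image.dtype)
    return out


def rolling_ball(
    image: np.ndarray,
    radius_px: Optional[int] = None,
    preserve_mean: bool = True,
    smooth_background: bool = False,
) -> np.ndarray:
    """Subtract the smooth background estimated by grayscale opening with a disk.

    A radius exceeding both image dimensions degrades (with a warning) to
    subtracting the global minimum.  The plain opening keeps the operation
    exactly idempotent; ``smooth_background`` optionally blurs the opened
    image so structuring-element plateau edges do not leak into the
    foreground (at the cost of strict idempotence).
    """
    if image.ndim != 2:
        raise ConfigurationError("rolling_ball expects a 2-D image")
    if radius_px is None:
        radius_px = max(1, image.shape[1] // 8)
    if radius_px < 1:
        raise ConfigurationError("radius_px must be >= 1")
    img = image.astype(np.float64)
    if radius_px > max(image.shape):
        warnings.warn(
            "rolling-ball radius exceeds both image dimensions; "
            "falling back to global-minimum subtraction",
            stacklevel=2,
        )
        background = np.full_like(img, img.min())
    else:
        background = ndimage.grey_opening(img, footprint=disk(radius_px))
        if smooth_background:
            background = ndimage.gaussian_filter(background, sigma=max(1.0, radius_px / 4.0))
    return _finalize(img - background, image, preserve_mean)


def _poly_basis(shape: Tuple[int, int], degree: int) -> np.ndarray:
    h, w = shape
    v, u = np.meshgrid(
        np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1),
        np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1),
        indexing="ij",
    )
    cols = [
        (u ** i * v ** j).ravel()
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.column_stack(cols)


def fit_polynomial_surface(image: np.ndarray, degree: int) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares 2-D polynomial surface of the given total degree.

    Returns ``(surface, coefficients)`` with the basis ordered by total
    degree, then by ascending power of the normalized x coordinate.
    """
    if not 0 <= degree <= 4:
        raise ConfigurationError("polynomial degree must be in [0, 4]")
    basis = _poly_basis(image.shape, degree)
    coeffs, *_ = np.linalg.lstsq(basis, image.astype(np.float64).ravel(), rcond=None)
    surface = (basis @ coeffs).reshape(image.shape)
    return surface, coeffs


def polynomial_flatfield(image: np.ndarray, degree: int = 2, preserve_mean: bool = True) -> np.ndarray:
    """Fit and subtract a smooth polynomial shading surface."""
    surface, _ = fit_polynomial_surface(image, degree)
    return _finalize(image.astype(np.float64) - surface, image, preserve_mean)


def highpass_transfer(freq: np.ndarray, cutoff_fraction: float) -> np.ndarray:
    """Gaussian high-pass amplitude response at normalized frequency (cycles/px)."""
    return 1.0 - np.exp(-(freq ** 2) / (2.0 * cutoff_fraction ** 2))


def highpass(image: np.ndarray, cutoff_fraction: float, preserve_mean: bool = True) -> np.ndarray:
    """Frequency-domain Gaussian high-pass with the stated normalized cutoff."""
    if not 0.0 < cutoff_fraction < 0.5:
        raise ConfigurationError("cutoff_fraction must lie in (0, 0.5)")
    img = image.astype(np.float64)
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    freq = np.sqrt(fy ** 2 + fx ** 2)
    out = np.real(np.fft.ifft2(np.fft.fft2(img) * highpass_transfer(freq, cutoff_fraction)))
    return _finalize(out, image, preserve_mean)


def apply_flatfield(image: np.ndarray, params: FlatfieldParams) -> np.ndarray:
    if params.method == "rolling_ball":
        return rolling_ball(image, params.radius_px, params.preserve_mean)
    if params.method == "polynomial":
        return polynomial_flatfield(image, params.degree, params.preserve_mean)
    return highpass(image, params.cutoff_fraction, params.preserve_mean)
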