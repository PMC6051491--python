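"""Spectral line shapes and point-spread profiles.

The pseudo-Voigt here matches the parameterisation used by the band-fitting
module (and by lmfit's ``PseudoVoigtModel``): a Lorentzian and a Gaussian
sharing the same center and full width at half maximum, mixed linearly, each
normalised to unit area so ``area`` is the integrated band intensity.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gaussian_area", "lorentzian_area", "pseudo_voigt", "gaussian_2d"]

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


def gaussian_area(x: np.ndarray, center: float, fwhm: float, area: float = 1.0) -> np.ndarray:
    """Area-normalised Gaussian with the given FWHM."""
    sigma = fwhm / (2.0 * _SQRT_2LN2)
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def lorentzian_area(x: np.ndarray, center: float, fwhm: float, area: float = 1.0) -> np.ndarray:
    """Area-normalised Lorentzian with the given FWHM."""
    gamma = fwhm / 2.0
    return area / np.pi * gamma / ((x - center) ** 2 + gamma**2)


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, area: float = 1.0, fraction: float = 0.5
) -> np.ndarray:
    """Linear Gaussian/Lorentzian mix; ``fraction`` is the Lorentzian weight."""
    return fraction * lorentzian_area(x, center, fwhm, area) + (1.0 - fraction) * gaussian_area(
        x, center, fwhm, area
    )


def gaussian_2d(
    shape: tuple[int, int],
    x0: float,
    y0: float,
    sd: float,
    amplitude: float,
    offset: float = 0.0,
) -> np.ndarray:
    """Symmetric 2-D Gaussian spot on a pixel grid.

    ``x0`` indexes columns and ``y0`` rows, in pixels. ``amplitude`` is the
    peak height above ``offset`` (counts), not an integrated intensity.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return offset + amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sd**2))
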