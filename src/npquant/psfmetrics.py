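"""Line-profile extraction and Gaussian FWHM fitting.

Used to calibrate the effective PSF and to measure apparent single-particle
widths: an intensity profile through a sub-resolution particle is close to
Gaussian, and its full width at half maximum (FWHM = 2 sqrt(2 ln 2) sigma
~ 2.3548 sigma) estimates the imaged spot size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .grids import VoxelGrid
from .synthetic import FWHM_PER_SIGMA


@dataclass
class LineProfile:
    """Intensity samples along a straight segment; positions in nm from p0."""

    positions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions_nm) != len(self.intensities):
            raise ValueError("positions and intensities must align")
        if len(self.positions_nm) < 5:
            raise ValueError("profile needs at least 5 samples")
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit a exp(-(x-c)^2 / 2 sigma^2) + offset."""

    amplitude: float
    center_nm: float
    sigma_nm: float
    offset: float
    amplitude_sd: float
    center_sd_nm: float
    sigma_sd_nm: float
    offset_sd: float

    @property
    def fwhm_nm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_nm

    @property
    def fwhm_sd_nm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_sd_nm


def extract_profile(
    grid: VoxelGrid,
    p0_nm: tuple[float, float, float],
    p1_nm: tuple[float, float, float],
    step_nm: float | None = None,
) -> LineProfile:
    """Linearly interpolated intensities along the segment p0 -> p1 (z, y, x nm).

    The sampling step defaults to half the smallest voxel spacing.
    """
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    spacing = np.asarray(grid.spacing_nm)
    extent = np.asarray(grid.extent_nm)
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > extent):
            raise ValueError(f"endpoint {tuple(p)} outside the grid extent {tuple(extent)}")
    if step_nm is None:
        step_nm = float(spacing.min()) / 2.0
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("endpoints coincide")
    n = max(5, int(math.floor(length / step_nm)) + 1)
    t = np.linspace(0.0, length, n)
    pts = p0[None, :] + (p1 - p0)[None, :] * (t / length)[:, None]
    # voxel centers sit at (i + 0.5) * spacing -> continuous index = pos/spacing - 0.5
    coords = (pts / spacing[None, :] - 0.5).T
    vals = ndi.map_coordinates(
        np.asarray(grid.data, dtype=float), coords, order=1, mode="nearest"
    )
    return LineProfile(positions_nm=t, intensities=vals)


def fit_gaussian(profile: LineProfile) -> GaussianFit:
    """Fit a Gaussian with constant offset; parameter SDs from the covariance.

    Initialization from the intensity moments around the peak; raises with the
    residual norm when the optimizer does not converge.
    """
    x = profile.positions_nm
    y = profile.intensities

    offset0 = float(np.min(y))
    w = np.clip(y - offset0, 0.0, None)
    if w.sum() == 0:
        raise ValueError("flat profile: nothing to fit")
    c0 = float((x * w).sum() / w.sum())
    var0 = float(((x - c0) ** 2 * w).sum() / w.sum())
    sigma0 = math.sqrt(max(var0, (x[1] - x[0]) ** 2))
    amp0 = float(np.max(y) - offset0)

    def model(xx, amp, center, sigma, offset):
        return amp * np.exp(-0.5 * ((xx - center) / sigma) ** 2) + offset

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[amp0, c0, sigma0, offset0], maxfev=20000
        )
    except RuntimeError as err:
        resid = float(np.linalg.norm(y - model(x, amp0, c0, sigma0, offset0)))
        raise RuntimeError(
            f"Gaussian fit did not converge (residual at init: {resid:.3g})"
        ) from err
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    amp, center, sigma, offset = popt
    if sigma < 0:
        sigma, perr_sigma = -sigma, perr[2]
    else:
        perr_sigma = perr[2]
    return GaussianFit(
        amplitude=float(amp),
        center_nm=float(center),
        sigma_nm=float(sigma),
        offset=float(offset),
        amplitude_sd=float(perr[0]),
        center_sd_nm=float(perr[1]),
        sigma_sd_nm=float(perr_sigma),
        offset_sd=float(perr[3]),
    )
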