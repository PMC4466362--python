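"""Deconvolution preceding segmentation.

The acquisition PSF is modeled as a separable 3D Gaussian with the lateral
and axial FWHMs of the imaging mode; stacks can be sharpened with
Richardson-Lucy iterations (multiplicative-update maximum-likelihood
deconvolution for Poisson noise) before thresholding.  Deconvolution is
optional in the pipeline — the counting workflow does not rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .grids import VoxelGrid
from .synthetic import AcquisitionConfig


@dataclass
class PSFKernel:
    """Discrete PSF: non-negative 3D array with unit sum and a centered peak."""

    data: np.ndarray
    spacing_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("PSF must be 3D")
        if np.any(self.data < 0):
            raise ValueError("PSF must be non-negative")
        s = self.data.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"PSF must sum to 1 (got {s!r})")
        peak = np.unravel_index(np.argmax(self.data), self.data.shape)
        center = tuple(n // 2 for n in self.data.shape)
        if peak != center:
            raise ValueError("PSF peak must be centered")


def gaussian_psf(acq: AcquisitionConfig, support_radius_fwhm: float = 3.0) -> PSFKernel:
    """Separable Gaussian PSF sampled on the acquisition grid.

    The kernel extends ``support_radius_fwhm`` FWHMs from the center along
    each axis (at least one voxel) and is normalized to unit sum.
    """
    if support_radius_fwhm < 2:
        raise ValueError("support radius must be at least 2 FWHM")
    spacing = acq.spacing_nm
    sigma = (acq.sigma_axial_nm, acq.sigma_lateral_nm, acq.sigma_lateral_nm)
    fwhm = (acq.axial_fwhm_nm, acq.lateral_fwhm_nm, acq.lateral_fwhm_nm)
    profiles = []
    for s, f, d in zip(sigma, fwhm, spacing):
        half = int(np.ceil(support_radius_fwhm * f / d))
        if half < 1:
            raise ValueError("PSF support smaller than one voxel")
        x = np.arange(-half, half + 1) * d
        profiles.append(np.exp(-0.5 * (x / s) ** 2))
    kernel = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    kernel /= kernel.sum()
    return PSFKernel(data=kernel, spacing_nm=spacing)


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflective boundary handling."""
    pad = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(image, pad, mode="reflect")
    out = fftconvolve(padded, kernel, mode="valid")
    return np.maximum(out, 0.0)


def richardson_lucy(
    grid: VoxelGrid,
    psf: PSFKernel,
    iterations: int = 40,
    background: float = 0.0,
) -> VoxelGrid:
    """Richardson-Lucy maximum-likelihood deconvolution.

    Multiplicative updates  u <- u * (K^T * (I / (K*u + b)))  starting from
    u = I, with reflective boundaries; ``iterations=0`` returns the input
    unchanged.  Output intensities stay non-negative.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if background < 0:
        raise ValueError("background must be >= 0")
    if not np.allclose(psf.spacing_nm, grid.spacing_nm):
        raise ValueError(
            f"PSF spacing {psf.spacing_nm} does not match grid spacing {grid.spacing_nm}"
        )
    image = grid.data.astype(np.float64)
    if iterations == 0:
        return VoxelGrid(image.copy(), grid.spacing_nm, grid.channel,
                         dict(grid.meta, rl_iterations=0))
    kernel = psf.data
    mirror = kernel[::-1, ::-1, ::-1]
    estimate = image.copy()
    eps = 1e-12
    for _ in range(iterations):
        blurred = _convolve_reflect(estimate, kernel) + background
        ratio = image / np.maximum(blurred, eps)
        estimate *= _convolve_reflect(ratio, mirror)
        np.maximum(estimate, 0.0, out=estimate)
    meta = dict(grid.meta, rl_iterations=iterations,
                flux_change=float(estimate.sum() / max(image.sum(), eps) - 1.0))
    return VoxelGrid(estimate, grid.spacing_nm, grid.channel, meta)
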