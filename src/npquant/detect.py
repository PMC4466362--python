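"""Detection, filtering and measurement of nanoparticle-channel objects.

Workflow on the NP channel: (1) Otsu threshold T; (2) Gaussian smoothing with
a configurable sigma (default 2.0 um); (3) marker-free watershed on the
inverted smoothed image restricted to the thresholded foreground, so touching
blobs split at smoothed-intensity minima; (4) discard objects whose peak
intensity is below T + f (I_max - T) with f = 0.05 by default (objects within
5% of the threshold-to-maximum range are treated as noise-floor artifacts);
(5) measure the survivors.

An object is counted as internalized only when every one of its voxels lies
inside the segmented cell region; objects straddling the membrane are
excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .cellmask import CellMask, otsu_threshold
from .grids import VoxelGrid


@dataclass
class ParticleObject:
    """One segmented NP-channel object."""

    label: int
    centroid_nm: tuple[float, float, float]  # (z, y, x)
    n_voxels: int
    peak_intensity: float
    mean_intensity: float
    lateral_width_nm: float
    inside: bool | None = None
    touches_z_border: bool = False
    voxel_indices: np.ndarray | None = None  # (n, 3) int array, (z, y, x)

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("object must contain at least one voxel")
        if self.peak_intensity < self.mean_intensity - 1e-9:
            raise ValueError("peak intensity cannot be below mean intensity")


@dataclass
class CellSummary:
    """Per-cell counting summary (internalized objects only)."""

    n_objects_inside: int
    objects_per_um2: float
    projected_area_um2: float
    n_objects_total: int
    mean_intensity_inside: float


def _smooth(data: np.ndarray, sigma_vox: tuple[float, float, float]) -> np.ndarray:
    """Gaussian smoothing; FFT-based for very wide kernels (sigma 2 um on a
    30 nm grid is ~67 pixels, where direct separable filtering is slow)."""
    if max(sigma_vox) > 12:
        padded = np.asarray(data, dtype=np.float64)
        out = ndi.fourier_gaussian(np.fft.rfftn(padded), sigma_vox, n=padded.shape[-1])
        return np.fft.irfftn(out, s=padded.shape)
    return ndi.gaussian_filter(np.asarray(data, dtype=np.float64), sigma_vox)


def _lateral_width_nm(
    voxels: np.ndarray, centroid_z: float, spacing_nm: tuple[float, float, float]
) -> float:
    """Maximum lateral extent of the object in the focal plane of its centroid.

    The width is the largest center-to-center distance among the object's
    voxels in the z-slice nearest the centroid, plus one pixel to account for
    the voxel footprint; a single-voxel object thus has width = pixel size.
    """
    dz, dy, dx = spacing_nm
    z_focal = voxels[np.argmin(np.abs(voxels[:, 0] - centroid_z / dz))][0]
    plane = voxels[voxels[:, 0] == z_focal][:, 1:]
    if len(plane) == 1:
        return float(dx)
    pts = plane * np.array([dy, dx])
    if len(pts) > 400:
        # reduce to the convex hull before the pairwise scan
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    return float(pdist(pts).max()) + float(dx)


def detect_particles(
    grid: VoxelGrid,
    watershed_sigma_um: float = 2.0,
    discard_fraction: float = 0.05,
    snr_guard: float = 15.0,
    threshold: float | None = None,
) -> list[ParticleObject]:
    """Detect and measure NP-channel objects.

    ``threshold`` overrides the Otsu threshold when given (e.g. for
    calibration fixtures); ``snr_guard`` protects against thresholding pure
    background: when the brightest voxel exceeds the threshold by less than
    ``snr_guard`` background-noise standard deviations (robustly estimated
    from the sub-threshold voxels), the channel is declared empty.  An empty
    foreground returns an empty list, not an error.
    """
    if watershed_sigma_um <= 0:
        raise ValueError("watershed sigma must be positive")
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard fraction must be in [0, 1)")
    data = grid.data
    if threshold is None:
        try:
            threshold = otsu_threshold(grid)
        except ValueError:
            return []
    i_max = float(data.max())

    background = data[data <= threshold]
    noise_sd = 1.4826 * np.median(np.abs(background - np.median(background)))
    if i_max < threshold + snr_guard * max(noise_sd, 1e-12):
        return []

    foreground = data > threshold
    if not foreground.any():
        return []

    sigma_vox = tuple(watershed_sigma_um * 1000.0 / s for s in grid.spacing_nm)
    smoothed = _smooth(data, sigma_vox)
    # Relief for the flooding: inverted smoothed intensity inside the
    # foreground, a high plateau outside, so each foreground component owns at
    # least one regional minimum and touching blobs split at internal minima.
    # The relief is quantized to 256 levels over its dynamic range: regional
    # minima then come from resolved intensity structure, not from
    # sub-resolution numerical ripple along thin objects (which would
    # fragment single blobs).
    relief = -smoothed
    quantum = (relief[foreground].max() - relief[foreground].min()) / 256.0
    if quantum > 0:
        relief = np.round(relief / quantum) * quantum
    fill_value = relief[foreground].max() + 1.0
    relief[~foreground] = fill_value
    markers, _ = ndi.label(local_minima(relief, connectivity=3),
                           structure=np.ones((3, 3, 3), dtype=bool))
    labels = watershed(relief, markers=markers, connectivity=3, mask=foreground)

    cutoff = threshold + discard_fraction * (i_max - threshold)
    objects: list[ParticleObject] = []
    nz = grid.shape[0]
    dz, dy, dx = grid.spacing_nm
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        offset = np.array([s.start for s in sl])
        vox = np.argwhere(labels[sl] == lab) + offset
        values = data[vox[:, 0], vox[:, 1], vox[:, 2]]
        peak = float(values.max())
        if peak < cutoff:
            continue
        centroid = (vox.mean(axis=0) + 0.5) * np.array([dz, dy, dx])
        obj = ParticleObject(
            label=int(lab),
            centroid_nm=tuple(centroid),
            n_voxels=len(vox),
            peak_intensity=peak,
            mean_intensity=float(values.mean()),
            lateral_width_nm=_lateral_width_nm(vox, centroid[0], grid.spacing_nm),
            touches_z_border=bool(vox[:, 0].min() == 0 or vox[:, 0].max() == nz - 1),
            voxel_indices=vox,
        )
        objects.append(obj)
    return objects


def measure_lateral_width(obj: ParticleObject, grid: VoxelGrid) -> float:
    """Lateral width (nm) of an object on its grid; see `_lateral_width_nm`."""
    if obj.voxel_indices is None:
        raise ValueError("object carries no voxel indices")
    return _lateral_width_nm(obj.voxel_indices, obj.centroid_nm[0], grid.spacing_nm)


def classify_inside(objects: list[ParticleObject], mask: CellMask,
                    grid: VoxelGrid) -> list[ParticleObject]:
    """Flag each object as internalized iff every voxel lies in the cell mask."""
    if mask.mask.shape != grid.shape or not np.allclose(mask.spacing_nm, grid.spacing_nm):
        raise ValueError(
            f"mask geometry {mask.mask.shape}/{mask.spacing_nm} does not match "
            f"grid {grid.shape}/{grid.spacing_nm}; resample with CellMask.on_grid"
        )
    for obj in objects:
        vox = obj.voxel_indices
        if vox is None:
            raise ValueError("object carries no voxel indices")
        obj.inside = bool(mask.mask[vox[:, 0], vox[:, 1], vox[:, 2]].all())
    return objects


def summarize(objects: list[ParticleObject], mask: CellMask) -> CellSummary:
    """Per-cell summary over the inside-flagged objects."""
    inside = [o for o in objects if o.inside]
    area = mask.projected_area_um2
    mean_int = float(np.mean([o.mean_intensity for o in inside])) if inside else 0.0
    return CellSummary(
        n_objects_inside=len(inside),
        objects_per_um2=len(inside) / area,
        projected_area_um2=area,
        n_objects_total=len(objects),
        mean_intensity_inside=mean_int,
    )


def objects_to_dataframe(objects: list[ParticleObject]) -> pd.DataFrame:
    """Flat object table (one row per object) for CSV export."""
    return pd.DataFrame(
        {
            "label": [o.label for o in objects],
            "centroid_z_nm": [o.centroid_nm[0] for o in objects],
            "centroid_y_nm": [o.centroid_nm[1] for o in objects],
            "centroid_x_nm": [o.centroid_nm[2] for o in objects],
            "n_voxels": [o.n_voxels for o in objects],
            "peak_intensity": [o.peak_intensity for o in objects],
            "mean_intensity": [o.mean_intensity for o in objects],
            "lateral_width_nm": [o.lateral_width_nm for o in objects],
            "inside": [o.inside for o in objects],
            "touches_z_border": [o.touches_z_border for o in objects],
        }
    )
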