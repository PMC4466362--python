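"""Whole-cell 3D region of interest from the membrane channel.

The membrane label marks a thin shell around the cell; the cell ROI is the
filled interior of that shell.  Pipeline: Otsu binarization -> morphological
closing then opening (ball of radius 2 voxels) -> 3D hole filling plus
per-slice 2D filling in all three axis orientations (a cavity truncated by
the stack border is open in 3D but closed in some 2D sections) -> largest
connected component, or the components intersecting a manually drawn polygon
when several cells share the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu as _skimage_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball

from .grids import VoxelGrid


def otsu_threshold(grid: VoxelGrid | np.ndarray, nbins: int = 256) -> float:
    """Otsu intensity threshold (maximizes between-class variance, 256 bins).

    Raises on constant images: a single-valued histogram has no separable
    classes.
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    if data.size == 0 or np.min(data) == np.max(data):
        raise ValueError("cannot threshold a constant image")
    return float(_skimage_otsu(data, nbins=nbins))


@dataclass
class CellMask:
    """Binary 3D cell region with the geometry needed by the dose metrics."""

    mask: np.ndarray
    spacing_nm: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("cell mask is empty")

    @property
    def projected_area_um2(self) -> float:
        """Area of the xy projection of the mask."""
        _, dy, dx = self.spacing_nm
        return float(self.mask.any(axis=0).sum()) * dy * dx / 1e6

    @property
    def volume_um3(self) -> float:
        dz, dy, dx = self.spacing_nm
        return float(self.mask.sum()) * dz * dy * dx / 1e9

    def on_grid(self, target: VoxelGrid) -> "CellMask":
        """Resample the mask onto another grid (nearest voxel-center lookup).

        Both grids must share the physical origin (voxel (0,0,0) centered at
        half a spacing), as produced by the scene renderer.
        """
        if target.shape == self.mask.shape and np.allclose(
            target.spacing_nm, self.spacing_nm
        ):
            return self
        idx = []
        for ax in range(3):
            centers = (np.arange(target.shape[ax]) + 0.5) * target.spacing_nm[ax]
            j = np.clip(
                np.floor(centers / self.spacing_nm[ax]).astype(int),
                0,
                self.mask.shape[ax] - 1,
            )
            idx.append(j)
        resampled = self.mask[np.ix_(idx[0], idx[1], idx[2])]
        return CellMask(
            mask=resampled,
            spacing_nm=target.spacing_nm,
            provenance=dict(self.provenance, resampled_from=self.mask.shape),
        )


def _fill_cavities(mask: np.ndarray) -> np.ndarray:
    """3D hole filling plus per-slice 2D filling along all three axes."""
    out = ndi.binary_fill_holes(mask)
    for axis in range(3):
        moved = np.moveaxis(out, axis, 0)
        for i in range(moved.shape[0]):
            moved[i] = ndi.binary_fill_holes(moved[i])
    return out


def segment_cell(
    grid: VoxelGrid,
    manual_polygon_xy_nm: np.ndarray | None = None,
    structuring_radius: int = 2,
    threshold: float | None = None,
) -> CellMask:
    """Segment the whole-cell ROI from the membrane channel.

    ``manual_polygon_xy_nm`` is an optional (n, 2) array of (y, x) vertices in
    nm; when given, only connected components whose xy projection intersects
    the polygon are kept (instead of the largest component).
    """
    thr = otsu_threshold(grid) if threshold is None else float(threshold)
    binary = grid.data > thr
    if not binary.any():
        raise ValueError("no voxels above threshold; cannot segment a cell")

    selem = ball(structuring_radius)
    closed = ndi.binary_closing(binary, structure=selem)
    opened = ndi.binary_opening(closed, structure=selem)
    filled = _fill_cavities(opened | binary)

    labels = cc_label(filled, connectivity=3)
    if labels.max() == 0:
        raise ValueError("segmentation produced an empty mask")

    if manual_polygon_xy_nm is None:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = {int(np.argmax(counts))}
        selection = "largest component"
    else:
        from shapely import contains_xy
        from shapely.geometry import Polygon

        poly = Polygon(np.asarray(manual_polygon_xy_nm, dtype=float))
        keep = set()
        for lab in range(1, labels.max() + 1):
            proj = (labels == lab).any(axis=0)
            ys, xs = np.nonzero(proj)
            y_nm = (ys + 0.5) * grid.spacing_nm[1]
            x_nm = (xs + 0.5) * grid.spacing_nm[2]
            # polygon vertices are (y, x); shapely's (x, y) maps to (y, x) here
            if len(y_nm) and contains_xy(poly, y_nm, x_nm).any():
                keep.add(lab)
        if not keep:
            raise ValueError("manual polygon intersects no segmented component")
        selection = "manual polygon"

    mask = np.isin(labels, sorted(keep))
    return CellMask(
        mask=mask,
        spacing_nm=grid.spacing_nm,
        provenance={
            "threshold": thr,
            "structuring_radius_voxels": structuring_radius,
            "operations": ["otsu", "closing", "opening", "fill_cavities", selection],
        },
    )
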