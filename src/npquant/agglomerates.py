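"""Estimate particle counts inside detected objects from their lateral widths.

An imaged object wider than a single-particle footprint is an agglomerate.
Because a z-stack only constrains the lateral extent w of an object, the
number of primary particles of diameter d it contains is bracketed by three
idealized geometries:

    chain (1D):  n1 = round(w / d)
    plate (2D):  n2 = round(0.91 * (w / d)^2)    (hexagonal packing, 0.91)
    ball  (3D):  n3 = round(0.74 * (w / d)^3)    (close packing, 0.74)

each clamped below at 1 — a detected object is at least one particle.  The 1D
model under-counts and the 3D model over-counts anything that is not actually
a chain or a ball, so the three totals form a plausible range per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

PACKING_2D = 0.91
PACKING_3D = 0.74

Model = Literal["1d", "2d", "3d"]

#: width cutoffs (nm) below which an object is treated as a single particle,
#: keyed by primary particle diameter (nm)
DEFAULT_SINGLE_CUTOFF_NM = {85.0: 150.0, 25.0: 75.0}


def classify_single(width_nm: float, particle_diameter_nm: float, cutoff_nm: float | None = None) -> str:
    """Classify an object as ``"single"`` or ``"agglomerate"`` by lateral width.

    Objects with width >= cutoff are agglomerates (strict ``<`` keeps singles).
    The default cutoff is 150 nm for 85 nm particles and 75 nm for 25 nm
    particles; other diameters default to ~1.75 x the particle diameter.
    """
    if width_nm <= 0 or particle_diameter_nm <= 0:
        raise ValueError("width and diameter must be positive")
    if cutoff_nm is None:
        cutoff_nm = DEFAULT_SINGLE_CUTOFF_NM.get(
            particle_diameter_nm, 1.75 * particle_diameter_nm
        )
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    return "single" if width_nm < cutoff_nm else "agglomerate"


def particles_in_object(width_nm: float, particle_diameter_nm: float, model: Model) -> int:
    """Number of primary particles in one object under a packing model."""
    if width_nm <= 0 or particle_diameter_nm <= 0:
        raise ValueError("width and diameter must be positive")
    ratio = width_nm / particle_diameter_nm
    if model == "1d":
        n = round(ratio)
    elif model == "2d":
        n = round(PACKING_2D * ratio**2)
    elif model == "3d":
        n = round(PACKING_3D * ratio**3)
    else:
        raise ValueError(f"unknown model {model!r}")
    return max(1, int(n))


@dataclass
class AgglomerateEstimate:
    """Per-object particle counts under the three packing models."""

    widths_nm: np.ndarray
    classes: list[str]
    counts_1d: np.ndarray
    counts_2d: np.ndarray
    counts_3d: np.ndarray

    @property
    def total_1d(self) -> int:
        return int(self.counts_1d.sum())

    @property
    def total_2d(self) -> int:
        return int(self.counts_2d.sum())

    @property
    def total_3d(self) -> int:
        return int(self.counts_3d.sum())

    @property
    def n_single(self) -> int:
        return sum(c == "single" for c in self.classes)

    def summary(self) -> dict:
        return {
            "n_objects": len(self.classes),
            "n_single": self.n_single,
            "n_agglomerate": len(self.classes) - self.n_single,
            "total_particles_1d": self.total_1d,
            "total_particles_2d": self.total_2d,
            "total_particles_3d": self.total_3d,
        }


def total_particles(
    widths_nm: Sequence[float] | Iterable[float],
    particle_diameter_nm: float,
    cutoff_nm: float | None = None,
    apply_to: Literal["all", "agglomerates"] = "agglomerates",
) -> AgglomerateEstimate:
    """Per-cell particle-count estimate from a list of object widths.

    ``apply_to="agglomerates"`` (default) counts every single-classified object
    as exactly 1 particle and applies the packing models only to agglomerates;
    ``apply_to="all"`` applies the models to every object.
    """
    widths = np.asarray(list(widths_nm), dtype=float)
    if widths.size == 0:
        raise ValueError("object list is empty")
    classes = [classify_single(w, particle_diameter_nm, cutoff_nm) for w in widths]
    counts = {m: np.ones(widths.size, dtype=int) for m in ("1d", "2d", "3d")}
    for i, (w, cls) in enumerate(zip(widths, classes)):
        if apply_to == "all" or cls == "agglomerate":
            for m in ("1d", "2d", "3d"):
                counts[m][i] = particles_in_object(w, particle_diameter_nm, m)
    return AgglomerateEstimate(
        widths_nm=widths,
        classes=classes,
        counts_1d=counts["1d"],
        counts_2d=counts["2d"],
        counts_3d=counts["3d"],
    )
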