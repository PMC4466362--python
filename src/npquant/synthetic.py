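"""Ground-truthed synthetic STED/confocal stacks of a nanoparticle-exposed cell.

The generator emulates sequential z-stack acquisition of an adherent alveolar
epithelial cell (A549-like) carrying three labels: a plasma-membrane label and
a nuclear-lamina label imaged in confocal mode (60 nm pixels, 277 nm lateral
PSF FWHM), and a nanoparticle label imaged in STED mode (30 nm pixels, 76 nm
lateral PSF FWHM).  The z-step is 130 nm in both modes.

The cell phantom is a half-ellipsoid resting on the substrate plane z = 0 with
an ellipsoidal nucleus inside.  Emitters (particles, or points densely covering
the membrane/lamina surfaces) are blurred with a separable 3D Gaussian PSF,
shot noise is Poisson, detector read noise is Gaussian, and bright signals
clip at the detector maximum (the testable analog of an avalanche photodiode
powering down on saturation).

All coordinates are physical nm, axis order (z, y, x); a voxel's position is
the position of its center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import VoxelGrid

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition descriptor for one imaging mode.

    ``detector_max`` is the hard saturation level in counts; ``background``
    the mean background count per voxel; ``read_noise_sd`` the Gaussian read
    noise (0 for photon-counting detectors).
    """

    mode: str
    pixel_nm: float
    z_step_nm: float
    lateral_fwhm_nm: float
    axial_fwhm_nm: float = 600.0
    detector_max: float = 65535.0
    background: float = 5.0
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.lateral_fwhm_nm <= 0 or self.axial_fwhm_nm <= 0:
            raise ValueError("PSF FWHMs must be positive")
        if self.background < 0 or self.detector_max <= self.background:
            raise ValueError("need saturation level > background >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read noise must be >= 0")

    @property
    def sigma_lateral_nm(self) -> float:
        return self.lateral_fwhm_nm / FWHM_PER_SIGMA

    @property
    def sigma_axial_nm(self) -> float:
        return self.axial_fwhm_nm / FWHM_PER_SIGMA

    @property
    def spacing_nm(self) -> tuple[float, float, float]:
        return (self.z_step_nm, self.pixel_nm, self.pixel_nm)


#: STED nanoparticle-channel acquisition: 30 nm pixels, 76 nm lateral FWHM
STED = AcquisitionConfig("STED", pixel_nm=30.0, z_step_nm=130.0, lateral_fwhm_nm=76.0)
#: diffraction-limited confocal acquisition: 60 nm pixels, 277 nm lateral FWHM
CONFOCAL = AcquisitionConfig(
    "confocal", pixel_nm=60.0, z_step_nm=130.0, lateral_fwhm_nm=277.0,
    background=10.0, read_noise_sd=3.0,
)


@dataclass(frozen=True)
class CellPhantom:
    """Half-ellipsoid cell on the substrate plane with an ellipsoidal nucleus.

    The cell interior is {z >= 0, (x/ax)^2 + (y/ay)^2 + (z/az)^2 <= 1} around
    a center on the substrate; the membrane is a thin shell on the curved
    surface and the basal ellipse.  Lengths are nm.
    """

    cell_semiaxes_nm: tuple[float, float, float]  # (ax, ay, az) lateral x, y, height z
    nucleus_semiaxes_nm: tuple[float, float, float]
    nucleus_center_nm: tuple[float, float, float]  # (z, y, x) scene coordinates
    center_xy_nm: tuple[float, float]  # (y, x) of the cell center on the substrate
    membrane_thickness_nm: float = 100.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.cell_semiaxes_nm + self.nucleus_semiaxes_nm):
            raise ValueError("all semi-axes must be positive")
        if self.membrane_thickness_nm <= 0:
            raise ValueError("membrane thickness must be positive")
        if not self._nucleus_contained():
            raise ValueError("nucleus is not strictly contained in the cell")

    # -- geometry helpers ---------------------------------------------------

    def _cell_scaled_radius(self, pos_nm: np.ndarray) -> np.ndarray:
        """|scaled position| wrt the cell ellipsoid; <= 1 and z >= 0 is interior."""
        pos = np.atleast_2d(pos_nm)
        ax, ay, az = self.cell_semiaxes_nm
        cy, cx = self.center_xy_nm
        return np.sqrt(
            ((pos[:, 2] - cx) / ax) ** 2
            + ((pos[:, 1] - cy) / ay) ** 2
            + (pos[:, 0] / az) ** 2
        )

    def contains(self, pos_nm: np.ndarray, margin_nm: float = 0.0) -> np.ndarray:
        """True for points inside the cell, at least ``margin_nm`` from the
        membrane (margin applied per axis, i.e. inside the shrunken ellipsoid
        and above z = margin)."""
        pos = np.atleast_2d(np.asarray(pos_nm, dtype=float))
        ax, ay, az = (a - margin_nm for a in self.cell_semiaxes_nm)
        if min(ax, ay, az) <= 0:
            return np.zeros(len(pos), dtype=bool)
        cy, cx = self.center_xy_nm
        r = np.sqrt(
            ((pos[:, 2] - cx) / ax) ** 2
            + ((pos[:, 1] - cy) / ay) ** 2
            + (pos[:, 0] / az) ** 2
        )
        ok = (r <= 1.0) & (pos[:, 0] >= margin_nm)
        return ok if np.asarray(pos_nm).ndim > 1 else ok

    def in_nucleus(self, pos_nm: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos_nm, dtype=float))
        nz, ny, nx = self.nucleus_center_nm
        # nucleus_semiaxes_nm is (ax, ay, az), like the cell's
        ax, ay, az = self.nucleus_semiaxes_nm
        r = np.sqrt(
            ((pos[:, 2] - nx) / ax) ** 2
            + ((pos[:, 1] - ny) / ay) ** 2
            + ((pos[:, 0] - nz) / az) ** 2
        )
        return r <= 1.0

    def _nucleus_contained(self, n_check: int = 720) -> bool:
        rng = np.random.default_rng(0)
        u = rng.normal(size=(n_check, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ax, ay, az = self.nucleus_semiaxes_nm
        nz, ny, nx = self.nucleus_center_nm
        pts = np.column_stack(
            [nz + u[:, 0] * az, ny + u[:, 1] * ay, nx + u[:, 2] * ax]
        )
        r = self._cell_scaled_radius(pts)
        return bool(np.all((r < 1.0) & (pts[:, 0] > 0.0)))

    @property
    def volume_um3(self) -> float:
        """Analytic half-ellipsoid volume (2/3) pi ax ay az."""
        ax, ay, az = self.cell_semiaxes_nm
        return 2.0 / 3.0 * math.pi * ax * ay * az / 1e9

    @property
    def projected_area_um2(self) -> float:
        """Area of the xy footprint, an ellipse: pi ax ay."""
        ax, ay, _ = self.cell_semiaxes_nm
        return math.pi * ax * ay / 1e6

    def fov_nm(self, pad_nm: float = 1000.0) -> tuple[float, float, float]:
        """(z, y, x) field of view covering the cell with a pad on all sides."""
        ax, ay, az = self.cell_semiaxes_nm
        cy, cx = self.center_xy_nm
        return (az + pad_nm, cy + ay + pad_nm, cx + ax + pad_nm)

    def voxelize(self, spacing_nm: tuple[float, float, float],
                 pad_nm: float = 500.0) -> np.ndarray:
        """Boolean interior grid over the padded field of view.

        A voxel is interior iff its center is inside the cell (unambiguous
        voxelization).
        """
        dz, dy, dx = spacing_nm
        fz, fy, fx = self.fov_nm(pad_nm)
        ax, ay, az = self.cell_semiaxes_nm
        cy, cx = self.center_xy_nm
        z = (np.arange(int(math.ceil(fz / dz))) + 0.5) * dz
        y = (np.arange(int(math.ceil(fy / dy))) + 0.5) * dy
        x = (np.arange(int(math.ceil(fx / dx))) + 0.5) * dx
        r2 = (
            (z[:, None, None] / az) ** 2
            + ((y[None, :, None] - cy) / ay) ** 2
            + ((x[None, None, :] - cx) / ax) ** 2
        )
        return r2 <= 1.0

    def surface_points(
        self, n: int, rng: np.random.Generator, which: str = "cell",
        include_basal: bool = True,
    ) -> np.ndarray:
        """~Uniform points on the membrane (or lamina) surface, (z, y, x) nm.

        The curved surface is sampled by mapping sphere directions to the
        ellipsoid with an area reweighting; the basal ellipse (cell only) is
        sampled in proportion to its share of the total area.
        """
        cy, cx = self.center_xy_nm
        if which == "cell":
            ax, ay, az = self.cell_semiaxes_nm
            center = np.array([0.0, cy, cx])
            half = True
        elif which == "nucleus":
            ax, ay, az = self.nucleus_semiaxes_nm
            center = np.array(self.nucleus_center_nm)
            half = False
        else:
            raise ValueError(f"unknown surface {which!r}")

        basal_area = math.pi * ax * ay if (half and include_basal) else 0.0
        curved_area = _ellipsoid_area(ax, ay, az) * (0.5 if half else 1.0)
        n_basal = int(round(n * basal_area / (basal_area + curved_area)))
        n_curved = n - n_basal

        # curved part: rejection sampling against the local area element
        pts = []
        target = n_curved
        while target > 0:
            u = rng.normal(size=(2 * target + 16, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            if half:
                u[:, 0] = np.abs(u[:, 0])  # upper hemisphere (z >= 0)
            p = np.column_stack([u[:, 0] * az, u[:, 1] * ay, u[:, 2] * ax])
            # area element weight ~ |n| of the mapped surface
            w = np.sqrt(
                (u[:, 0] * ay * ax) ** 2 + (u[:, 1] * az * ax) ** 2 + (u[:, 2] * az * ay) ** 2
            )
            keep = rng.random(len(w)) < w / w.max()
            p = p[keep][:target]
            pts.append(p)
            target -= len(p)
        curved = np.concatenate(pts) + center if n_curved else np.empty((0, 3))

        if n_basal:
            # uniform in the basal ellipse at z = 0
            r = np.sqrt(rng.random(n_basal))
            th = rng.uniform(0, 2 * math.pi, n_basal)
            basal = np.column_stack(
                [np.zeros(n_basal), cy + r * ay * np.sin(th), cx + r * ax * np.cos(th)]
            )
            return np.concatenate([curved, basal]) if n_curved else basal
        return curved


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Knud Thomsen approximation of the full ellipsoid surface area."""
    p = 1.6075
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def build_phantom(
    cell_semiaxes_um: tuple[float, float, float] = (13.0, 10.5, 5.6),
    nucleus_semiaxes_um: tuple[float, float, float] = (5.5, 4.5, 2.5),
    nucleus_height_um: float | None = None,
    membrane_thickness_nm: float = 100.0,
    pad_um: float = 1.0,
    seed: int | None = None,
) -> CellPhantom:
    """Construct the cell phantom; default volume ~1600 um^3 (a typical
    adherent A549 cell).

    The ``seed`` argument is accepted for interface symmetry with the samplers
    (the phantom itself is deterministic in its parameters).
    """
    ax, ay, az = (a * 1000.0 for a in cell_semiaxes_um)
    nx_, ny_, nz_ = (a * 1000.0 for a in nucleus_semiaxes_um)
    if not (nx_ < ax and ny_ < ay and nz_ < az):
        raise ValueError("nucleus semi-axes must be smaller than the cell's")
    if nucleus_height_um is None:
        nucleus_z = 1.05 * nz_  # resting just above the substrate
    else:
        nucleus_z = nucleus_height_um * 1000.0
    pad = pad_um * 1000.0
    center_xy = (ay + pad, ax + pad)  # (y, x)
    return CellPhantom(
        cell_semiaxes_nm=(ax, ay, az),
        nucleus_semiaxes_nm=(nx_, ny_, nz_),
        nucleus_center_nm=(nucleus_z, center_xy[0], center_xy[1]),
        center_xy_nm=center_xy,
        membrane_thickness_nm=membrane_thickness_nm,
    )


@dataclass
class EmitterSet:
    """Point emitters with ground-truth annotations; positions are (z, y, x) nm."""

    positions_nm: np.ndarray
    brightness: np.ndarray
    diameter_nm: np.ndarray
    cluster_id: np.ndarray
    inside: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions_nm)
        for name in ("brightness", "diameter_nm", "cluster_id", "inside"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-emitter arrays must share one length")
        if n and np.min(self.brightness) < 0:
            raise ValueError("brightness must be >= 0")

    def __len__(self) -> int:
        return len(self.positions_nm)

    @classmethod
    def empty(cls) -> "EmitterSet":
        return cls(
            positions_nm=np.empty((0, 3)),
            brightness=np.empty(0),
            diameter_nm=np.empty(0),
            cluster_id=np.empty(0, dtype=int),
            inside=np.empty(0, dtype=bool),
        )

    @classmethod
    def concatenate(cls, parts: list["EmitterSet"]) -> "EmitterSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            positions_nm=np.concatenate([p.positions_nm for p in parts]),
            brightness=np.concatenate([p.brightness for p in parts]),
            diameter_nm=np.concatenate([p.diameter_nm for p in parts]),
            cluster_id=np.concatenate([p.cluster_id for p in parts]),
            inside=np.concatenate([p.inside for p in parts]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.positions_nm[:, 0],
                "y_nm": self.positions_nm[:, 1],
                "x_nm": self.positions_nm[:, 2],
                "brightness": self.brightness,
                "diameter_nm": self.diameter_nm,
                "cluster_id": self.cluster_id,
                "inside": self.inside,
            }
        )


def _cluster_offsets(size: int, d: float, rng: np.random.Generator) -> np.ndarray:
    """Member positions of a compact cluster relative to its centroid.

    Clusters of 2-4 particles are regular simplexes with edge length d
    (segment, equilateral triangle, regular tetrahedron), so every member
    pair is in contact; larger clusters extend the tetrahedron by attaching
    each extra member in contact with the previous one.  The cluster is
    randomly oriented.
    """
    if size == 1:
        return np.zeros((1, 3))
    if size == 2:
        verts = np.array([[-0.5, 0, 0], [0.5, 0, 0]]) * d
    elif size == 3:
        r = d / math.sqrt(3.0)
        verts = r * np.array(
            [[1.0, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0]]
        )
    else:
        s = d / (2.0 * math.sqrt(2.0))
        verts = s * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        for _ in range(size - 4):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            verts = np.vstack([verts, verts[-1] + u * d])
        verts = verts - verts.mean(axis=0)
    # random proper rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return verts @ q.T


def sample_particles(
    phantom: CellPhantom,
    n_inside: int,
    n_outside: int,
    particle_diameter_nm: float = 85.0,
    cluster_sizes: int | list[int] = 1,
    brightness: float = 2.0e4,
    margin_nm: float | None = None,
    min_separation_nm: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> EmitterSet:
    """Place particle emitters inside the cell and on its outer membrane.

    Exactly ``n_inside`` emitters are placed with centers inside the cell, at
    least ``margin_nm`` (default: one particle diameter) from the membrane;
    ``n_outside`` emitters sit on/above the outer membrane surface.  Cluster
    members are placed in contact (center spacing = particle diameter); with a
    list of ``cluster_sizes`` each new cluster draws its size uniformly from
    the list.  ``min_separation_nm`` enforces a minimum distance between
    emitters of different clusters (used to build well-separated scenes).
    """
    if n_inside < 0 or n_outside < 0:
        raise ValueError("emitter counts must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = float(particle_diameter_nm)
    margin = d if margin_nm is None else float(margin_nm)
    sizes = [cluster_sizes] if isinstance(cluster_sizes, int) else list(cluster_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")

    ax, ay, az = phantom.cell_semiaxes_nm
    if n_inside > 0 and min(ax, ay, az) <= margin:
        raise ValueError("margin leaves no interior volume for inside emitters")
    cy, cx = phantom.center_xy_nm

    placed: list[np.ndarray] = []
    cluster_ids: list[int] = []
    inside_flags: list[bool] = []
    cluster = 0
    attempts = 0
    max_attempts = 20000 + 2000 * (n_inside + n_outside)

    def far_enough(pts: np.ndarray) -> bool:
        if min_separation_nm <= 0 or not placed:
            return True
        existing = np.concatenate(placed)
        dmin = cKDTree(existing).query(pts, k=1)[0].min()
        return dmin >= min_separation_nm

    # --- inside emitters ---------------------------------------------------
    remaining = n_inside
    while remaining > 0:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_inside} inside emitters: the phantom volume "
                f"is infeasible for the requested margin/separation"
            )
        size = min(int(rng.choice(sizes)), remaining)
        anchor = np.array(
            [
                rng.uniform(margin, az),
                rng.uniform(cy - ay, cy + ay),
                rng.uniform(cx - ax, cx + ax),
            ]
        )
        if not phantom.contains(anchor[None, :], margin)[0]:
            continue
        pts = anchor[None, :] + _cluster_offsets(size, d, rng)
        if not phantom.contains(pts, margin).all():
            continue
        if not far_enough(pts):
            continue
        placed.append(pts)
        cluster_ids.extend([cluster] * len(pts))
        inside_flags.extend([True] * len(pts))
        cluster += 1
        remaining -= len(pts)

    # --- outside emitters: resting on the outer membrane --------------------
    # Attachment sites are weighted by the upward component of the surface
    # normal: deposited particles arrive by settling from above, so the flux
    # onto a surface element scales with its vertical projection.
    remaining = n_outside
    while remaining > 0:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not place the requested outside emitters")
        p = phantom.surface_points(1, rng, which="cell", include_basal=False)[0]
        normal = np.array(
            [
                p[0] / az**2,
                (p[1] - cy) / ay**2,
                (p[2] - cx) / ax**2,
            ]
        )
        normal /= np.linalg.norm(normal)
        if rng.random() > max(normal[0], 0.0):
            continue
        p = p + normal * (phantom.membrane_thickness_nm / 2.0 + d / 2.0)
        if p[0] < 0:
            continue
        if not far_enough(p[None, :]):
            continue
        placed.append(p[None, :])
        cluster_ids.append(cluster)
        inside_flags.append(False)
        cluster += 1
        remaining -= 1

    if not placed:
        return EmitterSet.empty()
    positions = np.concatenate(placed)
    n = len(positions)
    return EmitterSet(
        positions_nm=positions,
        brightness=np.full(n, float(brightness)),
        diameter_nm=np.full(n, d),
        cluster_id=np.asarray(cluster_ids, dtype=int),
        inside=np.asarray(inside_flags, dtype=bool),
    )


def surface_emitters(
    phantom: CellPhantom,
    which: str,
    density_per_um2: float,
    brightness: float,
    rng: np.random.Generator,
) -> EmitterSet:
    """Dense label emitters on the membrane (``which="cell"``) or lamina
    (``which="nucleus"``) surface."""
    if which == "cell":
        ax, ay, az = phantom.cell_semiaxes_nm
        area_um2 = (_ellipsoid_area(ax, ay, az) / 2.0 + math.pi * ax * ay) / 1e6
    else:
        ax, ay, az = phantom.nucleus_semiaxes_nm
        area_um2 = _ellipsoid_area(ax, ay, az) / 1e6
    n = max(1, int(round(density_per_um2 * area_um2)))
    pts = phantom.surface_points(n, rng, which=which)
    return EmitterSet(
        positions_nm=pts,
        brightness=np.full(n, float(brightness)),
        diameter_nm=np.zeros(n),
        cluster_id=np.full(n, -1, dtype=int),
        inside=np.zeros(n, dtype=bool),
    )


def render_channel(
    emitters: EmitterSet,
    acq: AcquisitionConfig,
    fov_nm: tuple[float, float, float],
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    channel: str = "nanoparticle",
) -> VoxelGrid:
    """Render emitters into a voxel grid under the acquisition model.

    Expected intensity = background + sum of emitter brightness spread by a
    separable 3D Gaussian PSF (unit integral), sampled at voxel centers.  With
    ``noise=True`` the expected counts are Poisson-sampled, Gaussian read
    noise is added, and the result is clipped to [0, detector_max].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = np.array(acq.spacing_nm)
    shape = tuple(int(math.ceil(f / s)) for f, s in zip(fov_nm, spacing))
    if len(emitters):
        pos = emitters.positions_nm
        if pos.min() < -1e-9 or np.any(pos > np.asarray(fov_nm) + 1e-9):
            raise ValueError("field of view does not cover all emitters")
    expected = np.full(shape, float(acq.background), dtype=np.float64)

    sigma = np.array([acq.sigma_axial_nm, acq.sigma_lateral_nm, acq.sigma_lateral_nm])
    half = np.maximum(1, np.ceil(4.5 * sigma / spacing).astype(int))
    norm = spacing / (sigma * math.sqrt(2.0 * math.pi))

    for k in range(len(emitters)):
        p = emitters.positions_nm[k]
        b = emitters.brightness[k]
        if b == 0:
            continue
        center_idx = p / spacing - 0.5  # fractional voxel index of the emitter
        lo = np.maximum(0, np.ceil(center_idx - half).astype(int))
        hi = np.minimum(shape, np.floor(center_idx + half).astype(int) + 1)
        if np.any(lo >= hi):
            continue
        profiles = []
        for ax_ in range(3):
            coords = np.arange(lo[ax_], hi[ax_])
            x = (coords - center_idx[ax_]) * spacing[ax_]
            profiles.append(norm[ax_] * np.exp(-0.5 * (x / sigma[ax_]) ** 2))
        patch = b * profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
        expected[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += patch

    if noise:
        data = rng.poisson(expected).astype(np.float64)
        if acq.read_noise_sd > 0:
            data += rng.normal(0.0, acq.read_noise_sd, size=data.shape)
        data = np.clip(data, 0.0, acq.detector_max)
    else:
        data = np.minimum(expected, acq.detector_max)
    return VoxelGrid(data=data, spacing_nm=tuple(spacing), channel=channel,
                     meta={"mode": acq.mode, "noise": bool(noise)})


@dataclass
class GroundTruthTable:
    """Emitter records plus expected merged-object memberships.

    Two emitters belong to the same expected object when their centers are
    closer than ``separation_nm`` (transitively); this is the separation
    criterion at which an ideal detector would merge them.
    """

    table: pd.DataFrame
    separation_nm: float

    @property
    def n_inside(self) -> int:
        return int(self.table["inside"].sum())

    @property
    def n_outside(self) -> int:
        return int((~self.table["inside"]).sum())

    @property
    def n_expected_objects_inside(self) -> int:
        """Merged objects whose members are all inside the cell."""
        g = self.table.groupby("merged_object_id")["inside"]
        return int(g.all().sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def ground_truth_table(emitters: EmitterSet, separation_nm: float) -> GroundTruthTable:
    """Annotate emitters with merged-object ids at a separation criterion."""
    df = emitters.to_dataframe()
    n = len(df)
    if n == 0:
        df["merged_object_id"] = pd.Series(dtype=int)
        return GroundTruthTable(table=df, separation_nm=separation_nm)
    tree = cKDTree(emitters.positions_nm)
    pairs = tree.query_pairs(separation_nm, output_type="ndarray")
    # union-find over close pairs
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    df["merged_object_id"] = labels
    return GroundTruthTable(table=df, separation_nm=separation_nm)


def simulate_scene(
    phantom: CellPhantom,
    emitters: EmitterSet,
    acq_np: AcquisitionConfig = STED,
    acq_cell: AcquisitionConfig = CONFOCAL,
    membrane_density_per_um2: float = 80.0,
    lamina_density_per_um2: float = 80.0,
    surface_brightness: float = 3000.0,
    pad_um: float = 1.0,
    separation_nm: float | None = None,
    seed: int = 0,
    noise: bool = True,
) -> dict:
    """Render the full three-channel scene plus its ground truth.

    Returns a dict with keys ``"nanoparticle"``, ``"membrane"``, ``"lamina"``
    (VoxelGrids) and ``"ground_truth"`` (GroundTruthTable).  The separation
    criterion for expected merged objects defaults to the NP-channel lateral
    PSF FWHM.
    """
    rng = np.random.default_rng(seed)
    fov = phantom.fov_nm(pad_um * 1000.0)
    mem = surface_emitters(phantom, "cell", membrane_density_per_um2, surface_brightness, rng)
    lam = surface_emitters(phantom, "nucleus", lamina_density_per_um2, surface_brightness, rng)
    out = {
        "nanoparticle": render_channel(emitters, acq_np, fov, rng, noise=noise,
                                       channel="nanoparticle"),
        "membrane": render_channel(mem, acq_cell, fov, rng, noise=noise, channel="membrane"),
        "lamina": render_channel(lam, acq_cell, fov, rng, noise=noise, channel="lamina"),
    }
    sep = separation_nm if separation_nm is not None else acq_np.lateral_fwhm_nm
    out["ground_truth"] = ground_truth_table(emitters, sep)
    out["phantom"] = phantom
    return out
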