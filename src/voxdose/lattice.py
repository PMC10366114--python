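"""Uniform voxel lattice: point location, ray marching, phantom presets.

The geometry is the structured grid used for patient models in BNCT dose
calculation: a box of ``dims`` voxels with constant ``spacing``, each voxel
filled with exactly one material.  Voxels are half-open in every axis,
``[edge, next_edge)``; a particle exactly on a shared face belongs to the
voxel it is entering.  During transport the integer voxel indices are the
source of truth — marching never re-floors floating positions, which would
misclassify points sitting on boundaries after round-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .nuclear_data import Material, VACUUM, build_material

__all__ = [
    "OUTSIDE",
    "VoxelLattice",
    "Phantom",
    "locate_voxel",
    "distance_to_boundary",
    "ray_box_entry",
    "make_phantom",
    "write_phantom",
    "read_phantom",
]


class _Outside:
    """Sentinel: a position or step beyond the lattice (a value, not an error)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "OUTSIDE"


OUTSIDE = _Outside()


@dataclass
class VoxelLattice:
    """A uniform structured grid with one material id per voxel."""

    origin: tuple[float, float, float]  # cm, minimum corner
    spacing: tuple[float, float, float]  # cm
    material_id: np.ndarray  # int, shape dims

    def __post_init__(self) -> None:
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        self.material_id = np.ascontiguousarray(self.material_id, dtype=np.int32)
        if self.material_id.ndim != 3:
            raise ValueError("material_id must be a 3-d array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material_id.shape

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(o + n * s for o, n, s in zip(self.origin, self.dims, self.spacing))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def flat_index(self, ijk: tuple[int, int, int]) -> int:
        i, j, k = ijk
        _, ny, nz = self.dims
        return (i * ny + j) * nz + k


def locate_voxel(lattice: VoxelLattice, position) -> tuple[int, int, int] | _Outside:
    """Map a point to its voxel by per-axis floor; outside the box -> OUTSIDE."""
    ijk = []
    for x, o, s, n in zip(position, lattice.origin, lattice.spacing, lattice.dims):
        i = math.floor((x - o) / s)
        if i < 0 or i >= n:
            return OUTSIDE
        ijk.append(i)
    return tuple(ijk)


def distance_to_boundary(
    lattice: VoxelLattice,
    position,
    direction,
    voxel: tuple[int, int, int],
) -> tuple[float, tuple[int, int, int] | _Outside]:
    """Distance along ``direction`` to the current voxel's surface.

    Returns (distance cm, next voxel).  Every axis whose crossing distance
    ties the minimum within 1e-12 * min(spacing) is stepped (a corner-exact
    crossing advances all tied axes at once).  Stepping off the grid returns
    OUTSIDE.
    """
    norm = math.sqrt(sum(u * u for u in direction))
    if norm == 0.0:
        raise ValueError("direction vector must be nonzero")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"direction must be unit-norm, |u| = {norm}")
    dists = [math.inf, math.inf, math.inf]
    for ax in range(3):
        u = direction[ax]
        if u == 0.0:
            continue
        i = voxel[ax]
        o, s = lattice.origin[ax], lattice.spacing[ax]
        plane = o + (i + 1) * s if u > 0 else o + i * s
        dists[ax] = (plane - position[ax]) / u
    dmin = min(dists)
    tol = 1e-12 * min(lattice.spacing)
    nxt = list(voxel)
    for ax in range(3):
        if dists[ax] - dmin <= tol:
            nxt[ax] += 1 if direction[ax] > 0 else -1
    for ax in range(3):
        if nxt[ax] < 0 or nxt[ax] >= lattice.dims[ax]:
            return dmin, OUTSIDE
    return dmin, tuple(nxt)


def ray_box_entry(lattice: VoxelLattice, position, direction) -> float | None:
    """Distance to where a ray from outside first enters the lattice box.

    None if the ray misses the box.  A ray starting inside returns 0.
    """
    tmin, tmax = 0.0, math.inf
    for ax in range(3):
        u = direction[ax]
        lo = lattice.origin[ax]
        hi = lo + lattice.dims[ax] * lattice.spacing[ax]
        if u == 0.0:
            if not (lo <= position[ax] < hi):
                return None
            continue
        t0 = (lo - position[ax]) / u
        t1 = (hi - position[ax]) / u
        if t0 > t1:
            t0, t1 = t1, t0
        tmin = max(tmin, t0)
        tmax = min(tmax, t1)
    if tmin > tmax:
        return None
    return tmin


# ---------------------------------------------------------------------------
# phantom presets


@dataclass
class Phantom:
    """A lattice plus its material table and named region-of-interest masks."""

    name: str
    lattice: VoxelLattice
    materials: dict[int, Material]
    rois: dict[str, np.ndarray] = field(default_factory=dict)


# ICRU-like four-component soft tissue, mass fractions
TISSUE_FRACTIONS = {"H1": 0.101, "C12": 0.111, "N14": 0.026, "O16": 0.762}
BLOOD_PPM = 25.0
TUMOR_PPM = 75.0
# the clinical head-and-neck voxel pitch: 0.75 mm x 0.75 mm x 5 mm
HEAD_PITCH_CM = (0.075, 0.075, 0.5)
HEAD_DIMS = (259, 289, 34)


def _tissue_materials() -> dict[int, Material]:
    return {
        0: VACUUM,
        1: build_material(1, "tissue_blood", TISSUE_FRACTIONS, 1.0, boron10_ppm=BLOOD_PPM),
        2: build_material(2, "tumor", TISSUE_FRACTIONS, 1.0, boron10_ppm=TUMOR_PPM),
    }


def make_phantom(preset: str, scale: float = 1.0) -> Phantom:
    """Build a named phantom; ``scale`` shrinks voxel counts for tests.

    Presets:

    * ``homogeneous-slab`` — a 1-d row of 25 ppm tissue voxels (50 at
      scale 1), 1 mm pitch along x, thick transverse voxels.
    * ``cube-with-tumor`` — a tissue cube (blood, 25 ppm) with a central
      spherical tumor ROI (75 ppm) and a one-voxel air shell; 2.5 mm pitch,
      24^3 voxels at scale 1, tumor radius 15% of the cube side.
    * ``head-like-ellipsoid`` — an ellipsoidal head in air on the clinical
      grid (0.075 x 0.075 x 0.5 cm pitch, 259 x 289 x 34 voxels at scale 1)
      with an off-center tumor sphere.

    ROI masks use voxel-center membership.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    materials = _tissue_materials()
    if preset == "homogeneous-slab":
        n = max(1, round(50 * scale))
        ids = np.ones((n, 1, 1), dtype=np.int32)
        lat = VoxelLattice(origin=(0.0, 0.0, 0.0), spacing=(0.1, 10.0, 10.0), material_id=ids)
        rois = {"all": np.ones(lat.dims, dtype=bool)}
        return Phantom("homogeneous-slab", lat, materials, rois)
    if preset == "cube-with-tumor":
        n = max(6, round(24 * scale))
        pitch = 0.25
        ids = np.ones((n, n, n), dtype=np.int32)
        ids[0, :, :] = ids[-1, :, :] = 0
        ids[:, 0, :] = ids[:, -1, :] = 0
        ids[:, :, 0] = ids[:, :, -1] = 0
        side = n * pitch
        center = side / 2.0
        radius = 0.15 * side
        cx = (np.arange(n) + 0.5) * pitch
        dist2 = ((cx - center)[:, None, None] ** 2
                 + (cx - center)[None, :, None] ** 2
                 + (cx - center)[None, None, :] ** 2)
        tumor = (dist2 < radius * radius) & (ids == 1)
        ids[tumor] = 2
        lat = VoxelLattice(origin=(0.0, 0.0, 0.0), spacing=(pitch,) * 3, material_id=ids)
        rois = {"tumor": tumor, "tissue": ids == 1, "air": ids == 0}
        return Phantom("cube-with-tumor", lat, materials, rois)
    if preset == "head-like-ellipsoid":
        dims = tuple(max(1, round(d * scale)) for d in HEAD_DIMS)
        spacing = HEAD_PITCH_CM
        extent = [d * s for d, s in zip(dims, spacing)]
        centers = [
            (np.arange(d) + 0.5) * s - e / 2.0
            for d, s, e in zip(dims, spacing, extent)
        ]
        semi = [0.45 * e for e in extent]
        r2 = ((centers[0] / semi[0])[:, None, None] ** 2
              + (centers[1] / semi[1])[None, :, None] ** 2
              + (centers[2] / max(semi[2], 1e-12))[None, None, :] ** 2)
        ids = np.where(r2 < 1.0, 1, 0).astype(np.int32)
        # tumor sphere a quarter of the extent off-center along x (beam side)
        tumor_x = -0.25 * extent[0]
        tr = 0.12 * min(extent[0], extent[1])
        d2 = ((centers[0] - tumor_x)[:, None, None] ** 2
              + (centers[1][None, :, None]) ** 2
              + (centers[2][None, None, :]) ** 2)
        tumor = (d2 < tr * tr) & (ids == 1)
        ids[tumor] = 2
        lat = VoxelLattice(origin=(0.0, 0.0, 0.0), spacing=spacing, material_id=ids)
        rois = {"tumor": tumor, "brain": ids == 1, "air": ids == 0}
        return Phantom("head-like-ellipsoid", lat, materials, rois)
    raise ValueError(f"unknown phantom preset {preset!r}")


# ---------------------------------------------------------------------------
# phantom container I/O

PHANTOM_FORMAT_VERSION = "voxdose-phantom-1"


def _materials_to_json(materials: dict[int, Material]) -> str:
    return json.dumps({
        str(mid): {
            "name": m.name,
            "components": [[n, r] for n, r in m.components],
            "mass_density": m.mass_density,
            "boron10_ppm": m.boron10_ppm,
        }
        for mid, m in sorted(materials.items())
    }, sort_keys=True)


def _materials_from_json(text: str) -> dict[int, Material]:
    raw = json.loads(text)
    return {
        int(mid): Material(
            id=int(mid), name=d["name"],
            components=tuple((n, r) for n, r in d["components"]),
            mass_density=d["mass_density"], boron10_ppm=d["boron10_ppm"],
        )
        for mid, d in raw.items()
    }


def write_phantom(phantom: Phantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = PHANTOM_FORMAT_VERSION
        f.attrs["name"] = phantom.name
        g = f.create_group("lattice")
        g.create_dataset("origin", data=np.asarray(phantom.lattice.origin))
        g.create_dataset("spacing", data=np.asarray(phantom.lattice.spacing))
        g.create_dataset("dims", data=np.asarray(phantom.lattice.dims))
        g.create_dataset("material_id", data=phantom.lattice.material_id)
        f.attrs["materials"] = _materials_to_json(phantom.materials)
        r = f.create_group("roi")
        for name, mask in phantom.rois.items():
            r.create_dataset(name, data=mask.astype(np.uint8))


def read_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != PHANTOM_FORMAT_VERSION:
            raise ValueError(f"{path}: missing or unsupported phantom format version")
        g = f["lattice"]
        lat = VoxelLattice(
            origin=tuple(g["origin"][()]),
            spacing=tuple(g["spacing"][()]),
            material_id=g["material_id"][()],
        )
        materials = _materials_from_json(f.attrs["materials"])
        rois = {name: f["roi"][name][()].astype(bool) for name in f.get("roi", [])}
        return Phantom(str(f.attrs.get("name", "phantom")), lat, materials, rois)
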