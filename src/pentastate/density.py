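"""Density maps: Gaussian synthesis from coordinates, MRC I/O, comparison.

A map is a cubic-voxel 3-D grid with an origin in Å.  Synthesis places an
isotropic Gaussian of integral equal to the atom weight at every atom, with
σ = 0.225 × resolution — the width convention of the molmap-style tools
used for docking and rendering at these resolutions (overridable).  Grids
are indexed [ix, iy, iz]; the voxel centre of index i sits at
origin + i · voxel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "synthesize_map",
    "read_mrc",
    "write_mrc",
    "map_correlation",
    "invert_hand",
    "contour_for_mass",
    "SIGMA_PER_RESOLUTION",
    "PROTEIN_PACKING_DENSITY",
]

#: Gaussian σ as a fraction of the nominal resolution
SIGMA_PER_RESOLUTION = 0.225
#: protein packing density in Da/Å³ (≈ 1.35 g/cm³)
PROTEIN_PACKING_DENSITY = 0.81


@dataclass
class DensityMap:
    """3-D scalar field on a cubic grid: values, voxel size (Å) and origin (Å)."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be a 3-D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def box_center(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.voxel_size

    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    def integral(self) -> float:
        return float(self.grid.sum()) * self.voxel_volume()

    def copy(self) -> "DensityMap":
        return replace(self, grid=self.grid.copy(), origin=self.origin.copy())

    def same_grid_as(self, other: "DensityMap", rtol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.voxel_size - other.voxel_size) <= rtol * self.voxel_size)


def _as_points_weights(coords, weights):
    if hasattr(coords, "point_weights"):          # ConsensusEnsemble
        return np.asarray(coords.positions, float), np.asarray(coords.point_weights, float)
    if hasattr(coords, "positions"):              # ProtomerCoords / PentamerModel
        return np.asarray(coords.positions, float), np.asarray(coords.weights, float)
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
    return pts, w


def synthesize_map(coords, resolution: float, voxel_size: float, box_edge: float,
                   weights=None, center=None, sigma: float | None = None,
                   label: str = "") -> DensityMap:
    """Render a weighted point set as a Gaussian density map.

    ``coords`` may be an (N,3) array, a ProtomerCoords/PentamerModel, or a
    ConsensusEnsemble (whose member weights scale the atom weights).  The
    grid has ``round(box_edge/voxel_size)`` voxels per edge and is centered
    on the coordinate centroid unless ``center`` is given.  Each point
    contributes an isotropic Gaussian of integral equal to its weight with
    σ = 0.225 × resolution (or an explicit ``sigma``).
    """
    pts, w = _as_points_weights(coords, weights)
    if sigma is None:
        if resolution < 2.0 * voxel_size:
            raise ValueError(
                f"resolution {resolution} Å under-samples voxel {voxel_size} Å "
                "(need resolution >= 2×voxel)")
        sigma = SIGMA_PER_RESOLUTION * resolution
    n = int(round(box_edge / voxel_size))
    if n < 2:
        raise ValueError("box too small for the requested voxel size")
    if center is None:
        center = pts.mean(axis=0)
    center = np.asarray(center, dtype=float)
    origin = center - (n - 1) / 2.0 * voxel_size

    frac = (pts - origin) / voxel_size
    outside = np.where((frac < -0.5).any(axis=1) | (frac > n - 0.5).any(axis=1))[0]
    if outside.size:
        k = outside[0]
        raise ValueError(
            f"{outside.size} point(s) fall outside the box; first offender index {k} "
            f"at {np.round(pts[k], 3).tolist()}")

    grid = np.zeros((n, n, n))
    half = int(np.ceil(5.0 * sigma / voxel_size))
    norm = (2.0 * np.pi) ** -1.5 / sigma ** 3
    axis_coords = np.arange(n) * voxel_size
    for p, wj in zip(pts, w):
        if wj == 0.0:
            continue
        idx = np.round((p - origin) / voxel_size).astype(int)
        los = np.maximum(idx - half, 0)
        his = np.minimum(idx + half + 1, n)
        gs = []
        for ax in range(3):
            x = axis_coords[los[ax]:his[ax]] + origin[ax] - p[ax]
            gs.append(np.exp(-0.5 * (x / sigma) ** 2))
        blob = wj * norm * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        grid[los[0]:his[0], los[1]:his[1], los[2]:his[2]] += blob
    return DensityMap(grid=grid, voxel_size=voxel_size, origin=origin, label=label)


# ---------------------------------------------------------------------------
# MRC / CCP4 files
# ---------------------------------------------------------------------------

def write_mrc(density: DensityMap, path: str | Path) -> None:
    """Write a map in MRC/CCP4 format (float32; origin in the header ORIGIN fields)."""
    nx, ny, nz = density.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * density.voxel_size, ny * density.voxel_size,
                                   nz * density.voxel_size, 90, 90, 90))
    np.asarray(g)[...] = density.grid.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for i, v in enumerate(density.origin):
        m.set_header_float(50 + i, float(v))
    if density.label:
        m.set_header_str(57, density.label[:80])
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; anisotropic-voxel files are rejected."""
    m = gemmi.read_ccp4_map(str(path))
    sx, sy, sz = m.grid.spacing
    mean = (sx + sy + sz) / 3.0
    if max(abs(sx - mean), abs(sy - mean), abs(sz - mean)) > 1e-4 * mean:
        raise ValueError(
            f"{path}: anisotropic voxels {np.round((sx, sy, sz), 4)} not supported "
            "(this pipeline assumes cubic voxels)")
    origin = np.array([m.header_float(50 + i) for i in range(3)])
    return DensityMap(grid=np.array(m.grid, copy=True).astype(np.float32),
                      voxel_size=float(mean), origin=origin, label="")


# ---------------------------------------------------------------------------
# Comparison and simple transforms
# ---------------------------------------------------------------------------

def map_correlation(a: DensityMap, b: DensityMap, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two maps over all voxels (or a boolean mask)."""
    if not a.same_grid_as(b):
        raise ValueError(f"grid mismatch: {a.shape}@{a.voxel_size} vs {b.shape}@{b.voxel_size}")
    x = a.grid.ravel().astype(float)
    y = b.grid.ravel().astype(float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        x, y = x[m], y[m]
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance map: correlation undefined")
    return float(x @ y / (nx * ny))


def invert_hand(density: DensityMap) -> DensityMap:
    """Mirror the map through the plane z = box centre (a single-axis flip).

    This preserves the pore-axis frame; applying it twice returns the
    original map bit-exactly.
    """
    return replace(density, grid=density.grid[:, :, ::-1].copy(),
                   origin=density.origin.copy())


def contour_for_mass(density: DensityMap, mass_kda: float,
                     packing_density: float = PROTEIN_PACKING_DENSITY) -> float:
    """Contour threshold enclosing the volume of a given protein mass.

    The target volume is mass / packing_density (0.81 Da/Å³ ≈ 1.35 g/cm³);
    the returned level is the voxel value whose superlevel set best matches
    that volume.  A vanishing mass returns the map maximum.
    """
    if mass_kda < 0:
        raise ValueError("mass must be >= 0")
    target_volume = mass_kda * 1000.0 / packing_density
    box_volume = density.grid.size * density.voxel_volume()
    if target_volume > box_volume:
        raise ValueError(f"target volume {target_volume:.0f} Å³ exceeds the box ({box_volume:.0f} Å³)")
    n_target = target_volume / density.voxel_volume()
    flat = np.sort(density.grid.ravel())[::-1]
    k = int(round(n_target))
    if k <= 0:
        return float(flat[0])
    return float(flat[min(k, flat.size) - 1])
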