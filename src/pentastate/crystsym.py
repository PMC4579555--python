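"""Crystallographic symmetry diagnostics on desk-scale data.

Two classic diagnostics for the quaternary structure of a crystallized
oligomer:

* the native Patterson function — a Fourier synthesis with coefficients
  |F|² and zero phases; a large off-origin peak reveals translational
  non-crystallographic symmetry (two copies in the asymmetric unit related
  by a pure translation);
* a rotation function, evaluated here in real space as the Pearson
  self-correlation of a density map with a rotated copy of itself,
  parameterized by polar angles (ω, φ) and rotation angle κ.  A peak at
  κ = 360/n flags a Cₙ symmetry axis.  (A reciprocal-space Patterson
  overlap would serve the same purpose; the real-space form is the simplest
  faithful diagnostic for maps and needs no phase bookkeeping.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import gemmi
import numpy as np
from scipy import ndimage

from ._geometry import polar_axis, rotation_matrix
from .density import DensityMap

__all__ = [
    "ReflectionSet",
    "PattersonPeak",
    "RotationPeak",
    "filter_reflections",
    "native_patterson",
    "find_patterson_peaks",
    "rotational_correlation",
    "self_rotation_scan",
]


@dataclass
class ReflectionSet:
    """Integrated intensities I(hkl) with sigmas and the unit cell.

    ``cell`` is (a, b, c, α, β, γ) in Å and degrees; the b-unique convention
    is used for monoclinic cells, but any triclinic cell is handled through
    the standard fractional/orthogonal matrices.
    """

    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None
    cell: tuple[float, float, float, float, float, float]

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape[0] != self.hkl.shape[0]:
            raise ValueError("hkl and intensity lengths differ")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.intensity.shape:
                raise ValueError("sigma length differs from intensity")
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell edges must be > 0")
        if not all(0 < x < 180 for x in (al, be, ga)):
            raise ValueError("cell angles must lie in (0, 180)")

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def d_spacings(self) -> np.ndarray:
        cell = self.gemmi_cell
        inv_d2 = np.array([cell.calculate_1_d2(h) for h in self.hkl.tolist()])
        return 1.0 / np.sqrt(inv_d2)

    @classmethod
    def from_csv(cls, path, cell) -> "ReflectionSet":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        sigma = data[:, 4] if data.shape[1] > 4 else None
        return cls(hkl=data[:, :3].astype(int), intensity=data[:, 3], sigma=sigma,
                   cell=tuple(cell))


def filter_reflections(rs: ReflectionSet, d_min: float | None = None,
                       min_f_over_sigf: float | None = None) -> ReflectionSet:
    """Resolution / significance filters (F = sqrt(max(I,0)), σF ≈ σI / 2F)."""
    keep = np.ones(len(rs), dtype=bool)
    if d_min is not None:
        keep &= rs.d_spacings() >= d_min
    if min_f_over_sigf is not None and rs.sigma is not None:
        F = np.sqrt(np.clip(rs.intensity, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            sigF = np.where(F > 0, rs.sigma / (2.0 * F), np.inf)
        keep &= F / sigF >= min_f_over_sigf
    if not keep.any():
        raise ValueError("no reflections survive the filters")
    return ReflectionSet(hkl=rs.hkl[keep], intensity=rs.intensity[keep],
                         sigma=None if rs.sigma is None else rs.sigma[keep], cell=rs.cell)


# ---------------------------------------------------------------------------
# Native Patterson
# ---------------------------------------------------------------------------

def _patterson_grid_size(extent: float, spacing: float, max_index: int) -> int:
    n = int(np.ceil(extent / spacing))
    n = max(n, 2 * max_index + 2, 8)
    return n + (n % 2)


def native_patterson(reflections: ReflectionSet, grid_spacing: float = 3.0) -> DensityMap:
    """Patterson synthesis P(u,v,w) on a fractional grid.

    Coefficients are |F|² = max(I, 0) with zero phases; both Friedel mates
    are filled so the synthesis is real and centrosymmetric, with its global
    maximum at the origin.  The returned :class:`DensityMap` grid is indexed
    fractionally (index i along an axis of n voxels ↔ coordinate i/n);
    ``voxel_size`` records the nominal Å spacing for file output.
    """
    if len(reflections) < 10:
        raise ValueError("need at least 10 reflections for a Patterson synthesis")
    hkl = reflections.hkl
    f2 = np.clip(reflections.intensity, 0.0, None)
    a, b, c = reflections.cell[:3]
    hmax = np.abs(hkl).max(axis=0)
    dims = tuple(_patterson_grid_size(e, grid_spacing, m) for e, m in zip((a, b, c), hmax))

    coeff = np.zeros(dims, dtype=complex)
    idx1 = tuple((hkl % dims).T)
    idx2 = tuple((-hkl % dims).T)
    np.add.at(coeff, idx1, f2)
    np.add.at(coeff, idx2, f2)
    p = np.fft.ifftn(coeff).real * np.prod(dims)
    return DensityMap(grid=p, voxel_size=float(grid_spacing), origin=np.zeros(3),
                      label=f"patterson cell={reflections.cell}")


@dataclass(frozen=True)
class PattersonPeak:
    """Off-origin Patterson peak in fractional coordinates."""

    uvw: tuple[float, float, float]
    relative_height: float

    def __post_init__(self):
        if not 0.0 <= self.relative_height <= 1.0 + 1e-9:
            raise ValueError("relative height must lie in [0, 1]")


def _quadratic_refine(values: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """Sub-voxel peak position by per-axis parabola through the 3 neighbours."""
    out = []
    for ax, i in enumerate(idx):
        n = values.shape[ax]
        sl = list(idx)
        sl[ax] = (i - 1) % n
        y0 = values[tuple(sl)]
        y1 = values[idx]
        sl[ax] = (i + 1) % n
        y2 = values[tuple(sl)]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        out.append(i + np.clip(shift, -0.5, 0.5))
    return np.array(out)


def find_patterson_peaks(patterson: DensityMap, min_relative_height: float = 0.3,
                         origin_exclusion: int = 1) -> list[PattersonPeak]:
    """Local maxima of a fractional Patterson map, as fractions of the origin peak.

    The origin peak (and voxels within ``origin_exclusion`` of it, under
    periodic wrapping) is excluded; peaks are refined by quadratic
    interpolation and returned sorted by decreasing height.
    """
    p = patterson.grid
    origin_value = p[0, 0, 0]
    if origin_value <= 0:
        raise ValueError("origin peak is not positive; not a Patterson map?")
    local_max = p >= ndimage.maximum_filter(p, size=3, mode="wrap")
    dims = p.shape
    idxs = np.argwhere(local_max)
    peaks = []
    for idx in idxs:
        wrapped = np.minimum(idx, np.array(dims) - idx)
        if np.all(wrapped <= origin_exclusion):
            continue
        rel = p[tuple(idx)] / origin_value
        if rel >= min_relative_height:
            refined = _quadratic_refine(p, tuple(idx))
            uvw = tuple(float(x) for x in (refined / dims) % 1.0)
            peaks.append(PattersonPeak(uvw=uvw, relative_height=float(min(rel, 1.0))))
    peaks.sort(key=lambda pk: pk.relative_height, reverse=True)
    return peaks


# ---------------------------------------------------------------------------
# Rotation function (real space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotationPeak:
    """A rotation-function peak in polar angles (ω, φ, κ) with its correlation."""

    omega: float
    phi: float
    kappa: float
    correlation: float

    def __post_init__(self):
        if not 0 <= self.omega <= 90:
            raise ValueError("omega must lie in [0, 90] degrees")
        if not -180 < self.phi <= 180:
            raise ValueError("phi must lie in (-180, 180] degrees")
        if not 0 < self.kappa <= 180:
            raise ValueError("kappa must lie in (0, 180] degrees")


def _rotate_grid(grid: np.ndarray, axis: np.ndarray, kappa: float) -> np.ndarray:
    center = (np.array(grid.shape) - 1) / 2.0
    R = rotation_matrix(axis, kappa)
    # affine_transform maps output coords through the matrix: use inverse
    Rinv = R.T
    offset = center - Rinv @ center
    return ndimage.affine_transform(grid, Rinv, offset=offset, order=1,
                                    mode="constant", cval=np.nan, prefilter=False)


def rotational_correlation(density: DensityMap, omega: float, phi: float,
                           kappa: float, radius: float) -> float:
    """Self-correlation of a map under rotation about a polar axis through the box centre.

    Only voxels within ``radius`` (Å) of the centre — and whose rotated
    source voxel is inside the grid — enter the Pearson correlation.
    """
    half_edge = min(density.shape) * density.voxel_size / 2.0
    if radius > half_edge + 1e-9:
        raise ValueError(f"integration radius {radius} Å exceeds half box edge {half_edge:.1f} Å")
    axis = polar_axis(omega, phi)
    rotated = _rotate_grid(density.grid.astype(float), axis, kappa)

    center = (np.array(density.shape) - 1) / 2.0
    coords = np.meshgrid(*[np.arange(n) for n in density.shape], indexing="ij")
    r2 = sum((c - cc) ** 2 for c, cc in zip(coords, center)) * density.voxel_size ** 2
    mask = (r2 <= radius ** 2) & np.isfinite(rotated)
    x = density.grid[mask].astype(float)
    y = rotated[mask]
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero variance inside the integration sphere")
    return float(x @ y / (nx * ny))


def self_rotation_scan(density: DensityMap, kappa_list: Sequence[float],
                       omega_step: float = 15.0, phi_step: float = 30.0,
                       radius: float | None = None) -> list[RotationPeak]:
    """Grid scan of the rotation function; returns local maxima per κ section.

    ω runs over [0, 90] and φ over (−180, 180] at the given steps (ω = 0 is
    evaluated once since φ is then degenerate).  Peaks are grid points not
    exceeded by any (ω, φ) neighbour on their κ section, sorted by
    decreasing correlation.
    """
    if radius is None:
        radius = min(density.shape) * density.voxel_size / 2.0
    omegas = np.arange(0.0, 90.0 + 1e-9, omega_step)
    phis = np.arange(-180.0 + phi_step, 180.0 + 1e-9, phi_step)
    peaks: list[RotationPeak] = []
    for kappa in kappa_list:
        table = np.full((len(omegas), len(phis)), np.nan)
        for i, om in enumerate(omegas):
            if om == 0.0:
                c = rotational_correlation(density, 0.0, 0.0, kappa, radius)
                table[i, :] = c
                continue
            for j, ph in enumerate(phis):
                table[i, j] = rotational_correlation(density, om, ph, kappa, radius)
        for i in range(len(omegas)):
            for j in range(len(phis)):
                val = table[i, j]
                neighbours = []
                for di in (-1, 0, 1):
                    ii = i + di
                    if ii < 0 or ii >= len(omegas):
                        continue
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        neighbours.append(table[ii, (j + dj) % len(phis)])
                if val >= max(neighbours):
                    peaks.append(RotationPeak(omega=float(omegas[i]),
                                              phi=float(phis[j]),
                                              kappa=float(kappa),
                                              correlation=float(val)))
        # ω = 0 row duplicates across φ; keep a single representative
    uniq: dict[tuple[float, float, float], RotationPeak] = {}
    for pk in peaks:
        key = (pk.kappa, pk.omega, pk.phi if pk.omega > 0 else 0.0)
        if key not in uniq or pk.correlation > uniq[key].correlation:
            uniq[key] = pk
    out = sorted(uniq.values(), key=lambda p: p.correlation, reverse=True)
    return out
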