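"""Per-position taut/relaxed population fitting against a target map.

The asymmetric channel is modelled as five protomer positions, each a
two-state mixture: position k carries a fraction f_k of the taut
conformation and 1 − f_k of the relaxed one (the pair sums to one — five
partition variables in total, no global scale: map correlation is invariant
to affine intensity transformations).  The composite density

    M(f) = Σ_k [ f_k · t_k + (1 − f_k) · r_k ]

is compared to the target by Pearson correlation over voxels, and the
fractions live on a fixed search grid (default step 0.1).  The optimizer is
coordinate ascent with seeded random restarts; the 11⁵-point exhaustive
search is cheap enough to serve both as a fallback and as an oracle in
tests.

:class:`AbundanceModel` / :class:`AbundanceResult` follow the familiar
model-object pattern: build the model from data, call ``fit``, read the
estimates off the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density import DensityMap, map_correlation, synthesize_map
from .states import PentamerModel, StateString, TiltSpec, build_state_model, canonical_form, tilt_protomer
from .structures import PoreAxis, ProtomerCoords, symmetrize
from ._geometry import rotate_about_line

__all__ = [
    "MixtureWeights",
    "BasisMaps",
    "AbundanceModel",
    "AbundanceResult",
    "per_position_basis_maps",
    "fit_fractional_abundance",
    "composite_from_states",
]


@dataclass(frozen=True)
class MixtureWeights:
    """Per-position taut fractions; the relaxed fractions are the complement."""

    fraction_t: tuple[float, ...]

    def __post_init__(self):
        f = tuple(float(x) for x in self.fraction_t)
        if len(f) != 5:
            raise ValueError("need one fraction per protomer position (5)")
        if any(not 0.0 <= x <= 1.0 for x in f):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "fraction_t", f)

    @property
    def fraction_r(self) -> tuple[float, ...]:
        return tuple(1.0 - x for x in self.fraction_t)

    def canonical_rotation(self) -> "MixtureWeights":
        """Lexicographically smallest cyclic rotation (frame-ambiguity report)."""
        rots = [self.fraction_t[k:] + self.fraction_t[:k] for k in range(5)]
        return MixtureWeights(min(rots))


@dataclass
class BasisMaps:
    """The ten per-position state maps: t and r for each protomer position."""

    t: list[DensityMap]
    r: list[DensityMap]

    def __post_init__(self):
        if len(self.t) != 5 or len(self.r) != 5:
            raise ValueError("need 5 taut and 5 relaxed basis maps")
        ref = self.t[0]
        for m in self.t + self.r:
            if not m.same_grid_as(ref):
                raise ValueError("basis maps must share one grid")

    def composite(self, weights: MixtureWeights | Sequence[float]) -> DensityMap:
        f = weights.fraction_t if isinstance(weights, MixtureWeights) else tuple(weights)
        grid = sum(fk * tk.grid + (1 - fk) * rk.grid
                   for fk, tk, rk in zip(f, self.t, self.r))
        out = self.t[0].copy()
        out.grid = grid
        out.label = "composite"
        return out


def per_position_basis_maps(protomer: ProtomerCoords, axis: PoreAxis, tilts: TiltSpec,
                            resolution: float, voxel_size: float, box_edge: float,
                            center=None) -> BasisMaps:
    """Density of the single tilted protomer at each of the five positions.

    Basis map (k, state) is the protomer tilted per the state, rotated by
    72·k° about the pore axis and rendered on a common grid (centred on the
    untilted symmetric pentamer unless ``center`` is given).  By linearity
    of Gaussian synthesis, any per-position selection sums to the matching
    full-pentamer map.
    """
    if center is None:
        center = symmetrize(protomer, axis).positions.mean(axis=0)
    maps = {}
    for symbol, angle in (("t", tilts.angle_t), ("r", tilts.angle_r)):
        tilted = tilt_protomer(
            ProtomerCoords(protomer.atoms, tilts.pivot_residue, protomer.motif_residues),
            axis, angle)
        for k in range(5):
            pos = rotate_about_line(tilted.positions, axis.point, axis.direction, 72.0 * k)
            maps[(k, symbol)] = synthesize_map(
                pos, resolution=resolution, voxel_size=voxel_size, box_edge=box_edge,
                weights=tilted.weights, center=center, label=f"basis {symbol}{k}")
    return BasisMaps(t=[maps[(k, "t")] for k in range(5)],
                     r=[maps[(k, "r")] for k in range(5)])


# ---------------------------------------------------------------------------
# The fit
# ---------------------------------------------------------------------------

@dataclass
class AbundanceResult:
    """Fitted per-position fractions, the achieved correlation and the trace."""

    weights: MixtureWeights
    correlation: float
    trace: list[tuple[tuple[float, ...], float]]
    method: str
    grid_step: float

    @property
    def fraction_t(self) -> tuple[float, ...]:
        return self.weights.fraction_t

    @property
    def fraction_r(self) -> tuple[float, ...]:
        return self.weights.fraction_r

    def summary(self) -> str:
        lines = [
            "Per-position t/r abundance fit",
            "==============================",
            f"method:      {self.method} (grid step {self.grid_step})",
            f"correlation: {self.correlation:.6f}",
            "",
            "position   fraction_t   fraction_r",
        ]
        for k, (ft, fr) in enumerate(zip(self.fraction_t, self.fraction_r)):
            lines.append(f"   {'ABCDE'[k]}          {ft:4.2f}         {fr:4.2f}")
        canon = self.weights.canonical_rotation().fraction_t
        lines += ["", f"canonical cyclic rotation of fraction_t: {canon}"]
        return "\n".join(lines)


class AbundanceModel:
    """Two-state mixture model of a pentamer density, position by position.

    Parameters
    ----------
    target : DensityMap
        The map to be explained.
    basis : BasisMaps
        The ten single-protomer state maps on the same grid.
    """

    def __init__(self, target: DensityMap, basis: BasisMaps):
        if not target.same_grid_as(basis.t[0]):
            raise ValueError("target and basis maps must share one grid")
        self.target = target
        self.basis = basis
        self._prepare()

    def _prepare(self):
        N = self.target.grid.size
        T = self.target.grid.ravel().astype(float)
        Tc = T - T.mean()
        tt = float(Tc @ Tc)
        if tt == 0:
            raise ValueError("zero-variance target map")
        base = sum(m.grid for m in self.basis.r).ravel().astype(float)
        D = np.stack([(t.grid - r.grid).ravel().astype(float)
                      for t, r in zip(self.basis.t, self.basis.r)])
        base_c = base - base.mean()
        Dc = D - D.mean(axis=1, keepdims=True)
        self._tt = tt
        self._bT = float(base_c @ Tc)
        self._dT = Dc @ Tc
        self._bb = float(base_c @ base_c)
        self._bd = Dc @ base_c
        self._DD = Dc @ Dc.T

    def _corr(self, F: np.ndarray) -> np.ndarray:
        """Correlation with the target for fraction vectors F (…,5)."""
        F = np.atleast_2d(F)
        num = self._bT + F @ self._dT
        var = self._bb + 2.0 * (F @ self._bd) + np.einsum("ci,ij,cj->c", F, self._DD, F)
        var = np.clip(var, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = num / np.sqrt(var * self._tt)
        return np.where(var > 0, c, -np.inf)

    def correlation(self, weights: MixtureWeights | Sequence[float]) -> float:
        f = weights.fraction_t if isinstance(weights, MixtureWeights) else tuple(weights)
        return float(self._corr(np.array(f))[0])

    # -- optimizers ------------------------------------------------------
    def _grid(self, step: float) -> np.ndarray:
        n = int(round(1.0 / step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 12)

    def fit_exhaustive(self, grid_step: float = 0.1) -> AbundanceResult:
        """Enumerate every grid combination (11⁵ at step 0.1) and take the best."""
        g = self._grid(grid_step)
        combos = np.array(list(itertools.product(g, repeat=5)))
        corr = self._corr(combos)
        best = np.lexsort((combos.sum(axis=1), -corr))[0]  # ties -> larger fraction_r
        w = MixtureWeights(tuple(combos[best]))
        c = float(corr[best])
        return AbundanceResult(weights=w, correlation=c, trace=[(w.fraction_t, c)],
                               method="exhaustive", grid_step=grid_step)

    def fit(self, grid_step: float = 0.1, method: str = "ascent",
            n_restarts: int = 4, seed: int = 0, max_sweeps: int = 100) -> AbundanceResult:
        """Fit the fractions by coordinate ascent (or exhaustively).

        Coordinate ascent starts from f = (0.5, …) plus ``n_restarts``
        seeded random grid points; within each sweep every position is
        optimized over the full grid holding the others fixed.  Ties break
        toward the larger relaxed fraction.
        """
        if method == "exhaustive":
            return self.fit_exhaustive(grid_step)
        if method != "ascent":
            raise ValueError(f"unknown method {method!r}")
        g = self._grid(grid_step)
        rng = np.random.default_rng(seed)
        starts = [np.full(5, g[np.argmin(np.abs(g - 0.5))])]
        for _ in range(n_restarts):
            starts.append(rng.choice(g, size=5))

        best_f, best_c, best_trace = None, -np.inf, []
        for f0 in starts:
            f = f0.copy()
            trace = [(tuple(f), float(self._corr(f)[0]))]
            for _ in range(max_sweeps):
                changed = False
                for k in range(5):
                    cand = np.tile(f, (g.size, 1))
                    cand[:, k] = g
                    corr = self._corr(cand)
                    pick = np.lexsort((g, -corr))[0]  # ties -> smaller f_t
                    if cand[pick, k] != f[k] and corr[pick] > trace[-1][1] + 1e-15:
                        f = cand[pick]
                        changed = True
                trace.append((tuple(f), float(self._corr(f)[0])))
                if not changed:
                    break
            if trace[-1][1] > best_c or (trace[-1][1] == best_c and best_f is not None
                                         and f.sum() < np.sum(best_f)):
                best_f, best_c, best_trace = f, trace[-1][1], trace
        return AbundanceResult(weights=MixtureWeights(tuple(best_f)), correlation=float(best_c),
                               trace=best_trace, method="ascent", grid_step=grid_step)


def fit_fractional_abundance(target: DensityMap, basis: BasisMaps, grid_step: float = 0.1,
                             method: str = "ascent", seed: int = 0) -> AbundanceResult:
    """Functional wrapper: fit per-position t/r fractions to a target map."""
    return AbundanceModel(target, basis).fit(grid_step=grid_step, method=method, seed=seed)


def composite_from_states(models: Sequence[PentamerModel], weights: Sequence[float],
                          resolution: float, voxel_size: float, box_edge: float,
                          center=None) -> DensityMap:
    """Weighted sum of the state models' maps (weights normalized to one)."""
    w = np.asarray(weights, dtype=float)
    if len(models) != w.size:
        raise ValueError("need one weight per model")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    w = w / w.sum()
    if center is None:
        center = np.vstack([m.positions for m in models]).mean(axis=0)
    out = None
    for m, wk in zip(models, w):
        dm = synthesize_map(m, resolution=resolution, voxel_size=voxel_size,
                            box_edge=box_edge, center=center)
        if out is None:
            out = dm
            out.grid = wk * out.grid
        else:
            out.grid = out.grid + wk * dm.grid
    out.label = "composite " + "+".join(str(m.state) for m in models)
    return out
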