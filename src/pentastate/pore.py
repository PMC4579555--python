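"""Pore-axis geometry: motif radii, relative admittance, pore-radius profile.

The channel's openness proxy is geometric: the mean perpendicular distance
of the magnesium-recognition motif marker (Gly 278 C-alpha of the YGMNF
motif by default) from the pore axis.  Dividing a state model's mean motif
radius by that of the reference (the docked, untilted crystal conformation)
gives the *relative admittance* of the state.

The pore-radius profile is a simplified sphere probe: at each axial station
the radius is the distance from the axis point to the nearest atom surface
(centre distance minus van der Waals radius, floored at zero).  The probe
stays on the axis — no off-axis optimization — so the profile is a lower
bound on the true maximal-probe radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._geometry import distance_to_line, foot_on_line
from .states import PentamerModel
from .structures import ProtomerCoords

__all__ = [
    "VDW_RADII",
    "vdw_radius_of",
    "AdmittanceReport",
    "PoreProfile",
    "motif_radius",
    "relative_admittance",
    "tmvtt_disposition",
    "disposition_spread",
    "pore_profile",
    "min_pore_diameter_between",
]

#: Bondi-style van der Waals radii (Å) by element symbol
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "CA": 2.31, "MN": 2.00, "CO": 2.00, "SE": 1.90,
}


def vdw_radius_of(element: str, table: Mapping[str, float] | None = None) -> float | None:
    """Van der Waals radius for an element symbol, or None when unknown."""
    t = VDW_RADII if table is None else table
    return t.get(element.strip().upper())


def motif_radius(model: PentamerModel, residue: int = 278) -> float:
    """Mean perpendicular distance of a residue's C-alpha from the pore axis."""
    radii = []
    for prot in model.protomers:
        try:
            atom = prot.atom(residue, "CA")
        except KeyError:
            raise KeyError(f"chain {prot.chain_id}: residue {residue} has no C-alpha") from None
        radii.append(distance_to_line(atom.position, model.axis.point, model.axis.direction)[0])
    return float(np.mean(radii))


@dataclass(frozen=True)
class AdmittanceReport:
    """Mean motif radii per state, normalized to the reference conformation."""

    per_state_mean_radius: dict[str, float]
    reference_radius: float
    residue: int

    @property
    def relative_radius(self) -> dict[str, float]:
        return {s: r / self.reference_radius for s, r in self.per_state_mean_radius.items()}

    def summary(self) -> str:
        lines = [
            f"Relative admittance (motif residue {self.residue})",
            f"reference radius: {self.reference_radius:.2f} Å",
            "",
            "state    mean radius (Å)   relative",
        ]
        for s, r in self.per_state_mean_radius.items():
            lines.append(f"{s:8s}   {r:10.2f}      {r / self.reference_radius:6.2f}")
        return "\n".join(lines)


def relative_admittance(states: Sequence[PentamerModel], reference: PentamerModel,
                        residue: int = 278) -> AdmittanceReport:
    """Per-state mean motif radius divided by the reference conformation's.

    ``reference`` is normally the untilted docked crystal conformation
    symmetrized about the fitted pore axis.
    """
    ref_radius = motif_radius(reference, residue)
    if ref_radius == 0:
        raise ValueError("reference motif radius is zero: relative admittance undefined")
    per_state = {str(m.state): motif_radius(m, residue) for m in states}
    return AdmittanceReport(per_state_mean_radius=per_state,
                            reference_radius=ref_radius, residue=residue)


def tmvtt_disposition(model: PentamerModel, residue_range: Sequence[int]) -> np.ndarray:
    """Per-chain mean axial radius of the TMVTT-window residues (Å, length 5)."""
    residues = list(residue_range)
    if not residues:
        raise ValueError("residue range must be non-empty")
    radii = []
    for prot in model.protomers:
        pos = np.array([prot.atom(r, "CA").position for r in residues])
        radii.append(distance_to_line(pos, model.axis.point, model.axis.direction).mean())
    return np.array(radii)


def disposition_spread(models: Sequence[PentamerModel], residue_range: Sequence[int]
                       ) -> tuple[dict[str, float], float]:
    """Per-state mean TMVTT radius and its spread (max − min) across states."""
    per_state = {str(m.state): float(tmvtt_disposition(m, residue_range).mean())
                 for m in models}
    vals = list(per_state.values())
    return per_state, float(max(vals) - min(vals))


@dataclass
class PoreProfile:
    """Sphere-probe pore radius along the axis; diameter is twice the radius."""

    z: np.ndarray
    radius: np.ndarray
    capped: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.capped = np.asarray(self.capped, dtype=bool)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("axial stations must be strictly increasing")
        if np.any(self.radius < 0):
            raise ValueError("pore radius cannot be negative")

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.radius

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"z": self.z, "radius": self.radius,
                      "diameter": self.diameter, "capped": self.capped}
                     ).to_csv(path, index=False)


def _atom_arrays(model: PentamerModel, vdw_table: Mapping[str, float] | None):
    pos, rad = [], []
    names = set()
    for a in model.atoms():
        names.add(a.name)
        r = a.vdw_radius
        if r is None:
            r = vdw_radius_of(a.element or a.name[:1], vdw_table)
        if r is None:
            continue
        pos.append(a.position)
        rad.append(r)
    if not pos:
        raise ValueError("no atoms carry van der Waals radii; cannot profile the pore")
    if names == {"CA"} and all(a.vdw_radius is None for a in model.atoms()):
        raise ValueError("C-alpha-only model: pore profiling needs full atoms (or explicit radii)")
    return np.array(pos), np.array(rad)


def pore_profile(model: PentamerModel, z_range: tuple[float, float], z_step: float = 1.0,
                 vdw_table: Mapping[str, float] | None = None,
                 max_radius: float = 50.0) -> PoreProfile:
    """Pore radius at axial stations between z_range[0] and z_range[1].

    ``z`` is the signed coordinate along the pore axis measured from
    ``model.axis.point``.  At each station the probe radius is
    min over atoms of (distance to atom centre − vdW radius), floored at
    zero; stations with no atom surface within ``max_radius`` are capped at
    that value and flagged.
    """
    pos, rad = _atom_arrays(model, vdw_table)
    d = model.axis.direction
    p0 = model.axis.point
    z0, z1 = z_range
    if not z1 > z0:
        raise ValueError("z_range must be increasing")
    z = np.arange(z0, z1 + 0.5 * z_step, z_step)
    radius = np.empty_like(z)
    capped = np.zeros(z.size, dtype=bool)
    for i, zi in enumerate(z):
        center = p0 + zi * d
        gaps = np.linalg.norm(pos - center, axis=1) - rad
        r = float(gaps.min())
        if r > max_radius:
            radius[i] = max_radius
            capped[i] = True
        else:
            radius[i] = max(r, 0.0)
    return PoreProfile(z=z, radius=radius, capped=capped)


def min_pore_diameter_between(model: PentamerModel, residue_a: int, residues_b: Sequence[int],
                              z_step: float = 0.5,
                              vdw_table: Mapping[str, float] | None = None) -> float:
    """Minimum sphere-probe pore diameter between two motif planes.

    The planes are the mean axial coordinates of residue ``residue_a`` and
    of the ``residues_b`` window (C-alphas, averaged over chains).
    """
    d, p0 = model.axis.direction, model.axis.point

    def axial(residues):
        zs = []
        for prot in model.protomers:
            for r in residues:
                hits = [a for a in prot.atoms if a.residue_number == r]
                if not hits:
                    raise KeyError(f"chain {prot.chain_id}: no residue {r}")
                ca = [a for a in hits if a.name == "CA"]
                for a in ca or hits:
                    zs.append(float((a.position - p0) @ d))
        return float(np.mean(zs))

    za, zb = axial([residue_a]), axial(list(residues_b))
    lo, hi = sorted((za, zb))
    if hi - lo < z_step:
        hi = lo + z_step
    profile = pore_profile(model, (lo, hi), z_step=z_step, vdw_table=vdw_table)
    return float(profile.diameter.min())
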