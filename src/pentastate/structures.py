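"""Coordinate handling for homo-oligomeric channels.

Reads and writes PDB-format coordinates, groups atoms into protomers (one
per chain), finds the rotational-symmetry (pore) axis of a homo-oligomer by
least squares, and replicates a single protomer into a Cₙ-symmetric
assembly.

Conventions: coordinates are Å in the right-handed frame of the input file
(no re-centering on read); angles at public interfaces are degrees.  The
pore-axis direction points from the trans-membrane end of the molecule
toward the cytoplasmic end, resolved from the chain termini (the last
residues of a CorA chain are membrane-embedded, the first cytoplasmic).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.optimize import least_squares

from ._geometry import distance_to_line, rotate_about_line, unit

__all__ = [
    "AtomRecord",
    "ProtomerCoords",
    "PoreAxis",
    "AxisFit",
    "PdbParseError",
    "read_coordinates",
    "write_pdb",
    "fit_pore_axis",
    "symmetrize",
]

#: default pivot residue: narrowest point of the CorA crystal structure
DEFAULT_PIVOT_RESIDUE = 250
#: Gly C-alpha marking the YGMNF magnesium-recognition motif
DEFAULT_MOTIF_RESIDUE = 278
#: threonine-rich TMVTT stretch, close to the pivot (configurable)
DEFAULT_TMVTT_RANGE = tuple(range(255, 260))


class PdbParseError(ValueError):
    """Raised for malformed or unusable PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, residue number, chain, position and scattering weight."""

    name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    weight: float = 1.0
    vdw_radius: float | None = None
    element: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name} {self.residue_number}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.weight < 0:
            raise ValueError("atom weight must be >= 0")
        if self.vdw_radius is not None and not self.vdw_radius > 0:
            raise ValueError("vdw_radius must be > 0 when present")

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return dataclasses.replace(self, position=np.asarray(position, dtype=float))


@dataclass
class ProtomerCoords:
    """Ordered atoms of one subunit plus its pivot and motif annotations."""

    atoms: list[AtomRecord]
    pivot_residue: int = DEFAULT_PIVOT_RESIDUE
    motif_residues: tuple[int, ...] = (DEFAULT_MOTIF_RESIDUE,) + DEFAULT_TMVTT_RANGE

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a protomer needs at least one atom")
        resnums = [a.residue_number for a in self.atoms]
        if any(b < a for a, b in zip(resnums, resnums[1:])):
            raise ValueError("residue numbers must be non-decreasing within a chain")

    # -- basic accessors -------------------------------------------------
    @property
    def chain_id(self) -> str:
        return self.atoms[0].chain_id

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.weight for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, residue_number: int, name: str = "CA") -> AtomRecord:
        for a in self.atoms:
            if a.residue_number == residue_number and a.name == name:
                return a
        raise KeyError(f"chain {self.chain_id}: no atom {name!r} in residue {residue_number}")

    def ca_only(self) -> "ProtomerCoords":
        kept = [a for a in self.atoms if a.name == "CA"]
        if not kept:
            raise ValueError(f"chain {self.chain_id}: no C-alpha atoms")
        return ProtomerCoords(kept, self.pivot_residue, self.motif_residues)

    # -- rigid-body helpers ----------------------------------------------
    def with_positions(self, positions: np.ndarray, chain_id: str | None = None) -> "ProtomerCoords":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("position array shape does not match the atom list")
        atoms = []
        for a, p in zip(self.atoms, positions):
            a2 = a.moved_to(p)
            if chain_id is not None:
                a2 = dataclasses.replace(a2, chain_id=chain_id)
            atoms.append(a2)
        return ProtomerCoords(atoms, self.pivot_residue, self.motif_residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray = (0.0, 0.0, 0.0),
                    chain_id: str | None = None) -> "ProtomerCoords":
        new = self.positions @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)
        return self.with_positions(new, chain_id=chain_id)


@dataclass(frozen=True)
class PoreAxis:
    """A rotational symmetry axis: a point on it, a unit direction, and the order."""

    point: np.ndarray
    direction: np.ndarray
    order: int = 5

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector (|d| = 1 within 1e-9)")
        object.__setattr__(self, "direction", d)
        if self.order < 2:
            raise ValueError("rotational order must be >= 2")


@dataclass(frozen=True)
class AxisFit:
    """Result of :func:`fit_pore_axis`: the axis and the residual of the fit."""

    axis: PoreAxis
    residual_rmsd: float
    chain_permutation: tuple[int, ...]


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _check_atom_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbParseError(f"line {i}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PdbParseError(f"line {i}: unreadable coordinates in ATOM record") from None
            if line[26] not in (" ", ""):
                raise PdbParseError(f"line {i}: insertion codes are not supported")


def read_coordinates(
    source: str | Path,
    ca_only: bool = False,
    chains: Sequence[str] | None = None,
    pivot_residue: int = DEFAULT_PIVOT_RESIDUE,
    motif_residues: Sequence[int] = (DEFAULT_MOTIF_RESIDUE,) + DEFAULT_TMVTT_RANGE,
) -> list[ProtomerCoords]:
    """Read PDB-format coordinates and return one :class:`ProtomerCoords` per chain.

    ``source`` is a path or PDB-format text.  Of alternate locations the
    first is kept; insertion codes are rejected (this is low-resolution,
    whole-residue work).  ``chains`` restricts the selection; ``ca_only``
    keeps only C-alpha atoms.
    """
    from .pore import vdw_radius_of  # local import to avoid a cycle

    path = Path(source) if not str(source).lstrip().startswith(("ATOM", "HETATM", "HEADER", "REMARK", "CRYST", "MODEL", "TITLE")) else None
    text = path.read_text() if path is not None else str(source)
    _check_atom_lines(text)
    if "ATOM" not in text and "HETATM" not in text:
        raise PdbParseError("no ATOM records in input")
    structure = gemmi.read_pdb_string(text)
    structure.remove_alternative_conformations()
    if len(structure) == 0:
        raise PdbParseError("no models in input")
    model = structure[0]

    protomers: list[ProtomerCoords] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        atoms: list[AtomRecord] = []
        for residue in chain:
            for atom in residue:
                if ca_only and atom.name != "CA":
                    continue
                el = atom.element.name if atom.element else ""
                atoms.append(AtomRecord(
                    name=atom.name,
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    weight=1.0,
                    vdw_radius=vdw_radius_of(el) if el else None,
                    element=el,
                ))
        if atoms:
            protomers.append(ProtomerCoords(atoms, pivot_residue, tuple(motif_residues)))
    if not protomers:
        raise PdbParseError("empty selection: no atoms matched the requested chains/filters")
    return protomers


_PDB_ATOM = ("ATOM  {serial:5d} {name:^4s} {res:3s} {chain:1s}{resnum:4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n")


def write_pdb(protomers: Iterable[ProtomerCoords] | "object", path: str | Path) -> None:
    """Write protomers (or a PentamerModel) as a PDB file."""
    if hasattr(protomers, "protomers"):  # a PentamerModel
        protomers = protomers.protomers
    serial = 0
    with open(path, "w") as fh:
        for prot in protomers:
            for a in prot.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(_PDB_ATOM.format(
                    serial=serial % 100000, name=name, res="ALA", chain=a.chain_id[:1] or "A",
                    resnum=a.residue_number, x=a.position[0], y=a.position[1], z=a.position[2],
                    occ=1.0, b=0.0, el=(a.element or a.name[:1])[:2]))
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Pore-axis fitting
# ---------------------------------------------------------------------------

def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``direction`` to an orthonormal frame."""
    d = unit(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, helper))
    return e1, np.cross(d, e1)


def _match_chains(centroids: np.ndarray, point: np.ndarray, direction: np.ndarray,
                  angle_deg: float) -> tuple[int, ...] | None:
    """Permutation mapping chain k to the chain its rotated copy lands on."""
    rotated = rotate_about_line(centroids, point, direction, angle_deg)
    perm = []
    for r in rotated:
        perm.append(int(np.argmin(np.linalg.norm(centroids - r, axis=1))))
    return tuple(perm) if sorted(perm) == list(range(len(centroids))) else None


def fit_pore_axis(protomers: Sequence[ProtomerCoords], order: int = 5) -> AxisFit:
    """Least-squares Cₙ symmetry axis of a homo-oligomer.

    The axis minimizes the RMSD between the full coordinate set and its copy
    rotated by 360/order degrees (with the chain-to-chain correspondence
    resolved from the centroid ring).  Initialization is the normal of the
    best plane through the chain centroids; refinement is nonlinear least
    squares over the axis direction and its in-plane offset.
    """
    if len(protomers) != order:
        raise ValueError(f"expected {order} protomers, got {len(protomers)}")
    counts = {len(p) for p in protomers}
    if len(counts) != 1:
        raise ValueError(f"unequal chain lengths: {sorted(len(p) for p in protomers)}")

    coords = [p.positions for p in protomers]
    centroids = np.array([c.mean(axis=0) for c in coords])
    center = centroids.mean(axis=0)
    cov = np.cov((centroids - center).T)
    evals, evecs = np.linalg.eigh(cov)
    # ring of centroids: two large in-plane eigenvalues, one small along axis
    if evals[1] < 1e-12 * max(evals[2], 1.0) or not np.isfinite(evals).all():
        raise ValueError("degenerate (collinear or coincident) chain centroids: axis undefined")
    direction0 = evecs[:, 0]
    angle = 360.0 / order

    sense_perm = None
    for d_try in (direction0, -direction0):
        perm = _match_chains(centroids, center, d_try, angle)
        if perm is not None:
            direction0, sense_perm = d_try, perm
            break
    if sense_perm is None:
        raise ValueError("could not establish a cyclic chain correspondence; not a Cn ring?")

    e1, e2 = _axis_frame(direction0)
    X = np.vstack(coords)
    n_atoms = coords[0].shape[0]
    perm_rows = np.concatenate([np.arange(n_atoms) + sense_perm[k] * n_atoms
                                for k in range(order)])
    target = X[perm_rows]

    def residuals(params):
        a1, a2, q1, q2 = params
        d = unit(direction0 + a1 * e1 + a2 * e2)
        p = center + q1 * e1 + q2 * e2
        return (rotate_about_line(X, p, d, angle) - target).ravel()

    sol = least_squares(residuals, x0=np.zeros(4), method="lm")
    a1, a2, q1, q2 = sol.x
    direction = unit(direction0 + a1 * e1 + a2 * e2)
    point = center + q1 * e1 + q2 * e2
    rmsd = math.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 3) ** 2, axis=1)))

    # orientation: TM end (last residues) -> cytoplasmic end (first residues)
    firsts, lasts = [], []
    for p in protomers:
        firsts.extend(a.position for a in p.atoms[:30])
        lasts.extend(a.position for a in p.atoms[-30:])
    up = np.mean(firsts, axis=0) - np.mean(lasts, axis=0)
    if float(up @ direction) < 0:
        direction = -direction
    axis = PoreAxis(point=point, direction=direction, order=order)
    return AxisFit(axis=axis, residual_rmsd=rmsd, chain_permutation=sense_perm)


def symmetrize(protomer: ProtomerCoords, axis: PoreAxis, chain_ids: str = "ABCDE"):
    """Replicate one protomer into a C₅ pentamer about ``axis``.

    Chain k is the input rotated by 72·k degrees; returns a
    :class:`~pentastate.states.PentamerModel` with the uniform reference
    state (no tilts applied).
    """
    from .states import PentamerModel, StateString

    if axis.order != 5:
        raise ValueError("symmetrize builds pentamers: axis order must be 5")
    chains = []
    for k in range(5):
        pos = rotate_about_line(protomer.positions, axis.point, axis.direction, 72.0 * k)
        chains.append(protomer.with_positions(pos, chain_id=chain_ids[k]))
    return PentamerModel(
        protomers=chains, axis=axis, state=StateString("ttttt"), tilts=None,
        euler_angles=tuple((0.0, 0.0, 72.0 * k) for k in range(5)),
    )
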