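"""Cyclic taut/relaxed state classes and rigid tilted-pentamer models.

A pentamer state is a length-5 word over {t, r}: ``t`` (taut) protomers are
tilted inward about a pivot residue, ``r`` (relaxed) protomers outward.
Because the five chains are related by the C₅ pore axis, words that differ
only by a cyclic rotation describe the same physical assembly, so states
are enumerated as necklaces (orbits of the cyclic group; reflection is NOT
applied — a pentamer and its mirror image are distinct objects).  For the
two-letter alphabet and n = 5 there are 8 classes.

The tilt of a protomer is a rigid rotation about the line through the pivot
residue's C-alpha, directed radially away from the pore axis.  The sign
convention is geometric: a positive angle moves the channel's motif marker
(Gly 278 by default) AWAY from the pore axis, so positive "relaxed" angles
flare the trans-membrane domain outward and negative "taut" angles pull it
inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Iterable, Sequence

import numpy as np

from ._geometry import foot_on_line, rotate_about_line, unit
from .structures import PoreAxis, ProtomerCoords

__all__ = [
    "StateString",
    "TiltSpec",
    "PentamerModel",
    "ConsensusEnsemble",
    "enumerate_state_classes",
    "canonical_form",
    "count_state_classes",
    "tilt_protomer",
    "build_state_model",
    "consensus_overlay",
]

_DEFAULT_ALPHABET = "tr"  # ordering: 't' sorts before 'r'


@dataclass(frozen=True)
class StateString:
    """A word over the state alphabet, one symbol per protomer position."""

    symbols: str
    alphabet: str = _DEFAULT_ALPHABET

    def __post_init__(self):
        if not self.symbols:
            raise ValueError("state string must be non-empty")
        bad = set(self.symbols) - set(self.alphabet)
        if bad:
            raise ValueError(f"invalid state symbols {sorted(bad)}; alphabet is {self.alphabet!r}")

    def __str__(self) -> str:
        return self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def rotated(self, k: int) -> "StateString":
        k %= len(self.symbols)
        return StateString(self.symbols[k:] + self.symbols[:k], self.alphabet)

    def _key(self, word: str) -> tuple[int, ...]:
        return tuple(self.alphabet.index(c) for c in word)

    def canonical(self) -> "StateString":
        best = min((self.rotated(k).symbols for k in range(len(self))), key=self._key)
        return StateString(best, self.alphabet)

    def count(self, symbol: str) -> int:
        return self.symbols.count(symbol)


def canonical_form(state: StateString | str) -> StateString:
    """Lexicographically smallest cyclic rotation (with 't' ordered before 'r')."""
    if isinstance(state, str):
        state = StateString(state)
    return state.canonical()


def _totient(n: int) -> int:
    return sum(1 for k in range(1, n + 1) if gcd(k, n) == 1)


def count_state_classes(n: int, alphabet_size: int = 2) -> int:
    """Number of cyclic classes (necklaces) by Burnside's lemma:
    (1/n) Σ_{d|n} φ(d)·k^(n/d)."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    total = sum(_totient(d) * alphabet_size ** (n // d) for d in range(1, n + 1) if n % d == 0)
    return total // n


def enumerate_state_classes(n: int, alphabet_size: int = 2) -> list[StateString]:
    """One canonical representative per cyclic equivalence class of {t,r,…}ⁿ.

    Representatives are lexicographically smallest rotations under the
    alphabet order ('t' < 'r'), listed in that same order — for n = 5 this
    is ttttt, ttttr, tttrr, ttrtr, ttrrr, trtrr, trrrr, rrrrr.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 1 <= alphabet_size <= len("trsuv"):
        raise ValueError("alphabet_size out of range")
    alphabet = "trsuv"[:alphabet_size]
    seen: set[str] = set()
    out: list[StateString] = []
    for idx in np.ndindex(*([alphabet_size] * n)):
        word = "".join(alphabet[i] for i in idx)
        canon = StateString(word, alphabet).canonical()
        if canon.symbols not in seen:
            seen.add(canon.symbols)
            out.append(canon)
    out.sort(key=lambda s: s._key(s.symbols))
    return out


@dataclass(frozen=True)
class TiltSpec:
    """Pivot residue and the taut/relaxed tilt angles (degrees)."""

    pivot_residue: int = 250
    angle_t: float = -10.0
    angle_r: float = +20.0

    def __post_init__(self):
        if self.angle_t == self.angle_r:
            raise ValueError("taut and relaxed tilt angles must differ")

    def angle(self, symbol: str) -> float:
        if symbol == "t":
            return self.angle_t
        if symbol == "r":
            return self.angle_r
        raise ValueError(f"no tilt angle for state symbol {symbol!r}")


@dataclass
class PentamerModel:
    """Five protomers about a pore axis, with the state word that built them."""

    protomers: list[ProtomerCoords]
    axis: PoreAxis
    state: StateString
    tilts: TiltSpec | None = None
    euler_angles: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if len(self.protomers) != 5:
            raise ValueError("a pentamer has exactly 5 protomers")
        if len(self.state) != 5:
            raise ValueError("state string length must be 5")

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([p.positions for p in self.protomers])

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([p.weights for p in self.protomers])

    def atoms(self):
        for p in self.protomers:
            yield from p.atoms


# ---------------------------------------------------------------------------
# Rigid tilting
# ---------------------------------------------------------------------------

def _tilt_line(protomer: ProtomerCoords, axis: PoreAxis) -> tuple[np.ndarray, np.ndarray]:
    pivot = protomer.atom(protomer.pivot_residue, "CA").position
    foot = foot_on_line(pivot, axis.point, axis.direction)[0]
    radial = pivot - foot
    if np.linalg.norm(radial) <= 1e-6:
        raise ValueError("pivot lies on the pore axis: tilt axis undefined")
    return pivot, unit(radial)


def _tilt_sense(protomer: ProtomerCoords, axis: PoreAxis,
                pivot: np.ndarray, radial: np.ndarray) -> float:
    """+1/−1 so that a positive angle moves the motif marker off-axis.

    The derivative of the marker's axial radius under right-handed rotation
    about the radial line is (m − foot_axis(m)) · (u × (m − pivot)); its sign
    decides the rotation sense.  Falls back to +1 when no motif marker is
    annotated or the derivative vanishes.
    """
    try:
        m = protomer.atom(protomer.motif_residues[0], "CA").position
    except (KeyError, IndexError):
        return 1.0
    perp = m - foot_on_line(m, axis.point, axis.direction)[0]
    deriv = float(perp @ np.cross(radial, m - pivot))
    return -1.0 if deriv < 0 else 1.0


def tilt_protomer(protomer: ProtomerCoords, axis: PoreAxis, angle_deg: float,
                  sense: float | None = None) -> ProtomerCoords:
    """Rigidly tilt a protomer about the radial line through its pivot C-alpha.

    The rotation line passes through the pivot residue's C-alpha with
    direction from the foot of its perpendicular on the pore axis to the
    pivot (i.e. radially outward), which keeps tilted protomers clear of
    their neighbours.  The pivot itself does not move and all interatomic
    distances are preserved.  ``sense`` overrides the automatic sign
    convention (positive angle = motif marker moves away from the axis).
    """
    pivot, radial = _tilt_line(protomer, axis)
    if sense is None:
        sense = _tilt_sense(protomer, axis, pivot, radial)
    new = rotate_about_line(protomer.positions, pivot, radial, sense * angle_deg)
    return protomer.with_positions(new)


def build_state_model(protomer: ProtomerCoords, axis: PoreAxis,
                      state: StateString | str, tilts: TiltSpec = TiltSpec(),
                      chain_ids: str = "ABCDE") -> PentamerModel:
    """Assemble a pentamer in a given t/r state.

    Chain k is the docked protomer tilted by the angle of state symbol k
    (tilt first, in the docked frame), then rotated by 72·k degrees about
    the pore axis.
    """
    if isinstance(state, str):
        state = StateString(state)
    if len(state) != 5:
        raise ValueError("state string length must be 5")
    protomer = ProtomerCoords(protomer.atoms, tilts.pivot_residue, protomer.motif_residues)
    chains = []
    eulers = []
    for k, symbol in enumerate(state):
        tilted = tilt_protomer(protomer, axis, tilts.angle(symbol))
        pos = rotate_about_line(tilted.positions, axis.point, axis.direction, 72.0 * k)
        chains.append(tilted.with_positions(pos, chain_id=chain_ids[k]))
        eulers.append((0.0, 0.0, 72.0 * k))
    return PentamerModel(protomers=chains, axis=axis, state=state, tilts=tilts,
                         euler_angles=tuple(eulers))


# ---------------------------------------------------------------------------
# Weighted ensembles
# ---------------------------------------------------------------------------

@dataclass
class ConsensusEnsemble:
    """Superposed state models with per-model weights (normalized to one).

    Density synthesized from the flattened, weight-scaled point set equals
    the same weighted sum of the members' individual densities.
    """

    members: list[PentamerModel]
    weights: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([m.positions for m in self.members])

    @property
    def point_weights(self) -> np.ndarray:
        return np.concatenate([w * m.weights for m, w in zip(self.members, self.weights)])


def consensus_overlay(models: Sequence[PentamerModel], weights: Sequence[float]) -> ConsensusEnsemble:
    """Overlay state models weighted by their particle-population fractions."""
    if len(models) != len(weights):
        raise ValueError("need one weight per model")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return ConsensusEnsemble(members=list(models), weights=w / total)
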