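"""Shared fixtures: phantom structures, maps and deterministic RNGs."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pentastate as ps
from pentastate.synthdata import INTENDED_AXIS, PhantomSpec, make_phantom_protomer

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def phantom_protomer() -> ps.ProtomerCoords:
    return make_phantom_protomer(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def axis() -> ps.PoreAxis:
    return INTENDED_AXIS


@pytest.fixture(scope="session")
def phantom_pentamer(phantom_protomer, axis) -> ps.PentamerModel:
    return ps.symmetrize(phantom_protomer, axis)


@pytest.fixture(scope="session")
def c5_phantom_map(phantom_pentamer) -> ps.DensityMap:
    """A C₅-symmetric map, centred so its pore axis passes through the box centre."""
    return ps.synthesize_map(phantom_pentamer, resolution=25.0, voxel_size=3.5,
                             box_edge=168.0)


def deposited_structure_path() -> Path:
    """Path to the deposited MjCorA pentamer (PDB entry 4EV6).

    Looks for a local copy at data/4EV6.pdb (repo root) or scratch/4EV6.pdb,
    then attempts a one-time download into scratch/.  Raises when the entry
    cannot be obtained, e.g. in an offline environment.
    """
    candidates = [REPO_ROOT / "data" / "4EV6.pdb", REPO_ROOT / "scratch" / "4EV6.pdb"]
    for c in candidates:
        if c.exists():
            return c
    import urllib.request

    target = REPO_ROOT / "scratch" / "4EV6.pdb"
    target.parent.mkdir(exist_ok=True)
    url = "https://files.rcsb.org/download/4EV6.pdb"
    with urllib.request.urlopen(url, timeout=15) as resp:  # raises offline
        target.write_bytes(resp.read())
    return target


def load_deposited_structure(ca_only: bool = True) -> list[ps.ProtomerCoords]:
    return ps.read_coordinates(deposited_structure_path(), ca_only=ca_only)
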