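"""Synthetic fixtures: phantom protomers, state maps, half-maps, crystals.

Everything the pipeline consumes can be generated here at desk scale, with
all randomness drawn from one explicitly passed seed (reruns are
byte-identical).  The phantom protomer echoes the architecture of a CorA
subunit — a cytoplasmic blob, a conical stalk and a trans-membrane arm —
with two labelled markers: the pivot C-alpha (residue 250, the narrow waist
the rigid tilts rotate about) and the motif C-alpha (residue 278, the
YGMNF-style marker whose radius from the pore axis tracks pore openness).
A TMVTT-style window (residues 255–259) sits just below the pivot.  Default
dimensions echo the envelope scale of a detergent-solubilized CorA pentamer
(box 168 Å, particle diameter under ~175 Å).

The phantom's intended pore axis is +z through the origin; the motif marker
is placed with a tangential offset so that over the tilt range of interest
(−10° … +20°) its axial radius varies monotonically — taut tilts pull it
inward, relaxed tilts flare it outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import DensityMap, synthesize_map
from .states import PentamerModel, StateString, TiltSpec, build_state_model
from .structures import AtomRecord, PoreAxis, ProtomerCoords

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "INTENDED_AXIS",
    "make_phantom_protomer",
    "make_phantom_dataset",
    "make_crystal_case",
    "make_fsc_pair",
    "make_falloff_signal",
    "make_falloff_half_maps",
    "analytic_fsc_half_crossing",
]

#: the phantom's intended pore axis: +z through the origin
INTENDED_AXIS = PoreAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]), order=5)

_PIVOT_RADIUS = 12.0  # axial radius of the pivot marker, Å


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of the phantom protomer (lengths in Å, angles deg)."""

    n_atoms: int = 120
    stalk_length: float = 40.0
    cone_half_angle: float = 20.0
    tm_offset: float = 20.0
    motif_radius: float = 8.0
    pivot_z: float = 10.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 80:
            raise ValueError("phantom needs at least 80 atoms")
        for name in ("stalk_length", "cone_half_angle", "tm_offset", "motif_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_phantom_protomer(spec: PhantomSpec = PhantomSpec()) -> ProtomerCoords:
    """Deterministic pseudo-atom protomer with exact pivot and motif markers.

    Residues run consecutively; the trans-membrane arm occupies residues
    251–310 with the pivot at 250 and the motif marker at 278, placed
    exactly (no jitter) so its radius from the intended axis equals
    ``spec.motif_radius`` to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    n_blob = spec.n_atoms - 70
    first_res = 241 - n_blob

    u = np.array([1.0, 0.0, 0.0])   # radial at azimuth 0
    w = np.array([0.0, 1.0, 0.0])   # tangential
    d = np.array([0.0, 0.0, 1.0])   # axial (cytoplasmic = +z)
    pivot = _PIVOT_RADIUS * u + spec.pivot_z * d

    blob_base_z = spec.pivot_z + spec.stalk_length
    blob_radius = _PIVOT_RADIUS + spec.stalk_length * np.tan(np.deg2rad(spec.cone_half_angle))

    atoms: list[AtomRecord] = []

    def add(res: int, pos: np.ndarray, jitter: bool = True):
        p = np.asarray(pos, dtype=float)
        if jitter and spec.noise_sd > 0:
            p = p + rng.normal(0.0, spec.noise_sd, 3)
        atoms.append(AtomRecord(name="CA", residue_number=res, chain_id="A",
                                position=p, weight=1.0, element="C"))

    # (1) cytoplasmic blob: a short chiral spiral of pseudo-atoms
    for i in range(n_blob):
        t = i / max(n_blob - 1, 1)
        az = np.deg2rad(-28.0 + 56.0 * t)
        radius = blob_radius * (0.85 + 0.25 * np.sin(3.1 * np.pi * t))
        z = blob_base_z + 28.0 * (1.0 - t)
        pos = radius * (np.cos(az) * u + np.sin(az) * w) + z * d
        add(first_res + i, pos)

    # (2) conical stalk: straight run from blob base down to the pivot
    start = blob_radius * u + blob_base_z * d
    for i in range(10):
        t = (i + 1) / 10.0
        res = 241 + i
        pos = (1 - t) * start + t * pivot
        add(res, pos, jitter=(res != 250))  # the pivot marker is exact

    # (3) trans-membrane arm through the exact motif marker
    v_w = 0.75 * spec.motif_radius
    rho = np.sqrt(spec.motif_radius ** 2 - v_w ** 2)
    motif = rho * u + v_w * w + (spec.pivot_z - spec.tm_offset) * d
    f_motif = (278 - 250) / 60.0
    for i in range(60):
        res = 251 + i
        t = (i + 1) / 60.0
        pos = pivot + (t / f_motif) * (motif - pivot)
        exact = res in (278, 255, 256, 257, 258, 259)
        add(res, pos, jitter=not exact)

    return ProtomerCoords(atoms, pivot_residue=250,
                          motif_residues=(278, 255, 256, 257, 258, 259))


@dataclass
class PhantomDataset:
    """A ground-truth pentamer model, its (optionally noisy) map, and metadata."""

    model: PentamerModel
    density: DensityMap
    truth: dict


def make_phantom_dataset(state: StateString | str = "tttrr", tilts: TiltSpec = TiltSpec(),
                         resolution: float = 25.0, voxel_size: float = 3.5,
                         box_edge: float = 168.0, noise_sd: float = 0.0,
                         seed: int = 0, spec: PhantomSpec | None = None) -> PhantomDataset:
    """Ground-truth state model plus its map with seeded additive voxel noise."""
    ss = np.random.SeedSequence(seed)
    s_prot, s_noise = ss.spawn(2)
    if spec is None:
        spec = PhantomSpec(seed=int(s_prot.generate_state(1)[0] % 2**31))
    protomer = make_phantom_protomer(spec)
    model = build_state_model(protomer, INTENDED_AXIS, state, tilts)
    density = synthesize_map(model, resolution=resolution, voxel_size=voxel_size,
                             box_edge=box_edge, label=f"phantom {state}")
    if noise_sd > 0:
        rng = np.random.default_rng(s_noise)
        density.grid = density.grid + rng.normal(0.0, noise_sd, density.shape)
    return PhantomDataset(model=model, density=density,
                          truth={"state": str(model.state), "tilts": tilts,
                                 "resolution": resolution, "noise_sd": noise_sd,
                                 "seed": seed, "spec": spec})


# ---------------------------------------------------------------------------
# Crystallographic fixtures
# ---------------------------------------------------------------------------

def make_crystal_case(n_atoms: int = 30,
                      cell: tuple = (58.1, 75.5, 81.6, 90.0, 94.25, 90.0),
                      translation: tuple = (0.0, 0.0, 0.5),
                      d_min: float = 6.0, seed: int = 0,
                      sigma_frac: float = 0.02):
    """Dummy-atom structure factors with an (optional) translational NCS pair.

    Random fractional atoms plus copies shifted by ``translation`` are
    summed directly: F(hkl) = Σ_j exp(2πi·hkl·x_j); intensities are |F|²
    with proportional sigmas.  All (h,k,l) with d ≥ d_min over the full
    sphere are generated, so Friedel mates are present and consistent.
    """
    import gemmi

    from .crystsym import ReflectionSet

    rng = np.random.default_rng(seed)
    x = rng.random((n_atoms, 3))
    shift = np.asarray(translation, dtype=float)
    if np.any(shift != 0):
        x = np.vstack([x, (x + shift) % 1.0])

    gcell = gemmi.UnitCell(*cell)
    hmax = [int(np.floor(e / d_min)) for e in cell[:3]]
    hs = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1,
                  -hmax[2]:hmax[2] + 1].reshape(3, -1).T
    hs = hs[np.any(hs != 0, axis=1)]
    inv_d2 = np.array([gcell.calculate_1_d2(h) for h in hs.tolist()])
    hs = hs[1.0 / np.sqrt(inv_d2) >= d_min]

    phases = np.exp(2j * np.pi * (hs @ x.T))
    F = phases.sum(axis=1)
    I = np.abs(F) ** 2
    sigma = sigma_frac * np.maximum(I, np.median(I) * 1e-3)
    return ReflectionSet(hkl=hs, intensity=I, sigma=sigma, cell=tuple(cell))


# ---------------------------------------------------------------------------
# Half-map pairs for FSC work
# ---------------------------------------------------------------------------

def make_fsc_pair(signal: DensityMap, noise_sd: float, seed: int = 0
                  ) -> tuple[DensityMap, DensityMap]:
    """Two half-maps: the common signal plus independent seeded noise."""
    ss = np.random.SeedSequence(seed)
    halves = []
    for child in ss.spawn(2):
        rng = np.random.default_rng(child)
        g = signal.grid + (rng.normal(0.0, noise_sd, signal.shape) if noise_sd > 0 else 0.0)
        m = signal.copy()
        m.grid = g
        halves.append(m)
    return halves[0], halves[1]


def make_falloff_signal(n: int = 64, voxel_size: float = 3.5,
                        falloff_sigma: float = 0.05, amplitude: float = 3.0,
                        seed: int = 0) -> DensityMap:
    """Random signal map with a Gaussian spectral falloff.

    White noise is filtered so the amplitude spectrum is
    A(S) = amplitude · exp(−S² / (2·falloff_sigma²)); the per-shell
    signal power is then known analytically, which makes the expected FSC
    of two noisy half-maps a closed form.
    """
    rng = np.random.default_rng(seed)
    white = rng.normal(0.0, 1.0, (n, n, n))
    fw = np.fft.fftn(white)
    f = np.fft.fftfreq(n, d=voxel_size)
    fx, fy, fz = np.meshgrid(f, f, f, indexing="ij")
    s2 = fx ** 2 + fy ** 2 + fz ** 2
    filt = amplitude * np.exp(-s2 / (2.0 * falloff_sigma ** 2))
    sig = np.fft.ifftn(fw * filt).real
    return DensityMap(grid=sig, voxel_size=voxel_size, label="falloff signal")


def analytic_fsc_half_crossing(falloff_sigma: float, amplitude: float,
                               noise_sd: float) -> float:
    """S at which the expected half-map FSC crosses 0.5.

    With signal power amplitude²·exp(−S²/falloff_sigma²) and white noise of
    variance noise_sd², the expected FSC is SNR/(1+SNR) and equals 0.5 where
    the two powers match: S½ = falloff_sigma·sqrt(2·ln(amplitude/noise_sd)).
    """
    if not amplitude > noise_sd > 0:
        raise ValueError("need amplitude > noise_sd > 0 for a crossing")
    return falloff_sigma * np.sqrt(2.0 * np.log(amplitude / noise_sd))


def make_falloff_half_maps(n: int = 64, voxel_size: float = 3.5,
                           falloff_sigma: float = 0.05, amplitude: float = 3.0,
                           noise_sd: float = 1.0, seed: int = 0
                           ) -> tuple[DensityMap, DensityMap, float]:
    """Seeded half-map pair with a known analytic FSC = 0.5 crossing."""
    ss = np.random.SeedSequence(seed)
    s_sig, s_noise = ss.spawn(2)
    signal = make_falloff_signal(n, voxel_size, falloff_sigma, amplitude,
                                 seed=int(s_sig.generate_state(1)[0] % 2**31))
    a, b = make_fsc_pair(signal, noise_sd, seed=int(s_noise.generate_state(1)[0] % 2**31))
    return a, b, analytic_fsc_half_crossing(falloff_sigma, amplitude, noise_sd)
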