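"""Shell profiles: FSC, logistic resolution fits, 1-D scattering utilities.

All spatial frequencies are S = 1/d in Å⁻¹.  Momentum transfer q = 2πS is
accepted at the text interfaces via a flag and converted immediately; using
a single internal convention avoids factor-of-2π mistakes between the
scattering and map-resolution halves of the pipeline.

The Fourier Shell Correlation of two half-maps is the shell-wise normalized
complex cross-correlation of their Fourier transforms.  The resolution of a
reconstruction is read from the FSC curve either at the first downward 0.5
crossing or from a logistic model FSC(S) = 1/(1 + exp(aS − b)), whose 0.5
point is S½ = b/a, i.e. a resolution of a/b Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .density import DensityMap

__all__ = [
    "ShellProfile",
    "FscFit",
    "GuinierFit",
    "compute_fsc",
    "fit_fsc_logistic",
    "threshold_crossing",
    "spherical_average",
    "subtract_buffer",
    "merge_profiles",
    "guinier_fit",
]


@dataclass
class ShellProfile:
    """1-D profile vs spatial frequency S = 1/d (Å⁻¹), with optional errors."""

    s: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.values.shape:
            raise ValueError("s and values must be 1-D arrays of equal length")
        if np.any(self.s <= 0) or np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing and > 0")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.s.shape:
                raise ValueError("errors must match the profile length")

    def __len__(self) -> int:
        return self.s.size

    @classmethod
    def from_text(cls, path: str | Path, q_input: bool = False, label: str = "") -> "ShellProfile":
        """Read a 2- or 3-column whitespace/CSV profile (S-or-q, I, [σI])."""
        data = np.loadtxt(path, delimiter=None if "," not in Path(path).read_text()[:200] else ",")
        data = np.atleast_2d(data)
        s = data[:, 0] / (2.0 * np.pi) if q_input else data[:, 0]
        errors = data[:, 2] if data.shape[1] > 2 else None
        order = np.argsort(s)
        return cls(s=s[order], values=data[order, 1],
                   errors=None if errors is None else errors[order], label=label)

    def to_text(self, path: str | Path) -> None:
        cols = [self.s, self.values] + ([] if self.errors is None else [self.errors])
        np.savetxt(path, np.column_stack(cols), header="S(1/A) value" + (" sigma" if self.errors is not None else ""))


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

def _frequency_magnitudes(shape, voxel_size: float) -> np.ndarray:
    f = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    fx, fy, fz = np.meshgrid(*f, indexing="ij")
    return np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)


def compute_fsc(a: DensityMap, b: DensityMap, n_shells: int = 32) -> ShellProfile:
    """FSC between two maps in linear shells of S from 0 to Nyquist."""
    if not a.same_grid_as(b):
        raise ValueError("FSC needs maps on identical grids")
    if n_shells < 4:
        raise ValueError("need at least 4 shells")
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    smag = _frequency_magnitudes(a.shape, a.voxel_size)
    s_nyq = 1.0 / (2.0 * a.voxel_size)
    edges = np.linspace(0.0, s_nyq, n_shells + 1)
    which = np.clip(np.digitize(smag.ravel(), edges) - 1, 0, n_shells - 1)

    cross = np.bincount(which, weights=(fa * np.conj(fb)).real.ravel(), minlength=n_shells)
    pa = np.bincount(which, weights=(np.abs(fa) ** 2).ravel(), minlength=n_shells)
    pb = np.bincount(which, weights=(np.abs(fb) ** 2).ravel(), minlength=n_shells)
    counts = np.bincount(which, minlength=n_shells)

    keep = (counts > 0) & (pa > 0) & (pb > 0)
    keep[0] = False  # DC shell carries only the mean
    centers = 0.5 * (edges[:-1] + edges[1:])
    fsc = cross[keep] / np.sqrt(pa[keep] * pb[keep])
    return ShellProfile(s=centers[keep], values=np.clip(fsc, -1.0, 1.0), label="FSC")


@dataclass(frozen=True)
class FscFit:
    """Logistic FSC model 1/(1 + exp(aS − b)); resolution = a/b Å."""

    a: float
    b: float
    rss: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("logistic fit requires a > 0 and b > 0")

    @property
    def s_half(self) -> float:
        return self.b / self.a

    @property
    def resolution(self) -> float:
        return self.a / self.b

    def __call__(self, s) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(self.a * np.asarray(s, dtype=float) - self.b))


def fit_fsc_logistic(profile: ShellProfile, fit_window: tuple[float, float] = (0.02, 0.98)) -> FscFit:
    """Least-squares logistic fit to an FSC curve.

    Only shells with FSC inside ``fit_window`` enter the fit (the tails are
    noise-dominated); initialization is a logit-linear regression.  Raises
    if the curve never crosses 0.5.
    """
    v = profile.values
    if not (np.any(v > 0.5) and np.any(v < 0.5)):
        raise ValueError("no resolution crossing: FSC does not bracket 0.5")
    lo, hi = fit_window
    m = (v >= lo) & (v <= hi)
    if m.sum() < 3:
        m = (v > 0.0) & (v < 1.0)
    if m.sum() < 2:
        raise ValueError("too few usable FSC points for a logistic fit")
    s, y = profile.s[m], v[m]
    logit = np.log(1.0 / np.clip(y, 1e-12, 1 - 1e-12) - 1.0)
    A = np.column_stack([s, -np.ones_like(s)])
    a0, b0 = np.linalg.lstsq(A, logit, rcond=None)[0]
    if a0 <= 0:
        a0 = 1.0 / (s.max() - s.min() + 1e-9)
    if b0 <= 0:
        b0 = a0 * np.median(s)

    def model(sv, a, b):
        return 1.0 / (1.0 + np.exp(np.clip(a * sv - b, -500, 500)))

    popt, _ = curve_fit(model, s, y, p0=(a0, b0), maxfev=20000)
    rss = float(np.sum((model(s, *popt) - y) ** 2))
    return FscFit(a=float(popt[0]), b=float(popt[1]), rss=rss)


def threshold_crossing(profile: ShellProfile, level: float = 0.5) -> float:
    """S of the first downward crossing of ``level`` (linear interpolation)."""
    v, s = profile.values, profile.s
    for i in range(len(v)):
        if v[i] == level:
            return float(s[i])
        if i + 1 < len(v) and v[i] > level > v[i + 1]:
            f = (v[i] - level) / (v[i] - v[i + 1])
            return float(s[i] + f * (s[i + 1] - s[i]))
    raise ValueError(f"profile never crosses {level} downward")


# ---------------------------------------------------------------------------
# Crystallographic intensities -> 1-D profile
# ---------------------------------------------------------------------------

def spherical_average(reflections, n_bins: int = 150) -> ShellProfile:
    """Average reflection intensities into linear shells of S = 1/d.

    S for each (h,k,l) comes from the general triclinic reciprocal-cell
    metric; intensities are averaged per bin weighted by 1/σ² (plain means
    when no sigmas are given) with errors propagated.
    """
    import gemmi

    cell = gemmi.UnitCell(*reflections.cell)
    if cell.volume <= 0:
        raise ValueError("unit cell has zero volume")
    hkl = np.asarray(reflections.hkl, dtype=int)
    if hkl.size == 0:
        raise ValueError("no reflections to average")
    inv_d2 = np.array([cell.calculate_1_d2(h) for h in hkl.tolist()])
    s = np.sqrt(inv_d2)
    I = np.asarray(reflections.intensity, dtype=float)
    if reflections.sigma is not None:
        sig = np.asarray(reflections.sigma, dtype=float)
        wts = 1.0 / sig ** 2
    else:
        wts = np.ones_like(I)

    edges = np.linspace(s.min(), s.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    wsum = np.bincount(which, weights=wts, minlength=n_bins)
    iw = np.bincount(which, weights=wts * I, minlength=n_bins)
    keep = wsum > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = iw[keep] / wsum[keep]
    errors = np.sqrt(1.0 / wsum[keep]) if reflections.sigma is not None else None
    return ShellProfile(s=centers[keep], values=values, errors=errors, label="spherical average")


def subtract_buffer(sample: ShellProfile, buffer: ShellProfile) -> ShellProfile:
    """Point-wise sample − buffer; errors add in quadrature."""
    if len(sample) != len(buffer) or not np.allclose(sample.s, buffer.s, rtol=1e-9, atol=0):
        raise ValueError("sample and buffer profiles must share the same S grid")
    errors = None
    if sample.errors is not None and buffer.errors is not None:
        errors = np.hypot(sample.errors, buffer.errors)
    return ShellProfile(s=sample.s.copy(), values=sample.values - buffer.values,
                        errors=errors, label="buffer-subtracted")


def merge_profiles(low_s: ShellProfile, high_s: ShellProfile,
                   min_overlap: int = 3) -> tuple[ShellProfile, float]:
    """Scale-merge a higher-frequency profile onto a lower-frequency one.

    The high-S profile is interpolated onto the low-S grid over the overlap
    region; the least-squares scalar scale matching it to the low-S values
    is applied, the overlap region is taken from the low-S profile, and the
    concatenation (sorted in S) plus the scale is returned.
    """
    lo_max, hi_min = low_s.s.max(), high_s.s.min()
    overlap = (low_s.s >= hi_min) & (low_s.s <= high_s.s.max())
    if overlap.sum() < min_overlap:
        raise ValueError(f"profiles overlap in {int(overlap.sum())} point(s); need >= {min_overlap}")
    interp = np.interp(low_s.s[overlap], high_s.s, high_s.values)
    denom = float(interp @ interp)
    if denom == 0:
        raise ValueError("high-S profile vanishes on the overlap; cannot scale")
    scale = float(low_s.values[overlap] @ interp) / denom

    tail = high_s.s > lo_max
    s = np.concatenate([low_s.s, high_s.s[tail]])
    values = np.concatenate([low_s.values, scale * high_s.values[tail]])
    errors = None
    if low_s.errors is not None and high_s.errors is not None:
        errors = np.concatenate([low_s.errors, scale * high_s.errors[tail]])
    order = np.argsort(s)
    merged = ShellProfile(s=s[order], values=values[order],
                          errors=None if errors is None else errors[order], label="merged")
    return merged, scale


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierFit:
    """Guinier-regime fit: ln I = ln I₀ − (Rg²/3) q², with q = 2πS."""

    rg: float
    i0: float
    q_range_used: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if not self.rg > 0:
            raise ValueError("Rg must be > 0")


def guinier_fit(profile: ShellProfile, qrg_limit: float = 1.3,
                min_points: int = 5) -> GuinierFit:
    """Radius of gyration from the low-angle limit of a scattering profile.

    Fits ln I against q² (q = 2πS) by linear regression and iterates the
    upper fit limit until q_max·Rg ≤ ``qrg_limit`` (standard Guinier
    validity).  Raises on non-Guinier behaviour (non-negative slope).
    """
    q = 2.0 * np.pi * profile.s
    I = profile.values
    usable = I > 0
    if usable.sum() < min_points:
        raise ValueError("too few positive-intensity points for a Guinier fit")
    q, I = q[usable], I[usable]

    sel = np.ones(q.size, dtype=bool)
    rg = None
    for _ in range(100):
        if sel.sum() < min_points:
            raise ValueError(f"fewer than {min_points} points inside the Guinier range")
        slope, intercept = np.polyfit(q[sel] ** 2, np.log(I[sel]), 1)
        if slope >= 0:
            raise ValueError("non-Guinier behaviour: ln I does not decrease with q²")
        rg_new = float(np.sqrt(-3.0 * slope))
        new_sel = q * rg_new <= qrg_limit
        if new_sel.sum() == sel.sum() and np.all(new_sel == sel):
            rg = rg_new
            break
        sel = new_sel
        rg = rg_new
    i0 = float(np.exp(intercept))
    qs = q[sel]
    return GuinierFit(rg=rg, i0=i0, q_range_used=(float(qs.min()), float(qs.max())),
                      n_points=int(sel.sum()))
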