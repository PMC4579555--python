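"""Matplotlib views of the pipeline's result objects."""

from __future__ import annotations

import numpy as np

from .resolution import FscFit, GuinierFit, ShellProfile
from .pore import PoreProfile


def plot_fsc(profile: ShellProfile, fit: FscFit | None = None, ax=None):
    """FSC curve vs S with the 0.5 criterion line and an optional logistic fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.s, profile.values, "o-", ms=3, label="FSC")
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    if fit is not None:
        s = np.linspace(profile.s.min(), profile.s.max(), 200)
        ax.plot(s, fit(s), "--", label=f"logistic fit ({fit.resolution:.1f} Å)")
        ax.axvline(fit.s_half, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("S (Å$^{-1}$)")
    ax.set_ylabel("FSC")
    ax.legend()
    return ax


def plot_guinier(profile: ShellProfile, fit: GuinierFit, ax=None):
    """Guinier plot: ln I against q² with the fitted line over the used range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    q = 2.0 * np.pi * profile.s
    pos = profile.values > 0
    ax.plot(q[pos] ** 2, np.log(profile.values[pos]), "o", ms=3, label="data")
    qf = np.linspace(*fit.q_range_used, 50)
    ax.plot(qf ** 2, np.log(fit.i0) - fit.rg ** 2 / 3.0 * qf ** 2, "-",
            label=f"Guinier fit, Rg = {fit.rg:.1f} Å")
    ax.set_xlabel("q² (Å$^{-2}$)")
    ax.set_ylabel("ln I")
    ax.legend()
    return ax


def plot_pore_profile(profile: PoreProfile, ax=None):
    """Pore diameter along the axial coordinate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.z, profile.diameter, "-")
    ax.set_xlabel("z along pore axis (Å)")
    ax.set_ylabel("pore diameter (Å)")
    return ax
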