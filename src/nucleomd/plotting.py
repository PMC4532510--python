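"""Publication-style figures for the standard observables.

Thin matplotlib wrappers: each function draws onto a provided Axes (or a
fresh one) and returns it, so figures compose the usual way.
"""

from __future__ import annotations

import numpy as np

from .analysis import ForceProfile, UnwrapProfile


def plot_free_energy(profiles: list[UnwrapProfile], side: str = "left", ax=None):
    """Overlay free-energy profiles F(bp) = -ln(N p + 1), one line per
    condition (labelled by salt where available)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for prof in profiles:
        label = prof.label or (f"{prof.salt_mM:g} mM" if prof.salt_mM else None)
        ax.plot(np.arange(prof.n_bp + 1), prof.free_energy(side), label=label)
    ax.set_xlabel(f"unwrapped bp ({side} end)")
    ax.set_ylabel(r"$-\ln(N\,p + 1)$")
    if any(p.label or p.salt_mM for p in profiles):
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_force_distance(profile: ForceProfile, ax=None, show_individual=True):
    """Mean force-distance curve (thick) over the individual trajectories
    (thin), in the style of constant-velocity unwrapping figures."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = profile.bin_centres
    if show_individual:
        for curve in profile.per_trajectory:
            ax.plot(x, curve, lw=0.5, color="0.6", alpha=0.6)
    ax.plot(x, profile.mean_curve, lw=2.0, color="crimson")
    ax.set_xlabel("pulling distance d ($\\AA$)")
    ax.set_ylabel("force (pN)")
    return ax


def plot_tail_distances(r_hto: dict[str, np.ndarray], ax=None, bins=40):
    """Histograms of the tail-terminal-to-core distances r_HTO per tail."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for cid, r in r_hto.items():
        ax.hist(r, bins=bins, histtype="step", density=True, label=f"chain {cid}")
    ax.set_xlabel(r"$r_{HTO}$ ($\AA$)")
    ax.set_ylabel("probability density")
    ax.legend(frameon=False, fontsize=8)
    return ax
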