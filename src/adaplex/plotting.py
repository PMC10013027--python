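"""Optional quick-look plots (requires matplotlib).

These are diagnostic exports, not publication figures: mean-phase-velocity
profiles with nodes in display order, coupling-matrix heatmaps, and phase
space-time plots.
"""

from __future__ import annotations

import numpy as np

from .integrate import Trajectory
from .measures import mean_phase_velocity, sort_nodes_for_display


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_mpv_profile(traj: Trajectory, t_start: float, T: float, path) -> None:
    """Per-node mean phase velocities of both layers, nodes in display order."""
    plt = _mpl()
    mpv1, mpv2 = mean_phase_velocity(traj, t_start=t_start, T=T)
    idx_end = traj.index_of(t_start + T)
    order1 = sort_nodes_for_display(mpv1, traj.phases1[idx_end])
    order2 = sort_nodes_for_display(mpv2, traj.phases2[idx_end])
    n = traj.n
    fig, ax = plt.subplots(figsize=(6, 4))
    path_mask = traj.params.omega1[order1] != np.min(traj.params.omega1)
    ax.plot(np.arange(1, n + 1), mpv1[order1], ".", color="C0", label="parenchyma")
    if path_mask.any() and not path_mask.all():
        ax.plot(np.arange(1, n + 1)[path_mask], mpv1[order1][path_mask], ".",
                color="C3", label="pathological")
    ax.plot(np.arange(n + 1, 2 * n + 1), mpv2[order2], ".", color="C2", label="immune")
    ax.set_xlabel("node (sorted)")
    ax.set_ylabel("mean phase velocity")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kappa_heatmaps(traj: Trajectory, path, snapshot: int = -1) -> None:
    """Side-by-side heatmaps of the two coupling matrices at one snapshot."""
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, k, title in zip(
        axes, (traj.kappa1[snapshot], traj.kappa2[snapshot]), ("kappa1", "kappa2")
    ):
        im = ax.imshow(k, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower")
        ax.set_title(f"{title} (t={traj.kappa_times[snapshot]:g})")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_spacetime(traj: Trajectory, path, layer: int = 1) -> None:
    """Space-time plot of wrapped phases for one layer."""
    plt = _mpl()
    phases = traj.phases1 if layer == 1 else traj.phases2
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        np.mod(phases, 2 * np.pi).T,
        aspect="auto",
        origin="lower",
        extent=(traj.times[0], traj.times[-1], 0.5, traj.n + 0.5),
        cmap="twilight",
        vmin=0,
        vmax=2 * np.pi,
    )
    ax.set_xlabel("time")
    ax.set_ylabel(f"node (layer {layer})")
    fig.colorbar(im, ax=ax, label="phase mod 2pi")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
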