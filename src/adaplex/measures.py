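"""Diagnostics of collective states: mean phase velocities, dispersion,
frequency clusters, order parameters and state classification.

The central observable is the mean phase velocity of oscillator ``j`` in
layer ``mu`` over an averaging window ``T`` starting at ``t_start``::

    <dphi_j/dt> = (phi_j(t_start + T) - phi_j(t_start)) / T

Because phases are stored unwrapped the endpoint formula is exact (the time
integral of the phase velocity telescopes).  Defaults discard the first 1000
time units as transient and average over the following ``T = 1000``.

From the per-node velocities we form the layer mean ``omega_bar`` and the
population standard deviation ``sigma_chi``; a nonzero ``sigma_chi``
signals the splitting of a layer into multifrequency clusters, the model's
marker of a pathological state (pathogenicity in the parenchyma, activation
in the immune layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .integrate import Trajectory

__all__ = [
    "Dispersion",
    "FrequencyCluster",
    "LayerSummary",
    "mean_phase_velocity",
    "layer_dispersion",
    "order_parameter",
    "detect_frequency_clusters",
    "classify_layer",
    "summarize_layer",
    "summarize",
    "sort_nodes_for_display",
    "SYNCHRONIZED_LABELS",
    "PATHOLOGICAL_LABELS",
    "DEFAULT_FREQ_TOL",
    "DEFAULT_INPHASE_MIN",
    "DEFAULT_SPLAY_MAX",
    "NORM_GUARD_FLOOR",
]

#: Gap threshold (rad/time) between sorted mean phase velocities that
#: separates frequency clusters.  The endpoint formula over T = 1000 resolves
#: frequencies far more finely, but residual transients justify a margin of
#: about 2*pi/T ~ 6e-3; the default sits just above that.
DEFAULT_FREQ_TOL = 1e-2

#: Order-parameter thresholds for labeling a single frequency cluster as
#: in-phase (R1 close to 1) or splay (phases spread out, R1 close to 0).
#: These are documented implementation defaults, not literature values.
DEFAULT_INPHASE_MIN = 0.99
DEFAULT_SPLAY_MAX = 0.2

#: Guard floor for the normalized dispersion sigma_chi / |omega_bar|.  In the
#: co-rotating frame of the healthy cells omega_bar can be arbitrarily close
#: to zero, so the unguarded ratio is undefined; the guard is flagged rather
#: than hidden.
NORM_GUARD_FLOOR = 1e-6

LABEL_INPHASE = "in-phase synchronized"
LABEL_SPLAY = "splay synchronized"
LABEL_MULTIFREQUENCY = "multifrequency cluster"
LABEL_DESYNC = "desynchronized"
LABEL_PARTIAL = "partially coherent"

#: Labels counted as healthy (frequency-synchronized) outcomes.  A splay
#: state is healthy but vulnerable: frequency-locked with vanishing phase
#: coherence.
SYNCHRONIZED_LABELS = frozenset({LABEL_INPHASE, LABEL_SPLAY})
PATHOLOGICAL_LABELS = frozenset({LABEL_MULTIFREQUENCY, LABEL_DESYNC, LABEL_PARTIAL})


class Dispersion(NamedTuple):
    layer_mean: float
    sigma_chi: float
    sigma_chi_norm: float
    norm_guarded: bool


@dataclass(frozen=True)
class FrequencyCluster:
    """One frequency cluster: member node indices and collective frequency."""

    indices: np.ndarray
    frequency: float

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class LayerSummary:
    """Per-layer diagnostic bundle for one run."""

    layer: int
    mpv: np.ndarray
    layer_mean: float
    sigma_chi: float
    sigma_chi_norm: float
    norm_guarded: bool
    clusters: list[FrequencyCluster]
    cluster_order_params: list[float]
    label: str

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_row(self) -> dict:
        """Flat record for CSV summary tables (one row per layer)."""
        return {
            "layer": self.layer,
            "omega_bar": self.layer_mean,
            "sigma_chi": self.sigma_chi,
            "sigma_chi_norm": self.sigma_chi_norm,
            "norm_guarded": self.norm_guarded,
            "n_clusters": self.n_clusters,
            "label": self.label,
        }

    def partition_dict(self) -> dict:
        """JSON-serializable cluster partition (sidecar for the CSV row)."""
        return {
            "layer": self.layer,
            "clusters": [
                {
                    "frequency": c.frequency,
                    "size": c.size,
                    "order_param": float(r1),
                    "members": c.indices.tolist(),
                }
                for c, r1 in zip(self.clusters, self.cluster_order_params)
            ],
        }


def mean_phase_velocity(
    traj: Trajectory, t_start: float = 1000.0, T: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint-formula mean phase velocities for both layers.

    Raises ``ValueError`` if ``[t_start, t_start + T]`` is not covered by the
    trajectory's recording grid.
    """
    if T <= 0:
        raise ValueError(f"averaging window T must be positive, got {T}")
    i0 = traj.index_of(t_start)
    i1 = traj.index_of(t_start + T)
    mpv1 = (traj.phases1[i1] - traj.phases1[i0]) / T
    mpv2 = (traj.phases2[i1] - traj.phases2[i0]) / T
    return mpv1, mpv2


def layer_dispersion(mpv: np.ndarray, norm_floor: float = NORM_GUARD_FLOOR) -> Dispersion:
    """Layer mean, population standard deviation, and normalized deviation.

    The population form (``1/N``, not ``1/(N-1)``) is used.  The normalized
    value divides by ``max(|layer_mean|, norm_floor)``; ``norm_guarded`` is
    True when the floor binds.
    """
    mpv = np.asarray(mpv, dtype=np.float64)
    if not np.all(np.isfinite(mpv)):
        raise ValueError("mean phase velocities must be finite")
    mean = float(np.mean(mpv))
    sigma_chi = float(np.sqrt(np.mean((mpv - mean) ** 2)))
    denom = abs(mean)
    guarded = denom < norm_floor
    sigma_chi_norm = sigma_chi / max(denom, norm_floor)
    return Dispersion(mean, sigma_chi, sigma_chi_norm, guarded)


def order_parameter(phases: np.ndarray) -> float:
    """Magnitude ``R1 = |mean(exp(i phi))|`` of the Kuramoto order parameter."""
    phases = np.asarray(phases, dtype=np.float64)
    return float(np.abs(np.mean(np.exp(1j * phases))))


def detect_frequency_clusters(
    mpv: np.ndarray, tol: float = DEFAULT_FREQ_TOL
) -> list[FrequencyCluster]:
    """Partition nodes into frequency clusters.

    Nodes are sorted by mean phase velocity and split at every gap larger
    than ``tol``; on the sorted axis this equals single-linkage clustering at
    threshold ``tol``.  Clusters are returned in ascending frequency order.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    mpv = np.asarray(mpv, dtype=np.float64)
    order = np.argsort(mpv, kind="stable")
    sorted_v = mpv[order]
    cuts = np.flatnonzero(np.diff(sorted_v) > tol) + 1
    clusters = []
    for chunk in np.split(order, cuts):
        clusters.append(
            FrequencyCluster(indices=np.sort(chunk), frequency=float(np.mean(mpv[chunk])))
        )
    return clusters


def classify_layer(
    mpv: np.ndarray,
    final_phases: np.ndarray,
    tol: float = DEFAULT_FREQ_TOL,
    inphase_min: float = DEFAULT_INPHASE_MIN,
    splay_max: float = DEFAULT_SPLAY_MAX,
) -> tuple[str, list[FrequencyCluster], list[float]]:
    """Label the collective state of one layer.

    Rules (``k`` = number of frequency clusters, ``R1`` = order parameter of
    the whole layer at the final snapshot):

    * ``k = 1`` and ``R1 >= inphase_min``  -> in-phase synchronized
    * ``k = 1`` and ``R1 <= splay_max``    -> splay synchronized
    * ``2 <= k <= n/4``                    -> multifrequency cluster
    * ``k > n/4``                          -> desynchronized
    * otherwise                            -> partially coherent

    Returns the label, the cluster partition, and the per-cluster order
    parameters (computed on cluster members only).
    """
    mpv = np.asarray(mpv, dtype=np.float64)
    final_phases = np.asarray(final_phases, dtype=np.float64)
    if mpv.shape != final_phases.shape:
        raise ValueError("mpv and final_phases must have the same length")
    n = len(mpv)
    clusters = detect_frequency_clusters(mpv, tol=tol)
    r1s = [order_parameter(final_phases[c.indices]) for c in clusters]
    k = len(clusters)
    if k == 1:
        r1 = r1s[0]
        if r1 >= inphase_min:
            label = LABEL_INPHASE
        elif r1 <= splay_max:
            label = LABEL_SPLAY
        else:
            label = LABEL_PARTIAL
    elif k <= n / 4:
        label = LABEL_MULTIFREQUENCY
    else:
        label = LABEL_DESYNC
    return label, clusters, r1s


def summarize_layer(
    traj: Trajectory,
    layer: int,
    t_start: float = 1000.0,
    T: float = 1000.0,
    tol: float = DEFAULT_FREQ_TOL,
    inphase_min: float = DEFAULT_INPHASE_MIN,
    splay_max: float = DEFAULT_SPLAY_MAX,
) -> LayerSummary:
    """Full diagnostic bundle for one layer of a trajectory."""
    if layer not in (1, 2):
        raise ValueError(f"layer must be 1 or 2, got {layer}")
    mpv1, mpv2 = mean_phase_velocity(traj, t_start=t_start, T=T)
    mpv = mpv1 if layer == 1 else mpv2
    phases = traj.phases1 if layer == 1 else traj.phases2
    final_phases = phases[traj.index_of(t_start + T)]
    disp = layer_dispersion(mpv)
    label, clusters, r1s = classify_layer(
        mpv, final_phases, tol=tol, inphase_min=inphase_min, splay_max=splay_max
    )
    return LayerSummary(
        layer=layer,
        mpv=mpv,
        layer_mean=disp.layer_mean,
        sigma_chi=disp.sigma_chi,
        sigma_chi_norm=disp.sigma_chi_norm,
        norm_guarded=disp.norm_guarded,
        clusters=clusters,
        cluster_order_params=r1s,
        label=label,
    )


def summarize(
    traj: Trajectory, t_start: float = 1000.0, T: float = 1000.0, **kwargs
) -> tuple[LayerSummary, LayerSummary]:
    """Summaries of both layers (parenchyma first)."""
    return (
        summarize_layer(traj, 1, t_start=t_start, T=T, **kwargs),
        summarize_layer(traj, 2, t_start=t_start, T=T, **kwargs),
    )


def sort_nodes_for_display(mpv: np.ndarray, final_phases: np.ndarray) -> np.ndarray:
    """Display ordering of nodes: by mean phase velocity, then wrapped phase.

    The sort is stable, so exact ties keep the original node order.
    """
    mpv = np.asarray(mpv, dtype=np.float64)
    wrapped = np.mod(np.asarray(final_phases, dtype=np.float64), 2.0 * np.pi)
    if mpv.shape != wrapped.shape:
        raise ValueError("mpv and final_phases must have the same length")
    # np.lexsort: last key is the primary one.
    return np.lexsort((wrapped, mpv))
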