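"""Fixed-step classical Runge-Kutta (RK4) integration of the duplex model.

A fixed step size is used deliberately: it reproduces runs bit-identically
for a given initial state and parameters, and the accuracy check is step
halving (the global error of RK4 scales as ``dt**4``).  Defaults follow the
standard study protocol: ``dt = 0.05`` and a total simulation time of 2000
time units, of which the measures discard the first 1000 as transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import (
    DimensionError,
    DuplexState,
    KappaBoundError,
    ModelParams,
    NumericalStateError,
    _rhs_kernel,
)

__all__ = ["Trajectory", "rk4_step", "integrate"]


@njit(cache=True, fastmath=True)
def _integrate_kernel(
    phi1, phi2, k1, k2,
    omega1, omega2, alpha, beta, eps1, eps2, sigma, adj, literal,
    dt, n_steps, record_stride, kappa_stride,
    rec_phi1, rec_phi2, snap_k1, snap_k2,
):  # pragma: no cover - exercised through integrate()
    """Advance the state in place for ``n_steps`` RK4 steps.

    Records phases every ``record_stride`` steps and coupling matrices every
    ``kappa_stride`` steps into the preallocated output arrays (row 0 is
    filled by the caller with the initial condition).  Returns the maximum
    absolute coupling weight observed after any completed step.
    """
    n = phi1.shape[0]
    dP1 = np.empty((4, n))
    dP2 = np.empty((4, n))
    dK1 = np.empty((4, n, n))
    dK2 = np.empty((4, n, n))
    p1b = np.empty(n)
    p2b = np.empty(n)
    k1b = np.empty((n, n))
    k2b = np.empty((n, n))
    stage_dt = np.array([0.0, 0.5 * dt, 0.5 * dt, dt])

    kmax = 0.0
    for i in range(n):
        for j in range(n):
            a1 = abs(k1[i, j])
            a2 = abs(k2[i, j])
            if a1 > kmax:
                kmax = a1
            if a2 > kmax:
                kmax = a2

    rec_idx = 1
    snap_idx = 1
    for step in range(n_steps):
        for s in range(4):
            if s == 0:
                _rhs_kernel(
                    phi1, phi2, k1, k2,
                    omega1, omega2, alpha, beta, eps1, eps2, sigma, adj,
                    literal, dP1[0], dP2[0], dK1[0], dK2[0],
                )
            else:
                f = stage_dt[s]
                for i in range(n):
                    p1b[i] = phi1[i] + f * dP1[s - 1, i]
                    p2b[i] = phi2[i] + f * dP2[s - 1, i]
                    for j in range(n):
                        k1b[i, j] = k1[i, j] + f * dK1[s - 1, i, j]
                        k2b[i, j] = k2[i, j] + f * dK2[s - 1, i, j]
                _rhs_kernel(
                    p1b, p2b, k1b, k2b,
                    omega1, omega2, alpha, beta, eps1, eps2, sigma, adj,
                    literal, dP1[s], dP2[s], dK1[s], dK2[s],
                )
        h6 = dt / 6.0
        for i in range(n):
            phi1[i] += h6 * (dP1[0, i] + 2.0 * dP1[1, i] + 2.0 * dP1[2, i] + dP1[3, i])
            phi2[i] += h6 * (dP2[0, i] + 2.0 * dP2[1, i] + 2.0 * dP2[2, i] + dP2[3, i])
            for j in range(n):
                if j == i:
                    continue
                k1[i, j] += h6 * (
                    dK1[0, i, j] + 2.0 * dK1[1, i, j] + 2.0 * dK1[2, i, j] + dK1[3, i, j]
                )
                k2[i, j] += h6 * (
                    dK2[0, i, j] + 2.0 * dK2[1, i, j] + 2.0 * dK2[2, i, j] + dK2[3, i, j]
                )
                a1 = abs(k1[i, j])
                a2 = abs(k2[i, j])
                if a1 > kmax:
                    kmax = a1
                if a2 > kmax:
                    kmax = a2
        if (step + 1) % record_stride == 0:
            for i in range(n):
                rec_phi1[rec_idx, i] = phi1[i]
                rec_phi2[rec_idx, i] = phi2[i]
            rec_idx += 1
        if (step + 1) % kappa_stride == 0:
            for i in range(n):
                for j in range(n):
                    snap_k1[snap_idx, i, j] = k1[i, j]
                    snap_k2[snap_idx, i, j] = k2[i, j]
            snap_idx += 1
    return kmax


@dataclass
class Trajectory:
    """Time-stamped record of an integrated run.

    Attributes
    ----------
    times : (m,) ndarray
        Recording times (strictly increasing, constant spacing).
    phases1, phases2 : (m, n) ndarray
        Unwrapped phases of the two layers at the recording times.
    kappa_times : (k,) ndarray
        Times of the coupling-matrix snapshots (a subset of the step grid).
    kappa1, kappa2 : (k, n, n) ndarray
        Coupling-matrix snapshots.
    params : ModelParams
    dt : float
        Integration step.
    kappa_abs_max : float
        Largest ``|kappa|`` observed after any completed step (bound monitor).
    final_state : DuplexState
        Exact state at the end of the run (regardless of strides).
    meta : dict
        Provenance (scenario, seed, ...); free-form but JSON-serializable.
    """

    times: np.ndarray
    phases1: np.ndarray
    phases2: np.ndarray
    kappa_times: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    params: ModelParams
    dt: float
    kappa_abs_max: float
    final_state: DuplexState
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.phases1.shape[1]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def index_of(self, t: float) -> int:
        """Index of recording time ``t``; raises if ``t`` is not on the grid."""
        if len(self.times) == 1:
            if abs(t - self.times[0]) < 1e-9:
                return 0
            raise ValueError(f"time {t} outside trajectory (single record)")
        spacing = self.times[1] - self.times[0]
        idx = (t - self.times[0]) / spacing
        ridx = int(round(idx))
        if abs(idx - ridx) > 1e-6 or not (0 <= ridx < len(self.times)):
            raise ValueError(
                f"time {t} is not a recorded time of this trajectory "
                f"(range [{self.times[0]}, {self.times[-1]}], spacing {spacing})"
            )
        return ridx


def _unpack(params: ModelParams):
    return (
        params.omega1, params.omega2, params.alpha, params.beta,
        params.eps1, params.eps2, params.sigma, params.adjacency,
        params.literal_adaptation,
    )


def rk4_step(state: DuplexState, params: ModelParams, dt: float) -> DuplexState:
    """One classical RK4 step of length ``dt``; the input state is not modified."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if state.n != params.n:
        raise DimensionError(f"state has n={state.n} but params has n={params.n}")
    phi1 = state.phi1.copy()
    phi2 = state.phi2.copy()
    k1 = state.kappa1.copy()
    k2 = state.kappa2.copy()
    n = state.n
    _integrate_kernel(
        phi1, phi2, k1, k2, *_unpack(params),
        float(dt), 1, 1, 1,
        np.empty((2, n)), np.empty((2, n)),
        np.empty((2, n, n)), np.empty((2, n, n)),
    )
    for name, arr in (("phases", phi1), ("phases", phi2),
                      ("coupling weights", k1), ("coupling weights", k2)):
        if not np.all(np.isfinite(arr)):
            raise NumericalStateError(f"non-finite {name} after RK4 step")
    return DuplexState(phi1, phi2, k1, k2)


def integrate(
    state0: DuplexState,
    params: ModelParams,
    dt: float = 0.05,
    t_end: float = 2000.0,
    record_stride: int = 1,
    kappa_stride: int = 200,
    check_kappa_bounds: bool | None = None,
    kappa_tol: float = 1e-6,
    meta: dict | None = None,
) -> Trajectory:
    """Integrate the duplex model with fixed-step RK4.

    Parameters
    ----------
    state0 : DuplexState
        Initial condition (not modified).
    params : ModelParams
    dt : float
        Step size; ``t_end`` must be an integer multiple of ``dt`` (within
        rounding).
    t_end : float
        Total simulated time.  No transient is discarded here; the measures
        choose their own averaging window.
    record_stride : int
        Record phases every this many steps (plus the initial condition).
    kappa_stride : int
        Snapshot both coupling matrices every this many steps.  Snapshots
        are memory-hungry (two ``n x n`` matrices each), hence the coarse
        default of 200 steps (10 time units at the default ``dt``).
    check_kappa_bounds : bool, optional
        Verify that ``|kappa| <= 1 + kappa_tol`` throughout the run and
        raise :class:`KappaBoundError` otherwise.  Defaults to True for the
        bracketed adaptation law and False for the literal law (whose fixed
        points are unbounded by design).
    kappa_tol : float
        Allowed excess over the unit bound before the run is declared failed.
        No clipping is ever applied; a violation is an integration failure,
        not something to repair silently.
    meta : dict, optional
        Provenance attached to the returned trajectory.

    Raises
    ------
    NumericalStateError
        If any variable becomes non-finite; the message names the offending
        block and the first affected recording time.
    KappaBoundError
        If the coupling-weight bound is violated beyond ``kappa_tol``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if record_stride < 1 or kappa_stride < 1:
        raise ValueError("record strides must be >= 1")
    if state0.n != params.n:
        raise DimensionError(f"state has n={state0.n} but params has n={params.n}")
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9 * max(1.0, abs(t_end)):
        raise ValueError(f"t_end={t_end} is not a multiple of dt={dt}")
    if check_kappa_bounds is None:
        check_kappa_bounds = not params.literal_adaptation

    n = state0.n
    phi1 = state0.phi1.copy()
    phi2 = state0.phi2.copy()
    k1 = state0.kappa1.copy()
    k2 = state0.kappa2.copy()

    n_rec = n_steps // record_stride + 1
    n_snap = n_steps // kappa_stride + 1
    rec_phi1 = np.empty((n_rec, n))
    rec_phi2 = np.empty((n_rec, n))
    snap_k1 = np.empty((n_snap, n, n))
    snap_k2 = np.empty((n_snap, n, n))
    rec_phi1[0] = phi1
    rec_phi2[0] = phi2
    snap_k1[0] = k1
    snap_k2[0] = k2

    if n_steps > 0:
        kmax = _integrate_kernel(
            phi1, phi2, k1, k2, *_unpack(params),
            float(dt), n_steps, int(record_stride), int(kappa_stride),
            rec_phi1, rec_phi2, snap_k1, snap_k2,
        )
    else:
        kmax = state0.kappa_abs_max()

    times = dt * record_stride * np.arange(n_rec)
    kappa_times = dt * kappa_stride * np.arange(n_snap)

    for name, arr, tvec in (
        ("phases (layer 1)", rec_phi1, times),
        ("phases (layer 2)", rec_phi2, times),
        ("coupling weights (layer 1)", snap_k1, kappa_times),
        ("coupling weights (layer 2)", snap_k2, kappa_times),
    ):
        finite = np.isfinite(arr).all(axis=tuple(range(1, arr.ndim)))
        if not finite.all():
            t_bad = tvec[int(np.argmin(finite))]
            raise NumericalStateError(
                f"non-finite {name} first recorded at t={t_bad}"
            )
    if check_kappa_bounds and kmax > 1.0 + kappa_tol:
        raise KappaBoundError(
            f"coupling weights left [-1, 1] (max |kappa| = {kmax:.6g}); "
            "treating as integration failure"
        )

    final_state = DuplexState(phi1, phi2, k1, k2)
    return Trajectory(
        times=times,
        phases1=rec_phi1,
        phases2=rec_phi2,
        kappa_times=kappa_times,
        kappa1=snap_k1,
        kappa2=snap_k2,
        params=params,
        dt=float(dt),
        kappa_abs_max=float(kmax),
        final_state=final_state,
        meta=dict(meta or {}),
    )
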