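"""Core dynamical model: a duplex network of adaptively coupled phase oscillators.

The system consists of two layers of ``N`` phase oscillators each.  Layer 1
(the *parenchyma*, the functional tissue of an organ) carries a fixed binary
adjacency matrix ``a`` in addition to adaptive coupling weights; layer 2 (the
*immune* layer, i.e. the stroma) is coupled purely adaptively.  Node ``i`` of
one layer interacts only with node ``i`` of the other layer (multiplex
topology) with fixed symmetric strength ``sigma``.

The equations of motion are, for layers ``mu = 1, 2``::

    dphi1_i/dt = omega1_i - (1/N) sum_{j != i} (a_ij + k1_ij) sin(phi1_i - phi1_j + alpha)
                 - sigma * sin(phi1_i - phi2_i)
    dphi2_i/dt = omega2   - (1/N) sum_{j != i} k2_ij sin(phi2_i - phi2_j + alpha)
                 - sigma * sin(phi2_i - phi1_i)
    dk_ij/dt   = -eps_mu * [ k_ij + sin(phi_i - phi_j - beta) ]        (i != j)

The coupling weights ``k_ij`` ("cytokine activities") relax on a slow time
scale ``eps_mu`` toward the fixed point ``-sin(phi_i - phi_j - beta)``, which
keeps the hypercube ``[-1, 1]`` forward-invariant.  The phase lag ``alpha``
models a metabolic signaling delay; the adaptation lag ``beta`` (the "age
parameter") selects the plasticity rule and is the principal control
parameter for the transition from healthy (frequency-synchronized) to
pathological (multifrequency-cluster) collective states.

Notes
-----
Self-coupling is excluded throughout: the ``j = i`` term is omitted from all
sums and ``k_ii`` is frozen at zero (a cell does not signal itself).  Phases
are stored unwrapped on the real line; wrap them only for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "DuplexState",
    "Derivative",
    "rhs",
    "adaptation_fixed_point",
    "DimensionError",
    "NumericalStateError",
    "KappaBoundError",
]


class DimensionError(ValueError):
    """Shapes of states, parameters or arrays are mutually inconsistent."""


class NumericalStateError(RuntimeError):
    """A dynamical variable became non-finite (or otherwise invalid)."""


class KappaBoundError(NumericalStateError):
    """A coupling weight left [-1, 1] beyond the integrator tolerance."""


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=np.float64)
    if arr.shape != (n,):
        raise DimensionError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


def _as_matrix(x, n: int, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=np.float64)
    if arr.shape != (n, n):
        raise DimensionError(f"{name} must have shape ({n}, {n}), got {arr.shape}")
    return arr


@dataclass
class ModelParams:
    """Static parameters of the duplex model.

    Parameters
    ----------
    n : int
        Number of oscillators per layer (>= 2).
    omega1 : (n,) array_like
        Natural frequencies of the parenchymal oscillators (rad / time).
        Scenario constructors realize the two-point mixture of healthy
        (``omega_h``) and pathological (``omega_p``) frequencies here.
    omega2 : float
        Common natural frequency of the immune oscillators.
    alpha : float
        Intralayer interaction phase lag (radians).
    beta : float
        Adaptation phase lag ("age parameter", radians).
    eps1, eps2 : float
        Adaptation rates of the parenchymal and immune coupling weights
        (1 / time).  The model assumes slow-fast-faster time scales
        ``eps1 << eps2 << 1``; violations only warn, since they are
        legitimate for sensitivity studies.
    sigma : float
        Interlayer coupling strength (>= 0, dimensionless).
    adjacency : (n, n) array_like
        Binary parenchymal adjacency ``a_ij`` with zero diagonal.
    literal_adaptation : bool, optional
        If True, use the non-bracketed adaptation law
        ``dk/dt = -eps * k + sin(dphi - beta)``, whose fixed points are not
        confined to [-1, 1].  Intended only for sensitivity checks; the
        default bracketed law is the one whose weight range matches the
        cytokine-activity bound.
    """

    n: int
    omega1: np.ndarray
    omega2: float
    alpha: float
    beta: float
    eps1: float
    eps2: float
    sigma: float
    adjacency: np.ndarray
    literal_adaptation: bool = False

    def __post_init__(self) -> None:
        self.n = int(self.n)
        if self.n < 2:
            raise ValueError(f"need at least 2 oscillators per layer, got n={self.n}")
        self.omega1 = _as_vector(self.omega1, self.n, "omega1")
        self.omega2 = float(self.omega2)
        self.alpha = float(self.alpha)
        self.beta = float(self.beta)
        self.eps1 = float(self.eps1)
        self.eps2 = float(self.eps2)
        self.sigma = float(self.sigma)
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("adaptation rates eps1, eps2 must be positive")
        if not (self.eps1 < self.eps2 < 1.0):
            warnings.warn(
                "expected slow-fast-faster time scales eps1 < eps2 < 1 "
                f"(got eps1={self.eps1}, eps2={self.eps2})",
                stacklevel=2,
            )
        if self.sigma < 0:
            raise ValueError(f"interlayer coupling sigma must be >= 0, got {self.sigma}")
        adj = _as_matrix(self.adjacency, self.n, "adjacency")
        if not np.all((adj == 0.0) | (adj == 1.0)):
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(adj) != 0.0):
            raise ValueError("adjacency diagonal must be zero (no self-coupling)")
        self.adjacency = adj

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "omega1": self.omega1.tolist(),
            "omega2": self.omega2,
            "alpha": self.alpha,
            "beta": self.beta,
            "eps1": self.eps1,
            "eps2": self.eps2,
            "sigma": self.sigma,
            "adjacency": self.adjacency.tolist(),
            "literal_adaptation": self.literal_adaptation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class DuplexState:
    """Dynamic variables: phases of both layers and the two coupling matrices.

    Phases are unwrapped (real line).  Coupling matrices have an identically
    zero diagonal; off-diagonal entries live in [-1, 1] under the default
    adaptation law.
    """

    phi1: np.ndarray
    phi2: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.phi1).shape[0] if np.ndim(self.phi1) == 1 else -1
        if n < 2:
            raise DimensionError("phi1 must be a length-n vector with n >= 2")
        self.phi1 = _as_vector(self.phi1, n, "phi1")
        self.phi2 = _as_vector(self.phi2, n, "phi2")
        self.kappa1 = _as_matrix(self.kappa1, n, "kappa1")
        self.kappa2 = _as_matrix(self.kappa2, n, "kappa2")
        for name in ("phi1", "phi2", "kappa1", "kappa2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise NumericalStateError(f"non-finite entries in {name}")
        for name in ("kappa1", "kappa2"):
            k = getattr(self, name)
            if np.any(np.diag(k) != 0.0):
                raise ValueError(f"{name} diagonal must be identically zero")
        excess = self.kappa_abs_max() - 1.0
        if excess > 1e-9:
            warnings.warn(
                f"coupling weights exceed [-1, 1] by {excess:.3g}", stacklevel=2
            )

    @property
    def n(self) -> int:
        return self.phi1.shape[0]

    def copy(self) -> "DuplexState":
        return DuplexState(
            self.phi1.copy(), self.phi2.copy(), self.kappa1.copy(), self.kappa2.copy()
        )

    def kappa_abs_max(self) -> float:
        return float(
            max(np.abs(self.kappa1).max(), np.abs(self.kappa2).max())
        )


@dataclass
class Derivative:
    """Time derivative of a :class:`DuplexState` (same shapes)."""

    phi1: np.ndarray
    phi2: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray

    @property
    def n(self) -> int:
        return self.phi1.shape[0]


@njit(cache=True, fastmath=True)
def _rhs_kernel(
    phi1, phi2, k1, k2,
    omega1, omega2, alpha, beta, eps1, eps2, sigma, adj, literal,
    dphi1, dphi2, dk1, dk2,
):  # pragma: no cover - exercised through rhs()/integrate()
    n = phi1.shape[0]
    inv_n = 1.0 / n
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    sb = np.sin(beta)
    cb = np.cos(beta)
    # Each unordered pair is visited once; sin(d + alpha), sin(-d + alpha),
    # sin(d - beta) and sin(-d - beta) all derive from sin(d), cos(d) by the
    # angle-addition identities, halving the trig work.
    for i in range(n):
        dphi1[i] = 0.0
        dphi2[i] = 0.0
        dk1[i, i] = 0.0
        dk2[i, i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d1 = phi1[i] - phi1[j]
            s1 = np.sin(d1)
            c1 = np.cos(d1)
            dphi1[i] += (adj[i, j] + k1[i, j]) * (s1 * ca + c1 * sa)
            dphi1[j] += (adj[j, i] + k1[j, i]) * (-s1 * ca + c1 * sa)
            g_ij = s1 * cb - c1 * sb
            g_ji = -s1 * cb - c1 * sb
            d2 = phi2[i] - phi2[j]
            s2 = np.sin(d2)
            c2 = np.cos(d2)
            dphi2[i] += k2[i, j] * (s2 * ca + c2 * sa)
            dphi2[j] += k2[j, i] * (-s2 * ca + c2 * sa)
            h_ij = s2 * cb - c2 * sb
            h_ji = -s2 * cb - c2 * sb
            if literal:
                dk1[i, j] = -eps1 * k1[i, j] + g_ij
                dk1[j, i] = -eps1 * k1[j, i] + g_ji
                dk2[i, j] = -eps2 * k2[i, j] + h_ij
                dk2[j, i] = -eps2 * k2[j, i] + h_ji
            else:
                dk1[i, j] = -eps1 * (k1[i, j] + g_ij)
                dk1[j, i] = -eps1 * (k1[j, i] + g_ji)
                dk2[i, j] = -eps2 * (k2[i, j] + h_ij)
                dk2[j, i] = -eps2 * (k2[j, i] + h_ji)
    for i in range(n):
        dphi1[i] = omega1[i] - dphi1[i] * inv_n - sigma * np.sin(phi1[i] - phi2[i])
        dphi2[i] = omega2 - dphi2[i] * inv_n - sigma * np.sin(phi2[i] - phi1[i])


def rhs(state: DuplexState, params: ModelParams) -> Derivative:
    """Evaluate the right-hand side of the duplex model.

    Parameters
    ----------
    state : DuplexState
    params : ModelParams
        Must have the same node count as ``state``.

    Returns
    -------
    Derivative
        Time derivatives of all phases and coupling weights.  The diagonal
        of the coupling-weight derivatives is exactly zero.

    Raises
    ------
    DimensionError
        If ``state`` and ``params`` disagree on the node count.
    NumericalStateError
        If the state contains non-finite entries.
    """
    if state.n != params.n:
        raise DimensionError(
            f"state has n={state.n} but params has n={params.n}"
        )
    for name in ("phi1", "phi2", "kappa1", "kappa2"):
        if not np.all(np.isfinite(getattr(state, name))):
            raise NumericalStateError(f"non-finite entries in state.{name}")
    n = state.n
    dphi1 = np.empty(n)
    dphi2 = np.empty(n)
    dk1 = np.empty((n, n))
    dk2 = np.empty((n, n))
    _rhs_kernel(
        state.phi1, state.phi2, state.kappa1, state.kappa2,
        params.omega1, params.omega2, params.alpha, params.beta,
        params.eps1, params.eps2, params.sigma, params.adjacency,
        params.literal_adaptation,
        dphi1, dphi2, dk1, dk2,
    )
    return Derivative(dphi1, dphi2, dk1, dk2)


def adaptation_fixed_point(delta_phi, beta):
    """Stationary coupling weight of the adaptation law at fixed phase difference.

    For a frozen phase difference ``delta_phi = phi_i - phi_j`` the bracketed
    adaptation law relaxes to ``k* = -sin(delta_phi - beta)``, so ``|k*| <= 1``.
    Accepts scalars or arrays.
    """
    return -np.sin(np.asarray(delta_phi, dtype=np.float64) - beta)
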