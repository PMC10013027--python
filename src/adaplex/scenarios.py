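"""Scenario constructors: parameters and seeded initial conditions.

Two disease scenarios are provided on top of a generic random initial state:

* ``tumor`` -- a fraction ``r`` of parenchymal oscillators ("mutant cells")
  receives the pathological natural frequency ``omega_p`` while the rest stay
  at the healthy frequency ``omega_h``; all initial phases and coupling
  weights are random.
* ``sepsis`` -- natural frequencies are homogeneous, but the immune-layer
  coupling matrix starts from a deterministic two-block "systemic activation"
  pattern (weight 1 within each block, 0 between blocks) and the interlayer
  coupling is strong (``sigma = 1``).

Seeding: a single integer master seed deterministically derives four
independent sub-streams (phases, layer-1 weights, layer-2 weights, index
selection) via :class:`numpy.random.SeedSequence`, so changing how many draws
one component consumes never shifts the others.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .model import DuplexState, ModelParams

__all__ = [
    "ScenarioSpec",
    "ScenarioError",
    "tumor_scenario",
    "sepsis_scenario",
    "custom_scenario",
    "build_scenario",
    "random_state",
    "TUMOR_DEFAULT_SIGMA",
    "SEPSIS_DEFAULT_SIGMA",
]

#: Interlayer coupling defaults: moderate for tumor runs, strong for sepsis
#: (pro-inflammatory leakiness increases the immune-parenchyma interaction).
TUMOR_DEFAULT_SIGMA = 0.3
SEPSIS_DEFAULT_SIGMA = 1.0

_KINDS = ("tumor", "sepsis", "custom")


class ScenarioError(ValueError):
    """Invalid scenario specification."""


@dataclass
class ScenarioSpec:
    """Declarative description of one simulation scenario.

    Defaults are the reference study conditions: ``n = 200`` oscillators per
    layer, ``alpha = -0.28*pi``, ``eps1 = 0.03``, ``eps2 = 0.3``,
    ``omega_h = omega2 = 0`` (co-rotating frame of the healthy cells) and
    ``omega_p = 1``.  ``sigma`` and ``cluster_small`` default per kind when
    left as None (0.3 / 1.0 and, for sepsis, 40 nodes at ``n = 200``,
    i.e. 20% of the layer).
    """

    kind: str = "tumor"
    n: int = 200
    r: float = 0.01
    omega_h: float = 0.0
    omega_p: float = 1.0
    omega2: float = 0.0
    alpha: float = -0.28 * np.pi
    beta: float = 0.45 * np.pi
    eps1: float = 0.03
    eps2: float = 0.3
    sigma: float | None = None
    cluster_small: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}; choose from {_KINDS}")
        self.n = int(self.n)
        if self.n < 2:
            raise ScenarioError(f"need n >= 2 oscillators per layer, got {self.n}")
        self.r = float(self.r)
        if not 0.0 <= self.r <= 1.0:
            raise ScenarioError(f"pathological fraction r must be in [0, 1], got {self.r}")
        if self.sigma is not None and self.sigma < 0:
            raise ScenarioError(f"sigma must be >= 0, got {self.sigma}")
        if self.cluster_small is not None:
            self.cluster_small = int(self.cluster_small)
            if not 0 < self.cluster_small < self.n:
                raise ScenarioError(
                    f"cluster_small must be in (0, n={self.n}), got {self.cluster_small}"
                )
        self.seed = int(self.seed)

    # -- resolved defaults -------------------------------------------------
    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return SEPSIS_DEFAULT_SIGMA if self.kind == "sepsis" else TUMOR_DEFAULT_SIGMA

    def resolved_cluster_small(self) -> int:
        if self.cluster_small is not None:
            return self.cluster_small
        # 40 of 200 nodes in the reference setup; keep the 20% fraction at
        # other layer sizes.
        return max(1, int(round(0.2 * self.n)))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ScenarioError(f"scenario file {path} must contain a mapping")
        return cls.from_dict(data)


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent generators for (phases, kappa1, kappa2, indices)."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.Generator(np.random.PCG64(c)) for c in children)


def _random_phases(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    phi1 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    phi2 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return phi1, phi2


def _random_kappa(rng: np.random.Generator, n: int) -> np.ndarray:
    k = rng.uniform(-1.0, 1.0, size=(n, n))
    np.fill_diagonal(k, 0.0)
    return k


def random_state(n: int, seed: int) -> DuplexState:
    """Fully random initial condition.

    Phases are i.i.d. Uniform[0, 2*pi) in both layers; off-diagonal coupling
    weights are i.i.d. Uniform[-1, 1]; diagonals are zero.
    """
    if n < 2:
        raise ScenarioError(f"need n >= 2, got {n}")
    rng_phi, rng_k1, rng_k2, _ = _streams(seed)
    phi1, phi2 = _random_phases(rng_phi, n)
    return DuplexState(phi1, phi2, _random_kappa(rng_k1, n), _random_kappa(rng_k2, n))


def _global_adjacency(n: int) -> np.ndarray:
    adj = np.ones((n, n))
    np.fill_diagonal(adj, 0.0)
    return adj


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def tumor_scenario(spec: ScenarioSpec) -> tuple[ModelParams, DuplexState]:
    """Construct the tumor-disease experiment.

    Exactly ``R = round(r * n)`` oscillators at uniformly drawn distinct
    indices receive the pathological frequency ``omega_p``; everything else
    (phases, both coupling matrices) is random.  The parenchymal adjacency is
    all-to-all.
    """
    if spec.kind != "tumor":
        raise ScenarioError(f"tumor_scenario needs kind='tumor', got {spec.kind!r}")
    n = spec.n
    n_path = _round_half_up(spec.r * n)
    if spec.r > 0 and n_path == 0:
        warnings.warn(
            f"r={spec.r} rounds to zero pathological cells at n={n}", stacklevel=2
        )
    rng_phi, rng_k1, rng_k2, rng_idx = _streams(spec.seed)
    omega1 = np.full(n, spec.omega_h)
    path_idx = np.sort(rng_idx.choice(n, size=n_path, replace=False))
    omega1[path_idx] = spec.omega_p
    params = ModelParams(
        n=n, omega1=omega1, omega2=spec.omega2, alpha=spec.alpha, beta=spec.beta,
        eps1=spec.eps1, eps2=spec.eps2, sigma=spec.resolved_sigma(),
        adjacency=_global_adjacency(n),
    )
    phi1, phi2 = _random_phases(rng_phi, n)
    state = DuplexState(phi1, phi2, _random_kappa(rng_k1, n), _random_kappa(rng_k2, n))
    return params, state


def sepsis_block_matrix(n: int, cluster_small: int) -> np.ndarray:
    """Deterministic two-block immune coupling matrix (1 within, 0 between)."""
    if not 0 < cluster_small < n:
        raise ScenarioError(f"cluster_small must be in (0, {n}), got {cluster_small}")
    k2 = np.zeros((n, n))
    k2[:cluster_small, :cluster_small] = 1.0
    k2[cluster_small:, cluster_small:] = 1.0
    np.fill_diagonal(k2, 0.0)
    return k2


def sepsis_scenario(spec: ScenarioSpec) -> tuple[ModelParams, DuplexState]:
    """Construct the sepsis experiment.

    Natural frequencies are homogeneous (``omega_h`` everywhere, default 0);
    the initial immune coupling matrix is the deterministic two-block
    activation pattern with the smaller block of ``cluster_small`` nodes
    (default 20% of the layer, i.e. 40 at ``n = 200``); phases and the
    parenchymal coupling matrix are random as in the tumor scenario; the
    interlayer coupling defaults to ``sigma = 1``.
    """
    if spec.kind != "sepsis":
        raise ScenarioError(f"sepsis_scenario needs kind='sepsis', got {spec.kind!r}")
    n = spec.n
    cluster_small = spec.resolved_cluster_small()
    rng_phi, rng_k1, _rng_k2, _ = _streams(spec.seed)
    params = ModelParams(
        n=n, omega1=np.full(n, spec.omega_h), omega2=spec.omega2,
        alpha=spec.alpha, beta=spec.beta, eps1=spec.eps1, eps2=spec.eps2,
        sigma=spec.resolved_sigma(), adjacency=_global_adjacency(n),
    )
    phi1, phi2 = _random_phases(rng_phi, n)
    state = DuplexState(
        phi1, phi2, _random_kappa(rng_k1, n), sepsis_block_matrix(n, cluster_small)
    )
    return params, state


def custom_scenario(spec: ScenarioSpec) -> tuple[ModelParams, DuplexState]:
    """Homogeneous frequencies, fully random initial state (baseline runs)."""
    if spec.kind != "custom":
        raise ScenarioError(f"custom_scenario needs kind='custom', got {spec.kind!r}")
    params = ModelParams(
        n=spec.n, omega1=np.full(spec.n, spec.omega_h), omega2=spec.omega2,
        alpha=spec.alpha, beta=spec.beta, eps1=spec.eps1, eps2=spec.eps2,
        sigma=spec.resolved_sigma(), adjacency=_global_adjacency(spec.n),
    )
    return params, random_state(spec.n, spec.seed)


_BUILDERS = {
    "tumor": tumor_scenario,
    "sepsis": sepsis_scenario,
    "custom": custom_scenario,
}


def build_scenario(spec: ScenarioSpec) -> tuple[ModelParams, DuplexState]:
    """Dispatch on ``spec.kind``."""
    return _BUILDERS[spec.kind](spec)
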