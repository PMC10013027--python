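"""Seeded ensembles, (beta, r) regime maps and beta-sweep curves.

Every replicate in an ensemble is a fresh scenario draw from a seed derived
deterministically from ``(base_seed, cell, replicate)`` through
:class:`numpy.random.SeedSequence`, so any single replicate can be replayed
in isolation from its recorded seed.  The headline ensemble statistic is

    s_mu = (1 / N_E) * sum_E sigma_chi(omega_bar_E^mu)

the ensemble mean over the replicates' per-layer dispersions: a pathogenicity
measure for the parenchymal layer (mu = 1) and an activation measure for the
immune layer (mu = 2).  Normalized variants divide each replicate's
dispersion by its layer-mean frequency before averaging.
"""

from __future__ import annotations

import logging
import time as _time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .integrate import Trajectory, integrate
from .measures import LayerSummary, summarize
from .model import NumericalStateError
from .scenarios import ScenarioSpec, build_scenario

__all__ = [
    "ReplicateResult",
    "SweepResult",
    "replicate_seed",
    "run_scenario",
    "run_ensemble",
    "ensemble_frame",
    "ensemble_stats",
    "regime_map",
    "beta_curve",
    "smooth_curve",
]

logger = logging.getLogger("adaplex")

#: Standard integration protocol: step, total time, transient discard.
DEFAULT_DT = 0.05
DEFAULT_T_END = 2000.0
DEFAULT_T_DISCARD = 1000.0


def replicate_seed(base_seed: int, replicate: int, cell: int = 0) -> int:
    """Derive an independent, recordable scenario seed.

    Seeds come from ``SeedSequence((base_seed, cell, replicate))`` reduced to
    a 31-bit integer; distinct (cell, replicate) pairs give independent
    streams and the integer alone suffices to replay the replicate.
    """
    ss = np.random.SeedSequence((int(base_seed), int(cell), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass
class ReplicateResult:
    """Outcome of one scenario draw: seed, per-layer summaries or an error."""

    spec: ScenarioSpec
    seed: int
    summary1: LayerSummary | None = None
    summary2: LayerSummary | None = None
    kappa_abs_max: float = np.nan
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def rows(self) -> list[dict]:
        base = {
            "beta": self.spec.beta,
            "r": self.spec.r,
            "sigma": self.spec.resolved_sigma(),
            "seed": self.seed,
            "error": self.error,
        }
        if not self.ok:
            return [dict(base, layer=layer) for layer in (1, 2)]
        return [dict(base, **s.to_row()) for s in (self.summary1, self.summary2)]


def run_scenario(
    spec: ScenarioSpec,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    t_discard: float = DEFAULT_T_DISCARD,
    record_stride: int | None = None,
    kappa_stride: int | None = None,
    keep_trajectory: bool = False,
    **measure_kwargs,
) -> ReplicateResult | tuple[ReplicateResult, Trajectory]:
    """Build, integrate and measure one scenario.

    The averaging window is ``[t_discard, t_end]``.  By default phases are
    recorded once per time unit (enough for the endpoint-formula measures)
    and coupling matrices only at the start and end of the run; pass explicit
    strides for space-time plots.
    """
    if not 0 <= t_discard < t_end:
        raise ValueError(f"need 0 <= t_discard < t_end, got {t_discard}, {t_end}")
    n_steps = int(round(t_end / dt))
    if record_stride is None:
        record_stride = max(1, int(round(1.0 / dt)))
    if kappa_stride is None:
        kappa_stride = n_steps
    params, state0 = build_scenario(spec)
    t0 = _time.perf_counter()
    traj = integrate(
        state0, params, dt=dt, t_end=t_end,
        record_stride=record_stride, kappa_stride=kappa_stride,
        meta={"scenario": spec.to_dict(), "t_discard": t_discard},
    )
    s1, s2 = summarize(traj, t_start=t_discard, T=t_end - t_discard, **measure_kwargs)
    logger.debug(
        "scenario kind=%s seed=%d beta=%.4f: %.2fs, max|kappa|=%.6f, labels=(%s | %s)",
        spec.kind, spec.seed, spec.beta, _time.perf_counter() - t0,
        traj.kappa_abs_max, s1.label, s2.label,
    )
    result = ReplicateResult(
        spec=spec, seed=spec.seed, summary1=s1, summary2=s2,
        kappa_abs_max=traj.kappa_abs_max,
    )
    if keep_trajectory:
        return result, traj
    return result


def run_ensemble(
    spec: ScenarioSpec,
    n_ensemble: int,
    base_seed: int,
    cell: int = 0,
    **run_kwargs,
) -> list[ReplicateResult]:
    """Integrate and measure ``n_ensemble`` independent scenario draws.

    A replicate whose integration fails (non-finite state, coupling-weight
    bound violation) is recorded with its error message; the ensemble
    continues.
    """
    if n_ensemble < 1:
        raise ValueError(f"n_ensemble must be >= 1, got {n_ensemble}")
    results = []
    for e in range(n_ensemble):
        seed = replicate_seed(base_seed, e, cell=cell)
        rspec = replace(spec, seed=seed)
        try:
            results.append(run_scenario(rspec, **run_kwargs))
        except NumericalStateError as err:
            logger.warning("replicate %d (seed %d) failed: %s", e, seed, err)
            results.append(ReplicateResult(spec=rspec, seed=seed, error=str(err)))
    return results


def ensemble_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    """One row per layer per replicate (the CSV summary-table layout)."""
    rows = [row for res in results for row in res.rows()]
    return pd.DataFrame(rows)


def ensemble_stats(results: list[ReplicateResult]) -> dict:
    """Ensemble means of the dispersion measures.

    Returns ``s1``/``s2`` (means of ``sigma_chi`` per layer over successful
    replicates), their normalized variants, standard errors of the mean, the
    replicate count, and per-layer label counts.  Failed replicates are
    excluded from the averages but counted.
    """
    ok = [r for r in results if r.ok]
    out: dict = {"n_replicates": len(results), "n_ok": len(ok)}
    for layer in (1, 2):
        summaries = [getattr(r, f"summary{layer}") for r in ok]
        chi = np.array([s.sigma_chi for s in summaries])
        chi_norm = np.array([s.sigma_chi_norm for s in summaries])
        key = f"s{layer}"
        if len(chi) == 0:
            out[key] = out[f"{key}_norm"] = out[f"{key}_sem"] = np.nan
            out[f"{key}_norm_sem"] = np.nan
            out[f"labels{layer}"] = {}
            continue
        sem_div = max(1, len(chi) - 1)
        out[key] = float(np.mean(chi))
        out[f"{key}_sem"] = float(np.std(chi, ddof=0) / np.sqrt(sem_div))
        out[f"{key}_norm"] = float(np.mean(chi_norm))
        out[f"{key}_norm_sem"] = float(np.std(chi_norm, ddof=0) / np.sqrt(sem_div))
        labels: dict = {}
        for s in summaries:
            labels[s.label] = labels.get(s.label, 0) + 1
        out[f"labels{layer}"] = labels
    return out


@dataclass
class SweepResult:
    """Parameter-sweep container: per-replicate rows plus per-cell aggregates.

    ``replicates`` has one row per layer per replicate with the sweep
    coordinates attached; ``cells`` has one row per grid cell with the
    ensemble means ``s1``/``s2`` and friends from :func:`ensemble_stats`.
    """

    replicates: pd.DataFrame
    cells: pd.DataFrame
    beta_grid: np.ndarray
    r_grid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def regime_map(
    beta_grid,
    r_grid,
    spec: ScenarioSpec,
    n_ensemble: int,
    base_seed: int,
    **run_kwargs,
) -> SweepResult:
    """Ensemble statistics over the (beta, r) parameter plane.

    Large ``s1`` marks multifrequency clustering of the parenchyma
    (pathological); cells where every replicate failed carry NaN aggregates.
    """
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=np.float64))
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=np.float64))
    if beta_grid.size == 0 or r_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    rep_frames = []
    cell_rows = []
    for ib, beta in enumerate(beta_grid):
        for ir, r in enumerate(r_grid):
            cell = ib * len(r_grid) + ir
            cspec = replace(spec, beta=float(beta), r=float(r))
            results = run_ensemble(cspec, n_ensemble, base_seed, cell=cell, **run_kwargs)
            frame = ensemble_frame(results)
            frame.insert(0, "cell", cell)
            rep_frames.append(frame)
            stats = ensemble_stats(results)
            stats.pop("labels1", None)
            stats.pop("labels2", None)
            cell_rows.append({"cell": cell, "beta": float(beta), "r": float(r), **stats})
    return SweepResult(
        replicates=pd.concat(rep_frames, ignore_index=True),
        cells=pd.DataFrame(cell_rows),
        beta_grid=beta_grid,
        r_grid=r_grid,
        meta={"base_seed": int(base_seed), "n_ensemble": int(n_ensemble)},
    )


def smooth_curve(
    values: np.ndarray, window: int = 11, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay smoothing of a sweep curve (cubic by default).

    The window must be odd and larger than the polynomial order; if it
    exceeds the curve length, smoothing is skipped with a warning and the
    input is returned unchanged.  Edges use scipy's polynomial edge fit.
    """
    values = np.asarray(values, dtype=np.float64)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > len(values):
        warnings.warn(
            f"smoothing window ({window}) exceeds curve length ({len(values)}); "
            "skipping smoothing",
            stacklevel=2,
        )
        return values.copy()
    return savgol_filter(values, window_length=window, polyorder=polyorder, mode="interp")


def beta_curve(
    beta_grid,
    spec: ScenarioSpec,
    n_ensemble: int,
    base_seed: int,
    smooth: bool = True,
    window: int = 11,
    polyorder: int = 3,
    **run_kwargs,
) -> pd.DataFrame:
    """Ensemble-averaged dispersion versus the age parameter beta.

    ``r`` (tumor) or ``sigma`` (sepsis) stay fixed at the values in ``spec``.
    Returns one row per beta with ``s1``/``s2``, their normalized variants
    and standard errors; when ``smooth`` is set and the grid is long enough,
    ``*_smooth`` columns carry the cubic Savitzky-Golay-filtered normalized
    curves.
    """
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=np.float64))
    if beta_grid.size == 0:
        raise ValueError("beta grid must be non-empty")
    if np.any(np.diff(beta_grid) <= 0) and beta_grid.size > 1:
        raise ValueError("beta grid must be strictly increasing")
    sweep = regime_map(beta_grid, [spec.r], spec, n_ensemble, base_seed, **run_kwargs)
    curve = sweep.cells.drop(columns=["cell"]).copy()
    if smooth:
        for col in ("s1", "s2", "s1_norm", "s2_norm"):
            curve[f"{col}_smooth"] = smooth_curve(
                curve[col].to_numpy(), window=window, polyorder=polyorder
            )
    return curve
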