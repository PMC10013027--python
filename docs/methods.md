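# Methods

## Model

`adaplex` integrates a duplex (two-layer multiplex) network of `N` phase
oscillators per layer with adaptive intralayer coupling:

```
φ̇ᵢ¹ = ωᵢ¹ − (1/N) Σ_{j≠i} (aᵢⱼ¹ + κᵢⱼ¹) sin(φᵢ¹ − φⱼ¹ + α) − σ sin(φᵢ¹ − φᵢ²)
φ̇ᵢ² = ω²  − (1/N) Σ_{j≠i} κᵢⱼ² sin(φᵢ² − φⱼ² + α)          − σ sin(φᵢ² − φᵢ¹)
κ̇ᵢⱼ^μ = −ε^μ [ κᵢⱼ^μ + sin(φᵢ^μ − φⱼ^μ − β) ],   κᵢᵢ^μ ≡ 0
```

Layer 1 is the parenchyma (fixed all-to-all binary adjacency `a¹` plus
adaptive weights), layer 2 the immune layer (purely adaptive). The phase
φᵢ^μ abstracts the metabolic activity of cell *i*; κᵢⱼ^μ is the cytokine
activity (information flow) between cells *j* and *i*.

Assumptions worth making explicit:

* **Bracketed adaptation law.** The rate ε^μ multiplies the whole bracket,
  so each weight relaxes toward the fixed point κ* = −sin(Δφ − β) and the
  hypercube [−1, 1] is forward-invariant (at κ = ±1 the flow points
  inward). This is the reading consistent with the stated cytokine-activity
  range κ ∈ [−1, 1]; the alternative reading κ̇ = −εκ + sin(·), whose fixed
  points scale as 1/ε, is available via
  `ModelParams(literal_adaptation=True)` for sensitivity checks, with the
  bound monitor disabled.
* **No self-coupling.** The j = i term is excluded from all sums and
  κᵢᵢ ≡ 0 at all times (a cell does not signal itself). The normalization
  stays 1/N, not 1/(N−1).
* **Unwrapped phases.** Phases live on the real line so the endpoint
  formula for mean phase velocities is exact; wrapping to [0, 2π) happens
  only in display output.
* **No clipping.** κ leaving [−1, 1] by more than an integrator tolerance
  (default 10⁻⁶) raises an integration-failure error rather than being
  repaired silently.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| `n` | oscillators per layer | 200 | – |
| `alpha` | intralayer phase lag (signaling delay) | −0.28π | rad |
| `beta` | adaptation lag ("age parameter") | scenario-specific | rad |
| `eps1`, `eps2` | adaptation rates, parenchyma/immune | 0.03 / 0.3 | 1/time |
| `sigma` | interlayer coupling | 0.3 (tumor), 1.0 (sepsis) | – |
| `omega_h`, `omega2` | healthy/immune natural frequency | 0 (co-rotating frame) | rad/time |
| `omega_p` | pathological natural frequency | 1 | rad/time |
| `r` | pathological fraction (tumor) | scenario input | – |
| `cluster_small` | smaller immune block (sepsis) | 20% of n (40 at n = 200) | nodes |

ε¹ < ε² < 1 encodes slow–fast–faster time scales (cytokine relaxation in
the parenchyma is slower than in the immune layer); violations warn but do
not fail, since only the ordering, not specific values, is part of the
model.

## Integration

Classical fixed-step RK4 (`dt = 0.05`, total time `T_s = 2000`), chosen for
bit-reproducibility; accuracy is verified by step-halving (global error
fits slope 4 ± 0.3). The maximum |κ| after every completed step is tracked
inside the kernel and reported as `kappa_abs_max`. Phases are recorded
every step by default; coupling matrices every 200 steps (they cost
2·N² floats per snapshot). The numerical kernels are numba-jitted with
`fastmath`; each unordered node pair is visited once per evaluation, with
all four required sines derived from sin/cos of the phase difference via
angle-addition identities.

## Measures

* **Mean phase velocity**: endpoint formula over the window
  [t_discard, T_s], defaults 1000/2000 (the first 1000 time units are
  transient: the slow weights need several 1/ε¹ ≈ 33 time-unit periods to
  settle).
* **Dispersion** σ_χ: population (1/N) standard deviation of the mean
  phase velocities; the normalized variant divides by |ω̄| with a guard
  floor of 10⁻⁶ (flagged when it binds — ω̄ can legitimately vanish in the
  co-rotating frame).
* **Frequency clusters**: sort the mean phase velocities and cut at gaps
  larger than `tol = 10⁻²` rad/time (equivalent to single-linkage at that
  threshold). The default sits just above the residual-transient scale
  2π/T ≈ 6·10⁻³ at T = 1000.
* **Classification**: one cluster with order parameter R₁ ≥ 0.99 →
  *in-phase synchronized*; one cluster with R₁ ≤ 0.2 → *splay
  synchronized*; 2 … N/4 clusters → *multifrequency cluster*; more →
  *desynchronized*; a single cluster with intermediate R₁ is reported
  verbatim as *partially coherent* and counted as pathological. The
  0.99/0.2 thresholds are implementation defaults (the regimes are
  described only qualitatively in the literature) and are exposed as
  keyword arguments.
* **Ensemble statistic** s^μ: mean of σ_χ over replicates; standard errors
  use the population standard deviation over replicates divided by
  √(N_E − 1).

## Scenario generators (synthetic data)

The generators *are* the study conditions; no external data exists.

* **tumor**: exactly `R = round(r·N)` (round-half-up) nodes at uniformly
  drawn distinct indices get ω^p; phases i.i.d. Uniform[0, 2π), all
  off-diagonal κ i.i.d. Uniform[−1, 1]. Placement of the pathological
  indices is immaterial under all-to-all coupling.
* **sepsis**: homogeneous frequencies; κ²(0) is the deterministic
  two-block matrix (1 within, 0 between, 0 diagonal) with the smaller
  block of `cluster_small` nodes — 40 at N = 200, kept at 20% of N for
  other sizes; κ¹(0) and phases random as above; σ = 1.
* A master integer seed spawns four independent `SeedSequence` sub-streams
  (phases, κ¹, κ², index selection), so one component's draw count never
  shifts another's stream. Ensemble replicate seeds derive from
  `SeedSequence((base_seed, cell, replicate))`, reduced to 31 bits so they
  can be stored and replayed individually.

What the generators emulate — and what they do not: random initial phases
and cytokine activities stand for an unspecified pre-history of the
tissue; the two-point frequency mixture reduces tumor-cell heterogeneity to
a single metabolic-rate contrast; real parenchyma is not globally coupled,
cytokines are not a single scalar per cell pair, and disease progression
(time-varying r, σ) is not modeled. Passing tests therefore validate the
dynamical mechanism — loss of frequency synchrony under cytokine
adaptation — not any quantitative clinical prediction.

## Multistability and test-scale choices

The model is strongly multistable: in-phase, splay, and multifrequency
states coexist for the same parameters, and which one a run reaches
depends on the random initial condition. Single published space-time
panels are therefore individual realizations, and all regime claims in the
test suite are phrased over seed ensembles (majority or any-occurrence
logic).

The test suite runs scaled-down conditions — N = 50–150 oscillators
depending on how size-sensitive the regime under test is, T_s = 600 with
300 discarded, ensembles of 5–10 — so the whole suite stays desk-scale;
full-scale behavior (N = 200, T_s = 2000, N_E = 50–200) is available
through the same APIs and the CLI. Two size-dependent basin effects are
documented rather than hidden:

* the two-cluster (pathological tumor) state at (β = 0.60π, r = 4%) is a
  minority outcome of the random initial conditions at every size we
  probed — most seeds relax to the fully synchronized state (some split
  transiently and are re-entrained) — and the split is rarer the smaller
  N is;
* splay states, dominant at N = 200 for β ≳ 0.66π, are rare at N = 50 and
  common at N = 150: the in-phase basin shrinks as N grows.

## Numerical choices and degenerate inputs

* `t_end` must be a multiple of `dt`; recording strides must divide the
  places one wants to measure (the measures raise a range error otherwise).
* `t_end = 0` returns a single-record trajectory.
* Non-finite variables abort the run with the offending block and first
  affected time named.
* Savitzky–Golay smoothing of sweep curves is cubic with an 11-point
  default window; windows longer than the curve skip smoothing with a
  warning; edge samples use scipy's polynomial edge fit (`mode="interp"`).
* Ties in the display sort (by mean phase velocity, then wrapped phase)
  keep the original node order (stable sort).

## Known limitations

* Fixed-step RK4 only; no adaptive or stiff integrators, no event
  detection or continuation. The slow–fast structure (ε¹ = 0.03) is mild
  enough that dt = 0.05 is accurate (verified by step halving), but much
  stiffer parameterizations are the user's responsibility.
* The (β, r) regime boundaries are ensemble statements; near the
  boundaries the outcome probabilities shift with N, so scaled-down maps
  are qualitative previews of the full-size maps.
* The normalized dispersion is undefined in frames where ω̄ → 0; the guard
  makes this explicit rather than solving it.
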