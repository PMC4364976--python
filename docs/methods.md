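# Methods

## Compartmental model

Systemic contrast-agent kinetics are a linear two-compartment system:
arterial blood (compartment 1, volume `V1`) receives a zero-order infusion
`R0` on the window `[t0, t1]`, exchanges with a peripheral compartment via
fractional clearances `k12`/`k21`, and eliminates via `k10`.  With
`τ` the apparent elapsed infusion time (0 before arrival at `t0 + tlag`,
capped at `t1 − t0` after the infusion ends), the arterial concentration is
the bi-exponential

    C1(t) = (R0/V1) · Σ_{j=1,2} (1 − e^{λj τ}) (k21 − λj) e^{−λj (t − t0 − tlag)}
                                 / (−λj (λk − λj)),   k ≠ j

where `λ1 ≥ λ2 > 0` are the system eigenvalues.  The `(1 − e^{λτ})` factor
vanishes identically before contrast arrival, so causality holds exactly
without branching.  The infusion ratio `R0/V1` is treated as a single
parameter (mM/min); `t0` and `t1` are protocol inputs and are never fitted.

The extravascular extracellular space (EES) is driven one-way by the
arterial curve, `dCe/dt = k30 (C1 − Ce)`, giving a tri-exponential closed
form with the additional rate `k30`.  Tissue concentration follows the
extended Tofts model `C_T(t) = ve·Ce(t) + vb·C1(t)` with
`Ktrans = k30 · ve`.  `vb` is defined operationally as the coefficient
multiplying the arterial curve in the tissue model; no hematocrit
correction is applied.  The per-voxel lag `tlag` shifts the *entire* input
curve (both the EES and plasma terms), modelling local bolus arrival delay.

Time is in minutes throughout (so `Ktrans` and all rates are min⁻¹);
concentrations are mM.  The CLI accepts a seconds→minutes flag on input.

### Validation oracle

The closed forms are verified against `ode_reference_solution`, a direct
numerical integration of the compartment ODEs (DOP853, rtol 1e-11,
atol 1e-13, integrated piecewise across the input discontinuities).  The
test suite requires agreement to relative error < 1e-6 (relative to the
series peak) on 20 randomly sampled valid parameter sets plus the reference
set; observed agreement is ~1e-12.

### Degenerate rates

The distinct-exponent closed forms are the only ones implemented.  If the
two eigenvalues would coincide (possible only when `k12 ≈ 0` and
`k10 ≈ k21`), `k10` is nudged by +1e-6 relative with a logged warning;
likewise `k30` is nudged away from either eigenvalue when within 1e-8
relative.  Optimizer bounds make exact coincidence measure-zero, so the
confluent analytic limits are deliberately not implemented.

## Bound-constrained Nelder-Mead

Box constraints are enforced by the arcsine transform
`x_u = arcsin(2(x − lb)/(ub − lb) − 1)`; the inverse sine map returns *any*
real vector to the box, so every reported estimate satisfies its bounds by
construction.  Boundary inputs are clamped inward by `1e-12·(ub − lb)`
before the forward transform because `arcsin(±1)` kills the local slope of
the sine map.

Classic coefficients are used (reflection 1, expansion 2, contraction 0.5,
shrink 0.5).  The initial simplex perturbs each unconstrained coordinate of
the start point by +5% of its value, or by +0.00025 where the coordinate is
zero — the widely used seeding recipe.  Vertices are kept sorted by a
stable sort on the objective value (original index breaks ties) so results
are deterministic and backend-independent.  Non-finite objective values are
replaced by +inf (never selected) instead of aborting, because lockstep
batches cannot early-exit a single problem.

Two variants share identical update logic:

* **Serial** — classic branching control flow with conditional termination,
  used for the arterial fit and as the reference implementation.
* **Batched** — a fixed-iteration variant advancing B problems in lockstep.
  Every iteration computes reflection, expansion, both contractions and the
  shrink candidates for *all* problems and blends the accepted update
  through boolean masks; control flow is identical for every problem.
  Given the same initial simplex the two variants produce bit-identical
  vertex sequences (asserted in the tests), so batching is purely a
  restructuring, not an approximation.

**Convergence** is declared when both the function spread
`max_i |f_i − f_best|` *and* the vertex spread (max coordinate deviation
from the best vertex, in unconstrained space) fall below the tolerance
(default 1e-5).  Requiring both is stricter than either alone and never
freezes a voxel early by accident.  The serial variant checks every
iteration; the batched variant evaluates the flag on the final simplex
only.  An optional measurement-only monitor records, per problem, the first
iteration at which the criterion holds — it never alters control flow.

**Two-stage culling:** stage 1 runs a short batched minimisation (default
150 iterations) on all voxels; voxels whose final simplex has collapsed are
frozen (their results pass through bit-identical).  Stage 2 re-minimises
only the remainder (default 200 iterations) from fresh simplices seeded at
the stage-1 best estimates.  If the re-seeding round trip through the
boundary clamp leaves a problem marginally worse, the stage-1 result is
kept, so the best objective value is non-increasing per voxel.

### Initial estimates

The tissue-fit start point defaults to literature-plausible tumor values
(`ve = 0.2`, `k30 = 0.5 min⁻¹`, `vb = 0.05`, `tlag = 0.1 min`) rather than
the bound midpoints.  Midpoints map to exactly 0 in the arcsine space,
where the seeding recipe degenerates to the absolute 0.00025 step and the
simplex needs hundreds of iterations just to grow to the scale of the
search space; a start with non-zero unconstrained coordinates keeps the
seeded simplex responsive.  Arterial initial estimates default to plausible
systemic gadolinium kinetics (`R0/V1 = 10 mM/min`, `k10 = 0.5`,
`k12 = 0.3`, `k21 = 0.15 min⁻¹`, `tlag = 0.1 min`).  All starts, bounds and
iteration settings are configurable and echoed into the run manifest.

### Default bounds

`ve ∈ (1e-3, 1)`, `k30 ∈ (1e-3, 10) min⁻¹`, `vb ∈ (0, 1)`,
`tlag ∈ (0, 2) min` for tissue; for the arterial fit
`R0/V1 ∈ (0.5, 50) mM/min`, `k10, k12, k21 ∈ (0.05 or 0.01, 3) min⁻¹`,
`tlag ∈ (0, 1) min`.  These are physiologic-plausibility boxes, not priors;
estimates hitting a bound are returned as-is (NaN only marks excluded
voxels).

## Pipeline

1. **Arterial fit** — serial Nelder-Mead, 300 iterations, tol 1e-5, over
   `(R0/V1, k10, k12, k21, tlag)` with `t0`, `t1` fixed.
2. **Voxel screening** — exclude voxels with any missing/non-finite frame,
   with all frames negative, or with any frame above
   `factor × max_t C1(t; fitted)` (default factor 2.0: tissue cannot
   physically far exceed the arterial peak, and the fitted curve denoises
   the measured one).  Reason codes use the reporting precedence
   missing > all-negative > over-threshold; the excluded *set* is
   precedence-independent.  Negative but not all-negative series are fitted
   as-is — they are noise around zero.
3. **Tissue fit** — all kept voxels flattened into one batch and minimised
   by the two-stage scheme against the extended Tofts prediction.
4. **Maps and summaries** — `Ktrans = k30·ve` per voxel; medians of `ve`
   and `Ktrans` over non-excluded ROI voxels; percent change
   `100·(post − pre)/pre` between time points; display maps clipped to
   percentiles (default 0th/99th) of the finite values.

Grids are indexed `(row, column)`, 0-based, frame-major last.  NaN is the
sentinel for excluded voxels in memory and on disk (NIfTI-native).  The
output manifest embeds the full configuration and library versions; a run
is a pure function of (slice data, configuration, seed).

## Digital phantom

The generator emulates the per-slice data layout the pipeline consumes.
Defaults: 64×64 grid, 40 frames uniformly covering 8 min, arterial truth
`R0/V1 = 12 mM/min`, `k10 = 0.6`, `k12 = 0.4`, `k21 = 0.2 min⁻¹`,
infusion `t0 = 0.2 → t1 = 0.7 min`, systemic lag 0.05 min (arterial peak
≈ 4 mM, a realistic gadolinium bolus).  Truth fields span plausible
tumor/brain values — `ve` 0.05–0.45 (radial gradient), `k30` 0.1–2 min⁻¹
(horizontal), `vb` 0–0.1 (vertical), `tlag` 0–0.3 min (diagonal) — with a
disc ROI and additive Gaussian concentration noise (sd 0.02 mM).  Noise is
applied to concentrations, not MR signal: the package operates downstream
of signal-to-concentration conversion.  Each voxel's noise stream is seeded
from `(seed, voxel index)` so neither corruption nor evaluation order can
change the data; output is bit-identical under a fixed seed.  Requested
numbers of voxels are corrupted to trip each screening rule exactly
(a NaN frame; an all-negative series; a frame at 10× the arterial peak).

What the phantom does *not* emulate: anatomy, partial-volume and motion
effects, coil inhomogeneity, Rician signal statistics, temporal
autocorrelation of noise, or arterial input functions measured in a real
artery.  Passing tests therefore demonstrate algorithmic correctness and
self-consistency, not clinical accuracy on scanner data.

## Problem sizes and observed behaviour

The test suite exercises the full pipeline at 8×8–16×16 and the acceptance
checks at the stock 64×64 (one batched fit ≈ 30 s, the serial reference
≈ 3 min on one CPU core).  On the noise-free 64×64 phantom the arterial
parameters are recovered to ~1e-6 relative and ≥95% of voxels recover `ve`
and `Ktrans` within 5%; ROI medians land within fractions of a percent.

## Known limitations

* **Identifiability ridge.**  When `k30` is large the EES curve tracks the
  plasma curve closely, so `ve`, `vb` and `tlag` become nearly collinear at
  coarse temporal sampling (12 s frames).  With measurement noise the
  least-squares surface then has an almost flat valley: estimates with
  objective values agreeing to ~1e-8 can differ by tens of percent in `vb`
  or `tlag`.  Two equally correct optimizers — or the same optimizer from
  two starts — may halt at different points on that valley.  Agreement
  between the batched and serial variants is therefore limited by the data,
  not the lockstep restructuring: on the stock noisy phantom ~85% of voxels
  agree on all four parameters within 5%, while the disagreeing remainder
  sits on such valleys (their objective values match to ~1e-8, and `ve` and
  `k30` individually agree on ~98–99% of voxels).  When comparing
  parameters, values collapsed onto a zero bound are compared with
  `np.isclose` semantics (rtol 0.05, atol 1e-8) since pure relative
  difference is undefined at zero.
* **Convergence pace.**  With the 5%/0.00025 simplex seeding and the
  strict dual-spread criterion at 1e-5, voxels carrying real signal
  typically need 100–250 iterations to collapse; early convergence
  (< 100 iterations) is common only for voxels whose data are nearly
  flat, which the stock phantom deliberately lacks.
* Confluent (repeated-eigenvalue) analytic forms, non-Tofts models,
  T1/signal conversion, DICOM ingestion and motion correction are out of
  scope.
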