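# dcefit

Voxel-wise pharmacokinetic analysis of dynamic contrast-enhanced MRI
(DCE-MRI) slices with the extended Tofts model, built around a
bound-constrained, branch-free, *batched* Nelder-Mead minimiser.

## Who this is for

DCE-MRI quantifies tumor microvasculature by following a gadolinium
contrast agent through blood and tissue.  Fitting a compartmental model to
every voxel of a slice yields parametric maps of the fractional interstitial
volume `v_e` (unitless) and the volume transfer coefficient
`K^trans` (min⁻¹) — the two parameters most used to assess antivascular
therapy response.  Doing this voxel by voxel means tens of thousands of
derivative-free minimisations per slice; `dcefit` restructures that workload
so every voxel's simplex advances in lockstep through identical, branch-free
array operations — the shape of computation that vectorises on CPUs and maps
directly onto GPU-style backends.

## The model

Arterial blood (compartment 1) follows a linear two-compartment system
driven by a zero-order infusion on `[t0, t1]`; its concentration `C1(t)` is
bi-exponential with rates `λ1, λ2` — the eigenvalues
`λ_{1,2} = ½[(k10+k12+k21) ± √((k10+k12+k21)² − 4 k10 k21)]`.
Tissue follows the extended Tofts model

    C_tissue(t) = v_e · C_e(t) + v_b · C_p(t),      K^trans = k30 · v_e

where the extravascular extracellular space (EES) concentration `C_e`
satisfies `dC_e/dt = k30 (C_p − C_e)` and the plasma term `C_p` is taken
equal to `C1`.  Both closed forms are validated in the test suite against an
independent high-accuracy ODE integration (relative error < 1e-6).

Fits minimise the least-squares objective `f(p) = Σᵢ (cᵢ − ĉᵢ(p))²` under
box constraints enforced by an arcsine change of variables
`x_u = arcsin(2(x − lb)/(ub − lb) − 1)`, so any unconstrained simplex move
maps back inside the bounds — by construction, not by clipping.

A slice is processed in four steps: (1) serial Nelder-Mead fit of the
arterial curve (300 iterations, tolerance 1e-5); (2) voxel screening
(missing values, all-negative series, values above a multiple of the fitted
arterial peak); (3) two-stage batched fitting of all kept voxels (150
iterations on everything, then 200 more on the voxels whose simplex has not
collapsed, restarted from their stage-1 best estimates); (4) `K^trans`
derivation, ROI medians and display clipping.

## Worked example

Generate a 32×32 synthetic slice with known ground truth, then fit it:

```bash
$ dcefit make-phantom --out phantom --nx 32 --ny 32 --noise-sd 0.02
phantom written to phantom (32x32, 40 frames)

$ dcefit fit-slice --ct phantom/ct.nii.gz --roi phantom/roi.nii.gz \
                   --cv phantom/cv.csv --out fit
median ve=0.1789, median Ktrans=0.2316 /min over 69 ROI voxels
outputs in fit (9 files)
```

The phantom's true ROI medians are `v_e = 0.1771` and
`K^trans = 0.2337 min⁻¹`: with 0.02 mM concentration noise per frame the
fitted medians land within about 1% of truth.  `fit/` contains one NIfTI
per parameter map (`ve`, `k30`, `vb`, `tlag`, `ktrans`, `sse`), convergence
and exclusion-reason maps, heat-map PNGs, the ROI summary CSV and a JSON
manifest embedding the full configuration.

Comparing two time points prints the percent change in the ROI medians:

```bash
$ dcefit compare --pre pre.csv --post post.csv
median_ve: 0.242 -> 0.103 (-57.4%)
median_ktrans: 0.106 -> 0.0943 (-11.0%)
```

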