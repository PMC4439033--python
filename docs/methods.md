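# Methods

## Model

The package studies patch-occupancy dynamics on a fragmented landscape: `N`
habitat patches at positions `x_i` in `[0, L]^d`, each with a value
`A_i > 0` drawn i.i.d. with mean 1 and variance `σ²`. The exact dynamics is
a continuous-time Markov process on the 2^N occupancy configurations:
occupied patch `i` empties at rate `δ_i = δ/A_i`, and empty patch `i` is
colonized at rate `Σ_{j occupied} D_ij`, with
`D_ij = A_j f(|x_i − x_j|/ξ)`. Global extinction is the unique absorbing
state; supercritical systems spend a long time in a quasi-stationary state
before absorption, and that metastable state is the object of interest.

Closing the exact moment hierarchy under independence
(`E[S_i S_j] ≈ E[S_i]E[S_j]`) gives the mean-field system

    dp_i/dt = (1 − p_i) (D p)_i − δ_i p_i .

Because pairwise occupancy correlations in the exact process are
nonnegative, the closure overestimates occupancy; its persistence verdict
is therefore a conservative warning when it predicts extinction, and the
package's stochastic simulator exists to quantify the gap.

Persistence is spectral: with the symmetric dispersal matrix
`M_ij = A_i A_j f(|x_i − x_j|/ξ)` (zero diagonal), the Jacobian of the mean
field at the extinction state factorizes as `A^{-1}(M − δI)` with
`A = diag(A_i)`, which is similar to the symmetric
`A^{-1/2}(M − δI)A^{-1/2}` and hence shares its inertia. The extinct state
is unstable — and a unique positive stable equilibrium exists — exactly
when the leading eigenvalue λ of `M` (the metapopulation capacity) exceeds
δ. The package verifies this equivalence numerically by bisecting δ on the
positivity of the solved equilibrium and comparing with λ.

For uniform-random landscapes λ concentrates around the expected kernel row
sum, the *effective neighbor* number. Two estimators are provided:

- the asymptotic plug-in `n_e = (N/L^d) G_f(d) ξ^d`, with
  `G_f(d) = S_{d−1} ∫ x^{d−1} f(x) dx` the kernel mass (closed forms:
  Gaussian `(2π)^{d/2}`, rectangular the unit-ball volume, exponential
  `S_{d−1} Γ(d)`); valid for `ξ ≪ L`;
- a finite-box Monte Carlo estimator, `(N−1)·E[f(|x−y|/ξ)]` over uniform
  point pairs in the box, which retains the hard-edge deficit. At the
  dispersal lengths needed to reach `n_e ≈ 40` with `N ≤ 1000` in `d = 2`
  (`L/ξ ≈ 6–9`) the asymptotic formula overestimates the true expectation
  by 10–25%, so the collapse experiment and any quantitative comparison of
  λ against `n_e` use the Monte Carlo estimator; the plug-in is used for
  tuning ξ to a nominal target and for the analytic persistence criterion
  `n_e(1+σ²) > δ`, whose direction (a lower bound on λ via the Rayleigh
  quotient with trial vector `A`) is what makes it conservative.

## Kernels

All kernels are unit-scale in the scaled distance `x = r/ξ` — any other
scale constant would be absorbable into ξ: rectangular `1{x<1}` (with the
open-interval convention `f(1)=0`, a measure-zero choice for continuous
landscapes), Gaussian `exp(−x²/2)` (the scale fixed by the printed
`G_f(d) = (2π)^{d/2}`), exponential `exp(−x)`, and a hump-shaped "ring"
kernel `exp(−(x−μ)²/(2s²))` for dispersal that peaks at an intermediate
distance (fruiting/wind strategies, Janzen–Connell-type suppression near
the parent). Kernel masses use closed forms where available and adaptive
radial quadrature (relative tolerance 1e−8, truncation where analytic tail
bounds put the remainder below 1e−12) otherwise; the two routes agree to
1e−6 relative in the tests.

## Landscape generators

Positions and values come from separate child streams of one seed
(`numpy` `SeedSequence.spawn`), so changing σ² never moves the patches —
this enables exactly position-matched comparisons across value
distributions.

Patch values: lognormal (default; positive for any σ²), gamma, shifted
uniform (requires σ² < 1/3 for positivity), or degenerate (σ² = 0), all
two-moment matched to mean 1 and variance σ². The *choice of family
matters* beyond its first two moments: heavy-tailed values (lognormal at
σ² = 1) localize the leading eigenvector onto extreme-value patches and
lift λ far above `n_e(1+σ²)` at any N up to 5000, so the capacity collapse
is demonstrated with the bounded uniform family (σ² ≤ 0.25); with
heavy-tailed values only the bound direction `λ ≥ n_e(1+σ²)` survives.

The grid arrangement places `m^d` patches at cell centers `(i+½)L/m`, so a
periodic (torus) boundary has exactly equal nearest-neighbor spacings and
all dispersal-matrix row sums coincide — making λ equal the common row sum,
the degenerate baseline against which disorder is measured.

The jiggled arrangement interpolates from grid to disorder *cell-locally*:
`x_i = grid_i + η·u_i` with `u_i` uniform on `[−L/2m, L/2m]^d`. η = 0 is
the exact grid; η = 1 is stratified-uniform sampling (one patch per cell),
which has exactly uniform marginals on `[0, L]`. A global interpolation
toward one i.i.d.-uniform draw was tried first and rejected: its O(L)
displacements pull patches toward the box center, raising local density and
making λ non-monotone in η (it overshoots the fully random value at
η ≈ 0.5), which contradicts the behavior the sweep is meant to exhibit.
The cost of the cell-local scheme is that η = 1 is stratified rather than
i.i.d.; grid-vs-random comparisons therefore always use the i.i.d. random
generator for the random arm.

## Spectral computations

Distances use the minimum-image convention under periodic boundaries.
The leading eigenpair is computed densely (LAPACK `syevr`) up to n = 400
and by Lanczos (ARPACK, `which="LA"`) above, with a dense fallback on
non-convergence; either path must satisfy `‖Mw − λw‖/λ < 1e−10`. The
eigenvector is flipped to its nonnegative (Perron) orientation and
rounding-level negatives are zeroed; exact zeros are legitimate for
disconnected components (rectangular kernels at small ξ), where λ is the
maximum over components.

Patch importance: removing patch `i` drops λ by approximately `w_i² λ`
(first-order perturbation). Exact drops cost one eigensolve of each
`(n−1)×(n−1)` principal submatrix and are computed by default up to
n = 1000; beyond that only the `w_i²` approximation is returned unless
requested.

Localization is summarized by the normalized inverse participation ratio
`Ψ = (N Σ w_i⁴ − 1)/(N − 1)`, the unique affine function of `Σ w_i⁴` that
is 0 for a uniform eigenvector and 1 for a single-patch one. Its scale
should be read with the cluster picture in mind: if the eigenvector spreads
over a k-patch cluster, Ψ ≈ 1/k, so even strongly localized landscapes
(`n_e ≈ 1`, k ≈ 6) give Ψ ≈ 0.15–0.2, and Ψ > 0.3 indicates very small
sustaining clusters (`n_e ≲ 0.25`). In the delocalized regime Ψ is
dominated by density fluctuations (roughly `c/n_e`) rather than the
GOE-like `2/N` floor.

## Dynamics

The mean-field ODE is integrated with LSODA (default `rtol 1e−8`,
`atol 1e−10`); the `[0,1]^n` box is forward-invariant for the exact flow,
and the right-hand side clips rounding-level excursions.

Equilibria are found by iterating `p ← (Dp)/((Dp) + δ_vec)` from `p = 1`,
which descends monotonically to the maximal equilibrium of this cooperative
system; because the map is also concave with `T(0)=0`, the positive fixed
point (when it exists) is unique and globally attracting from positive
starts. Near the threshold the plain iteration slows critically (geometric
rate `1 − O(|λ−δ|/λ)`), so every 25 steps a component-wise Aitken
extrapolation jumps to the geometric limit; the extrapolated point is kept
only if it reduces the fixed-point residual (Steffensen restart) and
convergence is declared only from the residual itself. Persistence is
declared at mean occupancy > 1e−8. The bisection threshold finder brackets
with the row-sum bounds of `M`, resolves to 0.1% of the mean row sum, and
runs its internal solves at tolerance 1e−10 — misclassification is then
only possible within ~1e−4·λ of the true threshold, well inside the
bracketing resolution.

The stochastic simulator is an exact event-driven implementation: it keeps
the per-patch colonization pressure `D·s` (s the occupancy indicator)
incrementally up to date — one column of `D` per event, refreshed in full
every 20k events to cancel accumulated rounding — and samples the next
event from the exact exponential clock over all extinction and colonization
rates. No rate cutoff is applied, so the simulation is exact for every
kernel. Quasi-stationary occupancy is estimated by the simplest
survival-conditioned time average: runs alive at their horizon contribute
their post-burn-in (default `10/δ`) time-averaged occupancy; replicate
spread gives the standard error. This estimator is mildly biased relative
to Fleming–Viot-style resampling when extinction during the window is
non-negligible, which is why comparisons against the mean field are made
in clearly supercritical settings (λ/δ ≈ 3). For all-to-all couplings the
occupancy count is a birth–death chain whose quasi-stationary law is
computable by linear algebra on the transient generator; the tests use this
as an independent oracle for the simulator.

## Experiments and seeding

Each experiment row carries its full condition and seed. Replicate seeds
derive from `SeedSequence(root_seed, spawn_key=(crc32(condition), rep))`,
so subsetting or reordering a grid never changes any per-condition result,
and an η sweep reuses the same seed across η within a replicate — a
common-random-numbers path whose η = 0 row equals the grid result exactly.
Dense-eigensolve landscapes are capped at N = 5000.

Problem sizes in the test suite and acceptance script (N up to 1000 for the
collapse grid, N = 400 for exact removal scans, N = 2000 patches at most
for spectral checks, 100–200 stochastic runs) were chosen so the full suite
documents each claim at replicate counts where the medians are stable to
the asserted margins.

## What the synthetic landscapes do and do not show

The generators emulate the idealized study system: uniform (or grid-based)
patch positions, i.i.d. patch values, isotropic kernels, hard or periodic
boxes. Passing tests therefore demonstrate the internal consistency of the
theory — the spectral persistence condition, the `n_e(1+σ²)` collapse, the
grid/random ordering, localization — under those assumptions. They say
nothing about spatially correlated patch values, non-uniform position
densities (riverine or clustered habitats), anisotropic dispersal, or
within-patch demography, all of which are out of scope; for empirical
landscapes the framework serves as the null model against which such
structure can be detected.

## Known limitations

- The exact-removal scan is O(n) dense eigensolves; keep n ≤ 500 in sweeps.
- The quasi-stationary estimator conditions on survival only; near the
  threshold (λ/δ ≲ 1.5) it carries relaxation and selection bias.
- The analytic `n_e` criterion inherits the `L ≫ ξ` assumption; with
  `L < 10ξ` a warning is raised and the finite-box Monte Carlo estimator
  should be preferred.
- With heavy-tailed patch values the capacity is driven by extremes and
  concentrates slowly; replicate medians, not means, are reported in the
  sweep tables' summaries for that reason.
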