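# metacap

Metapopulation persistence in random fragmented landscapes — a library and
CLI for ecologists and epidemiologists who want to know whether a species
(or an epidemic, in the equivalent SIS reading) can persist on a network of
habitat patches coupled by distance-dependent dispersal.

## The model

`N` patches live in a d-dimensional cube of side `L`. Patch `i` has a
position `x_i` and a value `A_i > 0` (e.g. carrying capacity), drawn i.i.d.
with mean 1 and variance `σ²`. An occupied patch goes extinct at rate
`δ_i = δ/A_i`; an empty patch `i` is colonized by occupied patch `j` at rate
`D_ij = A_j f(|x_i − x_j|/ξ)`, where `f` is a dispersal kernel (rectangular,
Gaussian, exponential, or a hump-shaped "ring") and `ξ` the dispersal
length. Closing the exact 2^N-state Markov process under independence gives
the Hanski–Ovaskainen / NIMFA mean field

    dp_i/dt = (1 − p_i) Σ_{j≠i} A_j f(|x_i − x_j|/ξ) p_j − (δ/A_i) p_i .

Everything about persistence is encoded in the symmetric dispersal matrix
`M_ij = A_i A_j f(|x_i − x_j|/ξ)` (zero diagonal): the metapopulation
persists iff its leading eigenvalue λ — the **metapopulation capacity** —
exceeds δ. For random landscapes λ is governed by the **effective
neighbors** `n_e = (N/L^d) G_f(d) ξ^d`, with `G_f(d)` the kernel's integral
over d-space, giving the analytic, conservative persistence criterion

    n_e (1 + σ²) > δ .

The leading eigenvector `w` ranks patch importance (removing patch `i`
lowers λ by ≈ `w_i² λ`), and its inverse-participation statistic
`Ψ = (N Σ w_i⁴ − 1)/(N − 1)` detects the localized regime in which a small
spatial cluster of patches sustains the whole metapopulation.

The package provides:

- `landscape` — random / grid / cell-jiggled landscape generators with
  seeded, reproducible sub-streams, plus TSV (de)serialization;
- `kernels` — kernel evaluation, closed-form and quadrature kernel masses
  `G_f(d)`, analytic and finite-box Monte Carlo `n_e`;
- `spectral` — dispersal matrices (hard or periodic boundaries), λ and `w`,
  patch-removal impacts, Ψ;
- `dynamics` — mean-field ODE integration, an accelerated fixed-point
  equilibrium solver, bisection persistence thresholds, and an exact
  event-driven (Gillespie) simulator of the stochastic contact process with
  quasi-stationary estimators;
- `experiments` — replicated, seed-stable parameter sweeps (capacity
  collapse, grid vs random, η sweep, localization scan, removal ranking)
  returning tidy `pandas` tables, plus a one-shot persistence report.

## Worked example

```python
import metacap as mc

land = mc.generate_random_landscape(
    500, 2, 1.0, mc.ValueDistribution("uniform", 0.25), seed=42
)
kern = mc.KernelSpec("gaussian", dispersal_length=0.05)
dm = mc.build_dispersal_matrix(land, kern, delta=4.0)

spec = mc.metapopulation_capacity(dm)
eq = mc.solve_equilibrium(dm)
ne = mc.effective_neighbors_analytic(500, 2, 1.0, kern)

print(f"capacity lambda     = {spec.capacity:.3f}")
print(f"mean row sum        = {spec.mean_row_sum:.3f}")
print(f"analytic n_e        = {ne:.3f}")
print(f"criterion n_e(1+s2) = {ne * 1.25:.3f}  vs delta = 4.0")
print(f"psi (localization)  = {spec.psi:.4f}")
print(f"mean occupancy      = {eq.mean_occupancy:.3f}  persistent = {eq.persistent}")
```

prints

```
capacity lambda     = 16.848
mean row sum        = 7.772
analytic n_e        = 7.854
criterion n_e(1+s2) = 9.817  vs delta = 4.0
psi (localization)  = 0.0769
mean occupancy      = 0.448  persistent = True
```

The capacity λ = 16.8 respects its exact lower bound (the mean row sum,
7.77); with only ~8 effective neighbors the landscape sits near the
localized side of the spectrum, so λ noticeably exceeds the analytic
plug-in `n_e(1+σ²)` = 9.8 and Ψ is already a bit above zero. δ = 4 lies
below both verdicts' thresholds — the conservative analytic criterion and
the spectral one agree the metapopulation persists — and the mean field
settles at 45% patch occupancy.

The same analyses are available from the shell:

```sh
metacap landscape --n 500 --dim 2 --sigma2 0.5 --seed 42 --out land.tsv
metacap capacity --landscape land.tsv --kernel gaussian --xi 0.05 --delta 4.0
metacap dynamics --landscape land.tsv --kernel gaussian --xi 0.05 --delta 4.0 \
    --stochastic --runs 50 --t-end 20 --seed 1
metacap experiment --config config.json --out results.csv
```

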