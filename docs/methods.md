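# Methods

## Autocorrelation models

The package evaluates three stationary-diffusion FCS models on arbitrary
lag grids (lags and diffusion times in ms):

* **Single species, 2D** — `G(τ) = (1/N)(1 + τ/τ_D)⁻¹`. This is the
  correct limit for elongated confocal spots (w_z ≫ w_xy), where axial
  diffusion never decorrelates the signal inside the accessible lag
  range.
* **Single species, 3D** — the 2D form times `(1 + τ/(A²τ_D))^(-1/2)`
  with structure parameter A = w_z/w_xy (A > 1). The 3D model converges
  to the 2D model uniformly on any bounded lag grid as A → ∞, which the
  property tests verify.
* **Two species, equal brightness** —
  `G(τ) = [N₁g₁(τ) + N₂g₂(τ)]/(N₁+N₂)²` with gᵢ the kernel without its
  1/N prefactor. Among equal-brightness conventions this normalization is
  the unique one that collapses exactly to the single-species model when
  τ_D1 = τ_D2, which we treat as a defining (and tested) requirement.
  Equal brightness is appropriate for trace labeling: with a few nM
  labeled molecules in a large unlabeled excess, doubly labeled dimers
  are vanishingly rare, so monomers and dimers carry one fluorophore
  each.

Triplet/photophysics corrections, flow and anomalous diffusion are out of
scope. Some hardware correlators normalize to 1 + 1/N rather than 1/N;
an optional constant-baseline fit parameter (`fit_baseline=True`) absorbs
that convention.

## Fitting

`fit_curve` minimizes unweighted residuals (weights 1/sd² on request) with
lmfit's bounded trust-region least-squares driver, relative step/gradient
tolerances 1e-8, and a function-evaluation cap equivalent to 500
iterations. Defaults: fit range 1e-2–1e3 ms (trims correlator artifacts
at the extremes; configurable, `fit_range=None` keeps every lag); bounds
N ∈ (1e-3, 1e6), τ_D ∈ (1e-4, 1e5) ms; starting values from a
half-amplitude heuristic (N₀ = 1/G(first lag), τ_D0 = the interpolated
lag where G falls to half of its first value — exact for the 2D model
when the grid starts well below τ_D). Non-convergence is reported through
`converged=False`, never an exception; constant curves are rejected
before optimization. Two-species fits are label-symmetric, so results are
canonicalized with species sorted by ascending τ_D.

The model-robustness refit (`refit_3d_fixed_a`) repeats a converged 2D
fit with the 3D model at a frozen A (default 7, typical for single-photon
excitation). On pure 2D curves spanning the default grid this raises τ_D
by ~3%, and by dimensional analysis the shift depends only on A and the
grid-to-τ_D ratio — both properties are tested.

## Calibration and hydrodynamics

Lateral diffusion links time and coefficient through τ_D = ω²/(4D).
A built-in rhodamine 6G entry (D = 4.14·10⁻⁶ cm²/s; measured τ_D
0.38 ms) calibrates ω ≈ 793 nm; users supply their own instrument's
measured τ_D for any other setup. Public units are ms, nm and cm²/s with
SI internally; the unit conversions are pinned by hand-computed constants
in the tests.

Globular proteins are modelled as hydrated spheres: anhydrous volume
M·v̄/N_A, hydration h g/g of water at 1 cm³/g, Stokes–Einstein
D = k_BT/(6πηr). Defaults — T = 298.15 K, η = 8.9·10⁻⁴ Pa·s,
v̄ = 0.73 cm³/g, h = 0.3 g/g — are standard biophysical values; with them
a 99-kDa polymerase on a 780-nm spot predicts τ_D ≈ 2.1 ms, inside the
2–3 ms window expected for a protein of that size. Short duplex DNA does
not behave as a compact sphere, so its τ_D is scaled empirically from an
anchor measurement with τ_D ∝ bp^0.72. That flexible-chain exponent
under-predicts the ~15 ms a 452-bp template shows experimentally
(scaling a 70-bp/2.4-ms anchor gives ≈9.2 ms): short DNA in this length
range behaves more rod-like than the exponent assumes. The
detection-limit stage therefore consumes the dimer τ_D as a stated
constant (default 15 ms, the slowest component any dimer must contain)
rather than re-deriving it.

The non-interacting window for a complex of independently measured parts
is [max of component τ_Ds, sum of component τ_Ds]: a complex cannot
out-diffuse its largest part, and the sum is a conservative ceiling for a
compact assembly.

## Monomer–dimer equilibrium and the detection limit

For 2M ⇌ M₂ with K_d = [M]²/[M₂] and total molecules C = [M] + 2[M₂],
the free monomer is the positive quadratic root
m = (−K_d + √(K_d² + 8K_dC))/4. The fraction reported downstream is the
fraction of *molecules* in dimers, 2[M₂]/C — under trace labeling this is
the probability that a labeled complex sits in a dimer, i.e. the slow
number fraction an FCS mixture model needs. At C = 0.54 µM and
K_d = 1 µM this gives 39.5% ("~40% dimers / ~60% monomers"). An
alternative convention, treating the label as an infinitely dilute
partner of the unlabeled monomer pool (bound fraction m/(K_d+m) ≈ 0.25
at the same inputs), is provided as `trace_bound_fraction` but is not the
default, since only the molecules-in-dimers convention matches the 60/40
split that defines the scenario.

The detection limit composes equilibrium → two-species curve →
misspecified single-species fit. At the default scenario (0.54 µM,
K_d = 1 µM, 4 ms monomer, 15 ms dimer) the apparent τ_D is ≈6.9 ms; with
the fractions rounded to exactly 0.60/0.40 it is ≈6.93 ms. The apparent
value is fit-range dependent at the several-percent level, which is why
downstream comparisons carry a ±1 ms allowance. A Kd sweep flags a
scenario "distinguishable" when |apparent τ_D − measured τ_D| exceeds
3 measured standard deviations; the 3σ threshold is a package choice
(configurable) for an otherwise qualitative "clearly distinguishable"
criterion. Apparent τ_D is continuous, monotone decreasing in K_d and
bounded by the two species' τ_Ds (tested).

## 3C quantification

Band intensity factorizes as
`intensity = primer efficiency × ligation frequency × per-sample scale`.
The within-sample test-gene contact frequency (test pair / control pair,
ratio of replicate means at the reference template mass) cancels the
per-sample scale; the between-condition ratio of contact frequencies
cancels the primer efficiencies too, leaving the pure change in
interaction frequency. Both cancellations are exact for any positive
multipliers and are enforced as metamorphic tests at 1e-12. Uncertainty
is first-order propagation of replicate standard deviations; replicate
aggregation is ratio-of-means, matching triplicate-PCR densitometry
(mean-of-ratios differs only at second order in the noise for these CVs).
Dilution-series linearity is checked by ordinary least squares of
intensity on template mass (pass: r² ≥ 0.95 and intercept within 10% of
the fitted top-of-series intensity — both configurable), and digestion
efficiency is 1 − (cut-site ratio digested)/(cut-site ratio undigested),
clamped to [0, 1] with a warning.

## Synthetic data

`gen_curve` adds independent zero-mean Gaussian noise to the analytic
model with per-lag SD σ(τ) = σ₀·G(0)·(τ/τ_first)^(−p), defaults
σ₀ = 0.5% of G(0) and p = 0.25 (noise decays mildly toward long lags in
absolute terms while growing relative to G). This emulates the
magnitude, not the mechanism, of correlator noise from a ~10-s trace: it
is not a photon-level simulation and omits the inter-channel correlations
a multiple-tau correlator produces, so parameter-recovery results here
demonstrate estimator correctness, not instrument-grade error bars.
`gen_band_table` draws unit-mean lognormal multiplicative noise
(CV configurable, default replicates 3, matching triplicate PCR) on top of
the exact factorized intensity model, so the true interaction ratio is
recovered in expectation — verified to |mean log-ratio bias| < 0.01 over
1000 seeded tables. Both generators are pure functions of their arguments
including the seed.

## Interface

A strict-keyed YAML config drives `run_pipeline`, which executes stages in
dependency order, logs each stage's inputs and headline outputs, and
writes artifacts plus the fully resolved config and `results.json` to the
output directory; CLI flags override config values. Unknown config keys
(top-level, block, or stage names) are rejected. Two runs with identical
config and seed produce byte-identical numeric outputs (tested). Curve
and band-table files are delimited text written at 17 significant digits
and re-read with round-trip float parsing, so write∘read is bit-exact.

## Problem sizes

Tests and the acceptance script run on 200-point lag grids, ≤100-seed
Monte-Carlo batches for curve recovery and 200–1000 synthetic gel tables;
these sizes give the stated tolerances comfortable margins while keeping
the whole suite in a few seconds.

## Known limitations

* No triplet, flow, anomalous-diffusion or dual-color cross-correlation
  terms; no maximum-entropy τ_D distributions or global multi-curve fits.
* The DNA scaling law is a one-parameter empirical stopgap; worm-like
  chain hydrodynamics are out of scope.
* Higher-order oligomers and binding kinetics are not modelled.
* Densitometry (gel image → intensity) is upstream of this package; band
  intensities enter as numbers.
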