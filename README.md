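# fcs3c

Quantitative tools for deciding whether a polymerase (or any other
macromolecular complex) self-associates in solution and in vivo, built
around two assays:

* **Fluorescence correlation spectroscopy (FCS).** Labeled complexes
  diffusing through a confocal spot produce an intensity autocorrelation
  G(τ) whose amplitude encodes the mean occupancy *N* and whose decay
  encodes the diffusion time τ_D. Oligomerization slows diffusion, so a
  measured τ_D close to the monomer prediction bounds how tight any
  dimerization can be.
* **Chromosome conformation capture (3C).** The ligation frequency of two
  restriction fragments, read out as PCR band intensities, reports how
  often two genomic loci touch in vivo; a ratio-of-ratios normalization
  cancels primer efficiencies and per-sample 3C efficiency.

The package provides the analytic autocorrelation models, least-squares
fitting, confocal-volume calibration, hydrodynamic τ_D prediction, the
closed-form monomer–dimer equilibrium, the detection-limit construction
that ties them together, the 3C normalization algebra, and seeded
synthetic-data generators for all of it.

## Models

For an elongated confocal spot (w_z ≫ w_xy) the single-species 2D model is

    G(τ) = (1/N) · (1 + τ/τ_D)⁻¹

the full 3D model multiplies in `(1 + τ/(A²τ_D))^(-1/2)` with structure
parameter A = w_z/w_xy, and a mixture of two equally bright species is

    G(τ) = [N₁ g₁(τ) + N₂ g₂(τ)] / (N₁ + N₂)²,   gᵢ(τ) = (1 + τ/τ_Dᵢ)⁻¹

Calibration against a reference dye of known diffusion coefficient uses
τ_D = ω²/(4D). The monomer–dimer equilibrium 2M ⇌ M₂ with
K_d = [M]²/[M₂] is solved in closed form, and the detection limit for
dimerization is obtained by fitting the *predicted* mixture curve with the
(misspecified) single-species model and asking when the apparent τ_D
becomes distinguishable from the measurement.

## Worked example

```python
import numpy as np
from fcs3c import (
    ReferenceDye, beam_radius_from_reference, solve_monomer_dimer,
    DetectionScenario, apparent_tau_d_at_kd, protein_tau_d, ConfocalGeometry,
)

# 1. Calibrate the spot with rhodamine 6G (D = 4.14e-6 cm^2/s, tau_D = 0.38 ms)
omega = beam_radius_from_reference(ReferenceDye("r6g", d=4.14e-6, tau_d=0.38))
print(f"omega = {omega:.0f} nm")                 # omega = 793 nm

# 2. How big a 99-kDa globular protein looks on this spot
tau = protein_tau_d(99.0, ConfocalGeometry(omega=780.0))
print(f"protein tau_D = {tau:.2f} ms")           # protein tau_D = 2.13 ms

# 3. If complexes at 0.54 uM dimerized with Kd = 1 uM ...
eq = solve_monomer_dimer(0.54, 1.0)
print(f"{100*eq.frac_molecules_in_dimers:.1f}% of molecules in dimers")  # 39.5%

# 4. ... the assay would report an apparent tau_D of ~6-7 ms, far above
#    the ~4 ms a monomer shows, so such a Kd is excluded.
res = apparent_tau_d_at_kd(DetectionScenario())
print(f"apparent tau_D = {res.params['tau_d']:.2f} ms")  # apparent tau_D = 6.89 ms
```

The numbers read: a 793-nm spot; a free 99-kDa globular protein dwells
~2.1 ms; at K_d = 1 µM nearly 40% of molecules would sit in dimers,
pushing the single-species readout to ~6.9 ms — clearly separated from a
measured 4.2 ± 0.2 ms, so dimerization that tight is ruled out.

A command-line interface mirrors the library
(`fcs3c fit | calibrate | predict-tau | equilibrium | detect-limit |
threec-quant | simulate-curve | simulate-gel | run`); `fcs3c run
--config cfg.yaml` executes a whole configured pipeline and writes every
artifact plus the resolved configuration to the output directory.

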