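# eacspec

Why does dissolved glucose look different from every other scattering
perturbation in a near-infrared diffuse-reflectance measurement?

`eacspec` is a simulation and analysis package for this question, aimed at
people working on non-invasive glucose sensing and tissue-optics phantoms.
It models a diluted Intralipid suspension (soybean-oil droplets in water)
over 1000–1700 nm and computes how four factors perturb the measured
diffuse-reflectance signal: glucose concentration, NaCl concentration
(both act through the background refractive index; glucose additionally
through a weak absorption band above 1300 nm), scatterer volume fraction,
and scatterer radius.

## The model

Scattering follows the Graaff power-law approximation to Mie theory for
soft spheres (radius *a*, volume fraction φ, relative index *m* = n_in/n_ex):

    μs′ = 2.46 (φ/a) (2πa/λ)^0.37 (m − 1)^2.09

whose closed-form sensitivities are

    ∂μs′/∂n_ex = −2.09 μs′ (n_in/n_ex²) (m−1)⁻¹
    ∂μs′/∂φ    =  μs′/φ
    ∂μs′/∂a    = −0.63 μs′/a .

Because each factor rescales μs′(λ) by a wavelength-flat first-order
factor, pure scattering perturbations are mutually confusable; the
discriminant is glucose's absorption channel.

Light transport is computed by two engines:

* **diffusion** — the semi-infinite dipole solution R(r) with
  μeff = √(3 μa (μa + μs′)), z0 = 1/μs′, z_b = 2D; deterministic and fast;
* **mc** — an MCML-style weighted photon Monte Carlo (implicit capture,
  Henyey–Greenstein scattering, Fresnel boundary, Russian roulette) with
  per-photon counter-based random streams, so baseline and perturbed
  states can share common random numbers and tiny differential signals
  survive desk-scale photon counts.

The measured quantity is the change of the effective attenuation
coefficient extracted from differential absorbance between two
source–detector separations:

    Δμeff ≈ [A_D(perturbed) − A_D(baseline)] / (r_B − r_A),
    A_D = A(r_B) − A(r_A),   A = −ln(I/I0)   (natural log).

## Worked example

```python
import numpy as np
from eacspec import (
    build_intralipid_medium, make_perturbation, run_group,
    normalize_at_reference, extract_features, regime_valid_mask,
)

lam = np.arange(1000.0, 1661.0, 10.0)
medium = build_intralipid_medium(3.0, lam)          # 3% Intralipid, a = 0.5 um
state = medium.at(1000.0)
print(f"mu_s'(1000 nm) = {state['mu_s_prime']:.2f} cm^-1, "
      f"mu_a(1000 nm) = {state['mu_a']:.3f} cm^-1")

glucose = run_group(medium, make_perturbation("glucose", 100.0)).per_unit(1.0)
nacl = run_group(medium, make_perturbation("nacl", 100.0)).per_unit(1.0)
density = run_group(medium, make_perturbation("particle_density", 1.37e-5))

print(f"dmu_eff(1000 nm) per mM glucose = {glucose.at(1000.0):+.5f} cm^-1")
_, eq = normalize_at_reference([glucose, nacl, density])
print(f"NaCl equivalent of 1 mM glucose = {eq['nacl']:.2f} mM")

valid = regime_valid_mask(medium)   # wavelengths where mu_a <= mu_s'
for s in (glucose, nacl):
    peak = extract_features(s.restricted(valid)).peak_wavelength_nm
    print(f"{s.kind:8s} |dmu_eff| peak (regime-valid band): {peak:.0f} nm")
```

prints

```
mu_s'(1000 nm) = 22.11 cm^-1, mu_a(1000 nm) = 0.351 cm^-1
dmu_eff(1000 nm) per mM glucose = -0.00325 cm^-1
NaCl equivalent of 1 mM glucose = 2.57 mM
glucose  |dmu_eff| peak (regime-valid band): 1420 nm
nacl     |dmu_eff| peak (regime-valid band): 1510 nm
```

Reading this: a 3% suspension scatters with μs′ ≈ 22 cm⁻¹ at 1000 nm;
each mM of glucose lowers the extracted effective attenuation coefficient
there by ≈0.003 cm⁻¹; at 1000 nm (no glucose absorption) 2.57 mM NaCl is
indistinguishable from 1 mM glucose; but across the band, glucose's
absorption pulls its |Δμeff| peak to a shorter wavelength (≈1420 nm) than
the pure scattering confounders' (≈1510 nm) — the spectral signature that
lets a multivariate calibration separate them.

A `eacspec` command-line tool wraps the same pipeline (`eacspec medium`,
`eacspec simulate`, `eacspec experiment`, `eacspec features`), driven by a
validated YAML configuration; see `eacspec --help`.

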