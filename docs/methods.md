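# Methods

This note documents the models behind `eacspec`, the defaults and why they
were chosen, the numerical choices, and what the synthetic setup does and
does not capture.

## Scattering model

The medium is a monodisperse suspension of soft spheres. The reduced
scattering cross-section uses the Graaff power-law approximation,

σs′ = 3.28 π a² x^0.37 (m−1)^2.09, x = 2πa/λ,

and the reduced scattering coefficient of the suspension is
μs′ = (3φ/4πa³) σs′ = 2.46 (φ/a) x^0.37 (m−1)^2.09. The two forms are kept
consistent to machine precision (a tested invariant). The approximation is
derived for size parameters 5 < x < 50; Intralipid droplets probed at
1000–1700 nm sit at x ≈ 2–3. Routine tissue-optics practice extends the
law there, and this package follows that practice, but every evaluation
can report a regime flag (`size_parameter`) so the extrapolation is
visible rather than silent.

All three factor sensitivities — background index n_ex, volume fraction φ,
radius a — are closed-form logarithmic derivatives of the power law and
are validated against central finite differences to 1e−6 relative error.
A useful scale-free corollary, tested exactly: the volume-fraction and
radius changes producing the same Δμs′ satisfy |Δa|/a = (Δφ/φ)/0.63,
independent of wavelength and refractive indices. For the working state
(φ = 0.03237, a = 0.5 μm) this pairs Δφ = 0.00137 % with |Δa| = 0.336 nm.

Linearization error: because μs′ ∝ (m−1)^2.09, first-order estimates for
the solute (index) channel carry a relative error of roughly
0.55 × (relative change of m−1): about 1.5 % at Δn_ex = 3×10⁻³ (a 120 mM
glucose amplification). `apply_perturbation` therefore always recomputes
μs′ exactly from the perturbed state rather than adding sensitivity ×
amount.

## Medium defaults (synthetic reconstruction)

The per-wavelength optical state of a 3 % Intralipid dilution is built
from dispersion curves that are deliberately simple, fully overridable,
and labelled synthetic — the analysis is structural (orderings, shapes,
matched pairs), not tied to exact curve values:

| quantity | default | units | rationale |
|---|---|---|---|
| φ | 0.03237 · (c%/3) | — | oil volume fraction of a 3 % dilution, linear in concentration |
| a | 0.5 | μm | mean droplet radius (particle *size* ≈ 1 μm is the diameter) |
| n_ex(λ) | 1.3143 + 1.154e−2/λ² + 1.132e−3/λ⁴ (λ in μm) | — | Cauchy fit to water, pinned to n(1 μm) = 1.327 |
| n_in(λ) | n_ex(λ) + 0.14 | — | soybean-oil offset |
| μa(λ) | (1−φ) × packaged water table | cm⁻¹ | water dominates; table is a pchip interpolation (log space) through standard literature anchors (Hale & Querry 1973; Palmer & Williams 1974; Kou et al. 1993), 10 nm grid, band peak at 1450 nm ≈ 28 cm⁻¹ |
| g(λ) | clip(1.1 − 0.58 λ[μm], 0.2, 0.9) | — | empirical Intralipid-style decline; only the MC engine uses g (μs = μs′/(1−g)) |

Solute perturbations: dn_ex/dC = 2.5×10⁻⁵ RIU/mM (glucose) and
0.98×10⁻⁵ RIU/mM (NaCl). The glucose absorption template ε_g(λ) is zero
through 1300 nm, ramps linearly to 0.00065 cm⁻¹/mM at 1500 nm and is flat
beyond; only the null region and the 1500–1600 nm plateau are anchored by
solution measurements, the ramp is a modelling choice (configurable).
Solute water displacement (which would slightly *reduce* μa in the water
band) is deliberately excluded, matching the analysis convention this
package follows.

Instrument noise: additive zero-mean Gaussian absorbance fluctuations with
per-wavelength standard deviations (0.001, 0.002, 0.002, 0.004, 0.002,
0.003) a.u. at the six working wavelengths (1050, 1219, 1314, 1409, 1550,
1609 nm), stated at the farthest ring (2.3 mm); closer rings are scaled by
a configurable factor ≤ 1 (default 0.8) since they collect more light.

## Diffusion engine and EAC extraction

Reflectance uses the classic two-source (dipole) semi-infinite solution
with an isotropic source at z0 = 1/μs′ and mirror offset z_b = 2D (no
index-mismatch boundary factor — a deliberate simplification; the MC
engine carries the Fresnel boundary instead). Absorbance is natural-log
throughout: A = −ln(I/I0). Differential absorbance A_D = A(r_B) − A(r_A)
with r_B > r_A, and the extracted EAC change is ΔA_D/(r_B − r_A). With
this orientation A_D > 0 for decaying intensity and a perturbation that
raises μeff yields a positive Δμeff.

**Validity.** Differencing two *states* cancels the slowly varying
geometric factors only in the far field. Numerically, for a pure μs′
perturbation at r = 0.08/0.2 cm the extraction recovers the closed-form
μeff difference within 15 % once r_near ≳ 8 z0 (μs′ ≳ 100 cm⁻¹) with
μeff·Δr of order 1, and the error *grows as absorption falls* (the
geometric z0 terms dominate); at the phantom's own μs′ ≈ 20 cm⁻¹ the
estimate is inflated several-fold. This does not undermine the analysis:
all factors at a given wavelength pass through the same linear extraction
functional, so matched pairs, normalized-spectrum comparisons and peak
orderings are preserved. The package reports the operational quantity and
emits `DiffusionRegimeWarning` when r < 3 z0 or μa > μs′.

## Monte Carlo engine

MCML-style weighted packets: pencil beam, specular entry loss, step
sampling −ln ξ/μt, implicit capture (deposit w·μa/μt per collision),
Henyey–Greenstein deflection, unpolarized Fresnel reflection/total
internal reflection at the top boundary, annular exit tally (default
dr = 0.005 cm × 100 bins), Russian roulette below weight 10⁻⁴ with 1/10
survival. Bookkeeping is exact per run: specular + diffuse + absorbed = 1
to ~10⁻¹², with the roulette's net created/destroyed weight folded into
the absorbed tally (unbiased in expectation).

Randomness is a per-photon counter-based stream (splitmix64-seeded
xorshift64*), giving bit-identical runs for a fixed seed and independent
substreams per photon. Correlated sampling falls out of this design:
`paired_delta` runs baseline and perturbed states on identical per-photon
streams, so a null perturbation gives ΔA ≡ 0 exactly and small
differentials have far lower variance than independent runs. Standard
errors come from 10 photon batches (interleaved assignment), and ΔA
errors from a joint bootstrap over batches, preserving the
baseline/perturbed correlation.

Problem sizes: the validation run uses 10⁶ photons (≈ 20 s on one core),
at which the annular profile matches the dipole form within ~7 % over
r = 0.1–0.3 cm in a diffusive test state (μa = 0.1, μs′ = 10 cm⁻¹,
g = 0.8, matched boundary); unit tests use 0.5–4 ×10⁵ photons with
correspondingly wider statistical tolerances. Per-mM differentials are far
below desk-scale MC resolution; the pipeline follows the amplification
strategy (100 mM solutes, 0.5 % concentration steps) and divides down,
accepting the ≲1.5 % linearization error quantified above.

## Pipeline and features

`run_group` produces Δμeff(λ) per factor on the 1000–1660 nm, 10 nm grid
(diffusion default; MC for cross-validation at amplified amounts — the two
engines agree within two combined standard errors at a regime-valid
wavelength, a tested property). The glucose decomposition runs the same
perturbation with scattering-only / absorption-only / both masks; the two
channels are independent by construction and additive to first order.

`normalize_at_reference` rescales all spectra to agree at 1000 nm, where
no factor absorbs; the scale factors are the equivalent amounts (2.57 mM
NaCl per mM glucose — the analytic ratio 2.5/0.98 up to extraction
nonlinearity; 0.00136 % Intralipid concentration per mM glucose).

`extract_features` reports the discrete argmax of |Δμeff| over
1400–1700 nm (ties toward shorter wavelength) and the short-band
(1000–1300 nm) variation (range over mean magnitude). On the full grid
the long-band argmax of *every* factor falls on the 1450 nm water-band
core, where μa ≈ 27 cm⁻¹ exceeds μs′ and the diffusion engine is outside
its validity regime; the discriminating glucose-vs-confounder ordering is
therefore evaluated on the regime-valid wavelengths (μa ≤ μs′, via
`regime_valid_mask` / `EACSpectrum.restricted`), where glucose peaks near
1420 nm and the scattering factors near 1510 nm. With the default
template zero below 1300 nm, the short-band variation is common to all
factors (each is a rescaling of the same μs′-driven shape); the feature
is retained for media with short-band absorption structure.

## Known limitations

* The dispersion/absorption curves are synthetic reconstructions; absolute
  coefficient values (e.g. μs′(1000 nm) = 22.1 cm⁻¹) inherit their
  uncertainty, while orderings and matched pairs are insensitive to it.
* Monodisperse spheres: the ±0.07 μm radius spread of real Intralipid is
  not modelled, nor is the anisotropy factor derived from Mie theory.
* Single homogeneous semi-infinite layer: no layered skin, no
  time-resolved quantities, no polarization.
* The EAC extraction at the working separations is operational, not an
  unbiased estimator of μeff differences (quantified above).
* Noise is additive, Gaussian and wavelength-independent across repeats;
  real instruments drift and have inter-ring systematic offsets that are
  not emulated.
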