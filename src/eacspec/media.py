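"""Synthetic optical model of Intralipid phantoms and their perturbations.

This module builds the per-wavelength optical state of a diluted Intralipid
suspension over 1000–1700 nm and applies the four perturbations under study:
dissolved glucose, dissolved NaCl, particle (oil droplet) volume fraction and
particle radius.  Solutes act through the background refractive index (and,
for glucose only, a weak absorption band above 1300 nm); the particle factors
act through the Graaff scattering law directly.

The dispersion curves are a synthetic reconstruction, not a measurement:

* background index ``n_ex(λ)``: a three-coefficient Cauchy fit to water over
  1.0–1.7 μm (≈1.33 → 1.32);
* particle index ``n_in(λ) = n_ex(λ) + 0.14`` (soybean oil offset);
* background absorption: a packaged pure-water table
  (``data/water_absorption_synthetic.csv``, 10 nm grid, interpolated from
  standard literature anchor values; water band peaking near 1450 nm),
  weighted by the water fraction ``1 − φ``;
* anisotropy ``g(λ) = clip(1.1 − 0.58·λ[μm], 0.2, 0.9)``, an empirical
  Intralipid-style decline with wavelength.

All curves are overridable through :class:`DispersionConfig`.  The analysis
built on top is structural (orderings and spectral shapes), not tied to the
exact curve values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .optics import ScattererSpec, reduced_scattering_coefficient

__all__ = [
    "DispersionConfig",
    "MediumSpectrum",
    "PerturbationSpec",
    "NoiseModel",
    "INSTRUMENT_WAVELENGTHS_NM",
    "INSTRUMENT_NOISE_SD",
    "water_refractive_index",
    "water_absorption",
    "default_anisotropy",
    "glucose_absorption_per_mM",
    "build_intralipid_medium",
    "make_perturbation",
    "apply_perturbation",
]

#: instrument wavelengths (nm) and their 1-min absorbance fluctuation sd (a.u.)
#: at the farthest source–detector separation (2.3 mm)
INSTRUMENT_WAVELENGTHS_NM = np.array([1050.0, 1219.0, 1314.0, 1409.0, 1550.0, 1609.0])
INSTRUMENT_NOISE_SD = np.array([0.001, 0.002, 0.002, 0.004, 0.002, 0.003])

#: volume fraction of soybean oil in a 3% Intralipid dilution
PHI_3PCT = 0.03237

#: refractive-index increments of aqueous solutes, RIU per mM
DN_DC_GLUCOSE = 2.5e-5
DN_DC_NACL = 0.98e-5

#: glucose molar absorption plateau on 1500–1600 nm, cm^-1 per mM
GLUCOSE_EPS_PLATEAU = 0.00065

# Cauchy fit for water over 1.0-1.7 um, pinned to n(1.0 um) = 1.327
_CAUCHY_A, _CAUCHY_B, _CAUCHY_C = 1.3143, 1.154e-2, 1.132e-3


def water_refractive_index(wavelengths_nm):
    """Cauchy-model water refractive index on 1000–1700 nm."""
    lam_um = np.asarray(wavelengths_nm, dtype=float) / 1e3
    return _CAUCHY_A + _CAUCHY_B / lam_um**2 + _CAUCHY_C / lam_um**4


_water_table_cache: PchipInterpolator | None = None


def _water_interpolator() -> PchipInterpolator:
    global _water_table_cache
    if _water_table_cache is None:
        ref = importlib.resources.files("eacspec.data").joinpath(
            "water_absorption_synthetic.csv"
        )
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
        _water_table_cache = PchipInterpolator(
            table["wavelength_nm"].to_numpy(), np.log(table["mua_per_cm"].to_numpy())
        )
    return _water_table_cache


def water_absorption(wavelengths_nm):
    """Pure-water absorption coefficient (cm⁻¹) from the packaged table.

    Log-space monotone interpolation of the 10 nm synthetic table; requests
    outside 1000–1700 nm raise, matching the table's support.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    if np.any(lam < 1000.0) or np.any(lam > 1700.0):
        raise ValueError("wavelength outside the 1000-1700 nm table support")
    return np.exp(_water_interpolator()(lam))


def default_anisotropy(wavelengths_nm):
    """Empirical Intralipid-style anisotropy declining with wavelength."""
    lam_um = np.asarray(wavelengths_nm, dtype=float) / 1e3
    return np.clip(1.1 - 0.58 * lam_um, 0.2, 0.9)


def glucose_absorption_per_mM(wavelengths_nm):
    """Glucose molar absorption template ε_g(λ) in cm⁻¹/mM.

    Zero through 1300 nm, linear ramp to the 1500–1600 nm plateau of
    0.00065 cm⁻¹/mM, held flat beyond (O–H/C–H first-overtone region).
    Only the ≤1300 nm null and the plateau are anchored by solution
    measurements; the ramp between them is a modelling choice.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    eps = np.interp(lam, [1300.0, 1500.0], [0.0, GLUCOSE_EPS_PLATEAU])
    return eps if eps.ndim else float(eps)


@dataclass(frozen=True)
class DispersionConfig:
    """Overridable dispersion/absorption/anisotropy model of the medium."""

    n_ex: Callable = water_refractive_index
    n_in_offset: float = 0.14
    background_mua: Callable = water_absorption
    anisotropy: Callable = default_anisotropy


@dataclass(frozen=True)
class MediumSpectrum:
    """Per-wavelength optical state of a turbid medium.

    Invariants enforced on construction: non-negative coefficients,
    ``n_in > n_ex`` everywhere, and ``mu_s·(1−g) == mu_s_prime``.
    """

    wavelengths_nm: np.ndarray
    n_ex: np.ndarray
    n_in: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    g: np.ndarray
    scatterer: ScattererSpec | None
    mu_s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "n_ex", "n_in", "mu_a", "mu_s_prime", "g"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        n = self.wavelengths_nm.size
        for name in ("n_ex", "n_in", "mu_a", "mu_s_prime", "g"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch with wavelength grid")
        if np.any(self.mu_a < 0) or np.any(self.mu_s_prime < 0):
            raise ValueError("optical coefficients must be non-negative")
        if np.any(self.n_in <= self.n_ex):
            raise ValueError("n_in must exceed n_ex at every wavelength")
        if np.any((self.g < 0) | (self.g >= 1)):
            raise ValueError("anisotropy g must lie in [0, 1)")
        object.__setattr__(self, "mu_s", self.mu_s_prime / (1.0 - self.g))

    @property
    def m(self) -> np.ndarray:
        return self.n_in / self.n_ex

    def at(self, wavelength_nm: float) -> dict[str, float]:
        """Optical state at one grid wavelength (exact match required)."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(f"{wavelength_nm} nm not on the medium grid")
        i = int(idx[0])
        return {
            "wavelength_nm": float(self.wavelengths_nm[i]),
            "n_ex": float(self.n_ex[i]),
            "n_in": float(self.n_in[i]),
            "mu_a": float(self.mu_a[i]),
            "mu_s_prime": float(self.mu_s_prime[i]),
            "g": float(self.g[i]),
            "mu_s": float(self.mu_s[i]),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "n_ex": self.n_ex,
                "n_in": self.n_in,
                "mu_a": self.mu_a,
                "mu_s_prime": self.mu_s_prime,
                "g": self.g,
                "mu_s": self.mu_s,
            }
        )


def build_intralipid_medium(
    concentration_pct: float,
    wavelengths_nm,
    dispersion: DispersionConfig | None = None,
    radius_um: float = 0.5,
) -> MediumSpectrum:
    """Optical state of a diluted Intralipid suspension.

    The oil volume fraction scales linearly with dilution, φ = 0.03237·c/3;
    μs' follows the Graaff law; background absorption is the water table
    weighted by the water fraction (1 − φ).
    """
    if concentration_pct < 0:
        raise ValueError("concentration_pct must be non-negative")
    dispersion = dispersion or DispersionConfig()
    lam = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    phi = PHI_3PCT * concentration_pct / 3.0
    n_ex = np.broadcast_to(np.asarray(dispersion.n_ex(lam), float), lam.shape).copy()
    n_in = n_ex + dispersion.n_in_offset
    mu_a = (1.0 - phi) * np.asarray(dispersion.background_mua(lam), float)
    g = np.broadcast_to(np.asarray(dispersion.anisotropy(lam), float), lam.shape).copy()
    if phi > 0:
        spec = ScattererSpec(radius_um=radius_um, volume_fraction=phi)
        mus_p = reduced_scattering_coefficient(spec, lam / 1e3, n_in / n_ex)
    else:
        spec = None
        mus_p = np.zeros_like(lam)
    return MediumSpectrum(
        wavelengths_nm=lam,
        n_ex=n_ex,
        n_in=n_in,
        mu_a=mu_a,
        mu_s_prime=np.atleast_1d(mus_p),
        g=g,
        scatterer=spec,
    )


PerturbationKind = Literal[
    "glucose", "nacl", "particle_density", "particle_size", "intralipid_concentration"
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One factor's per-unit effect on the medium.

    Exactly the channels relevant to ``kind`` are non-zero; glucose is the
    only kind with an absorption channel.
    """

    kind: PerturbationKind
    amount: float  # mM for solutes, delta-phi for density, delta-a (um) for size
    dnex_per_unit: float = 0.0
    dmua_per_unit: Callable | None = None  # lambda_nm -> cm^-1 per unit amount
    dphi: float = 0.0
    da_um: float = 0.0


def make_perturbation(kind: PerturbationKind, amount: float) -> PerturbationSpec:
    """Construct the standard perturbation of one factor.

    ``amount`` units: mM for glucose/nacl; Δφ (absolute volume fraction) for
    particle_density; Δa in nm for particle_size; Δconcentration in percent
    points for intralipid_concentration.
    """
    if not np.isfinite(amount):
        raise ValueError("amount must be finite")
    if kind == "glucose":
        return PerturbationSpec(
            kind=kind,
            amount=amount,
            dnex_per_unit=DN_DC_GLUCOSE,
            dmua_per_unit=glucose_absorption_per_mM,
        )
    if kind == "nacl":
        return PerturbationSpec(kind=kind, amount=amount, dnex_per_unit=DN_DC_NACL)
    if kind == "particle_density":
        return PerturbationSpec(kind=kind, amount=amount, dphi=amount)
    if kind == "particle_size":
        return PerturbationSpec(kind=kind, amount=amount, da_um=amount * 1e-3)
    if kind == "intralipid_concentration":
        return PerturbationSpec(
            kind=kind, amount=amount, dphi=PHI_3PCT * amount / 3.0
        )
    raise ValueError(f"unknown perturbation kind: {kind!r}")


Mask = Literal["both", "scattering_only", "absorption_only"]


def apply_perturbation(
    medium: MediumSpectrum, p: PerturbationSpec, mask: Mask = "both"
) -> MediumSpectrum:
    """Perturbed medium with μs' recomputed exactly from the Graaff law.

    The scattering channel (n_ex, φ, a) and the absorption channel (μa) are
    independent by construction; ``mask`` selects either or both, enabling
    the glucose absorption/scattering decomposition.
    """
    if mask not in ("both", "scattering_only", "absorption_only"):
        raise ValueError(f"unknown mask {mask!r}")
    n_ex, n_in = medium.n_ex, medium.n_in
    mu_a = medium.mu_a
    mus_p = medium.mu_s_prime
    spec = medium.scatterer

    if mask in ("both", "scattering_only"):
        n_ex = medium.n_ex + p.amount * p.dnex_per_unit
        if np.any(n_in <= n_ex):
            raise ValueError("perturbation drives n_ex above n_in (unphysical)")
        if spec is not None and (p.dphi != 0.0 or p.da_um != 0.0 or p.dnex_per_unit):
            new_phi = spec.volume_fraction + p.dphi
            new_a = spec.radius_um + p.da_um
            spec = ScattererSpec(radius_um=new_a, volume_fraction=new_phi)
            mus_p = reduced_scattering_coefficient(
                spec, medium.wavelengths_nm / 1e3, n_in / n_ex
            )
    if mask in ("both", "absorption_only") and p.dmua_per_unit is not None:
        mu_a = medium.mu_a + p.amount * np.asarray(
            p.dmua_per_unit(medium.wavelengths_nm), dtype=float
        )
    return MediumSpectrum(
        wavelengths_nm=medium.wavelengths_nm,
        n_ex=n_ex,
        n_in=n_in,
        mu_a=mu_a,
        mu_s_prime=np.atleast_1d(mus_p),
        g=medium.g,
        scatterer=spec,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Additive absorbance noise of the four-ring instrument.

    ``sd`` holds the per-wavelength 1-min fluctuation standard deviations at
    the reference (farthest) separation; closer rings are scaled by
    ``closer_sds_factor`` ≤ 1, reflecting their larger collected intensity.
    """

    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: INSTRUMENT_WAVELENGTHS_NM.copy()
    )
    sd: np.ndarray = field(default_factory=lambda: INSTRUMENT_NOISE_SD.copy())
    reference_sds_cm: float = 0.23
    closer_sds_factor: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths_nm", np.asarray(self.wavelengths_nm, float))
        object.__setattr__(self, "sd", np.asarray(self.sd, float))
        if np.any(self.sd < 0):
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.closer_sds_factor <= 1:
            raise ValueError("closer_sds_factor must lie in [0, 1]")

    def sd_at(self, sds_cm: float) -> np.ndarray:
        """Per-wavelength sd at one separation."""
        if sds_cm >= self.reference_sds_cm:
            return self.sd
        return self.sd * self.closer_sds_factor

    def sample(self, sds_cm: float, n_repeats: int, rng) -> np.ndarray:
        """Zero-mean draws, shape (n_repeats, n_wavelengths).

        ``rng`` is a seeded :class:`numpy.random.Generator` (explicit seeding
        is the caller's contract; there is no implicit global state).
        """
        rng = np.random.default_rng(rng)
        return rng.normal(0.0, self.sd_at(sds_cm), size=(n_repeats, self.sd.size))
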