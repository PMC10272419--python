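"""Semi-infinite diffusion-theory reflectance and the EAC-difference chain.

Steady-state diffusion approximation for a pencil beam on a homogeneous
semi-infinite medium, in the classic two-source (dipole) form: an isotropic
source buried at ``z0 = 1/μs'`` and its mirror image above the extrapolated
boundary at ``zb = 2D``, with ``D = 1/(3(μa+μs'))`` and effective attenuation
coefficient ``μeff = sqrt(3 μa (μa+μs'))``.  The radial reflectance is

.. math::

    R(r) = \\frac{1}{4\\pi}\\left[
        z_0\\left(\\mu_{eff}+\\frac{1}{r_1}\\right)\\frac{e^{-\\mu_{eff}r_1}}{r_1^2}
        + (z_0+2z_b)\\left(\\mu_{eff}+\\frac{1}{r_2}\\right)
          \\frac{e^{-\\mu_{eff}r_2}}{r_2^2}\\right]

with :math:`r_1^2 = r^2+z_0^2`, :math:`r_2^2 = r^2+(z_0+2z_b)^2`.

Absorbance is **natural-log** throughout, ``A = −ln(I/I0)`` — note many
instruments report base-10 absorbance.  Differencing A between two
separations (``AD = A(r_B) − A(r_A)``, ``r_B > r_A``) isolates the
exponential decay and cancels source and instrument drift; differencing AD
between a perturbed and a baseline state and dividing by ``r_B − r_A``
yields the change of the effective attenuation coefficient,

.. math:: \\Delta\\mu_{eff} \\approx \\Delta A_D / (r_B - r_A),

because the slowly varying geometric factors cancel between the two states.
This recovery is quantitative only in the far field (``r_A`` several times
``z0`` and ``μeff·(r_B−r_A)`` of order 1); outside that regime it remains a
well-defined *operational* EAC change — the quantity the instrument and the
analysis actually work with — but is systematically scaled relative to
``μeff(perturbed) − μeff(baseline)``.  A :class:`DiffusionRegimeWarning` is
emitted when the approximation is degraded.

Sign convention: the dipole textbook form is written with ``r_B > r_A`` so
that AD > 0 for decaying intensity and a perturbation that raises μeff gives
a positive Δμeff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionRegimeWarning",
    "DiffusionState",
    "AbsorbanceRecord",
    "DifferentialAbsorbance",
    "diffusion_state",
    "reflectance",
    "absorbance",
    "differential_absorbance",
    "eac_change",
]


class DiffusionRegimeWarning(UserWarning):
    """Diffusion approximation degraded (r too close, or μa not ≪ μs')."""


@dataclass(frozen=True)
class DiffusionState:
    """Derived diffusion quantities for one (μa, μs') pair."""

    mu_a: float
    mu_s_prime: float
    mu_eff: float = field(init=False)
    D: float = field(init=False)
    z0: float = field(init=False)
    zb: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and self.mu_s_prime > 0):
            raise ValueError("mu_a and mu_s_prime must be positive")
        object.__setattr__(
            self, "mu_eff", np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))
        )
        object.__setattr__(self, "D", 1.0 / (3.0 * (self.mu_a + self.mu_s_prime)))
        object.__setattr__(self, "z0", 1.0 / self.mu_s_prime)
        object.__setattr__(self, "zb", 2.0 * self.D)


def diffusion_state(mu_a: float, mu_s_prime: float) -> DiffusionState:
    """Build a :class:`DiffusionState`, warning if μa > μs'."""
    state = DiffusionState(mu_a=mu_a, mu_s_prime=mu_s_prime)
    if mu_a > mu_s_prime:
        warnings.warn(
            f"mu_a={mu_a:g} exceeds mu_s'={mu_s_prime:g}; diffusion theory is "
            "unreliable here (strong-absorption regime, e.g. near the 1450 nm "
            "water band)",
            DiffusionRegimeWarning,
            stacklevel=2,
        )
    return state


def reflectance(state: DiffusionState, r) -> np.ndarray | float:
    """Diffuse reflectance ratio I(r)/I0 per unit area (cm⁻²) at radius r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("source-detector separation r must be positive")
    if np.any(r < 3.0 * state.z0):
        warnings.warn(
            "r < 3·z0: diffusion reflectance is not quantitative this close "
            "to the source",
            DiffusionRegimeWarning,
            stacklevel=2,
        )
    z0, zb, mueff = state.z0, state.zb, state.mu_eff
    r1 = np.sqrt(r**2 + z0**2)
    r2 = np.sqrt(r**2 + (z0 + 2.0 * zb) ** 2)
    out = (1.0 / (4.0 * np.pi)) * (
        z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    )
    return float(out) if out.ndim == 0 else out


def absorbance(intensity_ratio) -> np.ndarray | float:
    """Natural-log absorbance A = −ln(I/I0)."""
    ratio = np.asarray(intensity_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("intensity ratio must be positive")
    out = -np.log(ratio)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Natural-log absorbance at one separation and wavelength."""

    sds_cm: float
    A: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if not self.sds_cm > 0:
            raise ValueError("sds_cm must be positive")
        if not np.isfinite(self.A):
            raise ValueError("absorbance must be finite")


@dataclass(frozen=True)
class DifferentialAbsorbance:
    """AD = A(r_B) − A(r_A) for a far/near separation pair (r_B > r_A)."""

    r_near_cm: float
    r_far_cm: float
    AD: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if not self.r_far_cm > self.r_near_cm:
            raise ValueError("far separation must exceed near separation")


def differential_absorbance(
    far: AbsorbanceRecord, near: AbsorbanceRecord
) -> DifferentialAbsorbance:
    """Differential absorbance between two separations at one wavelength."""
    if far.wavelength_nm != near.wavelength_nm:
        raise ValueError(
            f"wavelength mismatch: {far.wavelength_nm} vs {near.wavelength_nm} nm"
        )
    if not far.sds_cm > near.sds_cm:
        raise ValueError("far record must have the larger separation")
    return DifferentialAbsorbance(
        r_near_cm=near.sds_cm,
        r_far_cm=far.sds_cm,
        AD=far.A - near.A,
        wavelength_nm=far.wavelength_nm,
    )


def eac_change(AD_perturbed, AD_baseline, r_near_cm: float, r_far_cm: float):
    """Change in effective attenuation coefficient from two AD values.

    Δμeff = (AD_perturbed − AD_baseline) / (r_far − r_near).  The geometric
    (non-exponential) factors of the dipole solution cancel in the state
    difference; see the module docstring for the validity discussion.
    """
    if not r_far_cm > r_near_cm:
        raise ValueError("r_far_cm must exceed r_near_cm")
    ad_p = AD_perturbed.AD if isinstance(AD_perturbed, DifferentialAbsorbance) else AD_perturbed
    ad_b = AD_baseline.AD if isinstance(AD_baseline, DifferentialAbsorbance) else AD_baseline
    return (np.asarray(ad_p, dtype=float) - np.asarray(ad_b, dtype=float)) / (
        r_far_cm - r_near_cm
    )
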