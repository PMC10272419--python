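"""Graaff approximation to Mie scattering for soft spherical particles.

For a dilute suspension of spheres of radius ``a`` whose interior refractive
index :math:`n_{in}` is close to that of the background :math:`n_{ex}`
(relative index :math:`m = n_{in}/n_{ex}` slightly above 1), the reduced
scattering cross-section is well approximated by the Graaff power law

.. math::

    \\sigma_s' = 3.28\\,\\pi a^2\\, x^{0.37}\\,(m-1)^{2.09},
    \\qquad x = 2\\pi a/\\lambda,

and for a volume fraction :math:`\\phi` of scatterers the reduced scattering
coefficient is

.. math::

    \\mu_s' = \\frac{3\\phi}{4\\pi a^3}\\,\\sigma_s'
            = 2.46\\,\\frac{\\phi}{a}\\, x^{0.37}\\,(m-1)^{2.09}.

Because the law is a pure power law, its logarithmic derivatives with respect
to the background index, the particle volume fraction and the particle radius
are closed-form.  These three sensitivities are what make dissolved solutes
(which raise :math:`n_{ex}` and hence lower :math:`m`), particle density and
particle size mutually confusable in a diffuse-reflectance measurement: to
first order each produces a wavelength-proportional rescaling of
:math:`\\mu_s'(\\lambda)`, differing only in magnitude and sign.

Units
-----
Radii and wavelengths are accepted in micrometres at this API; coefficients
are returned in cm⁻¹ (cross-sections in μm²).  Internally lengths are
converted once to cm.

The Graaff law is stated for size parameters :math:`5 < x < 50`.  Intralipid
oil droplets probed at 1000–1700 nm sit at :math:`x \\approx 2–3`; routine
use in tissue optics extends the law there, so the bound is reported as a
validity *flag*, never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScattererSpec",
    "RefractivePair",
    "SensitivityBundle",
    "MatchedPerturbation",
    "size_parameter",
    "reduced_scattering_cross_section",
    "reduced_scattering_coefficient",
    "sensitivities",
    "equivalent_perturbations",
]

#: exponents and prefactors of the Graaff power law
_GRAAFF_PREF_SIGMA = 3.28
_GRAAFF_PREF_MUS = 2.46  # = 3/(4*pi) * 3.28 * pi
_X_EXP = 0.37
_M_EXP = 2.09

_UM_PER_CM = 1e4


@dataclass(frozen=True)
class ScattererSpec:
    """Monodisperse spherical scatterer population.

    Parameters
    ----------
    radius_um : float
        Particle radius in μm (Intralipid oil droplets: ~0.50 μm).
    volume_fraction : float
        Volume fraction φ of scatterers, in (0, 1).
    """

    radius_um: float
    volume_fraction: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"radius_um must be positive, got {self.radius_um}")
        if not 0 < self.volume_fraction < 1:
            raise ValueError(
                f"volume_fraction must lie in (0, 1), got {self.volume_fraction}"
            )


@dataclass(frozen=True)
class RefractivePair:
    """Interior and background refractive indices with relative index m."""

    n_in: float
    n_ex: float
    m: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.n_in > 1 and self.n_ex > 1):
            raise ValueError("refractive indices must exceed 1")
        object.__setattr__(self, "m", self.n_in / self.n_ex)


@dataclass(frozen=True)
class SensitivityBundle:
    """Analytic derivatives of μs' at one wavelength.

    Signs for relatively refracting particles (m > 1): raising the background
    index lowers the contrast so ``dmus_dnex`` < 0; adding particles raises
    scattering so ``dmus_dphi`` > 0; growing the particles at fixed volume
    fraction reduces their number faster than each scatters more, so
    ``dmus_da`` < 0.
    """

    dmus_dnex: float  # cm^-1 per refractive-index unit
    dmus_dphi: float  # cm^-1 per unit volume fraction
    dmus_da: float  # cm^-1 per um of radius
    at_wavelength_nm: float


@dataclass(frozen=True)
class MatchedPerturbation:
    """Magnitude and sign of one factor's change matching a target |Δμs'|."""

    magnitude: float
    sign: int  # sign of the factor change that produces the TARGET-signed dmus


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive, got {value}")


def size_parameter(radius_um, wavelength_um):
    """Size parameter x = 2πa/λ and a Graaff-regime validity flag.

    Returns
    -------
    x : float or ndarray
    valid : bool or ndarray
        True iff 5 < x < 50 (the regime the power law was derived for).
    """
    _check_positive(radius_um=radius_um, wavelength_um=wavelength_um)
    x = 2.0 * np.pi * np.asarray(radius_um, dtype=float) / np.asarray(
        wavelength_um, dtype=float
    )
    valid = (x > 5.0) & (x < 50.0)
    if x.ndim == 0:
        return float(x), bool(valid)
    return x, valid


def reduced_scattering_cross_section(radius_um, wavelength_um, m):
    """Reduced scattering cross-section σs' = σs(1−g) in μm²."""
    _check_positive(radius_um=radius_um, wavelength_um=wavelength_um)
    m = np.asarray(m, dtype=float)
    if np.any(m < 1.0):
        raise ValueError("relative refractive index m < 1 is outside the model")
    x = 2.0 * np.pi * np.asarray(radius_um, dtype=float) / np.asarray(
        wavelength_um, dtype=float
    )
    sigma = (
        _GRAAFF_PREF_SIGMA
        * np.pi
        * np.asarray(radius_um, dtype=float) ** 2
        * x**_X_EXP
        * (m - 1.0) ** _M_EXP
    )
    if sigma.ndim == 0:
        return float(sigma)
    return sigma


def reduced_scattering_coefficient(spec: ScattererSpec, wavelength_um, m):
    """Reduced scattering coefficient μs' in cm⁻¹ for a sphere suspension."""
    _check_positive(wavelength_um=wavelength_um)
    m = np.asarray(m, dtype=float)
    if np.any(m < 1.0):
        raise ValueError("relative refractive index m < 1 is outside the model")
    a_cm = spec.radius_um / _UM_PER_CM
    x = 2.0 * np.pi * spec.radius_um / np.asarray(wavelength_um, dtype=float)
    mus = _GRAAFF_PREF_MUS * (spec.volume_fraction / a_cm) * x**_X_EXP * (
        m - 1.0
    ) ** _M_EXP
    if mus.ndim == 0:
        return float(mus)
    return mus


def sensitivities(
    spec: ScattererSpec, wavelength_um: float, rp: RefractivePair
) -> SensitivityBundle:
    """Analytic first derivatives of μs' at one wavelength.

    .. math::

        \\partial\\mu_s'/\\partial n_{ex} &= -2.09\\,\\mu_s'\\,
            \\frac{n_{in}}{n_{ex}^2}\\,(m-1)^{-1} \\\\
        \\partial\\mu_s'/\\partial\\phi &= \\mu_s'/\\phi \\\\
        \\partial\\mu_s'/\\partial a &= -0.63\\,\\mu_s'/a

    The radius derivative is returned per μm.
    """
    if rp.m <= 1.0:
        raise ValueError("sensitivities require m > 1")
    mus = reduced_scattering_coefficient(spec, wavelength_um, rp.m)
    dn = -_M_EXP * mus * rp.n_in / rp.n_ex**2 / (rp.m - 1.0)
    dphi = mus / spec.volume_fraction
    da = -(1.0 - _X_EXP) * mus / spec.radius_um
    return SensitivityBundle(
        dmus_dnex=dn,
        dmus_dphi=dphi,
        dmus_da=da,
        at_wavelength_nm=wavelength_um * 1e3,
    )


def equivalent_perturbations(
    target_dmus: float,
    spec: ScattererSpec,
    rp: RefractivePair,
    wavelength_um: float,
    dn_per_unit: dict[str, float] | None = None,
) -> dict[str, MatchedPerturbation]:
    """First-order perturbation of each factor matching a target Δμs'.

    For each factor the returned magnitude is ``|target_dmus / sensitivity|``
    and the sign is that of the factor change reproducing ``target_dmus``
    with its sign: a positive Δμs' needs Δφ > 0, Δa < 0, and (for
    solutes, which raise n_ex) a negative concentration change.

    Parameters
    ----------
    dn_per_unit : mapping of solute factor name to dn_ex per unit amount
        (defaults: glucose 2.5e-5 RIU/mM, nacl 0.98e-5 RIU/mM).
    """
    if dn_per_unit is None:
        dn_per_unit = {"glucose": 2.5e-5, "nacl": 0.98e-5}
    if not math.isfinite(target_dmus):
        raise ValueError("target_dmus must be finite")
    sens = sensitivities(spec, wavelength_um, rp)
    out: dict[str, MatchedPerturbation] = {}
    channels: dict[str, float] = {
        "particle_density": sens.dmus_dphi,
        "particle_size": sens.dmus_da,
    }
    for name, dn in dn_per_unit.items():
        channels[name] = sens.dmus_dnex * dn
    for name, slope in channels.items():
        if slope == 0.0:
            raise ValueError(f"degenerate configuration: zero sensitivity for {name}")
        delta = target_dmus / slope
        out[name] = MatchedPerturbation(
            magnitude=abs(delta), sign=0 if delta == 0 else (1 if delta > 0 else -1)
        )
    return out
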