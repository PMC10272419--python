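"""EAC-difference spectra per perturbing factor, and their discriminants.

The analysis pipeline mirrors the study design: for each factor (glucose,
NaCl, particle density/size, Intralipid concentration) the baseline and
perturbed media are pushed through a light-transport engine — closed-form
diffusion theory, or Monte Carlo at amplified perturbation amounts — to get
absorbances at two source–detector separations; differential absorbance is
differenced between states and divided by the separation gap to yield the
effective-attenuation-coefficient change spectrum Δμeff(λ).

Spectra are then normalized to agree at a reference wavelength (1000 nm,
where glucose has no absorption and every factor acts purely through μs'),
which expresses each confounder as an equivalent amount per unit of the
reference factor, and compared through simple spectral features: where the
|Δμeff| peak falls in the 1400–1700 nm water/glucose band, and how strongly
the spectrum varies over the absorption-free 1000–1300 nm band.  Glucose is
the only factor with an absorption channel, which both shifts its long-band
peak to shorter wavelengths and adds short-band structure — the
discriminants this package quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .diffusion import (
    DiffusionRegimeWarning,
    DiffusionState,
    absorbance,
    reflectance,
)
from .mc import MCConfig, run_mc
from .media import (
    INSTRUMENT_WAVELENGTHS_NM,
    Mask,
    MediumSpectrum,
    NoiseModel,
    PerturbationSpec,
    apply_perturbation,
)

__all__ = [
    "EACSpectrum",
    "SpectralFeatures",
    "run_group",
    "regime_valid_mask",
    "normalize_at_reference",
    "synth_experiment",
    "extract_features",
    "DEFAULT_SDS_PAIR_CM",
    "INSTRUMENT_SDS_CM",
]

#: separations used for differential processing of the simulation groups
DEFAULT_SDS_PAIR_CM = (0.08, 0.2)
#: the four detector-ring separations of the instrument (cm)
INSTRUMENT_SDS_CM = (0.125, 0.17, 0.20, 0.23)


@dataclass(frozen=True)
class EACSpectrum:
    """Δμeff(λ) for one factor, one separation pair, one engine."""

    kind: str
    amount: float
    mask: Mask
    engine: str  # "diffusion" | "mc"
    sds_pair_cm: tuple[float, float]
    wavelengths_nm: np.ndarray
    delta_mu_eff: np.ndarray
    stderr: np.ndarray | None = None  # mc engine only

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wavelengths_nm", np.asarray(self.wavelengths_nm, dtype=float)
        )
        object.__setattr__(
            self, "delta_mu_eff", np.asarray(self.delta_mu_eff, dtype=float)
        )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if not np.all(np.isfinite(self.delta_mu_eff)):
            raise ValueError("delta_mu_eff must be finite")

    def at(self, wavelength_nm: float) -> float:
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(f"{wavelength_nm} nm not on the spectrum grid")
        return float(self.delta_mu_eff[int(idx[0])])

    def restricted(self, mask: np.ndarray) -> "EACSpectrum":
        """Sub-spectrum on a boolean wavelength mask (e.g. regime-valid λ)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.wavelengths_nm.shape:
            raise ValueError("mask shape must match the wavelength grid")
        return replace(
            self,
            wavelengths_nm=self.wavelengths_nm[mask],
            delta_mu_eff=self.delta_mu_eff[mask],
            stderr=None if self.stderr is None else self.stderr[mask],
        )

    def per_unit(self, unit_amount: float = 1.0) -> "EACSpectrum":
        """Linearly rescaled spectrum for a different amount.

        Amplified runs (e.g. 100 mM) are scaled down by simple division —
        first-order linearity, no nonlinearity correction.
        """
        factor = unit_amount / self.amount
        return replace(
            self,
            amount=unit_amount,
            delta_mu_eff=self.delta_mu_eff * factor,
            stderr=None if self.stderr is None else self.stderr * abs(factor),
        )


@dataclass(frozen=True)
class SpectralFeatures:
    """Discriminating features of one Δμeff spectrum."""

    peak_wavelength_nm: float  # argmax |dmu_eff| over the long band
    shortband_variation: float  # range / mean magnitude over the short band
    monotone_direction: str  # "increasing" | "decreasing" | "mixed"


def regime_valid_mask(medium: MediumSpectrum) -> np.ndarray:
    """Wavelengths where the diffusion approximation is trustworthy.

    True where scattering dominates absorption (μa ≤ μs'); the 1430–1500 nm
    water-band core of an aqueous phantom fails this and any diffusion-engine
    quantity there is operational only.
    """
    return medium.mu_a <= medium.mu_s_prime


def _diffusion_AD(mu_a, mu_s_prime, r_near: float, r_far: float) -> np.ndarray:
    """Vector of AD = A(r_far) − A(r_near) from the dipole closed form."""
    ad = np.empty_like(np.atleast_1d(mu_a), dtype=float)
    for i, (a_, s_) in enumerate(zip(np.atleast_1d(mu_a), np.atleast_1d(mu_s_prime))):
        st = DiffusionState(mu_a=float(a_), mu_s_prime=float(s_))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DiffusionRegimeWarning)
            ad[i] = absorbance(reflectance(st, r_far)) - absorbance(
                reflectance(st, r_near)
            )
    return ad


def _warn_regime(medium: MediumSpectrum, r_near: float) -> None:
    bad_abs = medium.wavelengths_nm[medium.mu_a > medium.mu_s_prime]
    if bad_abs.size:
        warnings.warn(
            "diffusion approximation degraded (mu_a > mu_s') at "
            f"{bad_abs.min():.0f}-{bad_abs.max():.0f} nm",
            DiffusionRegimeWarning,
            stacklevel=3,
        )
    z0 = 1.0 / np.min(medium.mu_s_prime[medium.mu_s_prime > 0])
    if r_near < 3.0 * z0:
        warnings.warn(
            f"near separation {r_near} cm < 3·z0; EAC extraction is operational, "
            "not quantitative, this close to the source",
            DiffusionRegimeWarning,
            stacklevel=3,
        )


def run_group(
    medium: MediumSpectrum,
    perturbation: PerturbationSpec,
    engine: str = "diffusion",
    sds_pair_cm: tuple[float, float] = DEFAULT_SDS_PAIR_CM,
    mask: Mask = "both",
    mc_config: MCConfig | None = None,
    mc_window: int = 3,
) -> EACSpectrum:
    """Δμeff(λ) of one perturbation via one transport engine.

    For the MC engine, baseline and perturbed states run on common random
    numbers (same config and seed) per wavelength; ``mc_window`` adjacent
    rings are averaged around each separation, and standard errors are
    bootstrapped over photon batches jointly for the two radii.
    """
    r_near, r_far = sds_pair_cm
    if not r_far > r_near > 0:
        raise ValueError("sds_pair_cm must be (near, far) with 0 < near < far")
    perturbed = apply_perturbation(medium, perturbation, mask=mask)
    _warn_regime(medium, r_near)

    if engine == "diffusion":
        ad_base = _diffusion_AD(medium.mu_a, medium.mu_s_prime, r_near, r_far)
        ad_pert = _diffusion_AD(perturbed.mu_a, perturbed.mu_s_prime, r_near, r_far)
        delta = (ad_pert - ad_base) / (r_far - r_near)
        stderr = None
    elif engine == "mc":
        cfg = mc_config or MCConfig()
        delta = np.empty(medium.wavelengths_nm.size)
        stderr = np.empty_like(delta)
        for i in range(medium.wavelengths_nm.size):
            d, se = _mc_delta_ad(
                cfg,
                (medium.mu_a[i], medium.mu_s[i], medium.g[i], medium.n_ex[i]),
                (perturbed.mu_a[i], perturbed.mu_s[i], perturbed.g[i], perturbed.n_ex[i]),
                r_near,
                r_far,
                mc_window,
            )
            delta[i] = d / (r_far - r_near)
            stderr[i] = se / (r_far - r_near)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return EACSpectrum(
        kind=perturbation.kind,
        amount=perturbation.amount,
        mask=mask,
        engine=engine,
        sds_pair_cm=(r_near, r_far),
        wavelengths_nm=medium.wavelengths_nm,
        delta_mu_eff=delta,
        stderr=stderr,
    )


def _window_slices(dr: float, n_bins: int, r: float, window: int) -> slice:
    ir = int(r / dr)
    if ir >= n_bins:
        raise ValueError(f"SDS {r} cm outside the MC radial grid")
    return slice(max(0, ir - window // 2), min(n_bins, ir + window // 2 + 1))


def _mc_delta_ad(
    cfg: MCConfig,
    base_props: tuple[float, float, float, float],
    pert_props: tuple[float, float, float, float],
    r_near: float,
    r_far: float,
    window: int,
    n_bootstrap: int = 200,
) -> tuple[float, float]:
    """ΔAD and its bootstrap standard error from paired MC runs."""
    base = run_mc(cfg, *base_props)
    pert = run_mc(cfg, *pert_props)
    dr = cfg.radial_bin_dr_cm
    sl_n = _window_slices(dr, cfg.n_radial_bins, r_near, window)
    sl_f = _window_slices(dr, cfg.n_radial_bins, r_far, window)

    def delta_ad(bw: np.ndarray, pw: np.ndarray) -> float:
        # window sums; the ring-area normalization cancels between states
        bn, bf = bw[sl_n].sum(), bw[sl_f].sum()
        pn, pf = pw[sl_n].sum(), pw[sl_f].sum()
        if min(bn, bf, pn, pf) <= 0:
            return np.nan
        return (np.log(bf) - np.log(pf)) - (np.log(bn) - np.log(pn))

    total = delta_ad(
        base.batch_ring_weights.sum(axis=0), pert.batch_ring_weights.sum(axis=0)
    )
    if not np.isfinite(total):
        raise RuntimeError(
            "zero MC tally at a requested separation; increase n_photons"
        )
    rng = np.random.default_rng(np.uint32(cfg.seed) ^ np.uint32(0xB00357))
    nb = cfg.n_batches
    boots = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        idx = rng.integers(0, nb, size=nb)
        boots[k] = delta_ad(
            base.batch_ring_weights[idx].sum(axis=0),
            pert.batch_ring_weights[idx].sum(axis=0),
        )
    return total, float(np.nanstd(boots, ddof=1))


def normalize_at_reference(
    spectra: list[EACSpectrum],
    lambda0_nm: float = 1000.0,
    reference_kind: str = "glucose",
) -> tuple[list[EACSpectrum], dict[str, float]]:
    """Rescale spectra to agree with the reference factor at λ0.

    At 1000 nm every factor acts purely through scattering, so matching the
    spectra there expresses each confounder as an equivalent amount per
    ``reference.amount`` of the reference factor (e.g. mM NaCl per mM
    glucose).  Returns the rescaled spectra (reference included, unscaled)
    and a map kind → equivalent amount.
    """
    ref = next((s for s in spectra if s.kind == reference_kind), None)
    if ref is None:
        raise ValueError(f"no spectrum of reference kind {reference_kind!r}")
    ref0 = ref.at(lambda0_nm)
    scaled: list[EACSpectrum] = []
    equivalents: dict[str, float] = {}
    for s in spectra:
        s0 = s.at(lambda0_nm)
        if s0 == 0.0:
            raise ValueError(f"{s.kind} spectrum is zero at {lambda0_nm} nm")
        factor = ref0 / s0
        scaled.append(
            replace(
                s,
                delta_mu_eff=s.delta_mu_eff * factor,
                stderr=None if s.stderr is None else s.stderr * abs(factor),
            )
        )
        equivalents[s.kind] = s.amount * factor
    return scaled, equivalents


def synth_experiment(
    medium: MediumSpectrum,
    perturbations: list[PerturbationSpec],
    sds_cm: tuple[float, ...] = INSTRUMENT_SDS_CM,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> dict[str, dict[tuple[float, float], EACSpectrum]]:
    """Emulated four-ring instrument run at the six working wavelengths.

    Diffusion-engine absorbances at each separation, for baseline and each
    perturbed state, each corrupted by an independent draw of the
    per-wavelength instrument noise; adjacent separation pairs are then
    differenced into one EAC spectrum per pair.  Fully reproducible under a
    fixed seed.  The medium must be built on the instrument wavelength grid.
    """
    lam = medium.wavelengths_nm
    if not np.allclose(lam, INSTRUMENT_WAVELENGTHS_NM):
        raise ValueError(
            "synth_experiment expects the medium on the six instrument "
            f"wavelengths {INSTRUMENT_WAVELENGTHS_NM.tolist()} nm"
        )
    rng = np.random.default_rng(seed)

    def noisy_A(m: MediumSpectrum) -> dict[float, np.ndarray]:
        out = {}
        for r in sds_cm:
            a = np.empty(lam.size)
            for i in range(lam.size):
                st = DiffusionState(float(m.mu_a[i]), float(m.mu_s_prime[i]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DiffusionRegimeWarning)
                    a[i] = absorbance(reflectance(st, r))
            if noise is not None:
                a = a + noise.sample(r, 1, rng)[0]
            out[r] = a
        return out

    results: dict[str, dict[tuple[float, float], EACSpectrum]] = {}
    for p in perturbations:
        base_A = noisy_A(medium)
        pert_A = noisy_A(apply_perturbation(medium, p))
        pairs: dict[tuple[float, float], EACSpectrum] = {}
        for r_near, r_far in zip(sds_cm[:-1], sds_cm[1:]):
            ad_base = base_A[r_far] - base_A[r_near]
            ad_pert = pert_A[r_far] - pert_A[r_near]
            pairs[(r_near, r_far)] = EACSpectrum(
                kind=p.kind,
                amount=p.amount,
                mask="both",
                engine="diffusion",
                sds_pair_cm=(r_near, r_far),
                wavelengths_nm=lam,
                delta_mu_eff=(ad_pert - ad_base) / (r_far - r_near),
            )
        results[p.kind] = pairs
    return results


def extract_features(
    s: EACSpectrum,
    shortband_nm: tuple[float, float] = (1000.0, 1300.0),
    longband_nm: tuple[float, float] = (1400.0, 1700.0),
) -> SpectralFeatures:
    """Discriminating features of one EAC spectrum.

    The long-band peak is the discrete argmax of |Δμeff| on the sampled
    grid (ties resolved toward the shorter wavelength); the short-band
    variation is the value range over 1000–1300 nm divided by the mean
    magnitude there — large for glucose, small for the pure scattering
    confounders.
    """
    lam = s.wavelengths_nm
    long_mask = (lam >= longband_nm[0]) & (lam <= longband_nm[1])
    short_mask = (lam >= shortband_nm[0]) & (lam <= shortband_nm[1])
    if long_mask.sum() < 2 or short_mask.sum() < 2:
        raise ValueError("spectrum grid too narrow for feature extraction")
    mag = np.abs(s.delta_mu_eff[long_mask])
    peak = float(lam[long_mask][int(np.argmax(mag))])
    short = s.delta_mu_eff[short_mask]
    mean_mag = float(np.mean(np.abs(short)))
    variation = float((short.max() - short.min()) / mean_mag) if mean_mag > 0 else 0.0
    diffs = np.diff(short)
    if np.all(diffs > 0):
        direction = "increasing"
    elif np.all(diffs < 0):
        direction = "decreasing"
    else:
        direction = "mixed"
    return SpectralFeatures(
        peak_wavelength_nm=peak,
        shortband_variation=variation,
        monotone_direction=direction,
    )
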