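"""Graaff scattering law: closed forms, sensitivities, matched perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eacspec.optics import (
    RefractivePair,
    ScattererSpec,
    equivalent_perturbations,
    reduced_scattering_coefficient,
    reduced_scattering_cross_section,
    sensitivities,
    size_parameter,
)

STATE = dict(a=0.5, lam=1.0, m=1.468 / 1.327)


@pytest.mark.parametrize(
    "a, lam, x_expected, valid",
    [
        (0.5, 1.0, np.pi, False),  # Intralipid at 1000 nm: below Graaff's bound
        (1.0, 1.0, 2 * np.pi, True),
        (0.5, 1.609, 2 * np.pi * 0.5 / 1.609, False),
    ],
)
def test_size_parameter_and_regime_flag(a, lam, x_expected, valid):
    x, flag = size_parameter(a, lam)
    assert x == pytest.approx(x_expected, rel=1e-12)
    assert flag is valid


def test_size_parameter_rejects_nonpositive():
    with pytest.raises(ValueError):
        size_parameter(-0.5, 1.0)
    with pytest.raises(ValueError):
        size_parameter(0.5, 0.0)


def test_cross_section_matched_index_scatters_nothing():
    assert reduced_scattering_cross_section(0.5, 1.0, 1.0) == 0.0


def test_cross_section_value_and_radius_power_law():
    sigma = reduced_scattering_cross_section(STATE["a"], STATE["lam"], STATE["m"])
    assert sigma == pytest.approx(0.036306, rel=1e-4)  # independently evaluated
    ratio = reduced_scattering_cross_section(1.0, 1.0, STATE["m"]) / (
        reduced_scattering_cross_section(0.5, 1.0, STATE["m"])
    )
    assert ratio == pytest.approx(2**2.37, rel=1e-12)


def test_cross_section_rejects_inverted_contrast():
    with pytest.raises(ValueError):
        reduced_scattering_cross_section(0.5, 1.0, 0.98)


def test_mus_prime_intralipid_value(intralipid_spec, refractive_1000):
    mus = reduced_scattering_coefficient(intralipid_spec, 1.0, refractive_1000.m)
    assert mus == pytest.approx(22.445, rel=1e-3)


def test_mus_prime_linear_in_phi_and_zero_at_match(intralipid_spec):
    half = ScattererSpec(radius_um=0.5, volume_fraction=intralipid_spec.volume_fraction / 2)
    m = STATE["m"]
    assert reduced_scattering_coefficient(half, 1.0, m) == pytest.approx(
        reduced_scattering_coefficient(intralipid_spec, 1.0, m) / 2, rel=1e-12
    )
    assert reduced_scattering_coefficient(intralipid_spec, 1.0, 1.0) == 0.0


@settings(max_examples=200, deadline=None)
@given(
    a=st.floats(0.2, 2.0),
    phi=st.floats(0.005, 0.1),
    m=st.floats(1.02, 1.3),
    lam=st.floats(1.0, 1.7),
)
def test_coefficient_consistent_with_cross_section(a, phi, m, lam):
    """μs' from the per-volume form equals (3φ/4πa³)·σs' to machine precision."""
    spec = ScattererSpec(radius_um=a, volume_fraction=phi)
    mus = reduced_scattering_coefficient(spec, lam, m)
    sigma_um2 = reduced_scattering_cross_section(a, lam, m)
    # number density 3φ/(4πa³) in μm⁻³; μm⁻¹ → cm⁻¹ is 1e4
    oracle = 3 * phi / (4 * np.pi * a**3) * sigma_um2 * 1e4
    assert mus == pytest.approx(oracle, rel=1e-12)


def _fd_sensitivities(spec, lam, rp, rel_step=1e-6):
    """Central finite differences of the closed form (independent oracle)."""

    def mus(a, phi, nex):
        return reduced_scattering_coefficient(
            ScattererSpec(radius_um=a, volume_fraction=phi), lam, rp.n_in / nex
        )

    a, phi, nex = spec.radius_um, spec.volume_fraction, rp.n_ex
    ha, hp, hn = a * rel_step, phi * rel_step, nex * rel_step
    return (
        (mus(a, phi, nex + hn) - mus(a, phi, nex - hn)) / (2 * hn),
        (mus(a, phi + hp, nex) - mus(a, phi - hp, nex)) / (2 * hp),
        (mus(a + ha, phi, nex) - mus(a - ha, phi, nex)) / (2 * ha),
    )


def test_sensitivities_reference_values(intralipid_spec, refractive_1000):
    s = sensitivities(intralipid_spec, 1.0, refractive_1000)
    assert s.dmus_dphi == pytest.approx(693.4, rel=1e-3)
    assert s.dmus_da == pytest.approx(-28.28, rel=1e-3)
    assert s.dmus_dnex == pytest.approx(-368.0, rel=1e-3)
    # per-mM glucose scattering sensitivity via dn/dC = 2.5e-5 RIU/mM
    assert s.dmus_dnex * 2.5e-5 == pytest.approx(-0.0092, rel=2e-3)


@settings(max_examples=150, deadline=None)
@given(
    a=st.floats(0.2, 2.0),
    phi=st.floats(0.005, 0.1),
    m=st.floats(1.02, 1.3),
    lam=st.floats(1.0, 1.7),
)
def test_analytic_derivatives_match_finite_differences(a, phi, m, lam):
    spec = ScattererSpec(radius_um=a, volume_fraction=phi)
    nex = 1.32
    rp = RefractivePair(n_in=m * nex, n_ex=nex)
    s = sensitivities(spec, lam, rp)
    fd_n, fd_p, fd_a = _fd_sensitivities(spec, lam, rp)
    assert s.dmus_dnex == pytest.approx(fd_n, rel=1e-6)
    assert s.dmus_dphi == pytest.approx(fd_p, rel=1e-6)
    assert s.dmus_da == pytest.approx(fd_a, rel=1e-6)


def test_sensitivity_signs(intralipid_spec, refractive_1000):
    s = sensitivities(intralipid_spec, 1.3, refractive_1000)
    assert s.dmus_dphi > 0 and s.dmus_da < 0 and s.dmus_dnex < 0


@pytest.mark.parametrize("lam_pair", [(1.0, 1.2), (1.2, 1.5), (1.5, 1.7)])
def test_mus_prime_decreases_with_wavelength(intralipid_spec, lam_pair):
    m = STATE["m"]
    short, long = lam_pair
    assert reduced_scattering_coefficient(
        intralipid_spec, short, m
    ) > reduced_scattering_coefficient(intralipid_spec, long, m)


def test_mus_prime_increases_with_contrast(intralipid_spec):
    assert reduced_scattering_coefficient(
        intralipid_spec, 1.0, 1.12
    ) > reduced_scattering_coefficient(intralipid_spec, 1.0, 1.10)


class TestMatchedPerturbations:
    """The matched-pair worked example: Δφ = 0.00137% ↔ |Δa| = 0.336 nm."""

    def target(self, spec, rp, dphi=1.37e-5):
        return sensitivities(spec, 1.0, rp).dmus_dphi * dphi

    def test_density_to_size(self, intralipid_spec, refractive_1000):
        eq = equivalent_perturbations(
            self.target(intralipid_spec, refractive_1000),
            intralipid_spec,
            refractive_1000,
            1.0,
        )
        assert eq["particle_size"].magnitude * 1e3 == pytest.approx(0.336, abs=5e-4)
        assert eq["particle_size"].sign == -1  # shrink particles to raise μs'
        assert eq["particle_density"].sign == 1

    def test_size_to_density_round_trip(self, intralipid_spec, refractive_1000):
        s = sensitivities(intralipid_spec, 1.0, refractive_1000)
        eq = equivalent_perturbations(
            -0.336e-3 * s.dmus_da, intralipid_spec, refractive_1000, 1.0
        )
        assert eq["particle_density"].magnitude == pytest.approx(1.370e-5, rel=2e-3)

    def test_zero_target(self, intralipid_spec, refractive_1000):
        eq = equivalent_perturbations(0.0, intralipid_spec, refractive_1000, 1.0)
        assert all(v.magnitude == 0.0 for v in eq.values())

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(0.2, 2.0),
        phi=st.floats(0.005, 0.1),
        m=st.floats(1.02, 1.3),
        lam=st.floats(1.0, 1.7),
    )
    def test_scale_free_identity(self, a, phi, m, lam):
        """|Δa|/a = (Δφ/φ)/0.63 exactly, independent of indices and λ."""
        spec = ScattererSpec(radius_um=a, volume_fraction=phi)
        rp = RefractivePair(n_in=m * 1.33, n_ex=1.33)
        dphi = 0.01 * phi
        eq = equivalent_perturbations(
            sensitivities(spec, lam, rp).dmus_dphi * dphi, spec, rp, lam
        )
        assert eq["particle_size"].magnitude / a == pytest.approx(
            (dphi / phi) / 0.63, rel=1e-12
        )

    def test_solute_channels_scale_with_index_increment(
        self, intralipid_spec, refractive_1000
    ):
        eq = equivalent_perturbations(
            -0.01, intralipid_spec, refractive_1000, 1.0
        )
        assert eq["glucose"].magnitude * 2.5e-5 == pytest.approx(
            eq["nacl"].magnitude * 0.98e-5, rel=1e-12
        )
        assert eq["glucose"].sign == 1  # raising n_ex lowers μs'
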