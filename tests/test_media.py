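"""Intralipid medium construction, perturbations, and instrument noise."""

import numpy as np
import pytest

from eacspec.media import (
    INSTRUMENT_WAVELENGTHS_NM,
    NoiseModel,
    apply_perturbation,
    build_intralipid_medium,
    glucose_absorption_per_mM,
    make_perturbation,
    water_absorption,
)
from eacspec.optics import sensitivities, RefractivePair


class TestBuildMedium:
    def test_volume_fraction_scales_with_concentration(self, full_grid):
        assert build_intralipid_medium(3.0, full_grid).scatterer.volume_fraction == (
            pytest.approx(0.03237, rel=1e-12)
        )
        assert build_intralipid_medium(3.5, full_grid).scatterer.volume_fraction == (
            pytest.approx(0.0377650, rel=1e-6)
        )

    def test_zero_concentration_scatters_nothing(self, full_grid):
        med = build_intralipid_medium(0.0, full_grid)
        assert med.scatterer is None
        assert np.all(med.mu_s_prime == 0.0)

    def test_water_band_dominates_absorption(self, medium_3pct, full_grid):
        peak = full_grid[np.argmax(medium_3pct.mu_a)]
        assert 1400 <= peak <= 1500

    def test_scattering_declines_with_wavelength(self, medium_3pct):
        assert medium_3pct.at(1000)["mu_s_prime"] > medium_3pct.at(1660)["mu_s_prime"]

    def test_index_contrast_and_mus_identity(self, medium_3pct):
        assert np.all(medium_3pct.n_in > medium_3pct.n_ex)
        assert np.allclose(
            medium_3pct.mu_s * (1 - medium_3pct.g),
            medium_3pct.mu_s_prime,
            rtol=1e-12,
        )

    def test_grid_outside_table_support_rejected(self):
        with pytest.raises(ValueError):
            build_intralipid_medium(3.0, np.array([900.0, 1000.0]))
        with pytest.raises(ValueError):
            water_absorption([1800.0])


class TestMakePerturbation:
    def test_glucose_channels(self):
        p = make_perturbation("glucose", 100.0)
        assert p.amount * p.dnex_per_unit == pytest.approx(2.5e-3, rel=1e-12)
        assert p.dmua_per_unit(1550.0) == pytest.approx(0.00065, rel=1e-12)
        assert p.dmua_per_unit(1219.0) == 0.0
        assert p.dmua_per_unit(1300.0) == 0.0

    def test_nacl_is_index_only(self):
        p = make_perturbation("nacl", 100.0)
        assert p.amount * p.dnex_per_unit == pytest.approx(0.98e-3, rel=1e-12)
        assert p.dmua_per_unit is None

    def test_particle_channels(self):
        assert make_perturbation("particle_density", 1.37e-5).dphi == 1.37e-5
        assert make_perturbation("particle_size", -0.336).da_um == pytest.approx(
            -0.336e-3
        )
        assert make_perturbation(
            "intralipid_concentration", 0.5
        ).dphi == pytest.approx(0.03237 * 0.5 / 3.0, rel=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_perturbation("temperature", 1.0)


class TestApplyPerturbation:
    def test_zero_amount_is_identity(self, medium_3pct):
        out = apply_perturbation(medium_3pct, make_perturbation("glucose", 0.0))
        assert np.array_equal(out.mu_s_prime, medium_3pct.mu_s_prime)
        assert np.array_equal(out.mu_a, medium_3pct.mu_a)

    def test_glucose_scattering_mask(self, medium_3pct):
        out = apply_perturbation(
            medium_3pct, make_perturbation("glucose", 100.0), mask="scattering_only"
        )
        assert np.array_equal(out.mu_a, medium_3pct.mu_a)
        assert np.all(out.mu_s_prime < medium_3pct.mu_s_prime)

    def test_glucose_absorption_mask(self, medium_3pct):
        out = apply_perturbation(
            medium_3pct, make_perturbation("glucose", 100.0), mask="absorption_only"
        )
        assert np.array_equal(out.mu_s_prime, medium_3pct.mu_s_prime)
        short = medium_3pct.wavelengths_nm <= 1300
        assert np.array_equal(out.mu_a[short], medium_3pct.mu_a[short])
        assert np.all(out.mu_a[~short] >= medium_3pct.mu_a[~short])

    def test_masks_compose(self, medium_3pct):
        p = make_perturbation("glucose", 100.0)
        both = apply_perturbation(medium_3pct, p, mask="both")
        scat = apply_perturbation(medium_3pct, p, mask="scattering_only")
        absb = apply_perturbation(scat, p, mask="absorption_only")
        assert np.array_equal(both.mu_a, absb.mu_a)
        assert np.array_equal(both.mu_s_prime, absb.mu_s_prime)

    def test_matched_pair_produces_equal_scattering_change(self, medium_3pct):
        """Δφ = +1.37e-5 and Δa = −0.336 nm: same Δμs' at 1000 nm to <0.1%."""
        d_dens = apply_perturbation(
            medium_3pct, make_perturbation("particle_density", 1.37e-5)
        )
        d_size = apply_perturbation(
            medium_3pct, make_perturbation("particle_size", -0.336)
        )
        i = 0  # 1000 nm
        dd = d_dens.mu_s_prime[i] - medium_3pct.mu_s_prime[i]
        ds = d_size.mu_s_prime[i] - medium_3pct.mu_s_prime[i]
        assert dd > 0 and ds > 0
        assert abs(dd - ds) / dd < 1e-3

    @pytest.mark.parametrize(
        "kind, amount, tol",
        [
            # (m-1)^2.09 curvature: ~0.55 × relative (m-1) change, so the
            # solute channel carries ~1.5% linearization error at Δnex = 3e-3
            ("glucose", 120.0, 0.02),
            ("glucose", 40.0, 0.006),
            ("particle_density", 0.2 * 0.03237, 1e-9),  # μs' exactly linear in φ
            ("particle_size", 5.0, 1e-2),
        ],
    )
    def test_exact_change_matches_first_order(self, medium_3pct, kind, amount, tol):
        p = make_perturbation(kind, amount)
        out = apply_perturbation(medium_3pct, p, mask="scattering_only")
        i = 0
        exact = out.mu_s_prime[i] - medium_3pct.mu_s_prime[i]
        rp = RefractivePair(n_in=medium_3pct.n_in[i], n_ex=medium_3pct.n_ex[i])
        s = sensitivities(medium_3pct.scatterer, medium_3pct.wavelengths_nm[i] / 1e3, rp)
        first_order = (
            s.dmus_dnex * p.amount * p.dnex_per_unit
            + s.dmus_dphi * p.dphi
            + s.dmus_da * p.da_um
        )
        assert exact == pytest.approx(first_order, rel=tol)

    def test_unphysical_state_rejected(self, medium_3pct):
        with pytest.raises(ValueError):
            apply_perturbation(medium_3pct, make_perturbation("glucose", 1e4))


class TestNoiseModel:
    def test_zero_sd_draws_are_zero(self):
        nm = NoiseModel(sd=np.zeros(6))
        assert np.all(nm.sample(0.23, 100, rng=1) == 0.0)

    def test_seed_reproducibility(self):
        nm = NoiseModel()
        assert np.array_equal(nm.sample(0.23, 10, rng=42), nm.sample(0.23, 10, rng=42))

    def test_sample_sd_matches_configuration(self):
        nm = NoiseModel()
        draws = nm.sample(0.23, 100_000, rng=0)
        assert draws.shape == (100_000, 6)
        assert np.allclose(draws.mean(axis=0), 0.0, atol=5e-5 + 0.02 * nm.sd)
        assert np.allclose(draws.std(axis=0), nm.sd, rtol=0.02)

    def test_closer_separations_fluctuate_less(self):
        nm = NoiseModel()
        assert np.all(nm.sd_at(0.125) <= nm.sd_at(0.23))
        assert np.all(nm.sd_at(0.125) == nm.sd * nm.closer_sds_factor)


def test_glucose_template_anchors():
    lam = np.array([1000.0, 1300.0, 1400.0, 1500.0, 1550.0, 1600.0, 1700.0])
    eps = glucose_absorption_per_mM(lam)
    assert np.all(eps[:2] == 0.0)
    assert 0 < eps[2] < 0.00065
    assert np.all(eps[3:] == pytest.approx(0.00065, rel=1e-12))


def test_instrument_grid_is_the_six_wavelengths():
    assert INSTRUMENT_WAVELENGTHS_NM.tolist() == [1050, 1219, 1314, 1409, 1550, 1609]
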