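"""Transport coefficients and the sedimentation-diffusion deposition solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npquant.dosimetry import (
    MediumSpec,
    ParticleSpec,
    deposited_per_area,
    diffusivity,
    effective_cluster,
    settling_velocity,
    simulate_deposition,
)

MEDIUM = MediumSpec()


class TestSettlingVelocity:
    def test_neutral_buoyancy_is_zero(self):
        m = MediumSpec(density_g_cm3=1.8)
        assert settling_velocity(ParticleSpec(85.0, 1.8), m) == 0.0

    def test_quadratic_diameter_scaling(self):
        v1 = settling_velocity(ParticleSpec(40.0, 1.8), MEDIUM)
        v2 = settling_velocity(ParticleSpec(80.0, 1.8), MEDIUM)
        assert v2 == pytest.approx(4.0 * v1, rel=1e-12)

    def test_hand_computed_value(self):
        # independent arithmetic: g (rho_p-rho_m) d^2 / (18 mu) evaluated by
        # hand for d=85 nm, rho_p=1.8, rho_m=1.0, mu=7.0e-4 Pa s
        m = MediumSpec(viscosity_Pa_s=7.0e-4)
        assert settling_velocity(ParticleSpec(85.0, 1.8), m) == pytest.approx(
            4.49861e-9, rel=1e-5
        )


class TestDiffusivity:
    def test_inverse_diameter_scaling(self):
        d1 = diffusivity(ParticleSpec(25.0, 1.8), MEDIUM)
        d2 = diffusivity(ParticleSpec(50.0, 1.8), MEDIUM)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_hand_computed_value(self):
        # k_B T / (3 pi mu d) for d=25 nm, T=310.15 K, mu=7.0e-4 Pa s
        m = MediumSpec(viscosity_Pa_s=7.0e-4)
        assert diffusivity(ParticleSpec(25.0, 1.8), m) == pytest.approx(
            2.596246e-11, rel=1e-5
        )

    def test_linear_in_temperature(self):
        p = ParticleSpec(25.0, 1.8)
        d_cold = diffusivity(p, MediumSpec(temperature_K=310.15 / 1000.0))
        assert d_cold == pytest.approx(diffusivity(p, MEDIUM) / 1000.0, rel=1e-12)


class TestEffectiveCluster:
    def test_single_particle_identity(self):
        p = ParticleSpec(25.0, 1.8)
        assert effective_cluster(p, 1, MEDIUM, packing=1.0) is p

    def test_triplet_diameter(self):
        p = effective_cluster(ParticleSpec(25.0, 1.8), 3, MEDIUM, packing=0.637)
        assert p.diameter_nm == pytest.approx(25.0 * 1.67621, rel=1e-4)

    @given(packing=st.floats(0.05, 1.0), n=st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_density_is_convex_combination(self, packing, n):
        p = effective_cluster(ParticleSpec(25.0, 1.8), n, MEDIUM, packing=packing)
        assert MEDIUM.density_g_cm3 - 1e-12 <= p.density_g_cm3 <= 1.8 + 1e-12


class TestDeposition:
    def test_no_transport_no_deposition(self):
        # neutral buoyancy kills settling; near-zero temperature kills diffusion
        m = MediumSpec(density_g_cm3=1.8, temperature_K=1e-9)
        res = simulate_deposition(ParticleSpec(25.0, 1.8), m, duration_h=5.0,
                                  n_x=200, n_t=100)
        assert res.fraction < 1e-6

    def test_short_time_pure_diffusion_closed_form(self):
        # V=0: fraction(t) = 2 sqrt(Dt/pi) / h while the depletion layer is
        # thin; absorbing-wall solution of the half-space diffusion problem
        m = MediumSpec(density_g_cm3=1.8)  # neutral buoyancy -> V = 0
        p = ParticleSpec(25.0, 1.8)
        t_s = 600.0
        res = simulate_deposition(p, m, duration_h=t_s / 3600.0)
        expected = 2.0 * math.sqrt(diffusivity(p, m) * t_s / math.pi) / m.height_m
        assert res.fraction == pytest.approx(expected, rel=0.02)

    def test_mass_balance(self):
        res = simulate_deposition(ParticleSpec(25.0, 1.8), MEDIUM, duration_h=5.0)
        assert res.diagnostics["mass_balance_rel_error"] < 1e-6

    def test_monotone_in_time(self):
        res = simulate_deposition(ParticleSpec(85.0, 1.8), MEDIUM, duration_h=5.0)
        assert np.all(np.diff(res.fraction_series) >= -1e-14)
        assert 0.0 <= res.fraction <= 1.0

    def test_monotone_in_diffusivity_and_velocity(self):
        base = simulate_deposition(ParticleSpec(85.0, 1.8), MEDIUM, 5.0).fraction
        hot = MediumSpec(temperature_K=350.0)  # larger D
        assert simulate_deposition(ParticleSpec(85.0, 1.8), hot, 5.0).fraction > base
        dense = ParticleSpec(85.0, 3.6)  # larger V (and same D)
        assert simulate_deposition(dense, MEDIUM, 5.0).fraction > base

    def test_grid_convergence(self):
        p = ParticleSpec(25.0, 1.8)
        f1 = simulate_deposition(p, MEDIUM, 5.0, n_x=1000, n_t=800).fraction
        f2 = simulate_deposition(p, MEDIUM, 5.0, n_x=2000, n_t=1600).fraction
        assert abs(f2 - f1) * 100.0 < 0.1  # < 0.1 percentage point

    def test_long_time_complete_deposition(self):
        res = simulate_deposition(ParticleSpec(85.0, 1.8), MEDIUM, duration_h=2000.0)
        assert res.fraction > 0.99

    @pytest.mark.parametrize("diameter_nm", [25.0, 85.0])
    def test_weak_cluster_dependence(self, diameter_nm):
        # small clusters barely change the deposited fraction
        p = ParticleSpec(diameter_nm, 1.8)
        fractions = [
            simulate_deposition(effective_cluster(p, n, MEDIUM), MEDIUM, 5.0).fraction
            for n in (1, 3, 4)
        ]
        assert (max(fractions) - min(fractions)) * 100.0 < 5.0


class TestDepositedPerArea:
    def test_zero_fraction(self):
        assert deposited_per_area(0.0, 9.2e10, 0.5) == 0.0

    def test_printed_table_identities(self):
        # fraction x C0 x h reproduces the tabulated areal densities
        assert deposited_per_area(0.265, 9.2e10, 0.5) == pytest.approx(1.22e10, rel=5e-3)
        assert deposited_per_area(0.204, 9.2e10, 0.5) == pytest.approx(9.40e9, rel=5e-3)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            deposited_per_area(1.2, 9.2e10, 0.5)


class TestSpecs:
    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MediumSpec(height_mm=5.0, volume_ml=1.0, base_area_cm2=3.8)

    def test_consistent_geometry_accepted(self):
        m = MediumSpec(height_mm=5.0, volume_ml=1.0, base_area_cm2=2.0)
        assert m.area_cm2 == 2.0

    @pytest.mark.parametrize(
        "kwargs", [dict(diameter_nm=-1, density_g_cm3=1.8),
                   dict(diameter_nm=25, density_g_cm3=0),
                   dict(diameter_nm=25, density_g_cm3=1.8, cluster_size=0)]
    )
    def test_invalid_particle_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ParticleSpec(**kwargs)
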