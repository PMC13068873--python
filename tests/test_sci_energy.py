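"""Screened-Coulomb energetics: closed form, Fourier-space oracle, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sciapt.geometry import Lattice1D
from sciapt.sci_energy import (
    ScreeningParams,
    coulomb_pair,
    default_scale_grid,
    energy_profile,
    fourier_oracle,
    sci_energy_at_order,
    transition_extremes,
)

# e^2/(4 pi eps0) in eV nm, from CODATA constants
COULOMB_EV_NM = 1.439964548


def toy_lattice():
    return Lattice1D(
        positions=(0.0, 0.4, 0.9, 1.5),
        charges=(-1.0, 0.5, -0.25, 1.0),
        labels=("o", "m1", "m2", "t"),
    )


class TestCoulombPair:
    def test_unit_charges_at_one_nm_in_vacuum(self):
        sp = ScreeningParams(eps_r=1.0, lambda_D=1.0)
        assert coulomb_pair(1.0, -1.0, 1.0, sp) == pytest.approx(
            -COULOMB_EV_NM, rel=1e-8
        )

    def test_sign_flip_antisymmetry(self, sp):
        assert coulomb_pair(1.0, 1.0, 0.7, sp) == -coulomb_pair(1.0, -1.0, 0.7, sp)

    def test_dielectric_scaling(self):
        e1 = coulomb_pair(1.0, -1.0, 1.0, ScreeningParams(eps_r=1.0))
        e80 = coulomb_pair(1.0, -1.0, 1.0, ScreeningParams(eps_r=80.0))
        assert e80 == pytest.approx(e1 / 80.0)

    def test_nonpositive_separation_rejected(self, sp):
        with pytest.raises(ValueError):
            coulomb_pair(1.0, 1.0, 0.0, sp)

    def test_thermal_unit_conversion(self):
        ev = coulomb_pair(1.0, 1.0, 1.0, ScreeningParams(energy_unit="eV"))
        kt = coulomb_pair(1.0, 1.0, 1.0, ScreeningParams(energy_unit="kBT_298"))
        # 1 eV is ~38.9 kBT at 298 K
        assert kt / ev == pytest.approx(1.0 / 0.02568, rel=1e-3)


class TestSciEnergyAtOrder:
    def test_order_zero_is_solvent_screened_coulomb(self, sp):
        lat = toy_lattice()
        expected = coulomb_pair(-1.0, 0.5, 0.4, sp) * math.exp(-0.4 / sp.lambda_D)
        assert sci_energy_at_order(lat, 0, sp) == pytest.approx(expected)

    def test_one_unit_intervening_charge_halves_lambda(self):
        sp = ScreeningParams(eps_r=1.0, lambda_D=2.0)
        lat = Lattice1D(
            positions=(0.0, 0.5, 1.0),
            charges=(-1.0, 1.0, 1.0),
            labels=("o", "m", "t"),
        )
        # lambda_eff = 2.0 / (1 + 1) = 1.0
        expected = coulomb_pair(-1.0, 1.0, 1.0, sp) * math.exp(-1.0 / 1.0)
        assert sci_energy_at_order(lat, 1, sp) == pytest.approx(expected)

    def test_order_two_matches_hand_evaluation(self):
        # step-by-step arithmetic of the closed form, independent of the module:
        # r = 1.5 nm; intervening weights 0.5 + 0.25 -> lambda_eff = 1/1.75 nm
        sp = ScreeningParams(eps_r=80.0, lambda_D=1.0)
        hand = (1.439964548 * (-1.0) * 1.0 / (80.0 * 1.5)) * math.exp(-1.5 * 1.75)
        assert sci_energy_at_order(toy_lattice(), 2, sp) == pytest.approx(
            hand, rel=1e-8
        )

    def test_multiplicity_scales_screening_weight(self, sp):
        plain = Lattice1D(
            positions=(0.0, 0.5, 1.0), charges=(-1.0, -1.0, -1.0),
            labels=("o", "m", "t"),
        )
        coarse = Lattice1D(
            positions=(0.0, 0.5, 1.0), charges=(-1.0, -1.0, -1.0),
            labels=("o", "m", "t"), multiplicities=(1, 4, 1),
        )
        e_plain = sci_energy_at_order(plain, 1, sp)
        e_coarse = sci_energy_at_order(coarse, 1, sp)
        # lambda_eff 1/2 vs 1/5 -> coarse attenuated by exp(-3)
        assert e_coarse / e_plain == pytest.approx(math.exp(-3.0))

    def test_order_beyond_lattice_raises(self, sp):
        with pytest.raises(IndexError):
            sci_energy_at_order(toy_lattice(), 3, sp)

    def test_attenuation_monotone_in_intervening_charges(self, sp):
        # same terminal pair, growing number of intervening unit charges
        mags = []
        for n_between in range(4):
            inner = tuple(0.5 + 0.2 * k for k in range(n_between))
            lat = Lattice1D(
                positions=(0.0, *inner, 2.0),
                charges=(-1.0, *([-1.0] * n_between), -1.0),
                labels=tuple(str(i) for i in range(n_between + 2)),
            )
            mags.append(abs(sci_energy_at_order(lat, n_between, sp)))
        assert all(a > b for a, b in zip(mags, mags[1:]))

    @settings(max_examples=50, deadline=None)
    @given(q0=st.floats(0.1, 1.0), qt=st.floats(0.1, 1.0))
    def test_bilinear_in_terminal_charges(self, sp, q0, qt):
        base = Lattice1D(
            positions=(0.0, 0.5, 1.2), charges=(-1.0, 0.3, 1.0),
            labels=("o", "m", "t"),
        )
        scaled = Lattice1D(
            positions=(0.0, 0.5, 1.2), charges=(-q0, 0.3, qt),
            labels=("o", "m", "t"),
        )
        assert sci_energy_at_order(scaled, 1, sp) == pytest.approx(
            sci_energy_at_order(base, 1, sp) * q0 * qt
        )

    def test_unscreened_limit_recovers_bare_coulomb(self):
        # deviation at finite lambda is ~ r/lambda_D; infinite lambda is exact
        sp = ScreeningParams(eps_r=80.0, lambda_D=1e6)
        lat = toy_lattice()
        bare = coulomb_pair(-1.0, 0.5, 0.4, sp)
        assert abs(sci_energy_at_order(lat, 0, sp) - bare) / abs(bare) < 1e-6
        sp_inf = ScreeningParams(eps_r=80.0, lambda_D=math.inf)
        assert sci_energy_at_order(lat, 0, sp_inf) == coulomb_pair(-1.0, 0.5, 0.4, sp_inf)


class TestEnergyProfile:
    def test_single_point_profile_is_identity(self, sp):
        lat = toy_lattice()
        prof = energy_profile(lat, 1, sp, scale_grid=[1.0])
        assert prof.energies[0] == pytest.approx(sci_energy_at_order(lat, 1, sp))

    def test_doubling_distance_weakens_interaction(self, sp):
        lat = toy_lattice()
        prof = energy_profile(lat, 2, sp, scale_grid=[1.0, 2.0])
        assert abs(prof.energies[1]) < abs(prof.energies[0])

    def test_profile_matches_pointwise_reevaluation(self, registry, ps, sp):
        from sciapt.geometry import build_pair_lattice

        lat = build_pair_lattice(ps, registry["C"])
        grid = default_scale_grid()
        prof = energy_profile(lat, 1, sp, grid)
        for s, e in zip(prof.scale_grid[::30], prof.energies[::30]):
            assert e == pytest.approx(sci_energy_at_order(lat.scaled(s), 1, sp))

    def test_determinism(self, registry, ps, sp):
        from sciapt.geometry import build_pair_lattice

        lat = build_pair_lattice(ps, registry["G"])
        p1 = energy_profile(lat, 3, sp)
        p2 = energy_profile(lat, 3, sp)
        assert p1.energies == p2.energies  # bit-identical


class TestFourierOracle:
    def test_agrees_with_closed_form_across_parameter_box(self, sp):
        r = np.linspace(0.3, 5.0, 12)
        for lam in (0.3, 1.0, 3.0):
            numeric = fourier_oracle(-1.0, 1.0, lam, r, sp)
            closed = np.array(
                [coulomb_pair(-1.0, 1.0, ri, sp) * math.exp(-ri / lam) for ri in r]
            )
            assert np.all(np.abs(numeric - closed) <= 0.01 * np.abs(closed))

    def test_unscreened_limit_converges_to_bare_coulomb(self, sp):
        r = np.array([0.5, 1.0, 2.0])
        numeric = fourier_oracle(-1.0, 1.0, 1e6, r, sp)
        bare = np.array([coulomb_pair(-1.0, 1.0, ri, sp) for ri in r])
        assert numeric == pytest.approx(bare, rel=1e-5)

    def test_like_charges_repel_everywhere(self, sp):
        vals = fourier_oracle(1.0, 1.0, 1.0, np.linspace(0.3, 3.0, 7), sp)
        assert np.all(vals > 0)

    def test_rejects_bad_inputs(self, sp):
        with pytest.raises(ValueError):
            fourier_oracle(1.0, 1.0, -1.0, [1.0], sp)
        with pytest.raises(ValueError):
            fourier_oracle(1.0, 1.0, 1.0, [0.0], sp)


class TestTransitionExtremes:
    def test_direct_max_min_of_magnitudes(self):
        from sciapt.sci_energy import EnergyProfile

        prof = EnergyProfile(order=0, scale_grid=(1.0, 2.0, 3.0), energies=(-8.0, -2.0, -0.5))
        ext = transition_extremes(prof)
        assert ext.g_high == 8.0
        assert ext.g_low == 0.5
        assert ext.log_dg == pytest.approx(math.log10(8.0))

    def test_monotone_profile_extremes_at_grid_ends(self, registry, ps, sp):
        from sciapt.geometry import build_pair_lattice

        lat = build_pair_lattice(ps, registry["A"])
        prof = energy_profile(lat, 2, sp)
        ext = transition_extremes(prof)
        assert ext.g_high == pytest.approx(abs(prof.energies[0]))
        assert ext.g_low == pytest.approx(abs(prof.energies[-1]))

    def test_low_end_negligible_on_defaults(self, registry, ps, sp):
        # justifies treating dG ~ G_I
        from sciapt.geometry import build_pair_lattice

        lat = build_pair_lattice(ps, registry["G"])
        for order in lat.partner_orders():
            ext = transition_extremes(energy_profile(lat, order, sp))
            assert ext.g_low < 1e-6 * ext.g_high

    def test_degenerate_profile_rejected(self):
        from sciapt.sci_energy import EnergyProfile

        prof = EnergyProfile(order=0, scale_grid=(1.0, 2.0, 3.0), energies=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            transition_extremes(prof)
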