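import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import jv, yv

from flukeprop import (
    CoeffSurface,
    FoilState,
    InvalidInputError,
    feathering_parameter,
    foil_coefficients,
    reduced_frequency,
    theodorsen,
)
from flukeprop.exceptions import ConfigurationError
from flukeprop.foil import read_surface, write_surface


def theodorsen_oracle(k):
    """Independent closed form: F and G from J0, J1, Y0, Y1 directly."""
    j0, j1, y0, y1 = jv(0, k), jv(1, k), yv(0, k), yv(1, k)
    den = (j1 + y0) ** 2 + (y1 - j0) ** 2
    return (j1 * (j1 + y0) + y1 * (y1 - j0)) / den, -(y1 * y0 + j1 * j0) / den


class TestTheodorsen:
    def test_quasi_steady_limit(self):
        assert theodorsen(0.0) == 1.0 + 0.0j

    def test_high_frequency_asymptote(self):
        c = theodorsen(1e4)
        assert c.real == pytest.approx(0.5, abs=1e-3)
        assert c.imag == pytest.approx(0.0, abs=1e-3)

    def test_against_independent_bessel_oracle(self):
        for k in (0.05, 0.2, 0.5, 1.0, 3.0):
            c = theodorsen(k)
            f_ref, g_ref = theodorsen_oracle(k)
            assert c.real == pytest.approx(f_ref, abs=1e-10)
            assert c.imag == pytest.approx(g_ref, abs=1e-10)

    @given(k=st.floats(1e-4, 50))
    @settings(max_examples=100, derandomize=True)
    def test_bounds(self, k):
        """F in [1/2, 1], G <= 0 for all reduced frequencies."""
        c = theodorsen(k)
        assert 0.5 - 1e-9 <= c.real <= 1.0 + 1e-9
        assert c.imag <= 1e-12

    def test_negative_k_rejected(self):
        with pytest.raises(InvalidInputError):
            theodorsen(-0.1)


class TestReducedFrequency:
    def test_printed_blue_whale_means(self):
        # sigma = 2*pi*0.18 * 1.2 / (2 * 2.20)
        assert reduced_frequency(0.18, 1.2, 2.20) == pytest.approx(0.30844727871608874, rel=1e-12)

    def test_linear_in_chord(self):
        assert reduced_frequency(0.18, 2.4, 2.20) == pytest.approx(
            2 * reduced_frequency(0.18, 1.2, 2.20)
        )

    def test_zero_frequency(self):
        assert reduced_frequency(0.0, 1.2, 2.2) == 0.0

    def test_full_chord_convention_doubles(self):
        assert reduced_frequency(0.18, 1.2, 2.2, "full_chord") == pytest.approx(
            2 * reduced_frequency(0.18, 1.2, 2.2, "half_chord")
        )

    def test_zero_speed_rejected(self):
        with pytest.raises(InvalidInputError):
            reduced_frequency(0.18, 1.2, 0.0)


class TestFeatheringParameter:
    def test_printed_blue_whale_means(self):
        omega = 2 * math.pi * 0.18
        theta = feathering_parameter(math.radians(30), 2.20, omega, 0.2 * 22.41)
        assert theta == pytest.approx(0.2272464342968582, rel=1e-12)

    def test_pure_heave(self):
        assert feathering_parameter(0.0, 2.2, 1.1, 4.0) == 0.0

    def test_fully_feathered_at_path_angle(self):
        omega, h, u = 1.1, 4.0, 2.2
        alpha = omega * h / u
        assert feathering_parameter(alpha, u, omega, h) == pytest.approx(1.0)

    def test_clipping_above_one_warns(self):
        with pytest.warns(RuntimeWarning):
            assert feathering_parameter(1.0, 10.0, 0.5, 1.0) == 1.0

    def test_zero_heave_rejected(self):
        with pytest.raises(InvalidInputError):
            feathering_parameter(0.5, 2.0, 1.0, 0.0)


def _state(sigma_f=0.18, u=2.20, chord=1.2, length=22.41):
    return FoilState.from_kinematics(sigma_f, u, chord, 0.2 * length, math.radians(30))


class TestAnalyticEngine:
    def test_feathered_foil_produces_no_thrust(self):
        for sigma in (0.1, 0.5, 2.0):
            state = FoilState(sigma, 1.0, 1.0, 1.2, 4.482, 0.5, 2.2)
            ct, eta = foil_coefficients(state)
            assert ct == 0.0
            assert eta == pytest.approx(1.0)

    def test_quasi_steady_ideal_limit(self):
        state = FoilState(1e-6, 0.0, 1.0, 1.2, 4.482, 0.0, 2.2)
        _, eta = foil_coefficients(state)
        assert eta == pytest.approx(1.0, abs=1e-4)

    def test_blue_whale_worked_example_matches_theodorsen_oracle(self):
        """eta at the printed routine blue-whale state, fixed by the blend of
        the Garrick heave efficiency evaluated with the independent oracle."""
        state = _state()
        ct, eta = foil_coefficients(state)
        f_ref, g_ref = theodorsen_oracle(state.sigma)
        eta_heave = (f_ref**2 + g_ref**2) / f_ref
        eta_ref = (1 + state.theta) / 2 + (eta_heave - 0.5) * (1 - state.theta)
        assert eta == pytest.approx(eta_ref, rel=1e-10)
        assert eta > 0.75  # the stated high-efficiency class for rorquals
        assert ct > 0

    def test_eta_monotone_in_theta_ct_antitone(self):
        sigmas = np.linspace(0.05, 2.0, 12)
        thetas = np.linspace(0.0, 1.0, 12)
        for sigma in sigmas:
            cts, etas = [], []
            for theta in thetas:
                ct, eta = foil_coefficients(FoilState(sigma, theta, 1.0, 1.2, 4.482, 0.5, 2.2))
                cts.append(ct)
                etas.append(eta)
            assert np.all(np.diff(etas) >= -1e-12)
            assert np.all(np.diff(cts) <= 1e-12)

    def test_eta_to_one_as_sigma_vanishes_for_any_theta(self):
        for theta in (0.0, 0.3, 0.7, 1.0):
            _, eta = foil_coefficients(FoilState(1e-3, theta, 1.0, 1.2, 4.482, 0.5, 2.2))
            assert abs(eta - 1.0) < 0.01


def _bilinear_surface():
    """Table whose values are a bilinear function: interpolation must be exact."""
    sigma = np.array([0.1, 0.4, 0.9])
    theta = np.array([0.0, 0.5, 0.9])
    ct = np.add.outer(2.0 * sigma, -1.5 * theta) + 2.0
    eta = 0.05 * np.add.outer(sigma, theta) + 0.5
    return CoeffSurface(sigma, theta, ct, eta, provenance="synthetic bilinear")


class TestTabulatedEngine:
    def test_constant_table_returns_constant(self):
        sigma = np.array([0.1, 1.0])
        theta = np.array([0.0, 0.9])
        surf = CoeffSurface(sigma, theta, np.full((2, 2), 0.5), np.full((2, 2), 0.5))
        state = FoilState(0.4, 0.3, 1.0, 1.2, 4.482, 0.5, 2.2)
        assert foil_coefficients(state, "tabulated", surf) == (0.5, 0.5)

    def test_reproduces_nodes_exactly(self):
        surf = _bilinear_surface()
        for i, s in enumerate(surf.sigma_grid):
            for j, t in enumerate(surf.theta_grid):
                ct, eta = surf.interpolate(s, t)
                assert ct == pytest.approx(surf.ct_table[i, j], rel=1e-14)
                assert eta == pytest.approx(surf.eta_table[i, j], rel=1e-14)

    def test_bilinear_consistency_to_machine_precision(self):
        surf = _bilinear_surface()
        for s, t in [(0.2, 0.25), (0.55, 0.7), (0.85, 0.05)]:
            ct, eta = surf.interpolate(s, t)
            assert ct == pytest.approx(2.0 * s - 1.5 * t + 2.0, rel=1e-12)
            assert eta == pytest.approx(0.05 * (s + t) + 0.5, rel=1e-12)

    def test_out_of_grid_clips_with_warning(self):
        surf = _bilinear_surface()
        with pytest.warns(RuntimeWarning):
            ct, eta = surf.interpolate(2.0, 0.5)
        assert (ct, eta) == surf.interpolate(0.9, 0.5)

    def test_engine_without_surface_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            foil_coefficients(_state(), "tabulated", None)

    @pytest.mark.parametrize(
        "eta_val, ct_val", [(1.5, 1.0), (0.9, -1.0)]
    )
    def test_invalid_tables_rejected(self, eta_val, ct_val):
        sigma, theta = np.array([0.1, 1.0]), np.array([0.0, 0.5])
        with pytest.raises(InvalidInputError):
            CoeffSurface(sigma, theta, np.full((2, 2), max(ct_val, 0.0) if ct_val > 0 else ct_val),
                         np.full((2, 2), eta_val))

    def test_ct_must_vanish_when_fully_feathered(self):
        sigma, theta = np.array([0.1, 1.0]), np.array([0.0, 1.0])
        with pytest.raises(InvalidInputError):
            CoeffSurface(sigma, theta, np.full((2, 2), 1.0), np.full((2, 2), 0.9))

    def test_surface_file_round_trip(self, tmp_path):
        surf = _bilinear_surface()
        path = tmp_path / "surface.txt"
        write_surface(surf, path)
        back = read_surface(path)
        np.testing.assert_allclose(back.sigma_grid, surf.sigma_grid)
        np.testing.assert_allclose(back.ct_table, surf.ct_table)
        np.testing.assert_allclose(back.eta_table, surf.eta_table)
        assert back.provenance == "synthetic bilinear"
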