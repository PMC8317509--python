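import dataclasses

import numpy as np
import pytest

import flukeprop as fp
from flukeprop.exceptions import InvalidInputError
from flukeprop.tailbeats import LUNGE, ROUTINE


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fluking_frequency_hz": 3.0},
            {"drag_coefficient_true": 0.5},
            {"sampling_hz": 0.5},
            {"body_length_m": -1.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(InvalidInputError):
            fp.SimConfig(**kwargs)


class TestSampleMorphology:
    def test_cube_law_mass(self):
        cfg = fp.SimConfig(body_length_m=5.0, mass_a=10, mass_b=3,
                           calibrate_fluke_area=False)
        assert fp.sample_morphology(cfg).mass_kg == pytest.approx(1250.0)

    def test_square_law_wetted_area(self):
        cfg = fp.SimConfig(body_length_m=5.0, area_c=0.4, area_d=2,
                           calibrate_fluke_area=False)
        assert fp.sample_morphology(cfg).wetted_area_m2 == pytest.approx(10.0)

    def test_blue_whale_chord_fraction(self):
        cfg = fp.SimConfig(body_length_m=22.41, chord_fraction=0.054)
        assert fp.sample_morphology(cfg).fluke_chord_m == pytest.approx(1.21, abs=0.005)

    def test_calibration_balances_foil_thrust_with_drag_at_cruise(self):
        cfg = fp.SimConfig()
        morph = fp.sample_morphology(cfg)
        state = fp.FoilState.from_kinematics(
            cfg.fluking_frequency_hz, cfg.cruise_speed_mps,
            morph.fluke_chord_m, morph.heave_amplitude_m, morph.attack_angle_rad,
        )
        ct, _ = fp.foil_coefficients(state)
        thrust = 0.5 * cfg.rho * cfg.cruise_speed_mps**2 * morph.fluke_area_m2 * ct
        drag = (0.5 * cfg.rho * morph.wetted_area_m2 * cfg.drag_coefficient_true
                * cfg.cruise_speed_mps**2)
        assert thrust == pytest.approx(drag, rel=1e-3)

    def test_non_positive_length_rejected(self):
        with pytest.raises(InvalidInputError):
            fp.SimConfig(body_length_m=0.0)


class TestSimulateTailbeatSeries:
    def test_constant_balance_thrust_is_fixed_point(self):
        """With T(t) = drag at cruise, the speed never leaves the cruise value."""
        cfg = fp.SimConfig(n_routine_beats=40, n_lunges=0, noise_sd_rps=0.0,
                           thrust_model="balance", thrust_waveform="constant")
        morph = fp.sample_morphology(cfg)
        series, _ = fp.simulate_tailbeat_series(cfg, morph)
        np.testing.assert_allclose(series.speed_mps, cfg.cruise_speed_mps, rtol=1e-12)

    def test_noiseless_gyro_cycle_count(self):
        cfg = fp.SimConfig(fluking_frequency_hz=0.2, n_routine_beats=120,
                           n_lunges=0, noise_sd_rps=0.0)
        morph = fp.sample_morphology(cfg)
        series, truth = fp.simulate_tailbeat_series(cfg, morph)
        assert series.duration_s == pytest.approx(600.0, abs=0.11)
        # count complete zero-crossing-pair cycles of the constructed sinusoid
        s = np.sign(series.gyro_y_rps)
        ups = np.sum((s[:-1] < 0) & (s[1:] > 0))
        assert ups in (119, 120)
        assert len(truth.beat_boundaries) == 120

    def test_energy_bookkeeping_at_cruise(self):
        """Over the whole record the mean thrust balances mean drag within 1%."""
        cfg = fp.SimConfig(n_routine_beats=100, n_lunges=0, noise_sd_rps=0.0)
        morph = fp.sample_morphology(cfg)
        series, _ = fp.simulate_tailbeat_series(cfg, morph)
        u = series.speed_mps
        accel_force = (morph.mass_kg * (1 + morph.added_mass_coeff)
                       * (u[-1] - u[0]) / series.duration_s)
        drag_mean = 0.5 * cfg.rho * morph.wetted_area_m2 * cfg.drag_coefficient_true * np.mean(u**2)
        assert abs(accel_force) < 0.01 * drag_mean

    def test_speed_strictly_positive(self, deployment):
        _, series, _ = deployment
        assert np.all(series.speed_mps > 0)

    def test_truth_beat_count_matches_configuration(self):
        cfg = fp.SimConfig(n_routine_beats=75, n_lunges=0)
        series, truth = fp.simulate_tailbeat_series(cfg, fp.sample_morphology(cfg))
        assert len(truth.beat_boundaries) == 75
        assert all(m == ROUTINE for m in truth.beat_modes)

    def test_unstable_parameters_raise_simulation_error(self):
        # near-massless body with full-scale drag: explicit Euler overshoots
        # the decaying speed below zero within one step
        cfg = fp.SimConfig(n_routine_beats=40, n_lunges=0, mass_a=1e-4,
                           calibrate_fluke_area=False, fluke_area_fraction=1e-12)
        with pytest.raises(fp.SimulationError):
            fp.simulate_tailbeat_series(cfg, fp.sample_morphology(cfg))


class TestInjectLunges:
    def test_zero_lunges_is_identity(self):
        cfg = fp.SimConfig(n_routine_beats=50, n_lunges=0)
        morph = fp.sample_morphology(cfg)
        series, truth = fp.simulate_tailbeat_series(cfg, morph)
        out_series, out_truth = fp.inject_lunges(series, truth, cfg, morph)
        assert out_series is series and out_truth is truth

    def test_lunge_associated_beats_intersect_window(self, deployment):
        _, _, truth = deployment
        assert truth.lunge_times
        for (a, b), mode in zip(truth.beat_boundaries, truth.beat_modes):
            hits = any(a < tl and b > tl - 10.0 for tl in truth.lunge_times)
            assert (mode == LUNGE) == hits

    def test_frequency_increment_matches_configured_default(self, deployment):
        """Lunge-associated minus routine oscillatory frequency ~ +0.102 Hz."""
        _, _, truth = deployment
        freqs = {ROUTINE: [], LUNGE: []}
        for (a, b), mode in zip(truth.beat_boundaries, truth.beat_modes):
            freqs[mode].append(1.0 / (b - a))
        diff = np.mean(freqs[LUNGE]) - np.mean(freqs[ROUTINE])
        assert diff == pytest.approx(0.102, abs=1e-6)

    def test_pre_lunge_acceleration_and_post_lunge_decay(self, deployment):
        _, series, truth = deployment
        tl = truth.lunge_times[0]
        t = series.time_s
        u = series.speed_mps
        u_before = u[np.searchsorted(t, tl - 10.0)]
        u_at = u[np.searchsorted(t, tl)]
        u_after = u[np.searchsorted(t, tl + 15.0)]
        assert u_at > u_before  # rising speed during prey approach
        assert u_after < u_at - 0.5  # rapid deceleration with the mouth open

    def test_lunge_too_close_to_record_edge_rejected(self):
        cfg = fp.SimConfig(n_routine_beats=4, n_lunges=1)
        morph = fp.sample_morphology(cfg)
        series, truth = fp.simulate_tailbeat_series(cfg, morph)
        with pytest.raises(InvalidInputError):
            fp.inject_lunges(series, truth, cfg, morph)


class TestGenerateDeployment:
    def test_determinism_under_fixed_seed(self, blue_cfg):
        m1, s1, t1 = fp.generate_deployment(blue_cfg)
        m2, s2, t2 = fp.generate_deployment(blue_cfg)
        np.testing.assert_array_equal(s1.gyro_y_rps, s2.gyro_y_rps)
        np.testing.assert_array_equal(s1.speed_mps, s2.speed_mps)
        assert t1.beat_boundaries == t2.beat_boundaries
        assert m1 == m2

    def test_seed_changes_noise_only(self, blue_cfg):
        cfg2 = dataclasses.replace(blue_cfg, seed=blue_cfg.seed + 1)
        _, s1, t1 = fp.generate_deployment(blue_cfg)
        _, s2, t2 = fp.generate_deployment(cfg2)
        assert not np.array_equal(s1.gyro_y_rps, s2.gyro_y_rps)
        assert len(t1.beat_boundaries) == len(t2.beat_boundaries)

    def test_default_config_passes_inclusion_qc(self):
        cfg = fp.SimConfig()
        _, _, truth = fp.generate_deployment(cfg)
        assert sum(m == ROUTINE for m in truth.beat_modes) > 200
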