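"""Synthetic-data generator: traces, movies, fiducials, ground truth."""

import numpy as np
import pytest

from smstoich import (ComplexPopulationSpec, SimulationConfig, count_steps,
                      fit_chromatic_map, simulate_fiducials, simulate_movie,
                      simulate_trace)
from smstoich.register import ChromaticMap
from smstoich.simulate import _simulate_fluor


def quiet_config(**kw):
    """Config with noise and blinking off unless overridden."""
    base = dict(background_sd=0.0, shot_noise_factor=0.0,
                dark_entry_rate_per_s=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTrace:
    def test_no_emitters_is_pure_background(self):
        cfg = SimulationConfig(background_mean=100.0, background_sd=10.0,
                               shot_noise_factor=0.0)
        trace, truth = simulate_trace(0, cfg, np.random.default_rng(0))
        se = 10.0 / np.sqrt(len(trace))
        assert abs(trace.intensities.mean() - 100.0) < 3 * se
        assert truth.bleach_frames == []

    def test_noiseless_staircase_has_equal_unit_steps(self):
        cfg = quiet_config(unit_intensity=100.0)
        # seek a seed whose three bleach times are well separated and away
        # from the trace ends (coincident bleaching is physically possible
        # but is not the staircase under test)
        for seed in range(50):
            trace, truth = simulate_trace(3, cfg, np.random.default_rng(seed))
            bf = truth.bleach_frames
            if (len(bf) == 3 and min(bf) >= 5 and max(bf) <= 240
                    and np.all(np.diff(bf) >= 5)):
                break
        fit = count_steps(trace)
        assert fit.n_down_steps == 3
        assert list(fit.changepoints) == truth.bleach_frames
        assert fit.step_sizes == pytest.approx([-100.0] * 3, abs=1e-9)

    def test_mean_prebleach_level_matches_two_fluorophores(self):
        cfg = SimulationConfig(unit_intensity=100.0, background_mean=50.0,
                               background_sd=5.0, shot_noise_factor=0.0,
                               dark_entry_rate_per_s=0.0)
        rng = np.random.default_rng(1)
        first = []
        for _ in range(3000):
            trace, truth = simulate_trace(2, cfg, rng)
            first.append(trace.intensities[0])
        # frame 0 precedes any bleach (bleach frame >= 1 by construction)
        expect = 50.0 + 2 * 100.0
        se = np.std(first, ddof=1) / np.sqrt(len(first))
        assert abs(np.mean(first) - expect) < 4 * se

    def test_negative_emitter_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(-1, SimulationConfig())

    def test_bleach_steps_conserved(self):
        # with a lifetime much shorter than the record every fluorophore
        # bleaches on record: one ground-truth step per fluorophore placed
        cfg = quiet_config(bleach_mean_lifetime_s=0.5)
        rng = np.random.default_rng(2)
        for n in (1, 2, 5, 8):
            _, truth = simulate_trace(n, cfg, rng)
            assert len(truth.bleach_frames) == n

    def test_reproducible_for_equal_seeds(self):
        cfg = SimulationConfig()
        t1, _ = simulate_trace(3, cfg, np.random.default_rng(7))
        t2, _ = simulate_trace(3, cfg, np.random.default_rng(7))
        assert np.array_equal(t1.intensities, t2.intensities)


class TestDarkStateKinetics:
    def test_mean_dark_dwell_converges(self):
        cfg = SimulationConfig(dark_entry_rate_per_s=2.0,
                               dark_lifetime_mean_s=1.5,
                               bleach_mean_lifetime_s=1e6)
        dt = cfg.frame_dt_s
        dwells = []
        rng = np.random.default_rng(3)
        while len(dwells) < 10_000:
            _, _, dark = _simulate_fluor(10_000, dt, cfg.bleach_mean_lifetime_s,
                                         cfg.dark_entry_rate_per_s,
                                         cfg.dark_lifetime_mean_s, rng)
            dwells.extend((b - a) * dt for a, b in dark if b < 10_000)
        mean = np.mean(dwells[:10_000])
        # discrete-frame kinetics carry a +dt/2-sized bias; 5% band
        assert abs(mean - 1.5) / 1.5 < 0.05


class TestSimulateMovie:
    def test_unbound_population_gives_empty_green_channel(self):
        cfg = quiet_config(image_size=(64, 64))
        pop = ComplexPopulationSpec(n_complexes=10,
                                    stoichiometry_weights={0: 1.0})
        _, green, truth = simulate_movie(pop, cfg, np.random.default_rng(0))
        assert np.all(green.frames == cfg.background_mean)
        assert (truth.complexes.n_labeled == 0).all()

    def test_identity_map_zero_jitter_pairs_positions_exactly(self):
        cfg = quiet_config(image_size=(64, 64),
                           chromatic_map=ChromaticMap(),
                           green_position_jitter_sd=0.0)
        pop = ComplexPopulationSpec(n_complexes=10,
                                    stoichiometry_weights={1: 1.0})
        _, _, truth = simulate_movie(pop, cfg, np.random.default_rng(1))
        assert truth.complexes.x_green.to_numpy() == pytest.approx(
            truth.complexes.x_red.to_numpy())
        assert truth.complexes.y_green.to_numpy() == pytest.approx(
            truth.complexes.y_red.to_numpy())

    def test_emitter_bookkeeping_is_complete(self):
        cfg = SimulationConfig(image_size=(128, 128))
        pop = ComplexPopulationSpec(n_complexes=25,
                                    stoichiometry_weights={1: 0.5, 2: 0.5},
                                    p_label=0.7, dimer_fraction=0.2)
        _, _, truth = simulate_movie(pop, cfg, np.random.default_rng(2))
        assert len(truth.complexes) == 25
        assert len(truth.green_bleach_frames) == 25
        for n_labeled, bleaches in zip(truth.complexes.n_labeled,
                                       truth.green_bleach_frames):
            assert len(bleaches) <= n_labeled
            assert list(bleaches) == sorted(bleaches)

    def test_red_channel_frame_protocol(self):
        cfg = quiet_config(image_size=(64, 64))
        pop = ComplexPopulationSpec(n_complexes=5, stoichiometry_weights={1: 1.0})
        red, green, _ = simulate_movie(pop, cfg, np.random.default_rng(3))
        assert red.n_frames == cfg.n_frames_red == 50
        assert green.n_frames == cfg.n_frames_green == 250
        assert red.excitation_nm == 633.0 and green.excitation_nm == 488.0

    def test_overcrowded_field_warns(self):
        cfg = quiet_config(image_size=(64, 64))
        pop = ComplexPopulationSpec(n_complexes=60, stoichiometry_weights={1: 1.0})
        with pytest.warns(UserWarning, match="overlap"):
            simulate_movie(pop, cfg, np.random.default_rng(4))

    def test_determinism(self):
        cfg = SimulationConfig(image_size=(64, 64))
        pop = ComplexPopulationSpec(n_complexes=8, stoichiometry_weights={1: 1.0})
        _, g1, _ = simulate_movie(pop, cfg, np.random.default_rng(9))
        _, g2, _ = simulate_movie(pop, cfg, np.random.default_rng(9))
        assert np.array_equal(g1.frames, g2.frames)


class TestSimulateFiducials:
    def test_identity_map_no_jitter_gives_equal_pairs(self):
        df = simulate_fiducials(ChromaticMap(), 10, 0.0, np.random.default_rng(0))
        assert df.x_green.to_numpy() == pytest.approx(df.x_red.to_numpy())
        assert df.y_green.to_numpy() == pytest.approx(df.y_red.to_numpy())

    def test_affine_round_trip_is_exact(self):
        cmap = ChromaticMap(matrix=[[1.01, 0.002], [-0.001, 0.99]],
                            translation=[2.5, -1.0])
        df = simulate_fiducials(cmap, 12, 0.0, np.random.default_rng(1))
        fitted = fit_chromatic_map(df)
        assert fitted.matrix == pytest.approx(cmap.matrix, abs=1e-9)
        assert fitted.translation == pytest.approx(cmap.translation, abs=1e-9)

    def test_jittered_translation_recovered_within_standard_error(self):
        cmap = ChromaticMap(translation=[1.5, -0.5])
        df = simulate_fiducials(cmap, 50, 0.1, np.random.default_rng(2))
        fitted = fit_chromatic_map(df)
        tol = 3 * 0.1 / np.sqrt(50)
        assert abs(fitted.translation[0] - 1.5) < 3 * tol + 0.05
        assert abs(fitted.translation[1] + 0.5) < 3 * tol + 0.05

    def test_zero_fiducials_rejected(self):
        with pytest.raises(ValueError):
            simulate_fiducials(ChromaticMap(), 0)


class TestValidation:
    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ComplexPopulationSpec(n_complexes=5,
                                  stoichiometry_weights={1: 0.5, 2: 0.3})

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ComplexPopulationSpec(n_complexes=5, stoichiometry_weights={1: 1.0},
                                  p_label=1.5)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_frames_green=0)
        with pytest.raises(ValueError):
            SimulationConfig(psf_sigma=-1.0)

    def test_irradiation_time_matches_protocol(self):
        cfg = SimulationConfig()
        assert cfg.green_irradiation_s == pytest.approx(12.5)
        assert cfg.red_irradiation_s == pytest.approx(2.5)
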