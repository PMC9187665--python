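"""Simulator ground-truth contracts: diffusion statistics, ribosome
kinetics, tether dynamics, photon-conserving rendering, and truth I/O."""

import numpy as np
import pytest

from tnt.config import KineticsConfig, SimulationConfig
from tnt.simulate import (
    SimulationTruth,
    export_truth,
    generate_bead_pair,
    import_truth,
    render_movie,
    ribosome_signal,
    simulate_signals,
    simulate_trajectories,
)


class TestTrajectories:
    def test_zero_diffusion_is_static(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(),
                                  "diffusion_coeff_um2_s": 0.0})
        truth = simulate_trajectories(cfg)
        assert np.allclose(truth.positions, truth.positions[:, :1, :])

    def test_msd_matches_closed_form(self):
        """Empirical per-axis MSD over >= 1e4 steps matches 2 D dt to 5%."""
        d, dt = 0.05, 10.0
        cfg = SimulationConfig(
            field_size_px=(4096, 4096), pixel_size_nm=130.0, n_z_planes=1,
            duration_s=dt * 50, n_mrna=400, diffusion_coeff_um2_s=d,
            frame_interval_s={"mrna": dt, "translation": dt * 10, "tether": dt * 10},
            rng_seed=7,
        )
        truth = simulate_trajectories(cfg)
        xy_um = truth.positions[:, :, :2] * cfg.pixel_size_nm / 1000.0
        steps = np.diff(xy_um, axis=1)
        # reflections are vanishingly rare in a 532x532 um field
        msd_per_axis = np.mean(steps**2)
        assert msd_per_axis == pytest.approx(2 * d * dt, rel=0.05)

    def test_reflection_keeps_positions_in_field(self):
        cfg = SimulationConfig(field_size_px=(16, 16), n_z_planes=3,
                               duration_s=500.0, n_mrna=20,
                               diffusion_coeff_um2_s=5.0, rng_seed=1)
        truth = simulate_trajectories(cfg)
        assert truth.positions[:, :, 0].min() >= 0
        assert truth.positions[:, :, 0].max() <= 15
        assert truth.positions[:, :, 1].min() >= 0
        assert truth.positions[:, :, 1].max() <= 15
        assert truth.positions[:, :, 2].min() >= 0
        assert truth.positions[:, :, 2].max() <= 2

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimulationConfig(diffusion_coeff_um2_s=-0.1)

    def test_seed_reproducibility(self, small_config):
        a = simulate_trajectories(small_config)
        b = simulate_trajectories(small_config)
        other = SimulationConfig(**{**small_config.to_dict(), "rng_seed": 43})
        c = simulate_trajectories(other)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)


class TestSignals:
    def test_no_initiation_means_zero_signal(self, small_config):
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(small_config), kin)
        assert np.all(truth.translation_signal == 0.0)

    def test_preloaded_runoff_finishes_at_event_oracle_time(self):
        """Initiation halted at t=0 with ribosomes preloaded past the epitope:
        the last ribosome exits at exactly (L - x_min)/v (event-driven oracle
        on <= 5 ribosomes)."""
        cfg = SimulationConfig(field_size_px=(32, 32), n_z_planes=1,
                               duration_s=900.0, n_mrna=1,
                               frame_interval_s={"mrna": 1.0, "translation": 10.0,
                                                 "tether": 10.0},
                               diffusion_coeff_um2_s=0.0, rng_seed=0)
        kin = KineticsConfig(orf_length_aa=1885, epitope_region_end_aa=318,
                             elongation_rate_aa_s=2.0, init_rate_per_s=0.5,
                             silencing_time_s=0.0)
        x0 = np.array([400.0, 700.0, 1000.0, 1300.0, 1600.0])
        truth = simulate_signals(simulate_trajectories(cfg), kin,
                                 preloaded_positions=[x0])
        # oracle: ribosome starting at x exits at (L - x)/v
        exit_times = (1885.0 - x0) / 2.0
        sig = truth.translation_signal[0]
        t = truth.times
        # all preloaded ribosomes are past the epitope -> signal = count remaining
        expected = np.array([(exit_times > ti).sum() for ti in t], dtype=float)
        assert np.array_equal(sig, expected)
        last = exit_times.max()
        assert sig[t < last].min() >= 1.0
        assert np.all(sig[t >= last] == 0.0)

    def test_ribosome_positions_ordered_and_bounded(self, small_config):
        kin = KineticsConfig(init_rate_per_s=0.1, elongation_rate_aa_s=5.0)
        truth = simulate_signals(simulate_trajectories(small_config), kin)
        for per_mrna in truth.ribosome_positions:
            for pos in per_mrna:
                assert np.all(np.diff(pos) >= 0)
                if len(pos):
                    assert pos.max() < kin.orf_length_aa

    def test_signal_bounded_by_ribosome_count(self, small_config):
        kin = KineticsConfig(init_rate_per_s=0.05)
        truth = simulate_signals(simulate_trajectories(small_config), kin)
        counts = truth.n_ribosomes()
        assert np.all(truth.translation_signal <= counts + 1e-12)

    def test_absorbing_tethering_is_monotone_and_capped(self, small_config):
        kin = KineticsConfig(n_tether_sites=15, tether_on_rate_per_s=0.02,
                             tether_off_rate_per_s=0.0)
        truth = simulate_signals(simulate_trajectories(small_config), kin)
        for trace in truth.tether_count:
            assert np.all(np.diff(trace) >= 0)
            assert trace.max() <= 15

    def test_ribosome_signal_ramp_and_saturation(self):
        assert ribosome_signal([159.0], 318.0) == pytest.approx(0.5)
        assert ribosome_signal([318.0, 1000.0], 318.0) == pytest.approx(2.0)
        assert ribosome_signal([], 318.0) == 0.0


class TestRendering:
    def test_zero_everything_renders_zero(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(),
                                  "photons_per_mrna_probe": 0.0,
                                  "photons_per_translation_unit": 0.0,
                                  "photons_per_tether_unit": 0.0,
                                  "background_level": 0.0,
                                  "read_noise_sd": 0.0})
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(cfg), kin, cfg)
        stack = render_movie(truth, cfg, noise=False)
        assert np.nansum(np.abs(stack.data)) == 0.0

    def test_static_emitter_peak_at_its_pixel(self):
        cfg = SimulationConfig(field_size_px=(33, 33), n_z_planes=5,
                               duration_s=10.0, n_mrna=1,
                               diffusion_coeff_um2_s=0.0, background_level=0.0,
                               read_noise_sd=0.0, rng_seed=5)
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(cfg), kin, cfg)
        stack = render_movie(truth, cfg, noise=False)
        x, y, z = truth.positions[0, 0]
        frame = stack.get(0, "mrna")
        zi, yi, xi = np.unravel_index(np.nanargmax(frame), frame.shape)
        assert (xi, yi, zi) == (round(x), round(y), round(z))

    def test_photobleach_follows_closed_form(self):
        """Noiseless peak at exposure k equals I0 * exp(-b k) (rel 1e-6)."""
        b = 0.05
        cfg = SimulationConfig(field_size_px=(33, 33), n_z_planes=3,
                               duration_s=100.0, n_mrna=1,
                               diffusion_coeff_um2_s=0.0, background_level=0.0,
                               read_noise_sd=0.0,
                               bleach_rate_per_exposure={"mrna": b,
                                                         "translation": 0.0,
                                                         "tether": 0.0},
                               rng_seed=2)
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(cfg), kin, cfg)
        stack = render_movie(truth, cfg, noise=False)
        ci = stack.channel_index("mrna")
        peaks = np.nanmax(stack.data[:, :, ci], axis=(1, 2, 3))
        expected = peaks[0] * np.exp(-b * np.arange(len(peaks)))
        np.testing.assert_allclose(peaks, expected, rtol=1e-6)

    def test_photon_conservation(self):
        """Integrated noiseless spot intensity over the volume equals
        photons x gain to 1%."""
        cfg = SimulationConfig(field_size_px=(65, 65), n_z_planes=13,
                               duration_s=10.0, n_mrna=1,
                               diffusion_coeff_um2_s=0.0, background_level=0.0,
                               read_noise_sd=0.0, photons_per_mrna_probe=1000.0,
                               camera_gain=2.0, rng_seed=9)
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(cfg), kin, cfg)
        stack = render_movie(truth, cfg, noise=False)
        total = np.nansum(stack.get(0, "mrna"))
        assert total == pytest.approx(1000.0 * 2.0, rel=0.01)

    def test_memory_guard(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "max_voxels": 1000})
        kin = KineticsConfig(init_rate_per_s=0.0, preload_steady_state=False)
        truth = simulate_signals(simulate_trajectories(cfg), kin, cfg)
        with pytest.raises(MemoryError, match="voxel"):
            render_movie(truth, cfg)

    def test_staggered_channels_are_nan_when_unexposed(self, small_config,
                                                       runoff_kinetics):
        truth = simulate_signals(simulate_trajectories(small_config),
                                 runoff_kinetics)
        stack = render_movie(truth, small_config)
        ci = stack.channel_index("translation")
        # translation sampled every 100 s, union grid every 10 s
        assert np.isnan(stack.data[1, :, ci]).all()
        assert np.isfinite(stack.data[0, :, ci]).all()

    def test_same_seed_bit_identical(self, small_config, runoff_kinetics):
        def run():
            t = simulate_signals(simulate_trajectories(small_config),
                                 runoff_kinetics)
            return render_movie(t, small_config).data
        a, b = run(), run()
        assert np.array_equal(a, b, equal_nan=True)


class TestBeads:
    def test_identity_transform_zero_jitter(self):
        a, b, _, _ = generate_bead_pair(np.eye(3), n_beads=10)
        np.testing.assert_array_equal(a, b)

    def test_pure_translation(self):
        h = np.array([[1, 0, 3.5], [0, 1, -2.0], [0, 0, 1.0]])
        a, b, _, _ = generate_bead_pair(h, n_beads=8)
        np.testing.assert_allclose(b - a, np.broadcast_to([3.5, -2.0], a.shape))

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="nonsingular"):
            generate_bead_pair(np.zeros((3, 3)))


class TestTruthIO:
    def test_round_trip(self, tmp_path, small_config, runoff_kinetics):
        truth = simulate_signals(simulate_trajectories(small_config),
                                 runoff_kinetics)
        export_truth(truth, tmp_path / "t")
        back = import_truth(tmp_path / "t")
        np.testing.assert_allclose(back.positions, truth.positions)
        np.testing.assert_allclose(back.translation_signal,
                                   truth.translation_signal)
        np.testing.assert_array_equal(back.tether_count, truth.tether_count)
        for m in range(truth.n_mrna):
            for i in range(len(truth.times)):
                np.testing.assert_allclose(back.ribosome_positions[m][i],
                                           truth.ribosome_positions[m][i])

    def test_empty_truth_round_trips(self, tmp_path, runoff_kinetics):
        cfg = SimulationConfig(field_size_px=(32, 32), duration_s=50.0,
                               n_mrna=0, rng_seed=0)
        truth = simulate_signals(simulate_trajectories(cfg), runoff_kinetics, cfg)
        export_truth(truth, tmp_path / "e")
        assert (tmp_path / "e" / "truth.csv").exists()

    def test_missing_column_is_named(self, tmp_path, small_config,
                                     runoff_kinetics):
        truth = simulate_signals(simulate_trajectories(small_config),
                                 runoff_kinetics)
        export_truth(truth, tmp_path / "t")
        import pandas as pd
        df = pd.read_csv(tmp_path / "t" / "truth.csv").drop(columns=["x_px"])
        df.to_csv(tmp_path / "t" / "truth.csv", index=False)
        with pytest.raises(ValueError, match="x_px"):
            import_truth(tmp_path / "t")


def test_config_rejects_non_divisible_intervals():
    with pytest.raises(ValueError, match="divide"):
        SimulationConfig(frame_interval_s={"mrna": 10.0, "translation": 25.0,
                                           "tether": 100.0})
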