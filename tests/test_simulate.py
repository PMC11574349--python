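"""Synthetic embryo generator: level model, rendering, noise, truth."""

import numpy as np
import pytest

from optoquant import simulate as sim
from optoquant.simulate import (ConfigurationError, GradientSpec, NoiseSpec,
                                PerturbationSpec, SimConfig, apply_noise,
                                nuclear_level_model, simulate_fixed_embryo,
                                simulate_foci_movie, simulate_frap_movie,
                                simulate_nuclei_movie)


class TestNuclearLevelModel:
    def test_no_perturbation_constant(self):
        spec = PerturbationSpec()
        for t in (0.0, 3.7, 40.0):
            assert nuclear_level_model(t, spec, 100.0) == 100.0

    def test_export_closed_form_recovery(self):
        """Instant export to the floor, then I_ss - alpha e^(-beta t)."""
        spec = PerturbationSpec(mode="export", light_on_frame=0,
                                light_off_frame=24,
                                export_rate_per_min=1e9,
                                reimport_rate_per_min=0.5)
        t_off = 24 * 25.0 / 60.0
        v = nuclear_level_model(t_off + 1 / 0.5, spec, 100.0, 25.0)
        assert v == pytest.approx(100 - 90 * np.exp(-1), abs=1e-9)

    def test_degrade_zero_rate_constant(self):
        spec = PerturbationSpec(mode="degrade", light_on_frame=0,
                                light_off_frame=24, degrade_rate_per_min=0.0)
        assert nuclear_level_model(8.0, spec, 100.0, 25.0) == 100.0

    def test_degrade_holds_after_delay_no_recovery(self):
        spec = PerturbationSpec(mode="degrade", light_on_frame=0,
                                light_off_frame=12,
                                degrade_rate_per_min=0.3,
                                degrade_post_light_delay=2)
        t = np.linspace(0, 30, 400)
        y = nuclear_level_model(t, spec, 100.0, 25.0)
        t_stop = (12 + 2) * 25.0 / 60.0
        tail = y[t >= t_stop + 0.01]
        assert np.allclose(tail, tail[0])
        assert tail[0] < 100.0

    def test_continuity_at_boundaries(self):
        for mode in ("export", "degrade"):
            spec = PerturbationSpec(mode=mode, light_on_frame=10,
                                    light_off_frame=30)
            t = np.linspace(0, 25, 5000)
            y = nuclear_level_model(t, spec, 100.0, 25.0)
            # continuous: steps bounded by max slope (k * baseline) * dt
            dt = t[1] - t[0]
            max_rate = max(spec.export_rate_per_min,
                           spec.degrade_rate_per_min) * 100.0
            assert np.max(np.abs(np.diff(y))) < 1.5 * max_rate * dt

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            nuclear_level_model(-1.0, PerturbationSpec(), 100.0)


class TestSimulateNucleiMovie:
    def test_deterministic_under_seed(self):
        cfg = sim.default_nuclei_config(seed=11, n_frames=3,
                                        image_shape=(128, 128))
        s1, t1 = simulate_nuclei_movie(cfg)
        s2, t2 = simulate_nuclei_movie(cfg)
        assert np.array_equal(s1.data, s2.data)
        assert all(np.array_equal(a, b) for a, b in
                   zip(t1.nuclei_tracks, t2.nuclei_tracks))

    def test_constant_mode_constant_intensity(self, clean_nuclei_movie):
        _, stack, truth = clean_nuclei_movie
        tr = truth.nuclei_tracks[0]
        f0, y, x = tr[0]
        iy, ix = int(round(y)), int(round(x))
        vals = stack.data[:, iy, ix]
        assert np.max(np.abs(vals - vals[0])) <= 1.0

    def test_export_reaches_floor(self):
        cfg = sim.default_nuclei_config(
            mode="export", seed=1, n_frames=40,
            noise=NoiseSpec(gaussian_sd=0.0))
        cfg = sim.replace(cfg, perturbation=PerturbationSpec(
            mode="export", light_on_frame=0, light_off_frame=24,
            export_rate_per_min=3.0))
        stack, truth = simulate_nuclei_movie(cfg)
        levels = np.stack(truth.nuclear_level)
        assert np.all(levels[:, 23] < 0.15 * levels[:, 0])

    def test_export_conserves_total_signal(self, export_movie):
        cfg, stack, truth = export_movie
        tot = stack.data[:, truth.embryo_mask].sum(axis=1)
        lo, hi = cfg.perturbation.light_on_frame, \
            cfg.perturbation.light_off_frame
        window = tot[lo:hi]
        assert (window.max() - window.min()) / window.mean() < 0.02

    def test_degrade_monotone_decay(self):
        cfg = sim.default_nuclei_config(mode="degrade", seed=2, n_frames=40,
                                        noise=NoiseSpec(gaussian_sd=0.0))
        stack, truth = simulate_nuclei_movie(cfg)
        lo, hi = cfg.perturbation.light_on_frame, \
            cfg.perturbation.light_off_frame
        mean = stack.data[:, truth.embryo_mask].mean(axis=1)
        assert np.all(np.diff(mean[lo:hi]) <= 1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_nuclei_movie(SimConfig(image_shape=(40, 40), n_frames=2))


class TestSimulateFociMovie:
    def test_saturated_activation_constant_truth(self):
        cfg = sim.default_foci_config(seed=3, n_frames=5)
        cfg = sim.replace(cfg, foci=sim.replace(
            cfg.foci, activation_probability=1.0))
        _, truth = simulate_foci_movie(cfg)
        counts = [len(f) for f in truth.foci_truth]
        assert len(set(counts)) == 1
        assert counts[0] == int(truth.active_nuclei.sum())

    def test_export_truth_counts_fall_and_recover(self):
        cfg = sim.default_foci_config(mode="export", seed=0, n_frames=100)
        _, truth = simulate_foci_movie(cfg)
        counts = np.array([len(f) for f in truth.foci_truth])
        lo = cfg.perturbation.light_on_frame
        hi = cfg.perturbation.light_off_frame
        assert counts[0] > 0
        assert counts[lo + 15:hi].max() == 0
        assert counts[-1] > 0.8 * counts[0]

    def test_degrade_truth_counts_do_not_recover(self):
        cfg = sim.default_foci_config(mode="degrade", seed=0, n_frames=100)
        _, truth = simulate_foci_movie(cfg)
        counts = np.array([len(f) for f in truth.foci_truth])
        assert counts[0] > 0
        assert counts[-1] == 0

    def test_foci_inside_embryo_and_nucleus(self, sna_movie):
        cfg, stack, truth = sna_movie
        r = cfg.nucleus_radius_px
        for f, frame in enumerate(truth.foci_truth):
            for i, y, x in frame:
                assert truth.embryo_mask[int(round(y)), int(round(x))]
                _, ny, nx = truth.nuclei_tracks[i][f]
                assert np.hypot(y - ny, x - nx) <= 0.5 * r + 1e-9

    def test_empty_domain_rejected(self):
        cfg = sim.default_foci_config(seed=0, n_frames=2)
        cfg = sim.replace(cfg, foci=sim.replace(cfg.foci,
                                                domain_band=(0.0, 0.001)))
        with pytest.raises(ConfigurationError):
            simulate_foci_movie(cfg)

    def test_deterministic_truth(self):
        cfg = sim.default_foci_config(seed=4, n_frames=3,
                                      image_shape=(256, 256))
        _, t1 = simulate_foci_movie(cfg)
        _, t2 = simulate_foci_movie(cfg)
        assert t1.foci_truth == t2.foci_truth


class TestSimulateFrap:
    def test_bleach_depth_matches_model(self):
        """Center nucleus sits at I_ss - alpha right after bleaching."""
        cfg = sim.default_frap_config(seed=0, n_frames=60,
                                      noise=NoiseSpec(gaussian_sd=0.0))
        stack, truth = simulate_frap_movie(
            cfg, bleach_roi=(127, 127, 60), bleach_frames=(21, 40),
            frap_params=(8628.0, 7807.0, 0.23))
        i = truth.frap_nucleus_index
        level = truth.nuclear_level[i]
        assert level[39] == pytest.approx(8628 - 7807, abs=1e-6)
        # rendered pixel check at the nucleus center
        _, y, x = truth.nuclei_tracks[i][39]
        assert stack.data[39, int(y), int(x)] == pytest.approx(821, abs=2)

    def test_instant_recovery_limit(self):
        cfg = sim.default_frap_config(seed=0, n_frames=50,
                                      noise=NoiseSpec(gaussian_sd=0.0))
        stack, truth = simulate_frap_movie(
            cfg, bleach_roi=(127, 127, 60), bleach_frames=(10, 20),
            frap_params=(5000.0, 4000.0, 1e9))
        i = truth.frap_nucleus_index
        assert truth.nuclear_level[i][20] == pytest.approx(5000.0, rel=1e-6)

    def test_rendered_trace_matches_closed_form(self):
        cfg = sim.default_frap_config(seed=2, n_frames=80,
                                      noise=NoiseSpec(gaussian_sd=0.0))
        stack, truth = simulate_frap_movie(
            cfg, bleach_roi=(127, 127, 60), bleach_frames=(21, 40),
            frap_params=(8628.0, 7807.0, 0.23))
        i = truth.frap_nucleus_index
        _, y, x = truth.nuclei_tracks[i][0]
        t = stack.times_min()
        t_rec = t[40:] - t[39]
        expected = 8628 - 7807 * np.exp(-0.23 * t_rec)
        measured = stack.data[40:, int(y), int(x)]
        assert np.max(np.abs(measured - expected)) < 2.0

    def test_roi_outside_embryo_rejected(self):
        cfg = sim.default_frap_config(seed=0, n_frames=30)
        with pytest.raises(ConfigurationError):
            simulate_frap_movie(cfg, bleach_roi=(2, 2, 5),
                                bleach_frames=(5, 10),
                                frap_params=(100.0, 50.0, 0.5))


class TestApplyNoise:
    def test_zero_noise_is_identity(self, sna_movie):
        _, stack, _ = sna_movie
        out = apply_noise(stack, NoiseSpec(gaussian_sd=0.0), seed=0)
        assert np.array_equal(out.data, stack.data)

    def test_salt_pepper_replacement_count(self):
        from optoquant.stacks import ImageStack
        data = np.full((1, 512, 512), 1000.0)
        data[0, 0, 0] = 4095.0   # distinct max so salt pixels change value
        base = ImageStack(data, 0.29, 25.0)
        out = apply_noise(base, NoiseSpec(
            gaussian_sd=0.0, salt_pepper_fraction=0.001), seed=0)
        n_replaced = int(np.sum(out.data != base.data))
        # binomial n=262144, p=0.001 -> 262 +/- ~3 sd
        assert abs(n_replaced - 262) < 3 * 35

    def test_deterministic(self, sna_movie):
        _, stack, _ = sna_movie
        a = apply_noise(stack, NoiseSpec(gaussian_sd=50.0, poisson=True,
                                         salt_pepper_fraction=0.001), seed=7)
        b = apply_noise(stack, NoiseSpec(gaussian_sd=50.0, poisson=True,
                                         salt_pepper_fraction=0.001), seed=7)
        assert np.array_equal(a.data, b.data)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseSpec(salt_pepper_fraction=0.5)


class TestSimulateFixedEmbryo:
    def test_full_circumference_width_one(self):
        cfg = sim.default_fixed_config(seed=0)
        _, truth = simulate_fixed_embryo(
            cfg, [("gene", [(0.0, 2 * np.pi)])])
        assert truth.true_widths["gene"][0] == pytest.approx(1.0, abs=1e-9)

    def test_circle_quarter_interval(self):
        cfg = sim.default_fixed_config(seed=0, image_shape=(512, 512))
        cfg = sim.replace(cfg, embryo_axes_frac=(0.35, 0.35))
        _, truth = simulate_fixed_embryo(
            cfg, [("gene", [(0.0, np.pi / 2)])])
        assert truth.true_widths["gene"][0] == pytest.approx(0.25, abs=1e-9)

    def test_zero_amplitude_uniform_ring(self):
        cfg = sim.default_fixed_config(seed=0)
        cfg = sim.replace(cfg, gradient=GradientSpec(
            amplitude=0.0, peak_position=0.0, sigma=0.15, offset=50.0))
        chans, truth = simulate_fixed_embryo(cfg)
        from scipy import ndimage

        from optoquant.geometry import dv_profile
        img = ndimage.gaussian_filter(chans.channels[0], 4)
        pos, prof = dv_profile(img, truth.mid_ellipse, n_bins=32)
        assert (prof.max() - prof.min()) < 0.1 * prof.mean()

    def test_too_many_channels_rejected(self):
        cfg = sim.default_fixed_config(seed=0)
        with pytest.raises(ConfigurationError):
            simulate_fixed_embryo(cfg, [("g", [(0, 1)])] * 4)
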