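"""Nuclei segmentation, embryo ellipse, midline band, tracking."""

import numpy as np
import pytest

from optoquant import simulate as sim
from optoquant.geometry import EllipseParams
from optoquant.nuclei import (NucleusObject, SegParams, fit_embryo_ellipse,
                              intensity_timeseries, link_tracks,
                              midline_band_filter, segment_movie,
                              segment_nuclei_frame)
from optoquant.stacks import ImageStack


class TestSegmentFrame:
    def test_field_counts_and_centroids(self, flat_field_movie):
        """A resolvable field of uniform nuclei: every nucleus found,
        centroids at the rendered disk centers."""
        _, stack, truth = flat_field_movie
        seg = segment_nuclei_frame(stack.data[0], SegParams())
        tru = np.array([[t[0][1], t[0][2]] for t in truth.nuclei_tracks])
        det = np.array([o.centroid for o in seg.objects])
        assert len(det) == len(tru)
        d = np.hypot(det[:, 0, None] - tru[None, :, 0],
                     det[:, 1, None] - tru[None, :, 1])
        assert d.min(axis=1).max() < 1.5
        assert np.median(d.min(axis=1)) < 0.5

    def test_touching_disks_split_by_watershed(self):
        from scipy.special import erfc
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        for cy, cx in ((60.0, 45.0), (60.0, 63.0)):   # touching at r=9
            r = np.hypot(yy - cy, xx - cx)
            img += 5000.0 * 0.5 * erfc((r - 9.0) / (0.5 * np.sqrt(2)))
        seg = segment_nuclei_frame(img, SegParams())
        assert len(seg.objects) == 2
        cents = sorted(o.centroid for o in seg.objects)
        assert cents[0][1] == pytest.approx(45.0, abs=1.5)
        assert cents[1][1] == pytest.approx(63.0, abs=1.5)

    def test_blank_frame_carries_forward(self, flat_field_movie):
        _, stack, _ = flat_field_movie
        prev = segment_nuclei_frame(stack.data[0], SegParams(), frame=0)
        seg = segment_nuclei_frame(np.zeros_like(stack.data[0]),
                                   SegParams(), prev=prev, frame=1)
        assert seg.carried_forward
        assert len(seg.objects) == len(prev.objects)

    def test_blank_frame_without_prev_rejected(self):
        with pytest.raises(ValueError, match="no nuclei"):
            segment_nuclei_frame(np.zeros((64, 64)), SegParams())

    def test_consecutive_blank_frames_stable(self, flat_field_movie):
        _, stack, _ = flat_field_movie
        blank = np.zeros_like(stack.data[0])
        prev = segment_nuclei_frame(stack.data[0], SegParams())
        n = len(prev.objects)
        for f in (1, 2, 3):
            prev = segment_nuclei_frame(blank, SegParams(), prev=prev,
                                        frame=f)
            assert len(prev.objects) == n


class TestEmbryoEllipse:
    def test_generator_ellipse_recovered(self, clean_nuclei_movie):
        _, stack, truth = clean_nuclei_movie
        ell = fit_embryo_ellipse(stack, SegParams())
        te = truth.embryo_ellipse
        assert ell.semi_major == pytest.approx(te.semi_major, rel=0.02)
        assert ell.semi_minor == pytest.approx(te.semi_minor, rel=0.02)
        assert abs(ell.orientation - te.orientation) < np.deg2rad(2)

    def test_circular_embryo(self):
        cfg = sim.default_nuclei_config(
            seed=9, n_frames=2, image_shape=(400, 400),
            embryo_axes_frac=(0.4, 0.4), noise=sim.NoiseSpec(gaussian_sd=0.0))
        stack, _ = sim.simulate_nuclei_movie(cfg)
        ell = fit_embryo_ellipse(stack, SegParams())
        assert ell.semi_major / ell.semi_minor == pytest.approx(1.0, abs=0.01)

    def test_dark_stack_rejected(self):
        stack = ImageStack(np.zeros((2, 64, 64)), 0.29, 25.0)
        with pytest.raises(ValueError):
            fit_embryo_ellipse(stack, SegParams())


class TestMidlineBand:
    ellipse = EllipseParams(center=(250.0, 250.0), semi_major=200.0,
                            semi_minor=120.0, orientation=0.0)

    @staticmethod
    def obj(y, x):
        return NucleusObject(label=1, centroid=(y, x), area=100.0,
                             mean_intensity=1.0)

    def test_boundary_inclusive(self):
        """Distance exactly 100 is kept, 101 is excluded."""
        on_mid = self.obj(250.0, 300.0)
        at_100 = self.obj(150.0, 300.0)
        at_101 = self.obj(149.0, 300.0)
        kept = midline_band_filter([on_mid, at_100, at_101], self.ellipse,
                                   band_px=100.0)
        assert on_mid in kept and at_100 in kept and at_101 not in kept

    def test_band_respects_orientation(self):
        tilted = EllipseParams(center=(0.0, 0.0), semi_major=200.0,
                               semi_minor=100.0, orientation=np.pi / 2)
        # major axis now vertical: distance is horizontal offset
        assert midline_band_filter([self.obj(500.0, 40.0)], tilted, 100.0)
        assert not midline_band_filter([self.obj(0.0, 120.0)], tilted, 100.0)

    def test_analytic_count(self, clean_nuclei_movie):
        _, stack, truth = clean_nuclei_movie
        seg = segment_nuclei_frame(stack.data[0], SegParams())
        ell = truth.embryo_ellipse
        kept = midline_band_filter(seg.objects, ell, 100.0)
        expected = sum(
            1 for o in seg.objects if abs(o.centroid[0] - ell.center[0]) <= 100)
        assert len(kept) == expected


class TestIntensityTimeseries:
    def test_constant_movie_flat_trace(self, clean_nuclei_movie):
        _, stack, truth = clean_nuclei_movie
        segs = segment_movie(stack, SegParams())
        ts = intensity_timeseries(stack, segs, truth.embryo_ellipse)
        assert np.nanmax(np.abs(ts["mean"] - ts["mean"][0])) <= 2.0

    def test_export_trace_follows_level_model(self, export_movie):
        """Normalized mean trace tracks the generator's level model."""
        cfg, stack, truth = export_movie
        segs = segment_movie(stack, SegParams())
        ell = fit_embryo_ellipse(stack, SegParams())
        ts = intensity_timeseries(stack, segs, ell)
        shape_model = truth.nuclear_level[0] / truth.nuclear_level[0][0]
        shape_meas = ts["mean"] / ts["mean"][0]
        assert np.nanmax(np.abs(shape_meas - shape_model)) < 0.05

    def test_degrade_keeps_falling_after_light_off(self):
        cfg = sim.default_nuclei_config(
            mode="degrade", seed=6, n_frames=44, image_shape=(256, 256),
            noise=sim.NoiseSpec(gaussian_sd=0.0))
        cfg = sim.replace(cfg, perturbation=sim.replace(
            cfg.perturbation, degrade_rate_per_min=0.6,
            degrade_post_light_delay=4))
        stack, truth = sim.simulate_nuclei_movie(cfg)
        segs = segment_movie(stack, SegParams())
        ts = intensity_timeseries(stack, segs, None)
        off = cfg.perturbation.light_off_frame
        post = ts["mean"][off:off + cfg.perturbation.degrade_post_light_delay]
        assert np.all(np.diff(post) < 0)

    def test_empty_frames_flagged_missing(self):
        seg_empty = type("S", (), {"objects": []})()
        stack = ImageStack(np.zeros((1, 8, 8)) + 1.0, 0.29, 25.0)
        ts = intensity_timeseries(stack, [seg_empty])
        assert np.isnan(ts["mean"][0]) and ts["n"][0] == 0

    def test_permutation_invariance(self, clean_nuclei_movie):
        _, stack, truth = clean_nuclei_movie
        seg = segment_nuclei_frame(stack.data[0], SegParams())
        rng = np.random.default_rng(0)
        shuffled = type(seg)(frame=0, label_image=seg.label_image,
                             objects=list(rng.permutation(seg.objects)))
        a = intensity_timeseries(stack, [seg], truth.embryo_ellipse)
        b = intensity_timeseries(stack, [shuffled], truth.embryo_ellipse)
        assert a["mean"][0] == pytest.approx(b["mean"][0])
        assert a["sd"][0] == pytest.approx(b["sd"][0])


class TestLinkTracks:
    @pytest.fixture(scope="class")
    def drift_movie(self):
        cfg = sim.default_nuclei_config(
            seed=4, n_frames=100, image_shape=(256, 256),
            noise=sim.NoiseSpec(gaussian_sd=0.0),
            baseline_from_gradient=False,
            drift_px_per_frame=(0.2, 0.15), occlusions=((5, 40, 45),))
        stack, truth = sim.simulate_nuclei_movie(cfg)
        segs = segment_movie(stack, SegParams())
        return cfg, stack, truth, segs

    def test_static_movie_identity_tracks(self, flat_field_movie):
        _, stack, truth = flat_field_movie
        segs = segment_movie(stack, SegParams())
        tracks = link_tracks(segs, end_window=1, min_coverage=0.5)
        assert len(tracks.tracks) == len(truth.nuclei_tracks)
        assert all(not g for g in tracks.gaps)

    def test_drift_with_occlusion_bridged(self, drift_movie):
        cfg, stack, truth, segs = drift_movie
        tracks = link_tracks(segs)
        gaps = [g for g in tracks.gaps if g]
        assert gaps == [[(40, 45)]]

    def test_track_purity_under_slow_drift(self, drift_movie):
        cfg, stack, truth, segs = drift_movie
        tracks = link_tracks(segs)
        start = np.array([[t[0][1], t[0][2]] for t in truth.nuclei_tracks])
        drift = np.asarray(cfg.drift_px_per_frame)
        impure = 0
        for pts in tracks.tracks:
            ids = {int(np.argmin(np.hypot(
                start[:, 0] + drift[0] * f - y,
                start[:, 1] + drift[1] * f - x)))
                for f, (y, x), _ in pts}
            impure += len(ids) > 1
        assert impure == 0
        assert len(tracks.tracks) >= 0.9 * len(truth.nuclei_tracks)

    def test_one_to_one_assignment(self, drift_movie):
        *_, segs = drift_movie
        tracks = link_tracks(segs)
        for f in range(len(segs)):
            seen = [(y, x) for pts in tracks.tracks
                    for ff, (y, x), _ in pts if ff == f]
            assert len(seen) == len(set(seen))

    def test_late_track_removed(self):
        """A nucleus appearing only in the last 30% of frames fails the
        half-coverage and first-frames filters."""
        objs_by_frame = []
        n_frames = 60
        for f in range(n_frames):
            objs = [NucleusObject(1, (50.0, 50.0), 100.0, 1.0)]
            if f >= 42:
                objs.append(NucleusObject(2, (150.0, 150.0), 100.0, 1.0))
            seg = type("S", (), {"objects": objs})()
            objs_by_frame.append(seg)
        tracks = link_tracks(objs_by_frame, radius_px=6.0)
        assert len(tracks.tracks) == 1
        assert tracks.tracks[0][0][1] == (50.0, 50.0)
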