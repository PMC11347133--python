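"""Generator ground truth: geometry, motion statistics, blinking kinetics,
and photon-faithful rendering."""

import numpy as np
import pytest

from sgnano import synthgen
from sgnano.synthgen import (
    Disk,
    MotionParams,
    Photophysics,
    SceneConfig,
    make_scene,
    render_movie,
    sample_scene_localizations,
    simulate_blinking,
    simulate_tracks,
)

UM2 = 1.0e6  # nm^2 per um^2


def _one_sg_config(**kw):
    r = np.sqrt(UM2 / np.pi)  # area exactly 1 um^2
    defaults = dict(
        field_size=(4000.0, 4000.0),
        sg_regions=(((2000.0, 2000.0), r),),
        cores_per_sg_area=10.0,
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


class TestScene:
    def test_core_count_is_poisson_with_density_times_area(self):
        """Mean core count over many scene draws matches density x area."""
        cfg = _one_sg_config()
        counts = [
            len(make_scene(cfg, seed=s).core_centers[0]) for s in range(1000)
        ]
        assert 9.4 <= np.mean(counts) <= 10.6

    def test_zero_density_gives_sgs_without_cores(self):
        scene = make_scene(_one_sg_config(cores_per_sg_area=0.0), seed=0)
        assert len(scene.sgs) == 1
        assert scene.all_core_centers.shape == (0, 2)

    def test_core_centers_lie_inside_their_sg(self):
        scene = make_scene(_one_sg_config(cores_per_sg_area=30.0), seed=1)
        sg = scene.sgs[0]
        assert scene.core_centers[0].size > 0
        assert sg.contains(scene.core_centers[0]).all()

    def test_sg_exceeding_field_is_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(field_size=(1000.0, 1000.0),
                        sg_regions=(((500.0, 500.0), 600.0),))


class TestTracks:
    def test_diffusive_step_variance_matches_2_d_dt(self):
        """Per-axis Brownian step variance equals 2*D*dt (here 0.00828 um^2)."""
        m = MotionParams(mode_fractions=(0, 0, 1), D_diff=0.23,
                         loc_noise_sigma=0.0, track_length=40)
        ts, _ = simulate_tracks(None, m, 2600, seed=7)
        steps_um = np.vstack([np.diff(t.xy, axis=0) for t in ts]) / 1000.0
        assert steps_um.size / 2 >= 1e5
        assert np.var(steps_um) == pytest.approx(2 * 0.23 * 0.018, rel=0.02)

    def test_stationary_without_noise_does_not_move(self):
        m = MotionParams(mode_fractions=(1, 0, 0), loc_noise_sigma=0.0)
        ts, _ = simulate_tracks(None, m, 5, seed=0)
        for t in ts:
            assert np.all(t.displacements() == 0.0)

    def test_confined_msd_plateau_is_4_r2_over_3(self):
        """Long-lag time-averaged MSD of confined motion reaches the
        saturation level of the confined-diffusion model, 4*R_conf^2/3."""
        m = MotionParams(mode_fractions=(0, 1, 0), R_conf_true=100.0,
                         D_conf_true=0.05, loc_noise_sigma=0.0,
                         track_length=20000)
        ts, _ = simulate_tracks(None, m, 3, seed=3)
        plateaus = []
        for t in ts:
            xy = t.xy / 1000.0
            for lag in (1500, 3000):
                d = xy[lag:] - xy[:-lag]
                plateaus.append(np.mean(np.sum(d * d, axis=1)))
        assert np.mean(plateaus) == pytest.approx(4 * 0.1**2 / 3, rel=0.10)

    def test_mode_labels_converge_to_requested_fractions(self):
        m = MotionParams(track_length=2)
        _, gt = simulate_tracks(None, m, 10000, seed=5)
        for k, p in enumerate(m.mode_fractions):
            frac = np.mean(gt.true_mode_labels == k)
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10000)

    def test_reproducible_and_seed_sensitive(self):
        m = MotionParams(track_length=10)
        a, _ = simulate_tracks(None, m, 4, seed=9)
        b, _ = simulate_tracks(None, m, 4, seed=9)
        c, _ = simulate_tracks(None, m, 4, seed=10)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.xy, tb.xy)
        assert not np.array_equal(a[0].xy, c[0].xy)

    def test_scene_start_positions_inside_sgs(self):
        scene = make_scene(_one_sg_config(), seed=0)
        m = MotionParams(mode_fractions=(1, 0, 0), loc_noise_sigma=0.0,
                         track_length=5)
        ts, _ = simulate_tracks(scene, m, 50, seed=1)
        starts = np.vstack([t.xy[0] for t in ts])
        assert scene.sgs[0].contains(starts).all()


class TestBlinking:
    def test_dwell_time_means_recovered(self):
        """Schedule run lengths recover mean_on/mean_off within 3 s.e.

        The tolerance adds two small systematic allowances inherent to the
        measurement (not the generator): half a frame for the 50%-coverage
        discretization, and theta^2/T for length-biased truncation of gaps
        that must complete inside the finite recording of length T.
        """
        photo = Photophysics(mean_on=1.0, mean_off=2.0)
        dt = 1 / 55
        _, gt = simulate_blinking(photo, 10000, 3000, dt, seed=4,
                                  make_traces=False)
        on_runs, off_runs = [], []
        for row in gt.emitter_frames_on:
            padded = np.concatenate([[0], row.astype(int), [0]])
            d = np.diff(padded)
            starts, stops = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
            if len(starts) == 0:
                continue
            # drop the censored last event and the leading off period
            runs = stops - starts
            if row[-1]:
                runs = runs[:-1]
            on_runs.extend(runs * dt)
            off_runs.extend((starts[1:] - stops[:-1]) * dt)
        T = 3000 * dt
        for observed, expected in [(on_runs, 1.0), (off_runs, 2.0)]:
            observed = np.asarray(observed)
            se = observed.std() / np.sqrt(observed.size)
            tol = 3 * se + 0.5 * dt + 2 * expected**2 / T
            assert abs(observed.mean() - expected) < tol

    def test_bleach_prob_one_gives_single_event(self):
        photo = Photophysics(mean_on=0.5, mean_off=0.2,
                             bleach_prob_per_on_event=1.0)
        _, gt = simulate_blinking(photo, 200, 2000, 1 / 55, seed=6,
                                  make_traces=False)
        for row in gt.emitter_frames_on:
            d = np.diff(np.concatenate([[0], row.astype(int), [0]]))
            assert (d == 1).sum() <= 1

    def test_huge_mean_off_keeps_emitters_dark(self):
        photo = Photophysics(mean_on=1.0, mean_off=1e9)
        _, gt = simulate_blinking(photo, 300, 1000, 1 / 55, seed=7,
                                  make_traces=False)
        assert gt.emitter_frames_on.mean() < 1e-3

    def test_traces_reproducible(self):
        photo = Photophysics()
        tr_a, _ = simulate_blinking(photo, 3, 500, 1 / 55, seed=11)
        tr_b, _ = simulate_blinking(photo, 3, 500, 1 / 55, seed=11)
        for a, b in zip(tr_a, tr_b):
            np.testing.assert_array_equal(a.intensities, b.intensities)


class TestRendering:
    def test_noiseless_photon_conservation(self):
        """Without noise, the rendered frame integrates to the photon count
        (no PSF truncation loss beyond 1%)."""
        cfg = SceneConfig(field_size=(4800.0, 4800.0), n_frames=1,
                          sg_regions=())
        photo = Photophysics(background_photons=0.0, camera_noise_sigma=0.0)
        movie, _ = render_movie(cfg, static_positions=np.array([[2400.0, 2400.0]]),
                                photo=photo, noise=False, quantize=False)
        assert movie[0].sum() == pytest.approx(268.0, rel=0.01)

    def test_zero_emitters_gives_pure_background(self):
        cfg = SceneConfig(field_size=(1600.0, 1600.0), n_frames=20,
                          sg_regions=())
        photo = Photophysics(background_photons=10.0, camera_noise_sigma=0.0)
        movie, _ = render_movie(cfg, photo=photo, noise=True, seed=1)
        assert movie.mean() == pytest.approx(10.0, abs=0.5)

    def test_subpixel_position_preserved_in_centroid(self):
        """Centroid of a noiseless render reproduces a +0.3 px offset."""
        cfg = SceneConfig(field_size=(4800.0, 4800.0), n_frames=1,
                          sg_regions=())
        photo = Photophysics(background_photons=0.0, camera_noise_sigma=0.0)
        x_true = (15 + 0.5 + 0.3) * 160.0
        y_true = (15 + 0.5) * 160.0
        movie, _ = render_movie(cfg, static_positions=np.array([[x_true, y_true]]),
                                photo=photo, noise=False, quantize=False)
        img = movie[0]
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        cx = ((xx + 0.5) * img).sum() / img.sum() * 160.0
        cy = ((yy + 0.5) * img).sum() / img.sum() * 160.0
        assert abs(cx - x_true) < 0.05 * 160.0
        assert abs(cy - y_true) < 0.05 * 160.0

    def test_out_of_field_emitter_skipped_with_warning(self):
        cfg = SceneConfig(field_size=(1600.0, 1600.0), n_frames=1,
                          sg_regions=())
        photo = Photophysics(background_photons=0.0, camera_noise_sigma=0.0)
        with pytest.warns(UserWarning, match="outside field"):
            movie, _ = render_movie(
                cfg, static_positions=np.array([[-50.0, 800.0]]),
                photo=photo, noise=False)
        assert movie.sum() == 0

    def test_movie_rendering_reproducible(self):
        cfg = SceneConfig(field_size=(1600.0, 1600.0), n_frames=3,
                          sg_regions=())
        pos = np.array([[800.0, 800.0]])
        a, _ = render_movie(cfg, static_positions=pos, seed=2)
        b, _ = render_movie(cfg, static_positions=pos, seed=2)
        np.testing.assert_array_equal(a, b)


class TestSceneLocalizations:
    def test_localization_map_has_core_and_shell_points(self):
        scene = make_scene(_one_sg_config(core_loc_count=200.0,
                                          shell_loc_density=300.0), seed=2)
        locs = sample_scene_localizations(scene, seed=3)
        assert (locs["core_id"] >= 0).any() and (locs["core_id"] == -1).any()
        shell = locs[locs["core_id"] == -1][["x", "y"]].to_numpy()
        assert scene.sgs[0].contains(shell).all()

    def test_disk_uniform_sampler_stays_inside(self, rng):
        d = Disk((100.0, -50.0), 400.0)
        pts = d.sample_uniform(5000, rng)
        assert d.contains(pts).all()
        assert d.area_um2 == pytest.approx(np.pi * 0.4**2, rel=1e-12)
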