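"""Generative model log-density, MAP recovery and track reconstruction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from urbanrat.geometry import CameraParams, apparent_size, ground_coords, horizon_v
from urbanrat.movement import (NoiseParams, OptConfig, PriorSpec,
                               TrackObservations, _initialize, _nll, _Packed,
                               _unpack, fit_map, log_joint,
                               reconstruct_ground_tracks)
from urbanrat.simulate import SceneSimConfig, SizeMixture, simulate_tracks


def _tiny_obs(camera, path_xz, radius=0.3, frame_rate=30.0):
    """Noise-free observations generated at a given latent (x, z) path."""
    x = path_xz[:, 0]
    z = path_xz[:, 1]
    y = -x * camera.tan_tilt - camera.plane_offset
    f = camera.focal_length
    u = -f * z / x
    v = f * y / x
    s = np.array([
        apparent_size((np.array([xi, yi, zi]), radius), f)
        for xi, yi, zi in zip(x, y, z)
    ])
    df = pd.DataFrame({"track_id": "a", "frame": np.arange(len(x)),
                       "u": u, "v": v, "s": s})
    return TrackObservations(df, frame_rate)


class TestTrackObservations:
    def test_requires_two_frames_per_track(self):
        df = pd.DataFrame({"track_id": ["a"], "frame": [0],
                           "u": [0.0], "v": [0.0], "s": [1.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            TrackObservations(df, 30.0)

    def test_requires_increasing_frames(self):
        df = pd.DataFrame({"track_id": "a", "frame": [3, 3],
                           "u": [0.0, 0.0], "v": [0.0, 0.0], "s": [1.0, 1.0]})
        with pytest.raises(ValueError, match="strictly increasing"):
            TrackObservations(df, 30.0)


class TestLogJoint:
    def test_gaussian_algebra_for_pixel_noise_scale(self, camera, rng):
        """Doubling sigma2 at fixed residuals changes the density by the closed form."""
        path = np.column_stack([np.full(5, -12.0), np.linspace(0.0, 0.2, 5)])
        obs = _tiny_obs(camera, path)
        # offset pixels to create known residuals
        obs.data["u"] += 1.0
        priors = PriorSpec()
        sizes = {"a": 0.3}
        base = dict(obs=obs, latent_paths={"a": path}, camera=camera, sizes=sizes,
                    priors=priors)
        s2 = 0.7
        lj1 = log_joint(noise=NoiseParams((0.05, 0.05), s2, 1.0), **base)
        lj2 = log_joint(noise=NoiseParams((0.05, 0.05), 2 * s2, 1.0), **base)
        ssr = float(np.sum((1.0) ** 2 * np.ones(5)))  # u residuals 1 px, v residuals 0
        n = 5
        dlik = (1 - 0.25) * ssr / (2 * s2**2) - 2 * n * math.log(2.0)
        m, sd = priors.log_sigma2_mean, priors.log_sigma2_sd
        dprior = (((math.log(s2) - m) ** 2 - (math.log(2 * s2) - m) ** 2)
                  / (2 * sd**2))
        assert lj2 - lj1 == pytest.approx(dlik + dprior, rel=1e-9)

    def test_single_transition_standard_normal_term(self, camera):
        """With sigma1 = (1,1) a step of length d costs d^2/2 nats."""
        noise = NoiseParams((1.0, 1.0), 1e6, 1e6)  # flood the observation terms
        priors = PriorSpec(x0_sd=1e6, z0_sd=1e6)
        sizes = {"a": 0.3}
        d = 0.8
        path0 = np.array([[-12.0, 0.0], [-12.0, 0.0]])
        path1 = np.array([[-12.0, 0.0], [-12.0 + d, 0.0]])
        obs = _tiny_obs(camera, path0)
        lj0 = log_joint(obs, {"a": path0}, camera, sizes, noise, priors)
        lj1 = log_joint(obs, {"a": path1}, camera, sizes, noise, priors)
        assert lj0 - lj1 == pytest.approx(d**2 / 2.0, abs=1e-4)

    def test_maximized_at_generating_path(self, camera):
        """Grid search around the true 5-frame path never beats it."""
        path = np.column_stack([np.linspace(-12.0, -11.8, 5),
                                np.linspace(0.0, 0.3, 5)])
        obs = _tiny_obs(camera, path)
        noise = NoiseParams((0.05, 0.05), 0.01, 0.01)
        sizes = {"a": 0.3}
        best = log_joint(obs, {"a": path}, camera, sizes, noise)
        for dx in (-0.05, 0.0, 0.05):
            for dz in (-0.05, 0.0, 0.05):
                if dx == dz == 0.0:
                    continue
                pert = path + np.array([dx, dz])
                assert log_joint(obs, {"a": pert}, camera, sizes, noise) < best

    def test_gradient_matches_finite_differences(self, small_scene_cfg):
        obs, _ = simulate_tracks(small_scene_cfg)
        packed = _Packed(obs)
        priors = PriorSpec()
        rng = np.random.default_rng(0)
        theta = _initialize(packed, priors, rng, 0.0)
        theta += 0.01 * rng.standard_normal(theta.shape)
        _, grad = _nll(packed, *_unpack(theta, packed.n_anim, packed.n_obs), priors)
        eps = 1e-6
        check = list(range(7 + packed.n_anim)) + [7 + packed.n_anim + 3,
                                                  7 + packed.n_anim + packed.n_obs + 5]
        for i in check:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fp = _nll(packed, *_unpack(tp, packed.n_anim, packed.n_obs), priors,
                      want_grad=False)[0]
            fm = _nll(packed, *_unpack(tm, packed.n_anim, packed.n_obs), priors,
                      want_grad=False)[0]
            num = (fp - fm) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_beats_perturbed_latents(self, camera, rng):
        """The generating path outranks 5-sigma1 perturbations >= 99% of the time."""
        cfg = SceneSimConfig(n_animals=2, n_frames=30, seed=11, dropout=0.0)
        obs, truth = simulate_tracks(cfg)
        sizes = truth["track_radii"]
        noise = cfg.noise
        paths = truth["latent_paths"]
        base = log_joint(obs, paths, truth["camera"], sizes, noise)
        wins = 0
        trials = 1000
        sig = 5.0 * np.asarray(noise.sigma1)
        for _ in range(trials):
            pert = {tid: p + sig * rng.standard_normal(p.shape)
                    for tid, p in paths.items()}
            if any((q[:, 0] >= 0).any() for q in pert.values()):
                wins += 1  # invalid perturbation is certainly worse
                continue
            if base > log_joint(obs, pert, truth["camera"], sizes, noise):
                wins += 1
        assert wins / trials >= 0.99


class TestFitMap:
    def test_deterministic_given_seed(self, small_scene_cfg):
        obs, _ = simulate_tracks(small_scene_cfg)
        cfg = OptConfig(maxiter=300, maxfun=400)
        a = fit_map(obs, opt_config=cfg, seed=3)
        b = fit_map(obs, opt_config=cfg, seed=3)
        assert a.camera == b.camera
        assert a.sizes == b.sizes
        assert a.noise == b.noise

    def test_near_deterministic_limit_recovers_sizes(self):
        """Tiny observation noise plus tight true-Q priors pins sizes within 2%."""
        sim = SceneSimConfig(
            n_animals=4, n_frames=150, seed=5, dropout=0.0,
            noise=NoiseParams((0.03, 0.03), 1e-3, 1e-3),
            sizes=SizeMixture(include_outlier=False),
        )
        obs, truth = simulate_tracks(sim)
        priors = PriorSpec(
            alpha_mean=0.35, alpha_sd=1e-3, y0_mean=5.0, y0_sd=1e-3,
            f_mean=800.0, f_sd=0.5,
            log_sigma2_mean=math.log(1e-3), log_sigma2_sd=0.1,
            log_sigma3_mean=math.log(1e-3), log_sigma3_sd=0.1,
            log_sigma1_mean=(math.log(0.03), math.log(0.03)), log_sigma1_sd=0.2,
        )
        fit = fit_map(obs, priors=priors, opt_config=OptConfig(maxiter=4000,
                                                               maxfun=5000))
        for tid, true_r in truth["track_radii"].items():
            assert fit.sizes[tid] == pytest.approx(true_r, rel=0.02)

    def test_static_animal_matches_apparent_size_inversion(self, camera):
        """One still animal: the fitted radius inverts the size observation."""
        path = np.column_stack([np.full(10, -14.0), np.full(10, 1.5)])
        obs = _tiny_obs(camera, path, radius=0.35)
        priors = PriorSpec(
            alpha_mean=camera.tilt_angle, alpha_sd=1e-3,
            y0_mean=camera.plane_offset, y0_sd=1e-3,
            f_mean=camera.focal_length, f_sd=0.5,
        )
        fit = fit_map(obs, priors=priors, opt_config=OptConfig(maxiter=2000,
                                                               maxfun=2500))
        s_obs = float(obs.data["s"].iloc[0])
        x, z = -14.0, 1.5
        y = -x * camera.tan_tilt - camera.plane_offset
        c = np.array([x, y, z])
        r_inv = brentq(
            lambda r: apparent_size((c, r), camera.focal_length) - s_obs, 1e-3, 2.0)
        assert fit.sizes["a"] == pytest.approx(r_inv, rel=0.05)

    def test_scale_invariance_of_relative_sizes(self):
        """Doubling y0 (and the matching scales) rescales sizes but not ratios."""
        base = SceneSimConfig(n_animals=4, n_frames=120, seed=9, dropout=0.0)
        scaled = SceneSimConfig(
            n_animals=4, n_frames=120, seed=9, dropout=0.0,
            camera=CameraParams(800.0, 0.35, 10.0), size_scale=2.0,
            noise=NoiseParams((0.06, 0.06), 1.0, 1.0),
        )
        obs_a, _ = simulate_tracks(base)
        obs_b, _ = simulate_tracks(scaled)
        # the pixel-space data are bit-identical: the scene scale is unobservable
        pd.testing.assert_frame_equal(obs_a.data, obs_b.data)
        opt = OptConfig(maxiter=3000, maxfun=3500)
        fit_a = fit_map(obs_a, priors=PriorSpec(y0_mean=5.0), opt_config=opt)
        fit_b = fit_map(obs_b, priors=PriorSpec(y0_mean=10.0, y0_sd=4.0),
                        opt_config=opt)
        ids = list(fit_a.sizes)
        abs_ratio = np.array([fit_b.sizes[t] / fit_a.sizes[t] for t in ids])
        assert abs_ratio.mean() == pytest.approx(2.0, rel=0.1)
        for t in ids:
            assert fit_b.relative_sizes[t] == pytest.approx(
                fit_a.relative_sizes[t], rel=0.02)

    def test_loss_trace_tail_non_increasing(self, small_scene_cfg):
        obs, _ = simulate_tracks(small_scene_cfg)
        fit = fit_map(obs, opt_config=OptConfig(maxiter=800, maxfun=1000))
        tail = fit.loss_trace[-max(2, len(fit.loss_trace) // 10):]
        assert np.all(np.diff(tail) <= 1e-8 * np.abs(tail[:-1]) + 1e-9)


class TestReconstruction:
    def test_noiseless_round_trip(self):
        sim = SceneSimConfig(n_animals=3, n_frames=80, seed=2, dropout=0.0,
                             noise=NoiseParams((0.03, 0.03), 1e-9, 1e-9))
        obs, truth = simulate_tracks(sim)
        cam = truth["camera"]
        ground = reconstruct_ground_tracks(obs, cam)
        for tid, df in ground.items():
            lat = truth["latent_paths"][tid]
            x, z = lat[:, 0], lat[:, 1]
            y = -x * cam.tan_tilt - cam.plane_offset
            g_true = ground_coords(np.column_stack([x, y, z]), cam)
            np.testing.assert_allclose(
                df[["g1", "g2"]].to_numpy(), g_true, atol=1e-6)

    def test_static_pixel_gives_static_ground_point(self, camera):
        df = pd.DataFrame({"track_id": "a", "frame": np.arange(10),
                           "u": 15.0, "v": -40.0, "s": 100.0})
        ground = reconstruct_ground_tracks(TrackObservations(df, 30.0), camera)
        g = ground["a"][["g1", "g2"]].to_numpy()
        assert np.ptp(g, axis=0).max() == 0.0

    def test_noise_amplification_grows_with_distance(self, camera, rng):
        """Foreshortening: the same pixel jitter moves far points further."""
        vh = horizon_v(camera)
        sigma2 = 1.0
        spread = []
        for v_true in (150.0, 0.0, vh + 30.0):  # near -> far
            from urbanrat.geometry import ground_coords as gc
            from urbanrat.geometry import plane_point_from_pixel as bp
            u_noisy = 10.0 + sigma2 * rng.standard_normal(400)
            v_noisy = v_true + sigma2 * rng.standard_normal(400)
            g = gc(bp(u_noisy, v_noisy, camera), camera, check_plane=False)
            g0 = gc(bp(10.0, v_true, camera), camera, check_plane=False)
            spread.append(np.median(np.linalg.norm(g - np.asarray([g0.g1, g0.g2]),
                                                   axis=1)))
        assert spread[0] < spread[1] < spread[2]

    def test_horizon_error_names_frame(self, camera):
        df = pd.DataFrame({"track_id": "a", "frame": [0, 1],
                           "u": [0.0, 0.0], "v": [0.0, horizon_v(camera)],
                           "s": [10.0, 10.0]})
        from urbanrat.geometry import HorizonError
        with pytest.raises(HorizonError, match="frame 1"):
            reconstruct_ground_tracks(TrackObservations(df, 30.0), camera)
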