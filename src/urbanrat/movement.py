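"""Generative movement model and MAP inference of scene parameters.

The model: each animal i performs a 2D Gaussian random walk in (x, z) on
the tilted ground plane (y determined exactly by the plane equation),

    (x_{t+1}, z_{t+1}) = (x_t, z_t) + delta_t,   delta_t ~ N(0, diag(sigma1^2)),

is approximated by a sphere of radius S_i, and is observed through the
pinhole camera as a noisy pixel position and apparent size,

    (u~, v~) = (u, v) + eps,   eps ~ N(0, sigma2^2 I2),
    s~       = s + eta,        eta ~ N(0, sigma3^2),

where (u, v, s) follow :mod:`urbanrat.geometry`.  Gaussian priors are
placed on the camera parameters Q = (alpha, y0, f), on each animal's
initial position and size, and log-normal hyperpriors on the noise scales
(sigma1 ~ logNormal([0.5, 0.5], 0.3); sigma2, sigma3 ~ logNormal(0.01,
0.01), read as mean/sd of log sigma).

MAP estimates of Q, the sizes {S_i}, the noise scales and the latent paths
are found by maximizing the joint log-density.  Positivity constraints are
enforced by optimizing on log scales (x through log(-x)); the optimizer is
L-BFGS-B with analytic gradients, which is deterministic, so repeated fits
with the same inputs are bit-identical.  Occlusion gaps are marginalized
exactly: a transition across a gap of g frames has variance g * sigma1^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import CameraParams, HorizonError, ground_coords, plane_point_from_pixel
from .tracks import normalize_sizes

__all__ = [
    "NoiseParams",
    "TrackObservations",
    "PriorSpec",
    "OptConfig",
    "FitResult",
    "log_joint",
    "fit_map",
    "reconstruct_ground_tracks",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NoiseParams:
    """Noise scales: per-axis step sd sigma1 (x, z), pixel sd sigma2, size sd sigma3."""

    sigma1: tuple[float, float]
    sigma2: float
    sigma3: float

    def __post_init__(self) -> None:
        if not (self.sigma1[0] > 0 and self.sigma1[1] > 0 and self.sigma2 > 0 and self.sigma3 > 0):
            raise ValueError("all noise scales must be strictly positive")


class TrackObservations:
    """Per-frame pixel-space measurements (u, v, s) keyed by track id.

    Wraps a DataFrame with columns ``track_id, frame, u, v, s`` in centered
    image coordinates.  Frames within a track must be strictly increasing
    (missing frames are allowed) and every track must have at least 2
    observed frames.
    """

    COLUMNS = ("track_id", "frame", "u", "v", "s")

    def __init__(self, data: pd.DataFrame, frame_rate: float):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        data = data.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        for tid, grp in data.groupby("track_id", sort=False):
            frames = grp["frame"].to_numpy()
            if len(frames) < 2:
                raise ValueError(f"track {tid!r} has fewer than 2 observed frames")
            if not np.all(np.diff(frames) > 0):
                raise ValueError(f"track {tid!r} frames are not strictly increasing")
        if not np.isfinite(data[["u", "v", "s"]].to_numpy()).all():
            raise ValueError("u, v, s must be finite")
        self.data = data
        self.frame_rate = float(frame_rate)

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.data["track_id"]))

    def __len__(self) -> int:
        return len(self.data)

    def track(self, track_id) -> pd.DataFrame:
        return self.data[self.data["track_id"] == track_id]


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors on Q, initial positions and sizes; log-normal on sigmas.

    Defaults are this package's own weakly-informative choices (scene
    lengths in multiples of ~y0/5; see the methods note), except the
    log-normal hyperparameters of the noise scales, which default to the
    model's stated hyperpriors.
    """

    alpha_mean: float = 0.4
    alpha_sd: float = 0.2
    y0_mean: float = 5.0
    y0_sd: float = 2.0
    f_mean: float = 800.0
    f_sd: float = 300.0
    size_mean: float = 1.0
    size_sd: float = 1.0
    x0_mean: float = -15.0
    x0_sd: float = 30.0
    z0_mean: float = 0.0
    z0_sd: float = 30.0
    log_sigma1_mean: tuple[float, float] = (0.5, 0.5)
    log_sigma1_sd: float = 0.3
    log_sigma2_mean: float = 0.01
    log_sigma2_sd: float = 0.01
    log_sigma3_mean: float = 0.01
    log_sigma3_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha_sd", "y0_sd", "f_sd", "size_sd", "x0_sd", "z0_sd",
                     "log_sigma1_sd", "log_sigma2_sd", "log_sigma3_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class OptConfig:
    """L-BFGS-B settings and the convergence rule on the loss-trace tail."""

    maxiter: int = 10000
    maxfun: int = 12000
    maxcor: int = 50  # L-BFGS memory; the path block is large and stiff
    gtol: float = 1e-7
    init_jitter: float = 0.0  # sd of seeded jitter added to the path init
    conv_window_frac: float = 0.1
    conv_rtol: float = 1e-5


@dataclass
class FitResult:
    """MAP point estimates: camera Q~, per-track sizes, noise scales, diagnostics."""

    camera: CameraParams
    sizes: dict
    relative_sizes: dict
    noise: NoiseParams
    latent_paths: dict
    loss_trace: np.ndarray
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# packed representation and the joint density


class _Packed:
    """Flat arrays for vectorized evaluation of the joint density."""

    def __init__(self, obs: TrackObservations):
        df = obs.data
        ids = obs.track_ids
        self.track_ids = ids
        id_to_ix = {tid: i for i, tid in enumerate(ids)}
        self.anim = df["track_id"].map(id_to_ix).to_numpy(dtype=np.intp)
        self.frame = df["frame"].to_numpy(dtype=np.int64)
        self.u = df["u"].to_numpy(dtype=float)
        self.v = df["v"].to_numpy(dtype=float)
        self.s = df["s"].to_numpy(dtype=float)
        self.n_obs = len(df)
        self.n_anim = len(ids)
        # consecutive-row pairs within a track, with frame gaps
        same = self.anim[1:] == self.anim[:-1]
        idx = np.nonzero(same)[0]
        self.pair_prev = idx
        self.pair_next = idx + 1
        self.gaps = (self.frame[self.pair_next] - self.frame[self.pair_prev]).astype(float)
        first = np.ones(self.n_obs, dtype=bool)
        first[1:] = ~same
        self.first_idx = np.nonzero(first)[0]


def _nll(packed: _Packed, ta, ly0, lf, ls1, ls2, ls3, lS, lx, z, priors: PriorSpec,
         want_grad: bool = True):
    """Negative joint log-density and its gradient in the working parameters."""
    p = priors
    t_alpha = math.exp(ta)
    alpha = math.atan(t_alpha)
    y0 = math.exp(ly0)
    f = math.exp(lf)
    s1 = np.exp(ls1)
    s2 = math.exp(ls2)
    s3 = math.exp(ls3)
    r = np.exp(lS)  # per-animal radii
    x = -np.exp(lx)

    ra = r[packed.anim]
    y = -x * t_alpha - y0
    u_pred = -f * z / x
    v_pred = -f * t_alpha - f * y0 / x
    d2 = x * x + y * y + z * z
    r2 = ra * ra
    w = np.maximum(x * x - r2, 1e-12)
    q = np.maximum(d2 - r2, 1e-12)
    sqrt_q = np.sqrt(q)
    A = math.pi * f * f * r2 * sqrt_q / w**1.5

    ru = u_pred - packed.u
    rv = v_pred - packed.v
    rs = A - packed.s

    n = packed.n_obs
    nll = (
        0.5 * np.sum(ru * ru + rv * rv) / (s2 * s2)
        + n * (_LOG2PI + 2.0 * math.log(s2))
        + 0.5 * np.sum(rs * rs) / (s3 * s3)
        + 0.5 * n * (_LOG2PI + 2.0 * math.log(s3))
    )

    # random-walk transitions (variance compounds linearly across frame gaps)
    dx = x[packed.pair_next] - x[packed.pair_prev]
    dz = z[packed.pair_next] - z[packed.pair_prev]
    g = packed.gaps
    var_x = g * s1[0] ** 2
    var_z = g * s1[1] ** 2
    npairs = len(g)
    nll += (
        0.5 * np.sum(dx * dx / var_x) + 0.5 * np.sum(np.log(2.0 * math.pi * var_x))
        + 0.5 * np.sum(dz * dz / var_z) + 0.5 * np.sum(np.log(2.0 * math.pi * var_z))
    )

    # priors
    def _gauss(val, m, s):
        return 0.5 * ((val - m) / s) ** 2 + 0.5 * (_LOG2PI + 2.0 * math.log(s))

    x0 = x[packed.first_idx]
    z0 = z[packed.first_idx]
    nll += _gauss(alpha, p.alpha_mean, p.alpha_sd)
    nll += _gauss(y0, p.y0_mean, p.y0_sd)
    nll += _gauss(f, p.f_mean, p.f_sd)
    nll += np.sum(0.5 * ((r - p.size_mean) / p.size_sd) ** 2) \
        + packed.n_anim * 0.5 * (_LOG2PI + 2.0 * math.log(p.size_sd))
    nll += np.sum(0.5 * ((x0 - p.x0_mean) / p.x0_sd) ** 2) \
        + packed.n_anim * 0.5 * (_LOG2PI + 2.0 * math.log(p.x0_sd))
    nll += np.sum(0.5 * ((z0 - p.z0_mean) / p.z0_sd) ** 2) \
        + packed.n_anim * 0.5 * (_LOG2PI + 2.0 * math.log(p.z0_sd))
    m1 = np.asarray(p.log_sigma1_mean, dtype=float)
    nll += np.sum(0.5 * ((ls1 - m1) / p.log_sigma1_sd) ** 2) \
        + 2 * 0.5 * (_LOG2PI + 2.0 * math.log(p.log_sigma1_sd))
    nll += _gauss(ls2, p.log_sigma2_mean, p.log_sigma2_sd)
    nll += _gauss(ls3, p.log_sigma3_mean, p.log_sigma3_sd)

    if not want_grad:
        return float(nll), None

    inv_s2sq = 1.0 / (s2 * s2)
    inv_s3sq = 1.0 / (s3 * s3)
    wu = ru * inv_s2sq
    wv = rv * inv_s2sq
    ws = rs * inv_s3sq

    dA_dx = A * ((x - y * t_alpha) / q - 3.0 * x / w)
    dA_dz = A * z / q
    dA_dr = A * (2.0 / ra - ra / q + 3.0 * ra / w)

    g_x = wu * (f * z / (x * x)) + wv * (f * y0 / (x * x)) + ws * dA_dx
    g_z = wu * (-f / x) + ws * dA_dz

    # transitions
    tx = dx / var_x
    tz = dz / var_z
    np.add.at(g_x, packed.pair_next, tx)
    np.add.at(g_x, packed.pair_prev, -tx)
    np.add.at(g_z, packed.pair_next, tz)
    np.add.at(g_z, packed.pair_prev, -tz)
    # initial-position priors
    g_x[packed.first_idx] += (x0 - p.x0_mean) / p.x0_sd**2
    g_z[packed.first_idx] += (z0 - p.z0_mean) / p.z0_sd**2

    g_lx = g_x * x  # d x / d lx = x  (x = -exp(lx))

    g_lS_anim = np.bincount(packed.anim, weights=ws * dA_dr, minlength=packed.n_anim)
    g_lS = (g_lS_anim + (r - p.size_mean) / p.size_sd**2) * r

    # working variable is ta = log(tan alpha): d(tan a)/d ta = tan a,
    # d alpha/d ta = tan a / (1 + tan^2 a)
    d_alpha_d_ta = t_alpha / (1.0 + t_alpha * t_alpha)
    g_ta = (
        np.sum(wv * (-f) + ws * (A * (-x * y) / q)) * t_alpha
        + (alpha - p.alpha_mean) / p.alpha_sd**2 * d_alpha_d_ta
    )
    g_ly0 = (
        np.sum(wv * (-f / x) + ws * (A * (-y) / q)) + (y0 - p.y0_mean) / p.y0_sd**2
    ) * y0
    g_lf = (
        np.sum(wu * (u_pred / f) + wv * (v_pred / f) + ws * (2.0 * A / f))
        + (f - p.f_mean) / p.f_sd**2
    ) * f

    g_ls1 = np.array([
        np.sum(-dx * dx / var_x + 1.0),
        np.sum(-dz * dz / var_z + 1.0),
    ]) + (ls1 - m1) / p.log_sigma1_sd**2
    g_ls2 = np.sum(-(ru * ru + rv * rv) * inv_s2sq) + 2.0 * n \
        + (ls2 - p.log_sigma2_mean) / p.log_sigma2_sd**2
    g_ls3 = np.sum(-rs * rs * inv_s3sq) + n \
        + (ls3 - p.log_sigma3_mean) / p.log_sigma3_sd**2

    grad = np.concatenate((
        [g_ta, g_ly0, g_lf], g_ls1, [g_ls2, g_ls3], g_lS, g_lx, g_z,
    ))
    return float(nll), grad


def _unpack(theta: np.ndarray, n_anim: int, n_obs: int):
    ta, ly0, lf = theta[0], theta[1], theta[2]
    ls1 = theta[3:5]
    ls2, ls3 = theta[5], theta[6]
    lS = theta[7:7 + n_anim]
    lx = theta[7 + n_anim: 7 + n_anim + n_obs]
    z = theta[7 + n_anim + n_obs:]
    return ta, ly0, lf, ls1, ls2, ls3, lS, lx, z


def log_joint(obs: TrackObservations, latent_paths: dict, camera: CameraParams,
              sizes: dict, noise: NoiseParams, priors: PriorSpec | None = None) -> float:
    """Joint log-density of observations, latent paths, sizes and parameters.

    ``latent_paths`` maps track id to an (T_i, 2) array of (x, z) positions
    aligned with that track's observed frames; y is determined exactly by
    the plane equation.  ``sizes`` maps track id to sphere radius.
    """
    priors = priors or PriorSpec()
    packed = _Packed(obs)
    xs = np.empty(packed.n_obs)
    zs = np.empty(packed.n_obs)
    for i, tid in enumerate(packed.track_ids):
        sel = packed.anim == i
        path = np.asarray(latent_paths[tid], dtype=float)
        if path.shape != (int(sel.sum()), 2):
            raise ValueError(
                f"latent path for track {tid!r} must have shape (n_observed_frames, 2)"
            )
        xs[sel] = path[:, 0]
        zs[sel] = path[:, 1]
    if np.any(xs >= 0):
        raise ValueError("latent x coordinates must be negative (in front of camera)")
    r = np.array([sizes[tid] for tid in packed.track_ids], dtype=float)
    if np.any(r <= 0):
        raise ValueError("sizes must be positive")
    nll, _ = _nll(
        packed,
        math.log(math.tan(camera.tilt_angle)),
        math.log(camera.plane_offset),
        math.log(camera.focal_length),
        np.log(np.asarray(noise.sigma1, dtype=float)),
        math.log(noise.sigma2),
        math.log(noise.sigma3),
        np.log(r),
        np.log(-xs),
        zs,
        priors,
        want_grad=False,
    )
    if not np.isfinite(nll):
        raise FloatingPointError("log-joint is not finite for the given inputs")
    return -nll


def _initialize(packed: _Packed, priors: PriorSpec, rng: np.random.Generator,
                jitter: float) -> np.ndarray:
    """Back-project observations under the prior-mean camera to seed the paths."""
    cam0 = CameraParams(priors.f_mean, priors.alpha_mean, priors.y0_mean)
    denom = packed.v + cam0.focal_length * cam0.tan_tilt
    denom = np.maximum(denom, 1e-3 * cam0.focal_length)
    x = -cam0.focal_length * cam0.plane_offset / denom
    z = packed.u * cam0.plane_offset / denom
    d2 = x * x + (-x * cam0.tan_tilt - cam0.plane_offset) ** 2 + z * z
    # invert the far-field size law s ~ pi f^2 r^2 sqrt(d^2)/|x|^3
    r_obs = np.sqrt(
        np.maximum(packed.s, 1e-6) * np.abs(x) ** 3
        / (math.pi * cam0.focal_length**2 * np.sqrt(d2))
    )
    r_init = np.array([
        np.median(r_obs[packed.anim == i]) for i in range(packed.n_anim)
    ])
    r_init = np.clip(r_init, 1e-3, None)
    if jitter > 0:
        x = np.minimum(x + jitter * rng.standard_normal(x.shape), -1e-2)
        z = z + jitter * rng.standard_normal(z.shape)
    theta0 = np.concatenate((
        [
            math.log(math.tan(priors.alpha_mean)),
            math.log(priors.y0_mean),
            math.log(priors.f_mean),
        ],
        np.asarray(priors.log_sigma1_mean, dtype=float),
        [priors.log_sigma2_mean, priors.log_sigma3_mean],
        np.log(r_init),
        np.log(-x),
        z,
    ))
    return theta0


def fit_map(obs: TrackObservations, priors: PriorSpec | None = None,
            opt_config: OptConfig | None = None, seed: int = 0) -> FitResult:
    """MAP estimation of camera parameters, sizes, noise scales and paths.

    Deterministic given ``seed`` (which only seeds the optional path-init
    jitter); relative sizes are the fitted radii normalized to mean 1 via
    :func:`urbanrat.tracks.normalize_sizes`.
    """
    priors = priors or PriorSpec()
    cfg = opt_config or OptConfig()
    packed = _Packed(obs)
    if packed.n_anim < 1:
        raise ValueError("need at least one track")
    rng = np.random.default_rng(seed)
    theta0 = _initialize(packed, priors, rng, cfg.init_jitter)

    trace: list[float] = []
    last_nll = [math.inf]

    def objective(theta):
        nll, grad = _nll(packed, theta[0], theta[1], theta[2], theta[3:5],
                         theta[5], theta[6], theta[7:7 + packed.n_anim],
                         theta[7 + packed.n_anim: 7 + packed.n_anim + packed.n_obs],
                         theta[7 + packed.n_anim + packed.n_obs:], priors)
        last_nll[0] = nll
        return nll, grad

    def callback(theta):
        # the accepted iterate is the last point the objective evaluated
        trace.append(last_nll[0])

    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B", callback=callback,
        options={"maxiter": cfg.maxiter, "maxfun": cfg.maxfun, "gtol": cfg.gtol,
                 "maxcor": cfg.maxcor, "ftol": 1e-14},
    )
    theta = res.x
    ta, ly0, lf, ls1, ls2, ls3, lS, lx, z = _unpack(theta, packed.n_anim, packed.n_obs)
    camera = CameraParams(math.exp(lf), math.atan(math.exp(ta)), math.exp(ly0))
    noise = NoiseParams(tuple(np.exp(ls1)), math.exp(ls2), math.exp(ls3))
    r = np.exp(lS)
    sizes = {tid: float(r[i]) for i, tid in enumerate(packed.track_ids)}
    rel = normalize_sizes(r)
    relative_sizes = {tid: float(rel[i]) for i, tid in enumerate(packed.track_ids)}
    x = -np.exp(lx)
    latent_paths = {}
    for i, tid in enumerate(packed.track_ids):
        sel = packed.anim == i
        latent_paths[tid] = np.stack([x[sel], z[sel]], axis=1)

    loss_trace = np.asarray(trace, dtype=float)
    converged = True
    if len(loss_trace) >= 2:
        win = max(2, int(len(loss_trace) * cfg.conv_window_frac))
        drop = loss_trace[-win] - loss_trace[-1]
        converged = drop <= cfg.conv_rtol * max(1.0, abs(loss_trace[-1]))
    return FitResult(
        camera=camera, sizes=sizes, relative_sizes=relative_sizes, noise=noise,
        latent_paths=latent_paths, loss_trace=loss_trace, converged=bool(converged),
        seed=seed,
    )


def reconstruct_ground_tracks(obs: TrackObservations, camera: CameraParams,
                              *, order: str = "lateral_first") -> dict:
    """Back-project each track's pixels to ground-plane coordinates.

    Returns a dict mapping track id to a DataFrame with columns
    ``frame, g1, g2``; missing frames stay missing (no interpolation).
    A pixel at the horizon raises :class:`HorizonError` naming the frame.
    """
    out = {}
    for tid, grp in obs.data.groupby("track_id", sort=False):
        denom = grp["v"].to_numpy() + camera.focal_length * camera.tan_tilt
        bad = np.abs(denom) < 1e-8 * camera.focal_length
        if np.any(bad):
            frame = int(grp["frame"].to_numpy()[bad][0])
            raise HorizonError(f"track {tid!r} frame {frame}: pixel on horizon line")
        pts = plane_point_from_pixel(grp["u"].to_numpy(), grp["v"].to_numpy(), camera)
        g = ground_coords(pts, camera, order=order, check_plane=False)
        out[tid] = pd.DataFrame({
            "frame": grp["frame"].to_numpy(), "g1": g[:, 0], "g2": g[:, 1],
        })
    return out
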