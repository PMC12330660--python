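"""Synthetic data generators emulating the field recordings' structure.

Three generators, all seed-deterministic:

* :func:`simulate_tracks` — the movement model's own forward process:
  animals with a heavy-tailed size mixture (small rats, large rats, one
  squirrel-like outlier) perform ground-plane random walks, are projected
  through the pinhole camera with sphere apparent sizes, and observed with
  pixel/size noise, occlusion dropouts and frame exits/re-entries (which
  produce more tracklets than true animals).
* :func:`simulate_vocal_stream` — bout-structured ultrasonic chirp trains
  (near-22 kHz and near-50 kHz calls, audible squeaks) embedded in
  background noise at a configurable SNR, with exact syllable annotations.
* :func:`simulate_scene_cloud` — flat open ground plus an elevated canopy
  slab, the constructed oracle for the shelter statistic.

Scene scale: the plane offset y0 = 5 corresponds to a camera roughly 1.5 m
above the plane, i.e. 1 length unit is about 0.3 m; the default step sd of
0.03 units/frame at 30 fps is then a foraging speed of ~0.3 m/s, and the
sphere radii of 0.2-0.5 units are rat-sized bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CameraParams, plane_point_from_pixel
from .movement import NoiseParams, TrackObservations
from .scene import SplatCloud

__all__ = [
    "SizeMixture",
    "SceneSimConfig",
    "VocalSimConfig",
    "simulate_tracks",
    "simulate_syllables",
    "simulate_vocal_stream",
    "simulate_scene_cloud",
]


@dataclass(frozen=True)
class SizeMixture:
    """Two lognormal modes (small/large rats) plus one ~2.5x outlier."""

    small_median: float = 0.22
    large_median: float = 0.42
    log_sd: float = 0.12
    p_small: float = 0.5
    outlier_factor: float = 2.5
    include_outlier: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_small <= 1.0:
            raise ValueError("p_small must lie in [0, 1]")
        if min(self.small_median, self.large_median, self.log_sd) <= 0:
            raise ValueError("size-mixture scales must be positive")

    def sample(self, n: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
        """Draw n radii; when enabled, the last animal is the outlier."""
        modes = np.where(rng.random(n) < self.p_small,
                         self.small_median, self.large_median)
        sizes = modes * np.exp(self.log_sd * rng.standard_normal(n)) * scale
        if self.include_outlier and n >= 2:
            sizes[-1] = self.outlier_factor * sizes[:-1].mean()
        return sizes


@dataclass(frozen=True)
class SceneSimConfig:
    """Study conditions for the track generator (the model's forward process)."""

    camera: CameraParams = field(
        default_factory=lambda: CameraParams(focal_length=800.0, tilt_angle=0.35,
                                             plane_offset=5.0))
    n_animals: int = 8
    n_frames: int = 600
    frame_rate: float = 30.0
    sizes: SizeMixture = field(default_factory=SizeMixture)
    size_scale: float = 1.0
    noise: NoiseParams = field(
        default_factory=lambda: NoiseParams(sigma1=(0.03, 0.03), sigma2=1.0,
                                            sigma3=1.0))
    dropout: float = 0.05
    exit_prob: float = 0.0           # per-frame probability of leaving the view
    reentry_gap_mean_s: float = 1.0  # mean invisible time before re-entry
    speed_size_exponent: float = 0.0  # sigma1_i ~ (S_i / mean S)^exponent
    u_range: tuple[float, float] = (-280.0, 280.0)
    v_range: tuple[float, float] = (-180.0, 160.0)
    size_mode: str = "ellipse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        if not 0.0 <= self.exit_prob <= 1.0:
            raise ValueError("exit_prob must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        from .geometry import horizon_v
        if self.v_range[0] <= horizon_v(self.camera):
            raise ValueError("v_range reaches the plane's horizon line")


def _apparent_sizes(x, y, z, r, f, mode):
    d2 = x * x + y * y + z * z
    r2 = r * r
    if mode == "ellipse":
        return math.pi * f * f * r2 * np.sqrt(d2 - r2) / (x * x - r2) ** 1.5
    if mode == "bbox":
        from .geometry import silhouette_ellipse
        rr = np.broadcast_to(r, np.shape(x))
        out = np.empty_like(x)
        for i in range(len(x)):
            eu, ev, _ = silhouette_ellipse((x[i], y[i], z[i]), float(rr[i]), f)
            out[i] = 4.0 * eu * ev
        return out
    raise ValueError(f"unknown size_mode {mode!r}")


def simulate_tracks(cfg: SceneSimConfig) -> tuple[TrackObservations, dict]:
    """Sample the generative model forward; return observations and latents.

    The latents dict holds the true camera, per-animal radii, the
    track-id -> animal map, per-track noiseless latent paths (aligned with
    the emitted observation rows) and the full latent table.
    """
    rng = np.random.default_rng(cfg.seed)
    cam = cfg.camera
    f, t_alpha, y0 = cam.focal_length, cam.tan_tilt, cam.plane_offset

    radii = cfg.sizes.sample(cfg.n_animals, rng, cfg.size_scale)
    sig1 = np.asarray(cfg.noise.sigma1, dtype=float)
    if cfg.speed_size_exponent != 0.0:
        factor = (radii / radii.mean()) ** cfg.speed_size_exponent
    else:
        factor = np.ones(cfg.n_animals)

    rows = []
    track_animal: dict[str, int] = {}
    for i in range(cfg.n_animals):
        segment = 0
        t = 0
        while t < cfg.n_frames - 1:
            # new (re-)entry: uniform pixel in view, back-projected to the plane
            u0 = rng.uniform(*cfg.u_range)
            v0 = rng.uniform(*cfg.v_range)
            p0 = plane_point_from_pixel(u0, v0, cam)
            # segment length: geometric exit process (whole video if exit_prob=0)
            if cfg.exit_prob > 0:
                length = 1 + rng.geometric(cfg.exit_prob)
            else:
                length = cfg.n_frames - t
            length = min(length, cfg.n_frames - t)
            steps = (sig1 * factor[i]) * rng.standard_normal((length - 1, 2))
            x = p0.x + np.concatenate([[0.0], np.cumsum(steps[:, 0])])
            z = p0.z + np.concatenate([[0.0], np.cumsum(steps[:, 1])])
            y = -x * t_alpha - y0
            frames = np.arange(t, t + length)
            tid = f"a{i}_s{segment}"
            track_animal[tid] = i
            rows.append(pd.DataFrame({
                "track_id": tid, "frame": frames, "x": x, "y": y, "z": z,
                "animal": i,
            }))
            t += length
            if cfg.exit_prob > 0 and t < cfg.n_frames - 1:
                gap = 1 + rng.geometric(1.0 / (cfg.reentry_gap_mean_s * cfg.frame_rate))
                t += gap
            segment += 1

    latent = pd.concat(rows, ignore_index=True)
    r_per_row = radii[latent["animal"].to_numpy()]
    x, y, z = (latent[c].to_numpy() for c in ("x", "y", "z"))
    u = -f * z / x
    v = f * y / x
    s = _apparent_sizes(x, y, z, r_per_row, f, cfg.size_mode)

    n = len(latent)
    u_obs = u + cfg.noise.sigma2 * rng.standard_normal(n)
    v_obs = v + cfg.noise.sigma2 * rng.standard_normal(n)
    s_obs = np.maximum(s + cfg.noise.sigma3 * rng.standard_normal(n), 1e-6)

    keep = rng.random(n) >= cfg.dropout
    table = pd.DataFrame({
        "track_id": latent["track_id"], "frame": latent["frame"],
        "u": u_obs, "v": v_obs, "s": s_obs,
    })[keep]
    latent_kept = latent[keep].reset_index(drop=True)
    # drop tracks left with < 2 observations
    ok = table.groupby("track_id", sort=False)["frame"].transform("size") >= 2
    table = table[ok.to_numpy()].reset_index(drop=True)
    latent_kept = latent_kept[ok.to_numpy()].reset_index(drop=True)

    obs = TrackObservations(table, cfg.frame_rate)
    latent_paths = {
        tid: grp[["x", "z"]].to_numpy()
        for tid, grp in latent_kept.groupby("track_id", sort=False)
    }
    truth = {
        "camera": cam,
        "animal_radii": radii,
        "track_animal": {t: a for t, a in track_animal.items()
                         if t in set(table["track_id"])},
        "track_radii": {t: float(radii[a]) for t, a in track_animal.items()
                        if t in set(table["track_id"])},
        "latent_paths": latent_paths,
        "latent_table": latent_kept,
        "noise": cfg.noise,
    }
    return obs, truth


# ---------------------------------------------------------------------------
# vocal streams


@dataclass(frozen=True)
class VocalSimConfig:
    """Bout-structured call trains: gap supports must respect the bout rule."""

    n_bouts: int = 4
    syllables_per_bout_mean: float = 4.0  # 1 + Poisson(mean - 1)
    syllable_duration_range: tuple[float, float] = (0.03, 0.12)
    within_bout_gap_range: tuple[float, float] = (0.05, 0.20)
    between_bout_gap_range: tuple[float, float] = (0.40, 1.20)
    call_types: tuple = (
        ("usv22", 21_000.0, 24_000.0, 0.45),
        ("usv50", 45_000.0, 60_000.0, 0.45),
        ("squeak", 2_000.0, 8_000.0, 0.10),
    )
    chirp_max_slope_hz_s: float = 40_000.0
    snr_db: float = 10.0
    background: str = "white"
    sample_rate: int = 192_000
    gap_threshold_s: float = 0.250
    lead_in_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be >= 0")
        if not self.within_bout_gap_range[1] < self.gap_threshold_s:
            raise ValueError("within-bout gaps must stay below the bout gap threshold")
        if not self.between_bout_gap_range[0] > self.gap_threshold_s:
            raise ValueError("between-bout gaps must exceed the bout gap threshold")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        top = max(hi for _, _, hi, _ in self.call_types)
        if top >= self.sample_rate / 2:
            raise ValueError("call band reaches above the Nyquist frequency")


def simulate_syllables(cfg: VocalSimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ground-truth annotation table: onset_s, offset_s, label, f0 endpoints, bout."""
    rng = rng or np.random.default_rng(cfg.seed)
    labels = [ct[0] for ct in cfg.call_types]
    probs = np.array([ct[3] for ct in cfg.call_types], dtype=float)
    probs /= probs.sum()
    rows = []
    t = cfg.lead_in_s
    for b in range(cfg.n_bouts):
        if b > 0:
            t += rng.uniform(*cfg.between_bout_gap_range)
        n_syl = 1 + rng.poisson(max(cfg.syllables_per_bout_mean - 1.0, 0.0))
        label = labels[rng.choice(len(labels), p=probs)]
        _, lo, hi, _ = cfg.call_types[labels.index(label)]
        for k in range(n_syl):
            if k > 0:
                t += rng.uniform(*cfg.within_bout_gap_range)
            dur = rng.uniform(*cfg.syllable_duration_range)
            f0a = rng.uniform(lo, hi)
            slope = rng.uniform(-cfg.chirp_max_slope_hz_s, cfg.chirp_max_slope_hz_s)
            f0b = float(np.clip(f0a + slope * dur, lo, hi))
            rows.append({"onset_s": t, "offset_s": t + dur, "label": label,
                         "f0_start_hz": f0a, "f0_end_hz": f0b, "bout": b})
            t += dur
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "label",
                                       "f0_start_hz", "f0_end_hz", "bout"])


def simulate_vocal_stream(cfg: VocalSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the annotated stream to a mono waveform plus its annotations.

    Calls are linear FM chirps with 5 ms cosine on/off ramps; the
    background is gaussian noise (optionally 1/f-shaped), and ``snr_db`` is
    the RMS ratio of a call to the background.
    """
    rng = np.random.default_rng(cfg.seed)
    syl = simulate_syllables(cfg, rng)
    fs = cfg.sample_rate
    total = (syl["offset_s"].max() + cfg.lead_in_s) if len(syl) else 2.0 * cfg.lead_in_s
    n = int(math.ceil(total * fs))

    noise_rms = 0.01
    wave = noise_rms * rng.standard_normal(n)
    if cfg.background == "pink":
        spec = np.fft.rfft(wave)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        shaping = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
        shaped = np.fft.irfft(spec * shaping, n)
        wave = shaped * (noise_rms / np.sqrt(np.mean(shaped**2)))
    elif cfg.background != "white":
        raise ValueError(f"unknown background {cfg.background!r}")

    amp = noise_rms * 10.0 ** (cfg.snr_db / 20.0) * math.sqrt(2.0)
    ramp = int(0.005 * fs)
    for row in syl.itertuples():
        i0 = int(round(row.onset_s * fs))
        i1 = min(int(round(row.offset_s * fs)), n)
        m = i1 - i0
        if m <= 0:
            continue
        tt = np.arange(m) / fs
        dur = m / fs
        freq = row.f0_start_hz + (row.f0_end_hz - row.f0_start_hz) * tt / dur
        phase = 2.0 * np.pi * np.cumsum(freq) / fs
        chirp = amp * np.sin(phase)
        env = np.ones(m)
        k = min(ramp, m // 2)
        if k > 0:
            fade = 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / k))
            env[:k] = fade
            env[m - k:] = fade[::-1]
        wave[i0:i1] += chirp * env
    return wave.astype(np.float64), syl


# ---------------------------------------------------------------------------
# scene clouds


def simulate_scene_cloud(
    footprint: tuple[float, float] = (20.0, 20.0),
    canopy_fraction: float = 0.5,
    canopy_height: float = 2.0,
    density: float = 40.0,
    seed: int = 0,
    *,
    ground_jitter: float = 0.05,
) -> tuple[SplatCloud, dict]:
    """Flat ground plus an elevated canopy slab over part of the footprint.

    The canopy occupies the strip ``x < canopy_fraction * Lx`` (in footprint
    coordinates) at ``z = canopy_height``; both layers get gaussian height
    jitter.  Returns the cloud and a metadata dict with the canopy strip
    bounds for use as a test oracle.
    """
    if not 0.0 <= canopy_fraction <= 1.0:
        raise ValueError("canopy_fraction must lie in [0, 1]")
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    lx, ly = footprint
    n_ground = max(1, int(round(density * lx * ly)))
    xy = rng.uniform([0.0, 0.0], [lx, ly], size=(n_ground, 2))
    z = ground_jitter * rng.standard_normal(n_ground)
    pts = [np.column_stack([xy, z])]
    canopy_xmax = canopy_fraction * lx
    if canopy_fraction > 0.0:
        n_can = max(1, int(round(density * canopy_xmax * ly)))
        xy_c = rng.uniform([0.0, 0.0], [canopy_xmax, ly], size=(n_can, 2))
        z_c = canopy_height + ground_jitter * rng.standard_normal(n_can)
        pts.append(np.column_stack([xy_c, z_c]))
    cloud = SplatCloud(points=np.concatenate(pts, axis=0))
    meta = {"canopy_xmax": canopy_xmax, "canopy_height": canopy_height,
            "footprint": footprint, "ground_jitter": ground_jitter}
    return cloud, meta
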