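"""File I/O, run configuration and the staged pipeline.

Track tables are the CSV exports of a detector+tracker (one row per
detection: track id, frame, pixel position, apparent size); a
:class:`TrackTableDialect` maps arbitrary column names and pixel-origin
conventions onto the centered image frame the geometry expects.  Audio is
mono WAV; syllable annotations and feature-space reference regions are
small CSVs; splat clouds are PLY.

:func:`run_pipeline` ties the stages together (tracks -> fit -> movement
statistics; audio -> bouts -> features; ply -> shelter map), writing every
output table with a provenance sidecar (config hash, seed, library
versions) so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from scipy.io import wavfile

from . import bioacoustics as ba
from . import tracks as ta
from .movement import (OptConfig, TrackObservations, fit_map,
                       reconstruct_ground_tracks)
from .scene import ShelterMap, compute_shelter_map, load_splat_centers

log = logging.getLogger("urbanrat")

__all__ = [
    "TrackTableDialect",
    "SchemaError",
    "DataError",
    "PipelineError",
    "RunConfig",
    "read_tracks",
    "write_tracks",
    "read_wav",
    "write_wav",
    "read_syllables",
    "write_syllables",
    "read_regions",
    "write_shelter_map",
    "load_config",
    "run_pipeline",
]


class DataError(ValueError):
    """Problems with input data files."""


class SchemaError(DataError):
    """Input table lacks required columns."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class TrackTableDialect:
    """Column names and pixel conventions of a detector's track export.

    ``origin="centered"`` means the table already uses the centered frame
    (u rightward, v upward, origin at the principal point).
    ``origin="top_left"`` means row/col indices from the image's top-left
    corner; conversion needs ``image_width`` and ``image_height``:
    u = col - width/2, v = height/2 - row.
    """

    track_id: str = "track_id"
    frame: str = "frame"
    u: str = "u"
    v: str = "v"
    s: str = "s"
    origin: str = "centered"
    image_width: float | None = None
    image_height: float | None = None
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.origin not in ("centered", "top_left"):
            raise ValueError("origin must be 'centered' or 'top_left'")
        if self.origin == "top_left" and (self.image_width is None
                                          or self.image_height is None):
            raise ValueError("top_left origin needs image_width and image_height")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


def read_tracks(path, dialect: TrackTableDialect | None = None) -> TrackObservations:
    """Read a track table CSV into centered-coordinate observations.

    Rows with missing/NaN pixel or size values are dropped (count logged),
    as are tracks left with fewer than two observations.
    """
    dialect = dialect or TrackTableDialect()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty track file: {path}") from exc
    required = {dialect.track_id, dialect.frame, dialect.u, dialect.v, dialect.s}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"track table {path} missing columns: {missing}")
    if len(df) == 0:
        raise DataError(f"track file has a header but no rows: {path}")
    df = df.rename(columns={
        dialect.track_id: "track_id", dialect.frame: "frame",
        dialect.u: "u", dialect.v: "v", dialect.s: "s",
    })
    n0 = len(df)
    df = df.dropna(subset=["u", "v", "s", "frame"])
    if len(df) < n0:
        log.warning("dropped %d rows with missing values from %s", n0 - len(df), path)
    if dialect.origin == "top_left":
        df["u"] = df["u"] - dialect.image_width / 2.0
        df["v"] = dialect.image_height / 2.0 - df["v"]
    sizes = df.groupby("track_id", sort=False)["frame"].transform("size")
    short = sizes < 2
    if short.any():
        log.warning("dropped %d single-observation tracks from %s",
                    df.loc[short, "track_id"].nunique(), path)
        df = df[~short]
    if len(df) == 0:
        raise DataError(f"no usable observations in {path}")
    return TrackObservations(df.reset_index(drop=True), dialect.frame_rate)


def write_tracks(obs: TrackObservations, path) -> None:
    """Write observations as a centered-dialect CSV (full float precision)."""
    obs.data.to_csv(path, index=False)


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a mono WAV; returns (sample_rate, float waveform in [-1, 1])."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise DataError(f"expected mono WAV, got shape {data.shape}: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(float) / max(abs(info.min), info.max)
    else:
        data = data.astype(float)
    return float(rate), data


def write_wav(path, sample_rate: float, waveform: np.ndarray) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))


def read_syllables(path) -> list[ba.Syllable]:
    """Read an annotation CSV with columns onset_s, offset_s[, label]."""
    df = pd.read_csv(path)
    missing = sorted({"onset_s", "offset_s"} - set(df.columns))
    if missing:
        raise SchemaError(f"annotation table {path} missing columns: {missing}")
    label = df["label"] if "label" in df.columns else [""] * len(df)
    return [
        ba.Syllable(onset=float(o), offset=float(f), label=str(l))
        for o, f, l in zip(df["onset_s"], df["offset_s"], label)
    ]


def write_syllables(syllables, path) -> None:
    pd.DataFrame([
        {"onset_s": s.onset, "offset_s": s.offset, "label": s.label,
         "median_f0_hz": s.median_f0}
        for s in syllables
    ]).to_csv(path, index=False)


def read_regions(path) -> dict[str, list[tuple[float, float]]]:
    """Read feature-space polygons: CSV with region, duration_s, frequency_hz.

    Vertex order within a region follows row order.
    """
    df = pd.read_csv(path)
    missing = sorted({"region", "duration_s", "frequency_hz"} - set(df.columns))
    if missing:
        raise SchemaError(f"region table {path} missing columns: {missing}")
    return {
        str(name): list(zip(grp["duration_s"], grp["frequency_hz"]))
        for name, grp in df.groupby("region", sort=False)
    }


def write_shelter_map(smap: ShelterMap, csv_path, png_path=None) -> None:
    """Export the shelter grid as CSV (and optionally a heatmap image)."""
    pd.DataFrame(smap.z_sd).to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        m = ax.pcolormesh(smap.x_edges, smap.y_edges, smap.z_sd.T, shading="auto")
        fig.colorbar(m, ax=ax, label=f"{smap.up_axis}-sd (scene units)")
        ax.set_xlabel("ground axis 1")
        ax.set_ylabel("ground axis 2")
        ax.set_title("shelter metric: per-cell height sd")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# run configuration (schema-validated)


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TracksSimConfig(_Base):
    n_animals: int = 8
    n_frames: int = 600
    frame_rate: float = 30.0
    dropout: float = 0.05
    exit_prob: float = 0.0
    speed_size_exponent: float = 0.0


class TracksStageConfig(_Base):
    source: str = "simulate"  # "simulate" or a CSV path
    sim: TracksSimConfig = TracksSimConfig()
    fit_maxiter: int = 10000
    min_duration_s: float = 5.0
    max_gap_s: float = 1.0
    count_threshold: int = 3
    speed_threshold: Optional[float] = None


class AudioStageConfig(_Base):
    source: str = "simulate"  # "simulate" or a WAV path
    annotations: Optional[str] = None
    compare_with: Optional[str] = None
    n_bouts: int = 4
    snr_db: float = 10.0
    gap_threshold_s: float = 0.250
    band_low_hz: float = 15000.0
    band_high_hz: float = 90000.0


class SceneStageConfig(_Base):
    source: str = "simulate"  # "simulate" or a PLY path
    cell_size: float = 1.0
    up_axis: Literal["x", "y", "z"] = "z"
    min_count: int = 3


class RunConfig(_Base):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "results/run"
    stages: list[Literal["tracks", "audio", "scene"]] = ["tracks", "audio", "scene"]
    log_level: str = "INFO"
    tracks: TracksStageConfig = TracksStageConfig()
    audio: AudioStageConfig = AudioStageConfig()
    scene: SceneStageConfig = SceneStageConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# pipeline


def _provenance(cfg: RunConfig) -> dict:
    import scipy

    from . import __version__

    payload = cfg.model_dump()
    # where the run writes and how it logs are not analysis parameters
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "urbanrat": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def _write_with_sidecar(df: pd.DataFrame, path: Path, prov: dict) -> None:
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True))


def _stage_tracks(cfg: RunConfig, outdir: Path, prov: dict,
                  written: list[Path]) -> list[Path]:
    from .simulate import SceneSimConfig, simulate_tracks

    sc = cfg.tracks
    if sc.source == "simulate":
        sim = SceneSimConfig(
            n_animals=sc.sim.n_animals, n_frames=sc.sim.n_frames,
            frame_rate=sc.sim.frame_rate, dropout=sc.sim.dropout,
            exit_prob=sc.sim.exit_prob,
            speed_size_exponent=sc.sim.speed_size_exponent, seed=cfg.seed,
        )
        obs, _ = simulate_tracks(sim)
        p = outdir / "tracks.csv"
        _write_with_sidecar(obs.data, p, prov)
        written.append(p)
    else:
        obs = read_tracks(sc.source, TrackTableDialect(frame_rate=sc.sim.frame_rate))

    fit = fit_map(obs, opt_config=OptConfig(maxiter=sc.fit_maxiter,
                                            maxfun=sc.fit_maxiter + 2000),
                  seed=cfg.seed)
    fit_df = pd.DataFrame([{
        "tilt_angle_rad": fit.camera.tilt_angle,
        "plane_offset": fit.camera.plane_offset,
        "focal_length_px": fit.camera.focal_length,
        "sigma1_x": fit.noise.sigma1[0], "sigma1_z": fit.noise.sigma1[1],
        "sigma2_px": fit.noise.sigma2, "sigma3_px2": fit.noise.sigma3,
        "converged": fit.converged, "final_loss": fit.loss_trace[-1]
        if len(fit.loss_trace) else math.nan,
    }])
    p = outdir / "fit_params.csv"
    _write_with_sidecar(fit_df, p, prov)
    written.append(p)
    sizes_df = pd.DataFrame({
        "track_id": list(fit.sizes), "size": list(fit.sizes.values()),
        "relative_size": [fit.relative_sizes[t] for t in fit.sizes],
    })
    p = outdir / "sizes.csv"
    _write_with_sidecar(sizes_df, p, prov)
    written.append(p)

    ground = reconstruct_ground_tracks(obs, fit.camera)
    tracklets = ta.extract_and_filter_tracklets(
        ground, obs.frame_rate, min_duration_s=sc.min_duration_s,
        max_gap_s=sc.max_gap_s, relative_sizes=fit.relative_sizes,
    )
    tl_df = pd.DataFrame([{
        "tracklet": t.id, "track_id": t.track_id, "start": int(t.frames[0]),
        "end": int(t.frames[-1]), "duration_s": t.duration,
        "median_speed": t.median_speed, "relative_size": t.relative_size,
    } for t in tracklets])
    p = outdir / "tracklets.csv"
    _write_with_sidecar(tl_df, p, prov)
    written.append(p)

    ks_rows = []
    if len(tracklets) >= 8:
        ks = ta.quartile_speed_comparison(tracklets)
        ks_rows.append({"comparison": "speed_lower_vs_upper_size_quartile",
                        "D": ks.statistic, "p": ks.pvalue, "n1": ks.n1, "n2": ks.n2})
    counts, epochs = ta.detect_coordination(
        tracklets, speed_threshold=sc.speed_threshold,
        count_threshold=sc.count_threshold, frame_rate=obs.frame_rate)
    ep_df = pd.DataFrame([{
        "start": e.start, "end": e.end, "peak_count": e.peak_count,
        "participants": ";".join(sorted(e.participants)),
    } for e in epochs])
    p = outdir / "coordination_epochs.csv"
    _write_with_sidecar(ep_df, p, prov)
    written.append(p)
    if epochs:
        try:
            ks = ta.participant_size_comparison(tracklets, epochs)
            ks_rows.append({"comparison": "size_participants_vs_nonparticipants",
                            "D": ks.statistic, "p": ks.pvalue,
                            "n1": ks.n1, "n2": ks.n2})
        except ValueError:
            log.info("participant comparison skipped (degenerate groups)")
    p = outdir / "ks_results.csv"
    _write_with_sidecar(pd.DataFrame(ks_rows,
                                     columns=["comparison", "D", "p", "n1", "n2"]),
                        p, prov)
    written.append(p)
    return written


def _stage_audio(cfg: RunConfig, outdir: Path, prov: dict,
                 written: list[Path]) -> list[Path]:
    from .simulate import VocalSimConfig, simulate_vocal_stream

    ac = cfg.audio
    scfg = ba.SpectrogramConfig()
    if ac.source == "simulate":
        vc = VocalSimConfig(n_bouts=ac.n_bouts, snr_db=ac.snr_db, seed=cfg.seed)
        wave, ann = simulate_vocal_stream(vc)
        fs = float(vc.sample_rate)
        write_wav(outdir / "audio.wav", fs, wave)
        syllables = [ba.Syllable(onset=r.onset_s, offset=r.offset_s, label=r.label)
                     for r in ann.itertuples()]
    else:
        fs, wave = read_wav(ac.source)
        if ac.annotations is None:
            raise DataError("audio source file requires an annotations CSV")
        syllables = read_syllables(ac.annotations)
    scfg = ba.SpectrogramConfig(sample_rate=fs)

    band = (ac.band_low_hz, min(ac.band_high_hz, fs / 2 * 0.98))
    for s in syllables:
        i0, i1 = int(s.onset * fs), int(s.offset * fs)
        try:
            track = ba.estimate_f0(wave[i0:i1], scfg, band)
            s.median_f0 = track.median
            s.f0_track = track.f0
        except (ba.NoVoicedFramesError, ValueError):
            s.median_f0 = None
    p = outdir / "syllables.csv"
    _write_with_sidecar(pd.DataFrame([{
        "onset_s": s.onset, "offset_s": s.offset, "label": s.label,
        "duration_s": s.duration, "median_f0_hz": s.median_f0,
    } for s in syllables]), p, prov)
    written.append(p)

    bouts = ba.segment_bouts(syllables, ac.gap_threshold_s)
    rows = []
    for i, b in enumerate(bouts):
        if all(s.median_f0 is None for s in b.syllables):
            continue
        b2 = ba.Bout([s for s in b.syllables if s.median_f0 is not None])
        med, sd, durs = ba.bout_summary(b2)
        rows.append({"bout": i, "onset_s": b.onset, "offset_s": b.offset,
                     "n_syllables": len(b), "median_f0_hz": med, "sd_f0_hz": sd,
                     "mean_syllable_duration_s": float(np.mean(durs))})
    p = outdir / "bouts.csv"
    _write_with_sidecar(pd.DataFrame(rows), p, prov)
    written.append(p)

    if ac.compare_with is not None:
        _, other = read_wav(ac.compare_with)
        diff = ba.level_difference_db(wave, other)
        p = outdir / "level_difference.csv"
        _write_with_sidecar(pd.DataFrame([{"level_difference_db": diff}]), p, prov)
        written.append(p)
    return written


def _stage_scene(cfg: RunConfig, outdir: Path, prov: dict,
                 written: list[Path]) -> list[Path]:
    from .simulate import simulate_scene_cloud

    sc = cfg.scene
    if sc.source == "simulate":
        cloud, _ = simulate_scene_cloud(seed=cfg.seed)
    else:
        cloud = load_splat_centers(sc.source)
    smap = compute_shelter_map(cloud, sc.cell_size, up_axis=sc.up_axis,
                               min_count=sc.min_count)
    csv_path = outdir / "shelter_map.csv"
    written.append(csv_path)
    write_shelter_map(smap, csv_path, outdir / "shelter_map.png")
    csv_path.with_suffix(".csv.prov.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True))
    return written


_STAGES = {"tracks": _stage_tracks, "audio": _stage_audio, "scene": _stage_scene}


def run_pipeline(cfg: RunConfig) -> dict[str, list[Path]]:
    """Run the selected stages in dependency order; returns written paths.

    A failing stage aborts the run with :class:`PipelineError` naming the
    stage, after removing that stage's partial outputs.
    """
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    results: dict[str, list[Path]] = {}
    for stage in cfg.stages:
        log.info("stage %s starting (seed=%d)", stage, cfg.seed)
        written: list[Path] = []
        try:
            results[stage] = _STAGES[stage](cfg, outdir, prov, written)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done: %d outputs", stage, len(results[stage]))
    return results
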