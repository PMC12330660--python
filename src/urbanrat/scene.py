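"""Shelter statistics from gaussian-splat point clouds.

A gaussian-splat reconstruction represents a 3D scene as a cloud of
oriented gaussians; only their center coordinates are used here.  The
shelter metric is a top-down gridded standard deviation of center heights:
cells under overhead clutter (canopy, scaffolding, platform roofs) mix
ground-level and elevated points and get a high z-sd, while open ground is
near zero.  Per-cell sd is the population standard deviation (no n-1
correction) of unweighted centers; a ``weights`` hook is exposed for
opacity- or scale-weighted variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binned_statistic_2d

__all__ = [
    "SplatCloud",
    "ShelterMap",
    "PlyError",
    "load_splat_centers",
    "compute_shelter_map",
]


class PlyError(ValueError):
    """Malformed PLY file or missing vertex coordinate properties."""


@dataclass
class SplatCloud:
    """Centers of a gaussian-splat cloud: an (N, 3) array of xyz positions."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if len(self.points) < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ShelterMap:
    """Gridded z-sd over the ground footprint; NaN marks under-filled cells."""

    z_sd: np.ndarray  # (nx, ny), NaN where count < min_count
    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_size: float
    up_axis: str
    min_count: int
    z_mean: np.ndarray | None = None    # per-cell mean height (unmasked)
    z_sd_raw: np.ndarray | None = None  # per-cell sd before the min_count mask

    @property
    def occupied(self) -> np.ndarray:
        return self.counts >= self.min_count

    def pooled_sd(self) -> float:
        """Global height sd recombined from the cells (law of total variance)."""
        c = self.counts.astype(float)
        mask = c > 0
        n = c[mask].sum()
        mean = float((c[mask] * self.z_mean[mask]).sum() / n)
        var = float((c[mask] * (self.z_sd_raw[mask] ** 2
                                + (self.z_mean[mask] - mean) ** 2)).sum() / n)
        return math.sqrt(var)


_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def load_splat_centers(path) -> SplatCloud:
    """Read vertex x/y/z from a PLY file (ASCII or binary little-endian).

    Every other splat property (scales, rotations, spherical harmonics,
    opacity) is ignored.  Raises :class:`PlyError` on malformed headers,
    missing x/y/z properties, or an empty vertex element.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PlyError("not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise PlyError("unexpected EOF in header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise PlyError("property before any element")
                if tokens[1] == "list":
                    elements[-1][2].append(("__list__", tokens[-1]))
                else:
                    elements[-1][2].append((tokens[-1], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PlyError(f"unsupported PLY format {fmt!r}")
        body = fh.read()

    vertex = next((e for e in elements if e[0] == "vertex"), None)
    if vertex is None:
        raise PlyError("no vertex element")
    _, count, props = vertex
    names = [n for n, _ in props]
    if count < 1:
        raise PlyError("empty vertex element")
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PlyError(f"vertex element lacks property {axis!r}")
    if elements[0][0] != "vertex":
        raise PlyError("vertex must be the first element for streaming reads")
    if "__list__" in names:
        raise PlyError("list properties in the vertex element are unsupported")

    if fmt == "ascii":
        text = body.decode("ascii", "replace")
        rows = [ln.split() for ln in text.splitlines() if ln.strip()][:count]
        if len(rows) < count:
            raise PlyError("truncated vertex data")
        arr = np.array([[float(v) for v in row[: len(names)]] for row in rows])
        cols = {n: arr[:, i] for i, n in enumerate(names)}
    else:
        dtype = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
        need = dtype.itemsize * count
        if len(body) < need:
            raise PlyError("truncated vertex data")
        rec = np.frombuffer(body[:need], dtype=dtype)
        cols = {n: rec[n].astype(float) for n, _ in props}
    pts = np.stack([cols["x"], cols["y"], cols["z"]], axis=1)
    return SplatCloud(points=pts)


def compute_shelter_map(
    cloud: SplatCloud,
    cell_size: float,
    *,
    up_axis: str = "z",
    min_count: int = 3,
    weights: np.ndarray | None = None,
) -> ShelterMap:
    """Top-down grid of the per-cell sd of splat heights.

    Points are binned on the two non-up axes into square cells of side
    ``cell_size``; each cell's statistic is the (optionally weighted)
    population sd of the up-axis coordinate.  Cells with fewer than
    ``min_count`` points are flagged empty (NaN).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    axes = {"x": 0, "y": 1, "z": 2}
    if up_axis not in axes:
        raise ValueError(f"up_axis must be one of {sorted(axes)}")
    up = axes[up_axis]
    ground = [i for i in range(3) if i != up]
    a = cloud.points[:, ground[0]]
    b = cloud.points[:, ground[1]]
    h = cloud.points[:, up]
    span_a = a.max() - a.min()
    span_b = b.max() - b.min()
    if span_a == 0.0 or span_b == 0.0:
        raise ValueError("degenerate footprint: zero area on the ground axes")
    nx = max(1, int(np.ceil(span_a / cell_size)))
    ny = max(1, int(np.ceil(span_b / cell_size)))
    x_edges = a.min() + cell_size * np.arange(nx + 1)
    y_edges = b.min() + cell_size * np.arange(ny + 1)
    bins = [x_edges, y_edges]

    counts, _, _, _ = binned_statistic_2d(a, b, None, "count", bins=bins)
    mean, _, _, _ = binned_statistic_2d(a, b, h, "mean", bins=bins)
    if weights is None:
        sd, _, _, _ = binned_statistic_2d(a, b, h, np.std, bins=bins)
    else:
        w = np.asarray(weights, dtype=float)
        sw, _, _, _ = binned_statistic_2d(a, b, w, "sum", bins=bins)
        swh, _, _, _ = binned_statistic_2d(a, b, w * h, "sum", bins=bins)
        swh2, _, _, _ = binned_statistic_2d(a, b, w * h * h, "sum", bins=bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = swh / sw
            sd = np.sqrt(np.maximum(swh2 / sw - mean**2, 0.0))
    sd_raw = sd.copy()
    sd = np.where(counts >= min_count, sd, np.nan)
    return ShelterMap(z_sd=sd, counts=counts.astype(int), x_edges=x_edges,
                      y_edges=y_edges, cell_size=float(cell_size),
                      up_axis=up_axis, min_count=int(min_count),
                      z_mean=mean, z_sd_raw=sd_raw)
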