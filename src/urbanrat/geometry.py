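"""Pinhole-camera / ground-plane geometry.

A camera sits at the origin looking along the (-1, 0, 0) direction with
focal length ``f`` (pixels).  Animals move on a tilted ground plane

    y = -x * tan(alpha) - y0

where ``alpha`` is the tilt of the plane relative to the viewing direction
and ``y0 > 0`` sets the global scale (monocular geometry is scale-free, so
all 3D quantities are in multiples of ``y0`` unless a physical camera
height is supplied).

Image coordinates follow the centered convention

    u = -f z / x,    v = f y / x

with the origin at the principal point.  Detector exports indexed from the
image's top-left corner must be converted first (see
:class:`urbanrat.io.TrackTableDialect`).

Each animal is approximated by a sphere; its apparent size is the area of
the silhouette ellipse obtained by projecting the sphere (a quadric)
through the pinhole camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraParams",
    "CamPoint3D",
    "PixelObservation",
    "GroundPoint",
    "SphereAnimal",
    "GeometryError",
    "DegenerateInputError",
    "HorizonError",
    "OffPlaneError",
    "InvalidSphereError",
    "project_point",
    "plane_point_from_pixel",
    "ground_coords",
    "apparent_size",
    "silhouette_ellipse",
    "horizon_v",
]


class GeometryError(ValueError):
    """Base class for geometric domain errors."""


class DegenerateInputError(GeometryError):
    """Point lies in the camera plane (x = 0): no finite projection."""


class HorizonError(GeometryError):
    """Pixel lies on (or numerically at) the plane's horizon line."""


class OffPlaneError(GeometryError):
    """Point does not satisfy the ground-plane equation within tolerance."""


class InvalidSphereError(GeometryError):
    """Sphere is not strictly in front of the camera, or encloses it."""


@dataclass(frozen=True)
class CameraParams:
    """Latent scene parameters Q = (tilt_angle, plane_offset, focal_length).

    Parameters
    ----------
    focal_length
        f, in pixels. Must be positive.
    tilt_angle
        alpha, radians, in (0, pi/2): tilt of the ground plane relative to
        the camera viewing direction.
    plane_offset
        y0 > 0, scene length units; sets the global scale.
    """

    focal_length: float
    tilt_angle: float
    plane_offset: float

    def __post_init__(self) -> None:
        if not self.focal_length > 0:
            raise ValueError(f"focal_length must be > 0, got {self.focal_length}")
        if not 0.0 < self.tilt_angle < math.pi / 2:
            raise ValueError(
                f"tilt_angle must lie in (0, pi/2), got {self.tilt_angle}"
            )
        if not self.plane_offset > 0:
            raise ValueError(f"plane_offset must be > 0, got {self.plane_offset}")

    @property
    def tan_tilt(self) -> float:
        return math.tan(self.tilt_angle)


@dataclass(frozen=True)
class CamPoint3D:
    """Camera-centered 3D point; visible points have x < 0."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class PixelObservation:
    """Centered image-plane measurement (u, v) with optional area s [px^2]."""

    u: float
    v: float
    s: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("u, v must be finite")
        if self.s is not None and self.s < 0:
            raise ValueError(f"apparent size must be >= 0, got {self.s}")


@dataclass(frozen=True)
class GroundPoint:
    """In-plane 2D coordinates of a point on the ground plane."""

    g1: float
    g2: float


@dataclass(frozen=True)
class SphereAnimal:
    """Spherical animal body: center (camera frame) and radius r > 0."""

    center: CamPoint3D
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not (-self.center.x > self.radius):
            raise InvalidSphereError(
                "sphere must lie entirely in front of the camera (-x > r)"
            )


def horizon_v(camera: CameraParams) -> float:
    """Image row v = -f*tan(alpha) where ground-plane back-projection diverges."""
    return -camera.focal_length * camera.tan_tilt


def project_point(point, focal_length: float):
    """Project camera-frame point(s) to centered pixel coordinates.

    ``u = -f z / x``, ``v = f y / x``.  Accepts a :class:`CamPoint3D` or an
    array of shape (..., 3); returns ``(u, v)`` matching the input's shape.
    """
    if isinstance(point, CamPoint3D):
        p = point.as_array()
    else:
        p = np.asarray(point, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    if np.any(x == 0.0):
        raise DegenerateInputError("point has x = 0: lies in the camera plane")
    u = -focal_length * z / x
    v = focal_length * y / x
    return u, v


def plane_point_from_pixel(u, v, camera: CameraParams):
    """Back-project pixel(s) onto the ground plane.

    Inverts the projection restricted to the plane y = -x tan(alpha) - y0:

        x = -f y0 / (v + f tan a)
        y = -v y0 / (v + f tan a)
        z =  u y0 / (v + f tan a)

    Raises :class:`HorizonError` when ``|v + f tan a| < 1e-8 * f`` (the pixel
    has no finite intersection with the plane).  Scalar input returns a
    :class:`CamPoint3D`; array input returns an array of shape (..., 3).
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    f = camera.focal_length
    y0 = camera.plane_offset
    denom = v_arr + f * camera.tan_tilt
    if np.any(np.abs(denom) < 1e-8 * f):
        raise HorizonError("pixel lies on the plane's horizon line v = -f tan(alpha)")
    x = -f * y0 / denom
    y = -v_arr * y0 / denom
    z = u_arr * y0 / denom
    if u_arr.ndim == 0:
        return CamPoint3D(float(x), float(y), float(z))
    return np.stack([x, y, z], axis=-1)


def ground_coords(
    point,
    camera: CameraParams,
    *,
    order: str = "lateral_first",
    check_plane: bool = True,
    atol: float = 1e-9,
):
    """In-plane 2D coordinates of on-plane point(s).

    The plane directions are the image-horizontal axis (coordinate ``z``)
    and the up-slope axis (coordinate ``y / sin(alpha)``); restricted to the
    plane this map is an isometry.  ``order`` selects the component order:
    ``"lateral_first"`` returns ``(z, y/sin a)``, ``"slope_first"`` returns
    ``(y/sin a, z)``.  With ``check_plane`` the plane residual
    ``y + x tan a + y0`` is verified against ``atol`` (scaled by y0).
    """
    if order not in ("lateral_first", "slope_first"):
        raise ValueError(f"unknown order {order!r}")
    if isinstance(point, CamPoint3D):
        p = point.as_array()
        scalar = True
    else:
        p = np.asarray(point, dtype=float)
        scalar = p.ndim == 1
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    if check_plane:
        resid = y + x * camera.tan_tilt + camera.plane_offset
        if np.any(np.abs(resid) > atol * max(1.0, camera.plane_offset)):
            raise OffPlaneError(
                f"point off the ground plane: |residual| up to {np.max(np.abs(resid)):g}"
            )
    slope = y / math.sin(camera.tilt_angle)
    first, second = (z, slope) if order == "lateral_first" else (slope, z)
    if scalar:
        return GroundPoint(float(first), float(second))
    return np.stack([first, second], axis=-1)


def _sphere_checks(center: np.ndarray, radius, name: str = "sphere") -> None:
    x = center[..., 0]
    d2 = np.sum(center**2, axis=-1)
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise InvalidSphereError(f"{name}: radius must be > 0")
    if np.any(d2 <= r**2):
        raise InvalidSphereError(f"{name}: camera center inside or tangent to sphere")
    if np.any(-x <= r):
        raise InvalidSphereError(f"{name}: sphere not fully in front of camera")


def apparent_size(animal, focal_length: float | None = None, *, mode: str = "ellipse"):
    """Apparent size (px^2) of a sphere's silhouette.

    The silhouette of a sphere under a pinhole camera is an ellipse (the
    projection of the sphere's dual quadric); its area admits the closed
    form

        A = pi f^2 r^2 sqrt(d^2 - r^2) / (x_c^2 - r^2)^(3/2)

    with d the distance from the camera to the sphere center and x_c the
    center's coordinate along the optical axis.  On the optical axis
    (|x_c| = d) this reduces to ``pi f^2 r^2 / (d^2 - r^2)``.

    Parameters
    ----------
    animal
        A :class:`SphereAnimal`, or a tuple ``(center, radius)`` with
        ``center`` array-like (..., 3) and broadcastable radius.
    focal_length
        f in pixels.
    mode
        ``"ellipse"`` (default) returns the silhouette ellipse area;
        ``"bbox"`` returns the area of the axis-aligned bounding box of the
        ellipse in image coordinates (product of the two full extents).
    """
    if isinstance(animal, SphereAnimal):
        center = animal.center.as_array()
        radius = animal.radius
    else:
        center, radius = animal
        center = np.asarray(center, dtype=float)
    if focal_length is None:
        raise TypeError("focal_length is required")
    _sphere_checks(center, radius)
    if mode == "ellipse":
        return _ellipse_area(center, np.asarray(radius, dtype=float), focal_length)
    if mode == "bbox":
        a_u, a_v, _ = silhouette_ellipse(center, radius, focal_length)
        return 4.0 * a_u * a_v
    raise ValueError(f"unknown mode {mode!r}")


def _ellipse_area(center: np.ndarray, radius, f: float):
    x = center[..., 0]
    d2 = np.sum(center**2, axis=-1)
    r2 = np.asarray(radius, dtype=float) ** 2
    area = np.pi * f**2 * r2 * np.sqrt(d2 - r2) / (x**2 - r2) ** 1.5
    if area.ndim == 0:
        return float(area)
    return area


def silhouette_ellipse(center, radius: float, f: float):
    """Axis-aligned half-extents (eu, ev) and area of the silhouette ellipse.

    Works from the image conic of the tangent cone: a ray through pixel
    (u, v) has direction (-1, -v/f, u/f) and is tangent to the sphere when
    (dir . c)^2 = cos^2(theta) |dir|^2 d^2 with sin(theta) = r/d.  Returns
    ``(eu, ev, area)`` for a single sphere.
    """
    c = np.asarray(center, dtype=float)
    _sphere_checks(c, radius)
    cx, cy, cz = c
    d2 = float(cx**2 + cy**2 + cz**2)
    k = (d2 - radius**2) / d2  # cos^2 theta
    # Conic n n^T - k d^2 diag(1/f^2, 1/f^2, 1) on homogeneous (u, v, 1).
    n = np.array([cz / f, -cy / f, -cx])
    C = np.outer(n, n) - k * d2 * np.diag([1.0 / f**2, 1.0 / f**2, 1.0])
    M = C[:2, :2]
    b = C[:2, 2]
    c0 = C[2, 2]
    w0 = -np.linalg.solve(M, b)
    kappa = float(w0 @ M @ w0 - c0)
    # Normalize so the quadratic part is positive definite.
    if kappa < 0:
        M, kappa = -M, -kappa
    Minv = np.linalg.inv(M)
    eu = math.sqrt(kappa * Minv[0, 0])
    ev = math.sqrt(kappa * Minv[1, 1])
    area = math.pi * kappa / math.sqrt(np.linalg.det(M))
    return eu, ev, area
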