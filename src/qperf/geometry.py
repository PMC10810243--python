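"""Myocardial slice geometry: contours, insertion points, masks and angles.

Coordinates are 0-based pixel coordinates ``[x, y]`` where ``x`` is the image
column and ``y`` the image row.  Angles are measured in the image frame with
``atan2(y - cy, x - cx)``; the bullseye angle ``theta`` is measured from the
anterior right-ventricular (RV) insertion point, increasing toward the
inferior insertion point through the septum (the short way between the two
insertion points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

SLICE_LABELS = ("basal", "mid", "apical")

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Raised when slice geometry is degenerate or inconsistent."""


@dataclass(frozen=True)
class SliceGeometry:
    """Endo/epicardial contours and RV insertion points for one slice.

    Parameters
    ----------
    endo_contour, epi_contour:
        Closed simple polygons as ``(n, 2)`` arrays of ``[x, y]`` pixel
        coordinates.  The closing edge is implicit (last vertex connects
        back to the first).
    rv_anterior, rv_inferior:
        The two RV insertion points, ``[x, y]``.
    slice_label:
        One of ``basal``, ``mid``, ``apical``.
    """

    endo_contour: np.ndarray
    epi_contour: np.ndarray
    rv_anterior: np.ndarray
    rv_inferior: np.ndarray
    slice_label: str

    def __post_init__(self):
        for name in ("endo_contour", "epi_contour"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise GeometryError(f"{name} must be an (n>=3, 2) array")
            if not np.all(np.isfinite(c)):
                raise GeometryError(f"{name} contains non-finite vertices")
            object.__setattr__(self, name, c)
        for name in ("rv_anterior", "rv_inferior"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise GeometryError(f"{name} must be a finite [x, y] point")
            object.__setattr__(self, name, p)
        if self.slice_label not in SLICE_LABELS:
            raise GeometryError(
                f"slice_label must be one of {SLICE_LABELS}, got {self.slice_label!r}"
            )


def polygon_centroid(contour: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (shoelace formula), as ``[x, y]``."""
    c = np.asarray(contour, dtype=float)
    x, y = c[:, 0], c[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        raise GeometryError("degenerate polygon with zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def resample_contour(contour: np.ndarray, n: int = 360) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices equally spaced by arc length."""
    c = np.asarray(contour, dtype=float)
    closed = np.vstack([c, c[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("contour has zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def wrap_angle(a):
    """Wrap angle(s) into ``[0, 2*pi)``."""
    return np.mod(a, TWO_PI)


def _signed_wrap(a):
    """Wrap angle(s) into ``(-pi, pi]``."""
    return np.pi - np.mod(np.pi - np.asarray(a), TWO_PI)


class PolarContour:
    """Radius-vs-angle view of a star-shaped contour about a fixed center.

    The contour is resampled by arc length and converted to polar
    coordinates; radii at arbitrary angles are linearly interpolated between
    consecutive vertices.  Contours that are not star-shaped about the
    center (the polar angle does not sweep monotonically) are rejected,
    because a ray from the center would then cross the contour more than
    once.
    """

    def __init__(self, contour: np.ndarray, center: np.ndarray, n: int = 360):
        v = resample_contour(contour, n)
        d = v - np.asarray(center, dtype=float)
        phi = np.arctan2(d[:, 1], d[:, 0])
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-9):
            raise GeometryError("contour passes through the ray origin")
        dphi = _signed_wrap(np.diff(phi))
        if not (np.all(dphi > 0) or np.all(dphi < 0)):
            raise GeometryError(
                "contour is not star-shaped about the centroid; rays would "
                "intersect it more than once"
            )
        order = np.argsort(phi)
        self._phi = phi[order]
        self._r = r[order]

    def radius(self, phi):
        """Interpolated radius at image-frame angle(s) ``phi``."""
        phi = wrap_angle(np.asarray(phi, dtype=float) - self._phi[0]) + self._phi[0]
        phi_ext = np.concatenate([self._phi, [self._phi[0] + TWO_PI]])
        r_ext = np.concatenate([self._r, [self._r[0]]])
        return np.interp(phi, phi_ext, r_ext)


def angular_frame(geometry: SliceGeometry) -> tuple[np.ndarray, float, float]:
    """Angular reference frame anchored at the anterior RV insertion point.

    Returns ``(centroid, phi_anterior, direction)`` where ``direction`` is
    ``+1`` or ``-1`` such that the bullseye angle of an image point at polar
    angle ``phi`` is ``direction * (phi - phi_anterior)`` wrapped to
    ``[0, 2*pi)``, increasing from the anterior toward the inferior
    insertion point through the septum.
    """
    center = polygon_centroid(geometry.endo_contour)
    da = geometry.rv_anterior - center
    di = geometry.rv_inferior - center
    phi_a = float(np.arctan2(da[1], da[0]))
    phi_i = float(np.arctan2(di[1], di[0]))
    diff = float(_signed_wrap(phi_i - phi_a))
    if abs(diff) < 1e-6 or abs(abs(diff) - np.pi) < 1e-6:
        raise GeometryError(
            "RV insertion points coincident or collinear with the centroid"
        )
    direction = 1.0 if diff > 0 else -1.0
    return center, phi_a, direction


def bullseye_angle(points: np.ndarray, geometry: SliceGeometry) -> np.ndarray:
    """Bullseye angle (radians, ``[0, 2*pi)``) of ``[x, y]`` point(s)."""
    center, phi_a, direction = angular_frame(geometry)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    phi = np.arctan2(p[:, 1] - center[1], p[:, 0] - center[0])
    theta = wrap_angle(direction * (phi - phi_a))
    return theta if np.asarray(points).ndim > 1 else float(theta[0])


def myocardial_mask(geometry: SliceGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Binary myocardium mask (epicardium minus endocardium) on an image grid.

    ``shape`` is ``(n_rows, n_cols)``.  Contour coordinates are ``[x, y]``
    i.e. ``[col, row]``; ``polygon2mask`` expects ``(row, col)`` vertices.
    """
    epi_rc = geometry.epi_contour[:, ::-1]
    endo_rc = geometry.endo_contour[:, ::-1]
    epi = polygon2mask(shape, epi_rc)
    endo = polygon2mask(shape, endo_rc)
    if np.any(endo & ~epi):
        raise GeometryError("endocardial contour extends outside the epicardial one")
    mask = epi & ~endo
    if not mask.any():
        raise GeometryError("empty myocardial mask")
    return mask
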