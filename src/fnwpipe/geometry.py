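"""Minimum femoral neck width (FNW) from landmark annotations of hip DXA scans.

A hip outline is annotated with 85 ordered landmark points in image pixel
coordinates. The inferior femoral-neck contour is traced by points 6-12 and
the superior contour by points 32-38 (1-based indices). FNW is the minimum
distance, in millimetres, between the two contours after converting pixel
coordinates to mm with the per-axis pixel spacing.

The distance between the two open polylines is the exact bidirectional
point-to-segment minimum: the smallest distance from any vertex of one
polyline to any segment of the other, taken in both directions. For
non-crossing contours this equals the true segment-to-segment minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeAnnotation",
    "WidthResult",
    "INFERIOR_NECK_IDX",
    "SUPERIOR_NECK_IDX",
    "min_polyline_distance",
    "compute_fnw",
]

N_LANDMARKS = 85
#: 1-based landmark indices of the inferior and superior femoral-neck contours.
INFERIOR_NECK_IDX = tuple(range(6, 13))
SUPERIOR_NECK_IDX = tuple(range(32, 39))


@dataclass(frozen=True)
class ShapeAnnotation:
    """An 85-point hip outline with pixel spacing metadata.

    Parameters
    ----------
    points
        Array of shape (85, 2) of (x, y) landmark positions in pixel
        coordinates; x increases rightward, y downward. Landmark indices
        are 1-based when referred to by number.
    pixel_spacing_x, pixel_spacing_y
        Physical size of one pixel along each image axis, in mm/px.
    """

    points: np.ndarray
    pixel_spacing_x: float
    pixel_spacing_y: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"annotation must have exactly {N_LANDMARKS} (x, y) points, "
                f"got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)
        if not (self.pixel_spacing_x > 0 and self.pixel_spacing_y > 0):
            raise ValueError("pixel spacings must be positive")

    def landmarks(self, indices_1based) -> np.ndarray:
        """Return the (k, 2) pixel coordinates of 1-based landmark indices."""
        idx = np.asarray(indices_1based, dtype=int) - 1
        return self.points[idx]


@dataclass(frozen=True)
class WidthResult:
    """Minimum neck width and the geometry realizing it."""

    fnw_mm: float
    #: index of the realizing vertex on the 'point' side (0-based within its polyline)
    point_index: int
    #: index of the realizing segment on the 'segment' side, and parametric
    #: position t in [0, 1] of the foot of the minimum along that segment
    segment_index: int
    segment_t: float
    #: "inferior-to-superior" if the realizing vertex lies on the inferior
    #: polyline, else "superior-to-inferior"
    side_order: str


def _point_segment_distances(pts: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray):
    """Distances from each point to each segment [a_j, b_j].

    Returns (dist, t) where dist[i, j] is the distance from pts[i] to segment j
    and t[i, j] the parametric position of the closest point on the segment.
    """
    d = seg_b - seg_a  # (m, 2)
    len2 = np.einsum("ij,ij->i", d, d)  # (m,)
    diff = pts[:, None, :] - seg_a[None, :, :]  # (n, m, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nmk,mk->nm", diff, d) / len2[None, :]
    t = np.where(len2[None, :] > 0, t, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = seg_a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return dist, t


def _any_segments_cross(a: np.ndarray, b: np.ndarray) -> bool:
    """True if any segment of polyline a intersects any segment of b."""
    p, r = a[:-1], a[1:] - a[:-1]  # (na, 2)
    q, s = b[:-1], b[1:] - b[:-1]  # (nb, 2)

    def cross(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    qp = q[None, :, :] - p[:, None, :]  # (na, nb, 2)
    rxs = cross(r[:, None, :], s[None, :, :])
    t_num = cross(qp, s[None, :, :])
    u_num = cross(qp, r[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = t_num / rxs
        u = u_num / rxs
    proper = (np.abs(rxs) > 1e-300) & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
    return bool(np.any(proper))


def min_polyline_distance(poly_a: np.ndarray, poly_b: np.ndarray):
    """Exact minimum distance between two open polylines.

    Computes the minimum over (i) every vertex of A against every segment of
    B and (ii) every vertex of B against every segment of A. The result is
    symmetric in its arguments and never exceeds the minimum vertex-vertex
    distance.

    Returns
    -------
    (distance, argmin) where argmin is a dict with keys ``direction``
    ("a_to_b" or "b_to_a"), ``point_index``, ``segment_index`` and ``t``.
    """
    a = np.asarray(poly_a, dtype=float)
    b = np.asarray(poly_b, dtype=float)
    for name, p in (("A", a), ("B", b)):
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise ValueError(f"polyline {name} needs at least 2 (x, y) points")
        if not np.all(np.isfinite(p)):
            raise ValueError(f"polyline {name} contains non-finite coordinates")

    if _any_segments_cross(a, b):
        warnings.warn("polylines touch or cross; minimum width is 0", stacklevel=2)
        return 0.0, {"direction": "cross", "point_index": -1, "segment_index": -1, "t": 0.0}

    d_ab, t_ab = _point_segment_distances(a, b[:-1], b[1:])
    d_ba, t_ba = _point_segment_distances(b, a[:-1], a[1:])

    i_ab = np.unravel_index(np.argmin(d_ab), d_ab.shape)
    i_ba = np.unravel_index(np.argmin(d_ba), d_ba.shape)
    if d_ab[i_ab] <= d_ba[i_ba]:
        dist = float(d_ab[i_ab])
        argmin = {
            "direction": "a_to_b",
            "point_index": int(i_ab[0]),
            "segment_index": int(i_ab[1]),
            "t": float(t_ab[i_ab]),
        }
    else:
        dist = float(d_ba[i_ba])
        argmin = {
            "direction": "b_to_a",
            "point_index": int(i_ba[0]),
            "segment_index": int(i_ba[1]),
            "t": float(t_ba[i_ba]),
        }
    return dist, argmin


def compute_fnw(annotation: ShapeAnnotation) -> WidthResult:
    """Minimum femoral neck width in mm for one annotated hip image.

    Extracts the inferior (points 6-12) and superior (points 32-38) neck
    contours, scales x by ``pixel_spacing_x`` and y by ``pixel_spacing_y``
    to obtain mm coordinates, and returns their minimum polyline distance.
    Anisotropic spacing is supported; scaling precedes the distance
    computation.
    """
    scale = np.array([annotation.pixel_spacing_x, annotation.pixel_spacing_y])
    inferior = annotation.landmarks(INFERIOR_NECK_IDX) * scale
    superior = annotation.landmarks(SUPERIOR_NECK_IDX) * scale
    if not (np.all(np.isfinite(inferior)) and np.all(np.isfinite(superior))):
        raise ValueError("non-finite coordinates among femoral-neck landmarks")
    dist, argmin = min_polyline_distance(inferior, superior)
    side = "inferior-to-superior" if argmin["direction"] == "a_to_b" else "superior-to-inferior"
    return WidthResult(
        fnw_mm=dist,
        point_index=argmin["point_index"],
        segment_index=argmin["segment_index"],
        segment_t=argmin["t"],
        side_order=side,
    )
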