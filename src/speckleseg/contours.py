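"""Closed-contour utilities shared by the PCNN, Snake and cloud-ACM stages.

Contours are ``(n, 2)`` float arrays of ``(row, col)`` sub-pixel points,
implicitly closed (last point connects back to the first). Pixel ``(r, c)``
has its centre at coordinates ``(r, c)`` (the scikit-image convention), and
"clockwise" means clockwise as drawn on screen with the row axis pointing
down.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_contour",
    "signed_area",
    "contour_area",
    "ensure_clockwise",
    "arc_lengths",
    "resample_closed",
    "outward_normals",
    "contour_centroid",
]


def as_contour(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError(f"a contour needs at least 4 (row, col) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive contour points coincide")
    return pts


def signed_area(contour) -> float:
    """Shoelace area with x = col, y = row.

    Positive sign corresponds to clockwise traversal on screen (row axis
    down flips the usual orientation convention).
    """
    pts = np.asarray(contour, dtype=float)
    r, c = pts[:, 0], pts[:, 1]
    rn, cn = np.roll(r, -1), np.roll(c, -1)
    return 0.5 * float(np.sum(c * rn - cn * r))


def contour_area(contour) -> float:
    """Unsigned enclosed area of a closed polygon."""
    return abs(signed_area(contour))


def ensure_clockwise(contour) -> np.ndarray:
    """Return the contour traversed clockwise (in image coordinates)."""
    pts = np.asarray(contour, dtype=float)
    if signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return pts


def arc_lengths(contour) -> np.ndarray:
    """Cumulative arc length over the closed polygon; length n+1, starts at 0."""
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed(contour, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` points equally spaced in arc length."""
    pts = np.asarray(contour, dtype=float)
    if n < 4:
        raise ValueError("need at least 4 resampled points")
    s = arc_lengths(pts)
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour of zero length")
    closed = np.vstack([pts, pts[:1]])
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def contour_centroid(contour) -> np.ndarray:
    return np.asarray(contour, dtype=float).mean(axis=0)


def outward_normals(contour) -> np.ndarray:
    """Unit normals pointing away from the contour centroid.

    Tangents are central differences over the closed polygon; each normal is
    the tangent rotated by 90 degrees, its sign fixed so that it points away
    from the centroid (valid for the star-shaped contours this pipeline
    produces).
    """
    pts = as_contour(contour)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lengths = np.linalg.norm(norm, axis=1)
    lengths[lengths == 0] = 1.0
    norm /= lengths[:, None]
    outward = pts - contour_centroid(pts)
    flip = np.sum(norm * outward, axis=1) < 0
    norm[flip] *= -1.0
    return norm
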