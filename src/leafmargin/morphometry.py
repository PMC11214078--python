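"""Leaf-silhouette morphometrics.

A silhouette is a closed simple polygon (vertex list, millimetres).  The
complexity score is the Normalized Difference Margin Complexity

    NDMC = (P_contour - P_hull) / (P_contour + P_hull)

where P_contour is the silhouette perimeter and P_hull the perimeter of its
convex hull.  NDMC is 0 for convex outlines, grows with marginal
dissection (serrations, lobes, leaflets), and is invariant to rotation,
translation and uniform scaling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

__all__ = ["LeafSilhouette", "perimeter", "convex_hull", "ndmc"]


@dataclasses.dataclass
class LeafSilhouette:
    """Closed simple polygon; vertices are normalized to counterclockwise order."""

    vertices: np.ndarray
    name: Optional[str] = None
    validate: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if v.shape[0] > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # stored open; the contour is implicitly closed
        if v.shape[0] < 3:
            raise ValueError(f"a silhouette needs >= 3 vertices (got {v.shape[0]})")
        poly = Polygon(v)
        if self.validate:
            if not poly.is_valid or poly.area == 0:
                raise ValueError("silhouette polygon is self-intersecting or degenerate")
        if poly.area > 0:
            poly = orient(poly, sign=1.0)  # counterclockwise
            v = np.asarray(poly.exterior.coords)[:-1]
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def _as_silhouette(polygon) -> LeafSilhouette:
    if isinstance(polygon, LeafSilhouette):
        return polygon
    return LeafSilhouette(np.asarray(polygon, dtype=float))


def perimeter(polygon) -> float:
    """Perimeter of the closed contour (sum of edge lengths)."""
    return float(_as_silhouette(polygon).polygon.exterior.length)


def convex_hull(polygon) -> LeafSilhouette:
    """Convex hull of the silhouette's vertex set, as a silhouette."""
    sil = _as_silhouette(polygon)
    hull = sil.polygon.convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("degenerate hull: input vertices are collinear")
    out = LeafSilhouette(np.asarray(hull.exterior.coords)[:-1], name=sil.name)
    assert out.polygon.exterior.length <= sil.polygon.exterior.length + 1e-9
    return out


def ndmc(polygon) -> float:
    """Normalized Difference Margin Complexity of a silhouette, in [0, 1)."""
    sil = _as_silhouette(polygon)
    hull = convex_hull(sil)
    if sil.polygon.equals(hull.polygon):
        return 0.0  # convex contour: identically zero, no roundoff
    p_c = perimeter(sil)
    p_h = perimeter(hull)
    return (p_c - p_h) / (p_c + p_h)
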