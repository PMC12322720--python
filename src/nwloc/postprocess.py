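"""Voronoi-tessellation outlier exclusion.

Detections that are not colocalized with a nanowire tip are rejected: a
reference grid of tip positions (from bright-field localization or from the
fitted lattice) is tessellated, each detection is assigned to the cell of
its nearest reference tip, and it is kept only if it lies within a
colocalization radius ``r_max`` of that tip.  Because one wire is one
digital unit, at most the single nearest detection per cell is kept by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree
from skimage.feature import peak_local_max

__all__ = ["ReferenceGrid", "build_reference", "voronoi_exclude", "detect_tips"]

#: Default colocalization radius as a fraction of the lattice spacing.
DEFAULT_RMAX_FRACTION = 1.0 / 3.0


@dataclass
class ReferenceGrid:
    """Tip positions, their Voronoi tessellation, and the kept radius."""

    points_um: np.ndarray          # (n, 2)
    r_max_um: float
    voronoi: Voronoi = field(repr=False)
    _tree: cKDTree = field(repr=False)

    @property
    def n_points(self) -> int:
        return len(self.points_um)

    def boundary_cells(self) -> np.ndarray:
        """Mask of reference points whose Voronoi cell is unbounded."""
        vor = self.voronoi
        mask = np.zeros(len(self.points_um), bool)
        for i, region in enumerate(vor.point_region):
            verts = vor.regions[region]
            if -1 in verts or len(verts) == 0:
                mask[i] = True
        return mask

    def cell_polygon(self, i: int):
        """Shapely polygon of a bounded cell (None for unbounded cells)."""
        from shapely.geometry import Polygon

        vor = self.voronoi
        verts = vor.regions[vor.point_region[i]]
        if -1 in verts or len(verts) < 3:
            return None
        return Polygon(vor.vertices[verts])


def build_reference(
    points_um: np.ndarray, r_max_um: float | None = None, spacing_um: float = 0.99
) -> ReferenceGrid:
    """Voronoi tessellation of reference tip positions.

    ``r_max`` defaults to spacing/3 — well below the half-spacing that would
    make cell assignment ambiguous and well above typical localization
    error.  Raises for fewer than 4 points or a degenerate (collinear)
    configuration.
    """
    pts = np.asarray(points_um, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need at least 4 reference points of shape (n, 2)")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("reference points are collinear; cannot tessellate")
    if r_max_um is None:
        r_max_um = spacing_um * DEFAULT_RMAX_FRACTION
    return ReferenceGrid(
        points_um=pts,
        r_max_um=float(r_max_um),
        voronoi=Voronoi(pts),
        _tree=cKDTree(pts),
    )


def detect_tips(
    brightfield: np.ndarray,
    pixel_size_um: float,
    spacing_um: float = 0.99,
    threshold_rel: float = 0.3,
) -> np.ndarray:
    """Locate nanowire tips in a bright-field frame.

    Works for wires darker or brighter than the background: the dominant
    deviation sign from the median is detected.  Peaks are refined to
    subpixel precision by a local intensity centroid.  Returns (n, 2)
    positions in µm.
    """
    img = np.asarray(brightfield, float)
    d = img - np.median(img)
    if abs(d.min()) > abs(d.max()):
        d = -d
    d = ndimage.gaussian_filter(d, 1.0)
    min_dist = max(int(0.5 * spacing_um / pixel_size_um), 1)
    rc = peak_local_max(d, min_distance=min_dist, threshold_rel=threshold_rel)
    pts = []
    for r, c in rc:
        r0, r1 = max(r - 2, 0), min(r + 3, d.shape[0])
        c0, c1 = max(c - 2, 0), min(c + 3, d.shape[1])
        w = np.clip(d[r0:r1, c0:c1], 0, None)
        if w.sum() <= 0:
            pts.append((c, r))
            continue
        ys, xs = np.mgrid[r0:r1, c0:c1]
        pts.append((np.sum(xs * w) / w.sum(), np.sum(ys * w) / w.sum()))
    pts = np.asarray(pts, float)
    if len(pts) == 0:
        return pts.reshape(0, 2)
    return (pts + 0.5) * pixel_size_um


def voronoi_exclude(
    detections: pd.DataFrame,
    grid: ReferenceGrid,
    one_per_wire: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split detections into (kept, excluded) by tip colocalization.

    Each detection is assigned to its nearest reference tip (its Voronoi
    cell seed) and kept iff its distance to that tip is at most ``r_max``.
    With ``one_per_wire`` (default) at most one detection survives per cell:
    the nearest to the tip, ties broken by higher photon count.  The
    excluded table gains ``reason`` ∈ {far_from_tip, duplicate_in_cell};
    both tables gain ``cell`` and ``tip_distance_um``.  The result does not
    depend on the input row order.
    """
    det = detections.copy()
    if len(det) == 0:
        det["cell"] = pd.Series([], dtype=int)
        det["tip_distance_um"] = pd.Series([], dtype=float)
        excluded = det.copy()
        excluded["reason"] = pd.Series([], dtype=str)
        return det, excluded

    xy = det[["x_um", "y_um"]].to_numpy(float)
    dist, cell = grid._tree.query(xy)
    det["cell"] = cell
    det["tip_distance_um"] = dist
    reason = np.full(len(det), "", object)
    keep = dist <= grid.r_max_um
    reason[~keep] = "far_from_tip"

    if one_per_wire:
        # order-independent winner per cell: nearest, then brighter, then
        # lowest (y, x) as a final deterministic tie-break
        photons = det["photons"].to_numpy(float) if "photons" in det else np.zeros(len(det))
        order = np.lexsort(
            (det["x_um"].to_numpy(), det["y_um"].to_numpy(), -photons, dist)
        )
        seen: set[int] = set()
        for i in order:
            if not keep[i]:
                continue
            c = int(cell[i])
            if c in seen:
                keep[i] = False
                reason[i] = "duplicate_in_cell"
            else:
                seen.add(c)

    kept = det[keep].reset_index(drop=True)
    excluded = det[~keep].reset_index(drop=True)
    excluded["reason"] = reason[~keep]
    return kept, excluded
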