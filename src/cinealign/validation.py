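"""Validation of reconstructed surfaces against long-axis contours.

The reconstructed LV surface is intersected with each of the three long-axis
imaging planes; the resulting cross-section is compared with the LV contour
delineated on that plane using three criteria: the Hausdorff distance between
the boundary curves (curve-based, possibly infinite when one region is
empty), and the Dice and Jaccard region-overlap coefficients

    D = 2 |Re ∩ Tr| / (|Re| + |Tr|),      J = |Re ∩ Tr| / |Re ∪ Tr|,

where Re and Tr are the regions bounded by the reconstruction cross-section
and by the expert (here: phantom ground-truth) contour.  D and J satisfy
J = D / (2 - D) identically.  A Dice of 0.7 or above is conventionally read
as adequate overlap.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import PlaneMismatchError
from .geometry import LA_VIEWS, ImagePlane, SliceRecord
from .mesh import SurfaceMesh

__all__ = ["PlanarRegion", "ViewScores", "ValidationReport",
           "intersect_mesh_plane", "hausdorff", "dice", "jaccard", "validate"]

INF = float("inf")


@dataclass
class PlanarRegion:
    """Region(s) in an imaging plane, as closed polygons in in-plane mm coords."""

    plane: ImagePlane
    boundary: list[np.ndarray]

    def __post_init__(self):
        self.boundary = [np.asarray(b, float).reshape(-1, 2) for b in self.boundary
                         if len(np.atleast_2d(b)) >= 3]

    @property
    def is_empty(self) -> bool:
        return len(self.boundary) == 0

    def to_shapely(self):
        polys = []
        for b in self.boundary:
            p = Polygon(b)
            if not p.is_valid:
                p = p.buffer(0)
            if not p.is_empty:
                polys.append(p)
        return unary_union(polys) if polys else Polygon()

    def area(self) -> float:
        return float(self.to_shapely().area)


@dataclass(frozen=True)
class ViewScores:
    """Hausdorff (mm), Dice and Jaccard for one long-axis view."""

    hausdorff: float
    dice: float
    jaccard: float

    def __post_init__(self):
        if math.isinf(self.hausdorff) and (self.dice != 0 or self.jaccard != 0):
            raise ValueError("infinite Hausdorff implies zero overlap")
        if self.jaccard > self.dice + 1e-12:
            raise ValueError("Jaccard cannot exceed Dice")


@dataclass
class ValidationReport:
    """Per-view scores for 2CH/3CH/4CH plus their means.

    Views whose contours were absent from the input are recorded as None and
    excluded from the means; an infinite Hausdorff in any present view makes
    the mean Hausdorff infinite, matching how a no-intersection case
    dominates a per-case average.
    """

    per_view: dict[str, ViewScores | None]

    @property
    def mean_hausdorff(self) -> float:
        vals = [s.hausdorff for s in self.per_view.values() if s is not None]
        if not vals:
            return INF
        return INF if any(math.isinf(v) for v in vals) else float(np.mean(vals))

    @property
    def mean_dice(self) -> float:
        vals = [s.dice for s in self.per_view.values() if s is not None]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def mean_jaccard(self) -> float:
        vals = [s.jaccard for s in self.per_view.values() if s is not None]
        return float(np.mean(vals)) if vals else 0.0

    def rows(self, prefix: str = "") -> list[list[str]]:
        """CSV rows (view, H_mm, D, J) plus a means row; inf as literal 'inf'."""
        def fmt(x: float) -> str:
            return "inf" if math.isinf(x) else f"{x:.6f}"

        out = []
        for view in LA_VIEWS:
            s = self.per_view.get(view)
            if s is None:
                out.append([prefix + view, "absent", "absent", "absent"])
            else:
                out.append([prefix + view, fmt(s.hausdorff), fmt(s.dice), fmt(s.jaccard)])
        out.append([prefix + "mean", fmt(self.mean_hausdorff),
                    fmt(self.mean_dice), fmt(self.mean_jaccard)])
        return out

    def write_csv(self, path, prefix: str = "") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["view", "H_mm", "D", "J"])
            w.writerows(self.rows(prefix))


# ---------------------------------------------------------------------------
# mesh/plane intersection
# ---------------------------------------------------------------------------

def intersect_mesh_plane(surface: SurfaceMesh, plane: ImagePlane,
                         min_segment: float = 1e-9) -> PlanarRegion:
    """Cross-section of a closed surface with an imaging plane.

    Triangle-plane intersection segments are chained into closed polygons
    and expressed in the plane's in-plane mm coordinates; an empty region is
    returned when the plane misses the surface.  Degenerate polylines with
    near-zero extent are dropped.
    """
    surface.require_closed()
    tm = surface.to_trimesh()
    section = tm.section(plane_origin=plane.position, plane_normal=plane.normal)
    if section is None:
        return PlanarRegion(plane, [])
    polys = []
    for poly3 in section.discrete:
        p2 = plane.project_to_plane_mm(poly3)
        # drop the repeated closing vertex and degenerate loops
        if len(p2) > 1 and np.linalg.norm(p2[0] - p2[-1]) < min_segment:
            p2 = p2[:-1]
        if len(p2) >= 3 and abs(Polygon(p2).area) > 1e-3:
            polys.append(p2)
    return PlanarRegion(plane, polys)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _resample_curve(points: np.ndarray, step: float, closed: bool) -> np.ndarray:
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return pts
    ring = np.vstack([pts, pts[:1]]) if closed else pts
    out = [ring[0]]
    for a, b in zip(ring[:-1], ring[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        lam = (np.arange(n) + 1) / n
        out.extend(a[None, :] * (1 - lam)[:, None] + b[None, :] * lam[:, None])
    return np.asarray(out)


def _as_samples(x, step: float) -> np.ndarray:
    if isinstance(x, PlanarRegion):
        if x.is_empty:
            return np.zeros((0, 2))
        return np.vstack([_resample_curve(b, step, closed=True) for b in x.boundary])
    arr = np.atleast_2d(np.asarray(x, float))
    if arr.size == 0:
        return np.zeros((0, 2))
    return _resample_curve(arr, step, closed=len(arr) >= 3)


def hausdorff(X, Y, sample_step: float = 0.1) -> float:
    """Symmetric Hausdorff distance between two curves, in mm.

    Inputs are point arrays, polylines or PlanarRegions; curves are densely
    resampled at ``sample_step`` before the sup-inf distances are taken.
    Returns +inf iff exactly one input is empty, 0 when both are.
    """
    sx = _as_samples(X, sample_step)
    sy = _as_samples(Y, sample_step)
    if len(sx) == 0 and len(sy) == 0:
        return 0.0
    if len(sx) == 0 or len(sy) == 0:
        return INF
    d_xy = cKDTree(sy).query(sx)[0].max()
    d_yx = cKDTree(sx).query(sy)[0].max()
    return float(max(d_xy, d_yx))


def _check_same_plane(a: PlanarRegion, b: PlanarRegion) -> None:
    pa, pb = a.plane, b.plane
    if (np.abs(pa.normal - pb.normal).max() > 1e-6
            or abs(float((pa.position - pb.position) @ pa.normal)) > 1e-6):
        raise PlaneMismatchError("regions lie on different imaging planes")


def _overlap_areas(re: PlanarRegion, tr: PlanarRegion) -> tuple[float, float, float]:
    _check_same_plane(re, tr)
    A = re.to_shapely()
    B = tr.to_shapely()
    return float(A.intersection(B).area), float(A.area), float(B.area)


def dice(re: PlanarRegion, tr: PlanarRegion) -> float:
    """Dice overlap 2|Re ∩ Tr| / (|Re| + |Tr|); 0 when either region is empty."""
    inter, a, b = _overlap_areas(re, tr)
    return 0.0 if a + b == 0 else 2.0 * inter / (a + b)


def jaccard(re: PlanarRegion, tr: PlanarRegion) -> float:
    """Jaccard overlap |Re ∩ Tr| / |Re ∪ Tr|; 0 when either region is empty."""
    inter, a, b = _overlap_areas(re, tr)
    union = a + b - inter
    return 0.0 if union == 0 else inter / union


# ---------------------------------------------------------------------------
# full validation
# ---------------------------------------------------------------------------

def truth_region(record: SliceRecord, label: str = "LV") -> PlanarRegion | None:
    """Region bounded by the labeled contour of a long-axis record (mm coords)."""
    cont = record.contour(label)
    if cont is None:
        return None
    return PlanarRegion(record.plane, [record.plane.to_plane_mm(cont.points)])


def validate(surface: SurfaceMesh, lax_records: list[SliceRecord],
             sample_step: float = 0.1) -> ValidationReport:
    """Score a reconstruction against the LV contours of the long-axis views.

    For each of 2CH/3CH/4CH the surface cross-section is compared with the
    region bounded by that view's LV contour; a view whose plane misses the
    surface scores (inf, 0, 0); a missing view is reported as absent.
    """
    by_view = {r.view: r for r in lax_records if r.view in LA_VIEWS}
    per_view: dict[str, ViewScores | None] = {}
    for view in LA_VIEWS:
        rec = by_view.get(view)
        tr = truth_region(rec) if rec is not None else None
        if tr is None:
            per_view[view] = None
            continue
        re = intersect_mesh_plane(surface, rec.plane)
        if re.is_empty:
            per_view[view] = ViewScores(INF, 0.0, 0.0)
            continue
        per_view[view] = ViewScores(hausdorff(re, tr, sample_step),
                                    dice(re, tr), jaccard(re, tr))
    return ValidationReport(per_view)
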