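"""Core geometry: imaging planes, contours, rigid transforms, valentine pose.

Cine CMR slices are acquired in separate breath-holds; each slice carries its
own imaging-plane geometry (the DICOM Image Position/Orientation/Pixel Spacing
triple).  This module holds the in-memory types shared by the whole pipeline
and the coordinate machinery: the affine pixel-to-patient mapping, the rigid
transform group used for per-slice motion correction, and the "valentine"
normalization that stands the left ventricle on its apex with the atrium above.

Conventions: all lengths are millimeters, all angles radians.  Pixel indices
are 0-based and refer to pixel centers (DICOM PS3.3); (0, 0) is the center of
the first transmitted pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateAxisError, InvalidPlaneError

__all__ = [
    "ImagePlane",
    "Contour2D",
    "SliceRecord",
    "PointCloud3D",
    "RigidTransform",
    "pixel_to_patient",
    "project_record",
    "to_valentine",
    "valentine_transform",
    "best_fit_rigid",
    "SA",
    "LA_VIEWS",
]

SA = "SA"
LA_VIEWS = ("2CH", "3CH", "4CH")

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class ImagePlane:
    """Geometry of one imaging plane in patient coordinates.

    ``position`` is the patient-coordinate location of the center of the
    first transmitted pixel; ``row_dir``/``col_dir`` are the unit direction
    cosines of increasing column index (u) and row index (v) respectively;
    ``spacing`` is (du, dv) in mm/pixel.
    """

    position: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        for name in ("position", "row_dir", "col_dir", "spacing"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.position.shape != (3,) or self.row_dir.shape != (3,) or self.col_dir.shape != (3,):
            raise InvalidPlaneError("position/row_dir/col_dir must be 3-vectors")
        if self.spacing.shape != (2,):
            raise InvalidPlaneError("spacing must be a 2-vector (du, dv)")
        if abs(np.linalg.norm(self.row_dir) - 1.0) > _UNIT_TOL:
            raise InvalidPlaneError("row_dir is not a unit vector")
        if abs(np.linalg.norm(self.col_dir) - 1.0) > _UNIT_TOL:
            raise InvalidPlaneError("col_dir is not a unit vector")
        if abs(float(self.row_dir @ self.col_dir)) > _UNIT_TOL:
            raise InvalidPlaneError("row_dir and col_dir are not orthogonal")
        if np.any(self.spacing <= 0):
            raise InvalidPlaneError("pixel spacing must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal row_dir x col_dir."""
        n = np.cross(self.row_dir, self.col_dir)
        return n / np.linalg.norm(n)

    def to_patient(self, points_px: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel coordinates (u, v) to (n, 3) patient mm."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        u = pts[:, 0:1] * self.spacing[0]
        v = pts[:, 1:2] * self.spacing[1]
        return self.position[None, :] + u * self.row_dir[None, :] + v * self.col_dir[None, :]

    def to_plane_mm(self, points_px: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel coordinates to in-plane mm coordinates (u*du, v*dv)."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        return pts * self.spacing[None, :]

    def project_to_plane_mm(self, points_xyz: np.ndarray) -> np.ndarray:
        """Express 3-D patient points in the plane's in-plane mm coordinates."""
        d = np.atleast_2d(np.asarray(points_xyz, dtype=float)) - self.position[None, :]
        return np.stack([d @ self.row_dir, d @ self.col_dir], axis=1)


@dataclass(frozen=True)
class Contour2D:
    """An ordered delineated polyline in pixel coordinates.

    ``label`` names the delineated structure: LV (left ventricle),
    LA (left atrium) or AO (aorta).
    """

    points: np.ndarray
    label: str
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("contour points must be a non-empty (n, 2) array")
        object.__setattr__(self, "points", pts)
        if self.label not in ("LV", "LA", "AO"):
            raise ValueError(f"unknown contour label {self.label!r}")
        if self.closed and pts.shape[0] < 3:
            raise ValueError("a closed contour needs at least 3 points")
        seg = np.diff(pts, axis=0)
        if seg.size and np.any(np.all(np.abs(seg) < 1e-12, axis=1)):
            raise ValueError("contour has identical consecutive points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SliceRecord:
    """One imaging slice: its view, plane geometry and delineated contours."""

    view: str
    slice_index: int
    plane: ImagePlane
    contours: tuple[Contour2D, ...]

    def __post_init__(self):
        if self.view not in (SA,) + LA_VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        object.__setattr__(self, "contours", tuple(self.contours))

    def contour(self, label: str) -> Contour2D | None:
        for c in self.contours:
            if c.label == label:
                return c
        return None

    def with_plane(self, plane: ImagePlane) -> "SliceRecord":
        return SliceRecord(self.view, self.slice_index, plane, self.contours)

    @property
    def key(self) -> tuple[str, int]:
        return (self.view, self.slice_index)


@dataclass
class PointCloud3D:
    """Patient-coordinate point cloud with per-point provenance.

    ``source`` holds one (view, slice_index, label) tuple per point.
    """

    points: np.ndarray
    source: list[tuple[str, int, str]]

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        self.source = list(self.source)
        if len(self.source) != self.points.shape[0]:
            raise ValueError("source must have one entry per point")

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, label: str | None = None, view: str | None = None) -> "PointCloud3D":
        mask = np.ones(len(self), dtype=bool)
        for i, (v, _, lab) in enumerate(self.source):
            if label is not None and lab != label:
                mask[i] = False
            if view is not None and v != view:
                mask[i] = False
        return PointCloud3D(self.points[mask], [s for s, m in zip(self.source, mask) if m])

    @staticmethod
    def concatenate(clouds: Sequence["PointCloud3D"]) -> "PointCloud3D":
        clouds = [c for c in clouds if len(c)]
        if not clouds:
            return PointCloud3D(np.zeros((0, 3)), [])
        pts = np.vstack([c.points for c in clouds])
        src = [s for c in clouds for s in c.source]
        return PointCloud3D(pts, src)


class RigidTransform:
    """Proper rigid motion x -> R x + t of patient space.

    The rotation is checked to be orthonormal with determinant +1 to 1e-9;
    composition and inversion stay inside the group.
    """

    __slots__ = ("rotation", "translation")

    _TOL = 1e-9

    def __init__(self, rotation: np.ndarray, translation: np.ndarray):
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-7 or abs(np.linalg.det(R) - 1.0) > 1e-7:
            raise ValueError("rotation must be orthonormal with determinant +1")
        # project to the nearest rotation so long composition chains cannot drift
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:  # pragma: no cover - unreachable after check above
            raise ValueError("improper rotation")
        self.rotation = R
        self.translation = t

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix(), translation)

    @classmethod
    def about_point(cls, rotation: np.ndarray, center, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation about ``center`` followed by ``translation``."""
        R = np.asarray(rotation, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float)
        return cls(R, c - R @ c + t)

    # -- group operations -----------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, x):
        """Apply to an (n, 3) array, a PointCloud3D, an ImagePlane or a SliceRecord."""
        if isinstance(x, PointCloud3D):
            return PointCloud3D(self.apply(x.points), list(x.source))
        if isinstance(x, ImagePlane):
            return ImagePlane(self.rotation @ x.position + self.translation,
                              self.rotation @ x.row_dir,
                              self.rotation @ x.col_dir,
                              x.spacing)
        if isinstance(x, SliceRecord):
            return x.with_plane(self.apply(x.plane))
        pts = np.asarray(x, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation[None, :]
        return out[0] if single else out

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.abs(self.rotation - np.eye(3)).max() < tol
                and np.abs(self.translation).max() < tol)

    def __repr__(self) -> str:
        from scipy.spatial.transform import Rotation

        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        return (f"RigidTransform(rotvec={np.round(rv, 6).tolist()}, "
                f"t={np.round(self.translation, 6).tolist()})")


# ---------------------------------------------------------------------------
# pixel -> patient projection
# ---------------------------------------------------------------------------

def pixel_to_patient(contour: Contour2D, plane: ImagePlane,
                     view: str = SA, slice_index: int = 0) -> PointCloud3D:
    """Project a 2-D pixel-coordinate contour into patient coordinates.

    Each pixel point (u, v) maps to ``P + u*du*U + v*dv*V`` where P is the
    plane position, U/V its direction cosines and (du, dv) the pixel spacing.
    Point order is preserved.
    """
    pts = plane.to_patient(contour.points)
    src = [(view, slice_index, contour.label)] * len(contour)
    return PointCloud3D(pts, src)


def project_record(record: SliceRecord) -> PointCloud3D:
    """Project all contours of a slice into one labeled patient-space cloud."""
    clouds = [pixel_to_patient(c, record.plane, record.view, record.slice_index)
              for c in record.contours]
    return PointCloud3D.concatenate(clouds)


# ---------------------------------------------------------------------------
# valentine-position normalization
# ---------------------------------------------------------------------------

def _polygon_area_3d(points: np.ndarray) -> float:
    """Area of an ordered (roughly planar) closed 3-D polygon."""
    c = points.mean(axis=0)
    a = points - c
    b = np.roll(points, -1, axis=0) - c
    return 0.5 * np.linalg.norm(np.cross(a, b).sum(axis=0))


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation

        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def valentine_transform(clouds: Iterable[PointCloud3D]) -> RigidTransform:
    """Rigid transform standing the LV on its apex with the long axis on +z.

    The LV long axis is the least-squares line through the per-slice centroids
    of the short-axis LV contours; the apex is identified as the SA slice of
    smallest LV contour area and mapped to lower z than the base.  The
    remaining rotation about z is fixed by mapping the 4-chamber plane normal
    (estimated from the 4CH points when present) toward +y.  The centroid of
    the SA LV centroids goes to the origin.
    """
    clouds = list(clouds)
    per_slice: dict[int, list[np.ndarray]] = {}
    for cl in clouds:
        for p, (v, si, lab) in zip(cl.points, cl.source):
            if v == SA and lab == "LV":
                per_slice.setdefault(si, []).append(p)
    if len(per_slice) < 2:
        raise DegenerateAxisError(
            f"need LV contours on >= 2 SA slices to fit a long axis, got {len(per_slice)}")

    indices = sorted(per_slice)
    slice_pts = {i: np.asarray(per_slice[i]) for i in indices}
    centroids = np.array([slice_pts[i].mean(axis=0) for i in indices])
    areas = np.array([_polygon_area_3d(slice_pts[i]) for i in indices])

    # least-squares line through the centroids: principal direction
    c0 = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - c0)
    axis = vt[0]
    apex_c = centroids[int(np.argmin(areas))]
    # orient apex -> base
    if float(axis @ (c0 - apex_c)) < 0:
        axis = -axis
    R1 = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))

    # fix the axial (about-z) rotation with the 4CH plane normal -> +y
    R2 = np.eye(3)
    pts4 = [p for cl in clouds for p, (v, _, _) in zip(cl.points, cl.source) if v == "4CH"]
    if len(pts4) >= 3:
        pts4 = np.asarray(pts4)
        _, _, vt4 = np.linalg.svd(pts4 - pts4.mean(axis=0))
        n4 = R1 @ vt4[2]  # smallest principal direction = plane normal
        nxy = np.array([n4[0], n4[1], 0.0])
        if np.linalg.norm(nxy) > 1e-9:
            nxy /= np.linalg.norm(nxy)
            ang = np.arctan2(nxy[0], nxy[1])  # rotate nxy onto +y
            ca, sa_ = np.cos(ang), np.sin(ang)
            R2 = np.array([[ca, -sa_, 0.0], [sa_, ca, 0.0], [0.0, 0.0, 1.0]])
    R = R2 @ R1
    return RigidTransform(R, -R @ c0)


def to_valentine(clouds: Iterable[PointCloud3D]) -> tuple[list[PointCloud3D], RigidTransform]:
    """Apply one global valentine normalization to all clouds; return it too."""
    clouds = list(clouds)
    T = valentine_transform(clouds)
    return [T.apply(c) for c in clouds], T


# ---------------------------------------------------------------------------
# best-fit rigid alignment (Kabsch)
# ---------------------------------------------------------------------------

def best_fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping corresponded source -> target.

    Standard Kabsch/Procrustes solution via SVD of the cross-covariance;
    used to remove the global gauge freedom when comparing realigned
    configurations with ground truth.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) point arrays")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    H = (X - cx).T @ (Y - cy)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cy - R @ cx)
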