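"""Synthetic left-heart phantom and breath-hold misalignment simulator.

The phantom emulates the geometry of a clinical cine CMR study of the left
heart: a truncated ellipsoidal LV (apex down) joined at the base cut to a
spherical-cap left atrium and a cylindrical aortic stub, sliced by a parallel
stack of short-axis planes at fixed spacing plus three long-axis planes
(2-/3-/4-chamber) through the LV long axis.  Contours are exact analytic
plane-surface intersections, so every downstream stage can be validated
against known ground truth.

The misalignment simulator applies an independent random rigid motion to each
slice - the geometric effect of inconsistent breath-hold positions - plus
isotropic Gaussian delineation noise on the contour points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyPhantomError
from .geometry import (SA, LA_VIEWS, Contour2D, ImagePlane, RigidTransform,
                       SliceRecord, project_record)
from .mesh import SurfaceMesh

__all__ = ["PhantomSpec", "PerturbationSpec", "make_phantom", "perturb"]

# pixel-grid center of the emulated acquisition matrix (192 x 150 image)
_U0, _V0 = 96.0, 75.0
# azimuths (rad) of the three long-axis planes about the LV long axis
_LA_AZIMUTHS = {"2CH": 0.0, "3CH": math.radians(60.0), "4CH": math.radians(120.0)}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic left heart and its emulated acquisition.

    Defaults mirror a routine clinical short-axis protocol: 13 SA slices at
    8 mm spacing with 1.77 mm isotropic pixels, an LV of semi-axes
    25 x 25 x 45 mm truncated at 75% of its long axis, an 18 mm atrial
    chamber and a 12 mm aortic stub.
    """

    lv_semi_axes: tuple[float, float, float] = (25.0, 25.0, 45.0)
    lv_truncation_fraction: float = 0.75
    la_radius: float = 18.0
    ao_radius: float = 12.0
    n_sa_slices: int = 13
    sa_spacing: float = 8.0
    pixel_spacing: float = 1.77
    points_per_contour: int = 60
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.lv_semi_axes) or min(
                self.la_radius, self.ao_radius, self.sa_spacing,
                self.pixel_spacing) <= 0:
            raise ValueError("all phantom lengths must be positive")
        if not (0.0 < self.lv_truncation_fraction <= 1.0):
            raise ValueError("lv_truncation_fraction must be in (0, 1]")
        if self.n_sa_slices < 4:
            raise ValueError("need at least 4 short-axis slices")
        if self.points_per_contour < 8:
            raise ValueError("points_per_contour must be >= 8")

    # -- derived layout -------------------------------------------------
    @property
    def base_cut_z(self) -> float:
        """z of the basal truncation plane (apex at z = -c)."""
        c = self.lv_semi_axes[2]
        return c * (2.0 * self.lv_truncation_fraction - 1.0)

    @property
    def la_center(self) -> np.ndarray:
        """Center of the atrial sphere; sits above the base cut, offset laterally."""
        return np.array([-(self.la_radius - 4.0), 0.0,
                         self.base_cut_z + 2.0 * self.la_radius / 3.0])

    @property
    def ao_axis_x(self) -> float:
        return self.ao_radius + 6.0

    @property
    def ao_height(self) -> float:
        return 7.0 * self.ao_radius / 3.0

    @property
    def z_extent(self) -> tuple[float, float]:
        zmax = max(self.la_center[2] + self.la_radius,
                   self.base_cut_z + self.ao_height)
        return (-self.lv_semi_axes[2], zmax)


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-slice rigid misalignment plus delineation noise.

    ``max_translation`` bounds each translation component (uniform per axis);
    rotation axes are uniform on the sphere with angle uniform in
    [0, max_rotation].  ``noise_sigma`` is the in-plane Gaussian delineation
    noise, in mm.  Defaults are about one slice thickness of motion - the
    magnitude of real breath-hold displacement is not standardized, so these
    are tunable study conditions rather than physical constants.
    """

    max_translation: float = 8.0
    max_rotation: float = 5.0  # degrees
    in_plane_only: bool = False
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.max_translation, self.max_rotation, self.noise_sigma) < 0:
            raise ValueError("perturbation magnitudes must be non-negative")


# ---------------------------------------------------------------------------
# analytic contour sampling helpers
# ---------------------------------------------------------------------------

def _ellipse_points(center, semi_u, semi_v, n, t0=0.0, t1=2.0 * math.pi,
                    closed=True):
    """Sample an axis-aligned ellipse arc; closed=True omits the repeated endpoint."""
    t = np.linspace(t0, t1, n, endpoint=not closed)
    return np.stack([center[0] + semi_u * np.cos(t),
                     center[1] + semi_v * np.sin(t)], axis=1)


def _arc_with_chord(center, r_u, r_v, t_start, t_end, n):
    """Closed polygon: elliptical arc from t_start to t_end plus straight chord."""
    n_arc = max(4, int(round(0.85 * n)))
    n_chord = max(1, n - n_arc)
    t = np.linspace(t_start, t_end, n_arc)
    arc = np.stack([center[0] + r_u * np.cos(t),
                    center[1] + r_v * np.sin(t)], axis=1)
    a, b = arc[-1], arc[0]
    lam = np.linspace(0.0, 1.0, n_chord + 2)[1:-1, None]
    chord = a[None, :] * (1 - lam) + b[None, :] * lam
    return np.vstack([arc, chord])


def _rect_points(s_lo, s_hi, z_lo, z_hi, n):
    """Closed rectangle outline with corners included, ~n points by arc length."""
    corners = np.array([[s_lo, z_lo], [s_hi, z_lo], [s_hi, z_hi], [s_lo, z_hi]])
    lens = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
    alloc = np.maximum(1, np.round(n * lens / lens.sum()).astype(int))
    pts = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        lam = np.linspace(0.0, 1.0, alloc[i], endpoint=False)[:, None]
        pts.append(a[None, :] * (1 - lam) + b[None, :] * lam)
    return np.vstack(pts)


def _sa_plane(z: float, px: float) -> ImagePlane:
    return ImagePlane(position=(-_U0 * px, -_V0 * px, z),
                      row_dir=(1.0, 0.0, 0.0), col_dir=(0.0, 1.0, 0.0),
                      spacing=(px, px))


def _la_plane(azimuth: float, px: float) -> ImagePlane:
    u = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    v = np.array([0.0, 0.0, -1.0])
    pos = -_U0 * px * u + np.array([0.0, 0.0, _V0 * px])
    return ImagePlane(position=pos, row_dir=u, col_dir=v, spacing=(px, px))


def _xy_to_px(points_xy: np.ndarray, plane: ImagePlane) -> np.ndarray:
    """In-plane mm coordinates (along row_dir/col_dir) -> pixel coordinates."""
    return points_xy / plane.spacing[None, :]


def _sa_plane_coords(points_2d: np.ndarray, plane: ImagePlane) -> np.ndarray:
    """(x, y) patient coords in an SA plane -> pixel coordinates."""
    d = points_2d - plane.position[None, :2]
    return d / plane.spacing[None, :]


def _la_plane_coords(points_sz: np.ndarray, plane: ImagePlane) -> np.ndarray:
    """(s, z) coords (s along row_dir, z patient-z) -> pixel coordinates."""
    s0 = float(plane.position @ plane.row_dir)
    z0 = float(plane.position[2])
    u = (points_sz[:, 0] - s0) / plane.spacing[0]
    v = (z0 - points_sz[:, 1]) / plane.spacing[1]
    return np.stack([u, v], axis=1)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _sa_contours(spec: PhantomSpec, z: float) -> list[tuple[str, np.ndarray]]:
    """Analytic (x, y) contours cut by the SA plane at height z."""
    a, b, c = spec.lv_semi_axes
    zb = spec.base_cut_z
    out: list[tuple[str, np.ndarray]] = []
    n = spec.points_per_contour
    if -c < z < zb:
        f = math.sqrt(max(0.0, 1.0 - (z / c) ** 2))
        if a * f > 0.2:
            out.append(("LV", _ellipse_points((0.0, 0.0), a * f, b * f, n)))
    lc = spec.la_center
    if z >= zb and abs(z - lc[2]) < spec.la_radius:
        r = math.sqrt(spec.la_radius ** 2 - (z - lc[2]) ** 2)
        if r > 0.2:
            out.append(("LA", _ellipse_points((lc[0], lc[1]), r, r, n)))
    if zb <= z <= zb + spec.ao_height:
        out.append(("AO", _ellipse_points((spec.ao_axis_x, 0.0),
                                          spec.ao_radius, spec.ao_radius, n)))
    return out


def _la_contours(spec: PhantomSpec, azimuth: float) -> list[tuple[str, np.ndarray]]:
    """Analytic (s, z) contours cut by the LA plane at the given azimuth."""
    a, b, c = spec.lv_semi_axes
    zb = spec.base_cut_z
    n = spec.points_per_contour
    out: list[tuple[str, np.ndarray]] = []

    # LV: plane through the z axis cuts the ellipsoid in an ellipse of
    # semi-axes (A, c) with 1/A^2 = cos^2/a^2 + sin^2/b^2; truncate z <= zb.
    A = 1.0 / math.sqrt(math.cos(azimuth) ** 2 / a ** 2
                        + math.sin(azimuth) ** 2 / b ** 2)
    t_b = math.asin(zb / c)
    out.append(("LV", _arc_with_chord((0.0, 0.0), A, c,
                                      math.pi - t_b, 2.0 * math.pi + t_b, n)))

    # LA: sphere clipped to z >= zb
    lc = spec.la_center
    h = abs(lc[0] * math.sin(azimuth))  # distance of sphere center to plane
    if h < spec.la_radius:
        r = math.sqrt(spec.la_radius ** 2 - h ** 2)
        s_c = lc[0] * math.cos(azimuth)
        if lc[2] - r >= zb:
            out.append(("LA", _ellipse_points((s_c, lc[2]), r, r, n)))
        else:
            q = (zb - lc[2]) / r
            t1 = math.asin(max(-1.0, min(1.0, q)))
            out.append(("LA", _arc_with_chord((s_c, lc[2]), r, r,
                                              t1, math.pi - t1, n)))

    # AO: vertical cylinder; the plane hits it iff |x_axis sin(az)| < radius
    disc = spec.ao_radius ** 2 - (spec.ao_axis_x * math.sin(azimuth)) ** 2
    if disc > 1.0:  # ignore grazing intersections thinner than 2 mm
        m = spec.ao_axis_x * math.cos(azimuth)
        half = math.sqrt(disc)
        out.append(("AO", _rect_points(m - half, m + half, zb,
                                       zb + spec.ao_height, n)))
    return out


def _truth_mesh(spec: PhantomSpec, n_theta: int = 48, n_phi: int = 96) -> SurfaceMesh:
    """Triangulated truncated-ellipsoid LV with a flat basal cap, apex down."""
    a, b, c = spec.lv_semi_axes
    zb = spec.base_cut_z
    psi_max = math.acos(-zb / c)
    psis = np.linspace(0.0, psi_max, n_theta + 1)[1:]
    phis = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)

    verts = [np.array([0.0, 0.0, -c])]  # apex
    for psi in psis:
        z = -c * math.cos(psi)
        verts.extend(np.stack([a * math.sin(psi) * np.cos(phis),
                               b * math.sin(psi) * np.sin(phis),
                               np.full(n_phi, z)], axis=1))
    verts.append(np.array([0.0, 0.0, zb]))  # basal cap center
    V = np.vstack(verts)
    apex, cap = 0, len(V) - 1

    def ring(i):  # vertex index of ring i (0-based), azimuth j
        return 1 + i * n_phi

    tris = []
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        tris.append([apex, ring(0) + j, ring(0) + jn])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            v00, v01 = ring(i) + j, ring(i) + jn
            v10, v11 = ring(i + 1) + j, ring(i + 1) + jn
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    top = n_theta - 1
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        tris.append([cap, ring(top) + jn, ring(top) + j])
    mesh = SurfaceMesh(V, np.asarray(tris))
    if mesh.volume() < 0:  # orient outward
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    return mesh


def make_phantom(spec: PhantomSpec | None = None) -> tuple[SurfaceMesh, list[SliceRecord]]:
    """Build the analytic phantom: ground-truth LV surface plus true contours.

    Returns the triangulated LV endocardial surface (truncated ellipsoid with
    basal cap) and one SliceRecord per SA slice (indexed 1..L from base to
    apex) plus one per long-axis view, with contours labeled LV/LA/AO by the
    component each plane cuts.

    Raises EmptyPhantomError when the SA stack extends beyond the structure
    so that some slice would carry no contour.
    """
    spec = spec or PhantomSpec()
    px = spec.pixel_spacing
    zmin, zmax = spec.z_extent
    span = (spec.n_sa_slices - 1) * spec.sa_spacing
    z_top = (zmin + zmax) / 2.0 + span / 2.0

    records: list[SliceRecord] = []
    for i in range(spec.n_sa_slices):
        z = z_top - i * spec.sa_spacing
        plane = _sa_plane(z, px)
        named = _sa_contours(spec, z)
        if not named:
            raise EmptyPhantomError(
                f"SA slice {i + 1} at z={z:.2f} mm cuts no structure; "
                f"reduce n_sa_slices or sa_spacing")
        contours = tuple(Contour2D(_sa_plane_coords(pts, plane), label, closed=True)
                         for label, pts in named)
        records.append(SliceRecord(SA, i + 1, plane, contours))

    for view in LA_VIEWS:
        az = _LA_AZIMUTHS[view]
        plane = _la_plane(az, px)
        contours = tuple(Contour2D(_la_plane_coords(pts, plane), label, closed=True)
                         for label, pts in _la_contours(spec, az))
        records.append(SliceRecord(view, 0, plane, contours))

    return _truth_mesh(spec), records


# ---------------------------------------------------------------------------
# misalignment simulation
# ---------------------------------------------------------------------------

def perturb(records: list[SliceRecord], pspec: PerturbationSpec | None = None,
            ) -> tuple[list[SliceRecord], dict[tuple[str, int], RigidTransform]]:
    """Apply an independent random rigid motion plus contour noise per slice.

    Sampling scheme (documented so it can be re-implemented independently):
    one ``numpy.random.default_rng(seed)`` generator; slices processed in the
    order given.  Per slice, in this order:

    1. rotation axis: 3 standard normals, normalized;
    2. rotation angle: uniform on [0, max_rotation] (degrees -> radians);
    3. translation: 3 components uniform on [-max_translation, max_translation];
    4. per contour, per point: 2 standard normals scaled by
       noise_sigma / pixel_spacing, added to the pixel coordinates.

    The rotation is taken about the centroid of the slice's projected contour
    points.  With ``in_plane_only`` the axis is replaced by the plane normal
    and the translation by its first two components along row_dir/col_dir.
    The returned map holds the true transform applied to each slice, for
    recovery experiments.
    """
    pspec = pspec or PerturbationSpec()
    rng = np.random.default_rng(pspec.seed)
    max_rot = math.radians(pspec.max_rotation)
    out: list[SliceRecord] = []
    truth: dict[tuple[str, int], RigidTransform] = {}

    from scipy.spatial.transform import Rotation

    for rec in records:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_rot)
        trans = rng.uniform(-pspec.max_translation, pspec.max_translation, size=3)
        if pspec.in_plane_only:
            axis = rec.plane.normal
            trans = trans[0] * rec.plane.row_dir + trans[1] * rec.plane.col_dir
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        center = project_record(rec).points.mean(axis=0)
        T = RigidTransform.about_point(R, center, trans)
        truth[rec.key] = T

        moved = T.apply(rec)
        noisy = []
        for cont in moved.contours:
            dpx = rng.normal(size=cont.points.shape) * (
                pspec.noise_sigma / rec.plane.spacing[None, :])
            noisy.append(Contour2D(cont.points + dpx, cont.label, cont.closed))
        out.append(SliceRecord(moved.view, moved.slice_index, moved.plane,
                               tuple(noisy)))
    return out, truth
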