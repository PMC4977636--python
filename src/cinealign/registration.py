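"""Registration: generalized ICP and the iterative two-step slice realignment.

Two registration problems live here.

``gicp`` registers one free-form point cloud onto another: delineated points
are modeled as Gaussian samples around the true boundary curve, and the
rigid transform minimizes the summed Mahalanobis distance

    sum_i d_i^T (C_i^target + R C_i^source R^T)^{-1} d_i,

with nearest-neighbor correspondences re-estimated every iteration and pairs
beyond a gating distance discarded.  Contours are curves, so the per-point
covariance is tangent-based, eps*I + (1-eps)*t t^T: residual components
along the delineated curve are cheap (the sampling of a curve is arbitrary),
components across it are expensive.

``realign`` corrects breath-hold slice misalignment.  Two contours drawn on
different imaging planes can only genuinely coincide near the intersection
line of those planes, so the correspondences that carry information are the
crossings: the points where contour i crosses plane j, matched against the
points where the like-labeled contours of slice j cross plane i.  Each
round matches short-axis slices against the long-axis views and the
long-axis views against each other (short-axis planes are parallel and
never intersect one another), then moves every slice at once by solving one
regularized least-squares problem in all per-slice corrections under the
same Mahalanobis weighting as ``gicp``.  Rounds anneal: wide matching gates
and a permissive robust threshold first, then tighter; translation-only
rounds before full rigid ones.  A weak prior toward each slice's acquired
position keeps directions the contour geometry cannot observe (e.g.
out-of-plane shifts of a slice through the widest part of the ventricle)
from wandering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientPointsError, RegistrationFailedError
from .geometry import (SA, LA_VIEWS, PointCloud3D, RigidTransform, SliceRecord,
                       project_record)

__all__ = ["GicpParams", "RealignParams", "RealignResult",
           "estimate_point_covariances", "gicp", "realign"]


@dataclass(frozen=True)
class GicpParams:
    """Parameters shared by pairwise GICP and the realignment matcher."""

    k_neighbors: int = 8
    covariance_epsilon: float = 0.01
    max_correspondence_distance: float = 20.0  # mm
    max_inner_iterations: int = 50
    inner_tolerance: float = 1e-4  # mm, mean point displacement per iteration

    def __post_init__(self):
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be >= 3")
        if min(self.covariance_epsilon, self.max_correspondence_distance,
               self.inner_tolerance) <= 0 or self.max_inner_iterations < 1:
            raise ValueError("tolerances and iteration caps must be positive")


@dataclass(frozen=True)
class RealignParams:
    """Parameters of the outer realignment loop.

    ``position_prior`` anchors each slice to its acquired position along
    directions the crossings cannot observe; ``rotation_prior`` plays the
    same role for per-slice rotations.
    """

    max_outer_iterations: int = 20
    outer_tolerance: float = 0.05  # mm, mean point displacement per round
    gicp: GicpParams = field(default_factory=GicpParams)
    translation_rounds: int = 12
    rigid_rounds: int = 8
    position_prior: float = 0.3
    rotation_prior: float = 2e3
    anneal: float = 0.8

    def __post_init__(self):
        if self.max_outer_iterations < 1 or self.outer_tolerance <= 0:
            raise ValueError("positive fields required")
        if not (0.0 < self.anneal < 1.0):
            raise ValueError("anneal must be in (0, 1)")


@dataclass
class RealignResult:
    """Outcome of the iterative realignment."""

    realigned: list[SliceRecord]
    transforms: dict[tuple[str, int], RigidTransform]
    outer_iterations_used: int
    displacement_history: list[float]


# ---------------------------------------------------------------------------
# per-point covariance estimation
# ---------------------------------------------------------------------------

def estimate_point_covariances(cloud: PointCloud3D | np.ndarray,
                               params: GicpParams | None = None) -> np.ndarray:
    """Tangent-based covariance eps*I + (1-eps)*t t^T for every point.

    The tangent t is the principal axis of the point's k nearest neighbors
    (itself included); the result is symmetric PSD with eigenvalues
    {1, eps, eps}: unit variance along the contour, eps across it.
    """
    params = params or GicpParams()
    pts = cloud.points if isinstance(cloud, PointCloud3D) else np.asarray(cloud, float)
    n = len(pts)
    if n < params.k_neighbors + 1:
        raise InsufficientPointsError(
            f"{n} points < k_neighbors + 1 = {params.k_neighbors + 1}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=params.k_neighbors + 1)
    nb = pts[idx]
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb)
    _, v = np.linalg.eigh(cov)
    t = v[:, :, 2]  # largest eigenvalue last
    eps = params.covariance_epsilon
    return eps * np.eye(3)[None, :, :] + (1.0 - eps) * np.einsum("ni,nj->nij", t, t)


# ---------------------------------------------------------------------------
# pairwise generalized ICP
# ---------------------------------------------------------------------------

def _skew(p: np.ndarray) -> np.ndarray:
    out = np.zeros(p.shape[:-1] + (3, 3))
    out[..., 0, 1] = -p[..., 2]
    out[..., 0, 2] = p[..., 1]
    out[..., 1, 0] = p[..., 2]
    out[..., 1, 2] = -p[..., 0]
    out[..., 2, 0] = -p[..., 1]
    out[..., 2, 1] = p[..., 0]
    return out


def gicp(source: PointCloud3D, target: PointCloud3D,
         init: RigidTransform | None = None,
         params: GicpParams | None = None,
         return_history: bool = False):
    """Register source onto target; returns the source -> target rigid transform.

    Iterates nearest-neighbor correspondence (pairs beyond the gating
    distance discarded) with one Gauss-Newton step on the Mahalanobis
    objective per iteration, until the mean point displacement falls below
    ``inner_tolerance``.  ``return_history`` additionally yields the
    objective value per iteration.
    """
    from scipy.spatial.transform import Rotation

    params = params or GicpParams()
    T = init or RigidTransform.identity()
    if len(source) == 0 or len(target) == 0:
        raise RegistrationFailedError("empty point cloud")
    src = np.asarray(source.points, float)
    tgt = np.asarray(target.points, float)
    src_cov = estimate_point_covariances(src, params)
    tgt_cov = estimate_point_covariances(tgt, params)
    tree = cKDTree(tgt)

    history: list[float] = []
    prev = T.apply(src)
    for _ in range(params.max_inner_iterations):
        cur = T.apply(src)
        dist, j = tree.query(cur)
        keep = dist <= params.max_correspondence_distance
        if not np.any(keep):
            raise RegistrationFailedError(
                f"no correspondences within {params.max_correspondence_distance} mm gate")
        p = cur[keep]
        y = tgt[j[keep]]
        R = T.rotation
        M = tgt_cov[j[keep]] + np.einsum("ij,njk,lk->nil", R, src_cov[keep], R)
        W = np.linalg.inv(M)
        r = y - p
        history.append(float(np.einsum("ni,nij,nj->", r, W, r)))

        c = p.mean(axis=0)  # rotate about the correspondence centroid
        A = np.concatenate([-_skew(p - c), np.broadcast_to(np.eye(3), (len(p), 3, 3))],
                           axis=2)
        H = np.einsum("nai,nab,nbj->ij", A, W, A)
        g = np.einsum("nai,nab,nb->i", A, W, r)
        delta = np.linalg.solve(H + 1e-9 * np.eye(6), g)
        dR = Rotation.from_rotvec(delta[:3]).as_matrix()
        T = RigidTransform.about_point(dR, c, delta[3:]).compose(T)

        moved = T.apply(src)
        step = float(np.linalg.norm(moved - prev, axis=1).mean())
        prev = moved
        if step < params.inner_tolerance:
            break
    return (T, history) if return_history else T


# ---------------------------------------------------------------------------
# slice realignment
# ---------------------------------------------------------------------------

class _SliceState:
    """Mutable pose state of one slice during realignment."""

    __slots__ = ("key", "contours", "plane_point", "plane_normal", "points",
                 "initial_centroid", "cumulative")

    def __init__(self, record: SliceRecord):
        self.key = record.key
        self.contours = [(c.label, c.closed, record.plane.to_patient(c.points))
                         for c in record.contours]
        self.plane_point = record.plane.position.copy()
        self.plane_normal = record.plane.normal
        self.points = project_record(record).points
        self.initial_centroid = self.points.mean(axis=0)
        self.cumulative = RigidTransform.identity()

    def move(self, T: RigidTransform) -> None:
        self.contours = [(lab, cl, T.apply(p)) for lab, cl, p in self.contours]
        self.plane_point = T.apply(self.plane_point)
        self.plane_normal = T.rotation @ self.plane_normal
        self.points = T.apply(self.points)
        self.cumulative = T.compose(self.cumulative)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _crossings(poly: np.ndarray, closed: bool, plane_point: np.ndarray,
               plane_normal: np.ndarray, near_tol: float = 6.0,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Exact crossing points (and local tangents) of a polyline with a plane.

    When the polyline misses the plane but approaches within ``near_tol``,
    its closest vertex is returned as a pseudo-crossing so end slices near
    the caps of a structure still participate.
    """
    P = np.vstack([poly, poly[:1]]) if closed else poly
    s = (P - plane_point) @ plane_normal
    pts, tans = [], []
    for a in range(len(P) - 1):
        sa, sb = s[a], s[a + 1]
        if (sa < 0 <= sb) or (sb < 0 <= sa):
            t = sa / (sa - sb)
            x = P[a] * (1 - t) + P[a + 1] * t
            tan = P[a + 1] - P[a]
            norm = np.linalg.norm(tan)
            if norm > 0:
                pts.append(x)
                tans.append(tan / norm)
    if not pts and near_tol is not None:
        a = int(np.argmin(np.abs(s[:len(poly)])))
        if abs(s[a]) <= near_tol:
            tan = P[(a + 1) % len(poly)] - P[a - 1]
            norm = np.linalg.norm(tan)
            if norm > 0:
                pts.append(P[a])
                tans.append(tan / norm)
    return (np.asarray(pts).reshape(-1, 3), np.asarray(tans).reshape(-1, 3))


def _match_ordered(xs, xt, ys, yt, line_dir, gate):
    """Order-preserving matching of two crossing sets along the intersection line."""
    pairs = []
    if len(xs) == 0 or len(ys) == 0:
        return pairs
    ox = np.argsort(xs @ line_dir)
    oy = np.argsort(ys @ line_dir)
    xs, xt, ys, yt = xs[ox], xt[ox], ys[oy], yt[oy]
    nx, ny = len(xs), len(ys)
    if nx <= ny:
        costs = [np.linalg.norm(xs - ys[off:off + nx], axis=1)
                 for off in range(ny - nx + 1)]
        off = int(np.argmin([c.sum() for c in costs]))
        for a in range(nx):
            if costs[off][a] <= gate:
                pairs.append((xs[a], ys[off + a], xt[a], yt[off + a]))
    else:
        costs = [np.linalg.norm(xs[off:off + ny] - ys, axis=1)
                 for off in range(nx - ny + 1)]
        off = int(np.argmin([c.sum() for c in costs]))
        for a in range(ny):
            if costs[off][a] <= gate:
                pairs.append((xs[off + a], ys[a], xt[off + a], yt[a]))
    return pairs


def _crossing_pairs(states, sa_keys, la_keys, gate):
    """All matched crossing pairs between non-parallel slice pairs, label-aware."""
    combos = ([(ki, kj) for ki in sa_keys for kj in la_keys]
              + list(itertools.combinations(la_keys, 2)))
    out = []
    for ki, kj in combos:
        si, sj = states[ki], states[kj]
        line = np.cross(si.plane_normal, sj.plane_normal)
        norm = np.linalg.norm(line)
        if norm < 1e-6:
            continue
        line /= norm
        for lab, closed, pts in si.contours:
            xs, xt = _crossings(pts, closed, sj.plane_point, sj.plane_normal)
            if len(xs) == 0:
                continue
            ys_parts, yt_parts = [], []
            for tlab, tclosed, tpts in sj.contours:
                if tlab != lab:
                    continue
                ys, yt = _crossings(tpts, tclosed, si.plane_point, si.plane_normal)
                if len(ys):
                    ys_parts.append(ys)
                    yt_parts.append(yt)
            if not ys_parts:
                continue
            for x, y, tx, ty in _match_ordered(xs, xt, np.vstack(ys_parts),
                                               np.vstack(yt_parts), line, gate):
                out.append((ki, kj, x, y, tx, ty))
    return out


def _pair_weight(tx, ty, r, eps, huber):
    """Mahalanobis weight of one crossing pair, Huber-limited."""
    M = 2 * eps * np.eye(3) + (1 - eps) * (np.outer(tx, tx) + np.outer(ty, ty))
    W = np.linalg.inv(M)
    m = math.sqrt(max(float(r @ W @ r), 1e-12))
    return W * min(1.0, huber / m)


def _snap_to_axes(states, sa_keys) -> None:
    """Initialization: snap SA contour centroids toward robust straight-line
    fits of each label's centroid chain, in-plane only.

    The centroid chains of the delineated structures (LV cavity, atrial
    chamber, aortic root) run along nearly straight anatomical axes, so a
    slice centroid's deviation from its chain is almost entirely that
    slice's own in-plane misalignment.
    """
    chains: dict[str, list] = {}
    for k in sa_keys:
        for lab, _, pts in states[k].contours:
            chains.setdefault(lab, []).append((k, pts.mean(axis=0)))
    corrections: dict = {k: [] for k in sa_keys}
    for items in chains.values():
        if len(items) < 4:
            continue
        C = np.array([c for _, c in items])
        w = np.ones(len(C))
        for _ in range(5):  # IRLS line fit
            m = (C * w[:, None]).sum(axis=0) / w.sum()
            _, _, vt = np.linalg.svd((C - m) * np.sqrt(w)[:, None],
                                     full_matrices=False)
            d = vt[0]
            resid = np.linalg.norm(np.cross(C - m, d), axis=1)
            w = 1.0 / np.maximum(resid, 1.5)
        for k, c in items:
            delta = (m + ((c - m) @ d) * d) - c
            pn = states[k].plane_normal
            corrections[k].append(delta - (delta @ pn) * pn)
    for k in sa_keys:
        if corrections[k]:
            states[k].move(RigidTransform(np.eye(3), np.mean(corrections[k], axis=0)))


def _solve_round(states, keys, sa_keys, la_keys, params: RealignParams,
                 gate: float, huber: float, rigid: bool) -> float:
    """One matching + global least-squares round; returns mean displacement (mm)."""
    from scipy.spatial.transform import Rotation

    eps = params.gicp.covariance_epsilon
    pairs = _crossing_pairs(states, sa_keys, la_keys, gate)
    if not pairs:
        return 0.0
    idx = {k: i for i, k in enumerate(keys)}
    dof = 6 if rigid else 3
    n = len(keys)
    H = np.zeros((dof * n, dof * n))
    g = np.zeros(dof * n)
    cents = {k: states[k].centroid for k in keys}
    for ki, kj, x, y, tx, ty in pairs:
        r = y - x
        W = _pair_weight(tx, ty, r, eps, huber)
        i0, j0 = dof * idx[ki], dof * idx[kj]
        if rigid:
            Ai = np.hstack([-_skew(x - cents[ki]), np.eye(3)])
            Aj = np.hstack([-_skew(y - cents[kj]), np.eye(3)])
            H[i0:i0 + 6, i0:i0 + 6] += Ai.T @ W @ Ai
            H[j0:j0 + 6, j0:j0 + 6] += Aj.T @ W @ Aj
            H[i0:i0 + 6, j0:j0 + 6] -= Ai.T @ W @ Aj
            H[j0:j0 + 6, i0:i0 + 6] -= Aj.T @ W @ Ai
            g[i0:i0 + 6] += Ai.T @ W @ r
            g[j0:j0 + 6] -= Aj.T @ W @ r
        else:
            H[i0:i0 + 3, i0:i0 + 3] += W
            H[j0:j0 + 3, j0:j0 + 3] += W
            H[i0:i0 + 3, j0:j0 + 3] -= W
            H[j0:j0 + 3, i0:i0 + 3] -= W
            g[i0:i0 + 3] += W @ r
            g[j0:j0 + 3] -= W @ r
    lam = params.position_prior
    for k in keys:
        i0 = dof * idx[k]
        t_off = 3 if rigid else 0
        if rigid:
            H[i0:i0 + 3, i0:i0 + 3] += params.rotation_prior * np.eye(3)
        H[i0 + t_off:i0 + t_off + 3, i0 + t_off:i0 + t_off + 3] += lam * np.eye(3)
        g[i0 + t_off:i0 + t_off + 3] -= lam * (cents[k] - states[k].initial_centroid)
    xi = np.linalg.solve(H + 1e-9 * np.eye(dof * n), g)

    if rigid:
        # cap the largest per-slice motion; keeps the linearization honest
        mags = [np.linalg.norm(xi[6 * idx[k] + 3:6 * idx[k] + 6])
                + 30.0 * np.linalg.norm(xi[6 * idx[k]:6 * idx[k] + 3]) for k in keys]
        mx = max(mags)
        scale = min(1.0, 3.0 / mx) if mx > 0 else 1.0
    else:
        scale = 1.0
    disp = 0.0
    for k in keys:
        if rigid:
            d = scale * xi[6 * idx[k]:6 * idx[k] + 6]
            R = Rotation.from_rotvec(d[:3]).as_matrix()
            T = RigidTransform.about_point(R, cents[k], d[3:])
        else:
            T = RigidTransform(np.eye(3), xi[3 * idx[k]:3 * idx[k] + 3])
        before = states[k].points
        states[k].move(T)
        disp += float(np.linalg.norm(states[k].points - before, axis=1).mean())
    return disp / n


def realign(records: list[SliceRecord], params: RealignParams | None = None,
            ) -> RealignResult:
    """Correct per-slice breath-hold misalignment by crossing-consistency registration.

    After snapping each short-axis slice toward the robust straight-line fit
    of its structures' centroid chains, the solver runs annealed rounds of
    crossing matching (SA slices against LA views, LA views against each
    other) followed by one global regularized least-squares update of every
    slice's correction: translation-only rounds from a wide matching gate
    first, then full rigid rounds at tighter gates.  Rounds stop early once
    the mean contour-point displacement falls below ``outer_tolerance``.
    All labeled points of a slice move together: the slice, not the
    structure, is the motion unit.  The global pose is a gauge freedom;
    cumulative corrections are reported relative to the input configuration.
    """
    params = params or RealignParams()
    sa = sorted([r for r in records if r.view == SA], key=lambda r: r.slice_index)
    la = [r for v in LA_VIEWS for r in records if r.view == v]
    if len(sa) < 2 or len(la) < 1:
        raise ValueError("realign needs >= 2 SA slices and >= 1 LA view")
    ordered = sa + la
    states = {r.key: _SliceState(r) for r in ordered}
    sa_keys = [r.key for r in sa]
    la_keys = [r.key for r in la]
    keys = sa_keys + la_keys

    if not _crossing_pairs(states, sa_keys, la_keys,
                           params.gicp.max_correspondence_distance):
        raise RegistrationFailedError(
            "no usable slice-plane crossings between the SA stack and the LA views")

    _snap_to_axes(states, sa_keys)

    history: list[float] = []
    used = 0
    for rd in range(min(params.translation_rounds, params.max_outer_iterations)):
        used += 1
        gate = max(6.0, 20.0 * params.anneal ** rd)
        huber = max(1.5, 8.0 * params.anneal ** rd)
        disp = _solve_round(states, keys, sa_keys, la_keys, params, gate, huber,
                            rigid=False)
        history.append(disp)
        if disp < params.outer_tolerance:
            break
    for rd in range(min(params.rigid_rounds,
                        max(0, params.max_outer_iterations - used))):
        used += 1
        gate = max(4.0, 10.0 * params.anneal ** rd)
        huber = max(1.0, 4.0 * params.anneal ** rd)
        disp = _solve_round(states, keys, sa_keys, la_keys, params, gate, huber,
                            rigid=True)
        history.append(disp)
        if disp < params.outer_tolerance:
            break

    realigned = [states[r.key].cumulative.apply(r) for r in ordered]
    return RealignResult(realigned=realigned,
                         transforms={k: states[k].cumulative for k in keys},
                         outer_iterations_used=used,
                         displacement_history=history)
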