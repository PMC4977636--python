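"""LV endocardial surface reconstruction from (re)aligned contour points.

Pipeline: (1) intra-/inter-contour interpolation densifies the contour stack
into a point cloud C_inter; (2) a Delaunay tetrahedral mesh is built over the
region of interest from C_inter plus an auxiliary regular grid; (3) the
endocardial surface is the discrete minimizer of the weighted minimal-surface
energy

    E(S) = integral_S d(x, C_inter) dA,   d(x, C) = min_{y in C} |x - y|,

found as a max-flow/min-cut on the tetrahedron adjacency graph whose arc
capacities are shared-face area times the distance field at the face
centroid; (4) the cut surface is Taubin-smoothed and re-meshed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.spatial import Delaunay, cKDTree

from .errors import (DegenerateCloudError, OpenContourError, SeedConfigurationError,
                     SeedError)
from .geometry import SA, LA_VIEWS, PointCloud3D, SliceRecord
from .mesh import SurfaceMesh

__all__ = [
    "ReconstructionParams", "InterpolatedCloud", "TetMesh", "CutGraph",
    "interpolate_contours", "build_tet_mesh", "distance_field",
    "build_cut_graph", "min_cut_surface", "postprocess", "reconstruct",
]

# provenance codes for InterpolatedCloud
ORIGINAL, INTRA, INTER = 0, 1, 2


@dataclass(frozen=True)
class ReconstructionParams:
    """All knobs of the surface-reconstruction pipeline, in mm."""

    intra_step: float = 1.0          # arc-length spacing of intra-contour points
    n_inter_layers: int = 3          # interpolated contours between SA slices
    grid_step: float = 4.0           # auxiliary grid spacing
    margin: float = 10.0             # bounding-box expansion around the cloud
    exterior_band: float = 2.0       # sink-seed band at the box boundary
    smoothing_iterations: int = 10
    target_edge: float = 2.0         # isotropic re-meshing target edge (None = off)
    labels: tuple[str, ...] = ("LV",)
    include_lax: bool = True         # use long-axis contour points as evidence


@dataclass
class InterpolatedCloud:
    """Densified contour cloud; provenance flags 0=original 1=intra 2=inter."""

    points: PointCloud3D
    provenance: np.ndarray

    def __post_init__(self):
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        if len(self.provenance) != len(self.points):
            raise ValueError("provenance must have one flag per point")


@dataclass
class TetMesh:
    """Delaunay tetrahedral mesh over the region of interest."""

    vertices: np.ndarray
    tetrahedra: np.ndarray
    aux_flags: np.ndarray
    _delaunay: Delaunay | None = field(default=None, repr=False)

    def volumes(self) -> np.ndarray:
        v = self.vertices[self.tetrahedra]
        return np.einsum("ij,ij->i", v[:, 1] - v[:, 0],
                         np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])) / 6.0


@dataclass
class CutGraph:
    """Max-flow problem over tetrahedron adjacency.

    ``faces`` holds the three vertex indices of each internal shared face,
    ``arcs`` the two tetrahedra it separates, ``capacities`` the discrete
    surface-energy weight (face area x distance to the contour cloud).
    """

    n_tets: int
    arcs: np.ndarray          # (m, 2) tet indices
    faces: np.ndarray         # (m, 3) vertex indices of the shared face
    capacities: np.ndarray    # (m,)
    source_tets: np.ndarray
    sink_tets: np.ndarray


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _resample_intra(points: np.ndarray, step: float, closed: bool) -> np.ndarray:
    """Subdivide each segment into pieces no longer than ``step``.

    Original vertices are preserved exactly; with a step larger than every
    segment the contour is returned unchanged.
    """
    pts = np.asarray(points, float)
    ring = np.vstack([pts, pts[:1]]) if closed else pts
    out = []
    for a, b in zip(ring[:-1], ring[1:]):
        k = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        lam = np.arange(k)[:, None] / k
        out.append(a[None, :] * (1 - lam) + b[None, :] * lam)
    if not closed:
        out.append(ring[-1:])
    return np.vstack(out)


def _arc_sample(points: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sample a closed polygon at normalized arc-length parameters."""
    ring = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.asarray(params) * total
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    lam = (s - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return ring[idx] * (1 - lam)[:, None] + ring[idx + 1] * lam[:, None]


def _orient_and_anchor(points: np.ndarray, anchor_dir: np.ndarray) -> np.ndarray:
    """Make a closed 3-D contour CCW about +z and start it nearest anchor_dir."""
    c = points.mean(axis=0)
    d = points - c
    # signed area about +z
    area = 0.5 * np.sum(d[:, 0] * np.roll(d[:, 1], -1) - np.roll(d[:, 0], -1) * d[:, 1])
    pts = points[::-1] if area < 0 else points
    d = pts - c
    start = int(np.argmax(d[:, :2] @ anchor_dir[:2]))
    return np.roll(pts, -start, axis=0)


def interpolate_contours(records: list[SliceRecord], intra_step: float = 1.0,
                         n_inter_layers: int = 3,
                         labels: tuple[str, ...] = ("LV",),
                         include_lax: bool = True) -> InterpolatedCloud:
    """Densify the aligned contour stack into the reconstruction cloud C_inter.

    Intra: every SA contour is resampled along its arc at ``intra_step``
    spacing (original points kept).  Inter: between consecutive SA slices,
    ``n_inter_layers`` intermediate contours are formed by matching points of
    equal normalized arc length - both contours oriented CCW and anchored at
    the point nearest the 4CH-plane direction - and blending linearly.
    Long-axis contour points are included unmodified.
    """
    sa = sorted((r for r in records if r.view == SA), key=lambda r: r.slice_index)
    if not sa:
        raise ValueError("no SA slices to interpolate")

    # anchor direction: 4CH row direction when available, else +x
    anchor = np.array([1.0, 0.0, 0.0])
    for r in records:
        if r.view == "4CH":
            anchor = r.plane.row_dir
            break

    pts_out: list[np.ndarray] = []
    src_out: list[tuple[str, int, str]] = []
    prov_out: list[np.ndarray] = []

    def emit(arr: np.ndarray, src: tuple[str, int, str], code: int) -> None:
        pts_out.append(arr)
        src_out.extend([src] * len(arr))
        prov_out.append(np.full(len(arr), code, dtype=np.int8))

    lv_per_slice: list[tuple[SliceRecord, np.ndarray]] = []
    for rec in sa:
        for cont in rec.contours:
            if cont.label not in labels:
                continue
            if not cont.closed:
                raise OpenContourError(
                    f"SA slice {rec.slice_index} has an open {cont.label} contour")
            p3 = rec.plane.to_patient(cont.points)
            emit(p3, (rec.view, rec.slice_index, cont.label), ORIGINAL)
            dense = _resample_intra(p3, intra_step, closed=True)
            extra = dense[~_membership_mask(dense, p3)]
            if len(extra):
                emit(extra, (rec.view, rec.slice_index, cont.label), INTRA)
            if cont.label == "LV":
                # inter-layer blending works on the delineated vertices so
                # matched points stay on the drawn curve, not on its chords
                lv_per_slice.append((rec, p3))

    # inter-contour interpolation between consecutive SA LV contours,
    # ordered base -> apex by slice_index
    for (ra, pa), (rb, pb) in zip(lv_per_slice[:-1], lv_per_slice[1:]):
        if n_inter_layers <= 0:
            break
        A = _orient_and_anchor(pa, anchor)
        B = _orient_and_anchor(pb, anchor)
        n = max(len(A), len(B))
        params = np.arange(n) / n
        As = _arc_sample(A, params)
        Bs = _arc_sample(B, params)
        for k in range(1, n_inter_layers + 1):
            w = k / (n_inter_layers + 1)
            emit((1 - w) * As + w * Bs,
                 (SA, ra.slice_index, "LV"), INTER)

    if include_lax:
        for rec in records:
            if rec.view in LA_VIEWS:
                for cont in rec.contours:
                    if cont.label in labels:
                        emit(rec.plane.to_patient(cont.points),
                             (rec.view, rec.slice_index, cont.label), ORIGINAL)

    cloud = PointCloud3D(np.vstack(pts_out), src_out)
    return InterpolatedCloud(cloud, np.concatenate(prov_out))


def _membership_mask(dense: np.ndarray, originals: np.ndarray) -> np.ndarray:
    """Mark rows of ``dense`` that coincide with an original vertex."""
    tree = cKDTree(originals)
    d, _ = tree.query(dense)
    return d < 1e-9


# ---------------------------------------------------------------------------
# tetrahedral meshing
# ---------------------------------------------------------------------------

def build_tet_mesh(cloud: InterpolatedCloud | np.ndarray, grid_step: float = 4.0,
                   margin: float = 10.0) -> TetMesh:
    """Delaunay tetrahedralization of the cloud plus an auxiliary regular grid.

    The grid spans the cloud bounding box expanded by ``margin`` on every
    side, with spacing at most ``grid_step``; grid vertices are flagged
    auxiliary.  A grid_step larger than the expanded box suppresses the grid.
    """
    pts = cloud.points.points if isinstance(cloud, InterpolatedCloud) else np.asarray(cloud, float)
    if len(pts) < 4:
        raise DegenerateCloudError("need at least 4 points")
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    if np.all(hi - lo < grid_step):
        grid = np.zeros((0, 3))
    else:
        axes = [np.linspace(lo[d], hi[d], int(np.ceil((hi[d] - lo[d]) / grid_step)) + 1)
                for d in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        # drop grid points that duplicate cloud points
        d, _ = cKDTree(pts).query(grid)
        grid = grid[d > 1e-9]

    verts = np.vstack([pts, grid])
    aux = np.zeros(len(verts), dtype=bool)
    aux[len(pts):] = True

    # coplanarity check via singular values of the centered cloud
    sv = np.linalg.svd(verts - verts.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateCloudError("point cloud is coplanar")

    tri = Delaunay(verts)
    tets = tri.simplices.copy()
    # enforce positive orientation
    v = verts[tets]
    vol = np.einsum("ij,ij->i", v[:, 1] - v[:, 0],
                    np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]))
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return TetMesh(verts, tets, aux, _delaunay=tri)


# ---------------------------------------------------------------------------
# distance field
# ---------------------------------------------------------------------------

def distance_field(query: np.ndarray, cloud: InterpolatedCloud | PointCloud3D | np.ndarray,
                   ) -> np.ndarray:
    """Exact Euclidean distance from each query point to the nearest cloud point."""
    if isinstance(cloud, InterpolatedCloud):
        pts = cloud.points.points
    elif isinstance(cloud, PointCloud3D):
        pts = cloud.points
    else:
        pts = np.asarray(cloud, float)
    if len(pts) == 0:
        raise ValueError("empty cloud")
    d, _ = cKDTree(pts).query(np.atleast_2d(np.asarray(query, float)))
    return d


# ---------------------------------------------------------------------------
# graph construction and min cut
# ---------------------------------------------------------------------------

def build_cut_graph(mesh: TetMesh, cloud, interior_seed,
                    exterior_band: float = 2.0) -> CutGraph:
    """Discretize the minimal-surface energy as arc capacities on tet adjacency.

    Adjacent tetrahedra are linked with capacity = shared-face area (mm^2)
    times the distance field at the face centroid (mm), so that cutting a set
    of faces costs exactly the discrete surface energy.  Source seeds are all
    tetrahedra whose centroid lies within 0.9 x d(interior_seed, cloud) of
    ``interior_seed`` - a ball guaranteed to contain no contour point, which
    prevents the degenerate minimal cut that would otherwise collapse onto a
    single tetrahedron.  Every tet with a vertex within ``exterior_band`` of
    the bounding box is a sink.
    """
    seed = np.asarray(interior_seed, float).reshape(3)
    if mesh._delaunay is not None:
        s = int(mesh._delaunay.find_simplex(seed))
        if s < 0:
            raise SeedError(f"interior seed {seed.tolist()} lies outside the mesh")
        nbr = mesh._delaunay.neighbors
        simplices = mesh._delaunay.simplices
    else:  # pragma: no cover - meshes are always built through build_tet_mesh
        raise ValueError("mesh lacks Delaunay adjacency")

    m = len(simplices)
    # internal faces: (tet, neighbor) with tet < neighbor; face = simplex minus
    # the vertex opposite the neighbor (Delaunay convention: neighbors[i, k] is
    # opposite vertex k of simplex i)
    ti, k = np.nonzero(nbr >= 0)
    tj = nbr[ti, k]
    keep = ti < tj
    ti, tj, k = ti[keep], tj[keep], k[keep]
    faces = np.empty((len(ti), 3), dtype=np.int64)
    for kk in range(4):
        sel = k == kk
        cols = [c for c in range(4) if c != kk]
        faces[sel] = simplices[ti[sel]][:, cols]

    fv = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0]), axis=1)
    centroids = fv.mean(axis=1)
    caps = areas * distance_field(centroids, cloud)

    # source region: ball around the seed free of contour points, kept clear
    # of the sink band at the box boundary
    seed_clearance = float(distance_field(seed[None, :], cloud)[0])
    lo_box = mesh.vertices.min(axis=0)
    hi_box = mesh.vertices.max(axis=0)
    box_clearance = float(min((seed - lo_box).min(), (hi_box - seed).min()))
    r_source = min(0.9 * seed_clearance, 0.5 * box_clearance)
    tet_centroids = mesh.vertices[mesh.tetrahedra].mean(axis=1)
    source = np.nonzero(np.linalg.norm(tet_centroids - seed, axis=1)
                        <= r_source)[0]
    if s not in set(source.tolist()):
        source = np.append(source, s)

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    near_box = np.any((mesh.vertices - lo < exterior_band)
                      | (hi - mesh.vertices < exterior_band), axis=1)
    sink = np.nonzero(np.any(near_box[simplices], axis=1))[0]
    if set(source.tolist()) & set(sink.tolist()):
        raise SeedConfigurationError("interior and exterior seed tets overlap")

    return CutGraph(n_tets=m, arcs=np.stack([ti, tj], axis=1), faces=faces,
                    capacities=caps, source_tets=source, sink_tets=sink)


def _solve_min_cut(graph: CutGraph) -> np.ndarray:
    """Max-flow/min-cut; returns boolean interior labels per tetrahedron."""
    n = graph.n_tets
    src, snk = n, n + 1

    # scipy's max-flow works on int32 capacities; scale so the total fits
    total = float(graph.capacities.sum())
    scale = (2.0 ** 30) / max(total, 1e-12)
    caps = np.maximum(1, np.round(graph.capacities * scale)).astype(np.int32)
    caps[graph.capacities <= 0] = 0
    big = np.int32(2 ** 31 - 1)

    rows = np.concatenate([graph.arcs[:, 0], graph.arcs[:, 1],
                           np.full(len(graph.source_tets), src),
                           graph.sink_tets])
    cols = np.concatenate([graph.arcs[:, 1], graph.arcs[:, 0],
                           graph.source_tets,
                           np.full(len(graph.sink_tets), snk)])
    data = np.concatenate([caps, caps,
                           np.full(len(graph.source_tets), big, dtype=np.int32),
                           np.full(len(graph.sink_tets), big, dtype=np.int32)])
    g = coo_matrix((data, (rows, cols)), shape=(n + 2, n + 2)).tocsr()
    res = maximum_flow(g, src, snk)
    if res.flow_value >= big:
        raise SeedConfigurationError("infinite flow: seeds are not separable")

    residual = g - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, src, directed=True,
                                return_predecessors=False)
    labels = np.zeros(n, dtype=bool)
    labels[order[order < n]] = True
    return labels


def min_cut_surface(graph: CutGraph, mesh: TetMesh) -> SurfaceMesh:
    """Solve the min cut and extract the interior/exterior boundary surface.

    The returned triangles are the shared faces between differently labeled
    tetrahedra, oriented outward (from interior toward exterior); their cut
    cost equals the discrete surface energy of the extracted surface by
    construction.
    """
    labels = _solve_min_cut(graph)
    li = labels[graph.arcs[:, 0]]
    lj = labels[graph.arcs[:, 1]]
    cut = li != lj
    faces = graph.faces[cut].copy()
    provenance = np.nonzero(cut)[0]

    # orient each face so its normal points from the interior tet outward
    interior_tet = np.where(li[cut], graph.arcs[cut, 0], graph.arcs[cut, 1])
    tet_centroid = mesh.vertices[mesh.tetrahedra[interior_tet]].mean(axis=1)
    fv = mesh.vertices[faces]
    normal = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
    outward = np.einsum("ij,ij->i", normal, fv.mean(axis=1) - tet_centroid) > 0
    faces[~outward] = faces[~outward][:, ::-1]

    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], provenance=provenance)


def cut_energy(graph: CutGraph, surface: SurfaceMesh) -> float:
    """Discrete minimal-surface energy of an extracted cut surface."""
    if surface.provenance is None:
        raise ValueError("surface has no cut-face provenance")
    return float(graph.capacities[surface.provenance].sum())


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def postprocess(surface: SurfaceMesh, smoothing_iterations: int = 10,
                target_edge: float | None = 2.0) -> SurfaceMesh:
    """Taubin (lambda/mu) smoothing followed by re-meshing toward a target edge.

    Taubin's two-step signed smoothing avoids the volume shrinkage of plain
    Laplacian smoothing; re-meshing subdivides edges longer than
    ``target_edge``.  With zero iterations and target_edge None this is the
    identity.
    """
    surface.require_closed()
    if smoothing_iterations == 0 and target_edge is None:
        return SurfaceMesh(surface.vertices.copy(), surface.triangles.copy())
    tm = surface.to_trimesh(process=True)
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53,
                                        iterations=smoothing_iterations)
    if target_edge is not None:
        v, f = trimesh.remesh.subdivide_to_size(tm.vertices, tm.faces,
                                                max_edge=target_edge)
        tm = trimesh.Trimesh(vertices=v, faces=f, process=True)
    return SurfaceMesh.from_trimesh(tm)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def reconstruct(records: list[SliceRecord],
                params: ReconstructionParams | None = None) -> SurfaceMesh:
    """Contours -> interpolation -> tet mesh -> graph cut -> post-processed surface.

    The interior seed is the centroid of all LV contour points.  Deterministic
    given its inputs.
    """
    params = params or ReconstructionParams()
    if not any(r.view == SA for r in records):
        raise ValueError("no SA slices to reconstruct from")
    cloud = interpolate_contours(records, params.intra_step, params.n_inter_layers,
                                 labels=params.labels, include_lax=params.include_lax)
    mesh = build_tet_mesh(cloud, params.grid_step, params.margin)
    lv = cloud.points.select(label="LV")
    seed = (lv.points if len(lv) else cloud.points.points).mean(axis=0)
    graph = build_cut_graph(mesh, cloud, seed, params.exterior_band)
    raw = min_cut_surface(graph, mesh)
    return postprocess(raw, params.smoothing_iterations, params.target_edge)
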