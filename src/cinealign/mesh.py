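"""Triangular surface meshes shared by the phantom, reconstruction and validation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import OpenSurfaceError

__all__ = ["SurfaceMesh"]


@dataclass
class SurfaceMesh:
    """A triangular surface in patient coordinates (mm).

    ``provenance`` optionally records, per triangle, which pipeline stage
    produced it (e.g. the index of the cut graph face it came from).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    provenance: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    # -- conversions ----------------------------------------------------
    def to_trimesh(self, process: bool = False) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.triangles.copy(), process=process)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64))

    # -- queries ---------------------------------------------------------
    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        if self.n_triangles == 0:
            return False
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def volume(self) -> float:
        """Enclosed volume (mm^3), positive for outward-oriented closed surfaces."""
        v = self.vertices
        t = self.triangles
        return float(np.einsum("ij,ij->i", v[t[:, 0]],
                               np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0)

    def area(self) -> float:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return float(0.5 * np.linalg.norm(n, axis=1).sum())

    def require_closed(self) -> None:
        if not self.is_closed():
            raise OpenSurfaceError("surface is not a closed 2-manifold")

    # -- io ---------------------------------------------------------------
    def write(self, path) -> None:
        """Write as PLY or STL, chosen from the file extension."""
        self.to_trimesh().export(str(path))
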