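"""Triangulated tooth surfaces in millimetres.

The package works with occlusal-view height fields: every surface is
single-valued in z over the (x, y) plane once the pose is standardized
(occlusal direction along +z, mesiodistal along +x). ``ToothMesh`` is a thin
container over vertex/face arrays; file I/O goes through :mod:`trimesh`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh


class GeometryError(ValueError):
    """Raised for degenerate or unusable geometry."""


@dataclasses.dataclass
class ToothMesh:
    """A triangulated tooth surface.

    Parameters
    ----------
    vertices : (N, 3) float array, millimetres.
    faces : (M, 3) int array of vertex indices.
    pose_standardized : whether the mesh is in the canonical occlusal frame.
    """

    vertices: np.ndarray
    faces: np.ndarray
    pose_standardized: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (M, 3) array")
        if not np.isfinite(self.vertices).all():
            raise GeometryError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) coordinates."""
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "ToothMesh":
        return ToothMesh(
            self.vertices.copy(), self.faces.copy(), self.pose_standardized
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def drop_degenerate_faces(self, area_eps: float = 1e-12) -> "ToothMesh":
        """Return a copy without zero-area faces."""
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        area2 = np.linalg.norm(np.cross(a, b), axis=1)
        return ToothMesh(v.copy(), self.faces[area2 > area_eps], self.pose_standardized)

    def prune_unreferenced(self) -> "ToothMesh":
        """Drop vertices no face uses (reindexing faces)."""
        used = np.unique(self.faces)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return ToothMesh(
            self.vertices[used], remap[self.faces], self.pose_standardized
        )

    def save(self, path: str | Path) -> None:
        """Export as STL/OBJ/PLY (format from the file extension)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ToothMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))
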