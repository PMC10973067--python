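"""Triangulated lumen surfaces: marching-cubes extraction, umbrella
Laplacian smoothing, component cleanup, and perpendicular end-cutting with
prismatic extrusion of the inlet/outlet openings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage.measure import marching_cubes

from .segmentation import SegmentationMask
from .types import InvalidArgumentError


@dataclass
class SurfaceMesh:
    """Triangle surface in mm world coordinates plus per-opening metadata
    (populated by :func:`cut_and_extrude_ends`)."""

    vertices: np.ndarray
    faces: np.ndarray
    openings: list = field(default_factory=list)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @property
    def is_closed(self) -> bool:
        return self.as_trimesh().is_watertight

    @property
    def euler_number(self) -> int:
        return self.as_trimesh().euler_number

    def area(self) -> float:
        return float(self.as_trimesh().area)

    def volume(self) -> float:
        return float(abs(self.as_trimesh().volume))

    def export(self, path) -> None:
        """Write STL/PLY by file extension."""
        self.as_trimesh().export(str(path))


def _drop_degenerate(vertices, faces):
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    return tm


def extract_surface(mask: SegmentationMask, iso_level: float = 0.5,
                    smooth_sigma: float = 0.5) -> SurfaceMesh:
    """Closed isosurface of the mask at ``iso_level``.

    The binary indicator is Gaussian-smoothed (``smooth_sigma`` voxels) to
    reduce stair-stepping, with foreground voxel centres clamped above the
    iso level so no foreground feature can be smoothed away.  Vertices are
    returned in mm world coordinates.
    """
    fg = mask.mask.astype(bool)
    if not fg.any():
        raise InvalidArgumentError("mask has no foreground voxel")
    faces_touch = (fg[0].any() or fg[-1].any() or fg[:, 0].any() or
                   fg[:, -1].any() or fg[:, :, 0].any() or fg[:, :, -1].any())
    if faces_touch:
        raise InvalidArgumentError(
            "foreground touches the grid boundary; pad the mask before "
            "surface extraction")
    indicator = ndimage.gaussian_filter(fg.astype(np.float64), smooth_sigma)
    indicator[fg] = np.maximum(indicator[fg], iso_level + 1e-3)
    verts, faces, _normals, _vals = marching_cubes(
        indicator, level=iso_level, spacing=(mask.spacing,) * 3)
    tm = _drop_degenerate(verts + np.asarray(mask.origin)[None, :], faces)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces))


def _adjacency_matrix(vertices, faces):
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    n = len(vertices)
    a = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    a.data[:] = 1.0  # collapse duplicate entries
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ a


def smooth_surface(mesh: SurfaceMesh, iterations: int = 20,
                   step: float = 0.5) -> SurfaceMesh:
    """Umbrella-weight Laplacian smoothing: each iteration moves every
    vertex toward the centroid of its 1-ring by ``step``; connectivity is
    unchanged and ``iterations=0`` is the identity."""
    if iterations < 0:
        raise InvalidArgumentError("iterations must be >= 0")
    if not (0.0 < step <= 1.0):
        raise InvalidArgumentError("step must lie in (0, 1]")
    if iterations == 0:
        return SurfaceMesh(vertices=mesh.vertices.copy(),
                           faces=mesh.faces.copy(),
                           openings=list(mesh.openings))
    A = _adjacency_matrix(mesh.vertices, mesh.faces)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = v + step * (A @ v - v)
    return SurfaceMesh(vertices=v, faces=mesh.faces.copy(),
                       openings=list(mesh.openings))


def clean_mesh_components(mesh: SurfaceMesh) -> SurfaceMesh:
    """Retain only the largest-surface-area connected component."""
    tm = mesh.as_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    best = max(parts, key=lambda p: p.area)
    return SurfaceMesh(vertices=np.asarray(best.vertices),
                       faces=np.asarray(best.faces))


def boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of the open boundary (edges on exactly
    one triangle)."""
    faces = mesh.faces
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bedges = key[idx[counts == 1]]
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[int] = set()
    loops = []
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [n for n in adj[cur] if n != prev and n not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            loop.append(cur)
            seen.add(cur)
        loops.append(np.asarray(loop))
    return loops


def _loop_area_centroid(points: np.ndarray, normal: np.ndarray):
    """Planar polygon area (shoelace in an in-plane basis) and centroid."""
    c0 = points.mean(axis=0)
    n = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    q = points - c0
    x, y = q @ e1, q @ e2
    # order by polar angle to make the shoelace robust to loop orientation
    order = np.argsort(np.arctan2(y, x))
    x, y = x[order], y[order]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area), c0


def _local_plane_cut(verts, faces, point, normal, r_local):
    """Remove the mesh part on the positive-normal side of the plane,
    restricted to a ball of radius ``r_local`` around ``point``; crossing
    triangles are clipped exactly at the plane.  Returns (verts, faces,
    n_new_on_plane)."""
    s = (verts - point) @ normal
    local = np.linalg.norm(verts - point, axis=1) < r_local
    removed = (s > 1e-9) & local

    new_verts = list(map(tuple, verts))
    weld: dict[tuple, int] = {}

    def plane_point(i, j):
        t = s[i] / (s[i] - s[j])
        q = verts[i] + t * (verts[j] - verts[i])
        key = tuple(np.round(q, 9))
        if key not in weld:
            weld[key] = len(new_verts)
            new_verts.append(tuple(q))
        return weld[key]

    out_faces = []
    n_clipped = 0
    for tri in faces:
        rm = removed[tri]
        if not rm.any():
            out_faces.append(list(tri))
            continue
        if rm.all():
            n_clipped += 1
            continue
        n_clipped += 1
        # Sutherland-Hodgman clip of the triangle against the kept side
        poly = []
        for a in range(3):
            i, j = tri[a], tri[(a + 1) % 3]
            if not removed[i]:
                poly.append(int(i))
            if removed[i] != removed[j]:
                poly.append(plane_point(int(i), int(j)) if removed[j]
                            else plane_point(int(j), int(i)))
        for a in range(1, len(poly) - 1):  # fan triangulation
            out_faces.append([poly[0], poly[a], poly[a + 1]])
    return (np.asarray(new_verts, dtype=float),
            np.asarray(out_faces, dtype=int), n_clipped)


def cut_and_extrude_ends(mesh: SurfaceMesh, end_points,
                         extrusion_length: float = 5.0,
                         plane_tol: float | None = None,
                         locality_factor: float = 3.0) -> SurfaceMesh:
    """Cut each vessel end perpendicular to its centerline tangent and
    append a straight prismatic extension ending in an open boundary loop.

    ``end_points`` is a list of ``(id, position_mm, outward_unit_direction)``
    or ``(id, position, direction, radius_mm)`` tuples; the plane passes
    through the position with the direction as its normal, the distal cap
    is discarded (the cut acts only within ``locality_factor`` x radius of
    the end, so one vessel's plane cannot clip another vessel), and the
    per-opening planar cross-section area is recorded in ``openings``.
    """
    if extrusion_length < 0:
        raise InvalidArgumentError("extrusion_length must be >= 0")
    verts = mesh.vertices.copy()
    faces = mesh.faces.copy()
    planes = []
    for end in end_points:
        end_id, point, direction = end[0], end[1], end[2]
        radius = end[3] if len(end) > 3 else None
        d = np.asarray(direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise InvalidArgumentError(f"direction for end {end_id!r} is not unit-norm")
        point = np.asarray(point, dtype=float)
        r_local = locality_factor * radius if radius is not None else np.inf
        verts, faces, n_clipped = _local_plane_cut(verts, faces, point, d, r_local)
        if n_clipped == 0:
            raise InvalidArgumentError(
                f"slicing plane misses the mesh at end {end_id!r}")
        planes.append((end_id, point, d))
    tm = _drop_degenerate(verts, faces)
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    out = SurfaceMesh(vertices=verts, faces=faces)
    tol = plane_tol if plane_tol is not None else 1e-5
    openings = []
    loops = boundary_loops(out)
    new_verts = [verts]
    new_faces = [faces]
    offset = len(verts)
    for end_id, point, d in planes:
        matches = [lp for lp in loops if len(lp) >= 3 and
                   np.all(np.abs((verts[lp] - point) @ d) < max(tol, 1e-3))]
        if not matches:
            raise InvalidArgumentError(
                f"no boundary loop found on the cut plane of end {end_id!r}")
        loop = max(matches, key=lambda lp: _loop_area_centroid(verts[lp], d)[0])
        pts = verts[loop]
        area, centroid = _loop_area_centroid(pts, d)
        if extrusion_length > 0:
            ext = pts + d[None, :] * extrusion_length
            n = len(loop)
            idx_new = np.arange(offset, offset + n)
            side = []
            for i in range(n):
                j = (i + 1) % n
                side.append([loop[i], loop[j], idx_new[j]])
                side.append([loop[i], idx_new[j], idx_new[i]])
            new_verts.append(ext)
            new_faces.append(np.asarray(side))
            offset += n
        openings.append({"id": end_id,
                         "centroid": (centroid + d * extrusion_length).tolist(),
                         "normal": d.tolist(), "area_mm2": area})
    out = SurfaceMesh(vertices=np.vstack(new_verts),
                      faces=np.vstack(new_faces), openings=openings)
    return out
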