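"""Mesh and point-cloud primitives.

Triangle meshes are held as :class:`trimesh.Trimesh` (millimetre units
throughout); this module adds the seeded sampling, solid-volume and planar
cross-section operations the socket pipeline is built on.

Volume estimation voxelizes the watertight (boundary-capped) solid and
counts interior voxels at full weight and surface voxels at half weight,
which removes the half-voxel dilation bias of a surface voxelization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import MeshFormatError, TopologyError, InputError

__all__ = [
    "PointCloud",
    "SectionLoopSet",
    "load_mesh",
    "save_mesh",
    "sample_surface",
    "mesh_volume",
    "cap_openings",
    "slice_area",
    "polygon_area",
]


@dataclass
class PointCloud:
    """Points sampled on a surface, with optional outward unit normals."""

    points: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise InputError("PointCloud requires an (n, 3) array with n >= 1")
        if not np.isfinite(self.points).all():
            raise InputError("PointCloud coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise InputError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.abs(norms - 1.0).max() > 1e-6:
                raise InputError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        pts = self.points @ rotation.T + translation
        nrm = None if self.normals is None else self.normals @ rotation.T
        return PointCloud(pts, nrm)


@dataclass
class SectionLoopSet:
    """Planar cross-section at height ``z``: closed 2D loops and total area.

    Loops coming from open surface contours are closed by the straight chord
    between their endpoints before the shoelace area is taken.
    """

    z: float
    loops: list = field(default_factory=list)  # list of (m, 2) arrays
    area: float = 0.0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise InputError("section area must be non-negative")


def as_points(cloud) -> np.ndarray:
    """Accept a PointCloud or raw (n, 3) array and return the array."""
    if isinstance(cloud, PointCloud):
        return cloud.points
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError("expected a PointCloud or an (n, 3) array")
    return pts


def load_mesh(path: str | os.PathLike, from_meters: bool = False) -> trimesh.Trimesh:
    """Load an STL/PLY/OBJ triangle mesh, merging duplicate vertices.

    Parameters
    ----------
    path:
        Mesh file path; format inferred from the extension.
    from_meters:
        Convert coordinates from metres to the package-wide millimetre
        convention.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MeshFormatError(f"mesh file does not exist: {path}")
    if os.path.getsize(path) == 0:
        raise MeshFormatError(f"mesh file is empty: {path}")
    try:
        mesh = trimesh.load(path, force="mesh", process=True)
    except Exception as exc:  # trimesh raises a zoo of types for bad files
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"no triangle geometry found in {path}")
    mesh.merge_vertices()
    if len(mesh.vertices) < 4 or len(mesh.faces) < 4:
        raise MeshFormatError(f"degenerate mesh (<4 vertices or faces) in {path}")
    if not np.isfinite(mesh.vertices).all():
        raise MeshFormatError(f"non-finite vertex coordinates in {path}")
    if from_meters:
        mesh = mesh.copy()
        mesh.vertices *= 1000.0
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | os.PathLike) -> None:
    """Write a mesh; format from the extension (.stl/.ply/.obj)."""
    mesh.export(os.fspath(path))


def sample_surface(mesh: trimesh.Trimesh, n: int, seed: int) -> PointCloud:
    """Draw ``n`` points area-uniformly on the surface, with outward normals.

    Identical ``(mesh, n, seed)`` always yields a bitwise-identical cloud.
    """
    if n < 1:
        raise InputError("sample count must be >= 1")
    if mesh.area <= 0 or len(mesh.faces) == 0:
        raise MeshFormatError("cannot sample a zero-area mesh")
    points, face_index = trimesh.sample.sample_surface(mesh, n, seed=int(seed))
    normals = np.asarray(mesh.face_normals)[face_index]
    # guard: degenerate faces can yield zero normals; renormalize defensively
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    return PointCloud(np.asarray(points, dtype=float), normals / lens)


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of the mesh boundary (directed edges)."""
    edges = mesh.edges  # directed, one per face side
    edges_sorted = np.sort(edges, axis=1)
    unique_idx = trimesh.grouping.group_rows(edges_sorted, require_count=1)
    boundary = edges[unique_idx]
    if len(boundary) == 0:
        return []
    nxt = {}
    for a, b in boundary:
        # boundary edge appears with the winding of its single face; the
        # boundary curve follows it in reverse so caps close consistently
        nxt[int(b)] = int(a)
    loops = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start:
            if cur in seen:
                break  # non-manifold junction; emit what we have
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=int))
    return loops


def cap_openings(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close every boundary loop with a centroid-fan patch.

    Already-watertight meshes are returned unchanged. Caps follow the
    winding of the surrounding surface, so a consistently wound input stays
    consistently wound (outward) after capping.
    """
    if mesh.is_watertight:
        return mesh
    loops = _boundary_loops(mesh)
    if not loops:
        raise TopologyError("mesh is not watertight but has no boundary loops")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = [np.asarray(mesh.faces, dtype=np.int64)]
    new_vertices = [vertices]
    next_index = len(vertices)
    for loop in loops:
        pts = vertices[loop]
        centroid = pts.mean(axis=0)
        new_vertices.append(centroid[None, :])
        m = len(loop)
        fan = np.column_stack([
            loop,
            np.roll(loop, -1),
            np.full(m, next_index, dtype=np.int64),
        ])
        faces.append(fan)
        next_index += 1
    capped = trimesh.Trimesh(
        vertices=np.vstack(new_vertices),
        faces=np.vstack(faces),
        process=False,
    )
    if not capped.is_watertight:
        raise TopologyError("boundary loops could not be capped to a watertight solid")
    return capped


def mesh_volume(mesh: trimesh.Trimesh, pitch: float = 0.5) -> float:
    """Solid volume of the (capped) mesh on a voxel grid, mm^3.

    The mesh is closed with :func:`cap_openings` if needed, then voxel
    centres on a regular grid of the given pitch are classified inside or
    outside layer by layer: each z-layer's cross-section polygons (chord-
    closed like :func:`slice_area`) decide membership by the even-odd
    rule.  Counting centres, rather than surface-touching voxels, makes
    the estimate unbiased in the pitch.
    """
    if pitch <= 0:
        raise InputError("voxel pitch must be positive")
    from shapely import Polygon, contains_xy

    closed = cap_openings(mesh)
    (xmin, ymin, zmin), (xmax, ymax, zmax) = closed.bounds
    xs = np.arange(xmin + pitch / 2.0, xmax, pitch)
    ys = np.arange(ymin + pitch / 2.0, ymax, pitch)
    zs = np.arange(zmin + pitch / 2.0, zmax, pitch)
    if min(len(xs), len(ys), len(zs)) == 0:
        raise TopologyError("mesh is thinner than one voxel pitch")
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    count = 0
    for z in zs:
        try:
            section = slice_area(closed, z)
        except InputError:
            continue
        inside = np.zeros(len(gx), dtype=bool)
        for loop in section.loops:
            if len(loop) < 3:
                continue
            poly = Polygon(loop)
            if poly.area <= 0:
                continue
            inside ^= contains_xy(poly, gx, gy)  # even-odd handles nesting
        count += int(inside.sum())
    volume = count * pitch**3
    if volume <= 0:
        raise TopologyError("voxelized volume is non-positive; mesh may be degenerate")
    return float(volume)


def polygon_area(loop_xy: np.ndarray) -> float:
    """Absolute shoelace area of a 2D loop; the last->first chord closes it."""
    xy = np.asarray(loop_xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def slice_area(mesh: trimesh.Trimesh, z: float) -> SectionLoopSet:
    """Planar cross-section of the mesh at height ``z``.

    Open contours (e.g. across a socket's olecranon cutout) are closed by a
    straight chord between their endpoints; the total area is the sum of the
    absolute shoelace areas of the resulting loops.
    """
    zmin, zmax = mesh.bounds[:, 2]
    if not (zmin < z < zmax):
        raise InputError(
            f"slice height z={z:g} outside mesh z-extents ({zmin:g}, {zmax:g})"
        )
    section = mesh.section(plane_origin=[0.0, 0.0, float(z)],
                           plane_normal=[0.0, 0.0, 1.0])
    if section is None:
        return SectionLoopSet(z=float(z), loops=[], area=0.0)
    loops = []
    total = 0.0
    for entity in section.entities:
        pts = entity.discrete(section.vertices)
        if len(pts) < 3:
            continue
        xy = np.asarray(pts)[:, :2]
        loops.append(xy)
        total += polygon_area(xy)
    return SectionLoopSet(z=float(z), loops=loops, area=float(total))
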