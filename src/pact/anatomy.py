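"""Anatomical coordinate frame and rigid registration.

The canonical limb frame follows the clinical convention for transradial
residual limbs: origin at the midpoint of the humeral epicondyles, x along
the medio-lateral (frontal) axis positive toward lateral, y along the
anterior-posterior (sagittal) axis positive anterior (the olecranon lies on
the negative-y, posterior side), and z along the longitudinal axis
increasing distal-to-proximal.  Left limbs are mirrored about the sagittal
plane into this canonical right-side frame so retrieval can compare across
sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import GeometryError, RegistrationError, InputError
from .mesh_core import PointCloud, as_points

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "AnatomicalFrame",
    "AlignmentResult",
    "ICPResult",
    "align_limb",
    "register_socket_to_limb",
    "icp_register",
]

_MIN_LANDMARK_SEP = 5.0  # mm


@dataclass
class LandmarkSet:
    """The three bony landmarks used to anchor the limb frame."""

    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    olecranon: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        for name in ("medial_epicondyle", "lateral_epicondyle", "olecranon"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise InputError(f"landmark {name} has non-finite coordinates")
            setattr(self, name, p)
        if self.side not in ("left", "right"):
            raise InputError("side must be 'left' or 'right'")
        pts = self.as_array()
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(pts[i] - pts[j]) <= _MIN_LANDMARK_SEP:
                    raise GeometryError(
                        f"landmarks closer than {_MIN_LANDMARK_SEP} mm"
                    )
        v1 = self.lateral_epicondyle - self.medial_epicondyle
        v2 = self.olecranon - self.medial_epicondyle
        if np.linalg.norm(np.cross(v1, v2)) < 1e-9 * np.linalg.norm(v1) * np.linalg.norm(v2):
            raise GeometryError("landmarks are collinear")

    def as_array(self) -> np.ndarray:
        return np.stack([self.medial_epicondyle, self.lateral_epicondyle, self.olecranon])

    def to_dict(self) -> dict:
        return {
            "medial_epicondyle": self.medial_epicondyle.tolist(),
            "lateral_epicondyle": self.lateral_epicondyle.tolist(),
            "olecranon": self.olecranon.tolist(),
            "side": self.side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            medial_epicondyle=np.asarray(d["medial_epicondyle"], dtype=float),
            lateral_epicondyle=np.asarray(d["lateral_epicondyle"], dtype=float),
            olecranon=np.asarray(d["olecranon"], dtype=float),
            side=d.get("side", "right"),
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        R, t = np.asarray(rotation), np.asarray(translation)
        return LandmarkSet(
            medial_epicondyle=R @ self.medial_epicondyle + t,
            lateral_epicondyle=R @ self.lateral_epicondyle + t,
            olecranon=R @ self.olecranon + t,
            side=self.side,
        )


@dataclass
class RigidTransform:
    """Proper rigid map x -> R x + t (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper orthonormal (det = +1)")
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-8:
            raise GeometryError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return as_points(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame (rows of ``axes`` are x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows x (M-L), y (A-P), z (longitudinal)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.abs(self.axes @ self.axes.T - np.eye(3)).max() > 1e-9:
            raise GeometryError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("frame must be right-handed")

    @classmethod
    def canonical(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.eye(3))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (as_points(points) - self.origin) @ self.axes.T


@dataclass
class AlignmentResult:
    """Output of :func:`align_limb`.

    ``matrix`` is the 4x4 homogeneous map input -> aligned coordinates; for
    mirrored left limbs it contains a reflection (det -1), which is why the
    full map is not expressed as a :class:`RigidTransform`.
    """

    mesh: trimesh.Trimesh
    transform: RigidTransform
    frame: AnatomicalFrame
    mirrored: bool = False

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.transform.rotation
        M[:3, 3] = self.transform.translation
        if self.mirrored:
            F = np.diag([-1.0, 1.0, 1.0, 1.0])
            M = F @ M
        return M


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length direction vector")
    return v / n


def frame_from_landmarks(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame implied by the three landmarks (pre-mirroring).

    For left limbs the x axis is taken toward *medial* so that a subsequent
    reflection of the x coordinate lands the limb in the canonical
    right-side frame.
    """
    origin = 0.5 * (landmarks.medial_epicondyle + landmarks.lateral_epicondyle)
    x = _unit(landmarks.lateral_epicondyle - landmarks.medial_epicondyle)
    if landmarks.side == "left":
        x = -x
    posterior = landmarks.olecranon - origin
    perp = posterior - np.dot(posterior, x) * x
    if np.linalg.norm(perp) < 1e-9:
        raise GeometryError("olecranon lies on the epicondyle axis")
    y = -_unit(perp)  # anterior = away from the olecranon
    z = np.cross(x, y)
    return AnatomicalFrame(origin, np.stack([x, y, z]))


def align_limb(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    mirror_left: bool = True,
) -> AlignmentResult:
    """Express a limb mesh in the canonical anatomical frame.

    The output mesh has its origin at the epicondyle midpoint, x along the
    epicondyle axis (positive lateral), the olecranon on the posterior
    (negative-y) side, and z increasing distal to proximal.  Left limbs are
    mirrored about the sagittal plane (and their triangle winding flipped)
    unless ``mirror_left`` is False.
    """
    frame = frame_from_landmarks(landmarks)
    R = frame.axes  # world -> local rotation
    t = -R @ frame.origin
    transform = RigidTransform(R, t)
    vertices = transform.apply(np.asarray(mesh.vertices))
    faces = np.asarray(mesh.faces)
    mirrored = landmarks.side == "left" and mirror_left
    if mirrored:
        vertices = vertices.copy()
        vertices[:, 0] *= -1.0
        faces = faces[:, ::-1]  # keep outward winding under reflection
    aligned = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return AlignmentResult(
        mesh=aligned,
        transform=transform,
        frame=AnatomicalFrame.canonical(),
        mirrored=mirrored,
    )


def register_socket_to_limb(
    socket: trimesh.Trimesh,
    trimline_indent: np.ndarray,
    obturator_ref: np.ndarray,
    max_ref_dist: float = 5.0,
) -> tuple[trimesh.Trimesh, AnatomicalFrame]:
    """Register a socket mesh into its limb's anatomical frame.

    The longitudinal axis is the socket's principal (longest) axis oriented
    from the distal tip toward the proximal trimline; the transverse plane
    (z = 0) is placed at the height of the deepest trimline indent, and the
    sagittal plane passes through the olecranon obturator reference (or
    olecranon tip), which fixes the rotation about z with the reference on
    the posterior side.
    """
    indent = np.asarray(trimline_indent, dtype=float).reshape(3)
    obturator = np.asarray(obturator_ref, dtype=float).reshape(3)
    vertices = np.asarray(socket.vertices, dtype=float)
    tree = cKDTree(vertices)
    for name, p in (("trimline indent", indent), ("obturator reference", obturator)):
        d, _ = tree.query(p)
        if d > max_ref_dist:
            raise RegistrationError(
                f"{name} point is {d:.1f} mm from the socket surface (> {max_ref_dist} mm)"
            )
    centroid = vertices.mean(axis=0)
    # longitudinal axis = principal axis of the vertex cloud, oriented from
    # the distal tip toward the proximal trimline indent
    centered = vertices - centroid
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    z = eigvecs[:, np.argmax(eigvals)]
    if np.dot(indent - centroid, z) < 0:
        z = -z
    posterior = obturator - centroid
    perp = posterior - np.dot(posterior, z) * z
    if np.linalg.norm(perp) < 1e-9:
        raise RegistrationError("obturator reference lies on the longitudinal axis")
    y = -_unit(perp)
    x = np.cross(y, z)
    # transverse plane (z = 0) at the height of the deepest trimline indent
    origin = centroid + np.dot(indent - centroid, z) * z
    frame = AnatomicalFrame(origin, np.stack([x, y, z]))
    registered = trimesh.Trimesh(
        vertices=frame.to_local(vertices),
        faces=np.asarray(socket.faces),
        process=False,
    )
    return registered, frame


@dataclass
class ICPResult:
    transform: RigidTransform
    cloud: PointCloud
    residuals: list = field(default_factory=list)  # mean squared NN distance per iter
    converged: bool = False

    @property
    def residual(self) -> float:
        return self.residuals[-1] if self.residuals else float("nan")


def _check_not_degenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise RegistrationError("ICP requires at least 3 points per cloud")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise RegistrationError("point cloud is degenerate (collinear)")


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def icp_register(
    source,
    target,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ICPResult:
    """Centroid pre-alignment followed by point-to-point ICP.

    Minimizes the mean squared nearest-neighbour distance of the source
    cloud to the target; the residual is monotone non-increasing.  Stops
    when its relative change falls below ``tol`` or after ``max_iter``
    iterations.  Returns the accumulated rigid map source -> aligned and
    the transformed source cloud.
    """
    src = as_points(source)
    tgt = as_points(target)
    _check_not_degenerate(src)
    _check_not_degenerate(tgt)
    normals = source.normals if isinstance(source, PointCloud) else None

    total = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    current = total.apply(src)
    tree = cKDTree(tgt)
    residuals: list[float] = []
    converged = False
    for _ in range(int(max_iter)):
        dist, idx = tree.query(current)
        residuals.append(float(np.mean(dist**2)))
        if len(residuals) >= 2:
            prev, cur = residuals[-2], residuals[-1]
            if prev <= 0 or (prev - cur) / prev < tol:
                converged = True
                break
        step = _kabsch(current, tgt[idx])
        current = step.apply(current)
        total = step.compose(total)
    cloud = PointCloud(current, None if normals is None else normals @ total.rotation.T)
    return ICPResult(transform=total, cloud=cloud, residuals=residuals, converged=converged)
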