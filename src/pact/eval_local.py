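"""Localized deviation analysis.

Per participant: a signed distance field sampled on the predicted socket
(positive where the prediction lies outside / is larger than the
reference), mean-split thresholds flagging pronounced deviations, and
DBSCAN clustering of the flagged points into sign-specific regions.

Across participants: region centroids are normalized by each participant's
socket z-length, pooled, re-clustered with DBSCAN, and each pooled cluster
is summarized by an average unit direction vector from the anatomical
origin with per-axis standard deviations — the scale-free angular location
of a recurring deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .errors import InputError
from .mesh_core import sample_surface

__all__ = [
    "SignedDistanceField",
    "PronouncedDeviations",
    "DeviationRegion",
    "CommonRegion",
    "default_eps",
    "signed_distances",
    "pronounced_mask",
    "cluster_deviations",
    "aggregate_regions",
    "label_region",
    "CANONICAL_DIRECTIONS",
]

#: advisory label table: canonical unit directions (from the anatomical
#: origin) of the recurring deviation regions seen in transradial socket
#: rectification practice
CANONICAL_DIRECTIONS: dict[str, np.ndarray] = {
    "anterior_distal_trimline": np.array([-0.05, 0.97, 0.25]),
    "ap_compression": np.array([-0.09, -0.53, -0.84]),
    "distal_tip": np.array([0.0, 0.0, -1.0]),
    "supracondylar_compression": np.array([0.0, -0.71, 0.71]),
}
CANONICAL_DIRECTIONS = {
    k: v / np.linalg.norm(v) for k, v in CANONICAL_DIRECTIONS.items()
}


@dataclass
class SignedDistanceField:
    """Signed distances from points on the predicted socket to the reference."""

    points: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.points) != len(self.distances):
            raise InputError("points and distances must have equal length")


@dataclass
class PronouncedDeviations:
    points: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    threshold_pos: float | None
    threshold_neg: float | None

    @property
    def flagged_points(self) -> np.ndarray:
        return self.points[self.mask]

    @property
    def flagged_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class DeviationRegion:
    """One density-based cluster of pronounced deviation points."""

    points: np.ndarray
    centroid: np.ndarray
    sign: str  # "inflation" (predicted larger) or "deflation"
    participant_id: str = ""
    mean_deviation: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.points.min(axis=0), self.points.max(axis=0)
        if not np.all((self.centroid >= lo - 1e-9) & (self.centroid <= hi + 1e-9)):
            raise InputError("region centroid must lie in the member bounding box")


@dataclass
class CommonRegion:
    """A recurring deviation region pooled across participants."""

    sign: str
    member_centroids: np.ndarray      # normalized (dimensionless) space
    member_unit_vectors: np.ndarray   # one per member region
    participant_ids: list = field(default_factory=list)
    direction: np.ndarray = None
    direction_sd: np.ndarray = None
    label: str = ""

    @property
    def incidence(self) -> int:
        return len(set(self.participant_ids))

    def format_direction(self) -> str:
        """Human-readable unit vector with per-axis SDs in parentheses."""
        comps = []
        for value, sd, axis in zip(self.direction, self.direction_sd,
                                   ("x^", "y^", "z^")):
            comps.append(f"{value:+.2f} ({sd:.2f}) {axis}")
        return " ".join(comps)


def default_eps(
    z_length: float,
    surface_area: float,
    n_samples: int,
    eps_frac: float = 0.025,
    spacing_factor: float = 3.0,
) -> float:
    """DBSCAN neighbourhood radius for a sampled socket surface, mm.

    The scale-relative term (a fraction of the socket z-length) keeps the
    clustering size-invariant; the floor of ``spacing_factor`` times the
    mean sample spacing sqrt(area / n) guarantees that a contiguous
    flagged patch at the global sampling density can still form core
    points at realistic sample counts.
    """
    if z_length <= 0 or surface_area <= 0 or n_samples < 1:
        raise InputError("z_length, surface_area and n_samples must be positive")
    spacing = np.sqrt(surface_area / n_samples)
    return max(eps_frac * z_length, spacing_factor * spacing)


def signed_distances(
    pred: trimesh.Trimesh,
    ref: trimesh.Trimesh,
    n: int = 10_000,
    seed: int = 0,
) -> SignedDistanceField:
    """Signed surface distance at ``n`` sampled points of the prediction.

    Sign from the outward normal of the nearest reference sample: positive
    when the predicted point lies on the outward side (prediction larger).
    Assumes the meshes are already co-registered.
    """
    pred_cloud = sample_surface(pred, n, seed)
    ref_cloud = sample_surface(ref, n, seed)
    dist, idx = cKDTree(ref_cloud.points).query(pred_cloud.points)
    offset = pred_cloud.points - ref_cloud.points[idx]
    side = np.sign(np.einsum("ij,ij->i", offset, ref_cloud.normals[idx]))
    side[side == 0] = 1.0
    return SignedDistanceField(points=pred_cloud.points, distances=dist * side)


def pronounced_mask(field: SignedDistanceField) -> PronouncedDeviations:
    """Flag pronounced deviations by the mean-split rule.

    The positive and negative values form two groups; each group's mean is
    its threshold, and points beyond their group's threshold are flagged.
    An empty group has no threshold and flags nothing of that sign.
    """
    d = field.distances
    if len(d) == 0:
        raise InputError("cannot threshold an empty field")
    pos = d[d > 0]
    neg = d[d < 0]
    thr_pos = float(pos.mean()) if len(pos) else None
    thr_neg = float(neg.mean()) if len(neg) else None
    mask = np.zeros(len(d), dtype=bool)
    if thr_pos is not None:
        mask |= d > thr_pos
    if thr_neg is not None:
        mask |= d < thr_neg
    return PronouncedDeviations(
        points=field.points, values=d, mask=mask,
        threshold_pos=thr_pos, threshold_neg=thr_neg,
    )


def cluster_deviations(
    flagged: PronouncedDeviations,
    eps: float,
    min_samples: int = 20,
    participant_id: str = "",
) -> list[DeviationRegion]:
    """DBSCAN the flagged points into sign-specific regions.

    Inflation (positive) and deflation (negative) points are clustered
    separately, since a deviation region has one sign (material added or
    removed).  Noise points are discarded.
    """
    if eps <= 0:
        raise InputError("eps must be positive")
    if min_samples < 1:
        raise InputError("min_samples must be >= 1")
    regions: list[DeviationRegion] = []
    pts = flagged.flagged_points
    vals = flagged.flagged_values
    for sign, sel in (("inflation", vals > 0), ("deflation", vals < 0)):
        sub = pts[sel]
        sub_vals = vals[sel]
        if len(sub) == 0:
            continue
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(sub)
        for lab in sorted(set(labels) - {-1}):
            members = sub[labels == lab]
            regions.append(DeviationRegion(
                points=members,
                centroid=members.mean(axis=0),
                sign=sign,
                participant_id=participant_id,
                mean_deviation=float(sub_vals[labels == lab].mean()),
            ))
    return regions


def label_region(direction: np.ndarray) -> str:
    """Advisory name of the nearest canonical deviation direction."""
    direction = np.asarray(direction, dtype=float)
    best = max(CANONICAL_DIRECTIONS,
               key=lambda k: float(np.dot(direction, CANONICAL_DIRECTIONS[k])))
    return best


def aggregate_regions(
    regions: list[DeviationRegion],
    norm_scale: dict[str, float],
    origin: dict[str, np.ndarray] | None = None,
    eps_norm: float = 0.08,
    min_samples: int = 2,
) -> list[CommonRegion]:
    """Pool per-participant regions into recurring cross-participant regions.

    Centroids are divided by each participant's socket z-length
    (``norm_scale``), pooled per sign, re-clustered with DBSCAN in the
    normalized space, and each pooled cluster is summarized by the
    renormalized mean of its members' unit direction vectors from the
    anatomical origin, with per-axis SDs of the member unit vectors.
    """
    if not regions:
        return []
    origin = origin or {}
    out: list[CommonRegion] = []
    for sign in ("inflation", "deflation"):
        group = [r for r in regions if r.sign == sign]
        if not group:
            continue
        normed = np.stack([
            (r.centroid - origin.get(r.participant_id, np.zeros(3)))
            / norm_scale[r.participant_id]
            for r in group
        ])
        units = normed / np.linalg.norm(normed, axis=1, keepdims=True)
        labels = DBSCAN(eps=eps_norm, min_samples=min_samples).fit_predict(normed)
        for lab in sorted(set(labels) - {-1}):
            sel = labels == lab
            mean_vec = units[sel].mean(axis=0)
            norm = np.linalg.norm(mean_vec)
            if norm < 1e-12:
                continue
            direction = mean_vec / norm
            out.append(CommonRegion(
                sign=sign,
                member_centroids=normed[sel],
                member_unit_vectors=units[sel],
                participant_ids=[r.participant_id
                                 for r, s in zip(group, sel) if s],
                direction=direction,
                direction_sd=units[sel].std(axis=0, ddof=0),
                label=label_region(direction),
            ))
    out.sort(key=lambda r: -r.incidence)
    return out
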