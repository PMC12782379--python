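"""Retrieve-and-refine socket prediction.

Given an aligned residual-limb scan and a library of prosthetist-designed
limb-socket pairs, the method proceeds in three steps:

1. *Shape retrieval* — every library limb is isotropically normalized to
   the input limb's proximal-distal length (SF_k = L_input / L_k) and the
   closest limb is found by the mean nearest-neighbour Euclidean (L2)
   distance between sampled surface clouds.
2. *Socket selection and isotropic scaling* — the matched limb's socket is
   retrieved and scaled by the same SF_k.
3. *Anisotropic refinement* — the anterior-posterior (y) and medio-lateral
   (x) extents of the input limb relative to the scaled matched limb give
   SF_AP and SF_ML, applied about the frame origin with z preserved.

:class:`SocketPredictor` wraps the three steps as a scikit-learn style
estimator (``fit`` on a :class:`~pact.library.Library`, ``predict`` on a
limb mesh); the module-level functions are the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .anatomy import LandmarkSet, align_limb
from .config import RunConfig
from .errors import GeometryError, InputError, LibraryError
from .library import Library, LibraryEntry
from .mesh_core import PointCloud, as_points, sample_surface

__all__ = [
    "ScalingFactors",
    "PredictionResult",
    "shape_distance",
    "length_normalize",
    "measure_extent",
    "anisotropic_factors",
    "apply_scaling",
    "retrieve_best_match",
    "predict_socket",
    "SocketPredictor",
]

_AXIS_INDEX = {"x": 0, "y": 1}


@dataclass
class ScalingFactors:
    """Isotropic (sf_k) and anisotropic medio-lateral / anterior-posterior
    factors applied to a retrieved socket."""

    sf_k: float
    sf_ml: float = 1.0
    sf_ap: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sf_k", "sf_ml", "sf_ap"):
            if not getattr(self, name) > 0:
                raise InputError(f"scaling factor {name} must be strictly positive")

    def to_dict(self) -> dict:
        return {"SF_k": self.sf_k, "SF_M-L": self.sf_ml, "SF_A-P": self.sf_ap}


@dataclass
class PredictionResult:
    matched_id: str
    factors: ScalingFactors
    d_l2: float
    socket: trimesh.Trimesh
    #: retrieval distance per library entry, for diagnostics
    distances: dict | None = None

    def report(self) -> dict:
        return {
            "matched_id": self.matched_id,
            "factors": self.factors.to_dict(),
            "d_L2_mm": self.d_l2,
        }


def shape_distance(P, Q, symmetric: bool = False) -> float:
    """Mean Euclidean distance from each point of P to its nearest point in Q.

    One-directional P -> Q by default; ``symmetric`` averages both
    directions.
    """
    p = as_points(P)
    q = as_points(Q)
    if len(p) == 0 or len(q) == 0:
        raise InputError("shape_distance requires non-empty clouds")
    d_pq = float(cKDTree(q).query(p)[0].mean())
    if not symmetric:
        return d_pq
    d_qp = float(cKDTree(p).query(q)[0].mean())
    return 0.5 * (d_pq + d_qp)


def proximal_distal_length(mesh: trimesh.Trimesh) -> float:
    """Limb/socket length as the aligned mesh's z-extent, mm."""
    return float(np.ptp(np.asarray(mesh.vertices)[:, 2]))


def length_normalize(
    input_length: float, entry: LibraryEntry
) -> tuple[float, trimesh.Trimesh]:
    """Isotropic factor SF_k = L_input / L_k and the entry limb scaled by it
    about the frame origin."""
    entry_length = proximal_distal_length(entry.limb)
    if input_length <= 0 or entry_length <= 0:
        raise InputError("limb lengths must be strictly positive")
    sf_k = input_length / entry_length
    scaled = entry.limb.copy()
    scaled.vertices = np.asarray(scaled.vertices) * sf_k
    return sf_k, scaled


def measure_extent(mesh: trimesh.Trimesh, axis: str) -> float:
    """Maximum caliper extent along the named frame axis ('x' or 'y').

    Extents are frame-dependent by design: they are read along the fixed
    anatomical axes, not along rotated principal directions.
    """
    if axis not in _AXIS_INDEX:
        raise InputError("axis must be 'x' (M-L) or 'y' (A-P)")
    return float(np.ptp(np.asarray(mesh.vertices)[:, _AXIS_INDEX[axis]]))


def anisotropic_factors(
    input_mesh: trimesh.Trimesh, scaled_match: trimesh.Trimesh
) -> tuple[float, float]:
    """(SF_AP, SF_ML): y- and x-extent ratios of input over scaled match."""
    out = []
    for axis in ("y", "x"):
        num = measure_extent(input_mesh, axis)
        den = measure_extent(scaled_match, axis)
        if den <= 0 or num <= 0:
            raise GeometryError(f"zero {axis}-extent; cannot form anisotropic factor")
        out.append(num / den)
    return out[0], out[1]


def apply_scaling(socket: trimesh.Trimesh, factors: ScalingFactors) -> trimesh.Trimesh:
    """Scale a registered socket about the frame origin.

    Coordinates map (x, y, z) -> (SF_k*SF_ML*x, SF_k*SF_AP*y, SF_k*z), so
    the anisotropic step never changes the length set by SF_k.
    """
    scaled = socket.copy()
    diag = np.array([
        factors.sf_k * factors.sf_ml,
        factors.sf_k * factors.sf_ap,
        factors.sf_k,
    ])
    scaled.vertices = np.asarray(scaled.vertices) * diag
    return scaled


def retrieve_best_match(
    input_mesh: trimesh.Trimesh,
    lib: Library,
    n: int = 10_000,
    seed: int = 0,
    symmetric: bool = False,
) -> tuple[str, float, float, dict]:
    """Step 1: closest library limb after per-entry length normalization.

    Returns ``(matched_id, sf_k, d_l2, distances)``.  Ties on the distance
    are broken by the factor closest to 1 (least geometric distortion),
    then lexicographic id.
    """
    if len(lib) == 0:
        raise LibraryError("cannot retrieve from an empty library")
    input_length = proximal_distal_length(input_mesh)
    query = sample_surface(input_mesh, n, seed).points
    results: dict[str, tuple[float, float]] = {}
    for pid in lib.ids:
        entry = lib[pid]
        entry_length = proximal_distal_length(entry.limb)
        sf_k = input_length / entry_length
        # sampling commutes with uniform scaling: sample once, scale points
        cloud = sample_surface(entry.limb, n, seed).points * sf_k
        d = shape_distance(query, cloud, symmetric=symmetric)
        results[pid] = (d, sf_k)
    best = min(results, key=lambda pid: (results[pid][0],
                                         abs(results[pid][1] - 1.0), pid))
    d_best, sf_best = results[best]
    return best, sf_best, d_best, {pid: d for pid, (d, _) in results.items()}


def predict_socket(
    limb: trimesh.Trimesh,
    lib: Library,
    landmarks: LandmarkSet | None = None,
    config: RunConfig | None = None,
) -> PredictionResult:
    """Full three-step prediction of a socket for an input limb.

    If ``landmarks`` are given the limb is first aligned into the canonical
    anatomical frame; otherwise it is assumed already aligned.
    """
    cfg = config or RunConfig()
    if landmarks is not None:
        limb = align_limb(limb, landmarks, mirror_left=cfg.mirror_left).mesh
    matched_id, sf_k, d_l2, distances = retrieve_best_match(
        limb, lib, n=cfg.n_samples, seed=cfg.seed, symmetric=cfg.symmetric_distance
    )
    entry = lib[matched_id]
    _, scaled_limb = length_normalize(proximal_distal_length(limb), entry)
    sf_ap, sf_ml = anisotropic_factors(limb, scaled_limb)
    factors = ScalingFactors(sf_k=sf_k, sf_ml=sf_ml, sf_ap=sf_ap)
    socket = apply_scaling(entry.socket, factors)
    return PredictionResult(
        matched_id=matched_id,
        factors=factors,
        d_l2=d_l2,
        socket=socket,
        distances=distances,
    )


class SocketPredictor(BaseEstimator):
    """Retrieve-and-refine socket predictor with a scikit-learn interface.

    Parameters
    ----------
    n_samples:
        Surface points sampled per mesh for the retrieval distance.
    random_state:
        Seed for all surface sampling; fixed per run so retrieval is
        reproducible.
    symmetric_distance:
        Evaluate the retrieval distance in both directions and average,
        instead of the one-directional input -> library form.
    mirror_left:
        Mirror left-side limbs into the canonical right-side frame during
        alignment.

    Attributes
    ----------
    library_ : Library
        The fitted reference library.
    n_entries_ : int
        Number of limb-socket pairs in the library.

    Examples
    --------
    >>> from pact.synthetic import generate_cohort
    >>> lib, _ = generate_cohort(5, seed=0)
    >>> pred = SocketPredictor(n_samples=2000).fit(lib)
    >>> result = pred.predict(lib[lib.ids[0]].limb)
    >>> result.matched_id == lib.ids[0]
    True
    """

    def __init__(
        self,
        n_samples: int = 10_000,
        random_state: int = 0,
        symmetric_distance: bool = False,
        mirror_left: bool = True,
    ):
        self.n_samples = n_samples
        self.random_state = random_state
        self.symmetric_distance = symmetric_distance
        self.mirror_left = mirror_left

    def _config(self) -> RunConfig:
        return RunConfig(
            n_samples=self.n_samples,
            seed=self.random_state,
            symmetric_distance=self.symmetric_distance,
            mirror_left=self.mirror_left,
        )

    def fit(self, X: Library, y=None) -> "SocketPredictor":
        """Fit on a reference library (stores and validates it)."""
        if not isinstance(X, Library):
            raise InputError("SocketPredictor.fit expects a Library")
        self.library_ = X
        self.n_entries_ = len(X)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "library_"):
            raise NotFittedError(
                "This SocketPredictor instance is not fitted yet; call 'fit' "
                "with a Library first."
            )

    def predict(
        self, X: trimesh.Trimesh, landmarks: LandmarkSet | None = None
    ) -> PredictionResult:
        """Predict a socket mesh for one input limb."""
        self._check_fitted()
        return predict_socket(X, self.library_, landmarks=landmarks,
                              config=self._config())

    def predict_many(self, meshes, landmarks=None) -> list[PredictionResult]:
        """Predict sockets for a sequence of limbs."""
        self._check_fitted()
        if landmarks is None:
            landmarks = [None] * len(meshes)
        return [self.predict(m, lm) for m, lm in zip(meshes, landmarks)]
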