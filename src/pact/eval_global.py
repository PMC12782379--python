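"""Global comparison of a predicted socket against a reference socket.

Four measures: mean surface L2 distance after centroid + ICP
co-registration, signed/absolute percentage volume difference, a 100-slice
cross-sectional-area (CSA) difference profile along each socket's own
z-extent, and a volume-based fit classification (good / acceptable /
replace).

Sign convention for the volume difference: negative means the predicted
socket is *smaller* than the reference, i.e. signed = 100 * (V_pred -
V_ref) / V_ref.  The magnitude equals the conventional percentage
difference 100 * |V_ref - V_pred| / V_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import RunConfig
from .errors import InputError
from .anatomy import icp_register
from .mesh_core import mesh_volume, sample_surface, slice_area

__all__ = [
    "CSAProfile",
    "GlobalMetrics",
    "surface_deviation",
    "volume_difference",
    "csa_profile",
    "classify_fit",
    "evaluate_global",
]


@dataclass
class CSAProfile:
    """Slice-wise CSA comparison at matched fractional stations.

    Stations sit at fractions (j + 0.5) / n of each socket's own z-extent,
    j = 0..n-1, from the distal tip (0%) to the proximal trimline (100%).
    Stations where the reference area falls below ``min_stable_area`` are
    flagged unstable and their delta is NaN rather than a number.
    """

    station_pct: np.ndarray
    area_pred: np.ndarray
    area_ref: np.ndarray
    delta_pct: np.ndarray
    stable: np.ndarray

    def __len__(self) -> int:
        return len(self.station_pct)

    def to_rows(self) -> list[dict]:
        return [
            {
                "station_pct": float(s),
                "area_pred_mm2": float(ap),
                "area_ref_mm2": float(ar),
                "delta_pct": None if not st else float(d),
                "stable": bool(st),
            }
            for s, ap, ar, d, st in zip(
                self.station_pct, self.area_pred, self.area_ref,
                self.delta_pct, self.stable)
        ]


@dataclass
class GlobalMetrics:
    mean_l2: float
    v_diff_signed: float
    v_diff_abs: float
    csa: CSAProfile
    fit_class: str

    def to_dict(self) -> dict:
        return {
            "mean_L2_mm": self.mean_l2,
            "V_diff_signed_pct": self.v_diff_signed,
            "V_diff_abs_pct": self.v_diff_abs,
            "fit_class": self.fit_class,
        }


def surface_deviation(
    pred: trimesh.Trimesh,
    ref: trimesh.Trimesh,
    n: int = 10_000,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> float:
    """Mean nearest-neighbour L2 distance pred -> ref after co-registration.

    Both sockets are sampled, centroid-aligned and refined with ICP before
    the distance is read, so the measure is invariant to a moderate initial
    rigid displacement of the prediction.
    """
    pred_cloud = sample_surface(pred, n, seed)
    ref_cloud = sample_surface(ref, n, seed)
    result = icp_register(pred_cloud, ref_cloud, max_iter=max_iter, tol=tol)
    dist, _ = cKDTree(ref_cloud.points).query(result.cloud.points)
    return float(dist.mean())


def volume_difference(
    ref: trimesh.Trimesh,
    pred: trimesh.Trimesh,
    pitch: float = 0.5,
) -> tuple[float, float]:
    """(signed %, absolute %) volume difference of predicted vs reference.

    Negative signed values mean the predicted socket is smaller than the
    reference.
    """
    v_ref = mesh_volume(ref, pitch=pitch)
    v_pred = mesh_volume(pred, pitch=pitch)
    signed = 100.0 * (v_pred - v_ref) / v_ref
    return float(signed), float(abs(signed))


def csa_profile(
    pred: trimesh.Trimesh,
    ref: trimesh.Trimesh,
    n_slices: int = 100,
    min_stable_area: float = 1.0,
) -> CSAProfile:
    """Percentage CSA difference at matched fractional stations.

    Each socket is sliced over its *own* z-extent so the profile is
    invariant to overall length; delta = 100 * (A_pred - A_ref) / A_ref.
    """
    if n_slices < 2:
        raise InputError("n_slices must be >= 2")
    fractions = (np.arange(n_slices) + 0.5) / n_slices

    def areas(mesh: trimesh.Trimesh) -> np.ndarray:
        zmin, zmax = mesh.bounds[:, 2]
        heights = zmin + fractions * (zmax - zmin)
        return np.array([slice_area(mesh, z).area for z in heights])

    area_pred = areas(pred)
    area_ref = areas(ref)
    stable = area_ref >= min_stable_area
    delta = np.full(n_slices, np.nan)
    delta[stable] = 100.0 * (area_pred[stable] - area_ref[stable]) / area_ref[stable]
    return CSAProfile(
        station_pct=fractions * 100.0,
        area_pred=area_pred,
        area_ref=area_ref,
        delta_pct=delta,
        stable=stable,
    )


def classify_fit(
    v_diff_abs: float,
    good_pct: float = 5.0,
    acceptable_pct: float = 10.0,
) -> str:
    """Fit class from the absolute volume difference, percent.

    0-5% is a good fit, 5-10% acceptable, beyond that the socket should be
    replaced; boundary values take the better class.
    """
    if v_diff_abs < 0:
        raise InputError("absolute volume difference cannot be negative")
    if v_diff_abs <= good_pct:
        return "good"
    if v_diff_abs <= acceptable_pct:
        return "acceptable"
    return "replace"


def evaluate_global(
    pred: trimesh.Trimesh,
    ref: trimesh.Trimesh,
    config: RunConfig | None = None,
) -> GlobalMetrics:
    """All global metrics for one predicted/reference socket pair."""
    cfg = config or RunConfig()
    mean_l2 = surface_deviation(
        pred, ref, n=cfg.n_samples, seed=cfg.seed,
        max_iter=cfg.icp_max_iter, tol=cfg.icp_tol,
    )
    signed, absolute = volume_difference(ref, pred, pitch=cfg.voxel_pitch)
    profile = csa_profile(pred, ref, n_slices=cfg.n_slices,
                          min_stable_area=cfg.min_stable_area)
    return GlobalMetrics(
        mean_l2=mean_l2,
        v_diff_signed=signed,
        v_diff_abs=absolute,
        csa=profile,
        fit_class=classify_fit(absolute, cfg.fit_good_pct, cfg.fit_acceptable_pct),
    )
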