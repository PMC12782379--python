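"""Run configuration: every tunable the pipeline exposes, with defaults.

All lengths are millimetres. The single ``seed`` drives every surface
sampling call, so comparing a mesh against itself always pairs identical
point clouds and yields exactly zero distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InputError


@dataclass
class RunConfig:
    #: points sampled per mesh surface for distances / signed fields
    n_samples: int = 10_000
    #: seed for all surface sampling (logged into every report)
    seed: int = 0
    #: voxel pitch for solid volume estimation, mm
    voxel_pitch: float = 0.5
    #: ICP iteration cap and relative residual-change stopping tolerance
    icp_max_iter: int = 100
    icp_tol: float = 1e-6
    #: participant-level DBSCAN: eps as a fraction of socket z-length
    dbscan_eps_frac: float = 0.025
    dbscan_min_samples: int = 20
    #: pooled (cross-participant) DBSCAN in length-normalized space
    dbscan_eps_norm: float = 0.08
    dbscan_min_samples_pooled: int = 2
    #: cross-sectional stations along each socket's own z-extent
    n_slices: int = 100
    #: reference slice area below which a station is flagged unstable, mm^2
    min_stable_area: float = 1.0
    #: volume-difference fit bands, percent (boundaries go to the better class)
    fit_good_pct: float = 5.0
    fit_acceptable_pct: float = 10.0
    #: evaluate the retrieval distance in both directions and average
    symmetric_distance: bool = False
    #: mirror left limbs into the canonical right-side frame before retrieval
    mirror_left: bool = True
    #: A-P / M-L dimensions from whole-mesh extents ("global") or the widest
    #: single cross-section ("slice")
    extent_mode: str = "global"

    def __post_init__(self) -> None:
        positive = (
            "n_samples", "voxel_pitch", "icp_max_iter", "icp_tol",
            "dbscan_eps_frac", "dbscan_min_samples", "dbscan_eps_norm",
            "dbscan_min_samples_pooled", "min_stable_area",
            "fit_good_pct", "fit_acceptable_pct",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise InputError(f"config field {name!r} must be positive")
        if self.n_slices < 2:
            raise InputError("n_slices must be >= 2")
        if self.extent_mode not in ("global", "slice"):
            raise InputError("extent_mode must be 'global' or 'slice'")

    def to_dict(self) -> dict:
        return asdict(self)
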