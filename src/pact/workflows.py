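"""Batch workflows: the leave-one-out evaluation over a whole library.

For every participant the prosthetist socket is removed from the library,
a socket is predicted from the remaining pairs, and the prediction is
compared to the held-out socket globally (surface L2, volume difference,
CSA profile, fit class) and locally (signed-distance clusters).  The
cohort summary aggregates factor tables, metric means, the slice-wise mean
CSA profile and cross-participant deviation regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .eval_global import GlobalMetrics, evaluate_global
from .eval_local import (DeviationRegion, aggregate_regions,
                         cluster_deviations, default_eps, pronounced_mask,
                         signed_distances)
from .library import Library
from .predict import PredictionResult, SocketPredictor, proximal_distal_length

__all__ = ["LOOEntry", "LOOResult", "run_loo"]


@dataclass
class LOOEntry:
    participant_id: str
    prediction: PredictionResult
    metrics: GlobalMetrics
    regions: list

    def to_dict(self) -> dict:
        d = {"participant_id": self.participant_id}
        d.update(self.prediction.report())
        d.update(self.metrics.to_dict())
        d["n_regions"] = len(self.regions)
        return d


@dataclass
class LOOResult:
    entries: list = field(default_factory=list)
    common_regions: list = field(default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)
    failures: dict = field(default_factory=dict)

    def factor_table(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"participant_id": e.participant_id,
                   "matched_id": e.prediction.matched_id,
                   "d_L2_mm": e.prediction.d_l2}
            row.update(e.prediction.factors.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def metric_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "participant_id": e.participant_id,
            "mean_L2_mm": e.metrics.mean_l2,
            "V_diff_signed_pct": e.metrics.v_diff_signed,
            "V_diff_abs_pct": e.metrics.v_diff_abs,
            "fit_class": e.metrics.fit_class,
        } for e in self.entries])

    def mean_csa_profile(self) -> pd.DataFrame:
        """Station-wise mean +/- SD of the CSA difference across the cohort."""
        deltas = np.stack([e.metrics.csa.delta_pct for e in self.entries])
        stations = self.entries[0].metrics.csa.station_pct
        with np.errstate(invalid="ignore"):
            return pd.DataFrame({
                "station_pct": stations,
                "mean_delta_pct": np.nanmean(deltas, axis=0),
                "sd_delta_pct": np.nanstd(deltas, axis=0, ddof=1),
                "n_stable": np.sum(~np.isnan(deltas), axis=0),
            })

    def summary(self) -> dict:
        mt = self.metric_table()
        csa = self.mean_csa_profile()
        thirds = np.digitize(csa["station_pct"], [100 / 3, 200 / 3])
        abs_mean = np.abs(csa["mean_delta_pct"].to_numpy())
        return {
            "n_participants": len(self.entries),
            "mean_L2_mm": {"mean": float(mt["mean_L2_mm"].mean()),
                           "sd": float(mt["mean_L2_mm"].std(ddof=1))},
            "V_diff_abs_pct": {"mean": float(mt["V_diff_abs_pct"].mean()),
                               "sd": float(mt["V_diff_abs_pct"].std(ddof=1))},
            "fit_classes": mt["fit_class"].value_counts().to_dict(),
            "csa_abs_mean_delta_by_third": {
                "distal": float(np.nanmean(abs_mean[thirds == 0])),
                "middle": float(np.nanmean(abs_mean[thirds == 1])),
                "proximal": float(np.nanmean(abs_mean[thirds == 2])),
            },
            "common_regions": [{
                "sign": r.sign,
                "incidence": r.incidence,
                "label": r.label,
                "direction": r.format_direction(),
            } for r in self.common_regions],
            "failures": dict(self.failures),
            "config": self.config.to_dict(),
        }


def run_loo(lib: Library, config: RunConfig | None = None) -> LOOResult:
    """Leave-one-out prediction + evaluation for every library entry."""
    cfg = config or RunConfig()
    result = LOOResult(config=cfg)
    all_regions: list[DeviationRegion] = []
    norm_scale: dict[str, float] = {}
    for pid in lib.ids:
        try:
            reduced = lib.leave_one_out(pid)
            predictor = SocketPredictor(
                n_samples=cfg.n_samples, random_state=cfg.seed,
                symmetric_distance=cfg.symmetric_distance,
                mirror_left=cfg.mirror_left,
            ).fit(reduced)
            prediction = predictor.predict(lib[pid].limb)
            reference = lib[pid].socket
            metrics = evaluate_global(prediction.socket, reference, cfg)
            field_ = signed_distances(prediction.socket, reference,
                                      n=cfg.n_samples, seed=cfg.seed)
            z_len = proximal_distal_length(reference)
            eps = default_eps(z_len, prediction.socket.area, cfg.n_samples,
                              eps_frac=cfg.dbscan_eps_frac)
            regions = cluster_deviations(
                pronounced_mask(field_),
                eps=eps,
                min_samples=cfg.dbscan_min_samples,
                participant_id=pid,
            )
            norm_scale[pid] = z_len
            all_regions.extend(regions)
            result.entries.append(LOOEntry(
                participant_id=pid, prediction=prediction,
                metrics=metrics, regions=regions))
        except Exception as exc:  # partial failures are reported, not fatal
            result.failures[pid] = f"{type(exc).__name__}: {exc}"
    result.common_regions = aggregate_regions(
        all_regions, norm_scale=norm_scale,
        eps_norm=cfg.dbscan_eps_norm,
        min_samples=cfg.dbscan_min_samples_pooled,
    )
    return result
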