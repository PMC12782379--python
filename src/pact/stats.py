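"""Subgroup statistics: Welch t-tests, Pearson correlation, Holm correction.

The subgroup analysis asks whether participant characteristics influence
prediction accuracy.  Four binary factors (sex, limb shape, limb length
class, pediatric/adult age group) are each tested against the two global
outcomes (signed volume difference and mean L2 distance) with Welch's
unequal-variance t-test; age as a continuous covariate is tested against
both outcomes with Pearson's r.  The resulting family of 10 p-values is
corrected with the Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "SubgroupResult",
    "welch_t",
    "pearson_r",
    "holm_bonferroni",
    "run_subgroup_analysis",
]

#: age below which a participant counts as pediatric, years
PEDIATRIC_CUTOFF = 18.0


@dataclass
class SubgroupResult:
    factor: str
    outcome: str
    test: str                      # "welch" or "pearson"
    groups: dict                   # label -> {"n", "mean", "sd"} (welch only)
    statistic: float
    df: float
    p: float
    holm_p: float = float("nan")
    estimable: bool = True

    def to_dict(self) -> dict:
        d = {
            "factor": self.factor, "outcome": self.outcome, "test": self.test,
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "holm_p": self.holm_p, "estimable": self.estimable,
        }
        for label, g in self.groups.items():
            d[f"{label}_n"] = g["n"]
            d[f"{label}_mean"] = g["mean"]
            d[f"{label}_sd"] = g["sd"]
        return d


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-tailed p).

    Does not assume equal group variances.  Two zero-variance groups with
    equal means return t = 0, p = 1 rather than a division error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("Welch test requires at least 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("Welch test requires finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-tailed p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("Pearson r requires paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InputError("Pearson r is undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


_BINARY_FACTORS = {
    "sex": ("F", "M", "sex"),
    "limb_shape": ("conical", "cylindrical", "shape_class"),
    "limb_length": ("short", "very_short", "length_class"),
    "age_group": ("pediatric", "adult", None),  # derived from age
}
_OUTCOMES = ("v_diff_signed", "mean_l2")


def run_subgroup_analysis(data: pd.DataFrame) -> list[SubgroupResult]:
    """The full subgroup family: 8 Welch tests + 2 age correlations.

    ``data`` needs one row per participant with columns ``v_diff_signed``
    (signed volume difference, %), ``mean_l2`` (mm), ``sex``,
    ``shape_class``, ``length_class`` and ``age``.  A factor level with
    fewer than 2 members makes that test non-estimable; it is reported but
    excluded from the Holm family (shrinking m).
    """
    required = {"v_diff_signed", "mean_l2", "sex", "shape_class",
                "length_class", "age"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    df = data.copy()
    df["age_group"] = np.where(df["age"] < PEDIATRIC_CUTOFF, "pediatric", "adult")

    results: list[SubgroupResult] = []
    for factor, (level_a, level_b, column) in _BINARY_FACTORS.items():
        col = column or "age_group"
        for outcome in _OUTCOMES:
            a = df.loc[df[col] == level_a, outcome].to_numpy(dtype=float)
            b = df.loc[df[col] == level_b, outcome].to_numpy(dtype=float)
            groups = {
                level_a: {"n": len(a), "mean": float(a.mean()) if len(a) else np.nan,
                          "sd": float(a.std(ddof=1)) if len(a) > 1 else np.nan},
                level_b: {"n": len(b), "mean": float(b.mean()) if len(b) else np.nan,
                          "sd": float(b.std(ddof=1)) if len(b) > 1 else np.nan},
            }
            if len(a) < 2 or len(b) < 2:
                results.append(SubgroupResult(
                    factor=factor, outcome=outcome, test="welch", groups=groups,
                    statistic=np.nan, df=np.nan, p=np.nan, estimable=False))
                continue
            t, dof, p = welch_t(a, b)
            results.append(SubgroupResult(
                factor=factor, outcome=outcome, test="welch", groups=groups,
                statistic=t, df=dof, p=p))
    for outcome in _OUTCOMES:
        age = df["age"].to_numpy(dtype=float)
        y = df[outcome].to_numpy(dtype=float)
        try:
            r, p = pearson_r(age, y)
            results.append(SubgroupResult(
                factor="age", outcome=outcome, test="pearson", groups={},
                statistic=r, df=float(len(age) - 2), p=p))
        except InputError:
            results.append(SubgroupResult(
                factor="age", outcome=outcome, test="pearson", groups={},
                statistic=np.nan, df=np.nan, p=np.nan, estimable=False))

    estimable = [r for r in results if r.estimable]
    if estimable:
        adjusted = holm_bonferroni([r.p for r in estimable])
        for r, ap in zip(estimable, adjusted):
            r.holm_p = float(ap)
    return results


def subgroup_table(results: list[SubgroupResult]) -> pd.DataFrame:
    """Flat DataFrame of the subgroup family (one row per test)."""
    return pd.DataFrame([r.to_dict() for r in results])
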