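"""Downstream verification arithmetic: moisture, ANOVA, germination rates.

These mirror the wet-lab bookkeeping that closes the loop on the
classifier: gravimetric moisture content on wet weight, one-way ANOVA
comparing the predicted-viable and predicted-nonviable groups
(per variety, no multiple-testing correction), and germination-rate
accounting for the accepted lot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plsda import ConfusionMatrix, evaluate

__all__ = [
    "AnovaResult",
    "moisture_content",
    "one_way_anova",
    "germination_report",
    "group_difference_report",
]

ALPHA = 0.05


def moisture_content(wet_g, dry_g):
    """Moisture content on a wet-weight basis: (Ww - Wd) * 100 / Ww."""
    wet = np.asarray(wet_g, dtype=float)
    dry = np.asarray(dry_g, dtype=float)
    if np.any(dry <= 0) or np.any(wet <= 0):
        raise ValueError("weights must be positive")
    if np.any(dry > wet):
        raise ValueError("dry weight exceeds wet weight")
    mc = (wet - dry) * 100.0 / wet
    return float(mc) if mc.ndim == 0 else mc


@dataclass(frozen=True)
class AnovaResult:
    ms_between: float
    ms_within: float
    f_value: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def one_way_anova(*groups) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition.

    Identical groups (zero between- and within-variance) return F = 0,
    p = 1 rather than an indeterminate form.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) \
            and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    n = all_vals.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(0.0, 0.0, 0.0, 1.0)
        return AnovaResult(float(ms_between), 0.0, float("inf"), 0.0)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, k - 1, n - k))
    return AnovaResult(float(ms_between), float(ms_within), float(f), p)


def germination_report(assay: pd.DataFrame) -> dict:
    """Germination rates per predicted group plus the outcome confusion.

    ``assay`` needs ``predicted`` (0/1) and ``germination`` (0/1)
    columns. Rates are percentages; an empty group reports NaN (n/a),
    never 0. The confusion matrix scores the prediction against the
    germination outcome as ground truth.
    """
    for col in ("predicted", "germination"):
        if col not in assay.columns:
            raise KeyError(f"assay table lacks a '{col}' column")
    rates = {}
    for name, code in (("viable", 1), ("nonviable", 0)):
        grp = assay.loc[assay["predicted"] == code, "germination"]
        rates[name] = float("nan") if grp.empty else 100.0 * float(grp.mean())
    cm: ConfusionMatrix = evaluate(assay["predicted"].to_numpy(dtype=int),
                                   assay["germination"].to_numpy(dtype=int))
    overall = 100.0 * float(assay["germination"].mean()) if len(assay) else float("nan")
    return {
        "viable_group_rate_pct": rates["viable"],
        "nonviable_group_rate_pct": rates["nonviable"],
        "overall_rate_pct": overall,
        "confusion": cm,
    }


def germination_table(reports: dict[str, dict], given_rates: dict[str, float],
                      preprocessing: dict[str, str]) -> pd.DataFrame:
    """Assemble per-variety rows: given rate vs final (accepted-lot) rate."""
    rows = []
    for variety, rep in reports.items():
        rows.append({
            "variety": variety,
            "preprocessing": preprocessing.get(variety, ""),
            "given_rate_pct": given_rates.get(variety, float("nan")),
            "final_rate_pct": rep["viable_group_rate_pct"],
        })
    return pd.DataFrame(rows)


def group_difference_report(assay: pd.DataFrame, analyte: str,
                            group_col: str = "predicted") -> pd.DataFrame:
    """Viable-vs-nonviable mean difference and ANOVA, per variety.

    ``analyte`` names a numeric column (e.g. a peak-area percentage or
    a moisture column). One row per variety with group means +/- sd,
    the difference, and the one-way ANOVA F and p.
    """
    if analyte not in assay.columns:
        raise KeyError(f"assay table lacks analyte column '{analyte}'")
    if group_col not in assay.columns:
        raise KeyError(f"assay table lacks group column '{group_col}'")
    varieties = (assay["variety"].unique() if "variety" in assay.columns
                 else ["all"])
    rows = []
    for variety in varieties:
        sub = (assay if variety == "all"
               else assay[assay["variety"] == variety])
        viable = sub.loc[sub[group_col] == 1, analyte].to_numpy(float)
        nonviable = sub.loc[sub[group_col] == 0, analyte].to_numpy(float)
        if viable.size == 0 or nonviable.size == 0:
            raise ValueError(f"variety {variety}: a group is empty")
        res = one_way_anova(viable, nonviable)
        rows.append({
            "variety": variety,
            "analyte": analyte,
            "viable_mean": viable.mean(),
            "viable_sd": viable.std(ddof=1),
            "nonviable_mean": nonviable.mean(),
            "nonviable_sd": nonviable.std(ddof=1),
            "difference": viable.mean() - nonviable.mean(),
            "ms_between": res.ms_between,
            "ms_within": res.ms_within,
            "f_value": res.f_value,
            "p_value": res.p_value,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
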