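"""Per-case model evaluation and cohort-level statistics.

Given corrected per-case lengths (cm), the pipeline derives the model
columns (inner angle, tangent angle, model arc) from each case's fusiform
length and width, summarises every quantity by body location and overall
(mean, sample SD), and runs the two paired comparisons against the
postoperative incision: designed length vs. post incision and designed
arc vs. post incision (paired two-sided t-test plus Pearson correlation).

The container is a pandas DataFrame in the package's corrected-mode
schema (see :mod:`fusiform.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LOCATIONS",
    "PairedComparison",
    "CohortSummary",
    "compute_model_columns",
    "summarize_by_location",
    "compare_paired",
    "analyze_cohort",
]

#: The five body sites of the study design, in reporting order.
LOCATIONS: Tuple[str, ...] = ("head", "neck", "abdomen", "upper_limbs", "lower_limbs")

#: Quantities summarised per location (column -> human label).
SUMMARY_QUANTITIES: Dict[str, str] = {
    "corrected_width": "Preoperative Width (cm)",
    "corrected_length": "Preoperative Length (cm)",
    "designed_arc": "Preoperative Designed Arc (cm)",
    "model_arc": "Model Arc (cm)",
    "post_incision": "Postoperative Incision (cm)",
    "model_beta": "Apical Inner Angle (degree)",
    "model_alpha": "Apical Tangent Angle / Central Angle (degree)",
}

SIGNIFICANCE_LEVEL = 0.05


def compute_model_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Add model-derived columns to a corrected-mode cohort table.

    For each case the fusiform length and width feed the intersecting-
    circle model, yielding ``model_beta`` (apical inner angle, degrees),
    ``model_alpha`` (apical tangent angle = central angle, degrees) and
    ``model_arc`` (predicted wound length, cm). Vectorised and
    deterministic; returns a copy.
    """
    for col in ("corrected_width", "corrected_length"):
        if col not in records.columns:
            raise CohortValidationError(f"cohort table lacks required column {col!r}")
    w = pd.to_numeric(records["corrected_width"], errors="coerce")
    l = pd.to_numeric(records["corrected_length"], errors="coerce")
    bad = ~((w > 0) & (l > 0) & np.isfinite(w) & np.isfinite(l))
    if bad.any():
        ids = (
            records.loc[bad, "case_id"].tolist()
            if "case_id" in records.columns
            else records.index[bad].tolist()
        )
        raise CohortValidationError(
            f"{int(bad.sum())} record(s) have missing or non-positive "
            f"length/width; case ids: {ids}"
        )
    out = records.copy()
    beta = np.degrees(2.0 * np.arctan2(w.to_numpy(float), l.to_numpy(float)))
    half = np.radians(beta) / 2.0
    out["model_beta"] = beta
    out["model_alpha"] = 2.0 * beta
    out["model_arc"] = (beta / 360.0) * np.pi * (1.0 + 1.0 / np.tan(half) ** 2) * w.to_numpy(float)
    return out


@dataclass(frozen=True)
class PairedComparison:
    """Result of one paired comparison between two cohort columns."""

    x_col: str
    y_col: str
    n: int
    n_dropped: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    mean_difference: float
    pearson_r: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    #: False when the difference vector has zero variance, making the
    #: paired t-test undefined (p_value is None then, never silently 1.0).
    p_defined: bool = True

    @property
    def significant(self) -> Optional[bool]:
        if not self.p_defined:
            return None
        return self.p_value < SIGNIFICANCE_LEVEL

    def as_dict(self) -> Dict[str, object]:
        return {
            "x_col": self.x_col,
            "y_col": self.y_col,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "mean_x": self.mean_x,
            "sd_x": self.sd_x,
            "mean_y": self.mean_y,
            "sd_y": self.sd_y,
            "mean_difference": self.mean_difference,
            "pearson_r": self.pearson_r,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "p_defined": self.p_defined,
            "significant": self.significant,
        }


def compare_paired(x_col: str, y_col: str, records: pd.DataFrame) -> PairedComparison:
    """Paired two-sided t-test and Pearson correlation of two columns.

    Rows with a missing value in either column are dropped listwise (the
    dropped count is logged and reported). The measurements are pre/post
    values of the same incision, so the paired — not two-sample — test is
    the appropriate one. A zero-variance difference vector (e.g. comparing
    a column with itself) leaves the p-value explicitly undefined.
    """
    for col in (x_col, y_col):
        if col not in records.columns:
            raise CohortValidationError(f"cohort table lacks column {col!r}")
    x = pd.to_numeric(records[x_col], errors="coerce")
    y = pd.to_numeric(records[y_col], errors="coerce")
    keep = x.notna() & y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "compare_paired(%s, %s): dropped %d incomplete row(s)", x_col, y_col, n_dropped
        )
    xv = x[keep].to_numpy(float)
    yv = y[keep].to_numpy(float)
    n = xv.size
    if n < 3:
        raise CohortValidationError(
            f"paired comparison of {x_col!r} vs {y_col!r} needs at least 3 complete pairs, got {n}"
        )
    diff = yv - xv
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        r = float("nan")  # correlation undefined for a constant column
    else:
        r = float(stats.pearsonr(xv, yv).statistic)
    if np.std(diff) == 0.0:
        if diff[0] == 0.0:
            # identical columns: the paired test is genuinely undefined
            t_stat, p_val, defined = None, None, False
        else:
            # exactly constant nonzero shift: infinitely strong evidence
            t_stat, p_val, defined = float(np.sign(diff[0]) * np.inf), 0.0, True
    else:
        res = stats.ttest_rel(yv, xv)
        t_stat, p_val, defined = float(res.statistic), float(res.pvalue), True
    return PairedComparison(
        x_col=x_col,
        y_col=y_col,
        n=n,
        n_dropped=n_dropped,
        mean_x=float(np.mean(xv)),
        sd_x=float(np.std(xv, ddof=1)),
        mean_y=float(np.mean(yv)),
        sd_y=float(np.std(yv, ddof=1)),
        mean_difference=float(np.mean(diff)),
        pearson_r=r,
        t_statistic=t_stat,
        p_value=p_val,
        p_defined=defined,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Per-location and overall descriptive statistics plus paired comparisons.

    ``table`` is a tidy DataFrame with one row per (location, quantity)
    pair — location ``"overall"`` pools every case — carrying n, mean and
    sample SD. ``degenerate_groups`` lists (location, n) pairs with a
    single case, whose SD is reported as 0 by convention.
    """

    table: pd.DataFrame
    comparisons: List[PairedComparison]
    n_total: int
    degenerate_groups: List[Tuple[str, int]] = field(default_factory=list)

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_total": self.n_total,
            "by_location": self.table.to_dict(orient="records"),
            "comparisons": [c.as_dict() for c in self.comparisons],
            "degenerate_groups": [list(g) for g in self.degenerate_groups],
        }


def summarize_by_location(records: pd.DataFrame) -> CohortSummary:
    """Mean (sample SD) of every model and clinical quantity, by site and overall.

    SD uses the n-1 convention; a single-case site is flagged degenerate
    and its SD reported as 0. The overall row pools all cases, so its n is
    the sum of the per-location n.
    """
    if len(records) == 0:
        raise CohortValidationError("cannot summarise an empty cohort")
    if "location" not in records.columns:
        raise CohortValidationError("cohort table lacks a 'location' column")
    df = records
    if "model_arc" not in df.columns:
        df = compute_model_columns(df)
    unknown = set(df["location"]) - set(LOCATIONS)
    if unknown:
        raise CohortValidationError(f"unknown location value(s): {sorted(unknown)}")

    rows = []
    degenerate: List[Tuple[str, int]] = []
    groups = [(loc, df[df["location"] == loc]) for loc in LOCATIONS if (df["location"] == loc).any()]
    groups.append(("overall", df))
    for loc, g in groups:
        n = len(g)
        if n == 1 and loc != "overall":
            degenerate.append((loc, n))
        for col, label in SUMMARY_QUANTITIES.items():
            if col not in g.columns:
                continue
            vals = pd.to_numeric(g[col], errors="coerce").dropna().to_numpy(float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {"location": loc, "quantity": label, "column": col, "n": n, "mean": mean, "sd": sd}
            )
    table = pd.DataFrame(rows)

    comparisons = []
    if {"corrected_length", "designed_arc", "post_incision"} <= set(df.columns) and len(df) >= 3:
        comparisons = [
            compare_paired("corrected_length", "post_incision", df),
            compare_paired("designed_arc", "post_incision", df),
        ]
    return CohortSummary(
        table=table, comparisons=comparisons, n_total=len(df), degenerate_groups=degenerate
    )


def analyze_cohort(records: pd.DataFrame) -> CohortSummary:
    """Convenience end-to-end: model columns then the full summary."""
    return summarize_by_location(compute_model_columns(records))
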