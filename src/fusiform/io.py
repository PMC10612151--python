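"""Cohort CSV schemas, validated readers/writers and report rendering.

Two CSV modes share the demographic columns (case_id, age, sex,
location):

* **raw mode** carries the eight photographic values per case
  (measured_length, measured_width, pre_i, pre_s, pre_r, post_i, post_s,
  post_r, all in photo units);
* **corrected mode** carries cm lengths ready for the model
  (corrected_width, corrected_length, designed_arc, post_incision),
  optionally with the derived model columns.

Files are UTF-8, comma-delimited, '.'-decimal; the mode is detected from
the header and mixed headers are rejected. Malformed rows are reported
with their CSV line numbers. Writing uses Python float repr, so a
write -> read round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from typing import List, Tuple

import numpy as np
import pandas as pd

from .cohort import LOCATIONS, CohortSummary
from .errors import CohortSchemaError, CohortValidationError
from .photo import correct_postoperative, correct_preoperative

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_COLUMNS",
    "CORRECTED_COLUMNS",
    "detect_mode",
    "read_cohort",
    "write_cohort",
    "correct_cohort",
    "render_report",
]

DEMOGRAPHIC_COLUMNS: Tuple[str, ...] = ("case_id", "age", "sex", "location")
RAW_VALUE_COLUMNS: Tuple[str, ...] = (
    "measured_length", "measured_width",
    "pre_i", "pre_s", "pre_r", "post_i", "post_s", "post_r",
)
CORRECTED_VALUE_COLUMNS: Tuple[str, ...] = (
    "corrected_width", "corrected_length", "designed_arc", "post_incision",
)
RAW_COLUMNS: Tuple[str, ...] = DEMOGRAPHIC_COLUMNS + RAW_VALUE_COLUMNS
CORRECTED_COLUMNS: Tuple[str, ...] = DEMOGRAPHIC_COLUMNS + CORRECTED_VALUE_COLUMNS


def detect_mode(columns) -> str:
    """Classify a header as ``"raw"`` or ``"corrected"``; reject mixtures."""
    cols = set(columns)
    has_raw = bool(cols & set(RAW_VALUE_COLUMNS))
    has_corr = bool(cols & set(CORRECTED_VALUE_COLUMNS))
    if has_raw and has_corr:
        raise CohortSchemaError("header mixes raw and corrected measurement columns")
    if has_raw:
        missing = set(RAW_COLUMNS) - cols
        if missing:
            raise CohortSchemaError(f"raw-mode header lacks columns: {sorted(missing)}")
        return "raw"
    if has_corr:
        missing = set(CORRECTED_COLUMNS) - cols
        if missing:
            raise CohortSchemaError(f"corrected-mode header lacks columns: {sorted(missing)}")
        return "corrected"
    raise CohortSchemaError(
        "header matches neither schema mode; expected the raw or corrected cohort columns"
    )


def _validate_rows(df: pd.DataFrame, value_cols: Tuple[str, ...], positive_cols: Tuple[str, ...]) -> None:
    """Numeric/positivity/location checks, errors naming 1-based CSV line numbers."""
    problems: List[str] = []
    # CSV line = dataframe position + 2 (header is line 1)
    lines = df.reset_index(drop=True).index + 2
    for col in value_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna().to_numpy() & df[col].notna().to_numpy()
        bad |= df[col].isna().to_numpy()
        for ln in lines[bad]:
            problems.append(f"line {ln}: column {col!r} is missing or not a number")
        df[col] = numeric
    for col in positive_cols:
        nonpos = (df[col] <= 0).to_numpy() & df[col].notna().to_numpy()
        for ln in lines[nonpos]:
            problems.append(f"line {ln}: column {col!r} must be strictly positive")
    if "location" in df.columns:
        bad_loc = ~df["location"].isin(LOCATIONS).to_numpy()
        for ln, val in zip(lines[bad_loc], df.loc[bad_loc, "location"]):
            problems.append(f"line {ln}: unknown location {val!r}")
    if problems:
        raise CohortValidationError(
            f"{len(problems)} malformed row value(s):\n  " + "\n  ".join(problems)
        )


def read_cohort(path, mode: str = "auto") -> Tuple[pd.DataFrame, str]:
    """Read and validate a cohort CSV; returns ``(records, mode)``.

    ``mode`` may be ``"raw"``, ``"corrected"`` or ``"auto"`` (detect from
    the header). Validation failures carry CSV line numbers.
    """
    df = pd.read_csv(
        path,
        dtype={"case_id": str, "sex": str, "location": str},
        encoding="utf-8",
        float_precision="round_trip",
    )
    detected = detect_mode(df.columns)
    if mode != "auto" and mode != detected:
        raise CohortSchemaError(f"expected {mode}-mode file but header is {detected}-mode")
    if detected == "raw":
        _validate_rows(df, RAW_VALUE_COLUMNS, ("pre_s", "pre_r", "post_s", "post_r"))
    else:
        _validate_rows(df, CORRECTED_VALUE_COLUMNS, CORRECTED_VALUE_COLUMNS)
    logger.info("read %d %s-mode records from %s", len(df), detected, path)
    return df, detected


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort CSV at full float precision (lossless round trip)."""
    # shortest round-trip repr, not pandas' default display formatting
    records.to_csv(path, index=False, encoding="utf-8", float_format=lambda v: repr(float(v)))


def correct_cohort(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the photographic corrections to a raw-mode table, row-wise.

    Returns a corrected-mode table with the same demographics. Width,
    length and the designed incision line use the preoperative rule; the
    postoperative incision uses the reference-object altitude correction.
    """
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise CohortSchemaError(f"raw-mode table lacks columns: {sorted(missing)}")
    out = raw[list(DEMOGRAPHIC_COLUMNS)].copy()
    out["corrected_width"] = [
        correct_preoperative(m, s) for m, s in zip(raw["measured_width"], raw["pre_s"])
    ]
    out["corrected_length"] = [
        correct_preoperative(m, s) for m, s in zip(raw["measured_length"], raw["pre_s"])
    ]
    out["designed_arc"] = [
        correct_preoperative(m, s) for m, s in zip(raw["pre_i"], raw["pre_s"])
    ]
    out["post_incision"] = [
        correct_postoperative(m, prer, posts, postr)
        for m, prer, posts, postr in zip(
            raw["post_i"], raw["pre_r"], raw["post_s"], raw["post_r"]
        )
    ]
    return out


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def render_report(summary: CohortSummary) -> Tuple[str, dict]:
    """Render a cohort summary as text tables plus a full-precision dict.

    The text mirrors the descriptive-table layout (quantities as rows,
    body sites plus overall as columns, mean (SD) at 3 decimals); the
    dict is JSON-serialisable and keeps full float precision.
    """
    t = summary.table
    locs = [loc for loc in list(LOCATIONS) + ["overall"] if (t["location"] == loc).any()]
    n_by_loc = {loc: int(t.loc[t["location"] == loc, "n"].iloc[0]) for loc in locs}
    header = ["Quantity"] + [f"{loc} (n={n_by_loc[loc]})" for loc in locs]
    lines = []
    for qty in t["quantity"].unique():
        row = [qty]
        for loc in locs:
            sel = t[(t["location"] == loc) & (t["quantity"] == qty)]
            row.append(
                f"{_fmt(sel['mean'].iloc[0])} ({_fmt(sel['sd'].iloc[0])})" if len(sel) else "-"
            )
        lines.append(row)
    widths = [max(len(r[i]) for r in [header] + lines) for i in range(len(header))]
    fmt_row = lambda r: "  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip()
    text = [
        f"Cohort summary (N = {summary.n_total}), mean (SD)",
        fmt_row(header),
        fmt_row(["-" * w for w in widths]),
        *[fmt_row(r) for r in lines],
    ]
    if summary.degenerate_groups:
        text.append(
            "Degenerate single-case group(s), SD reported as 0: "
            + ", ".join(loc for loc, _ in summary.degenerate_groups)
        )
    for c in summary.comparisons:
        p_txt = "undefined (zero-variance differences)" if not c.p_defined else (
            "< 0.001" if c.p_value < 0.001 else _fmt(c.p_value)
        )
        text += [
            "",
            f"Paired comparison: {c.x_col} vs {c.y_col} (n={c.n}, dropped {c.n_dropped})",
            f"  mean {c.x_col} = {_fmt(c.mean_x)} ({_fmt(c.sd_x)}), "
            f"mean {c.y_col} = {_fmt(c.mean_y)} ({_fmt(c.sd_y)})",
            f"  Pearson r = {_fmt(c.pearson_r)}, paired t-test P {p_txt}",
        ]
    payload = summary.as_dict()
    json.dumps(payload)  # guarantee serialisability before returning
    return "\n".join(text), payload
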