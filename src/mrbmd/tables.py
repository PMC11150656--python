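"""Internal-consistency checks on the published MR result tables.

The package bundles the five published result tables (one per instrument
threshold/outcome combination) as plain TSV.  Every row carries a (beta, SE)
pair together with the derived cells (OR, 95% CI, two-sided p).  Because
OR = exp(beta), CI = exp(beta -/+ z_0.975 * SE), and p = 2(1 - Phi(|beta/SE|))
are pure arithmetic, each derived cell can be recomputed from its (beta, SE)
pair and compared against the printed value — a self-contained consistency
check that needs no external data.

Two comparisons are reported per cell:

* ``*_match`` — strict: the recomputed value, rounded to the printed number
  of digits, equals the printed cell (within half a unit in the last digit).
* ``*_consistent`` — precision-aware: the printed beta and SE are themselves
  rounded to three significant digits, so each derived cell is only
  determined up to an interval; the cell is consistent when that feasible
  interval overlaps the printed cell's own representation interval
  (allowing either round-half or truncation as the display convention).
"""

from __future__ import annotations

import importlib.resources
import math
import re
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z975, summarize_estimate

_DERIVED_COLS = ("or", "ci_low", "ci_high", "pval")


def _ulp(printed: str) -> float:
    """One unit in the last printed digit of a numeric string."""
    s = printed.strip().upper()
    m = re.match(r"^-?(\d+)(?:\.(\d+))?(?:E([+-]?\d+))?$", s)
    if m is None:
        raise ValueError(f"cannot parse printed number {printed!r}")
    decimals = len(m.group(2) or "")
    exp = int(m.group(3) or 0)
    return 10.0 ** (exp - decimals)


def _display_interval(printed: str) -> tuple[float, float]:
    """Values that could display as ``printed`` under rounding *or*
    truncation toward zero: [v - ulp/2, v + ulp] for positive v."""
    v = float(printed)
    u = _ulp(printed)
    if v >= 0:
        return v - u / 2, v + u
    return v - u, v + u / 2


def _input_interval(printed: str) -> tuple[float, float]:
    """Half-ulp interval for a printed input (beta or SE), rounding only."""
    v = float(printed)
    u = _ulp(printed)
    return v - u / 2, v + u / 2


def _feasible_intervals(beta_str: str, se_str: str) -> dict[str, tuple[float, float]]:
    """Range of each derived cell over the beta/SE rounding intervals.

    All four quantities are monotone in beta and SE separately, so the
    extrema sit at corners of the (beta, SE) rectangle.
    """
    b_lo, b_hi = _input_interval(beta_str)
    s_lo, s_hi = _input_interval(se_str)
    s_lo = max(s_lo, 1e-12)
    corners = [(b, s) for b in (b_lo, b_hi) for s in (s_lo, s_hi)]
    out: dict[str, tuple[float, float]] = {}
    for key, fn in (
        ("or", lambda b, s: math.exp(b)),
        ("ci_low", lambda b, s: math.exp(b - Z975 * s)),
        ("ci_high", lambda b, s: math.exp(b + Z975 * s)),
        ("pval", lambda b, s: 2.0 * stats.norm.sf(abs(b) / s)),
    ):
        vals = [fn(b, s) for b, s in corners]
        out[key] = (min(vals), max(vals))
    return out


def load_study_tables() -> pd.DataFrame:
    """The bundled published result tables as a DataFrame.

    Numeric cells are kept as the printed strings (so their precision is
    recoverable) alongside float columns with a ``_value`` suffix.
    """
    ref = importlib.resources.files("mrbmd").joinpath("data/tables/study_tables.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("beta", "se", "pval", "or", "ci_low", "ci_high",
                "steiger_p", "q", "q_pval"):
        df[col + "_value"] = pd.to_numeric(df[col].replace("NA", None))
    df["n_snps"] = df["n_snps"].astype(int)
    df["table"] = df["table"].astype(int)
    return df


def check_tables(table: Optional[int] = None) -> pd.DataFrame:
    """Recompute OR/CI/p from each published (beta, SE) pair.

    Returns one row per table row with the recomputed values plus per-cell
    ``*_match`` (strict) and ``*_consistent`` (precision-aware) flags, and
    row-level ``row_match`` / ``row_consistent`` conjunctions.
    """
    df = load_study_tables()
    if table is not None:
        df = df[df["table"] == table].reset_index(drop=True)
    out_rows = []
    for rec in df.to_dict("records"):
        beta = rec["beta_value"]
        se = rec["se_value"]
        or_, lo, hi, p = summarize_estimate(beta, se)
        computed = {"or": or_, "ci_low": lo, "ci_high": hi, "pval": p}
        feasible = _feasible_intervals(rec["beta"], rec["se"])
        row = {
            "table": rec["table"], "exposure": rec["exposure"],
            "outcome": rec["outcome"], "method": rec["method"],
            "beta": beta, "se": se,
        }
        all_match = all_cons = True
        for col in _DERIVED_COLS:
            printed = float(rec[col + "_value"])
            tol = 0.5 * _ulp(rec[col]) + 1e-12
            ok = abs(computed[col] - printed) <= tol
            d_lo, d_hi = _display_interval(rec[col])
            f_lo, f_hi = feasible[col]
            cons = (f_lo <= d_hi + 1e-12) and (d_lo <= f_hi + 1e-12)
            row[f"{col}_printed"] = printed
            row[f"{col}_computed"] = computed[col]
            row[f"{col}_match"] = ok
            row[f"{col}_consistent"] = cons
            all_match = all_match and ok
            all_cons = all_cons and cons
        row["row_match"] = all_match
        row["row_consistent"] = all_cons
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def check_tables_summary(result: Optional[pd.DataFrame] = None) -> dict:
    """Cell- and row-level agreement summary of :func:`check_tables`."""
    res = check_tables() if result is None else result
    summary = {"n_rows": int(len(res))}
    for col in _DERIVED_COLS:
        summary[f"{col}_match_pct"] = float(100.0 * res[f"{col}_match"].mean())
        summary[f"{col}_consistent_pct"] = float(100.0 * res[f"{col}_consistent"].mean())
    summary["row_match_pct"] = float(100.0 * res["row_match"].mean())
    summary["row_consistent_pct"] = float(100.0 * res["row_consistent"].mean())
    return summary


def q_df_consistency() -> pd.DataFrame:
    """Check q_df = n_snps - 1 for every row that reports a Q statistic."""
    df = load_study_tables()
    sub = df[df["q"] != "NA"].copy()
    sub["q_df_expected"] = sub["n_snps"] - 1
    sub["q_df_match"] = sub["q_df"].astype(int) == sub["q_df_expected"]
    return sub[["table", "exposure", "outcome", "n_snps", "q_df",
                "q_df_expected", "q_df_match"]]
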