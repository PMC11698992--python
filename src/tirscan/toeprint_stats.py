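"""Toeprint (primer-extension) quantification from band-intensity tables.

A toeprint lane carries two intensities in arbitrary densitometry units:
T, the main reverse-transcriptase arrest band (~+16/+17 of the start
codon), and RT, the read-through band.  The toeprint statistic is the
percentage of T relative to T + RT.  Within each mRNA group, signals can
be normalized so the mean of a reference condition (monophosphorylated
mRNA by default) equals exactly 100%.  Condition summaries report the mean
and sample standard deviation (n-1 denominator; NA for a single lane).

Input is the table, not gel images — densitometry is upstream of this
module.  No background subtraction is applied.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ValidationError

REQUIRED_COLUMNS = ("lane_id", "condition", "mrna", "T", "RT")
DEFAULT_REFERENCE_CONDITION = "monophosphate"


def read_lane_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"lane table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return validate_lane_table(df)


def validate_lane_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"lane table missing column(s) {sorted(missing)}")
    if df.empty:
        raise InputError("lane table has no rows")
    for col in ("T", "RT"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "lane_id"].tolist()
            raise ValidationError(f"non-numeric {col} in lane(s) {bad}")
        if (vals < 0).any():
            bad = df.loc[vals < 0, "lane_id"].tolist()
            raise ValidationError(f"negative {col} in lane(s) {bad}")
        df = df.assign(**{col: vals.astype(float)})
    if df["lane_id"].duplicated().any():
        raise ValidationError("duplicate lane ids")
    return df


def toeprint_percent(T: float, RT: float) -> float:
    """100 * T / (T + RT)."""
    if T < 0 or RT < 0:
        raise ValidationError("band intensities must be non-negative")
    if T + RT == 0:
        raise ValidationError("unquantifiable lane: T + RT == 0")
    # ratio first: keeps the result <= 100 exactly when RT == 0
    return 100.0 * (T / (T + RT))


def add_percent(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``percent_toeprint`` column; errors on unquantifiable lanes."""
    total = df["T"] + df["RT"]
    if (total == 0).any():
        bad = df.loc[total == 0, "lane_id"].tolist()
        raise ValidationError(f"unquantifiable lane(s) with T + RT == 0: {bad}")
    return df.assign(percent_toeprint=100.0 * (df["T"] / total))


def normalize_to_reference(
    df: pd.DataFrame, reference_condition: str = DEFAULT_REFERENCE_CONDITION
) -> pd.DataFrame:
    """Scale ``percent_toeprint`` within each mRNA group so the reference
    condition's mean maps to exactly 100."""
    if "percent_toeprint" not in df.columns:
        df = add_percent(df)
    out = df.copy()
    out["normalized_percent"] = np.nan
    for mrna, grp in df.groupby("mrna"):
        ref = grp.loc[grp["condition"] == reference_condition, "percent_toeprint"]
        if ref.empty:
            raise ValidationError(
                f"mRNA group {mrna!r} has no lane in reference condition "
                f"{reference_condition!r}"
            )
        ref_mean = ref.mean()
        if ref_mean == 0:
            raise ValidationError(f"mRNA group {mrna!r}: reference mean is zero")
        out.loc[grp.index, "normalized_percent"] = (
            100.0 * grp["percent_toeprint"] / ref_mean
        )
    return out


def summarize_conditions(
    df: pd.DataFrame,
    value: str = "percent_toeprint",
    by: Sequence[str] = ("mrna", "condition"),
) -> pd.DataFrame:
    """Per-group mean, sample SD (NaN when n == 1) and n."""
    if value not in df.columns:
        df = add_percent(df)
    g = df.groupby(list(by))[value]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return out


def compare_conditions(
    df: pd.DataFrame,
    mrna: str,
    condition_a: str,
    condition_b: str,
    value: str = "percent_toeprint",
    equal_var: bool = False,
) -> dict[str, float]:
    """Two-sample t-test (Welch by default) between two conditions of one
    mRNA group; a convenience, not a core statistic."""
    if value not in df.columns:
        df = add_percent(df)
    sub = df[df["mrna"] == mrna]
    a = sub.loc[sub["condition"] == condition_a, value].to_numpy()
    b = sub.loc[sub["condition"] == condition_b, value].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two lanes per condition for a t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "n_a": len(a), "n_b": len(b)}


def write_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
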