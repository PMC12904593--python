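"""CSV ingestion, result serialization and calendar-aware summaries.

Wide CSV: first column is the time index (reals or ISO dates), remaining
columns are one unit each.  Long CSV: columns (unit, time, value).  Dates are
mapped to day-of-year rescaled to [0, 1] for smoothing, with the original
calendar retained on the grid for monthly-weight summaries.
"""

from __future__ import annotations

import datetime as _dt
import json

import numpy as np
import pandas as pd

from . import __version__
from .curves import RawCurveSet, TimeGrid
from .exceptions import InvalidArgumentError
from .ranking import RankingResult
from .segmentation import SegmentationResult
from .ranking import SegmentWeights

__all__ = [
    "read_wide_csv",
    "read_long_csv",
    "write_ranking_csv",
    "write_diagnostics_json",
    "monthly_weights",
    "DEFAULT_NA_TOKENS",
]

DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")


def _parse_time_column(col: pd.Series):
    """Return (numeric time points, dates-or-None)."""
    try:
        pts = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
        return pts, None
    except (ValueError, TypeError):
        pass
    dates = pd.to_datetime(col, errors="raise")
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    span = 366.0 if dates.dt.is_leap_year.any() else 365.0
    pts = (doy - 1.0) / (span - 1.0)
    # multi-year spans: fall back to days since the first date
    if np.any(np.diff(pts) <= 0):
        pts = (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float)
        pts = pts / max(pts.max(), 1.0)
    return pts, tuple(d.date() for d in dates)


def read_wide_csv(path, time_column: str | None = None,
                  na_tokens=DEFAULT_NA_TOKENS) -> RawCurveSet:
    """Wide table -> RawCurveSet (columns = curves, rows = grid)."""
    df = pd.read_csv(path, comment="#", na_values=list(na_tokens),
                     keep_default_na=False, skip_blank_lines=True)
    if df.shape[1] < 3:
        raise InvalidArgumentError("wide CSV needs a time column and >= 2 unit columns")
    tcol = time_column or df.columns[0]
    if tcol not in df.columns:
        raise InvalidArgumentError(f"time column {tcol!r} not found")
    unit_cols = [c for c in df.columns if c != tcol]
    if len(set(unit_cols)) != len(unit_cols):
        raise InvalidArgumentError("duplicate unit column names")
    pts, dates = _parse_time_column(df[tcol])
    if np.any(np.diff(pts) <= 0):
        bad = int(np.argmax(np.diff(pts) <= 0)) + 2
        raise InvalidArgumentError(
            f"time column must be strictly increasing (violated near row {bad})"
        )
    values = df[unit_cols].to_numpy(dtype=float).T  # (N, T)
    grid = TimeGrid(pts, dates=dates)
    return RawCurveSet(grid=grid, values=values, unit_names=unit_cols)


def read_long_csv(path, unit_col="unit", time_col="time", value_col="value",
                  na_tokens=DEFAULT_NA_TOKENS) -> RawCurveSet:
    """Long table (unit, time, value) -> RawCurveSet."""
    df = pd.read_csv(path, comment="#", na_values=list(na_tokens),
                     keep_default_na=False)
    for c in (unit_col, time_col, value_col):
        if c not in df.columns:
            raise InvalidArgumentError(f"column {c!r} not found in long CSV")
    wide = df.pivot_table(index=time_col, columns=unit_col, values=value_col,
                          aggfunc="first", dropna=False)
    wide = wide.sort_index()
    pts, dates = _parse_time_column(pd.Series(wide.index))
    grid = TimeGrid(pts, dates=dates)
    return RawCurveSet(grid=grid, values=wide.to_numpy(dtype=float).T,
                       unit_names=[str(c) for c in wide.columns])


def _header_comment(config_repr: str) -> str:
    return f"# fpowa {__version__} | {config_repr}\n"


def write_ranking_csv(result: RankingResult, path, config_repr: str = ""):
    names = result.unit_names or [f"unit_{i+1}" for i in range(result.scores.size)]
    df = pd.DataFrame({
        "unit": names,
        "score": result.scores,
        "rank": result.ranking,
    }).sort_values("rank")
    with open(path, "w") as fh:
        fh.write(_header_comment(f"method={result.method} {config_repr}".strip()))
        df.to_csv(fh, index=False, float_format="%.17g")


def write_diagnostics_json(result: RankingResult, path):
    diag = {}
    seg = result.diagnostics.get("segmentation")
    if isinstance(seg, SegmentationResult):
        diag["segmentation"] = seg.to_dict()
    w = result.diagnostics.get("segment_weights")
    if w is not None:
        diag["segment_weights"] = [float(x) for x in w.weights]
        diag["segment_mean_depths"] = [float(x) for x in w.mean_depths]
    payload = {
        "version": __version__,
        "method": result.method,
        "unit_names": result.unit_names,
        "scores": [float(x) for x in result.scores],
        "ranking": [float(x) for x in result.ranking],
        "diagnostics": diag,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def monthly_weights(seg: SegmentationResult, weights: SegmentWeights,
                    dates) -> dict[int, float]:
    """Per-month pollution-contribution shares.

    Each segment's weight is spread over calendar months in proportion to
    the number of that segment's days falling in the month; shares are
    renormalized to sum to one over the months present.
    """
    if dates is None:
        raise InvalidArgumentError("monthly weights require a calendar grid")
    dates = [d if isinstance(d, _dt.date) else pd.Timestamp(d).date() for d in dates]
    shares: dict[int, float] = {}
    for (i0, i1), w in zip(seg.segments, weights.weights):
        seg_dates = dates[i0 : i1 + 1]
        total_days = len(seg_dates)
        for d in seg_dates:
            shares[d.month] = shares.get(d.month, 0.0) + w / total_days
    total = sum(shares.values())
    return {m: v / total for m, v in sorted(shares.items())}
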