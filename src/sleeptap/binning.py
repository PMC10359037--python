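"""Convert raw interaction events into daily 96-bin activity sequences.

Each calendar day is represented by 96 binary values, one per 15-minute bin
(bin ``k`` covers ``[15k, 15(k+1))`` minutes after local midnight). A bin is
active iff at least one interaction event starts inside it. Day-level data
adequacy requires activity in at least 4 distinct clock hours; patient-level
adequacy requires at least 28 adequate days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "BIN_COLUMNS",
    "N_BINS",
    "MIN_UNIQUE_ACTIVE_HOURS",
    "MIN_ADEQUATE_DAYS",
    "bin_events",
    "filter_patients",
    "window_days",
]

logger = logging.getLogger(__name__)

N_BINS = 96
#: Wide-format column names for the 96 bins, b0..b95.
BIN_COLUMNS = [f"b{k}" for k in range(N_BINS)]
#: A day is adequate iff activity spans at least this many distinct hours.
MIN_UNIQUE_ACTIVE_HOURS = 4
#: A patient is retained iff they have at least this many adequate days.
MIN_ADEQUATE_DAYS = 28


def unique_active_hours(bins: np.ndarray) -> np.ndarray:
    """Number of distinct clock hours with >=1 active bin, per row.

    ``bins`` is an ``(n, 96)`` (or ``(96,)``) binary array.
    """
    arr = np.atleast_2d(np.asarray(bins))
    by_hour = arr.reshape(arr.shape[0], 24, 4).any(axis=2)
    out = by_hour.sum(axis=1).astype(int)
    return out if np.asarray(bins).ndim == 2 else out[0]


def bin_events(events: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an event stream into per-day 96-bin activity rows.

    Parameters
    ----------
    events
        Columns ``patient_id``, ``timestamp`` (datetime-like or ISO-8601
        strings, local naive time), arbitrary extra columns ignored. Input
        order is irrelevant.

    Returns
    -------
    DataFrame with columns ``patient_id, date, b0..b95, unique_active_hours,
    adequate``, one row per calendar day inside each patient's first-to-last
    event span (days with no events appear as all-zero rows and are
    inadequate by the distinct-hours rule).

    Rows whose timestamp cannot be parsed are skipped; their count is logged.
    """
    if len(events) == 0:
        return _empty_days_frame()

    ts = pd.to_datetime(events["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna()
    if bad.any():
        logger.warning("bin_events: skipped %d rows with unparseable timestamps", int(bad.sum()))
    pid = np.asarray(events["patient_id"])[~bad.to_numpy()]
    ts = ts[~bad]
    if len(ts) == 0:
        return _empty_days_frame()

    day = ts.dt.normalize().to_numpy()
    bin_idx = (ts.dt.hour * 4 + ts.dt.minute // 15).to_numpy()

    frames = []
    order = np.argsort(pid, kind="stable")
    pid, day, bin_idx = pid[order], day[order], bin_idx[order]
    boundaries = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1], True])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        p_days, p_bins = day[lo:hi], bin_idx[lo:hi]
        first, last = p_days.min(), p_days.max()
        all_days = pd.date_range(first, last, freq="D")
        day_pos = ((p_days - first) / np.timedelta64(1, "D")).astype(int)
        mat = np.zeros((len(all_days), N_BINS), dtype=np.int8)
        mat[day_pos, p_bins] = 1  # duplicate (day,bin) hits OR together
        df = pd.DataFrame(mat, columns=BIN_COLUMNS)
        df.insert(0, "date", all_days)
        df.insert(0, "patient_id", pid[lo])
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    uah = unique_active_hours(out[BIN_COLUMNS].to_numpy())
    out["unique_active_hours"] = uah
    out["adequate"] = uah >= MIN_UNIQUE_ACTIVE_HOURS
    return out


def _empty_days_frame() -> pd.DataFrame:
    cols = ["patient_id", "date", *BIN_COLUMNS, "unique_active_hours", "adequate"]
    return pd.DataFrame(columns=cols)


def filter_patients(days: pd.DataFrame, min_adequate_days: int = MIN_ADEQUATE_DAYS) -> set:
    """Patients with at least ``min_adequate_days`` adequate days (any days,
    not necessarily consecutive)."""
    if len(days) == 0:
        return set()
    counts = days.groupby("patient_id")["adequate"].sum()
    return set(counts.index[counts >= min_adequate_days])


def window_days(days: pd.DataFrame, window_len: int = 30) -> pd.DataFrame:
    """Assign each patient-day to a consecutive non-overlapping window.

    Windows are anchored at each patient's first observed day. A window is
    valid iff it spans the full ``window_len`` days *and* at least half of
    them (>=15 for a 30-day window) are adequate; trailing partial windows
    are invalid.

    Returns the input with ``window_index`` and ``window_valid`` columns
    added.
    """
    if len(days) == 0:
        out = days.copy()
        out["window_index"] = pd.Series(dtype=int)
        out["window_valid"] = pd.Series(dtype=bool)
        return out
    out = days.sort_values(["patient_id", "date"]).reset_index(drop=True)
    date = pd.to_datetime(out["date"])
    first = date.groupby(out["patient_id"]).transform("min")
    day_offset = (date - first).dt.days.to_numpy()
    out["window_index"] = day_offset // window_len

    # window validity: full length and >= ceil(window_len/2) adequate days
    min_adequate = (window_len + 1) // 2
    grp = out.groupby(["patient_id", "window_index"])
    n_adequate = grp["adequate"].transform("sum")
    # a trailing window is partial iff the patient's span ends before the
    # window's last scheduled day
    span_days = date.groupby(out["patient_id"]).transform("max")
    full_len = ((out["window_index"] + 1) * window_len - 1) <= (span_days - first).dt.days
    out["window_valid"] = (n_adequate >= min_adequate) & full_len
    return out
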