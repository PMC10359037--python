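"""Behavioral sleep measures from daily 96-bin activity sequences.

Four measures are derived:

* **ISP** (inferred sleep period): the longest run of inactive 15-min bins
  within one calendar day, scanned from 00:00 to 23:59 (non-circular, so an
  individual day's sleep that crosses midnight is truncated at the boundary;
  this known bias is accepted, not corrected).
* **ESP** (expected sleep period): for each non-overlapping 30-day window,
  the per-bin fraction of adequate days with activity is binarized by a
  deterministic 1-D two-means clustering, and the longest *circular* run of
  inactive bins is the habitual sleep window (circularity lets a nocturnal
  period that spans midnight form a single run).
* **Overlap percentage**: fraction of a day's ISP bins that fall inside the
  window's ESP — a regularity proxy for sleep timing, deliberately naive to
  duration (a short ISP fully inside the ESP scores 100%).
* **Disruptions**: number of active bins inside the ESP on a given day — a
  proxy for nocturnal wakefulness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BIN_COLUMNS, N_BINS

__all__ = [
    "RunSpan",
    "compute_isp",
    "binarize_window",
    "compute_esp",
    "overlap_percentage",
    "count_disruptions",
    "compute_esp_windows",
    "compute_daily_measures",
]


@dataclass(frozen=True)
class RunSpan:
    """A run of consecutive bins, possibly wrapping past bin 95 into bin 0."""

    start_bin: int
    length: int
    circular: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start_bin < N_BINS:
            raise ValueError("start_bin must be in [0, 96)")
        if not 1 <= self.length <= N_BINS:
            raise ValueError("length must be in [1, 96]")
        if not self.circular and self.start_bin + self.length > N_BINS:
            raise ValueError("non-circular span exceeds bin 95")

    def bins(self) -> np.ndarray:
        """Member bin indices, modulo 96."""
        return (self.start_bin + np.arange(self.length)) % N_BINS

    def mask(self) -> np.ndarray:
        out = np.zeros(N_BINS, dtype=bool)
        out[self.bins()] = True
        return out

    @property
    def duration_h(self) -> float:
        return self.length * 0.25


def longest_zero_runs(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row longest run of zeros in an ``(n, 96)`` binary matrix.

    Returns ``(start, length)`` int arrays; rows without any zero get
    ``(-1, 0)``. Ties are broken by the earliest start. Runs are
    non-circular (each row is scanned left to right).
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=np.int8))
    n, width = mat.shape
    padded = np.ones((n, width + 2), dtype=np.int8)
    padded[:, 1:-1] = mat
    flat = padded.ravel()
    zeros = flat == 0
    run_start = np.flatnonzero(zeros & ~np.r_[False, zeros[:-1]])
    run_end = np.flatnonzero(zeros & ~np.r_[zeros[1:], False])
    starts = np.full(n, -1, dtype=int)
    lengths = np.zeros(n, dtype=int)
    if run_start.size:
        length = run_end - run_start + 1
        row = run_start // (width + 2)
        col = run_start % (width + 2) - 1
        # stable first-max per row: order by (row, -length, col)
        order = np.lexsort((col, -length, row))
        row, col, length = row[order], col[order], length[order]
        first = np.r_[True, row[1:] != row[:-1]]
        starts[row[first]] = col[first]
        lengths[row[first]] = length[first]
    return starts, lengths


def compute_isp(bins: np.ndarray) -> RunSpan | None:
    """Inferred sleep period of one day: longest maximal run of inactive
    bins, non-circular, earliest on ties; ``None`` if every bin is active."""
    start, length = longest_zero_runs(np.asarray(bins).reshape(1, N_BINS))
    if length[0] == 0:
        return None
    return RunSpan(int(start[0]), int(length[0]), circular=False)


def _longest_circular_ones_run(seq: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest circular run of 1s, earliest on ties.

    Assumes at least one 1 and at least one 0.
    """
    dbl = np.concatenate([seq, seq])
    start, length = longest_zero_runs((1 - dbl).reshape(1, -1))
    # longest_zero_runs on the doubled inverted sequence finds the earliest
    # longest ones-run with start possibly in [0, 192); because there is a 0
    # somewhere, no run reaches length 96 twice, and the earliest longest run
    # always starts in [0, 96).
    s, ln = int(start[0]), int(length[0])
    return s % N_BINS, min(ln, N_BINS)


def compute_esp(binarized: np.ndarray) -> RunSpan | None:
    """Expected sleep period: longest circular run of 0s in a binarized
    96-bin profile.

    Ties are broken by the run whose start comes earliest when scanning
    forward from the end of the longest active run. Returns ``None`` if no
    bin is 0; an all-0 profile yields the degenerate full-day span.
    """
    seq = np.asarray(binarized, dtype=np.int8).reshape(N_BINS)
    if not (seq == 0).any():
        return None
    if not (seq == 1).any():
        return RunSpan(0, N_BINS, circular=True)
    a_start, a_len = _longest_circular_ones_run(seq)
    origin = (a_start + a_len) % N_BINS  # first bin after the active anchor
    rotated = np.roll(seq, -origin)  # rotated[-1] == 1, so no wrap inside
    start, length = longest_zero_runs(rotated.reshape(1, N_BINS))
    s = (int(start[0]) + origin) % N_BINS
    ln = int(length[0])
    return RunSpan(s, ln, circular=s + ln > N_BINS)


def binarize_window(fractions: np.ndarray) -> np.ndarray | None:
    """Binarize a 96-bin activity-fraction profile by two-means clustering.

    The k-means objective with two clusters on scalar data is minimised by a
    threshold in sorted order, so the global optimum is found exactly by
    scanning all splits of the sorted profile (prefix sums; ties in the
    objective broken toward the smaller low cluster, which makes the result
    deterministic). The lower-mean cluster maps to 0 (inactive), the other
    to 1.

    Returns ``None`` (no habitual sleep window derivable) when all 96 values
    are identical.
    """
    x = np.asarray(fractions, dtype=float).reshape(N_BINS)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("activity fractions must lie in [0, 1]")
    sx = np.sort(x)
    if sx[0] == sx[-1]:
        return None
    n = sx.size
    s = np.cumsum(sx)
    ss = np.cumsum(sx * sx)
    k = np.arange(1, n)  # low cluster = sx[:k]
    wcss_low = ss[k - 1] - s[k - 1] ** 2 / k
    wcss_high = (ss[-1] - ss[k - 1]) - (s[-1] - s[k - 1]) ** 2 / (n - k)
    wcss = wcss_low + wcss_high
    wcss[sx[k - 1] == sx[k]] = np.inf  # equal values cannot straddle a split
    best = int(np.argmin(wcss))  # first minimum: smallest low cluster on ties
    threshold = 0.5 * (sx[best] + sx[best + 1])
    return (x > threshold).astype(np.int8)


def overlap_percentage(isp: RunSpan, esp: RunSpan) -> float:
    """Fraction of the day's ISP bins that fall inside the ESP (in [0, 1])."""
    isp_mask, esp_mask = isp.mask(), esp.mask()
    return float((isp_mask & esp_mask).sum()) / isp.length


def count_disruptions(bins: np.ndarray, esp: RunSpan) -> int:
    """Number of the day's active bins inside the ESP."""
    day = np.asarray(bins).reshape(N_BINS).astype(bool)
    return int((day & esp.mask()).sum())


# ---------------------------------------------------------------------------
# Frame-level pipeline


def compute_esp_windows(days: pd.DataFrame) -> pd.DataFrame:
    """Per-(patient, window) ESP profile and span.

    ``days`` must carry ``window_index`` / ``window_valid`` columns (see
    :func:`sleeptap.binning.window_days`). The activity fraction of bin k is
    the share of the window's *adequate* days with bin k active; inadequate
    days carry no usable signal. Invalid windows and windows whose profile
    cannot be binarized yield no ESP (``valid`` False).

    Returns columns ``patient_id, window_index, valid, esp_start, esp_len,
    esp_duration_h`` plus ``f0..f95`` activity fractions and ``z0..z95``
    binarized values (NaN/-1 where undefined).
    """
    records = []
    frac_cols = [f"f{k}" for k in range(N_BINS)]
    bin_cols = [f"z{k}" for k in range(N_BINS)]
    for (pid, widx), grp in days.groupby(["patient_id", "window_index"], sort=True):
        window_valid = bool(grp["window_valid"].iloc[0])
        adequate = grp[grp["adequate"].astype(bool)]
        rec = {
            "patient_id": pid,
            "window_index": widx,
            "valid": False,
            "esp_start": -1,
            "esp_len": 0,
            "esp_duration_h": np.nan,
        }
        if window_valid and len(adequate) > 0:
            frac = adequate[BIN_COLUMNS].to_numpy(dtype=float).mean(axis=0)
            rec.update(dict(zip(frac_cols, frac)))
            z = binarize_window(frac)
            if z is not None:
                esp = compute_esp(z)
                if esp is not None:
                    rec.update(dict(zip(bin_cols, z.astype(int))))
                    rec.update(
                        valid=True,
                        esp_start=esp.start_bin,
                        esp_len=esp.length,
                        esp_duration_h=esp.duration_h,
                    )
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    for c in frac_cols + bin_cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[["patient_id", "window_index", "valid", "esp_start", "esp_len",
                "esp_duration_h", *frac_cols, *bin_cols]]


def compute_daily_measures(days: pd.DataFrame, esp_windows: pd.DataFrame) -> pd.DataFrame:
    """Per-day ISP, overlap fraction, disruption count and ESP duration.

    A day is *viable* iff it is adequate, its window has a valid ESP, and an
    ISP exists; overlap and disruptions are reported only for viable days.

    Returns columns ``patient_id, date, window_index, isp_start, isp_len,
    overlap, disruptions, esp_duration_h, viable``.
    """
    days = days.reset_index(drop=True)
    mat = days[BIN_COLUMNS].to_numpy(dtype=np.int8)
    isp_start, isp_len = longest_zero_runs(mat)

    esp = esp_windows.set_index(["patient_id", "window_index"])
    key = pd.MultiIndex.from_frame(days[["patient_id", "window_index"]])
    esp_row = esp.reindex(key)
    esp_valid = esp_row["valid"].fillna(False).to_numpy(dtype=bool)
    esp_start = esp_row["esp_start"].fillna(-1).to_numpy(dtype=int)
    esp_len = esp_row["esp_len"].fillna(0).to_numpy(dtype=int)
    esp_dur = esp_row["esp_duration_h"].to_numpy(dtype=float)

    cols = np.arange(N_BINS)
    # circular ESP membership mask per day
    rel = (cols[None, :] - esp_start[:, None]) % N_BINS
    esp_mask = (rel < esp_len[:, None]) & esp_valid[:, None]
    isp_mask = (cols[None, :] >= isp_start[:, None]) & (
        cols[None, :] < (isp_start + isp_len)[:, None]
    )

    viable = days["adequate"].to_numpy(dtype=bool) & esp_valid & (isp_len > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap = (isp_mask & esp_mask).sum(axis=1) / np.where(isp_len > 0, isp_len, 1)
    disruptions = ((mat.astype(bool)) & esp_mask).sum(axis=1)

    out = days[["patient_id", "date", "window_index"]].copy()
    out["isp_start"] = isp_start
    out["isp_len"] = isp_len
    out["overlap"] = np.where(viable, overlap, np.nan)
    out["disruptions"] = np.where(viable, disruptions.astype(float), np.nan)
    out["esp_duration_h"] = np.where(viable, esp_dur, np.nan)
    out["viable"] = viable
    return out
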