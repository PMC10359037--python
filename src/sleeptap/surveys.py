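"""Symptom-survey scoring and model-ready observation assembly.

Surveys are DSM-5 Level-1 style items on a 0-4 Likert scale, grouped into
three domains: sleep disturbance (1 item), depression (2 items: anhedonia,
depressed mood) and anxiety (3 items: nervousness, panic, avoidance). A
domain score is the mean of its items and is missing whenever any item is
missing — partial surveys contribute only their complete domains.

Each survey occasion is linked to the mean of the behavioral measures over
the 14 calendar days ending the day *before* the survey (the instrument's
two-week recall window; same-day behavior postdates part of it). Occasions
with fewer than 3 viable behavioral days are dropped. Aggregates are then
split into a between-person component (the person's mean over retained
occasions) and a within-person deviation, so the multilevel model can
separate stable differences between people from changes within a person.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DOMAIN_ITEMS",
    "DOMAINS",
    "MEASURE_NAMES",
    "score_surveys",
    "aggregate_presurvey",
    "decompose_within_between",
    "weekday_weekend_summary",
]

logger = logging.getLogger(__name__)

DOMAIN_ITEMS: dict[str, tuple[str, ...]] = {
    "sleep": ("sleep",),
    "depression": ("anhedonia", "depressed_mood"),
    "anxiety": ("nervous", "panic", "avoidance"),
}
DOMAINS = tuple(DOMAIN_ITEMS)
#: Behavioral measures aggregated per survey, in (overlap, disruption,
#: duration) order: overlap is a 0-1 fraction, disruption a bin count,
#: duration in hours.
MEASURE_NAMES = ("overlap", "disruptions", "esp_duration_h")
AGG_WINDOW_DAYS = 14
MIN_VIABLE_DAYS = 3


def score_surveys(items: pd.DataFrame) -> pd.DataFrame:
    """Score item-level responses into per-domain scores.

    ``items`` has columns ``patient_id, date, item_id, response``. Responses
    outside {0..4} are rejected (count logged); a domain with any missing or
    rejected item is absent for that occasion.

    Returns one row per (patient_id, date) with columns ``sleep, depression,
    anxiety`` (floats in [0, 4], NaN where incomplete).
    """
    df = items.copy()
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    ok = df["response"].isin([0, 1, 2, 3, 4])
    if (~ok).any():
        logger.warning("score_surveys: rejected %d out-of-range item responses", int((~ok).sum()))
    df = df[ok]
    wide = df.pivot_table(
        index=["patient_id", "date"], columns="item_id", values="response", aggfunc="first"
    )
    out = pd.DataFrame(index=wide.index)
    for domain, cols in DOMAIN_ITEMS.items():
        present = [c for c in cols if c in wide.columns]
        if len(present) < len(cols):
            out[domain] = np.nan
            continue
        block = wide[list(cols)]
        score = block.mean(axis=1)
        score[block.isna().any(axis=1)] = np.nan
        out[domain] = score
    return out.reset_index()


def aggregate_presurvey(
    measures: pd.DataFrame,
    surveys: pd.DataFrame,
    window_days: int = AGG_WINDOW_DAYS,
    min_viable: int = MIN_VIABLE_DAYS,
) -> pd.DataFrame:
    """Attach pre-survey behavioral aggregates to each survey occasion.

    For each survey, the aggregate of each measure is its mean over *viable*
    days in the ``window_days`` calendar days ending the day before the
    survey date. Occasions with fewer than ``min_viable`` viable days are
    dropped.

    Returns the survey rows (with their domain scores) plus ``agg_overlap,
    agg_disruptions, agg_esp_duration_h, n_viable_days``.
    """
    meas = measures[measures["viable"]].copy()
    meas["date"] = pd.to_datetime(meas["date"])
    out_rows = []
    surveys = surveys.copy()
    surveys["date"] = pd.to_datetime(surveys["date"])
    by_patient = {pid: grp for pid, grp in meas.groupby("patient_id")}
    for _, srow in surveys.iterrows():
        grp = by_patient.get(srow["patient_id"])
        if grp is None:
            continue
        end = srow["date"]  # exclusive
        start = end - pd.Timedelta(days=window_days)
        win = grp[(grp["date"] >= start) & (grp["date"] < end)]
        if len(win) < min_viable:
            continue
        rec = srow.to_dict()
        for m in MEASURE_NAMES:
            rec[f"agg_{m}"] = float(win[m].mean())
        rec["n_viable_days"] = len(win)
        out_rows.append(rec)
    cols = list(surveys.columns) + [f"agg_{m}" for m in MEASURE_NAMES] + ["n_viable_days"]
    return pd.DataFrame(out_rows, columns=cols)


def decompose_within_between(rows: pd.DataFrame) -> pd.DataFrame:
    """Split each aggregate into between-person and within-person parts.

    ``bp_x`` is the person's mean of ``agg_x`` over their retained occasions;
    ``wp_x = agg_x - bp_x``, so within-person deviations average to zero for
    every person and ``wp_x + bp_x`` reconstructs the aggregate exactly.
    """
    out = rows.copy()
    short = {"overlap": "overlap", "disruptions": "disruption", "esp_duration_h": "duration"}
    for m, name in short.items():
        agg = out[f"agg_{m}"].astype(float)
        bp = agg.groupby(out["patient_id"]).transform("mean")
        out[f"bp_{name}"] = bp
        out[f"wp_{name}"] = agg - bp
    _check_units(out)
    return out


def _check_units(rows: pd.DataFrame) -> None:
    """Guard against scale mix-ups (overlap must be a 0-1 fraction, etc.)."""
    if len(rows) == 0:
        return
    ov = rows["agg_overlap"].to_numpy(dtype=float)
    if np.nanmin(ov) < 0 or np.nanmax(ov) > 1:
        raise ValueError("overlap aggregates must be fractions in [0, 1]")
    if np.nanmin(rows["agg_disruptions"].to_numpy(dtype=float)) < 0:
        raise ValueError("disruption aggregates must be non-negative counts")
    dur = rows["agg_esp_duration_h"].to_numpy(dtype=float)
    if np.nanmin(dur) <= 0 or np.nanmax(dur) > 24:
        raise ValueError("ESP durations must be hours in (0, 24]")


def weekday_weekend_summary(
    measures: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Mean weekday vs weekend overlap and disruptions per age decade.

    Weekend days are Saturday and Sunday. Age groups are decades
    (20-29, ..., 70-79). Groups with no viable days on either day type are
    omitted.
    """
    meas = measures[measures["viable"]].copy()
    meas["date"] = pd.to_datetime(meas["date"])
    meas = meas.merge(demographics[["patient_id", "age"]], on="patient_id")
    meas["weekend"] = meas["date"].dt.dayofweek >= 5
    meas["age_group"] = (meas["age"] // 10 * 10).astype(int).astype(str) + "s"
    rows = []
    for group, grp in meas.groupby("age_group"):
        wd, we = grp[~grp["weekend"]], grp[grp["weekend"]]
        if len(wd) == 0 or len(we) == 0:
            continue
        rows.append(
            {
                "age_group": group,
                "n_weekday": len(wd),
                "n_weekend": len(we),
                "weekday_overlap": wd["overlap"].mean(),
                "weekend_overlap": we["overlap"].mean(),
                "overlap_diff": we["overlap"].mean() - wd["overlap"].mean(),
                "weekday_disruptions": wd["disruptions"].mean(),
                "weekend_disruptions": we["disruptions"].mean(),
                "disruptions_diff": we["disruptions"].mean() - wd["disruptions"].mean(),
            }
        )
    return pd.DataFrame(rows)
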