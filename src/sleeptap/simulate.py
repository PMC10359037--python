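"""Synthetic cohort generator with known ground truth.

Generation is two-phase. Phase one draws per-person sleep phenotypes
(habitual onset, duration, day-to-day onset jitter, nocturnal disruption
rate) and emits a continuous event stream: waking 15-min bins are active with
a fixed probability, bins inside each night's realized sleep interval are
inactive except for Poisson-placed disruption bins, and whole days go missing
at random. Sleep intervals are placed on a continuous timeline and may cross
midnight; slicing into calendar days is left to the binning stage.

Phase two runs the *actual* measurement pipeline (binning, windowing, sleep
measures, pre-survey aggregation, within/between decomposition) on those
events and generates survey outcomes from the two-level linear model on the
pipeline-computed predictors, so the generating model and the fitted model
share predictors exactly and parameter recovery is unbiased in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import surveys as survey_mod
from .config import GeneratorConfig
from .pipeline import measures_from_events

__all__ = [
    "EVENT_TYPES",
    "generate_demographics",
    "generate_events",
    "generate_domain_scores",
    "generate_surveys",
    "simulate_cohort",
    "SimulatedCohort",
]

EVENT_TYPES = ("tap", "scroll", "type", "app_change", "screen_on")
#: Day 0 of every synthetic observation window (a Monday).
BASE_DATE = np.datetime64("2022-01-03")
#: First survey is scheduled once a full 30-day window plus a 14-day recall
#: window can exist.
FIRST_SURVEY_DAY = 44

_MS_PER_BIN = 15 * 60 * 1000

# Cohort marginals of a large adult virtual-behavioral-health population.
_GENDER = (("female", 0.736), ("male", 0.251), ("unspecified", 0.013))
_DIAGNOSIS = (
    ("major_depression", 0.406),
    ("bipolar", 0.200),
    ("personality_disorder", 0.034),
    ("schizophrenia", 0.065),
    ("other", 0.295),
)
_ETHNICITY = (
    ("white", 0.489),
    ("black", 0.105),
    ("hispanic_latino", 0.034),
    ("multiracial", 0.021),
    ("other", 0.008),
    (None, 0.343),
)
_AGE_MEAN, _AGE_SD = 56.7, 11.3
_P_RURAL = 0.553


def _patient_ids(n: int) -> np.ndarray:
    return np.array([f"p{i:05d}" for i in range(n)])


def _choice(rng: np.random.Generator, table, n: int) -> np.ndarray:
    labels = np.array([t[0] for t in table], dtype=object)
    probs = np.array([t[1] for t in table], dtype=float)
    return labels[rng.choice(len(labels), size=n, p=probs / probs.sum())]


def generate_demographics(config: GeneratorConfig) -> pd.DataFrame:
    """Draw demographics with cohort-like marginals.

    Ages are uncentered years; gender/location enter the model as indicator
    columns with female/urban reference; primary-diagnosis indicators are
    0/1; ethnicity is generated with substantial missingness (and is expected
    to be excluded from confounder screening on that ground).
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_patients
    age = np.clip(np.round(rng.normal(_AGE_MEAN, _AGE_SD, n)), 18, 79).astype(int)
    gender = _choice(rng, _GENDER, n)
    diagnosis = _choice(rng, _DIAGNOSIS, n)
    ethnicity = _choice(rng, _ETHNICITY, n)
    rural = rng.random(n) < _P_RURAL
    df = pd.DataFrame(
        {
            "patient_id": _patient_ids(n),
            "age": age,
            "gender": gender,
            "location": np.where(rural, "rural", "urban"),
            "diagnosis": diagnosis,
            "ethnicity": ethnicity,
        }
    )
    df["gender_male"] = (df["gender"] == "male").astype(int)
    df["location_rural"] = rural.astype(int)
    df["dx_majordep"] = (df["diagnosis"] == "major_depression").astype(int)
    df["dx_personality"] = (df["diagnosis"] == "personality_disorder").astype(int)
    df["dx_schizophrenia"] = (df["diagnosis"] == "schizophrenia").astype(int)
    return df


def generate_events(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the event stream and the per-patient truth records.

    Returns ``(events, truth)``. Events have columns ``patient_id,
    timestamp, event_type`` (naive local timestamps at millisecond
    resolution, strictly inside each patient's observation window). Truth
    holds each patient's sleep phenotype and the random effects used for
    outcome generation (columns ``u0_<domain>..u3_<domain>``).
    """
    rng = np.random.default_rng([config.seed, 202])
    n, n_days = config.n_patients, config.days_per_patient
    pids = _patient_ids(n)

    onset = rng.normal(config.sleep_onset_mean_h, config.sleep_onset_sd_h, n)
    duration = np.clip(
        rng.normal(config.sleep_duration_mean_h, config.sleep_duration_sd_h, n), 2.0, 16.0
    )
    if config.onset_jitter_sd_h > 0:
        jitter_sd = rng.gamma(shape=2.0, scale=config.onset_jitter_sd_h / 2.0, size=n)
    else:
        jitter_sd = np.zeros(n)
    if config.disruption_rate > 0:
        disr_rate = rng.gamma(shape=4.0, scale=config.disruption_rate / 4.0, size=n)
    else:
        disr_rate = np.zeros(n)

    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "sleep_onset_h": onset,
            "sleep_duration_h": duration,
            "onset_jitter_sd_h": jitter_sd,
            "disruption_rate": disr_rate,
        }
    )
    for domain in survey_mod.DOMAINS:
        for j, vname in enumerate(
            ("var_intercept", "var_wp_overlap", "var_wp_disruption", "var_wp_duration")
        ):
            sd = np.sqrt(config.variance(vname))
            truth[f"u{j}_{domain}"] = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    total_bins = 96 * n_days
    all_pid, all_ts, all_type = [], [], []
    for i in range(n):
        asleep = np.zeros(total_bins, dtype=bool)
        disrupted = np.zeros(total_bins, dtype=bool)
        # nights indexed by the day on which they start; day -1 covers the
        # first morning
        for d in range(-1, n_days):
            onset_h = onset[i] + rng.normal(0.0, jitter_sd[i]) if jitter_sd[i] > 0 else onset[i]
            if config.weekend_onset_shift_h:
                # BASE_DATE is a Monday; nights starting Fri (d%7==4) or Sat
                weekday = d % 7
                if weekday in (4, 5):
                    onset_h += config.weekend_onset_shift_h
            start_bin = int(round((24.0 * d + onset_h) * 4.0))
            end_bin = start_bin + int(round(duration[i] * 4.0))
            lo, hi = max(start_bin, 0), min(end_bin, total_bins)
            if hi <= lo:
                continue
            asleep[lo:hi] = True
            if disr_rate[i] > 0:
                k = rng.poisson(disr_rate[i])
                k = min(k, hi - lo)
                if k > 0:
                    picks = rng.choice(hi - lo, size=k, replace=False) + lo
                    disrupted[picks] = True

        active = (~asleep) & (rng.random(total_bins) < config.daytime_activity_prob)
        active |= disrupted
        if config.missing_day_prob > 0:
            missing = rng.random(n_days) < config.missing_day_prob
            active &= ~np.repeat(missing, 96)

        bins_on = np.flatnonzero(active)
        if bins_on.size == 0:
            continue
        offset_ms = rng.integers(0, _MS_PER_BIN, size=bins_on.size)
        ts = (
            BASE_DATE.astype("datetime64[ms]")
            + (bins_on * _MS_PER_BIN + offset_ms).astype("timedelta64[ms]")
        )
        all_pid.append(np.repeat(pids[i], bins_on.size))
        all_ts.append(ts)
        all_type.append(np.array(EVENT_TYPES, dtype=object)[
            rng.integers(0, len(EVENT_TYPES), size=bins_on.size)
        ])

    if all_pid:
        events = pd.DataFrame(
            {
                "patient_id": np.concatenate(all_pid),
                "timestamp": pd.DatetimeIndex(np.concatenate(all_ts)),
                "event_type": np.concatenate(all_type),
            }
        )
    else:
        events = pd.DataFrame(columns=["patient_id", "timestamp", "event_type"])
    return events, truth


def _survey_day_offsets(config: GeneratorConfig) -> np.ndarray:
    return np.arange(FIRST_SURVEY_DAY, config.days_per_patient, config.survey_interval_days)


def _items_from_score(score: float, items: tuple[str, ...]) -> dict[str, int]:
    """Item responses whose mean equals ``score`` rounded to the domain's
    attainable resolution (1/n_items)."""
    n = len(items)
    total = int(np.floor(score * n + 0.5))
    total = min(max(total, 0), 4 * n)
    base, extra = divmod(total, n)
    return {item: base + (1 if j < extra else 0) for j, item in enumerate(items)}


def generate_domain_scores(
    measures: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Continuous domain outcomes from pipeline-computed measures.

    For each scheduled survey with at least 3 viable prior days, each
    domain's outcome is the two-level linear predictor (fixed effects on the
    within/between-decomposed 14-day aggregates and demographics, plus that
    domain's person random effects and a normal residual), clamped to the
    instrument's [0, 4] range.

    Surveys with insufficient prior data are still emitted (flagged via the
    ``insufficient_history`` column) with outcomes generated from the
    intercept and random intercept only; the downstream pipeline drops them.

    Returns ``patient_id, date, domain, score, insufficient_history``.
    """
    rng = np.random.default_rng([config.seed, 303])
    offsets = _survey_day_offsets(config)
    pids = truth["patient_id"].to_numpy()
    dates = BASE_DATE + offsets.astype("timedelta64[D]")
    schedule = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, len(offsets)),
            "date": pd.to_datetime(np.tile(dates, len(pids))),
        }
    )
    agg = survey_mod.aggregate_presurvey(measures, schedule)
    rows = survey_mod.decompose_within_between(agg) if len(agg) else agg
    key = set(zip(rows["patient_id"], rows["date"])) if len(rows) else set()
    rows = rows.set_index(["patient_id", "date"]) if len(rows) else rows

    demo = demographics.set_index("patient_id")
    tr = truth.set_index("patient_id")
    g = config.gamma
    resid_sd = np.sqrt(config.resid_variance)

    out = []
    for pid in pids:
        drow = demo.loc[pid]
        trow = tr.loc[pid]
        demo_part = (
            g("age") * drow["age"]
            + g("gender_male") * drow["gender_male"]
            + g("dx_majordep") * drow["dx_majordep"]
            + g("dx_personality") * drow["dx_personality"]
            + g("dx_schizophrenia") * drow["dx_schizophrenia"]
            + g("location_rural") * drow["location_rural"]
        )
        for date in dates:
            date = pd.Timestamp(date)
            has_history = (pid, date) in key
            for domain in survey_mod.DOMAINS:
                u0 = trow[f"u0_{domain}"]
                if has_history:
                    r = rows.loc[(pid, date)]
                    lp = (
                        g("intercept")
                        + (g("wp_overlap") + trow[f"u1_{domain}"]) * r["wp_overlap"]
                        + (g("wp_disruption") + trow[f"u2_{domain}"]) * r["wp_disruption"]
                        + (g("wp_duration") + trow[f"u3_{domain}"]) * r["wp_duration"]
                        + g("bp_overlap") * r["bp_overlap"]
                        + g("bp_disruption") * r["bp_disruption"]
                        + g("bp_duration") * r["bp_duration"]
                        + demo_part
                        + u0
                    )
                else:
                    lp = g("intercept") + u0
                score = lp + (rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0)
                score = min(max(score, 0.0), 4.0)
                out.append(
                    {
                        "patient_id": pid,
                        "date": date,
                        "domain": domain,
                        "score": score,
                        "insufficient_history": not has_history,
                    }
                )
    return pd.DataFrame(out)


def generate_surveys(
    measures: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Item-level survey responses (see :func:`generate_domain_scores`).

    Each domain's continuous score is converted to item responses whose mean
    equals the score rounded to the domain's attainable resolution
    (1/n_items). Returns long-format items: ``patient_id, date, item_id,
    response, insufficient_history``.
    """
    scores = generate_domain_scores(measures, truth, config, demographics)
    out = []
    for rec in scores.itertuples(index=False):
        item_names = survey_mod.DOMAIN_ITEMS[rec.domain]
        for item, resp in _items_from_score(rec.score, item_names).items():
            out.append(
                {
                    "patient_id": rec.patient_id,
                    "date": rec.date,
                    "item_id": item,
                    "response": resp,
                    "insufficient_history": rec.insufficient_history,
                }
            )
    return pd.DataFrame(out)


@dataclass
class SimulatedCohort:
    """All artifacts of one synthetic cohort."""

    config: GeneratorConfig
    events: pd.DataFrame
    truth: pd.DataFrame
    demographics: pd.DataFrame
    days: pd.DataFrame
    esp_windows: pd.DataFrame
    measures: pd.DataFrame
    survey_items: pd.DataFrame


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Run the full two-phase generation: events, pipeline measures, surveys."""
    demographics = generate_demographics(config)
    events, truth = generate_events(config)
    days, esp_windows, measures = measures_from_events(events)
    survey_items = generate_surveys(measures, truth, config, demographics)
    return SimulatedCohort(
        config=config,
        events=events,
        truth=truth,
        demographics=demographics,
        days=days,
        esp_windows=esp_windows,
        measures=measures,
        survey_items=survey_items,
    )
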