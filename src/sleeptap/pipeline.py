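"""End-to-end convenience pipeline: events -> measures -> model-ready rows."""

from __future__ import annotations

import pandas as pd

from . import binning, sleep
from .model import ModelFit, cooks_filter, fit_model
from .surveys import aggregate_presurvey, decompose_within_between, score_surveys

__all__ = [
    "measures_from_events",
    "observations_from_measures",
    "fit_outcome_pipeline",
    "replicate_parameter_recovery",
]


def measures_from_events(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bin events, drop patients with fewer than 28 adequate days, assign
    30-day windows, derive ESP profiles and daily measures.
    Returns ``(days, esp_windows, daily_measures)``."""
    days = binning.bin_events(events)
    included = binning.filter_patients(days)
    days = days[days["patient_id"].isin(included)].reset_index(drop=True)
    days = binning.window_days(days)
    esp_windows = sleep.compute_esp_windows(days)
    measures = sleep.compute_daily_measures(days, esp_windows)
    return days, esp_windows, measures


def observations_from_measures(
    measures: pd.DataFrame,
    survey_items: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score surveys, attach 14-day pre-survey aggregates, decompose into
    within/between components, and merge demographics.

    Returns one row per retained survey occasion with the three domain
    scores, the ``wp_*``/``bp_*`` predictors, and demographic columns.
    """
    scored = score_surveys(survey_items)
    rows = aggregate_presurvey(measures, scored)
    rows = decompose_within_between(rows)
    if demographics is not None:
        rows = rows.merge(demographics, on="patient_id", how="left")
    return rows


def fit_outcome_pipeline(
    rows: pd.DataFrame, outcome: str = "sleep", cooks_multiplier: float = 4.0
) -> ModelFit:
    """Influence filtering followed by the mixed-model fit for one outcome."""
    retained, _ = cooks_filter(rows, outcome, multiplier=cooks_multiplier)
    return fit_model(retained, outcome, n_removed=len(rows) - len(retained))


def replicate_parameter_recovery(
    n_replicates: int = 20,
    outcome: str = "sleep",
    seed: int = 1,
    **config_updates,
) -> pd.DataFrame:
    """Repeated end-to-end recovery runs under the default study conditions.

    Each replicate generates a fresh cohort (events -> binning -> sleep
    measures -> survey aggregation -> within/between decomposition), applies
    the Cook's-distance filter and fits the two-level model. Returns one row
    per replicate with each term's estimate and standard error plus the
    removed fraction and variance components.
    """
    from .config import GeneratorConfig
    from .simulate import simulate_cohort

    records = []
    for rep in range(n_replicates):
        cfg = GeneratorConfig(
            seed=(seed * 100003 + rep) % 2**31, **config_updates
        )
        cohort = simulate_cohort(cfg)
        rows = observations_from_measures(
            cohort.measures, cohort.survey_items, cohort.demographics
        )
        retained, removed_frac = cooks_filter(rows, outcome)
        fit = fit_model(retained, outcome, n_removed=len(rows) - len(retained))
        rec = {"replicate": rep, "removed_fraction": removed_frac,
               "n_obs": fit.n_obs, "n_patients": fit.n_patients,
               "converged": fit.converged}
        for term, row in fit.fixed_effects.iterrows():
            rec[f"est_{term}"] = row["estimate"]
            rec[f"se_{term}"] = row["se"]
        rec.update(fit.variances)
        records.append(rec)
    return pd.DataFrame(records)
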