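"""Configuration for the synthetic smartphone-interaction cohort generator.

The generator emulates a virtual-behavioral-health cohort: per-patient
circadian event streams (tap/scroll/type/app-change/screen-on interactions),
periodic DSM-5 Level-1 style symptom surveys, and demographics. Survey
outcomes are produced from the same two-level linear model the package fits,
so every downstream stage has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "GeneratorConfig",
    "DEFAULT_FIXED_EFFECTS",
    "DEFAULT_RE_VARIANCES",
    "FIXED_EFFECT_NAMES",
    "RE_VARIANCE_NAMES",
]

#: Fixed-effect names of the two-level model, in design order.
#: ``wp_*`` are occasion-level (within-person) deviations, ``bp_*`` are
#: person-level means; demographics are person-level covariates.
FIXED_EFFECT_NAMES: tuple[str, ...] = (
    "intercept",
    "wp_overlap",
    "wp_disruption",
    "wp_duration",
    "bp_overlap",
    "bp_disruption",
    "bp_duration",
    "age",
    "gender_male",
    "dx_majordep",
    "dx_personality",
    "dx_schizophrenia",
    "location_rural",
)

RE_VARIANCE_NAMES: tuple[str, ...] = (
    "var_intercept",
    "var_wp_overlap",
    "var_wp_disruption",
    "var_wp_duration",
)

#: Sleep-disturbance fixed effects reported for a ~2,300-patient clinical
#: cohort; overlap enters as a 0-1 fraction, disruption as a bin count,
#: duration in hours, age uncentered in years.
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 2.49,
    "wp_overlap": -0.21,
    "wp_disruption": 0.045,
    "wp_duration": -0.03,
    "bp_overlap": -0.90,
    "bp_disruption": 0.098,
    "bp_duration": 0.015,
    "age": -0.0044,
    "gender_male": -0.0012,
    "dx_majordep": -0.0052,
    "dx_personality": 0.11,
    "dx_schizophrenia": -0.40,
    "location_rural": -0.065,
}

#: Matching random-effect variances (intercept and the three within-person
#: slopes) and residual variance for the sleep-disturbance outcome.
DEFAULT_RE_VARIANCES: dict[str, float] = {
    "var_intercept": 0.97,
    "var_wp_overlap": 0.28,
    "var_wp_disruption": 0.0012,
    "var_wp_duration": 0.0082,
}
DEFAULT_RESID_VARIANCE: float = 0.67


class ConfigurationError(ValueError):
    """Raised when generator settings are out of their valid range."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_patients
        Number of patients to simulate.
    days_per_patient
        Observation span per patient, in days (constant across patients).
    survey_interval_days
        Days between consecutive symptom surveys (30 or 60 in routine care).
    sleep_onset_mean_h, sleep_onset_sd_h
        Population mean/SD of habitual sleep onset, hours after midnight
        (values > 24 place onset after the following midnight; 23.0 means
        11 pm, so sleep routinely crosses the day boundary).
    sleep_duration_mean_h, sleep_duration_sd_h
        Population mean/SD of habitual nightly sleep duration in hours.
    onset_jitter_sd_h
        Population mean of the person-specific day-to-day onset jitter SD
        (hours). Person SDs are drawn from a Gamma(shape=2) with this mean,
        so sleep *regularity* varies between people.
    disruption_rate
        Population mean of the person-specific expected number of active
        15-min bins per night inside the sleep interval (nocturnal phone
        checks). Person rates are drawn from a Gamma(shape=4) with this mean.
    daytime_activity_prob
        Probability that a waking 15-min bin contains at least one
        interaction.
    missing_day_prob
        Probability that a calendar day yields no events at all (phone off,
        no data transmitted).
    weekend_onset_shift_h
        Optional additive shift of sleep onset on Friday/Saturday nights.
    fixed_effects, re_variances, resid_variance
        Parameters of the outcome-generating two-level model; see
        :data:`FIXED_EFFECT_NAMES` / :data:`RE_VARIANCE_NAMES`.
    seed
        Seed for all randomness; a fixed seed reproduces the cohort exactly.
    """

    n_patients: int = 300
    days_per_patient: int = 270
    survey_interval_days: int = 30
    sleep_onset_mean_h: float = 23.0
    sleep_onset_sd_h: float = 1.0
    sleep_duration_mean_h: float = 8.4
    sleep_duration_sd_h: float = 1.0
    onset_jitter_sd_h: float = 1.0
    disruption_rate: float = 4.85
    daytime_activity_prob: float = 0.6
    missing_day_prob: float = 0.05
    weekend_onset_shift_h: float = 0.0
    fixed_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    re_variances: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RE_VARIANCES)
    )
    resid_variance: float = DEFAULT_RESID_VARIANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.days_per_patient < 1:
            raise ConfigurationError("days_per_patient must be >= 1")
        if self.survey_interval_days < 1:
            raise ConfigurationError("survey_interval_days must be >= 1")
        for name in ("daytime_activity_prob", "missing_day_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.disruption_rate < 0:
            raise ConfigurationError("disruption_rate must be >= 0")
        if self.onset_jitter_sd_h < 0:
            raise ConfigurationError("onset_jitter_sd_h must be >= 0")
        if self.sleep_duration_mean_h <= 0 or self.sleep_duration_mean_h > 24:
            raise ConfigurationError("sleep_duration_mean_h must be in (0, 24]")
        if self.sleep_onset_sd_h < 0 or self.sleep_duration_sd_h < 0:
            raise ConfigurationError("sleep onset/duration SDs must be >= 0")
        unknown = set(self.fixed_effects) - set(FIXED_EFFECT_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown fixed-effect names: {sorted(unknown)}")
        unknown = set(self.re_variances) - set(RE_VARIANCE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown variance names: {sorted(unknown)}")
        if any(v < 0 for v in self.re_variances.values()):
            raise ConfigurationError("random-effect variances must be >= 0")
        if self.resid_variance < 0:
            raise ConfigurationError("resid_variance must be >= 0")

    def gamma(self, name: str) -> float:
        """Fixed-effect value, defaulting to 0 for unset coefficients."""
        return float(self.fixed_effects.get(name, 0.0))

    def variance(self, name: str) -> float:
        return float(self.re_variances.get(name, 0.0))

    def with_(self, **updates) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)
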