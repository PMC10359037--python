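"""Weekday-versus-weekend contrast of the daily sleep measures by age group.

With a weekend onset shift in the generator, weekend nights start later than
the habitual 30-day window expects, so weekend overlap percentages drop.
"""

from sleeptap import GeneratorConfig, simulate_cohort, weekday_weekend_summary

cfg = GeneratorConfig(
    n_patients=60, days_per_patient=120, weekend_onset_shift_h=1.0, seed=19
)
cohort = simulate_cohort(cfg)
table = weekday_weekend_summary(cohort.measures, cohort.demographics)
print(table.round(3).to_string(index=False))
print("\noverlap_diff < 0 means weekend nights align less with the habitual window")
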