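"""Generate a small synthetic cohort and summarize its sleep measures.

The generator draws per-person sleep phenotypes (habitual onset, duration,
day-to-day regularity, nocturnal disruption rate), emits a smartphone
interaction event stream, and the pipeline converts it to daily measures:
the inferred sleep period (ISP), the 30-day expected sleep period (ESP),
the daily overlap percentage and the disruption count.
"""

from sleeptap import GeneratorConfig, simulate_cohort

cfg = GeneratorConfig(n_patients=40, days_per_patient=120, seed=7)
cohort = simulate_cohort(cfg)

viable = cohort.measures[cohort.measures["viable"]]
print(f"patients: {cfg.n_patients}, events: {len(cohort.events):,}")
print(f"viable patient-days: {len(viable):,}")
print(f"mean overlap:        {viable['overlap'].mean():.2f} "
      "(fraction of the daily ISP inside the habitual ESP; 1.0 = perfectly regular)")
print(f"mean disruptions:    {viable['disruptions'].mean():.2f} "
      "(active 15-min bins inside the ESP per night)")
print(f"mean ESP duration:   {viable['esp_duration_h'].mean():.2f} h "
      "(length of the habitual nightly inactivity window)")
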