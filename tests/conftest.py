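import numpy as np
import pandas as pd
import pytest

from sleeptap import GeneratorConfig, observations_from_measures, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests."""
    cfg = GeneratorConfig(n_patients=30, days_per_patient=120, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_observations(small_cohort):
    c = small_cohort
    return observations_from_measures(c.measures, c.survey_items, c.demographics)


def brute_longest_zero_run(seq):
    """Oracle: scan all maximal zero-runs, return (start, length) of the
    longest (earliest on ties), or None."""
    seq = list(seq)
    best = None
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == 0:
            j = i
            while j < n and seq[j] == 0:
                j += 1
            if best is None or (j - i) > best[1]:
                best = (i, j - i)
            i = j
        else:
            i += 1
    return best


def brute_circular_longest_zero_len(seq):
    """Oracle: length of the longest circular zero-run (None if no zeros)."""
    seq = list(seq)
    if 0 not in seq:
        return None
    if 1 not in seq:
        return len(seq)
    runs = []
    dbl = seq + seq
    i, n = 0, len(dbl)
    while i < n:
        if dbl[i] == 0:
            j = i
            while j < n and dbl[j] == 0:
                j += 1
            if i < len(seq):
                runs.append(min(j - i, len(seq)))
            i = j
        else:
            i += 1
    return max(runs)


def brute_two_means_partition(x):
    """Oracle: optimal 1-D 2-cluster partition by exhausting all sorted-order
    split thresholds, minimizing within-cluster sum of squares.

    Returns a binary label array (1 = upper cluster) or None if degenerate.
    """
    x = np.asarray(x, dtype=float)
    sx = np.sort(x)
    if sx[0] == sx[-1]:
        return None
    best = (np.inf, None)
    for k in range(1, len(sx)):
        if sx[k - 1] == sx[k]:
            continue
        lo, hi = sx[:k], sx[k:]
        w = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if w < best[0]:
            best = (w, 0.5 * (sx[k - 1] + sx[k]))
    return (x > best[1]).astype(int)


def synthetic_observation_rows(
    n_patients=60,
    n_occasions=6,
    gamma=None,
    var_u0=0.3,
    var_e=0.4,
    seed=0,
    outcome="sleep",
):
    """Model-ready observation rows drawn directly from the two-level model
    (no event simulation) for fast model/bootstrap unit tests."""
    from sleeptap.config import DEFAULT_FIXED_EFFECTS

    g = {k: 0.0 for k in DEFAULT_FIXED_EFFECTS}
    if gamma:
        g.update(gamma)
    rng = np.random.default_rng(seed)
    pid = np.repeat([f"s{i:04d}" for i in range(n_patients)], n_occasions)
    bp_ov = np.clip(rng.normal(0.75, 0.15, n_patients), 0.05, 1.0)
    bp_di = rng.gamma(4.0, 4.85 / 4.0, n_patients)
    bp_du = np.clip(rng.normal(8.4, 1.2, n_patients), 4, 12)
    u0 = rng.normal(0, np.sqrt(var_u0), n_patients)
    age = np.clip(np.round(rng.normal(56.7, 11.3, n_patients)), 18, 79)
    male = (rng.random(n_patients) < 0.25).astype(int)
    rural = (rng.random(n_patients) < 0.55).astype(int)
    dx = rng.choice(4, n_patients, p=[0.40, 0.05, 0.07, 0.48])

    def center(w):
        return w - w.reshape(n_patients, n_occasions).mean(axis=1).repeat(n_occasions)

    wp_ov = center(rng.normal(0, 0.08, n_patients * n_occasions))
    wp_di = center(rng.normal(0, 1.2, n_patients * n_occasions))
    wp_du = center(rng.normal(0, 0.6, n_patients * n_occasions))

    rep = lambda a: np.repeat(a, n_occasions)
    lp = (
        g["intercept"]
        + g["wp_overlap"] * wp_ov
        + g["wp_disruption"] * wp_di
        + g["wp_duration"] * wp_du
        + g["bp_overlap"] * rep(bp_ov)
        + g["bp_disruption"] * rep(bp_di)
        + g["bp_duration"] * rep(bp_du)
        + g["age"] * rep(age)
        + g["gender_male"] * rep(male)
        + g["dx_majordep"] * rep((dx == 0).astype(int))
        + g["dx_personality"] * rep((dx == 1).astype(int))
        + g["dx_schizophrenia"] * rep((dx == 2).astype(int))
        + g["location_rural"] * rep(rural)
        + rep(u0)
    )
    y = lp + rng.normal(0, np.sqrt(var_e), n_patients * n_occasions)
    return pd.DataFrame(
        {
            "patient_id": pid,
            outcome: y,
            "wp_overlap": wp_ov,
            "wp_disruption": wp_di,
            "wp_duration": wp_du,
            "bp_overlap": rep(bp_ov),
            "bp_disruption": rep(bp_di),
            "bp_duration": rep(bp_du),
            "agg_overlap": rep(bp_ov) + wp_ov,
            "agg_disruptions": rep(bp_di) + wp_di,
            "agg_esp_duration_h": rep(bp_du) + wp_du,
            "age": rep(age),
            "gender_male": rep(male),
            "dx_majordep": rep((dx == 0).astype(int)),
            "dx_personality": rep((dx == 1).astype(int)),
            "dx_schizophrenia": rep((dx == 2).astype(int)),
            "location_rural": rep(rural),
        }
    )
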