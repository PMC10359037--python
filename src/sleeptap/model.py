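"""Two-level association models between sleep measures and symptom scores.

The outcome (one symptom-domain score per survey occasion) is regressed on
the within-person (occasion deviation) and between-person (person mean)
components of the three behavioral measures, plus person-level demographics:

    y_it = b0_i + b1_i wp.Overlap_it + b2_i wp.Disruption_it
                + b3_i wp.Duration_it + e_it
    b0_i = g00 + g01 bp.Overlap_i + g02 bp.Disruption_i + g03 bp.Duration_i
               + (demographics) + u0_i
    bk_i = gk0 + uk_i            (k = 1..3)

with mutually independent zero-mean normal random effects u0..u3 and residual
e. Estimation is restricted maximum likelihood via statsmodels MixedLM
(random intercept, independent variance components for the three
within-person slopes); inference on fixed effects is Wald-z.

Before fitting, observations with outsized influence on a pooled
ordinary-least-squares version of the model (no demographics) are removed by
a Cook's-distance rule, and a Kolmogorov-Smirnov check verifies the cleaning
did not distort the variable distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "BEHAVIOR_PREDICTORS",
    "DEFAULT_DEMOGRAPHICS",
    "ModelFit",
    "screen_demographics",
    "cooks_filter",
    "fit_model",
    "ks_compare",
]

logger = logging.getLogger(__name__)

#: The six behavioral predictors, in design order.
BEHAVIOR_PREDICTORS = (
    "wp_overlap",
    "wp_disruption",
    "wp_duration",
    "bp_overlap",
    "bp_disruption",
    "bp_duration",
)
#: Person-level covariates of the full model.
DEFAULT_DEMOGRAPHICS = (
    "age",
    "gender_male",
    "dx_majordep",
    "dx_personality",
    "dx_schizophrenia",
    "location_rural",
)
_WP_PREDICTORS = BEHAVIOR_PREDICTORS[:3]


class _GuardedMixedLM(sm.MixedLM):
    """MixedLM whose likelihood tolerates boundary evaluations.

    The REML profiling inverts the random-effect covariance, so an optimizer
    line search that lands exactly on a zero variance raises a linear-algebra
    error and aborts the whole fit. Nudging the packed (square-root scale)
    variance parameters off exact zero keeps the objective finite there
    without affecting any interior solution.
    """

    _BOUNDARY_EPS = 1e-6
    _PARAM_CAP = 1e4
    _PENALTY = -1e12

    def loglike(self, params, profile_fe=True):
        try:
            value = super().loglike(params, profile_fe=profile_fe)
        except np.linalg.LinAlgError:
            safe = np.clip(
                np.array(params, dtype=float, copy=True),
                -self._PARAM_CAP,
                self._PARAM_CAP,
            )
            tiny = np.abs(safe) < self._BOUNDARY_EPS
            safe[tiny] = np.where(
                np.signbit(safe[tiny]), -self._BOUNDARY_EPS, self._BOUNDARY_EPS
            )
            try:
                value = super().loglike(safe, profile_fe=profile_fe)
            except np.linalg.LinAlgError:
                return self._PENALTY
        return value if np.isfinite(value) else self._PENALTY

    def get_fe_params(self, cov_re, vcomp, tol=1e-10):
        try:
            return super().get_fe_params(cov_re, vcomp, tol=tol)
        except np.linalg.LinAlgError:
            cov = np.array(cov_re, dtype=float, copy=True)
            k = cov.shape[0] if cov.ndim == 2 else 0
            if k:
                idx = np.arange(k)
                cov[idx, idx] = np.maximum(cov[idx, idx], self._BOUNDARY_EPS**2)
            vc = np.maximum(np.asarray(vcomp, dtype=float), self._BOUNDARY_EPS**2)
            return super().get_fe_params(cov, vc, tol=tol)

    def score(self, params, profile_fe=True):
        try:
            grad = super().score(params, profile_fe=profile_fe)
        except np.linalg.LinAlgError:
            safe = np.clip(
                np.array(params, dtype=float, copy=True),
                -self._PARAM_CAP,
                self._PARAM_CAP,
            )
            tiny = np.abs(safe) < self._BOUNDARY_EPS
            safe[tiny] = np.where(
                np.signbit(safe[tiny]), -self._BOUNDARY_EPS, self._BOUNDARY_EPS
            )
            try:
                grad = super().score(safe, profile_fe=profile_fe)
            except np.linalg.LinAlgError:
                return np.zeros(np.asarray(params).shape)
        return np.where(np.isfinite(grad), grad, 0.0)


@dataclass
class ModelFit:
    """Estimates for one outcome's two-level model."""

    outcome: str
    fixed_effects: pd.DataFrame  # index: term; estimate, se, ci_low, ci_high, pvalue
    variances: dict[str, float]  # var_intercept, var_wp_*, var_residual
    n_obs: int
    n_patients: int
    n_removed: int = 0
    converged: bool = True
    dropped_slopes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def removed_fraction(self) -> float:
        total = self.n_obs + self.n_removed
        return self.n_removed / total if total else 0.0

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "pvalue"])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fixed_effects": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.fixed_effects.iterrows()
            },
            "variances": {k: float(v) for k, v in self.variances.items()},
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "n_removed": self.n_removed,
            "removed_fraction": self.removed_fraction,
            "converged": self.converged,
            "dropped_slopes": list(self.dropped_slopes),
        }


def _complete_rows(rows: pd.DataFrame, outcome: str, predictors) -> pd.DataFrame:
    cols = [outcome, *predictors]
    return rows.dropna(subset=[c for c in cols if c in rows.columns])


def screen_demographics(
    rows: pd.DataFrame,
    demographics: tuple[str, ...],
    outcomes: tuple[str, ...] = ("sleep", "depression", "anxiety"),
    alpha: float = 0.05,
    max_missing: float = 0.30,
) -> pd.DataFrame:
    """Screen candidate person-level confounders one at a time.

    Each demographic is regressed against each outcome in a random-intercept
    model; a variable is flagged for inclusion iff it is significant
    (p < ``alpha``) with at least one outcome. Variables missing in more than
    ``max_missing`` of observations, or constant, are excluded before testing.

    Categorical variables are expanded to indicator columns (first level as
    reference); the variable's p-value per outcome is the smallest Wald
    p-value across its indicators.

    Returns one row per (demographic, outcome) with ``estimate, pvalue,
    tested, reason`` plus an ``included`` flag constant within demographic.
    """
    results = []
    for var in demographics:
        col = rows[var]
        missing_frac = col.isna().mean()
        reason = ""
        if missing_frac > max_missing:
            reason = f"missingness {missing_frac:.0%} > {max_missing:.0%}"
        elif col.dropna().nunique() < 2:
            reason = "constant"
            logger.warning("screen_demographics: %s is constant; excluded", var)
        for outcome in outcomes:
            rec = {
                "demographic": var,
                "outcome": outcome,
                "estimate": np.nan,
                "pvalue": np.nan,
                "tested": reason == "",
                "reason": reason,
            }
            if reason == "":
                sub = rows[[outcome, var, "patient_id"]].dropna()
                if pd.api.types.is_numeric_dtype(sub[var]):
                    X = sub[[var]].astype(float)
                else:
                    X = pd.get_dummies(sub[var], prefix=var, drop_first=True, dtype=float)
                X = sm.add_constant(X)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = _GuardedMixedLM(
                        sub[outcome].astype(float), X, groups=sub["patient_id"]
                    ).fit(reml=True, method="lbfgs", maxiter=500)
                terms = [c for c in X.columns if c != "const"]
                pvals = 2 * stats.norm.sf(np.abs(res.fe_params[terms] / res.bse_fe[terms]))
                j = int(np.argmin(pvals))
                rec["estimate"] = float(res.fe_params[terms].iloc[j])
                rec["pvalue"] = float(pvals[j])
            results.append(rec)
    out = pd.DataFrame(results)
    sig = out.groupby("demographic")["pvalue"].min() < alpha
    out["included"] = out["demographic"].map(sig).fillna(False)
    return out


def cooks_filter(
    rows: pd.DataFrame,
    outcome: str,
    multiplier: float = 4.0,
    baseline: str = "mean",
) -> tuple[pd.DataFrame, float]:
    """Remove observations with outsized influence on the pooled regression.

    An ordinary-least-squares regression of the outcome on the six
    within/between behavioral predictors (no demographics, no random effects)
    provides each observation's Cook's distance D; observations with
    ``D > multiplier * baseline(D)`` are removed. ``baseline`` is ``"mean"``
    (mean of D, the default reading of "four times Cook's distance") or
    ``"4_over_n"`` (the classical 4/n cutoff, in which case ``multiplier`` is
    ignored).

    Only rows complete in the outcome and predictors participate; others pass
    through untouched. Returns ``(retained rows, removed fraction)`` where the
    fraction is relative to the complete rows.
    """
    complete = _complete_rows(rows, outcome, BEHAVIOR_PREDICTORS)
    if len(complete) < 10:
        raise ValueError("cooks_filter needs at least 10 complete observations")
    if complete[[outcome, *BEHAVIOR_PREDICTORS]].nunique().max() == 1:
        # degenerate data: every observation identical, all influence equal
        return rows, 0.0
    X = sm.add_constant(complete[list(BEHAVIOR_PREDICTORS)].astype(float))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"singular design in Cook's-distance regression: {bad}")
    ols = sm.OLS(complete[outcome].astype(float), X).fit()
    d = OLSInfluence(ols).cooks_distance[0]
    if baseline == "mean":
        cutoff = multiplier * float(np.mean(d))
    elif baseline == "4_over_n":
        cutoff = 4.0 / len(complete)
    else:
        raise ValueError(f"unknown baseline rule: {baseline!r}")
    removed_idx = complete.index[d > cutoff]
    retained = rows.drop(index=removed_idx)
    return retained, len(removed_idx) / len(complete)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    arr = X.to_numpy(dtype=float)
    base_rank = np.linalg.matrix_rank(arr)
    for j, name in enumerate(X.columns):
        if np.linalg.matrix_rank(np.delete(arr, j, axis=1)) == base_rank:
            bad.append(name)
    return bad


def fit_model(
    rows: pd.DataFrame,
    outcome: str,
    demographics: tuple[str, ...] = DEFAULT_DEMOGRAPHICS,
    n_removed: int = 0,
    random_slopes: tuple[str, ...] = _WP_PREDICTORS,
) -> ModelFit:
    """Fit the two-level model for one outcome by REML.

    Random structure: person random intercept plus independent random slopes
    (variance components) on the three within-person predictors
    (``random_slopes`` restricts them, e.g. to an intercept-only model). Rows
    missing the outcome or any predictor are dropped (missing-at-random
    assumption). If the optimizer fails to converge, random slopes whose
    variances sit at the zero boundary are dropped one at a time and the
    model refit; dropped slopes are reported on the fit.
    """
    predictors = list(BEHAVIOR_PREDICTORS) + list(demographics)
    data = _complete_rows(rows, outcome, predictors).copy()
    if len(data) == 0:
        raise ValueError("no complete observations to fit")
    data[predictors] = data[predictors].astype(float)

    # Standardize predictors internally: raw scales differ by orders of
    # magnitude (age in years vs overlap fractions), which makes the profiled
    # GLS cross-product numerically singular. Within-person columns are
    # scaled only (their means are ~0 by construction and leaving them
    # uncentered keeps the random-slope structure exactly equivalent);
    # person-level columns are centered and scaled. Estimates and their
    # covariance are transformed back exactly below.
    means, scales = {}, {}
    for p in predictors:
        s = float(data[p].std(ddof=0))
        if s == 0.0:
            raise ValueError(f"predictor {p!r} is constant; drop it before fitting")
        m = 0.0 if p in _WP_PREDICTORS else float(data[p].mean())
        means[p], scales[p] = m, s
        data[p] = (data[p] - m) / s
    formula = f"{outcome} ~ " + " + ".join(predictors)

    slopes = [s for s in _WP_PREDICTORS if s in random_slopes]
    while True:
        vcf = {s: f"0 + {s}" for s in slopes}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = _GuardedMixedLM.from_formula(
                formula,
                data=data,
                groups=data["patient_id"],
                re_formula="1",
                vc_formula=vcf or None,
            )
            res = mod.fit(reml=True, method="lbfgs", maxiter=500)
        if res.converged or not slopes:
            break
        # drop the slope whose variance collapsed to the boundary
        vcomp = dict(zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)))
        drop = min(vcomp, key=vcomp.get)
        logger.info(
            "fit_model(%s): non-convergence; dropping boundary random slope %s",
            outcome,
            drop,
        )
        slopes.remove(drop)

    # back-transform from the standardized to the raw predictor scale:
    # beta_raw_j = beta_std_j / s_j and the intercept absorbs the centering
    terms = ["intercept"] + predictors
    k = len(terms)
    fe_std = res.fe_params.to_numpy()
    T = np.zeros((k, k))
    T[0, 0] = 1.0
    for j, p in enumerate(predictors, start=1):
        T[j, j] = 1.0 / scales[p]
        T[0, j] = -means[p] / scales[p]
    fe = T @ fe_std
    cov_std = np.asarray(res.cov_params())[:k, :k]
    cov = T @ cov_std @ T.T
    with np.errstate(invalid="ignore", divide="ignore"):
        # a boundary solution can leave the curvature estimate non-PD; the
        # affected terms get NaN uncertainty rather than a fabricated one
        se = np.sqrt(np.diag(cov))
        z = fe / se
        pvals = 2 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "ci_low": fe - 1.959963984540054 * se,
            "ci_high": fe + 1.959963984540054 * se,
            "pvalue": pvals,
        },
        index=pd.Index(terms, name="term"),
    )
    variances = {"var_intercept": float(np.asarray(res.cov_re)[0, 0])}
    vcomp = np.atleast_1d(res.vcomp)
    vc_names = list(res.model.exog_vc.names) if slopes else []
    for name, value in zip(vc_names, vcomp):
        variances[f"var_{name}"] = float(value) / scales[name] ** 2
    for s in _WP_PREDICTORS:
        variances.setdefault(f"var_{s}", 0.0)
    variances["var_residual"] = float(res.scale)
    return ModelFit(
        outcome=outcome,
        fixed_effects=fixed,
        variances=variances,
        n_obs=len(data),
        n_patients=int(data["patient_id"].nunique()),
        n_removed=n_removed,
        converged=bool(res.converged),
        dropped_slopes=tuple(s for s in _WP_PREDICTORS if s not in slopes),
    )


def ks_compare(
    before: pd.DataFrame,
    after: pd.DataFrame,
    columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov comparison per variable.

    Compares the distribution of each column before vs after cleaning.
    Returns one row per variable with ``statistic`` and ``pvalue``; a
    non-significant p supports that the cleaning left the distribution
    intact.
    """
    if columns is None:
        columns = tuple(
            c for c in before.columns if pd.api.types.is_numeric_dtype(before[c])
        )
    rows = []
    for c in columns:
        a = before[c].dropna().to_numpy(dtype=float)
        b = after[c].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        res = stats.ks_2samp(a, b)
        rows.append({"variable": c, "statistic": res.statistic, "pvalue": res.pvalue})
    return pd.DataFrame(rows)
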