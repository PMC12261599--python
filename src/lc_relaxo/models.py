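"""Statistical models linking LC qMRI metrics to age and cognition.

Four model families, all adjusted for sex, race (dummy-coded against the
largest category) and years of education (EDY):

1. linear age trend of a qMRI metric (OLS);
2. quadratic age trend with mean-centered age (OLS) — the age^2 term tests
   an inverted-U trajectory without age/age^2 collinearity;
3. cross-sectional association of a cognitive domain z-score at the time
   of MRI with the qMRI metric (OLS);
4. longitudinal linear mixed model of repeated domain z-scores on
   age x qMRI x time with all lower-order terms, a random intercept per
   participant, and REML estimation. The qMRI metric is mean-centered (and
   by default age as well, which stabilizes the three-way interaction and
   is an equivalent reparameterization); the key coefficients are
   qMRI x time (difference in annual cognitive change per unit qMRI) and
   qMRI x time x age (age moderation of that difference).

Multiple testing across the declared family (subregion variants x five
cognitive domains per metric and effect) is controlled by the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "FdrResult",
    "fit_linear_age",
    "fit_quadratic_age",
    "fit_cross_sectional",
    "fit_longitudinal",
    "bh_fdr",
    "fit_slice_ages",
    "predict_profile_at_ages",
]


@dataclass
class ModelFit:
    """Coefficients, uncertainties and bookkeeping for one fitted model."""

    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    n: int
    converged: bool
    random_intercept_sd: float | None = None
    residual_sd: float | None = None
    meta: dict = field(default_factory=dict)
    sm_result: object = None

    def term(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) for one coefficient."""
        return float(self.params[name]), float(self.bse[name]), float(self.pvalues[name])


@dataclass
class FdrResult:
    """Benjamini-Hochberg adjustment over one declared test family."""

    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    q: float
    family: tuple[str, ...] = ()


def _race_term(data: pd.DataFrame) -> str:
    """Dummy coding with the largest race category as reference."""
    if data["race"].nunique() < 2:
        return ""  # single category: drop the term instead of a rank error
    ref = data["race"].value_counts().idxmax()
    return f" + C(race, Treatment(reference='{ref}'))"


def _check_estimable(data: pd.DataFrame, cols: list[str]) -> None:
    for col in cols:
        if data[col].nunique() <= 1 and col not in ("sex",):
            raise ValueError(f"term {col!r} is constant; model is rank deficient")


def _ols_fit(formula: str, data: pd.DataFrame, family: str, meta: dict | None = None) -> ModelFit:
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        names = model.exog_names
        raise ValueError(f"rank-deficient design; check terms {names}")
    res = model.fit()
    return ModelFit(
        family=family,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        n=int(res.nobs),
        converged=True,
        residual_sd=float(np.sqrt(res.scale)),
        meta=meta or {},
        sm_result=res,
    )


def fit_linear_age(cohort: pd.DataFrame, metric: str) -> ModelFit:
    """qMRI ~ age + sex + race + EDY (OLS); the age slope is the estimand."""
    data = cohort.dropna(subset=[metric, "age", "sex", "race", "edy"])
    if len(data) <= 5:
        raise ValueError("too few observations for the linear age model")
    formula = f"{metric} ~ age + sex{_race_term(data)} + edy"
    fit = _ols_fit(formula, data, "linear_age", {"metric": metric})
    fit.meta["age_range"] = (float(data["age"].min()), float(data["age"].max()))
    fit.meta["edy_mean"] = float(data["edy"].mean())
    return fit


def fit_quadratic_age(cohort: pd.DataFrame, metric: str) -> ModelFit:
    """Adds mean-centered age squared; the age^2 coefficient is the estimand."""
    data = cohort.dropna(subset=[metric, "age", "sex", "race", "edy"]).copy()
    age_mean = float(data["age"].mean())
    data["age_c"] = data["age"] - age_mean
    data["age_c2"] = data["age_c"] ** 2
    formula = f"{metric} ~ age_c + age_c2 + sex{_race_term(data)} + edy"
    fit = _ols_fit(formula, data, "quadratic_age", {"metric": metric, "age_mean": age_mean})
    return fit


def fit_cross_sectional(
    cohort: pd.DataFrame, cognition_at_mri: pd.DataFrame | None, metric: str,
    domain: str = "memory",
) -> ModelFit:
    """Domain z-score at MRI ~ age + sex + race + EDY + qMRI (OLS).

    ``cognition_at_mri`` has one row per participant with the domain
    z-scores at the scan date; pass None if the domain columns already sit
    on the cohort table.
    """
    data = cohort if cognition_at_mri is None else cohort.merge(
        cognition_at_mri, on="participant_id", how="inner"
    )
    data = data.dropna(subset=[domain, metric, "age", "sex", "race", "edy"])
    formula = f"{domain} ~ age + sex{_race_term(data)} + edy + {metric}"
    return _ols_fit(formula, data, "cross_sectional", {"metric": metric, "domain": domain})


def fit_longitudinal(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    metric: str,
    domain: str = "memory",
    center_age: bool = True,
    reml: bool = True,
) -> ModelFit:
    """Random-intercept mixed model of repeated domain z-scores.

    Fixed effects: age, sex, race, EDY, time, qMRI, age x time, qMRI x age,
    qMRI x time and qMRI x time x age; random intercept per participant.
    The qMRI metric is always mean-centered; age is mean-centered by
    default (coefficient-equivalent reparameterization).
    """
    data = visits.merge(
        cohort[["participant_id", "age", "sex", "race", "edy", metric]],
        on="participant_id",
        how="inner",
    ).dropna(subset=[domain, metric, "time"])
    n_multi = data.groupby("participant_id").size()
    if (n_multi >= 2).mean() < 0.2:
        warnings.warn("fewer than 20% of participants have repeated visits", stacklevel=2)
    data = data.copy()
    data["qmri_c"] = data[metric] - data[metric].mean()
    data["age_x"] = data["age"] - data["age"].mean() if center_age else data["age"]
    formula = (
        f"{domain} ~ age_x*qmri_c*time + sex{_race_term(data)} + edy"
    )
    model = smf.mixedlm(formula, data=data, groups=data["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
    re_sd = float(np.sqrt(res.cov_re.iloc[0, 0]))
    return ModelFit(
        family="longitudinal_mixed",
        params=res.params[: len(res.fe_params)],
        bse=res.bse[: len(res.fe_params)],
        pvalues=res.pvalues[: len(res.fe_params)],
        conf_int=res.conf_int().iloc[: len(res.fe_params)],
        n=int(res.nobs),
        converged=bool(res.converged),
        random_intercept_sd=re_sd,
        residual_sd=float(np.sqrt(res.scale)),
        meta={
            "metric": metric,
            "domain": domain,
            "center_age": center_age,
            "reml": reml,
            "qmri_time_term": "qmri_c:time",
            "qmri_time_age_term": "age_x:qmri_c:time",
        },
        sm_result=res,
    )


def bh_fdr(p_values, q: float = 0.05, family: tuple[str, ...] = ()) -> FdrResult:
    """Benjamini-Hochberg step-up adjustment.

    adjusted p_(i) = min_{j >= i} m * p_(j) / j, capped at 1; a hypothesis
    is rejected when its adjusted p is <= q. Input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return FdrResult(
        raw_p=p, adjusted_p=adjusted, rejected=adjusted <= q, q=q,
        family=tuple(family),
    )


def fit_slice_ages(slice_table: pd.DataFrame, metric: str) -> list[ModelFit]:
    """Per-slice linear-age fits from a long (participant x slice) table.

    ``slice_table`` columns: participant_id, age, sex, race, edy,
    slice_percentile, and the metric. Returns one fit per distinct slice
    percentile, rostral first.
    """
    fits = []
    for pct in sorted(slice_table["slice_percentile"].unique()):
        sub = slice_table[slice_table["slice_percentile"] == pct]
        fit = fit_linear_age(sub, metric)
        fit.meta["slice_percentile"] = float(pct)
        fits.append(fit)
    return fits


def predict_profile_at_ages(
    slice_fits: list[ModelFit],
    ages=(40.0, 75.0),
    sex: int = 0,
    race: str | None = None,
    edy: float | None = None,
) -> pd.DataFrame:
    """Predicted metric per slice at reference ages (the topography plot).

    Covariates are fixed at reference values: sex at the coded reference
    (0), race at the dummy-coding reference (largest category), EDY at the
    cohort mean. Warns when an age lies outside the fitted cohort range.
    """
    rows = []
    for fit in slice_fits:
        res = fit.sm_result
        lo, hi = fit.meta.get("age_range", (-np.inf, np.inf))
        data_race = res.model.data.frame["race"] if "race" in res.model.data.frame else None
        ref_race = race or (data_race.value_counts().idxmax() if data_race is not None else None)
        for age in ages:
            if not (lo <= age <= hi):
                warnings.warn(
                    f"age {age} lies outside the fitted range [{lo:.1f}, {hi:.1f}]",
                    stacklevel=2,
                )
            new = pd.DataFrame(
                {
                    "age": [age],
                    "sex": [sex],
                    "edy": [edy if edy is not None else fit.meta.get("edy_mean", 0.0)],
                    "race": [ref_race],
                }
            )
            rows.append(
                {
                    "slice_percentile": fit.meta.get("slice_percentile", np.nan),
                    "age": age,
                    "predicted": float(res.predict(new).iloc[0]),
                }
            )
    return pd.DataFrame(rows)
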