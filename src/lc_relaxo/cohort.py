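"""Synthetic longitudinal cohort generator.

Emulates a cognitively normal aging cohort (default n = 120, ages 22-94,
53% male, 68% White / 19% Black, ~16 years of education, ~3 cognitive
assessments per participant) with:

* per-participant LC qMRI summaries (whole / rostral-middle / caudal x
  R1 / R2 / MWF) drawn from configurable age-trend models, and
* longitudinal cognitive domain z-scores generated from the same linear
  mixed-model structure the analysis fits: fixed effects for age, sex,
  race, education, time, the qMRI metric, all two-way interactions of
  age x qMRI x time and the three-way interaction, plus a Gaussian random
  intercept per participant and i.i.d. residuals.

Age and qMRI values enter the generative linear predictor mean-centered
(the same parameterization the fitted model uses), so fitted coefficients
estimate the generating ones directly. Visit times are in years relative
to the MRI scan, which is time 0; preceding visits run backwards at the
configured spacing, matching a design where cognitive testing mostly
precedes or coincides with imaging.

Default qMRI age-model values (intercepts ~ R1 1.1 1/s, R2 17 1/s,
MWF 0.12, with modest negative age slopes) are plausible brainstem
relaxometry magnitudes, not published LC constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QmriAgeModel",
    "CognitionBetas",
    "CohortGenSpec",
    "generate_cohort",
    "generate_raw_test_scores",
    "QMRI_COLUMNS",
    "DOMAINS",
]

DOMAINS = ("memory", "attention", "executive", "fluency", "processing_speed")

QMRI_COLUMNS = tuple(
    f"{region}_{metric}"
    for region in ("lc", "rostral", "caudal")
    for metric in ("r1", "r2", "mwf")
)


@dataclass
class QmriAgeModel:
    """Cross-sectional age trend of one qMRI summary.

    value = intercept + linear * age_c + quadratic * age_c^2 + N(0, resid_sd),
    with age_c the mean-centered age in years.
    """

    intercept: float
    linear: float = 0.0
    quadratic: float = 0.0
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")


@dataclass
class CognitionBetas:
    """Fixed-effect coefficients of the longitudinal cognition model.

    ``qmri_column`` names the metric driving this domain. Age (years) and
    the qMRI value enter mean-centered; time is years from MRI.
    """

    qmri_column: str = "rostral_r2"
    intercept: float = 0.0
    age: float = 0.0
    sex: float = 0.0
    edy: float = 0.0
    race: dict[str, float] = field(default_factory=dict)
    time: float = 0.0
    qmri: float = 0.0
    age_time: float = 0.0
    qmri_age: float = 0.0
    qmri_time: float = 0.0
    qmri_time_age: float = 0.0


def _default_qmri_models() -> dict[str, QmriAgeModel]:
    base = {
        "r1": QmriAgeModel(intercept=1.10, linear=-0.0005, quadratic=-1.5e-5, resid_sd=0.05),
        "r2": QmriAgeModel(intercept=17.0, linear=-0.03, resid_sd=1.0),
        "mwf": QmriAgeModel(intercept=0.12, linear=-1e-4, resid_sd=0.02),
    }
    out = {}
    for region, factor in (("lc", 1.0), ("rostral", 1.0), ("caudal", 1.0)):
        for metric, m in base.items():
            out[f"{region}_{metric}"] = QmriAgeModel(
                m.intercept * factor, m.linear, m.quadratic, m.resid_sd
            )
    # rostral-middle LC carries the steeper age effects
    out["rostral_r2"] = QmriAgeModel(16.5, -0.045, resid_sd=1.0)
    out["rostral_mwf"] = QmriAgeModel(0.11, -2e-4, resid_sd=0.02)
    return out


def _default_cognition_betas() -> dict[str, CognitionBetas]:
    betas = {}
    for domain in DOMAINS:
        betas[domain] = CognitionBetas(
            qmri_column="rostral_r2", time=-0.02, age_time=-0.0005
        )
    # lower rostral-middle R2 -> steeper memory decline, more so at older
    # ages (positive qmri x time and qmri x time x age coefficients)
    betas["memory"] = CognitionBetas(
        qmri_column="rostral_r2",
        time=-0.02, age_time=-0.0005,
        qmri=0.05, qmri_time=0.01, qmri_time_age=0.001,
    )
    betas["fluency"] = CognitionBetas(
        qmri_column="lc_r1", time=-0.02, age_time=-0.0005, qmri_time=0.2
    )
    return betas


@dataclass
class CohortGenSpec:
    """Configuration of the synthetic cohort generator."""

    n_participants: int = 120
    age_range: tuple[float, float] = (22.0, 94.0)
    sex_prob: float = 0.533  # P(male); sex coded 1 = male
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"white": 0.683, "black": 0.192, "other": 0.125}
    )
    edy_mean_sd: tuple[float, float] = (16.3, 2.7)
    qmri_age_model: dict[str, QmriAgeModel] = field(default_factory=_default_qmri_models)
    cognition_betas: dict[str, CognitionBetas] = field(
        default_factory=_default_cognition_betas
    )
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.3
    visits_mean: float = 3.0  # mean of the >=1-truncated Poisson visit count
    visit_spacing: float = 1.5  # years between consecutive assessments
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")
        if not (0 <= self.sex_prob <= 1):
            raise ValueError("sex_prob must be a probability")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be >= 0")
        if self.visits_mean < 1:
            raise ValueError("visits_mean must be >= 1")


def _truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson counts conditioned on >= 1 with the requested mean.

    Solves lambda / (1 - exp(-lambda)) = mean, then samples the truncated
    distribution by inverse-CDF on the conditional uniform.
    """
    lam = mean
    for _ in range(100):  # fixed-point iteration for the truncated mean
        lam = mean * (1.0 - np.exp(-lam))
    p0 = stats.poisson.cdf(0, lam)
    u = rng.uniform(p0, 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(int)


def generate_cohort(spec: CohortGenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the participant table and the longitudinal cognition table.

    Returns ``(cohort, visits)``: one row per participant (covariates +
    qMRI summaries) and one row per visit (time from MRI in years, with
    time 0 the scan date, plus the five domain z-scores).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.binomial(1, spec.sex_prob, size=n)
    races = list(spec.race_probs)
    race = rng.choice(races, p=[spec.race_probs[r] for r in races], size=n)
    edy = np.clip(rng.normal(*spec.edy_mean_sd, size=n), 0.0, None)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "edy": edy,
        }
    )
    age_c = age - age.mean()
    for col in QMRI_COLUMNS:
        m = spec.qmri_age_model[col]
        cohort[col] = (
            m.intercept
            + m.linear * age_c
            + m.quadratic * age_c**2
            + rng.normal(0.0, m.resid_sd, size=n)
        )

    n_visits = _truncated_poisson(spec.visits_mean, n, rng)
    b = rng.normal(0.0, spec.random_intercept_sd, size=(n, len(DOMAINS)))
    edy_c = edy - edy.mean()

    rows = []
    for i in range(n):
        k = n_visits[i]
        times = (np.arange(k) - (k - 1)) * spec.visit_spacing  # ..., -s, 0
        for t in times:
            row = {
                "participant_id": cohort.at[i, "participant_id"],
                "time": float(t),
            }
            for d, domain in enumerate(DOMAINS):
                beta = spec.cognition_betas[domain]
                q = cohort.at[i, beta.qmri_column]
                q_c = q - cohort[beta.qmri_column].mean()
                lp = (
                    beta.intercept
                    + beta.age * age_c[i]
                    + beta.sex * sex[i]
                    + beta.race.get(race[i], 0.0)
                    + beta.edy * edy_c[i]
                    + beta.time * t
                    + beta.qmri * q_c
                    + beta.age_time * age_c[i] * t
                    + beta.qmri_age * q_c * age_c[i]
                    + beta.qmri_time * q_c * t
                    + beta.qmri_time_age * q_c * t * age_c[i]
                )
                row[domain] = lp + b[i, d] + rng.normal(0.0, spec.residual_sd)
            rows.append(row)
    visits = pd.DataFrame(rows)
    return cohort, visits


def generate_raw_test_scores(
    n_participants: int = 120,
    n_visits: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw neuropsychological instrument scores from a latent ability.

    Synthetic stand-in for raw test exports, used to exercise the cognition
    preprocessing chain: each participant has a latent ability a ~ N(0, 1);
    count/score instruments increase in a, timed instruments (TMT A/B
    completion seconds) decrease in a, so after log-transform + inversion
    every derived domain must correlate positively with ability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        a = rng.normal()
        for v in range(n_visits):
            rows.append(
                {
                    "participant_id": f"P{i:04d}",
                    "time": float(v),
                    "ability": a,
                    "cvlt_imm": 50 + 10 * a + rng.normal(0, 3),
                    "cvlt_delay": 11 + 2.5 * a + rng.normal(0, 1),
                    "tmt_a_s": float(np.exp(3.3 - 0.3 * a + rng.normal(0, 0.1))),
                    "tmt_b_s": float(np.exp(4.2 - 0.35 * a + rng.normal(0, 0.12))),
                    "digit_span_fwd": 10 + 2 * a + rng.normal(0, 1),
                    "digit_span_bwd": 8 + 2 * a + rng.normal(0, 1),
                    "fluency_category": 20 + 4 * a + rng.normal(0, 2),
                    "fluency_letter": 13 + 3.5 * a + rng.normal(0, 2),
                    "dsst": 50 + 9 * a + rng.normal(0, 3),
                }
            )
    return pd.DataFrame(rows)
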