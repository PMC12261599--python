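"""Neuropsychological preprocessing: baseline z-scoring, Trail Making Test
transform, and the five cognitive domain composites.

Domains and constituents:

* memory            = mean(CVLT immediate z, CVLT long-delay z)
* attention         = mean(TMT-A z, Digit Span forward z)
* executive         = mean(TMT-B z, Digit Span backward z)
* fluency           = mean(Category fluency z, Letter fluency z)
* processing_speed  = mean(TMT-A z, DSST z)

TMT completion times are log-transformed (natural log; the base cancels in
z-scores) and sign-inverted before z-scoring so that higher z is better on
every instrument. Each raw score is z-scored against the mean and SD of the
cohort's baseline (first) assessments, pooled across participants. Missing
constituents fall back to the mean of the available ones, with a
completeness flag, rather than dropping the visit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DOMAIN_CONSTITUENTS",
    "TMT_TESTS",
    "zscore_baseline",
    "transform_tmt",
    "domain_scores",
    "baseline_stats",
    "prepare_cognition",
]

TMT_TESTS = ("tmt_a_s", "tmt_b_s")

#: raw-score column -> z-score column produced by `prepare_cognition`
RAW_TESTS = (
    "cvlt_imm",
    "cvlt_delay",
    "tmt_a_s",
    "tmt_b_s",
    "digit_span_fwd",
    "digit_span_bwd",
    "fluency_category",
    "fluency_letter",
    "dsst",
)

DOMAIN_CONSTITUENTS: dict[str, tuple[str, ...]] = {
    "memory": ("cvlt_imm_z", "cvlt_delay_z"),
    "attention": ("tmt_a_s_z", "digit_span_fwd_z"),
    "executive": ("tmt_b_s_z", "digit_span_bwd_z"),
    "fluency": ("fluency_category_z", "fluency_letter_z"),
    "processing_speed": ("tmt_a_s_z", "dsst_z"),
}


def zscore_baseline(
    scores: np.ndarray | pd.Series, baseline_mean: float, baseline_sd: float
):
    """z = (x - baseline_mean) / baseline_sd, applied to all visits."""
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be > 0")
    return (scores - baseline_mean) / baseline_sd


def transform_tmt(seconds: np.ndarray | float):
    """-log(completion seconds): strictly decreasing, so faster is higher."""
    s = np.asarray(seconds, dtype=float)
    if np.any(s <= 0):
        raise ValueError("TMT completion times must be > 0 seconds")
    out = -np.log(s)
    return float(out) if np.ndim(seconds) == 0 else out


def baseline_stats(
    visits: pd.DataFrame,
    tests: tuple[str, ...] = RAW_TESTS,
    id_col: str = "participant_id",
    time_col: str = "time",
) -> pd.DataFrame:
    """Mean and SD of each (transformed) test over first assessments.

    The baseline is each participant's earliest visit; statistics are
    pooled across all participants.
    """
    first = visits.sort_values(time_col).groupby(id_col, sort=False).head(1)
    rows = {}
    for test in tests:
        if test not in first:
            continue
        vals = first[test].dropna().to_numpy(dtype=float)
        if test in TMT_TESTS:
            vals = transform_tmt(vals)
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            raise ValueError(f"cannot form baseline statistics for {test}")
        rows[test] = {"mean": float(vals.mean()), "sd": float(np.std(vals, ddof=1))}
    return pd.DataFrame(rows).T


def domain_scores(test_zscores: pd.DataFrame) -> pd.DataFrame:
    """Average constituent z-scores into the five domain scores.

    Returns the domain columns plus a ``<domain>_complete`` flag that is
    False where at least one constituent was missing (the domain is then
    the mean of the available constituents); a domain with no constituents
    at all is NaN with the flag False.
    """
    out = pd.DataFrame(index=test_zscores.index)
    for domain, cols in DOMAIN_CONSTITUENTS.items():
        present = [c for c in cols if c in test_zscores.columns]
        if not present:
            out[domain] = np.nan
            out[f"{domain}_complete"] = False
            continue
        block = test_zscores[present]
        out[domain] = block.mean(axis=1, skipna=True)
        out[f"{domain}_complete"] = block.notna().sum(axis=1) == len(cols)
    return out


def prepare_cognition(
    visits: pd.DataFrame,
    stats: pd.DataFrame | None = None,
    id_col: str = "participant_id",
    time_col: str = "time",
) -> pd.DataFrame:
    """Full preprocessing chain: transform, baseline z-score, composites.

    Adds a ``<test>_z`` column per raw instrument and the five domain
    scores (plus completeness flags). Baseline statistics are computed from
    the table itself unless supplied (e.g. to score a follow-up export
    against an existing baseline).
    """
    visits = visits.copy()
    if stats is None:
        stats = baseline_stats(visits, id_col=id_col, time_col=time_col)
    zcols = {}
    for test in stats.index:
        vals = visits[test].to_numpy(dtype=float)
        if test in TMT_TESTS:
            with np.errstate(invalid="ignore"):
                vals = np.where(np.isnan(vals), np.nan, vals)
            ok = ~np.isnan(vals)
            t = np.full_like(vals, np.nan)
            t[ok] = transform_tmt(vals[ok])
            vals = t
        zcols[f"{test}_z"] = zscore_baseline(
            vals, stats.at[test, "mean"], stats.at[test, "sd"]
        )
    z = pd.DataFrame(zcols, index=visits.index)
    return pd.concat([visits, z, domain_scores(z)], axis=1)
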