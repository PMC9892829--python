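"""Signature sum scores, quartile stratification, and survival association.

The per-sample sum score de-logs the members' log2 relative abundances, sums
them on the linear scale, and re-logs: score = log2(sum_m 2^v_m).  The
GPC/GM log2 ratio is the difference of the two arm scores.  Survival
association uses Cox proportional-hazards partial likelihood (Efron ties)
adjusted for age and sex, with a likelihood-ratio test against the
covariate-only model, and Kaplan-Meier curves with a log-rank test across
quartile-based categories.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .io import ExpressionMatrix, SurvivalRecord

log = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "KMResult",
    "sum_score",
    "score_table",
    "stratify",
    "cox_association",
    "km_logrank",
]


def sum_score(
    matrix: ExpressionMatrix,
    protein_set,
    mode: str = "linear",
) -> pd.Series:
    """Per-sample signature sum score over the set members present.

    ``linear`` (default): log2 of the linear-scale sum of the members'
    de-logged values (log-sum-exp in base 2).  ``log_z``: plain sum of log2
    values, z-scaled across samples.  Members absent from the matrix are
    skipped with a reported count; missing per-sample values are ignored.
    """
    members = [m for m in protein_set if m in matrix.values.index]
    skipped = len(list(protein_set)) - len(members)
    if not members:
        raise ValueError("no signature members present in matrix")
    if skipped:
        log.info("sum_score: %d member(s) absent from matrix", skipped)
    sub = matrix.values.loc[members]
    if mode == "linear":
        arr = np.ma.masked_invalid(sub.to_numpy())
        score = np.ma.log2(np.ma.power(2.0, arr).sum(axis=0)).filled(np.nan)
        return pd.Series(score, index=matrix.col_ids, name="sum_score")
    if mode == "log_z":
        raw = sub.sum(axis=0, skipna=True)
        return ((raw - raw.mean()) / raw.std(ddof=1)).rename("sum_score")
    raise ValueError(f"unknown mode {mode!r}")


def score_table(
    matrix: ExpressionMatrix,
    gpc_set,
    gm_set,
    mode: str = "linear",
) -> pd.DataFrame:
    """Per-sample GPC-like and GM-like sum scores and their log2 ratio."""
    gpc = sum_score(matrix, gpc_set, mode)
    gm = sum_score(matrix, gm_set, mode)
    frame = pd.DataFrame(
        {"gpc_sum_score": gpc, "gm_sum_score": gm, "log2_ratio": gpc - gm}
    )
    frame["ratio_category"] = stratify(frame["log2_ratio"], mode="three_level")
    return frame


def stratify(scores: pd.Series, mode: str = "two_level") -> pd.Series:
    """Quartile categories (linear-interpolation quantiles).

    ``two_level``: low (score <= Q1) vs high_medium.  ``three_level``:
    low <= Q1 < medium <= Q3 < high.  Scores exactly at a boundary fall in
    the lower category.
    """
    scores = pd.Series(scores)
    if len(scores) < 4:
        raise ValueError("need >= 4 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("degenerate quartiles: all scores identical")
    q1 = float(np.quantile(scores, 0.25))
    if mode == "two_level":
        return pd.Series(
            np.where(scores <= q1, "low", "high_medium"),
            index=scores.index, name="category",
        )
    if mode == "three_level":
        q3 = float(np.quantile(scores, 0.75))
        cats = np.where(
            scores <= q1, "low", np.where(scores <= q3, "medium", "high")
        )
        return pd.Series(cats, index=scores.index, name="category")
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CoxFit:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    lrt_p: float
    coef: float
    covariates: list[str]
    n: int
    n_events: int


def _records_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_months": [r.os_months for r in records],
            "event": [r.event for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    ).set_index("patient_id")
    frame["sex_male"] = (frame["sex"] == "male").astype(float)
    return frame


def cox_association(
    score: pd.Series,
    records: list[SurvivalRecord],
    adjust: bool = True,
) -> CoxFit:
    """Cox PH fit of hazard ~ score (+ age + sex), Efron tie handling.

    The likelihood-ratio p compares against the covariate-only model (or the
    null model when unadjusted).  The hazard ratio is per unit of score.
    """
    frame = _records_frame(records)
    frame = frame.join(score.rename("score"), how="inner")
    n_events = int(frame["event"].sum())
    if n_events < 10:
        raise ValueError("need >= 10 events for a stable Cox fit")
    covariates = ["age", "sex_male"] if adjust and frame["age"].notna().all() else []
    cols = ["os_months", "event", "score", *covariates]
    full = CoxPHFitter()
    try:
        full.fit(frame[cols], duration_col="os_months", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model did not converge: {exc}") from exc
    if covariates:
        reduced = CoxPHFitter()
        reduced.fit(
            frame[["os_months", "event", *covariates]],
            duration_col="os_months", event_col="event",
        )
        ll_reduced = reduced.log_likelihood_
    else:
        null = CoxPHFitter()
        null.fit(
            frame[["os_months", "event"]].assign(_const=0.0),
            duration_col="os_months", event_col="event",
        )
        ll_reduced = null.log_likelihood_
    lrt = 2.0 * (full.log_likelihood_ - ll_reduced)
    lrt_p = float(sps.chi2.sf(max(lrt, 0.0), df=1))
    coef = float(full.params_["score"])
    ci = full.confidence_intervals_.loc["score"]
    return CoxFit(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        lrt_p=max(lrt_p, np.nextafter(0, 1)),
        coef=coef,
        covariates=covariates,
        n=len(frame),
        n_events=n_events,
    )


@dataclass
class KMResult:
    groups: list[str]
    median_os: dict
    survival_curves: dict  # group -> pd.DataFrame(timeline, survival)
    logrank_p: float
    n_per_group: dict


def km_logrank(categories: pd.Series, records: list[SurvivalRecord]) -> KMResult:
    """Product-limit curves per category with a log-rank test across groups."""
    frame = _records_frame(records).join(categories.rename("group"), how="inner")
    counts = frame["group"].value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("log-rank requires >= 2 non-empty groups")
    curves, medians = {}, {}
    for group, sub in frame.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(sub["os_months"], sub["event"], label=str(group))
        curves[group] = km.survival_function_
        medians[group] = float(km.median_survival_time_)
    test = multivariate_logrank_test(
        frame["os_months"], frame["group"], frame["event"]
    )
    return KMResult(
        groups=list(counts.index),
        median_os=medians,
        survival_curves=curves,
        logrank_p=float(test.p_value),
        n_per_group=counts.to_dict(),
    )
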