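"""Lifetime risk trajectories, prevalence-to-incidence conversion,
survival-weighted expected age of diagnosis, and prospective follow-up
classification.

Lifetime risk P_a is the cumulative probability of having been diagnosed
by age a; within each risk-score stratum it is estimated retrospectively
from cross-sectional reports, conditioning on participants old enough to
have reached age a, and smoothed by isotonic regression so it is
non-decreasing.  The m-year incidence at age a follows
``I_a = (P_a - P_{a-m}) / (1 - P_{a-m})``, and the expected age of
diagnosis is the survival-weighted mean of the incidence curve:
``m = sum(S_a I_a a) / sum(S_a I_a)`` over the age grid, with the
matching weighted SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass
class TrajectorySet:
    """Per-stratum lifetime risk curves on an integer age grid."""

    ages: np.ndarray                 # integer age grid
    strata: list                     # (label, (pct_low, pct_high))
    prevalence: np.ndarray           # strata x ages, smoothed, in [0,1]
    raw_prevalence: np.ndarray       # before isotonic smoothing
    at_risk: np.ndarray              # strata x ages denominator counts
    unstable: list                   # labels of strata under the size floor


@dataclass
class OnsetSummary:
    """Expected (survival-weighted) mean age of diagnosis and SD."""

    mean: float
    sd: float


def synthetic_survival_schedule(age_range=(30, 90)) -> pd.DataFrame:
    """Synthetic population survival table (age, survival fraction).

    A Gompertz mortality schedule (yearly hazard 5e-4 * exp(0.09 * (a-30)))
    standing in for an official life table; survival is 1 at the grid
    start and declines to roughly 0.3 by age 90.  Any user table with the
    same two columns can replace it.
    """
    a = np.arange(age_range[0], age_range[1] + 1, dtype=float)
    hazard = 5e-4 * np.exp(0.09 * (a - age_range[0]))
    surv = np.concatenate([[1.0], np.cumprod(1.0 - hazard[:-1])])
    return pd.DataFrame({"age": a.astype(int), "survival": surv})


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    t = table[["age", "survival"]].copy()
    s = t["survival"].to_numpy(dtype=float)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("survival fractions must lie in (0, 1]")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("survival must be non-increasing in age")
    return t


def assign_strata(score, strata: Sequence[tuple]) -> pd.Series:
    """Percentile-range stratum labels for a score vector.

    ``strata`` is a list of ``(label, (pct_low, pct_high))`` with
    half-open ranges (low, high]; percentile 0 belongs to the first band.
    """
    score = np.asarray(score, dtype=float)
    pct = 100.0 * stats.rankdata(score, method="average") / len(score)
    labels = np.full(len(score), None, dtype=object)
    for label, (lo, hi) in strata:
        sel = (pct > lo) & (pct <= hi) if lo > 0 else (pct <= hi)
        labels[sel] = label
    return pd.Series(labels)


DEFAULT_STRATA = [("0-20", (0, 20)), ("20-40", (20, 40)),
                  ("40-60", (40, 60)), ("60-80", (60, 80)),
                  ("80-90", (80, 90)), ("90-100", (90, 100))]


def lifetime_risk_curves(current_age, age_at_diagnosis, score=None,
                         strata: Optional[Sequence[tuple]] = None,
                         age_range=(30, 90), smooth: bool = True,
                         min_stratum: int = 100) -> TrajectorySet:
    """Retrospective lifetime-risk curves stratified by score percentiles.

    For stratum g and age a, the raw estimate is
    ``#(cases in g with age_dx <= a and current_age >= a) /
    #(in g with current_age >= a)``; isotonic regression in a (weighted
    by the at-risk counts) enforces monotonicity.  With ``score=None`` a
    single all-participant stratum is used.  Strata under ``min_stratum``
    participants are flagged unstable with a warning.
    """
    cur = np.asarray(current_age, dtype=float)
    dx = np.asarray(age_at_diagnosis, dtype=float)
    ages = np.arange(age_range[0], age_range[1] + 1)
    if score is None:
        labels = pd.Series(np.full(len(cur), "all", dtype=object))
        strata = [("all", (0, 100))]
    else:
        strata = list(strata) if strata is not None else DEFAULT_STRATA
        labels = assign_strata(score, strata)
    P = np.zeros((len(strata), len(ages)))
    raw = np.zeros_like(P)
    at_risk = np.zeros_like(P, dtype=int)
    unstable = []
    for gi, (label, _) in enumerate(strata):
        sel = (labels == label).to_numpy()
        if int(sel.sum()) < min_stratum:
            unstable.append(label)
            warnings.warn(f"stratum {label!r} has {int(sel.sum())} "
                          f"participants (< {min_stratum}); curve unstable")
        cur_g, dx_g = cur[sel], dx[sel]
        for ai, a in enumerate(ages):
            denom = cur_g >= a
            at_risk[gi, ai] = int(denom.sum())
            if at_risk[gi, ai] == 0:
                raw[gi, ai] = raw[gi, ai - 1] if ai else 0.0
                continue
            num = (denom & np.isfinite(dx_g) & (dx_g <= a)).sum()
            raw[gi, ai] = num / at_risk[gi, ai]
        if smooth:
            w = np.maximum(at_risk[gi], 1)
            iso = IsotonicRegression(y_min=0.0, y_max=1.0)
            P[gi] = iso.fit_transform(ages, raw[gi], sample_weight=w)
        else:
            P[gi] = raw[gi]
    return TrajectorySet(ages=ages, strata=list(strata), prevalence=P,
                         raw_prevalence=raw, at_risk=at_risk,
                         unstable=unstable)


def incidence_from_prevalence(P, m: int = 1) -> np.ndarray:
    """m-year incidence I_a = (P_a - P_{a-m}) / (1 - P_{a-m}).

    The first ``m`` grid points are NaN (no lagged prevalence); ages with
    P_{a-m} = 1 are NaN (everyone already diagnosed).  Negative raw
    incidences — impossible after isotonic smoothing — clamp to 0 with a
    warning.
    """
    P = np.asarray(P, dtype=float)
    if m < 1 or m >= P.size:
        raise ValueError("window m must satisfy 1 <= m < len(P)")
    I = np.full(P.size, np.nan)
    lag = P[:-m]
    with np.errstate(divide="ignore", invalid="ignore"):
        I[m:] = (P[m:] - lag) / (1.0 - lag)
    I[m:][lag >= 1.0] = np.nan
    neg = np.nan_to_num(I) < 0
    if neg.any():
        warnings.warn("negative incidence clamped to 0 (non-monotone "
                      "prevalence input)")
        I[neg] = 0.0
    return I


def reconstruct_prevalence(I, P0: float) -> np.ndarray:
    """Invert the 1-year incidence transform: P'_a = 1 - prod(1 - I_k)."""
    I = np.asarray(I, dtype=float)
    P = np.empty(I.size)
    P[0] = P0
    for k in range(1, I.size):
        P[k] = 1.0 - (1.0 - P[k - 1]) * (1.0 - I[k])
    return P


def expected_age_of_diagnosis(I, survival, ages=None) -> OnsetSummary:
    """Survival-weighted mean and SD of the age of diagnosis.

    ``survival`` is a (age, survival) table or an array aligned with
    ``ages`` (default: the incidence curve's own integer grid starting at
    30).  NaN incidences contribute zero weight.  All-zero weights are an
    error (no expected onset).
    """
    I = np.asarray(I, dtype=float)
    if ages is None:
        ages = np.arange(30, 30 + I.size)
    ages = np.asarray(ages, dtype=float)
    if isinstance(survival, pd.DataFrame):
        t = validate_survival_table(survival)
        S = t.set_index("age")["survival"].reindex(ages.astype(int)) \
            .to_numpy(dtype=float)
        if np.isnan(S).any():
            raise ValueError("survival table does not cover the age grid")
    else:
        S = np.asarray(survival, dtype=float)
        if S.size != I.size:
            raise ValueError("survival and incidence grids differ")
    w = S * np.nan_to_num(I)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero survival-weighted incidence; "
                         "no expected onset")
    mean = float((w * ages).sum() / total)
    sd = float(np.sqrt((w * (ages - mean) ** 2).sum() / total))
    return OnsetSummary(mean=mean, sd=sd)


FOLLOWUP_STATUSES = ("incident", "cancer_free", "unchanged_control",
                     "persistent_case", "non_respondent")


def classify_followup(table: pd.DataFrame, cancer: str,
                      followup_years: int) -> pd.Series:
    """Per-participant prospective status for one cancer.

    incident: control at baseline reporting a diagnosis in any wave;
    cancer_free: case at baseline reporting no treatment in any answered
    wave; persistent_case: case reporting treatment (or, contradictorily,
    a first diagnosis); unchanged_control: control with no new diagnosis;
    non_respondent: answered no wave (excluded from rates downstream).
    """
    n = len(table)
    is_case = table[f"case_{cancer}"].to_numpy() == 1
    diag = np.zeros(n, dtype=bool)
    treat = np.zeros(n, dtype=bool)
    responded = np.zeros(n, dtype=bool)
    for k in range(1, followup_years + 1):
        d = table.get(f"fu{k}_diag_{cancer}")
        t = table.get(f"fu{k}_treat_{cancer}")
        if d is not None:
            dv = d.to_numpy(dtype=float)
            responded |= np.isfinite(dv)
            diag |= dv == 1.0
        if t is not None:
            tv = t.to_numpy(dtype=float)
            responded |= np.isfinite(tv)
            treat |= tv == 1.0
    status = np.full(n, "non_respondent", dtype=object)
    r = responded
    status[r & ~is_case & diag] = "incident"
    status[r & ~is_case & ~diag] = "unchanged_control"
    status[r & is_case & (treat | diag)] = "persistent_case"
    status[r & is_case & ~treat & ~diag] = "cancer_free"
    return pd.Series(status, index=table.index)


def expected_vs_observed_incidence(traj: TrajectorySet,
                                   table: pd.DataFrame, cancer: str,
                                   score=None,
                                   window: int = 2) -> pd.DataFrame:
    """Per-stratum expected vs observed window incidence with binomial CIs.

    Observed: among baseline controls who answered every wave of the
    ``window`` (so the whole window is actually observed — partial
    responders would dilute a multi-year rate with shorter exposure),
    the fraction reporting a diagnosis in any wave, with a Wilson 95%
    CI.  Expected: the stratum's ``window``-year incidence from its
    lifetime-risk curve, evaluated at each such participant's attained
    age (current age + window, capped at the grid end) and averaged
    within stratum.  Strata with no at-risk participants are absent.
    """
    from statsmodels.stats.proportion import proportion_confint
    cur = table["current_age"].to_numpy(dtype=float)
    is_case = table[f"case_{cancer}"].to_numpy() == 1
    full_resp = np.ones(len(table), dtype=bool)
    converted = np.zeros(len(table), dtype=bool)
    for k in range(1, window + 1):
        d = table.get(f"fu{k}_diag_{cancer}")
        if d is None:
            raise ValueError(f"follow-up wave {k} absent for {cancer}")
        dv = d.to_numpy(dtype=float)
        full_resp &= np.isfinite(dv) | is_case
        converted |= dv == 1.0
    labels = assign_strata(score, traj.strata) if score is not None else \
        pd.Series(np.full(len(cur), traj.strata[0][0], dtype=object))
    rows = []
    for gi, (label, rng) in enumerate(traj.strata):
        I = incidence_from_prevalence(traj.prevalence[gi], m=window)
        sel = (labels == label).to_numpy()
        at_risk = sel & ~is_case & full_resp
        n_risk = int(at_risk.sum())
        if n_risk == 0:
            continue
        a_idx = np.clip(cur[at_risk] + window - traj.ages[0], window,
                        traj.ages.size - 1).astype(int)
        expected = float(np.nanmean(I[a_idx]))
        n_inc = int(converted[at_risk].sum())
        observed = n_inc / n_risk
        lo, hi = proportion_confint(n_inc, n_risk, alpha=0.05,
                                    method="wilson")
        rows.append({"stratum": label, "percentiles": rng,
                     "n_at_risk": n_risk, "n_incident": n_inc,
                     "expected": expected, "observed": observed,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "concordant": bool(lo <= expected <= hi)})
    return pd.DataFrame(rows)
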