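"""Validation-set evaluation: discrimination, OR per SD, percentile
binning with tail enrichment, per-bin ages of diagnosis, and score
correlation / age-dependency diagnostics.

Percentile binning is rank based with stable tie-breaking by input order,
so bin summaries are invariant under monotone transforms of the score.
Report cells that would derive from fewer than five participants are
masked (NaN).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .risk_scores import standardize

#: minimum participants behind any reported cell
MASK_MIN = 5


def roc_auc(score, label):
    """AUC by the rank (Mann-Whitney) statistic, plus ROC curve points.

    AUC = P(score_case > score_control) + 0.5 P(tie).  Returns
    ``(auc, fpr, tpr)`` with one curve point per distinct threshold.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-score, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.where(np.diff(score[order]))[0], len(ys) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    return float(auc), fpr, tpr


def precision_recall_auc(score, label) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=float)
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise ValueError("both classes must be present")
    order = np.argsort(-score, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    precision = tps / np.arange(1, len(ys) + 1)
    recall = tps / n1
    distinct = np.r_[np.where(np.diff(score[order]))[0], len(ys) - 1]
    p, r = precision[distinct], recall[distinct]
    return float(np.sum(np.diff(np.r_[0.0, r]) * p))


def or_per_sd(score, label, covariates: Optional[pd.DataFrame] = None,
              reference=None):
    """Odds ratio per standard-deviation increase of the score.

    The score is z-scaled (against ``reference`` when given, e.g. the
    training scores) and entered in a logistic fit of the label; returns
    ``(or, ci_low, ci_high)`` from the Wald 95% interval.
    """
    z, _, _ = standardize(score, reference)
    y = np.asarray(label, dtype=float)
    X = z[:, None] if covariates is None else np.column_stack(
        [z, np.asarray(covariates, dtype=float)])
    res = sm.GLM(y, sm.add_constant(X),
                 family=sm.families.Binomial()).fit()
    beta, se = res.params[1], res.bse[1]
    return (float(np.exp(beta)), float(np.exp(beta - 1.96 * se)),
            float(np.exp(beta + 1.96 * se)))


def percentile_bins(score, n_bins: int = 100) -> np.ndarray:
    """Rank-based percentile bin assignment, 1..n_bins.

    Ties break by stable input order; bin sizes differ by at most one
    (earlier bins take the extra participant).
    """
    score = np.asarray(score, dtype=float)
    n = len(score)
    if n < n_bins:
        raise ValueError(f"n = {n} < n_bins = {n_bins}; use fewer bins")
    order = np.argsort(score, kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins = np.empty(n, dtype=int)
    start = 0
    for b, s in enumerate(sizes, start=1):
        bins[order[start:start + s]] = b
        start += s
    return bins


def summarize_bins(bins, labels, ages_at_diagnosis=None,
                   middle: tuple = (48, 53)) -> pd.DataFrame:
    """Per-percentile-bin prevalence, fold enrichment, and age at diagnosis.

    Fold enrichment compares each bin's prevalence with the pooled
    prevalence of the ``middle`` percentile band (inclusive bin range).
    Mean age at diagnosis (cases only) carries a normal-approximation 95%
    CI; cells from fewer than five cases are masked.
    """
    bins = np.asarray(bins)
    y = np.asarray(labels, dtype=float)
    ages = (np.asarray(ages_at_diagnosis, dtype=float)
            if ages_at_diagnosis is not None else None)
    uniq = np.arange(bins.min(), bins.max() + 1)
    mid_mask = (bins >= middle[0]) & (bins <= middle[1])
    mid_n = int(mid_mask.sum())
    mid_cases = int(y[mid_mask].sum())
    mid_prev = mid_cases / mid_n if mid_n else np.nan
    if mid_cases == 0:
        warnings.warn("middle band has no cases; fold enrichment undefined")
    rows = []
    for b in uniq:
        m = bins == b
        n = int(m.sum())
        cases = int(y[m].sum())
        prev = cases / n if n else np.nan
        fold = (prev / mid_prev if mid_cases > 0 and n else np.nan)
        rec = {"bin": int(b), "n": n, "cases": cases, "prevalence": prev,
               "fold_vs_middle": fold, "mean_age_dx": np.nan,
               "age_dx_ci_low": np.nan, "age_dx_ci_high": np.nan}
        if ages is not None:
            a = ages[m & (y == 1)]
            a = a[np.isfinite(a)]
            if a.size >= MASK_MIN:
                mu = a.mean()
                half = 1.96 * a.std(ddof=1) / np.sqrt(a.size)
                rec.update(mean_age_dx=mu, age_dx_ci_low=mu - half,
                           age_dx_ci_high=mu + half)
        rows.append(rec)
    return pd.DataFrame(rows)


def tail_strata_summary(bins, labels, ages_at_diagnosis=None,
                        followup_status=None,
                        bands: Optional[dict] = None) -> pd.DataFrame:
    """Bottom / middle / top strata table (case counts, ages, follow-up).

    ``bands`` maps stratum name to an inclusive percentile-bin range;
    defaults to bottom 5, middle 48-53, top 5.  When ``followup_status``
    (per-participant strings) is given, incident and cancer-free counts
    and rates are included.  Cells behind fewer than five participants
    are masked.
    """
    bins = np.asarray(bins)
    y = np.asarray(labels, dtype=float)
    bands = bands or {"bottom": (1, 5), "middle": (48, 53),
                      "top": (96, 100)}
    rows = []
    for name, (lo, hi) in bands.items():
        m = (bins >= lo) & (bins <= hi)
        n = int(m.sum())
        cases = int(y[m].sum())
        rec = {"stratum": name, "n": n,
               "cases": cases if cases >= MASK_MIN or cases == 0 else np.nan,
               "prevalence": cases / n if n else np.nan}
        if ages_at_diagnosis is not None:
            a = np.asarray(ages_at_diagnosis, dtype=float)[m & (y == 1)]
            a = a[np.isfinite(a)]
            rec["mean_age_dx"] = a.mean() if a.size >= MASK_MIN else np.nan
            rec["sd_age_dx"] = (a.std(ddof=1) if a.size >= MASK_MIN
                                else np.nan)
        if followup_status is not None:
            st = np.asarray(followup_status, dtype=object)[m]
            inc = int((st == "incident").sum())
            free = int((st == "cancer_free").sum())
            atrisk = inc + int((st == "unchanged_control").sum())
            ncase = free + int((st == "persistent_case").sum())
            rec["incident"] = inc if inc >= MASK_MIN or inc == 0 else np.nan
            rec["cancer_free"] = (free if free >= MASK_MIN or free == 0
                                  else np.nan)
            rec["incident_rate"] = (inc / atrisk if atrisk >= MASK_MIN
                                    else np.nan)
            rec["cancer_free_rate"] = (free / ncase if ncase >= MASK_MIN
                                       else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def score_diagnostics(scores: pd.DataFrame, ages=None,
                      risk_groups: Optional[Sequence[tuple]] = None) -> dict:
    """Correlations, PCA, and age-dependency profile of component scores.

    Returns a dict with the pairwise Spearman matrix, PCA loadings and
    explained variances of the (unscaled) component scores, and — when
    ``ages`` is given — the mean score per age decile within low/middle/
    high risk groups (percentile ranges given by ``risk_groups``).
    Constant scores are excluded from the correlation matrix with a note.
    """
    keep = [c for c in scores.columns if scores[c].std() > 0]
    dropped = [c for c in scores.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant scores excluded from correlations: "
                      f"{dropped}")
    S = scores[keep]
    rho = pd.DataFrame(stats.spearmanr(S.to_numpy())[0]
                       if len(keep) > 1 else np.ones((1, 1)),
                       index=keep, columns=keep)
    M = S.to_numpy(dtype=float)
    Mc = M - M.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Mc, full_matrices=False)
    explained = sv ** 2 / (len(M) - 1)
    loadings = pd.DataFrame(Vt.T, index=keep,
                            columns=[f"PC{i + 1}" for i in range(len(sv))])
    out = {"spearman": rho, "pca_loadings": loadings,
           "pca_explained_var": explained}
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        deciles = np.clip(np.digitize(
            ages, np.quantile(ages, np.linspace(0.1, 0.9, 9))), 0, 9)
        groups = risk_groups or [("low", (0, 20)), ("middle", (40, 60)),
                                 ("high", (80, 100))]
        prof = {}
        for name in keep:
            pct = 100.0 * stats.rankdata(S[name]) / len(S)
            for gname, (lo, hi) in groups:
                sel = (pct > lo) & (pct <= hi)
                prof[(name, gname)] = pd.Series(
                    S[name][sel].groupby(deciles[sel]).mean())
        out["age_profile"] = pd.DataFrame(prof)
    return out
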