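"""Design construction, phenotype imputation, factor selection, and the
final per-cancer binomial GLM with its diagnostics.

The risk model is an ordinary maximum-likelihood logistic regression
(binomial GLM, logit link).  Categorical factors are reference-coded with
the most frequent level as reference; continuous factors enter through
orthogonal polynomial bases (degree 2-4, chosen by sequential likelihood-
ratio tests); ordinal survey factors enter as single numeric columns.
Model fit is summarized by deviance explained, 1 - deviance/null deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import CANCERS, FactorSpec, GROUP_DEMOGRAPHIC


# ---------------------------------------------------------------------------
# orthogonal polynomials (Forsythe three-term recurrence, exact on the
# training sample; the stored recurrence reapplies the same basis to new data)

@dataclass
class OrthoPoly:
    degree: int
    alpha: np.ndarray   # recurrence centers, length degree
    beta: np.ndarray    # recurrence norm ratios, length degree
    scale: np.ndarray   # column norms used to normalize, length degree

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cols = []
        p_prev = np.zeros_like(x)
        p_cur = np.ones_like(x)
        for k in range(self.degree):
            p_next = (x - self.alpha[k]) * p_cur - self.beta[k] * p_prev
            p_prev, p_cur = p_cur, p_next
            cols.append(p_cur / self.scale[k])
        return np.column_stack(cols)


def fit_ortho_poly(x: np.ndarray, degree: int) -> OrthoPoly:
    x = np.asarray(x, dtype=float)
    n = x.size
    alpha = np.zeros(degree)
    beta = np.zeros(degree)
    scale = np.zeros(degree)
    p_prev = np.zeros(n)
    p_cur = np.ones(n)
    norm_prev = float(n)
    for k in range(degree):
        alpha[k] = np.sum(x * p_cur * p_cur) / np.sum(p_cur * p_cur)
        beta[k] = 0.0 if k == 0 else np.sum(p_cur * p_cur) / norm_prev
        p_next = (x - alpha[k]) * p_cur - beta[k] * p_prev
        norm_prev = np.sum(p_cur * p_cur)
        p_prev, p_cur = p_cur, p_next
        nrm = np.sqrt(np.sum(p_cur * p_cur))
        if nrm < 1e-10:
            raise ValueError(f"degree {degree} unsupported: x has too few "
                             "distinct values")
        scale[k] = nrm
    return OrthoPoly(degree=degree, alpha=alpha, beta=beta, scale=scale)


# ---------------------------------------------------------------------------
# factor design matrix

@dataclass
class FactorMatrix:
    """Design columns with the factor -> columns / group bookkeeping."""

    X: pd.DataFrame
    factor_columns: dict
    groups: dict
    transforms: dict = field(default_factory=dict)

    def columns_of(self, factors: Sequence[str]) -> list:
        cols = []
        for f in factors:
            if f not in self.factor_columns:
                raise KeyError(f"unknown factor {f!r}")
            cols.extend(self.factor_columns[f])
        return cols

    def subset(self, factors: Sequence[str]) -> "FactorMatrix":
        cols = self.columns_of(factors)
        return FactorMatrix(X=self.X[cols],
                            factor_columns={f: self.factor_columns[f]
                                            for f in factors},
                            groups={f: self.groups[f] for f in factors},
                            transforms={f: self.transforms[f]
                                        for f in factors
                                        if f in self.transforms})


def build_design(table: pd.DataFrame, factors: Sequence[FactorSpec],
                 poly_degrees: Optional[dict] = None,
                 extra_numeric: Optional[dict] = None,
                 reference_fm: Optional[FactorMatrix] = None) -> FactorMatrix:
    """Expand a participant table into a GLM design.

    ``poly_degrees`` maps continuous factor names to polynomial degree
    (default 2).  ``extra_numeric`` adds pre-computed numeric columns
    (e.g. age basis, PCs, PRS) as single-column factors keyed by
    ``(name, group)``.  Passing ``reference_fm`` re-applies a training
    design's stored transforms (polynomial bases, dummy level order) to a
    new table, as needed for validation-set scoring.
    """
    poly_degrees = poly_degrees or {}
    cols = {}
    fcols: dict = {}
    groups: dict = {}
    transforms: dict = {}
    ref_t = reference_fm.transforms if reference_fm is not None else {}
    for spec in factors:
        v = table[spec.name]
        if spec.kind in ("binary", "ordinal"):
            cols[spec.name] = v.to_numpy(dtype=float)
            fcols[spec.name] = [spec.name]
        elif spec.kind == "continuous":
            if spec.name in ref_t:
                op = ref_t[spec.name]
            else:
                deg = int(poly_degrees.get(spec.name, 2))
                op = fit_ortho_poly(v.to_numpy(dtype=float), deg)
            B = op.transform(v.to_numpy(dtype=float))
            names = [f"{spec.name}^{d + 1}" for d in range(op.degree)]
            for nm, col in zip(names, B.T):
                cols[nm] = col
            fcols[spec.name] = names
            transforms[spec.name] = op
        else:  # categorical: reference-coded, most frequent level = reference
            if spec.name in ref_t:
                levels = ref_t[spec.name]
            else:
                counts = v.value_counts()
                ref = counts.index[0]
                levels = [ref] + [lv for lv in spec.params["levels"]
                                  if lv != ref]
            names = []
            for lv in levels[1:]:
                nm = f"{spec.name}[{lv}]"
                cols[nm] = (v == lv).to_numpy(dtype=float)
                names.append(nm)
            fcols[spec.name] = names
            transforms[spec.name] = levels
        groups[spec.name] = spec.group
    if extra_numeric:
        for (name, group), values in extra_numeric.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim == 1:
                cols[name] = arr
                fcols[name] = [name]
            else:
                names = [f"{name}^{d + 1}" for d in range(arr.shape[1])]
                for nm, col in zip(names, arr.T):
                    cols[nm] = col
                fcols[name] = names
            groups[name] = group
    X = pd.DataFrame(cols, index=table.index)
    return FactorMatrix(X=X, factor_columns=fcols, groups=groups,
                        transforms=transforms)


def choose_poly_degree(x: np.ndarray, y: np.ndarray, max_degree: int = 4,
                       alpha: float = 0.01) -> int:
    """Sequential LRT for the polynomial degree of one continuous factor.

    Starting from degree 2, the next degree is added while its single-
    factor likelihood-ratio test improves the fit at p < ``alpha``,
    up to ``max_degree``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    degree = 2
    op = fit_ortho_poly(x, degree)
    prev = sm.GLM(y, sm.add_constant(op.transform(x)),
                  family=sm.families.Binomial()).fit()
    while degree < max_degree:
        op = fit_ortho_poly(x, degree + 1)
        cur = sm.GLM(y, sm.add_constant(op.transform(x)),
                     family=sm.families.Binomial()).fit()
        lr = prev.deviance - cur.deviance
        p = stats.chi2.sf(max(lr, 0.0), df=1)
        if p >= alpha:
            break
        degree += 1
        prev = cur
    return degree


# ---------------------------------------------------------------------------
# phenotype imputation

def impute_phenotypes(table: pd.DataFrame,
                      columns: Optional[Sequence[str]] = None,
                      max_missing: float = 0.5):
    """Complete a factor table by predictive-mean-matching.

    Numeric columns with missing cells are regressed (OLS) on the
    complete numeric columns; each missing cell takes the observed value
    of the donor row with the nearest prediction (fallback: column mean
    when no complete predictors exist).  Categorical columns take the
    modal class.  Columns missing >= ``max_missing`` are dropped with a
    warning.  Returns ``(completed table, boolean imputation flags)``;
    non-missing cells are never changed.
    """
    out = table.copy()
    columns = list(columns) if columns is not None else [
        c for c in table.columns if table[c].isna().any()]
    flags = pd.DataFrame(False, index=table.index, columns=columns)
    dropped = []
    for c in columns:
        if out[c].isna().mean() >= max_missing:
            dropped.append(c)
    if dropped:
        warnings.warn(f"columns dropped for >= {max_missing:.0%} "
                      f"missingness: {dropped}")
        out = out.drop(columns=dropped)
        columns = [c for c in columns if c not in dropped]
        flags = flags.drop(columns=dropped)
    numeric = [c for c in out.columns
               if pd.api.types.is_numeric_dtype(out[c])]
    complete = [c for c in numeric if out[c].notna().all()]
    for c in columns:
        miss = out[c].isna()
        if not miss.any():
            continue
        flags[c] = miss
        if not pd.api.types.is_numeric_dtype(out[c]):
            mode = out[c].mode(dropna=True)
            out.loc[miss, c] = mode.iloc[0]
            continue
        preds = [p for p in complete if p != c]
        if preds:
            Z = out[preds].to_numpy(dtype=float)
            Z = np.column_stack([np.ones(len(Z)), Z])
            obs = (~miss).to_numpy()
            coef, *_ = np.linalg.lstsq(Z[obs], out.loc[~miss, c]
                                       .to_numpy(dtype=float), rcond=None)
            pred = Z @ coef
            obs_pred = pred[obs]
            obs_vals = out.loc[~miss, c].to_numpy(dtype=float)
            order = np.argsort(obs_pred, kind="stable")
            sorted_pred = obs_pred[order]
            pm = pred[miss.to_numpy()]
            j = np.clip(np.searchsorted(sorted_pred, pm), 0,
                        len(sorted_pred) - 1)
            jm1 = np.maximum(j - 1, 0)
            take_prev = (j > 0) & (np.abs(sorted_pred[jm1] - pm)
                                   <= np.abs(sorted_pred[j] - pm))
            donor = np.where(take_prev, jm1, j)
            out.loc[miss, c] = obs_vals[order[donor]]
        else:
            out.loc[miss, c] = out[c].mean()
    return out, flags


# ---------------------------------------------------------------------------
# the GLM risk model

@dataclass
class RiskModel:
    """Fitted binomial GLM: coefficients plus factor bookkeeping."""

    cancer: str
    intercept: float
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    deviance: float
    null_deviance: float
    nobs: int
    factor_columns: dict
    groups: dict

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    def linear_predictor(self, X: pd.DataFrame,
                         include_intercept: bool = True) -> np.ndarray:
        eta = X[self.coef.index].to_numpy(dtype=float) @ self.coef.to_numpy()
        return eta + (self.intercept if include_intercept else 0.0)

    def factor_p_min(self) -> pd.Series:
        return pd.Series({f: float(self.pvalues[cols].min())
                          for f, cols in self.factor_columns.items()})


def fit_glm(design: FactorMatrix, outcome, cancer: str = "") -> RiskModel:
    """Maximum-likelihood logit fit of ``outcome`` on the design columns."""
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = design.X
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError("design is rank deficient; most collinear pair: "
                         f"{X.columns[i]!r}, {X.columns[j]!r}")
    res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    if not res.converged:
        raise RuntimeError(f"GLM did not converge after {res.fit_history}")
    names = list(X.columns)
    return RiskModel(
        cancer=cancer,
        intercept=float(res.params[0]),
        coef=pd.Series(res.params[1:], index=names),
        se=pd.Series(res.bse[1:], index=names),
        pvalues=pd.Series(res.pvalues[1:], index=names),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        nobs=int(res.nobs),
        factor_columns=dict(design.factor_columns),
        groups=dict(design.groups),
    )


class LogisticRiskModel:
    """Sklearn-style wrapper: binomial GLM with fitted-attribute access.

    ``fit(X, y)`` accepts a :class:`FactorMatrix` or a plain DataFrame;
    fitted attributes: ``coef_``, ``intercept_``, ``pvalues_``,
    ``deviance_``, ``model_`` (the underlying :class:`RiskModel`).
    """

    def __init__(self, cancer: str = ""):
        self.cancer = cancer

    def get_params(self, deep: bool = True) -> dict:
        return {"cancer": self.cancer}

    def set_params(self, **params) -> "LogisticRiskModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _as_fm(self, X) -> FactorMatrix:
        if isinstance(X, FactorMatrix):
            return X
        X = pd.DataFrame(X)
        return FactorMatrix(X=X,
                            factor_columns={c: [c] for c in X.columns},
                            groups={c: "" for c in X.columns})

    def fit(self, X, y) -> "LogisticRiskModel":
        self.model_ = fit_glm(self._as_fm(X), y, cancer=self.cancer)
        self.coef_ = self.model_.coef.to_numpy()
        self.intercept_ = self.model_.intercept
        self.pvalues_ = self.model_.pvalues.to_numpy()
        self.deviance_ = self.model_.deviance
        return self

    def decision_function(self, X) -> np.ndarray:
        fm = self._as_fm(X)
        return self.model_.linear_predictor(fm.X)

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# selection stages

@dataclass
class SelectionTrace:
    """Per-cancer p-values and the union keep rule's outcome."""

    per_cancer: dict           # cancer -> DataFrame(factor, p_min, kept)
    kept: list                 # union over cancers (plus always-kept)
    always_kept: list


def stage1_select(design: FactorMatrix, outcomes: dict, alpha: float = 0.05,
                  always_keep: Optional[Sequence[str]] = None) \
        -> SelectionTrace:
    """First-stage factor screen on the all-factor GLM.

    Per cancer, fit the full model and flag factors whose every design
    column has Wald p >= ``alpha``.  Demographic covariates in
    ``always_keep`` are never dropped.  The final kept set is the union of
    per-cancer keeps.
    """
    if always_keep is None:
        always_keep = [f for f, g in design.groups.items()
                       if g == GROUP_DEMOGRAPHIC]
    per_cancer = {}
    union = set(always_keep)
    for cancer, y in outcomes.items():
        model = fit_glm(design, y, cancer=cancer)
        pmin = model.factor_p_min()
        kept_flags = (pmin < alpha) | pmin.index.isin(always_keep)
        per_cancer[cancer] = pd.DataFrame({
            "factor": pmin.index, "p_min": pmin.values,
            "kept": kept_flags.values})
        union |= set(pmin.index[kept_flags])
    kept = [f for f in design.factor_columns if f in union]
    return SelectionTrace(per_cancer=per_cancer, kept=kept,
                          always_kept=list(always_keep))


def scan_additional(design: FactorMatrix, outcomes: dict,
                    extra: pd.DataFrame, alpha: float = 1e-8,
                    alias_r2: float = 0.999):
    """Screen extra phenotypes one at a time against the base model.

    Each extra phenotype is appended (as one numeric column) to the base
    design and the augmented GLM is fitted per cancer; candidates are the
    phenotypes reaching Wald p < ``alpha`` in at least one cancer.
    Phenotypes aliased with the base design (R^2 > ``alias_r2``) are
    skipped with a note.  Returns ``(results DataFrame, candidate list)``.
    """
    Xb = design.X.to_numpy(dtype=float)
    Zb = np.column_stack([np.ones(len(Xb)), Xb])
    rows = []
    candidates = []
    for name in extra.columns:
        v = extra[name].to_numpy(dtype=float)
        coef, res_ss, *_ = np.linalg.lstsq(Zb, v, rcond=None)
        tot = np.sum((v - v.mean()) ** 2)
        r2 = 1.0 if tot == 0 else 1.0 - float(np.sum((v - Zb @ coef) ** 2)) / tot
        if r2 > alias_r2:
            rows.append({"phenotype": name, "cancer": None, "beta": np.nan,
                         "p_value": np.nan, "note": "aliased"})
            continue
        best_p = np.inf
        for cancer, y in outcomes.items():
            aug = FactorMatrix(
                X=design.X.assign(**{name: v}),
                factor_columns={**design.factor_columns, name: [name]},
                groups={**design.groups, name: "Candidate"})
            model = fit_glm(aug, y, cancer=cancer)
            p = float(model.pvalues[name])
            rows.append({"phenotype": name, "cancer": cancer,
                         "beta": float(model.coef[name]), "p_value": p,
                         "note": ""})
            best_p = min(best_p, p)
        if best_p < alpha:
            candidates.append(name)
    return pd.DataFrame(rows), candidates


# ---------------------------------------------------------------------------
# mixed-variable clustering (homogeneity = first PCAmix eigenvalue)

def _mix_columns(v: pd.Series) -> np.ndarray:
    """Represent one variable for PCAmix: standardized column (numeric) or
    centered indicators scaled by 1/sqrt(level frequency) (categorical)."""
    if pd.api.types.is_numeric_dtype(v):
        x = v.to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            return np.zeros((len(x), 1))
        return ((x - x.mean()) / sd)[:, None]
    codes, levels = pd.factorize(v)
    n = len(v)
    cols = []
    for k in range(len(levels)):
        ind = (codes == k).astype(float)
        p = ind.mean()
        cols.append((ind - p) / np.sqrt(p))
    return np.column_stack(cols)


def _homogeneity(mats: Sequence[np.ndarray]) -> float:
    """First eigenvalue of the PCAmix of the variables in the cluster."""
    M = np.column_stack(mats)
    n = M.shape[0]
    s = np.linalg.svd(M / np.sqrt(n), compute_uv=False)
    return float(s[0] ** 2)


def cluster_variables(candidates: pd.DataFrame, n_clusters: int,
                      scan_pvalues: Optional[pd.Series] = None,
                      missing_fraction: Optional[pd.Series] = None):
    """Hierarchical clustering of mixed variables by homogeneity loss.

    Cluster homogeneity is the first eigenvalue of the PCAmix of its
    members — equivalently the sum of squared correlations (quantitative)
    and correlation ratios (qualitative) between the members and the
    cluster's first principal component.  Merging proceeds greedily,
    always joining the pair with the smallest homogeneity decrease, until
    ``n_clusters`` remain.  The representative of each cluster is its
    member with the smallest scan p-value, ties broken by lower
    missingness then name.  Returns ``(labels Series, representatives)``.
    """
    names = list(candidates.columns)
    if len(names) < 1:
        raise ValueError("need at least one candidate variable")
    if len(names) == 1:
        return pd.Series([0], index=names), {0: names[0]}
    n_clusters = max(1, min(n_clusters, len(names)))
    mats = {nm: _mix_columns(candidates[nm]) for nm in names}
    clusters = [[nm] for nm in names]
    homog = [_homogeneity([mats[nm] for nm in c]) for c in clusters]
    while len(clusters) > n_clusters:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = _homogeneity([mats[nm] for nm in clusters[i] + clusters[j]])
                loss = homog[i] + homog[j] - h
                if best is None or loss < best[0] - 1e-12:
                    best = (loss, i, j, h)
        _, i, j, h = best
        clusters[i] = clusters[i] + clusters[j]
        homog[i] = h
        del clusters[j], homog[j]
    labels = pd.Series(index=names, dtype=int)
    reps = {}
    for k, members in enumerate(clusters):
        for nm in members:
            labels[nm] = k
        def key(nm):
            p = float(scan_pvalues.get(nm, 1.0)) if scan_pvalues is not None \
                else 1.0
            m = float(missing_fraction.get(nm, 0.0)) \
                if missing_fraction is not None else 0.0
            return (p, m, nm)
        reps[k] = sorted(members, key=key)[0]
    return labels, reps


# ---------------------------------------------------------------------------
# diagnostics

def deviance_decomposition(design: FactorMatrix, outcome,
                           cancer: str = "") -> pd.DataFrame:
    """Rank factors by single-factor deviance explained, then refit
    cumulatively in that order; report single, cumulative and marginal
    deviance-explained per factor."""
    y = np.asarray(outcome, dtype=float)
    singles = {}
    for f in design.factor_columns:
        m = fit_glm(design.subset([f]), y, cancer=cancer)
        singles[f] = m.deviance_explained
    order = sorted(singles, key=lambda f: -singles[f])
    rows = []
    prev = 0.0
    for k in range(1, len(order) + 1):
        m = fit_glm(design.subset(order[:k]), y, cancer=cancer)
        cum = m.deviance_explained
        rows.append({"factor": order[k - 1], "single": singles[order[k - 1]],
                     "cumulative": cum, "marginal": cum - prev})
        prev = cum
    return pd.DataFrame(rows)


def vif(design: FactorMatrix) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per design column.

    Exact collinearity reports infinity (with the offending pair noted in
    a warning).
    """
    X = design.X.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 design columns for VIF")
    out = {}
    for j, name in enumerate(design.X.columns):
        yj = X[:, j]
        Z = np.delete(X, j, axis=1)
        Z = np.column_stack([np.ones(len(Z)), Z])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        tot = np.sum((yj - yj.mean()) ** 2)
        if tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / tot
        if r2 > 1.0 - 1e-12:
            warnings.warn(f"column {name!r} is exactly collinear with the "
                          "remaining design")
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def test_interactions(design: FactorMatrix, outcome,
                      pairs: Sequence[tuple], cancer: str = "") \
        -> pd.DataFrame:
    """Likelihood-ratio tests for pairwise product terms.

    For each factor pair, the main-effects model is compared against the
    model augmented with all cross products of the two factors' design
    columns (so interactions with a polynomial block are tested against
    the whole block).  Returns per-pair LR statistic, df, p and deviance
    gain.
    """
    y = np.asarray(outcome, dtype=float)
    base = fit_glm(design, y, cancer=cancer)
    rows = []
    for (f1, f2) in pairs:
        if f1 == f2:
            raise ValueError(f"cannot interact factor {f1!r} with itself")
        cols1 = design.factor_columns[f1]
        cols2 = design.factor_columns[f2]
        Xa = design.X.copy()
        fcols = dict(design.factor_columns)
        inter_cols = []
        for c1 in cols1:
            for c2 in cols2:
                nm = f"{c1}:{c2}"
                Xa[nm] = design.X[c1] * design.X[c2]
                inter_cols.append(nm)
        fcols[f"{f1}:{f2}"] = inter_cols
        groups = {**design.groups, f"{f1}:{f2}": "Interaction"}
        aug = FactorMatrix(X=Xa, factor_columns=fcols, groups=groups)
        try:
            m = fit_glm(aug, y, cancer=cancer)
        except ValueError:
            rows.append({"factor1": f1, "factor2": f2, "lr": np.nan,
                         "df": len(inter_cols), "p_value": np.nan,
                         "deviance_gain": np.nan})
            continue
        lr = base.deviance - m.deviance
        df = len(inter_cols)
        rows.append({"factor1": f1, "factor2": f2, "lr": lr, "df": df,
                     "p_value": float(stats.chi2.sf(max(lr, 0.0), df=df)),
                     "deviance_gain": (base.deviance - m.deviance)
                     / base.null_deviance})
    return pd.DataFrame(rows)


test_interactions.__test__ = False  # keep pytest from collecting the API name
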