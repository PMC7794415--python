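"""Per-variant association scan, PCs, genomic control, clumping+thresholding
PRS, and analytic power for the additive case-control association test.

The polygenic risk score follows the standard clumping-and-thresholding
recipe: greedily keep the most significant variant passing the p-value
cutoff, discard its correlated neighbours (same chromosome, within the
clump window, dosage r^2 above the cap), repeat.  Scores are weighted sums
of dosages, with missing dosages mean-imputed at 2*MAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeMatrix:
    """Participants x variants dosage matrix with a variant sidecar.

    ``dosages`` holds values in [0, 2] (NaN = missing); ``variants`` has
    columns variant_id, chrom, pos (1-based), effect_allele, maf.
    """

    dosages: np.ndarray
    participant_ids: list
    variants: pd.DataFrame

    def __post_init__(self):
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[0] != len(self.participant_ids):
            raise ValueError("row count != number of participant ids")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count != number of variants")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @classmethod
    def empty(cls, n: int) -> "GenotypeMatrix":
        return cls(dosages=np.zeros((n, 0)),
                   participant_ids=[f"P{i + 1:07d}" for i in range(n)],
                   variants=pd.DataFrame(columns=[
                       "variant_id", "chrom", "pos", "effect_allele", "maf"]))

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(j) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, j[0]]


@dataclass
class PRSModel:
    """Selected variants and their log-odds weights."""

    variant_ids: list
    weights: np.ndarray
    p_threshold: float
    window_bp: int
    r2_max: float
    maf: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.variant_ids)


def compute_pcs(genotypes: GenotypeMatrix, k: int = 5) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Constant columns are excluded with a warning.  Sign convention: the
    first nonzero loading of each component is positive, so results do not
    depend on the SVD implementation's sign choices.  Returns an (n, k)
    array of participant coordinates ordered by decreasing variance.
    """
    if k == 0:
        return np.zeros((genotypes.n, 0))
    if k >= min(genotypes.n, genotypes.m):
        raise ValueError("k must be < min(n_participants, n_variants)")
    X = genotypes.dosages.astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant dosage columns "
                      "excluded from PCA")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        nz = np.nonzero(Vt[i])[0]
        if nz.size and Vt[i, nz[0]] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return U * S


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10):
    """Newton/IRLS logistic fit; returns (beta, cov) or raises on failure."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        if W.max() < 1e-12:
            raise np.linalg.LinAlgError("degenerate weights")
        XtW = X.T * W
        H = XtW @ X
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
        raise np.linalg.LinAlgError("separation / non-convergence")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * W) @ X)
    return beta, cov


def run_gwas(genotypes: GenotypeMatrix, phenotype: np.ndarray,
             covariates: Optional[pd.DataFrame] = None,
             maf_floor: float = 0.01) -> pd.DataFrame:
    """Per-variant logistic association scan (outcome ~ dosage + covariates).

    Returns an association table (variant_id, chrom, pos, effect_allele,
    maf, beta, se, p_value, converged).  Variants with empirical MAF below
    ``maf_floor`` are skipped (NaN stats); fits that separate are flagged
    non-converged and carry no p-value.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("phenotype must contain both classes")
    n = genotypes.n
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        base = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(base) < base.shape[1]:
            raise ValueError("covariates are rank deficient")
    else:
        base = np.ones((n, 1))

    rows = []
    for j in range(genotypes.m):
        g = genotypes.dosages[:, j].astype(float)
        if np.isnan(g).any():
            g = np.where(np.isnan(g),
                         2.0 * genotypes.variants["maf"].iloc[j], g)
        emp_maf = g.mean() / 2.0
        emp_maf = min(emp_maf, 1.0 - emp_maf)
        rec = dict(genotypes.variants.iloc[j])
        if emp_maf < maf_floor:
            rec.update(beta=np.nan, se=np.nan, p_value=np.nan,
                       converged=False)
            rows.append(rec)
            continue
        X = np.column_stack([base, g])
        try:
            beta, cov = _logistic_irls(X, y)
            b, se = beta[-1], np.sqrt(cov[-1, -1])
            p = 2.0 * stats.norm.sf(abs(b) / se)
            rec.update(beta=b, se=se, p_value=max(p, 1e-320), converged=True)
        except np.linalg.LinAlgError:
            rec.update(beta=np.nan, se=np.nan, p_value=np.nan,
                       converged=False)
        rows.append(rec)
    return pd.DataFrame(rows)


def genomic_control_lambda(p_values) -> float:
    """Median-based genomic-control inflation factor.

    lambda = median(qchisq(1 - p, df=1)) / qchisq(0.5, df=1); the null
    median of a 1-df chi-square is 0.4549364.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need >= 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def _dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    s1, s2 = g1.std(), g2.std()
    if s1 == 0 or s2 == 0:
        return 0.0
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def clump_threshold(assoc: pd.DataFrame, genotypes: GenotypeMatrix,
                    p_threshold: float = 1e-6, window_bp: int = 250_000,
                    r2_max: float = 0.1) -> PRSModel:
    """Greedy clumping-and-thresholding variant selection.

    Repeatedly take the unselected variant with the smallest p-value at or
    below ``p_threshold``; discard all unselected variants on the same
    chromosome within ``window_bp`` whose empirical dosage r^2 with it
    exceeds ``r2_max``.  Ties in p break by (chrom, pos).  An empty
    selection is permitted.
    """
    tab = assoc.dropna(subset=["p_value"]).copy()
    tab = tab[tab["p_value"] <= p_threshold]
    tab = tab.sort_values(["p_value", "chrom", "pos"], kind="stable")
    id2col = {vid: j for j, vid in
              enumerate(genotypes.variants["variant_id"])}
    selected = []
    dropped = set()
    for _, row in tab.iterrows():
        vid = row["variant_id"]
        if vid in dropped:
            continue
        selected.append(row)
        g_sel = genotypes.dosages[:, id2col[vid]]
        near = tab[(tab["chrom"] == row["chrom"])
                   & (np.abs(tab["pos"] - row["pos"]) <= window_bp)
                   & (tab["variant_id"] != vid)]
        for _, other in near.iterrows():
            ov = other["variant_id"]
            if ov in dropped or any(s["variant_id"] == ov for s in selected):
                continue
            if _dosage_r2(g_sel, genotypes.dosages[:, id2col[ov]]) > r2_max:
                dropped.add(ov)
    ids = [r["variant_id"] for r in selected]
    weights = np.array([r["beta"] for r in selected], dtype=float)
    mafs = np.array([r["maf"] for r in selected], dtype=float)
    return PRSModel(variant_ids=ids, weights=weights,
                    p_threshold=p_threshold, window_bp=window_bp,
                    r2_max=r2_max, maf=mafs)


def compute_prs(genotypes: GenotypeMatrix, model: PRSModel) -> np.ndarray:
    """Weighted dosage sum; missing dosages imputed at 2*MAF."""
    if len(model) == 0:
        return np.zeros(genotypes.n)
    id2col = {vid: j for j, vid in
              enumerate(genotypes.variants["variant_id"])}
    missing = [v for v in model.variant_ids if v not in id2col]
    if missing:
        raise KeyError(f"model variants absent from matrix: {missing}")
    cols = [id2col[v] for v in model.variant_ids]
    D = genotypes.dosages[:, cols].astype(float)
    if np.isnan(D).any():
        fill = (2.0 * model.maf if model.maf is not None
                else np.nanmean(D, axis=0))
        D = np.where(np.isnan(D), fill, D)
    return D @ model.weights


def association_power(maf: float, odds_ratio: float, alpha: float,
                      n_cases: int, n_controls: int) -> float:
    """Analytic power of the two-sided additive-dosage Wald test.

    Under the case-control allele model the control effect-allele
    frequency is ``p = maf`` and the case frequency implied by the
    per-allele odds ratio is ``pbar = OR*p / (1 - p + OR*p)``.  The Wald
    statistic for the log-OR has asymptotic variance
    ``1/(2*n_cases*pbar*(1-pbar)) + 1/(2*n_controls*p*(1-p))``; power is
    the probability that |Z| exceeds the two-sided alpha critical value
    given the resulting non-centrality.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    p = float(maf)
    pbar = odds_ratio * p / (1.0 - p + odds_ratio * p)
    var = (1.0 / (2.0 * n_cases * pbar * (1.0 - pbar))
           + 1.0 / (2.0 * n_controls * p * (1.0 - p)))
    ncp = np.log(odds_ratio) / np.sqrt(var)
    z = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))


class ClumpThresholdPRS:
    """Sklearn-style estimator wrapping scan + clump + score.

    Parameters mirror :func:`clump_threshold`; ``fit`` runs the per-variant
    scan on the training genotypes and phenotype, then the greedy
    selection; ``transform`` (= ``predict``) scores any genotype matrix
    with the fitted weights.
    """

    def __init__(self, p_threshold: float = 1e-6, window_bp: int = 250_000,
                 r2_max: float = 0.1, maf_floor: float = 0.01):
        self.p_threshold = p_threshold
        self.window_bp = window_bp
        self.r2_max = r2_max
        self.maf_floor = maf_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"p_threshold": self.p_threshold, "window_bp": self.window_bp,
                "r2_max": self.r2_max, "maf_floor": self.maf_floor}

    def set_params(self, **params) -> "ClumpThresholdPRS":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, genotypes: GenotypeMatrix, y,
            covariates: Optional[pd.DataFrame] = None) -> "ClumpThresholdPRS":
        self.assoc_ = run_gwas(genotypes, y, covariates,
                               maf_floor=self.maf_floor)
        self.model_ = clump_threshold(self.assoc_, genotypes,
                                      p_threshold=self.p_threshold,
                                      window_bp=self.window_bp,
                                      r2_max=self.r2_max)
        self.n_variants_ = len(self.model_)
        return self

    def transform(self, genotypes: GenotypeMatrix) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return compute_prs(genotypes, self.model_)

    predict = transform
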