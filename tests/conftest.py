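"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from dermrisk.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size cohort with genotypes, used by several read-only tests."""
    cfg = GeneratorConfig(n_participants=8000, n_variants=60, seed=11)
    cohort, genotypes = generate_cohort(cfg)
    return cfg, cohort, genotypes


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent brute-force Newton optimizer for the logistic MLE.

    Deliberately minimal: dense Hessian, no line search, no clever
    initialization — the cross-check for the package's GLM fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = mu * (1 - mu)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def greedy_clump_oracle(pvals, chrom, pos, dosages, p_threshold, window_bp,
                        r2_max):
    """Exhaustive re-implementation of greedy clumping for tiny instances."""
    m = len(pvals)
    candidates = [j for j in range(m)
                  if np.isfinite(pvals[j]) and pvals[j] <= p_threshold]
    candidates.sort(key=lambda j: (pvals[j], chrom[j], pos[j]))
    selected, removed = [], set()
    for j in candidates:
        if j in removed:
            continue
        selected.append(j)
        for k in candidates:
            if k == j or k in removed or k in selected:
                continue
            if chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= window_bp:
                g1, g2 = dosages[:, j], dosages[:, k]
                if g1.std() == 0 or g2.std() == 0:
                    continue
                r2 = np.corrcoef(g1, g2)[0, 1] ** 2
                if r2 > r2_max:
                    removed.add(k)
    return selected


def pair_concordance_auc(score, label):
    """O(n^2) all-pairs concordance count: the AUC oracle."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    cases = score[label == 1]
    ctrls = score[label == 0]
    wins = ties = 0
    for s1 in cases:
        for s0 in ctrls:
            if s1 > s0:
                wins += 1
            elif s1 == s0:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(ctrls))
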