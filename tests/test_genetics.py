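"""Association scan, PCs, genomic control, clumping, PRS, and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import newton_logistic
from dermrisk.genetics import (ClumpThresholdPRS, GenotypeMatrix, PRSModel,
                               association_power, clump_threshold,
                               compute_pcs, compute_prs,
                               genomic_control_lambda, run_gwas)
from dermrisk.evaluation import roc_auc
from dermrisk.synthetic import generate_genotypes


def _matrix(dosages, maf=None):
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": np.ones(m, dtype=int),
        "pos": (np.arange(m) + 1) * 1000,
        "effect_allele": ["A"] * m,
        "maf": maf if maf is not None else dosages.mean(axis=0) / 2})
    return GenotypeMatrix(dosages=dosages.astype(float),
                          participant_ids=[f"P{i}" for i in range(n)],
                          variants=variants)


class TestPCs:
    def test_planted_population_split_lands_on_pc1(self):
        rng = np.random.default_rng(0)
        n, m = 1000, 80
        pop = np.repeat([0, 1], n // 2)
        f0 = rng.uniform(0.1, 0.5, m)
        shift = np.clip(f0 + np.where(rng.random(m) < 0.5, 0.25, -0.08),
                        0.02, 0.95)
        freq = np.where(pop[:, None] == 0, f0, shift)
        g = _matrix(rng.binomial(2, freq).astype(float))
        pcs = compute_pcs(g, k=2)
        r = stats.pointbiserialr(pop, pcs[:, 0]).statistic
        assert abs(r) > 0.9

    def test_k_zero_gives_empty_coordinates(self):
        g = _matrix(np.random.default_rng(1).binomial(2, 0.3, (50, 10)))
        assert compute_pcs(g, k=0).shape == (50, 0)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        g = _matrix(rng.binomial(2, 0.3, (200, 30)).astype(float))
        pcs = compute_pcs(g, k=3)
        perm = rng.permutation(200)
        gp = _matrix(g.dosages[perm])
        assert np.allclose(compute_pcs(gp, k=3), pcs[perm], atol=1e-8)


class TestGwas:
    def test_planted_effect_recovered_within_3se(self):
        rng = np.random.default_rng(3)
        n, beta = 20000, 0.3
        g = rng.binomial(2, 0.3, n).astype(float)
        eta = -2.0 + beta * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        gm = _matrix(g[:, None])
        tab = run_gwas(gm, y)
        assert abs(tab["beta"][0] - beta) < 3 * tab["se"][0]

    def test_fit_matches_independent_newton_oracle(self):
        rng = np.random.default_rng(4)
        n = 2000
        g = rng.binomial(2, 0.25, n).astype(float)
        cov = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.4 * g + 0.3 * cov)))
             ).astype(float)
        tab = run_gwas(_matrix(g[:, None]), y,
                       covariates=pd.DataFrame({"c": cov}))
        X = np.column_stack([np.ones(n), cov, g])
        beta_oracle = newton_logistic(X, y)
        assert abs(tab["beta"][0] - beta_oracle[-1]) < 1e-6

    def test_dosage_identical_to_covariate_flagged(self):
        rng = np.random.default_rng(5)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        tab = run_gwas(_matrix(g[:, None]), y,
                       covariates=pd.DataFrame({"c": g}))
        assert not tab["converged"][0]
        assert np.isnan(tab["p_value"][0])

    def test_rare_variants_skipped_below_maf_floor(self):
        rng = np.random.default_rng(6)
        n = 2000
        d = np.column_stack([rng.binomial(2, 0.005, n),
                             rng.binomial(2, 0.3, n)]).astype(float)
        y = (rng.random(n) < 0.2).astype(float)
        tab = run_gwas(_matrix(d), y, maf_floor=0.01)
        assert np.isnan(tab["p_value"][0]) and np.isfinite(tab["p_value"][1])

    def test_one_class_phenotype_rejected(self):
        g = _matrix(np.random.default_rng(7).binomial(2, 0.3, (100, 2)))
        with pytest.raises(ValueError):
            run_gwas(g, np.zeros(100))


class TestLambda:
    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(8)
        lam = genomic_control_lambda(rng.uniform(0, 1, 100000))
        assert 0.98 < lam < 1.02

    def test_point_mass_at_half_gives_exactly_one(self):
        assert genomic_control_lambda(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_scale_equivariance_of_chi_square(self):
        rng = np.random.default_rng(9)
        chi2 = stats.chi2.rvs(1, size=5000, random_state=rng)
        p1 = stats.chi2.sf(chi2, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        lam1 = genomic_control_lambda(p1)
        lam2 = genomic_control_lambda(p2)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_control_lambda(np.full(50, 0.5))


class TestClump:
    def _assoc(self, pvals, gm, betas=None):
        tab = gm.variants.copy()
        tab["beta"] = betas if betas is not None else np.ones(len(pvals))
        tab["se"] = 1.0
        tab["p_value"] = pvals
        return tab

    def test_nothing_significant_gives_empty_model(self):
        g = _matrix(np.random.default_rng(10).binomial(2, 0.3, (100, 5)))
        model = clump_threshold(self._assoc(np.full(5, 0.5), g), g)
        assert len(model) == 0

    def test_independent_significant_variants_all_kept(self):
        g = _matrix(np.random.default_rng(11).binomial(2, 0.3, (2000, 6))
                    .astype(float))
        model = clump_threshold(self._assoc(np.full(6, 1e-8), g), g,
                                window_bp=10_000, r2_max=0.1)
        assert len(model) == 6

    def test_duplicate_column_keeps_smaller_p(self):
        rng = np.random.default_rng(12)
        base = rng.binomial(2, 0.3, 500).astype(float)
        d = np.column_stack([base, base, rng.binomial(2, 0.3, 500)])
        g = _matrix(d)
        p = np.array([1e-7, 1e-9, 1e-8])
        model = clump_threshold(self._assoc(p, g), g, window_bp=10_000)
        assert model.variant_ids == ["v1", "v2"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(13)
        d = rng.binomial(2, 0.3, (800, 10)).astype(float)
        g = _matrix(d)
        p = rng.uniform(0, 1e-6, 10)
        assoc = self._assoc(p, g)
        m1 = clump_threshold(assoc, g)
        m2 = clump_threshold(assoc.sample(frac=1, random_state=1), g)
        assert m1.variant_ids == m2.variant_ids


class TestPrs:
    def test_arithmetic_identities(self):
        rng = np.random.default_rng(14)
        d = rng.binomial(2, 0.4, (50, 3)).astype(float)
        g = _matrix(d)
        zero = PRSModel(["v0", "v1"], np.zeros(2), 1e-6, 250000, 0.1)
        assert np.all(compute_prs(g, zero) == 0)
        one = PRSModel(["v1"], np.array([1.0]), 1e-6, 250000, 0.1)
        assert np.array_equal(compute_prs(g, one), d[:, 1])
        ln2 = PRSModel(["v2"], np.array([np.log(2)]), 1e-6, 250000, 0.1)
        assert np.allclose(np.unique(compute_prs(g, ln2)),
                           np.log(2) * np.unique(d[:, 2]))

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(15)
        g = _matrix(rng.binomial(2, 0.3, (100, 4)).astype(float))
        ids = ["v0", "v1", "v2", "v3"]
        w1, w2 = rng.standard_normal(4), rng.standard_normal(4)
        args = (1e-6, 250000, 0.1)
        s12 = compute_prs(g, PRSModel(ids, w1 + w2, *args))
        s1 = compute_prs(g, PRSModel(ids, w1, *args))
        s2 = compute_prs(g, PRSModel(ids, w2, *args))
        assert np.allclose(s12, s1 + s2)

    def test_missing_dosage_imputed_at_twice_maf(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0]])
        g = _matrix(d, maf=np.array([0.3, 0.2]))
        model = PRSModel(["v1"], np.array([1.0]), 1e-6, 250000, 0.1,
                         maf=np.array([0.2]))
        assert np.allclose(compute_prs(g, model), [0.4, 1.0])

    def test_absent_variant_error_lists_ids(self):
        g = _matrix(np.zeros((5, 1)) + 1.0, maf=np.array([0.3]))
        model = PRSModel(["nope"], np.array([1.0]), 1e-6, 250000, 0.1)
        with pytest.raises(KeyError, match="nope"):
            compute_prs(g, model)

    def test_null_phenotype_prs_has_no_discrimination(self):
        """Selection and evaluation on disjoint splits: validation AUC
        stays at chance even though variants are picked at p < 0.05."""
        rng = np.random.default_rng(16)
        n, m = 20000, 200
        g = generate_genotypes(n, rng.uniform(0.05, 0.5, m), seed=17)
        y = (rng.random(n) < 0.1).astype(float)
        half = n // 2
        train = GenotypeMatrix(g.dosages[:half], g.participant_ids[:half],
                               g.variants)
        valid = GenotypeMatrix(g.dosages[half:], g.participant_ids[half:],
                               g.variants)
        est = ClumpThresholdPRS(p_threshold=0.05)
        est.fit(train, y[:half])
        assert est.n_variants_ > 0
        auc, _, _ = roc_auc(est.transform(valid), y[half:])
        assert 0.48 < auc < 0.52


class TestPower:
    def test_null_odds_ratio_power_equals_alpha(self):
        for alpha in (0.05, 1e-4):
            assert association_power(0.2, 1.0, alpha, 1000, 1000) == \
                pytest.approx(alpha, rel=1e-6)

    def test_monotone_in_sample_size_effect_and_alpha(self):
        base = association_power(0.1, 1.2, 1e-6, 5000, 50000)
        assert association_power(0.1, 1.2, 1e-6, 10000, 50000) > base
        assert association_power(0.1, 1.2, 1e-6, 5000, 100000) > base
        assert association_power(0.1, 1.3, 1e-6, 5000, 50000) > base
        assert association_power(0.1, 1.2, 1e-5, 5000, 50000) > base

    def test_protective_direction_also_detected(self):
        risk = association_power(0.3, 1.5, 1e-4, 800, 800)
        prot = association_power(0.3, 1 / 1.5, 1e-4, 800, 800)
        assert prot > 0.5 and risk > 0.5  # two-sided test sees both tails

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            association_power(0.0, 1.2, 1e-6, 100, 100)
        with pytest.raises(ValueError):
            association_power(0.1, -1.0, 1e-6, 100, 100)
        with pytest.raises(ValueError):
            association_power(0.1, 1.2, 1.5, 100, 100)


class TestEstimator:
    def test_get_set_params_roundtrip(self):
        est = ClumpThresholdPRS()
        est.set_params(p_threshold=1e-4, r2_max=0.2)
        assert est.get_params()["p_threshold"] == 1e-4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_transform_before_fit_raises(self):
        g = _matrix(np.ones((4, 1)), maf=np.array([0.3]))
        with pytest.raises(RuntimeError):
            ClumpThresholdPRS().transform(g)
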