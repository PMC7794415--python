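"""Design construction, imputation, GLM fitting, selection, clustering,
and collinearity / interaction diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import newton_logistic
from dermrisk.model_build import (FactorMatrix, FactorSpec,
                                  LogisticRiskModel, build_design,
                                  choose_poly_degree, cluster_variables,
                                  deviance_decomposition, fit_glm,
                                  fit_ortho_poly, impute_phenotypes,
                                  scan_additional, stage1_select,
                                  test_interactions, vif)


def _fm(X: pd.DataFrame) -> FactorMatrix:
    return FactorMatrix(X=X, factor_columns={c: [c] for c in X.columns},
                        groups={c: "" for c in X.columns})


def _logit_draw(eta, rng):
    return (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(float)


class TestOrthoPoly:
    def test_basis_is_orthonormal_on_training_sample(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 10, 500)
        op = fit_ortho_poly(x, 4)
        B = op.transform(x)
        assert np.allclose(B.T @ B, np.eye(4), atol=1e-8)
        assert np.allclose(B.sum(axis=0), 0, atol=1e-8)

    def test_transform_reapplies_training_basis_to_new_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 300)
        op = fit_ortho_poly(x, 3)
        # a cubic in x must be exactly representable in the basis
        xs = rng.normal(0, 1, 100)
        target = 1.5 * xs ** 3 - 2 * xs + 0.5
        B = np.column_stack([np.ones(100), op.transform(xs)])
        coef, res, *_ = np.linalg.lstsq(B, target, rcond=None)
        assert np.allclose(B @ coef, target, atol=1e-8)

    def test_deviance_invariant_to_affine_recoding(self):
        rng = np.random.default_rng(2)
        n = 3000
        x = rng.normal(0, 1, n)
        y = _logit_draw(-1 + 0.8 * x - 0.3 * x ** 2, rng)
        t1 = pd.DataFrame({"x": x})
        t2 = pd.DataFrame({"x": 12.0 + 7.0 * x})
        spec = FactorSpec("x", "continuous", "Miscellaneous",
                          {"mean": 0, "sd": 1})
        d1 = fit_glm(build_design(t1, [spec], poly_degrees={"x": 3}), y)
        d2 = fit_glm(build_design(t2, [spec], poly_degrees={"x": 3}), y)
        assert d1.deviance_explained == pytest.approx(
            d2.deviance_explained, abs=1e-10)

    def test_degree_selection_detects_curvature(self):
        rng = np.random.default_rng(3)
        n = 8000
        x = rng.normal(0, 1, n)
        y_lin = _logit_draw(-1 + 0.5 * x, rng)
        y_cub = _logit_draw(-1 + 0.5 * x + 0.4 * x ** 3, rng)
        assert choose_poly_degree(x, y_lin) == 2
        assert choose_poly_degree(x, y_cub) >= 3


class TestFitGlm:
    def test_single_binary_factor_equals_table_log_odds_ratio(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = (rng.random(n) < 0.3).astype(float)
        y = _logit_draw(-1 + 0.9 * x, rng)
        model = fit_glm(_fm(pd.DataFrame({"x": x})), y)
        tab = pd.crosstab(x, y).to_numpy().astype(float)
        lor = np.log(tab[1, 1] * tab[0, 0] / (tab[1, 0] * tab[0, 1]))
        assert model.coef["x"] == pytest.approx(lor, abs=1e-8)

    def test_null_design_has_no_deviance_explained(self):
        rng = np.random.default_rng(5)
        n = 5000
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=list("abcd"))
        y = (rng.random(n) < 0.2).astype(float)
        model = fit_glm(_fm(X), y)
        assert model.deviance_explained < 0.005
        assert np.all(np.abs(model.coef) < 3 * model.se)

    def test_matches_independent_newton_oracle(self):
        rng = np.random.default_rng(6)
        n, p = 3000, 6
        X = rng.standard_normal((n, p))
        beta = rng.normal(0, 0.5, p)
        y = _logit_draw(-0.5 + X @ beta, rng)
        model = fit_glm(_fm(pd.DataFrame(X, columns=[f"x{j}" for j in
                                                     range(p)])), y)
        oracle = newton_logistic(np.column_stack([np.ones(n), X]), y)
        assert np.allclose(model.coef.to_numpy(), oracle[1:], atol=1e-6)
        assert model.intercept == pytest.approx(oracle[0], abs=1e-6)

    def test_rank_deficiency_names_offending_columns(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        X = pd.DataFrame({"a": x, "b": 2 * x,
                          "c": rng.standard_normal(200)})
        y = (rng.random(200) < 0.5).astype(float)
        with pytest.raises(ValueError, match="'a'.*'b'|'b'.*'a'"):
            fit_glm(_fm(X), y)

    def test_one_class_outcome_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_glm(_fm(X), np.ones(10))


class TestEstimatorWrapper:
    def test_sklearn_surface(self):
        rng = np.random.default_rng(8)
        n = 1500
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = _logit_draw(-1 + X["x"].to_numpy(), rng)
        est = LogisticRiskModel(cancer="bcc").fit(X, y)
        assert est.get_params() == {"cancer": "bcc"}
        assert est.coef_.shape == (1,)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}


class TestImpute:
    def test_complete_table_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, 0.1, 0.9]})
        out, flags = impute_phenotypes(df)
        pd.testing.assert_frame_equal(out, df)
        assert not flags.to_numpy().any()

    def test_overly_missing_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [np.nan] * 8 + [1.0, 2.0],
                           "b": np.arange(10.0)})
        with pytest.warns(UserWarning, match="missingness"):
            out, _ = impute_phenotypes(df)
        assert "a" not in out.columns

    def test_mcar_imputation_preserves_mean(self):
        rng = np.random.default_rng(9)
        n = 5000
        z = rng.standard_normal(n)
        x = 2.0 + z + 0.5 * rng.standard_normal(n)
        xm = x.copy()
        miss = rng.random(n) < 0.10
        xm[miss] = np.nan
        df = pd.DataFrame({"x": xm, "z": z})
        out, flags = impute_phenotypes(df)
        se = x[~miss].std() / np.sqrt(miss.sum())
        assert abs(out["x"].mean() - x[~miss].mean()) < 2 * se
        # observed cells untouched
        assert np.array_equal(out.loc[~miss, "x"], x[~miss])
        assert flags["x"].sum() == miss.sum()

    def test_categorical_missing_takes_modal_class(self):
        df = pd.DataFrame({
            "c": pd.Categorical(["a", "a", "b", None, "a", None]),
            "z": np.arange(6.0)})
        out, _ = impute_phenotypes(df)
        assert (out["c"] == "a").sum() == 5


class TestSelection:
    def _cohortish(self, rng, n=20000):
        x_signal = (rng.random(n) < 0.3).astype(float)
        x_noise = rng.standard_normal(n)
        age = rng.integers(30, 91, n).astype(float)
        eta = {"bcc": -2 + 0.7 * x_signal, "scc": -2.5 + 0.0 * x_signal,
               "melanoma": -3 + 0.0 * x_signal}
        X = pd.DataFrame({"signal": x_signal, "noise": x_noise,
                          "age_col": (age - 60) / 13})
        fm = FactorMatrix(X=X,
                          factor_columns={"signal": ["signal"],
                                          "noise": ["noise"],
                                          "demo": ["age_col"]},
                          groups={"signal": "Mole", "noise": "Exposure",
                                  "demo": "Demographic"})
        outcomes = {c: _logit_draw(eta[c], rng) for c in eta}
        return fm, outcomes

    def test_union_rule_keeps_single_cancer_signal_for_all(self):
        rng = np.random.default_rng(10)
        fm, outcomes = self._cohortish(rng)
        trace = stage1_select(fm, outcomes, alpha=0.05,
                              always_keep=["demo"])
        assert "signal" in trace.kept            # driven by BCC only
        assert "demo" in trace.kept              # never dropped
        for c, df in trace.per_cancer.items():
            assert set(df.columns) == {"factor", "p_min", "kept"}

    def test_alpha_one_keeps_everything(self):
        rng = np.random.default_rng(11)
        fm, outcomes = self._cohortish(rng, n=2000)
        trace = stage1_select(fm, outcomes, alpha=1.0, always_keep=[])
        assert set(trace.kept) == {"signal", "noise", "demo"}

    def test_scan_skips_aliased_and_finds_planted_phenotype(self):
        rng = np.random.default_rng(12)
        n = 50000
        base = (rng.random(n) < 0.3).astype(float)
        planted = (rng.random(n) < 0.4).astype(float)
        y = _logit_draw(-2.2 + 0.5 * base + np.log(1.5) * planted, rng)
        fm = _fm(pd.DataFrame({"base": base}))
        extra = pd.DataFrame({"copy_of_base": base, "planted": planted,
                              "noise": rng.standard_normal(n)})
        tab, candidates = scan_additional(fm, {"bcc": y}, extra,
                                          alpha=1e-8)
        aliased = tab[tab["phenotype"] == "copy_of_base"]
        assert (aliased["note"] == "aliased").all()
        assert candidates == ["planted"]


class TestClusterVariables:
    def test_identical_pair_merges_with_zero_loss(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(300)
        df = pd.DataFrame({"a": x, "b": x.copy(),
                           "c": rng.standard_normal(300)})
        labels, reps = cluster_variables(df, n_clusters=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_block_structure_recovered_with_mixed_types(self):
        rng = np.random.default_rng(14)
        n = 400
        z = rng.standard_normal(n)
        block = pd.DataFrame({
            "q1": z + 0.1 * rng.standard_normal(n),
            "q2": -z + 0.1 * rng.standard_normal(n),
            "cat": pd.Categorical(np.where(z > 0, "hi", "lo")),
            "n1": rng.standard_normal(n),
            "n2": rng.standard_normal(n)})
        labels, _ = cluster_variables(block, n_clusters=3)
        assert labels["q1"] == labels["q2"] == labels["cat"]
        assert len({labels["q1"], labels["n1"], labels["n2"]}) == 3

    def test_representative_prefers_low_pvalue_then_missingness(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"a": x, "b": x + 0.01 * rng.standard_normal(200)})
        p = pd.Series({"a": 0.5, "b": 1e-9})
        labels, reps = cluster_variables(df, 1, scan_pvalues=p)
        assert reps[0] == "b"

    def test_single_candidate_is_trivial_singleton(self):
        df = pd.DataFrame({"only": np.arange(10.0)})
        labels, reps = cluster_variables(df, 3)
        assert reps == {0: "only"}


class TestDiagnostics:
    def test_deviance_decomposition_telescopes_and_ranks(self):
        rng = np.random.default_rng(16)
        n = 8000
        strong = rng.standard_normal(n)
        weak = rng.standard_normal(n)
        null = rng.standard_normal(n)
        y = _logit_draw(-1.5 + 1.2 * strong + 0.2 * weak, rng)
        fm = _fm(pd.DataFrame({"strong": strong, "weak": weak,
                               "null": null}))
        tab = deviance_decomposition(fm, y)
        assert list(tab["factor"])[0] == "strong"
        full = fit_glm(fm, y).deviance_explained
        assert tab["marginal"].sum() == pytest.approx(full, abs=1e-10)
        assert tab.set_index("factor").loc["null", "marginal"] < 0.005

    def test_vif_identities(self):
        rng = np.random.default_rng(17)
        n = 5000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        out = vif(_fm(pd.DataFrame({"a": a, "b": b})))
        assert np.allclose(out, 1.0, atol=0.01)
        rho = 0.95
        c = rho * a + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        out = vif(_fm(pd.DataFrame({"a": a, "c": c})))
        assert out["a"] == pytest.approx(1 / (1 - rho ** 2), rel=0.1)
        with pytest.warns(UserWarning, match="collinear"):
            out = vif(_fm(pd.DataFrame({"a": a, "dup": a.copy()})))
        assert np.isinf(out["a"]) and np.isinf(out["dup"])

    def test_interaction_lrt_detects_planted_product(self):
        rng = np.random.default_rng(18)
        n = 20000
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        y = _logit_draw(-1.5 + 0.3 * x1 + 0.3 * x2 + 0.8 * x1 * x2, rng)
        fm = _fm(pd.DataFrame({"x1": x1, "x2": x2}))
        tab = test_interactions(fm, y, [("x1", "x2")])
        assert tab["p_value"][0] < 1e-6
        assert tab["deviance_gain"][0] > 0

    def test_self_pair_rejected(self):
        fm = _fm(pd.DataFrame({"x1": np.arange(10.0),
                               "x2": np.arange(10.0) ** 2}))
        with pytest.raises(ValueError, match="itself"):
            test_interactions(fm, (np.arange(10) % 2).astype(float),
                              [("x1", "x1")])
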