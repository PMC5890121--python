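import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ernet.errors import DegenerateInputError, ValidationError
from ernet.sem import (
    SEMResult,
    StructuralEquationModel,
    association_report,
    bonferroni,
    fit_acceptable,
    fit_sem,
    simulate_sem_dataset,
)


def _exact_cov_data(sigma, n, seed=0):
    """Data whose sample covariance (ddof=1) equals sigma exactly."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, sigma.shape[0]))
    x = x - x.mean(0)
    s = np.cov(x, rowvar=False, ddof=1)
    whiten = np.linalg.inv(np.linalg.cholesky(s))
    return (x @ whiten.T) @ np.linalg.cholesky(sigma).T


class TestPopulationConsistency:
    def test_estimates_recover_generating_parameters(self):
        """On model-implied covariance input the fit reproduces the truth."""
        model = StructuralEquationModel()
        struct = model._structure()
        # truth in standardized metric: all loadings 0.8, beta_ES = -0.4
        lam_marker = 0.8
        theta0 = np.zeros(struct.q)
        theta0[:struct.n_lam] = 1.0                 # loadings equal to markers
        beta = np.array([-0.4 / lam_marker, 0, 0, 0, 0])
        theta0[struct.n_lam:struct.n_lam + 5] = beta
        phi = np.eye(5)
        phi[0, 0] = phi[1, 1] = lam_marker ** 2
        L = np.linalg.cholesky(phi)
        i0 = struct.n_lam + 5
        theta0[i0:i0 + struct.n_chol] = L[struct.tril]
        theta0[i0 + struct.n_chol:i0 + struct.n_chol + 10] = 1 - lam_marker ** 2
        theta0[-1] = 1 - 0.4 ** 2
        sigma0 = struct.implied(theta0)
        data = _exact_cov_data(sigma0, n=400, seed=1)
        X = pd.DataFrame(data, columns=struct.observed)
        model.fit(X)
        assert model.converged_
        assert model.beta_["ES"] == pytest.approx(-0.4, abs=1e-3)
        for item, val in model.loadings_.items():
            assert val == pytest.approx(0.8, abs=1e-3)
        f = model.fit_indices_
        assert f["chi2"] == pytest.approx(0.0, abs=1e-4)
        assert f["CFI"] == pytest.approx(1.0, abs=1e-6)
        assert f["RMSEA"] == pytest.approx(0.0, abs=1e-6)
        assert f["SRMR"] == pytest.approx(0.0, abs=1e-4)


class TestCrossCheckAgainstFactorAnalysis:
    def test_cr_loadings_match_ml_factor_analysis(self):
        """Measurement part agrees with an independent ML factor analysis."""
        from statsmodels.multivariate.factor import Factor

        df = simulate_sem_dataset(2000, loading=0.8, beta={}, seed=7)
        res = fit_sem(df.drop(columns="efficiency"), df["efficiency"])
        items = df[[f"cr{i}" for i in range(1, 7)]].to_numpy()
        fa = Factor(endog=(items - items.mean(0)) / items.std(0, ddof=1),
                    n_factor=1, method="ml").fit()
        ref = np.abs(fa.loadings[:, 0])
        mine = np.array([res.loadings[f"cr{i}"] for i in range(1, 7)])
        np.testing.assert_allclose(mine, ref, atol=0.03)


class TestRecoveryAndCalibration:
    def test_parameter_recovery_smoke(self):
        biases = []
        for s in range(20):
            df = simulate_sem_dataset(500, loading=0.8, beta={"ES": -0.4}, seed=100 + s)
            res = fit_sem(df.drop(columns="efficiency"), df["efficiency"])
            assert res.converged
            biases.append(res.beta["ES"] + 0.4)
        assert abs(np.mean(biases)) < 0.05

    def test_rescaling_invariance(self):
        df = simulate_sem_dataset(300, beta={"ES": -0.4}, seed=5)
        r1 = fit_sem(df.drop(columns="efficiency"), df["efficiency"])
        r2 = fit_sem(df.drop(columns="efficiency"), 100.0 * df["efficiency"])
        for k in r1.beta:
            assert r1.beta[k] == pytest.approx(r2.beta[k], abs=1e-6)

    def test_robust_se_leaves_estimates_unchanged(self):
        df = simulate_sem_dataset(300, beta={"ES": -0.4}, seed=6)
        plain = fit_sem(df.drop(columns="efficiency"), df["efficiency"])
        robust = fit_sem(df.drop(columns="efficiency"), df["efficiency"], robust_se=True)
        assert plain.beta["ES"] == pytest.approx(robust.beta["ES"], abs=1e-9)
        assert plain.beta_se["ES"] != robust.beta_se["ES"]

    def test_supplementary_variant_without_na(self):
        df = simulate_sem_dataset(300, beta={"ES": -0.4}, seed=8)
        res = fit_sem(df.drop(columns=["efficiency", "na_score"]),
                      df["efficiency"], include_na=False)
        assert "na_score" not in res.beta
        assert res.beta["ES"] == pytest.approx(-0.4, abs=0.15)


class TestDegenerateInputs:
    def test_constant_efficiency_rejected(self):
        df = simulate_sem_dataset(200, seed=2)
        with pytest.raises(DegenerateInputError, match="efficiency"):
            fit_sem(df.drop(columns="efficiency"), np.ones(200))

    def test_misaligned_efficiency_rejected(self):
        df = simulate_sem_dataset(100, seed=2)
        with pytest.raises(ValidationError):
            fit_sem(df.drop(columns="efficiency"), np.ones(50))

    def test_small_sample_warns(self):
        df = simulate_sem_dataset(25, seed=3)
        with pytest.warns(UserWarning, match="n = 25"):
            fit_sem(df.drop(columns="efficiency"), df["efficiency"])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.004, 10, 0.04), (0.2, 10, 1.0), (0.05, 1, 0.05),
    ])
    def test_examples(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni(1.5, 10)

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50), st.integers(1, 50))
    def test_monotone_and_capped(self, p1, p2, m1, m2):
        if p1 <= p2:
            assert bonferroni(p1, m1) <= bonferroni(p2, m1)
        if m1 <= m2:
            assert bonferroni(p1, m1) <= bonferroni(p1, m2)
        assert bonferroni(p1, m1) <= 1.0


def _result(beta_es=0.0, p_es=1.0, fit=None):
    fit = fit or {"chi2": 10.0, "df": 66.0, "pvalue": 0.9,
                  "CFI": 0.97, "TLI": 0.96, "RMSEA": 0.03, "SRMR": 0.04}
    items = {f"es{i}": 0.8 for i in range(1, 5)} | {f"cr{i}": 0.8 for i in range(1, 7)}
    return SEMResult(
        loadings=items, loadings_se={k: 0.05 for k in items},
        beta={"ES": beta_es, "CR": 0.0, "age": 0.0, "gender": 0.0, "na_score": 0.0},
        beta_se={k: 0.1 for k in ("ES", "CR", "age", "gender", "na_score")},
        beta_pvalues={"ES": p_es, "CR": 0.8, "age": 0.9, "gender": 0.9, "na_score": 0.9},
        fit=fit, converged=True, n_obs=100,
    )


class TestFitAcceptable:
    def test_all_pass(self):
        ok, verdicts = fit_acceptable(_result())
        assert ok and all(verdicts.values())

    def test_cfi_flagged(self):
        bad = _result(fit={"chi2": 99.0, "df": 66.0, "pvalue": 0.01,
                           "CFI": 0.85, "TLI": 0.96, "RMSEA": 0.03, "SRMR": 0.04})
        ok, verdicts = fit_acceptable(bad)
        assert not ok and not verdicts["CFI"] and verdicts["TLI"]


class TestAssociationReport:
    def test_grid_layout_flags_and_na(self):
        results = {
            ("FPN", 0.15): _result(-0.4, 0.002),
            ("FPN", 0.20): _result(-0.3, 0.006),
            ("DMN", 0.15): _result(0.1, 0.5),
        }
        rep = association_report(results, "ES", ["FPN", "DMN"], [0.15, 0.20], m=10)
        assert rep.grid.loc["0.15", "FPN"] == "-0.400"
        assert rep.grid.loc["0.15 (p)", "FPN"] == "0.020"
        assert rep.grid.loc["0.20", "DMN"] == "N\\A"
        tidy = rep.tidy.set_index(["network", "threshold"])
        assert tidy.loc[("FPN", 0.15), "significant"]
        assert not tidy.loc[("FPN", 0.20), "significant"]
        assert tidy.loc[("FPN", 0.20), "marginal"]      # corrected p = 0.06
        assert not tidy.loc[("DMN", 0.15), "significant"]

    def test_all_excluded_gives_all_na(self):
        rep = association_report({}, "CR", ["FPN"], [0.15, 0.20], m=10)
        assert (rep.grid.values == "N\\A").all()
        assert len(rep.tidy) == 0
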