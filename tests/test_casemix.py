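"""Logistic case-mix model: closed-form oracles, score equations, covariance."""

import numpy as np
import pytest
from scipy.special import expit

import careprofiler as cp
from careprofiler.registry import DesignMatrix
from conftest import binary_cohort, make_cohort


class TestMaximumLikelihood:
    def test_intercept_only_closed_form(self):
        """25 events in 100 at one covariate pattern: logit of the proportion.

        The hospital column is dropped to make the model intercept-only."""
        cohort = binary_cohort({"A": (25, 100)})
        # single hospital: build a bare intercept+age design by hand
        X = np.column_stack([np.ones(100)])
        design = DesignMatrix(X, ["intercept"], "reference", ["A", "B"],
                              n_covariate_columns=1)
        # patch: hospital pattern columns absent; bypass rank of hosp block
        y = cohort.df["outcome"].to_numpy(float)
        fit = cp.fit_casemix_model(design, y)
        assert fit.theta[0] == pytest.approx(np.log(25 / 75), abs=1e-8)

    def test_two_hospital_log_odds_ratio(self):
        """(10/100) vs (20/100) with no covariates: psi_2 = log OR of the 2x2."""
        cohort = binary_cohort({"A": (10, 100), "B": (20, 100)})
        design = cp.encode_design(cohort)
        # age is constant -> collinear with intercept; drop it for this oracle
        keep = [0] + list(range(2, design.X.shape[1]))
        design = DesignMatrix(design.X[:, keep],
                              [design.column_labels[j] for j in keep],
                              "reference", design.hospital_levels,
                              n_covariate_columns=design.n_covariate_columns - 1)
        # constant dummy columns are all-zero -> drop zero-variance columns
        nz = [j for j in range(design.X.shape[1])
              if design.X[:, j].any() or design.column_labels[j] == "intercept"]
        design = DesignMatrix(design.X[:, nz], [design.column_labels[j] for j in nz],
                              "reference", design.hospital_levels,
                              n_covariate_columns=1)
        y = cohort.df["outcome"].to_numpy(float)
        fit = cp.fit_casemix_model(design, y)
        expected = np.log((20 / 80) / (10 / 90))
        assert fit.theta[-1] == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(0.8109, abs=5e-5)

    def test_score_equations_vanish(self, small_registry):
        """At the optimum, sum_i (y_i - p_i) x_i = 0 componentwise."""
        fit, design, y = (small_registry["fit"], small_registry["design"],
                          small_registry["y"])
        assert not fit.penalized
        score = design.X.T @ (y - fit.fitted_risks)
        assert np.max(np.abs(score)) < 1e-6

    def test_matches_statsmodels(self, small_registry):
        """Independent cross-check: statsmodels Logit agrees on theta and SEs."""
        import statsmodels.api as sm

        design, y = small_registry["design"], small_registry["y"]
        sm_fit = sm.Logit(y, design.X).fit(disp=0, method="newton", tol=1e-10)
        fit = small_registry["fit"]
        np.testing.assert_allclose(fit.theta, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.covariance)),
                                   sm_fit.bse, rtol=1e-5)

    def test_covariance_matches_numerical_hessian(self):
        """Inverse covariance equals the numerically differentiated Hessian."""
        cohort = binary_cohort({"A": (8, 30), "B": (12, 30)})
        rng = np.random.default_rng(0)
        cohort.df["age"] = rng.uniform(60, 70, 60).round(1)
        design = cp.encode_design(cohort)
        design.X[:, 1] -= 65.0  # center age so the FD oracle is well conditioned
        keep = [0, 1, design.column_labels.index("hospital=B")]
        design = DesignMatrix(design.X[:, keep],
                              [design.column_labels[j] for j in keep],
                              "reference", ["A", "B"], n_covariate_columns=2)
        y = cohort.df["outcome"].to_numpy(float)
        fit = cp.fit_casemix_model(design, y)

        def negll(theta):
            eta = design.X @ theta
            return -np.sum(y * eta - np.logaddexp(0, eta))

        eps = 1e-4
        p = len(fit.theta)
        H = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                ei = np.eye(p)[i] * eps
                ej = np.eye(p)[j] * eps
                H[i, j] = (negll(fit.theta + ei + ej) - negll(fit.theta + ei - ej)
                           - negll(fit.theta - ei + ej) + negll(fit.theta - ei - ej)
                           ) / (4 * eps ** 2)
        np.testing.assert_allclose(fit.covariance, np.linalg.inv(H), rtol=1e-4)

    def test_zero_event_hospital_triggers_firth(self):
        """A hospital with no events separates; Firth keeps estimates finite."""
        cohort = binary_cohort({"A": (20, 80), "B": (0, 25), "C": (15, 60)})
        design = cp.encode_design(cohort)
        keep = [0] + list(range(design.n_covariate_columns, design.X.shape[1]))
        design = DesignMatrix(design.X[:, keep],
                              [design.column_labels[j] for j in keep],
                              "reference", design.hospital_levels,
                              n_covariate_columns=1)
        y = cohort.df["outcome"].to_numpy(float)
        fit = cp.fit_casemix_model(design, y)
        assert fit.penalized
        assert np.isfinite(fit.theta).all()
        assert np.abs(fit.theta).max() < 10

    def test_rank_deficient_design_names_columns(self, small_registry):
        design = small_registry["design"]
        X = np.hstack([design.X, design.X[:, [1]]])
        dup = DesignMatrix(X, design.column_labels + ["age_copy"], "reference",
                           design.hospital_levels,
                           n_covariate_columns=design.n_covariate_columns + 1)
        with pytest.raises(ValueError, match="rank deficient"):
            cp.fit_casemix_model(dup, small_registry["y"])

    def test_codings_give_identical_fitted_risks(self, small_registry):
        """Reference and effects coding span the same space: same risks."""
        cohort, y = small_registry["cohort"], small_registry["y"]
        fit_ref = small_registry["fit"]
        fit_eff = cp.fit_casemix_model(cp.encode_design(cohort, "effects"), y)
        np.testing.assert_allclose(fit_ref.fitted_risks, fit_eff.fitted_risks,
                                   atol=1e-8)


class TestPredictRisk:
    def test_hand_arithmetic(self, small_registry):
        fit = small_registry["fit"]
        rec = {"age": 60.0, "sex": "male", "consciousness": "alert",
               "subtype": "ischemic", "smoking": "no",
               "atrial_fibrillation": "no", "diabetes": "no"}
        h = fit.hospital_levels[2]
        from careprofiler.registry import encode_covariate_row
        eta = encode_covariate_row(rec) @ fit.theta[:fit.n_covariate_columns] \
            + fit.psi_full()[2]
        assert cp.predict_risk(fit, rec, h) == pytest.approx(expit(eta))

    def test_monotone_in_psi(self, small_registry):
        fit = small_registry["fit"]
        rec = {"age": 70.0, "sex": "female", "consciousness": "alert",
               "subtype": "hemorrhagic", "smoking": "no",
               "atrial_fibrillation": "no", "diabetes": "no"}
        psi = fit.psi_full()
        risks = [cp.predict_risk(fit, rec, h) for h in fit.hospital_levels]
        assert np.argsort(risks).tolist() == np.argsort(psi).tolist()

    def test_unknown_hospital_errors(self, small_registry):
        with pytest.raises(KeyError, match="nowhere"):
            cp.predict_risk(small_registry["fit"], {"age": 70.0, "sex": "female",
                            "consciousness": "alert", "subtype": "hemorrhagic",
                            "smoking": "no", "atrial_fibrillation": "no",
                            "diabetes": "no"}, "nowhere")


class TestHospitalOddsRatios:
    def test_two_hospital_symmetry(self):
        """psi = (0, 0.2): ORs are exp(-0.1) and exp(+0.1) about the average."""
        cohort = binary_cohort({"A": (10, 100), "B": (20, 100)})
        design = cp.encode_design(cohort)
        y = cohort.df["outcome"].to_numpy(float)
        keep = [0, design.column_labels.index("hospital=B")]
        design = DesignMatrix(design.X[:, keep],
                              [design.column_labels[j] for j in keep],
                              "reference", ["A", "B"], n_covariate_columns=1)
        fit = cp.fit_casemix_model(design, y)
        ors = cp.hospital_or_vs_average(fit)
        psi2 = fit.theta[-1]
        assert ors["A"] == pytest.approx(np.exp(-psi2 / 2))
        assert ors["B"] == pytest.approx(np.exp(psi2 / 2))

    def test_geometric_mean_is_one(self, small_registry):
        ors = cp.hospital_or_vs_average(small_registry["fit"])
        assert np.exp(np.mean(np.log(ors))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_effects_coding_fit(self, small_registry):
        """Reference-coding ORs equal exponentiated effects-coding effects."""
        cohort, y = small_registry["cohort"], small_registry["y"]
        fit_eff = cp.fit_casemix_model(cp.encode_design(cohort, "effects"), y)
        ors_ref = cp.hospital_or_vs_average(small_registry["fit"])
        ors_eff = np.exp(fit_eff.psi_full())
        np.testing.assert_allclose(ors_ref.to_numpy(), ors_eff, rtol=1e-6)


class TestCoefficientTable:
    @pytest.mark.parametrize("estimate,printed_or", [
        (0.422, 1.525),   # diabetes
        (0.378, 1.459),   # atrial fibrillation
        (-0.870, 0.419),  # ischemic vs hemorrhagic
    ])
    def test_or_reproduces_published_rows(self, estimate, printed_or):
        """exp(beta) reproduces published odds ratios to 3 decimals."""
        assert np.exp(estimate) == pytest.approx(printed_or, abs=5e-4)

    def test_table_contents(self, small_registry):
        fit, design, y = (small_registry["fit"], small_registry["design"],
                          small_registry["y"])
        table = cp.coefficient_table(fit, design, y)
        np.testing.assert_allclose(table["or"], np.exp(table["estimate"]))
        np.testing.assert_allclose(table["ci_low"],
                                   np.exp(table["estimate"] - 1.96 * table["se"]))
        # one LR p-value per multi-level factor, shared across its terms
        assert table.loc["consciousness=drowsy", "p_lr_factor"] == \
            table.loc["consciousness=unconscious", "p_lr_factor"]
        assert 0 <= table.loc["sex=male", "p_lr_factor"] <= 1

    def test_null_effect_symmetric_ci(self):
        """estimate 0: OR 1 with multiplicatively symmetric CI."""
        est, se = 0.0, 0.3
        lo, hi = np.exp(est - 1.96 * se), np.exp(est + 1.96 * se)
        assert lo * hi == pytest.approx(1.0)
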