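"""Design coding, SSCP decomposition, Wilks lambda and the Rao transform."""

import numpy as np
import pytest
from scipy import stats

import connmanova as cm
from connmanova.exceptions import DegenerateDataError, RankError
from connmanova.manova import MultivariateManova, wilks_lambda

from conftest import factorial_design


class TestBuildDesign:
    def test_cell_codings(self, paper_cohort):
        design = cm.build_design(paper_cohort)
        X = design.matrix
        male_asd = np.flatnonzero((paper_cohort.sex == 1) & (paper_cohort.diagnosis == 1))[0]
        female_td = np.flatnonzero((paper_cohort.sex == -1) & (paper_cohort.diagnosis == -1))[0]
        assert tuple(X[male_asd]) == (1, 1, 1, 1)
        # concordant codes make the interaction +1 even for female TD
        assert tuple(X[female_td]) == (1, -1, -1, 1)
        assert design.q == 3

    def test_balanced_sex_column_has_zero_mean(self):
        import pandas as pd

        rows = []
        for i in range(8):
            rows.append(
                {
                    "subject_id": f"s{i}", "site": "site1",
                    "sex": "M" if i % 2 else "F",
                    "diagnosis": "ASD" if i < 4 else "TD",
                    "age": 10.0 + i, "das_v": 100, "das_nv": 100, "das_s": 100,
                    "das_gca": 100, "das_snc": 100, "ticv": 200.0,
                }
            )
        design = cm.build_design(cm.CohortTable(pd.DataFrame(rows)))
        assert design.matrix[:, 1].mean() == 0.0

    def test_empty_cell_raises(self, paper_cohort):
        f = paper_cohort.frame.copy()
        f.loc[(f["sex"] == -1) & (f["diagnosis"] == 1), "sex"] = 1  # no ASD females
        with pytest.raises(RankError, match="cell"):
            cm.build_design(cm.CohortTable(f))


class TestFit:
    def test_noise_free_interpolation_recovers_coefficients(self, rng):
        design = factorial_design(rng, 40)
        B0 = rng.standard_normal((4, 6))
        Y = design.matrix @ B0
        fit = MultivariateManova().fit(Y, design=design)
        np.testing.assert_allclose(fit.coef_, B0, atol=1e-10)
        np.testing.assert_allclose(fit.e_, 0.0, atol=1e-8)

    def test_sscp_decomposition_identity(self, rng):
        design = factorial_design(rng, 60)
        Y = rng.standard_normal((60, 8))
        fit = MultivariateManova().fit(Y, design=design)
        Yc = Y - Y.mean(axis=0)
        np.testing.assert_allclose(fit.h_ + fit.e_, Yc.T @ Yc, atol=1e-8)

    def test_single_response_matches_univariate_closed_form(self, rng):
        n = 50
        x = rng.standard_normal(n)
        X = cm.DesignMatrix(np.column_stack([np.ones(n), x]), ("intercept", "x"))
        y = 2.0 + 0.7 * x + rng.standard_normal(n)
        fit = MultivariateManova().fit(y[:, None], design=X)
        xc = x - x.mean()
        slope = (xc @ y) / (xc @ xc)
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(fit.coef_[:, 0], [intercept, slope], atol=1e-10)


class TestWilksLambda:
    def test_zero_hypothesis_gives_one(self):
        e = np.eye(4) * 3.0
        assert wilks_lambda(np.zeros((4, 4)), e) == 1.0

    def test_scalar_reduction(self):
        assert wilks_lambda(np.array([[3.0]]), np.array([[1.0]])) == pytest.approx(0.25)

    def test_matches_eigenvalue_identity(self, rng):
        design = factorial_design(rng, 50)
        Y = rng.standard_normal((50, 4))
        fit = MultivariateManova().fit(Y, design=design)
        lam = wilks_lambda(fit.h_, fit.e_)
        eigs = np.linalg.eigvals(np.linalg.solve(fit.e_, fit.h_)).real
        assert lam == pytest.approx(np.prod(1.0 / (1.0 + eigs)), abs=1e-10)

    def test_invariant_under_response_mixing(self, rng):
        design = factorial_design(rng, 60)
        Y = rng.standard_normal((60, 6))
        A = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        f1 = MultivariateManova().fit(Y, design=design)
        f2 = MultivariateManova().fit(Y @ A, design=design)
        lam1 = wilks_lambda(f1.h_, f1.e_)
        lam2 = wilks_lambda(f2.h_, f2.e_)
        assert lam1 == pytest.approx(lam2, abs=1e-8)

    def test_singular_error_matrix_advises(self, rng):
        design = factorial_design(rng, 10)
        Y = rng.standard_normal((10, 9))  # p > vE
        fit = MultivariateManova().fit(Y, design=design)
        with pytest.raises(DegenerateDataError, match="reduce p|singular"):
            wilks_lambda(fit.h_, fit.e_)


class TestRaoF:
    def test_study_dimension_df_pair(self):
        res = cm.rao_f(0.5, p=165, v_h=3, v_e=189)
        assert res.df1 == 495
        assert res.df2_rounded == 76
        assert res.df2 == pytest.approx(75.97, abs=0.01)

    def test_single_response_reduces_to_exact_univariate_f(self, rng):
        # p = 1: t = 1 and F = ((1-L)/L)(vE/vH) with (vH, vE) df
        n = 40
        design = factorial_design(rng, n)
        y = rng.standard_normal((n, 1))
        fit = MultivariateManova().fit(y, design=design)
        res = fit.omnibus()
        assert res.t == 1.0 and res.df1 == 3 and res.df2 == n - 4
        lam = wilks_lambda(fit.h_, fit.e_)
        assert res.f == pytest.approx((1 - lam) / lam * (n - 4) / 3, rel=1e-12)
        # agrees with the classical univariate ANOVA F of the same regression
        sse = fit.e_[0, 0]
        ssr = fit.h_[0, 0]
        f_anova = (ssr / 3) / (sse / (n - 4))
        assert res.f == pytest.approx(f_anova, rel=1e-10)

    def test_single_predictor_exact_case(self):
        # vH = 1: F exact with (p, vE - p + 1) df
        p, v_e, lam = 5, 30, 0.7
        res = cm.rao_f(lam, p=p, v_h=1, v_e=v_e)
        assert res.t == 1.0
        assert res.df1 == p and res.df2 == v_e - p + 1
        assert res.f == pytest.approx((1 - lam) / lam * (v_e - p + 1) / p, rel=1e-12)
        assert res.p == pytest.approx(stats.f.sf(res.f, p, v_e - p + 1), rel=1e-12)

    def test_out_of_range_lambda_rejected(self):
        with pytest.raises(DegenerateDataError):
            cm.rao_f(0.0, 3, 3, 30)
        with pytest.raises(DegenerateDataError):
            cm.rao_f(1.5, 3, 3, 30)


class TestPredictorLoo:
    def test_matches_brute_force_ratio_of_full_wilks(self, small_dataset):
        _, cohort, panels = small_dataset
        design = cm.build_design(cohort)
        fit = MultivariateManova().fit(panels["CD"], design=design)
        table = fit.predictor_loo()
        lam_full = wilks_lambda(fit.h_, fit.e_)
        for name in cm.PREDICTORS:
            red = MultivariateManova().fit(panels["CD"], design=design.drop(name))
            lam_red = wilks_lambda(red.h_, red.e_)
            assert table.loc[name, "partial_wilks"] == pytest.approx(
                lam_full / lam_red, abs=1e-12
            )

    def test_preresidualized_predictor_has_no_signal(self, small_dataset):
        _, cohort, panels = small_dataset
        Y = panels["CD"].data
        sex = cohort.sex.astype(float)
        sexc = sex - sex.mean()
        Y_wiped = Y - np.outer(sexc, (sexc @ Y) / (sexc @ sexc))
        table = cm.predictor_loo_step2(Y_wiped, cohort)
        assert table.loc["sex", "partial_wilks"] > 0.5
        assert not table.loc["sex", "reject"]

    def test_alternative_df_convention_reported(self, small_dataset):
        _, cohort, panels = small_dataset
        table = cm.predictor_loo_step2(panels["CD"], cohort)
        p, n = panels["CD"].p, cohort.n
        assert (table["df2_alt"] == n - 4 - p).all()
        assert (table["df1_alt"] == 3).all()


class TestOmnibusStep1:
    def test_table_shape_and_columns(self, small_dataset):
        _, cohort, panels = small_dataset
        table = cm.omnibus_step1(panels, cohort)
        assert len(table) == 5
        assert {"wilks", "f", "df1", "df2", "p", "p_adj", "reject"} <= set(table.columns)
        assert set(table.index) == set(cm.METRICS)
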