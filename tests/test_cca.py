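"""Canonical correlations, their Wilks identity, the LOO tables and BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connmanova as cm
from connmanova.cca import CanonicalCorrelation, response_loo_step4
from connmanova.exceptions import DegenerateDataError
from connmanova.manova import MultivariateManova, wilks_lambda

from conftest import factorial_design


class TestPartitionCovariance:
    def test_block_shapes(self, small_dataset):
        _, cohort, panels = small_dataset
        blocks = cm.partition_covariance(panels["CD"], cohort=cohort)
        p = panels["CD"].p
        assert blocks.s_yy.shape == (p, p)
        assert blocks.s_yx.shape == (p, 3)
        assert blocks.s_xx.shape == (3, 3)

    def test_cross_block_is_transpose(self, rng):
        Y = rng.standard_normal((20, 4))
        X = rng.standard_normal((20, 2))
        blocks = cm.partition_covariance(Y, X)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        np.testing.assert_allclose(blocks.s_yx, ((Xc.T @ Yc) / 19).T, atol=1e-12)

    def test_three_subject_hand_computation(self):
        Y = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.0]])
        X = np.array([[0.0], [1.0], [2.0]])
        blocks = cm.partition_covariance(Y, X)
        # covariances about the means with denominator n-1 = 2
        np.testing.assert_allclose(blocks.s_xx, [[1.0]])
        np.testing.assert_allclose(blocks.s_yy, [[1.0, 1.5], [1.5, 3.0]])
        np.testing.assert_allclose(blocks.s_yx, [[0.5], [0.0]])

    def test_zero_variance_column_rejected(self, rng):
        Y = rng.standard_normal((10, 3))
        Y[:, 1] = 7.0
        with pytest.raises(DegenerateDataError, match="zero-variance"):
            cm.partition_covariance(Y, rng.standard_normal((10, 2)))


class TestCanonicalCorrelations:
    def test_single_predictor_equals_multiple_correlation(self, rng):
        n, p = 60, 5
        Y = rng.standard_normal((n, p))
        x = Y @ rng.standard_normal(p) * 0.3 + rng.standard_normal(n)
        cca = CanonicalCorrelation().fit(Y, x[:, None])
        # R^2 of regressing x on (1, Y)
        Z = np.column_stack([np.ones(n), Y])
        xhat = Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        r2 = 1 - ((x - xhat) ** 2).sum() / ((x - x.mean()) ** 2).sum()
        assert cca.correlations_[0] ** 2 == pytest.approx(r2, abs=1e-10)

    def test_brute_force_two_by_two(self, rng):
        for _ in range(5):
            n = 40
            Y = rng.standard_normal((n, 2))
            X = Y @ rng.standard_normal((2, 2)) * 0.5 + rng.standard_normal((n, 2))
            cca = CanonicalCorrelation().fit(Y, X)
            theta = np.linspace(0, np.pi, 700, endpoint=False)
            W = np.vstack([np.cos(theta), np.sin(theta)])
            U = (Y - Y.mean(0)) @ W
            V = (X - X.mean(0)) @ W
            U /= np.linalg.norm(U, axis=0)
            V /= np.linalg.norm(V, axis=0)
            r_bf = np.abs(U.T @ V).max()
            assert cca.correlations_[0] == pytest.approx(r_bf, abs=1e-3)

    def test_variates_realize_the_correlations(self, small_dataset):
        _, cohort, panels = small_dataset
        cca = CanonicalCorrelation().fit(panels["CD"], cohort=cohort)
        for k in range(3):
            r = np.corrcoef(cca.y_scores_[:, k], cca.x_scores_[:, k])[0, 1]
            assert r == pytest.approx(cca.correlations_[k], abs=1e-8)
        cross = np.corrcoef(cca.y_scores_.T, cca.x_scores_.T)[:3, 3:]
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8

    def test_correlations_sorted_and_bounded(self, small_dataset):
        _, cohort, panels = small_dataset
        r = CanonicalCorrelation().fit(panels["CD"], cohort=cohort).correlations_
        assert (np.diff(r) <= 1e-12).all()
        assert (r >= 0).all() and (r <= 1).all()

    def test_invariance_under_block_transforms(self, rng):
        n = 50
        Y = rng.standard_normal((n, 4))
        X = rng.standard_normal((n, 3))
        A = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        r1 = CanonicalCorrelation().fit(Y, X).correlations_
        r2 = CanonicalCorrelation().fit(Y @ A, X @ B).correlations_
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_p_exceeding_n_advises(self, rng):
        # blocks themselves are computable; the eigen-solver must refuse
        blocks = cm.partition_covariance(
            rng.standard_normal((10, 12)), rng.standard_normal((10, 2))
        )
        with pytest.raises(DegenerateDataError, match="responses"):
            cm.canonical_correlations(blocks)


class TestWilksIdentity:
    def test_cca_product_equals_det_ratio(self, rng):
        for _ in range(20):
            n, p = 60, int(rng.integers(2, 21))
            design = factorial_design(rng, n)
            Y = rng.standard_normal((n, p))
            fit = MultivariateManova().fit(Y, design=design)
            lam_det = wilks_lambda(fit.h_, fit.e_)
            lam_cca = CanonicalCorrelation().fit(Y, design).wilks()
            assert lam_cca == pytest.approx(lam_det, abs=1e-10)

    def test_trivial_values(self):
        assert cm.cca_wilks([0.0, 0.0]) == 1.0
        assert cm.cca_wilks([1.0, 0.3]) == 0.0


class TestPredictorLooStep3:
    def test_identical_inferences_to_step2(self, small_dataset):
        _, cohort, panels = small_dataset
        s2 = cm.predictor_loo_step2(panels["CD"], cohort)
        s3 = cm.predictor_loo_step3(panels["CD"], cohort)
        np.testing.assert_allclose(s2["partial_wilks"], s3["partial_wilks"], atol=1e-10)
        np.testing.assert_allclose(s2["partial_f"], s3["partial_f"], rtol=1e-8)
        assert (s2["reject"] == s3["reject"]).all()

    def test_planted_interaction_has_smallest_p(self, small_dataset):
        _, cohort, panels = small_dataset
        s3 = cm.predictor_loo_step3(panels["CD"], cohort)
        assert s3["p"].idxmin() == "interaction"

    def test_pure_noise_predictor_has_unit_partial_lambda(self, rng):
        n = 60
        Y = rng.standard_normal((n, 6))
        x1 = Y[:, 0] + 0.5 * rng.standard_normal(n)  # informative
        x2 = rng.standard_normal(n)  # noise
        X = cm.DesignMatrix(
            np.column_stack([np.ones(n), x1, x2]), ("intercept", "signal", "noise")
        )
        from connmanova.cca import predictor_loo_step3

        table = predictor_loo_step3(Y, design=X)
        assert table.loc["noise", "partial_wilks"] > 0.8
        assert table.loc["signal", "partial_wilks"] < table.loc["noise", "partial_wilks"]


class TestResponseLooStep4:
    def test_incremental_matches_two_full_evaluations(self, small_dataset):
        _, cohort, panels = small_dataset
        table = response_loo_step4(panels["CD"], cohort)
        design = cm.build_design(cohort)
        fit = MultivariateManova().fit(panels["CD"], design=design)
        lam_full = wilks_lambda(fit.h_, fit.e_)
        p = panels["CD"].p
        for j in [0, 7, p - 1]:
            keep = [k for k in range(p) if k != j]
            lam_red = wilks_lambda(
                fit.h_[np.ix_(keep, keep)], fit.e_[np.ix_(keep, keep)]
            )
            assert table["partial_wilks"].iloc[j] == pytest.approx(
                lam_full / lam_red, abs=1e-12
            )

    def test_ranking_invariant_to_parcel_order(self, small_dataset):
        _, cohort, panels = small_dataset
        panel = panels["CD"]
        perm = np.random.default_rng(3).permutation(panel.p)
        atlas = cm.ParcelAtlas(tuple(panel.atlas.labels[i] for i in perm))
        shuffled = cm.MetricPanel("CD", panel.values.iloc[:, perm], atlas)
        a = response_loo_step4(panel, cohort).set_index("parcel")["partial_f"]
        b = response_loo_step4(shuffled, cohort).set_index("parcel")["partial_f"]
        np.testing.assert_allclose(a.sort_index(), b.sort_index(), rtol=1e-9)

    def test_duplicated_noise_parcel_contributes_nothing(self, rng):
        n, p = 80, 6
        design = factorial_design(rng, n)
        Y = rng.standard_normal((n, p))
        # near-duplicate of a pure-noise column: its unique contribution is noise
        Y = np.column_stack([Y, Y[:, 0] + 0.05 * rng.standard_normal(n)])
        table = response_loo_step4(Y, design=design)
        assert table["partial_f"].iloc[-1] < 5.0
        assert not table["reject"].iloc[-1]

    def test_critical_f_is_min_rejected(self, small_dataset):
        _, cohort, panels = small_dataset
        table = response_loo_step4(panels["CD"], cohort, alpha=0.5)
        if table["reject"].any():
            assert table.attrs["critical_f"] == pytest.approx(
                table.loc[table["reject"], "partial_f"].min()
            )
        else:
            assert np.isnan(table.attrs["critical_f"])


class TestBhFdr:
    def test_hand_applied_step_up_rule(self):
        p_adj, reject = cm.bh_fdr([0.001, 0.008, 0.039, 0.041], alpha=0.05)
        assert reject.all()  # largest p <= (4/4) * 0.05
        np.testing.assert_allclose(p_adj, [0.004, 0.016, 0.041, 0.041], atol=1e-12)

    def test_all_ones_rejects_nothing(self):
        _, reject = cm.bh_fdr([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()

    def test_single_p_is_unadjusted(self):
        p_adj, reject = cm.bh_fdr([0.04], alpha=0.05)
        assert p_adj[0] == 0.04 and reject[0]

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_monotone_in_raw_rank(self, ps):
        p_adj, _ = cm.bh_fdr(ps, alpha=0.05)
        order = np.argsort(ps)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DegenerateDataError):
            cm.bh_fdr([0.5, 1.5])
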