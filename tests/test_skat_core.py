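"""Score statistic, null mixture and p-value numerics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from trioskat import (
    KernelSpec,
    SimConfig,
    center_genotypes,
    compute_statistic,
    fit_null_model,
    generate_cohort,
    mixture_pvalue,
    null_eigenvalues,
    pvalue_cf_inversion,
    pvalue_moment_matching,
    run_test,
)
from trioskat.skat_core import CFInversionError
from trioskat.trio_data import GenotypeMatrix, PhenotypeTable, TrioCohort


class TestFitNullModel:
    def test_intercept_only_mean_centers(self):
        Y = np.array([1.0, 2.0, 3.0])
        C = np.ones((3, 1))
        null = fit_null_model(Y, C)
        assert null.alpha_hat[0] == pytest.approx(2.0)
        np.testing.assert_allclose(null.residuals, [-1, 0, 1])
        assert null.residuals.sum() == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_fit_zeroes_residuals(self):
        C = np.column_stack([np.ones(5), np.arange(5.0)])
        Y = 2.0 + 3.0 * np.arange(5.0)
        null = fit_null_model(Y, C)
        np.testing.assert_allclose(null.residuals, 0, atol=1e-10)

    def test_dichotomous_intercept_only(self):
        Y = np.array([1.0] * 3 + [0.0] * 7)
        null = fit_null_model(Y, np.ones((10, 1)), trait_type="dichotomous")
        np.testing.assert_allclose(null.mu0, 0.3, atol=1e-6)
        assert null.alpha_hat[0] == pytest.approx(np.log(3 / 7), abs=1e-6)
        assert np.all((null.mu0 > 0) & (null.mu0 < 1))

    def test_rank_deficiency_rejected(self):
        C = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_null_model(np.arange(4.0), C)


def _toy_matrix(pat, mat, off):
    pat = np.asarray(pat, dtype=float)
    return GenotypeMatrix(
        variant_ids=[f"v{j}" for j in range(pat.shape[1])],
        offspring=np.asarray(off, dtype=float),
        paternal=pat,
        maternal=np.asarray(mat, dtype=float),
    )


class TestCenterGenotypes:
    def test_informative_and_uninformative_cells(self):
        g = _toy_matrix([[1, 0]], [[1, 0]], [[2, 0]])
        s = center_genotypes(g)
        assert s.scores[0, 0] == pytest.approx(1.0)  # 2 - E=1
        assert s.scores[0, 1] == 0.0  # parents (0,0): no information
        assert s.variances[0, 0] == pytest.approx(0.5)
        assert s.variances[0, 1] == 0.0

    def test_three_trio_table_matches_hand_enumeration(self):
        pat = [[1, 2], [0, 1], [2, 1]]
        mat = [[1, 0], [1, 1], [2, 0]]
        off = [[0, 1], [1, 2], [2, 1]]
        s = center_genotypes(_toy_matrix(pat, mat, off))
        # cell-by-cell: offspring - (gf+gm)/2
        expected = np.array([[0 - 1.0, 1 - 1.0], [1 - 0.5, 2 - 1.0], [2 - 2.0, 1 - 0.5]])
        np.testing.assert_allclose(s.scores, expected)
        assert np.all(np.abs(s.scores) <= 2)

    def test_mendelian_error_zeroed_and_counted(self):
        g = _toy_matrix([[0]], [[0]], [[1]])  # impossible offspring
        s = center_genotypes(g)
        assert s.scores[0, 0] == 0.0 and s.variances[0, 0] == 0.0
        assert s.n_mendelian_errors == 1

    def test_missing_member_zeroed(self):
        g = _toy_matrix([[np.nan]], [[1]], [[1]])
        s = center_genotypes(g)
        assert s.scores[0, 0] == 0.0 and s.variances[0, 0] == 0.0


def sum_form_statistic(r, S, w):
    """The explicit double-loop 'simple expression' for the rho=0 statistic."""
    q = 0.0
    for j in range(S.shape[1]):
        inner = 0.0
        for i in range(S.shape[0]):
            inner += r[i] * S[i, j]
        q += w[j] ** 2 * inner**2
    return q


small_instance = st.integers(min_value=2, max_value=6).flatmap(
    lambda n: st.integers(min_value=1, max_value=4).flatmap(
        lambda m: st.tuples(
            hnp.arrays(np.int8, (n, m), elements=st.integers(0, 2)),
            hnp.arrays(np.int8, (n, m), elements=st.integers(0, 2)),
            hnp.arrays(
                np.float64, (n,), elements=st.floats(-3, 3, allow_nan=False)
            ),
            hnp.arrays(
                np.float64, (m,), elements=st.floats(0.01, 5, allow_nan=False)
            ),
        )
    )
)


class TestComputeStatistic:
    def test_zero_residuals_give_zero(self):
        g = _toy_matrix([[1, 1]], [[1, 0]], [[2, 1]])
        s = center_genotypes(g)
        k = KernelSpec(rho=0.0, weights=np.ones(2))
        assert compute_statistic(np.zeros(1), s, k) == 0.0

    def test_offspring_at_expectation_give_zero(self):
        pat = np.array([[1.0, 2.0], [1.0, 0.0]])
        mat = np.array([[1.0, 0.0], [1.0, 2.0]])
        off = (pat + mat) / 2
        s = center_genotypes(_toy_matrix(pat, mat, off))
        k = KernelSpec(rho=0.0, weights=np.ones(2))
        assert compute_statistic(np.array([1.0, -2.0]), s, k) == 0.0

    @given(small_instance)
    @settings(max_examples=100)
    def test_matrix_form_equals_sum_form_at_rho_zero(self, inst):
        pat, mat, r, w = inst
        rng = np.random.default_rng(abs(hash(pat.tobytes())) % 2**31)
        off = rng.binomial(1, pat / 2.0) + rng.binomial(1, mat / 2.0)
        s = center_genotypes(_toy_matrix(pat, mat, off))
        k = KernelSpec(rho=0.0, weights=w)
        q_matrix = compute_statistic(r, s, k)
        q_sum = sum_form_statistic(r, s.scores, w)
        assert q_matrix == pytest.approx(q_sum, rel=1e-10, abs=1e-12)

    @given(small_instance)
    @settings(max_examples=50)
    def test_burden_is_squared_weighted_score_sum(self, inst):
        pat, mat, r, w = inst
        rng = np.random.default_rng(abs(hash(mat.tobytes())) % 2**31)
        off = rng.binomial(1, pat / 2.0) + rng.binomial(1, mat / 2.0)
        s = center_genotypes(_toy_matrix(pat, mat, off))
        q = compute_statistic(r, s, KernelSpec(rho=1.0, weights=w))
        expected = float(np.sum(w * (s.scores.T @ r))) ** 2
        assert q == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_nonnegative_and_continuous_in_rho(self, toy_cohort):
        cohort, _ = toy_cohort
        g = cohort.genotypes
        s = center_genotypes(g)
        r = cohort.phenotypes.trait("trait1")
        r = r - r.mean()
        w = np.linspace(0.5, 2.0, g.n_variants)
        grid = np.linspace(0, 1, 21)
        qs = [compute_statistic(r, s, KernelSpec(rho=x, weights=w)) for x in grid]
        assert all(q >= 0 for q in qs)
        diffs = np.abs(np.diff(qs))
        assert diffs.max() < 0.2 * (max(qs) - min(qs) + 1e-12) + 1e-9

    def test_no_variants_is_an_error(self):
        s = center_genotypes(_toy_matrix(np.zeros((2, 0)), np.zeros((2, 0)),
                                         np.zeros((2, 0))))
        with pytest.raises(ValueError, match="no testable variants"):
            compute_statistic(np.ones(2), s, KernelSpec(rho=0, weights=np.ones(0)))


class TestNullEigenvalues:
    def test_zero_residuals_degenerate(self):
        g = _toy_matrix([[1]], [[1]], [[2]])
        s = center_genotypes(g)
        lam = null_eigenvalues(np.zeros(1), s, KernelSpec(rho=0, weights=np.ones(1)))
        assert lam.tolist() == [0.0]

    def test_single_variant_scalar_oracle(self):
        pat = np.array([[1.0], [1.0], [0.0]])
        mat = np.array([[1.0], [0.0], [0.0]])
        off = np.array([[2.0], [1.0], [0.0]])
        s = center_genotypes(_toy_matrix(pat, mat, off))
        r = np.array([0.5, -1.5, 2.0])
        lam = null_eigenvalues(r, s, KernelSpec(rho=0.0, weights=np.ones(1)))
        # Var(X|parents): (1,1)->0.5, (1,0)->0.25, (0,0)->0
        expected = r[0] ** 2 * 0.5 + r[1] ** 2 * 0.25
        assert lam[0] == pytest.approx(expected, rel=1e-12)

    def test_empirical_estimator_uses_score_outer_products(self):
        pat = np.array([[1.0, 1.0], [1.0, 1.0]])
        mat = np.array([[1.0, 1.0], [0.0, 1.0]])
        off = np.array([[2.0, 0.0], [1.0, 2.0]])
        s = center_genotypes(_toy_matrix(pat, mat, off))
        r = np.array([1.0, 2.0])
        w = np.array([1.0, 0.5])
        lam = null_eigenvalues(r, s, KernelSpec(rho=0.0, weights=w),
                               covariance="empirical")
        V = s.scores.T @ np.diag(r**2) @ s.scores
        ref = np.linalg.eigvals(np.diag(w**2) @ V).real
        np.testing.assert_allclose(sorted(lam), sorted(ref[ref > 1e-12]), rtol=1e-8)


class TestPValues:
    def test_single_component_matches_chi2_tail(self):
        assert pvalue_cf_inversion(3.841459, np.array([1.0])) == pytest.approx(
            stats.chi2.sf(3.841459, 1), abs=1e-8
        )
        assert pvalue_moment_matching(3.841459, np.array([1.0])) == pytest.approx(
            stats.chi2.sf(3.841459, 1), rel=1e-10
        )

    def test_two_equal_components_match_chi2_df2(self):
        assert pvalue_cf_inversion(5.991465, np.array([1.0, 1.0])) == pytest.approx(
            stats.chi2.sf(5.991465, 2), abs=1e-8
        )

    def test_scale_equivariance(self):
        p1 = pvalue_cf_inversion(2 * 3.3, np.array([2.0]))
        p2 = pvalue_cf_inversion(3.3, np.array([1.0]))
        assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("lam", [[3.0, 1.0, 0.5], [2.0, 2.0, 0.1, 0.1],
                                     [5.0, 1.0], [1.0] * 10])
    def test_inversion_close_to_moment_matching_midrange(self, lam):
        lam = np.array(lam)
        for target in (0.4, 0.1, 0.02):
            # pick q near the target tail probability using the surrogate
            lo, hi = 0.0, 50 * lam.sum()
            for _ in range(60):
                mid = (lo + hi) / 2
                if pvalue_moment_matching(mid, lam) > target:
                    lo = mid
                else:
                    hi = mid
            q = (lo + hi) / 2
            p_cf = pvalue_cf_inversion(q, lam)
            p_mm = pvalue_moment_matching(q, lam)
            assert p_cf == pytest.approx(p_mm, rel=0.10)

    def test_degenerate_all_zero(self):
        assert mixture_pvalue(0.0, np.array([0.0]))[0] == 1.0

    def test_fallback_path(self, monkeypatch):
        import trioskat.skat_core as sc

        def boom(q, lam, accuracy=1e-9):
            raise CFInversionError("forced")

        monkeypatch.setattr(sc, "pvalue_cf_inversion", boom)
        p, method = sc.mixture_pvalue(3.0, np.array([1.0, 0.5]))
        assert method == "moment_matching" and 0 < p < 1


class TestRunTest:
    def test_skat_equals_rho_zero_and_burden_equals_rho_one(self, toy_cohort):
        cohort, _ = toy_cohort
        a = run_test(cohort, "trait1", method="skat")
        b = run_test(cohort, "trait1", method="rho=0")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-8)
        c = run_test(cohort, "trait1", method="burden")
        d = run_test(cohort, "trait1", method="rho=1")
        assert c.statistic == pytest.approx(d.statistic, rel=1e-12)

    def test_shift_invariance_with_intercept(self, toy_cohort):
        cohort, _ = toy_cohort
        base = run_test(cohort, "trait1", method="skat")
        shifted = TrioCohort(
            trios=cohort.trios,
            genotypes=cohort.genotypes,
            phenotypes=PhenotypeTable(traits=cohort.phenotypes.traits + 100.0),
        )
        res = run_test(shifted, "trait1", method="skat")
        assert res.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_empty_stratum_is_untestable_not_error(self):
        # every variant is a parental singleton: MAF 1/120 << 0.05, so the
        # common stratum is empty by construction
        n, m = 30, 5
        pat = np.zeros((n, m))
        pat[:m, :] = np.eye(m)
        mat = np.zeros((n, m))
        rng = np.random.default_rng(3)
        off = rng.binomial(1, pat / 2).astype(float)
        import pandas as pd

        from trioskat.trio_data import Trio

        cohort = TrioCohort(
            trios=[Trio(f"F{i}", f"M{i}", f"O{i}", f"FAM{i}", i) for i in range(n)],
            genotypes=GenotypeMatrix([f"v{j}" for j in range(m)], off, pat, mat),
            phenotypes=PhenotypeTable(traits=pd.DataFrame({"trait1": rng.normal(size=n)})),
        )
        res = run_test(cohort, "trait1", stratum="common")
        assert not res.testable
        assert res.p_method == "untestable" and res.n_variants == 0

    def test_metadata_recorded(self, toy_cohort):
        cohort, _ = toy_cohort
        res = run_test(cohort, "trait2", method="burden", stratum="all")
        assert res.hypothesis == "H0: tau=0"
        assert res.n_trios == cohort.n_trios
        assert 0 <= res.p_value <= 1 and res.statistic >= 0
        assert np.all(res.eigenvalues >= 0)


class TestNullCalibration:
    def test_pvalues_uniform_where_asymptotics_hold(self):
        """Common variants at N=93: null p-values are uniform for both kernels."""
        config = SimConfig(proportion_rare=0.0, causal_fraction=0.0, effect_scale=0.0)
        seqs = np.random.SeedSequence(555).spawn(400)
        ps = {"skat": [], "burden": []}
        for seq in seqs:
            cohort, _ = generate_cohort(config, rng=np.random.default_rng(seq))
            for method in ps:
                ps[method].append(run_test(cohort, "null_trait", method=method).p_value)
        for method, vals in ps.items():
            stat = stats.kstest(vals, "uniform")
            assert stat.pvalue > 1e-3, f"{method}: KS p={stat.pvalue}"

    def test_rare_variant_regime_is_valid_never_anticonservative(self, null_pvalues):
        """Under the rare-heavy default spectrum the test may be conservative
        (singleton transmissions carry deterministic score contributions) but
        must never exceed the nominal level."""
        n = len(null_pvalues["skat"])
        se = np.sqrt(0.05 * 0.95 / n)
        for method, vals in null_pvalues.items():
            rate = float(np.mean(vals <= 0.05))
            assert rate <= 0.05 + 3 * se, f"{method} inflated: {rate}"
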