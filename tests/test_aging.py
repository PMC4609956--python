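import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coage import (
    AnalysisConfig,
    ExpressionMatrix,
    bh_adjust,
    bootstrap_consensus,
    build_correction_model,
    call_aging_genes,
    compute_expression_pcs,
    fit_gene_age_regression,
    low_expression_filter,
    permutation_null,
    select_m8_subset,
    select_model_by_reference_enrichment,
    subsample_power_curve,
)
from coage.aging import CorrectionModel, ExpressionPCs


def _matrix(values, tissue="t"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        tissue,
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
    )


class TestExpressionPCs:
    def test_rank_one_matrix_concentrates_variance(self):
        pattern = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = _matrix(np.outer([1.0, 2.0, -1.0], pattern))
        pcs = compute_expression_pcs(expr, ages=pattern, k=2)
        assert pcs.variance_explained[0] == pytest.approx(1.0)
        assert pcs.variance_explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 5))
        expr = _matrix(X)
        ages = np.array([20.0, 30, 40, 50, 60])
        pcs = compute_expression_pcs(expr, ages, k=4)
        Xc = X - X.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        for i in range(4):
            ref = evecs[:, i] * np.sqrt(evals[i])
            got = pcs.coordinates[:, i]
            err = min(np.abs(got - ref).max(), np.abs(got + ref).max())
            assert err < 1e-8
        np.testing.assert_allclose(
            pcs.variance_explained, evals[:4] / evals.sum(), atol=1e-10
        )

    def test_age_aligned_component_reports_perfect_correlation(self):
        ages = np.array([20.0, 30, 40, 50, 60, 70])
        expr = _matrix(np.outer([1.0, 0.5, 2.0], ages))
        pcs = compute_expression_pcs(expr, ages, k=1)
        assert abs(pcs.age_corr_r[0]) == pytest.approx(1.0)
        assert pcs.age_corr_p[0] < 1e-8

    def test_constant_matrix_rejected(self):
        expr = _matrix(np.ones((4, 5)))
        with pytest.raises(ValueError, match="zero variance"):
            compute_expression_pcs(expr, np.arange(5.0), k=2)


class TestCorrectionModels:
    def _pcs(self, rs, ps):
        rs, ps = np.asarray(rs, float), np.asarray(ps, float)
        n = len(rs)
        return ExpressionPCs(
            sample_ids=[f"s{i}" for i in range(10)],
            coordinates=np.zeros((10, n)),
            variance_explained=np.linspace(0.5, 0.1, n),
            age_corr_r=rs,
            age_corr_p=ps,
        )

    def test_m1_has_no_covariates(self):
        m = build_correction_model("M1")
        assert not m.include_sex and m.n_genotype_pcs == 0
        assert m.expression_pc_indices == ()

    def test_m5_threshold_rule(self):
        pcs = self._pcs([0.9, 0.25, 0.05, 0.4, 0.1], [0.0] * 5)
        m = build_correction_model("M5", pcs)
        assert m.expression_pc_indices == (2, 3, 5)

    def test_m9_p_value_rule(self):
        pcs = self._pcs([0.0] * 5, [0.001, 0.2, 0.8, 0.04, 0.5])
        m = build_correction_model("M9", pcs)
        assert m.expression_pc_indices == (2, 3, 5)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_correction_model("M10")

    @pytest.mark.parametrize(
        "mid,threshold", [("M3", 0.1), ("M4", 0.2), ("M6", 0.4), ("M7", 0.5)]
    )
    def test_m3_m7_threshold_family(self, mid, threshold):
        rs = np.array([0.05, 0.15, 0.25, 0.35, 0.45])
        pcs = self._pcs(rs, [0.5] * 5)
        m = build_correction_model(mid, pcs)
        expected = tuple(i + 1 for i in range(5) if rs[i] < threshold)
        assert m.expression_pc_indices == expected


class TestRegression:
    def test_exact_linear_gene(self):
        ages = np.array([20.0, 30, 40, 50, 60, 70])
        rng = np.random.default_rng(0)
        Y = np.vstack([2.0 * ages, rng.normal(size=6)])
        res = fit_gene_age_regression(_matrix(Y), ages, build_correction_model("M1"))
        assert res.loc["g0", "gamma"] == pytest.approx(2.0)
        assert res.loc["g0", "p_value"] < 1e-10
        assert res.loc["g0", "direction"] == "up"

    def test_matches_hand_computed_partialled_regression(self):
        # 6-sample instance with one confounder; oracle = normal equations
        ages = np.array([25.0, 32, 41, 48, 57, 66])
        conf = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        y = 0.3 * ages - 2.0 * conf + np.array([0.1, -0.2, 0.05, 0.15, -0.1, 0.0])
        X = np.column_stack([np.ones(6), ages, conf])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        expr = _matrix(y[None, :])
        pcs = ExpressionPCs(
            sample_ids=[f"s{j}" for j in range(6)],
            coordinates=conf[:, None],
            variance_explained=np.array([1.0]),
            age_corr_r=np.array([0.0]),
            age_corr_p=np.array([1.0]),
        )
        model = CorrectionModel("M9", include_sex=False, n_genotype_pcs=0, expression_pc_indices=(1,))
        res = fit_gene_age_regression(expr, ages, model, pcs=pcs)
        assert res.loc["g0", "gamma"] == pytest.approx(beta_oracle[1], abs=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 70, size=50)
        Y = rng.normal(size=(1000, 50))
        res = fit_gene_age_regression(_matrix(Y), ages, build_correction_model("M1"))
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 1e-3
        assert np.abs(res["gamma"]).median() < 0.05

    def test_zero_variance_gene_is_neutral(self):
        ages = np.array([20.0, 30, 40, 50, 60, 70])
        Y = np.vstack([np.full(6, 3.0), 2 * ages])
        res = fit_gene_age_regression(_matrix(Y), ages, build_correction_model("M1"))
        assert res.loc["g0", "gamma"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_rank_deficient_design_names_columns(self):
        ages = np.array([20.0, 30, 40, 50, 60, 70])
        pcs = ExpressionPCs(
            sample_ids=[f"s{j}" for j in range(6)],
            coordinates=ages[:, None],  # collinear with age
            variance_explained=np.array([1.0]),
            age_corr_r=np.array([1.0]),
            age_corr_p=np.array([0.0]),
        )
        model = CorrectionModel("M9", False, 0, (1,))
        with pytest.raises(ValueError, match="expr_pc1"):
            fit_gene_age_regression(_matrix(np.ones((2, 6)) * ages), ages, model, pcs=pcs)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_output_bounded_and_dominates_input(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_is_monotone_and_order_preserving(ps):
    """BH dominates its input, stays in [0,1], and preserves the p ordering."""
    q = bh_adjust(ps)
    p = np.asarray(ps)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


class TestLowExpressionFilter:
    def test_exact_drop_count(self):
        rng = np.random.default_rng(0)
        expr = _matrix(rng.normal(size=(10, 8)))
        kept, dropped = low_expression_filter(expr, expr.gene_ids, 0.25, 0.20)
        assert len(dropped) == 2 and len(kept) == 8

    def test_ties_drop_lexicographically_last(self):
        expr = _matrix(np.ones((10, 8)))
        kept, dropped = low_expression_filter(expr, expr.gene_ids, 0.25, 0.20)
        assert sorted(dropped) == ["g8", "g9"]

    def test_hand_instance_matches_spreadsheet_scores(self):
        # 5 genes x 8 samples; top-2 (ceil(0.25*8)) sample means decide
        vals = np.array(
            [
                [9, 1, 1, 1, 1, 1, 1, 7],  # top2 mean 8.0
                [5, 5, 5, 5, 5, 5, 5, 5],  # 5.0
                [10, 0, 0, 0, 0, 0, 0, 0],  # 5.0 (tie with g1 -> g1 ranks first)
                [2, 2, 2, 2, 2, 2, 2, 2],  # 2.0
                [1, 1, 1, 1, 1, 1, 1, 1],  # 1.0
            ],
            dtype=float,
        )
        expr = _matrix(vals)
        kept, dropped = low_expression_filter(expr, expr.gene_ids, 0.25, 0.40)
        assert dropped == ["g3", "g4"]
        assert kept == ["g0", "g1", "g2"]

    def test_empty_input_passes_through(self):
        expr = _matrix(np.ones((3, 4)))
        assert low_expression_filter(expr, []) == ([], [])


class TestM8Search:
    def _cohort(self, seed=0, n=60, g=120):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 70, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        geno = rng.normal(size=(n, 3))
        batch = np.repeat([0.0, 1.0], n // 2)
        loadings = rng.normal(0, 2.0, size=g)
        gamma = np.zeros(g)
        gamma[: g // 4] = 0.04 * rng.choice([-1, 1], size=g // 4)
        Y = (
            gamma[:, None] * ages[None, :]
            + loadings[:, None] * batch[None, :]
            + rng.normal(size=(g, n))
        )
        return _matrix(Y), ages, sex, geno

    def test_empty_search_space_equals_m2(self):
        expr, ages, sex, geno = self._cohort()
        pcs = compute_expression_pcs(expr, ages, k=3)
        empty = ExpressionPCs(pcs.sample_ids, pcs.coordinates[:, :0], pcs.variance_explained[:0],
                              pcs.age_corr_r[:0], pcs.age_corr_p[:0])
        m = select_m8_subset(expr, ages, empty, sex, geno)
        assert m.expression_pc_indices == ()
        assert m.include_sex and m.n_genotype_pcs == 3

    def test_batch_masking_pc_is_selected(self):
        expr, ages, sex, geno = self._cohort(seed=4)
        pcs = compute_expression_pcs(expr, ages, k=3)
        # the dominant batch factor is PC1 by construction
        m = select_m8_subset(expr, ages, pcs, sex, geno)
        assert 1 in m.expression_pc_indices

    def test_matches_brute_force_enumeration(self):
        expr, ages, sex, geno = self._cohort(seed=9, n=50, g=200)
        k = 3
        pcs = compute_expression_pcs(expr, ages, k=k)
        best_key = None
        for size in range(k + 1):
            for subset in itertools.combinations(range(1, k + 1), size):
                model = CorrectionModel("M8", True, 3, subset)
                res = fit_gene_age_regression(expr, ages, model, sex, geno, pcs)
                count = int((res["fdr"] < 0.05).sum())
                key = (-count, len(subset), subset)
                if best_key is None or key < best_key:
                    best_key = key
        m = select_m8_subset(expr, ages, pcs, sex, geno)
        assert m.expression_pc_indices == best_key[2]

    def test_oversized_search_rejected(self):
        expr, ages, sex, geno = self._cohort(n=40, g=60)
        pcs = compute_expression_pcs(expr, ages, k=9)
        with pytest.raises(ValueError, match="256"):
            select_m8_subset(expr, ages, pcs, sex, geno)


class TestCallAgingGenes:
    def test_null_cohort_calls_almost_nothing(self, null_cohort):
        mats, donors, smap, _ = null_cohort
        cfg = AnalysisConfig(seed=1)
        counts = []
        for seed in range(5):
            gs, _ = call_aging_genes(mats["lung"], donors, smap, cfg)
            counts.append(len(gs))
        assert np.mean(counts) < 2

    def test_strong_signal_recovered_with_directions(self, strong_cohort):
        mats, donors, smap, truth = strong_cohort
        cfg = AnalysisConfig(seed=1)
        gs, res = call_aging_genes(mats["heart"], donors, smap, cfg, apply_filter=False)
        true = truth.aging_genes["heart"]
        called = set(gs.genes)
        assert len(set(true) & called) / len(true) > 0.9
        for g, gamma in true.items():
            if g in called:
                assert res.at[g, "direction"] == ("up" if gamma > 0 else "down")

    def test_vanishing_alpha_empties_signature(self, strong_cohort):
        mats, donors, smap, _ = strong_cohort
        cfg = AnalysisConfig(seed=1, fdr_alpha=1e-300)
        gs, _ = call_aging_genes(mats["heart"], donors, smap, cfg)
        assert len(gs) == 0


class TestBootstrap:
    def test_strong_genes_reach_full_support(self, strong_cohort):
        mats, donors, smap, truth = strong_cohort
        cfg = AnalysisConfig(seed=3, bootstrap_runs=20, bootstrap_support_min=10)
        gs, res = bootstrap_consensus(mats["heart"], donors, smap, cfg)
        true = set(truth.aging_genes["heart"])
        supports = [gs.bootstrap_support[g] for g in true]
        assert np.median(supports) == cfg.bootstrap_runs
        noise_support = [
            gs.bootstrap_support[g] for g in mats["heart"].gene_ids if g not in true
        ]
        assert np.median(noise_support) <= 2
        assert set(gs.genes) <= set(res.index[res["significant"]])

    def test_unattainable_support_threshold_empties_set(self, strong_cohort):
        mats, donors, smap, _ = strong_cohort
        cfg = AnalysisConfig(seed=3, bootstrap_runs=5, bootstrap_support_min=6)
        gs, _ = bootstrap_consensus(mats["heart"], donors, smap, cfg)
        assert len(gs) == 0


class TestPermutation:
    def test_zero_observed_count_always_matched(self, null_cohort):
        mats, donors, smap, _ = null_cohort
        cfg = AnalysisConfig(seed=5, n_permutations=20, permutation_model="M9")
        summ = permutation_null(mats["lung"], donors, smap, cfg, observed_count=0)
        assert summ.frequency_ge_observed == summ.n_permutations

    def test_strong_signal_never_matched(self, strong_cohort):
        mats, donors, smap, _ = strong_cohort
        cfg = AnalysisConfig(seed=5, n_permutations=30, permutation_model="M9")
        gs, _ = call_aging_genes(mats["heart"], donors, smap, cfg)
        summ = permutation_null(mats["heart"], donors, smap, cfg, observed_count=len(gs))
        assert summ.frequency_ge_observed == 0
        assert not summ.exceeds_threshold

    def test_null_mean_matches_independent_reimplementation(self, null_cohort):
        """Oracle: a from-scratch permutation loop (statsmodels OLS + BH)."""
        from statsmodels.stats.multitest import multipletests
        import statsmodels.api as sm

        mats, donors, smap, _ = null_cohort
        expr = ExpressionMatrix("lung", mats["lung"].data.iloc[:120])
        cfg = AnalysisConfig(
            seed=9, n_permutations=60, permutation_model="M1", low_expr_drop_frac=0.2
        )
        summ = permutation_null(expr, donors, smap, cfg, observed_count=1, apply_filter=False)

        from coage.containers import aligned_covariates

        ages, _, _, _ = aligned_covariates(expr, donors, smap)
        rng = np.random.default_rng(9)
        counts = []
        for _ in range(60):
            perm = rng.permutation(ages)
            X = sm.add_constant(perm)
            ps = []
            for y in expr.values:
                ps.append(sm.OLS(y, X).fit().pvalues[1])
            counts.append(int((multipletests(ps, method="fdr_bh")[1] < 0.05).sum()))
        assert abs(summ.mean_count - np.mean(counts)) < 0.5


class TestSubsampleAndModelSelection:
    def test_full_size_single_repeat_equals_full_run(self, strong_cohort):
        mats, donors, smap, _ = strong_cohort
        cfg = AnalysisConfig(seed=2, permutation_model="M9")
        full, _ = call_aging_genes(mats["heart"], donors, smap, cfg, model_id="M9")
        table = subsample_power_curve(
            mats["heart"], donors, smap, cfg, sizes=[mats["heart"].n_samples], repeats=1,
            model_id="M9",
        )
        assert table["mean_count"].iloc[0] == len(full)

    def test_power_grows_with_sample_size(self, strong_cohort):
        mats, donors, smap, _ = strong_cohort
        cfg = AnalysisConfig(seed=2, permutation_model="M9")
        table = subsample_power_curve(
            mats["heart"], donors, smap, cfg, sizes=[30, 60, 90], repeats=3, model_id="M9"
        )
        rho = stats.spearmanr(table["size"], table["mean_count"]).statistic
        assert rho >= 0

    def test_reference_of_planted_genes_prefers_signal_models(self, strong_cohort):
        mats, donors, smap, truth = strong_cohort
        cfg = AnalysisConfig(seed=2)
        reference = list(truth.aging_genes["heart"])
        best, table = select_model_by_reference_enrichment(
            mats["heart"], donors, smap, reference, mats["heart"].gene_ids, cfg,
            model_ids=("M1", "M2", "M9"),
        )
        assert table.loc[best, "p_filtered"] < 1e-10

    def test_single_model_table(self, strong_cohort):
        mats, donors, smap, truth = strong_cohort
        cfg = AnalysisConfig(seed=2)
        best, table = select_model_by_reference_enrichment(
            mats["heart"], donors, smap, list(truth.aging_genes["heart"]),
            mats["heart"].gene_ids, cfg, model_ids=("M9",),
        )
        assert best == "M9" and len(table) == 1
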