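import numpy as np
import pandas as pd
import pytest

from wmnet import (
    CohortConfig,
    bonferroni,
    chi_square_2x2,
    compute_all,
    generate_cohort,
    glm_group_test,
    partial_pearson,
    run_group_analysis,
    threshold_network,
    ttest_two_sample,
)


def _cohort(n1, n2, rng):
    n = n1 + n2
    return pd.DataFrame(
        {
            "group": ["HC"] * n1 + ["SSNHL"] * n2,
            "age": rng.normal(38, 12, n),
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(13, 3, n),
        }
    )


class TestTTest:
    def test_identical_groups(self):
        t, p, df = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0) and df == 4

    def test_hand_computed_pooled_t(self):
        t, p, df = ttest_two_sample([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.6742, abs=1e-4)  # 3 / (1 * sqrt(2/3))
        assert df == 4

    def test_degenerate_zero_variance(self):
        t, p, _ = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(0)
        rej = 0
        reps = 10_000
        for _ in range(reps):
            _, p, _ = ttest_two_sample(rng.normal(size=50), rng.normal(size=50))
            rej += p < 0.05
        assert 0.04 <= rej / reps <= 0.06


class TestChiSquare:
    def test_balanced_table_is_null(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_perfect_association(self):
        chi2, _ = chi_square_2x2([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)  # N(ad-bc)^2 / prod(marginals)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 10], [0, 10]])

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(1)
        rej = 0
        reps = 10_000
        for _ in range(reps):
            a = rng.binomial(100, 0.5)
            b = rng.binomial(100, 0.5)
            tab = [[a, 100 - a], [b, 100 - b]]
            try:
                _, p = chi_square_2x2(tab)
            except ValueError:
                continue
            rej += p < 0.05
        assert 0.04 <= rej / reps <= 0.065


class TestGLM:
    def test_constant_covariates_reduce_to_t_test(self):
        rng = np.random.default_rng(2)
        n1, n2 = 30, 40
        cohort = pd.DataFrame(
            {
                "group": ["HC"] * n1 + ["SSNHL"] * n2,
                "age": np.full(n1 + n2, 40.0),
                "gender": np.zeros(n1 + n2),
                "education": np.full(n1 + n2, 12.0),
            }
        )
        y = rng.normal(size=n1 + n2) + np.r_[np.full(n1, 0.4), np.zeros(n2)]
        res = glm_group_test(y, cohort)
        t, p, df = ttest_two_sample(y[:n1], y[n1:])
        assert res.t_value == pytest.approx(t, abs=1e-9)
        assert res.p_raw == pytest.approx(p, abs=1e-9)
        assert res.df == df

    def test_exact_group_effect_recovered(self):
        rng = np.random.default_rng(3)
        cohort = _cohort(25, 25, rng)
        y = 2.0 * (cohort["group"] == "HC").to_numpy(dtype=float)
        res = glm_group_test(y, cohort)
        assert res.p_raw < 1e-9
        assert res.group1_mean - res.group2_mean == pytest.approx(2.0)

    def test_positive_t_means_hc_above_patients(self):
        rng = np.random.default_rng(4)
        cohort = _cohort(40, 40, rng)
        y = rng.normal(size=80) + 1.0 * (cohort["group"] == "HC").to_numpy(float)
        res = glm_group_test(y, cohort)
        assert res.t_value > 0

    def test_collinear_design_rejected_with_names(self):
        rng = np.random.default_rng(5)
        cohort = _cohort(20, 20, rng)
        cohort["education"] = cohort["age"]  # exact collinearity
        with pytest.raises(ValueError, match="age.*education|education.*age"):
            glm_group_test(rng.normal(size=40), cohort)

    def test_adjustment_removes_covariate_confounding(self):
        # age differs by group; metric depends only on age -> test stays at level
        rng = np.random.default_rng(6)
        reps, rej = 2000, 0
        for _ in range(reps):
            cohort = _cohort(30, 30, rng)
            cohort.loc[cohort["group"] == "HC", "age"] += 8.0
            y = 0.1 * cohort["age"].to_numpy() + rng.normal(size=60)
            rej += glm_group_test(y, cohort).p_raw < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestBonferroni:
    def test_direct_product_and_cap(self):
        np.testing.assert_allclose(
            bonferroni([0.0005, 0.5], n_tests=90), [0.045, 1.0]
        )

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        adj = bonferroni(p, n_tests=90)
        assert (adj >= p).all() and (adj <= 1).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], n_tests=1)


class TestPartialPearson:
    def test_identity_without_covariates(self):
        x = np.arange(10.0)
        res = partial_pearson(x, x)
        assert res.r == pytest.approx(1.0) and res.p < 1e-12

    def test_pure_covariate_signal_vanishes(self):
        # y is covariate-driven: after residualization only noise remains
        rng = np.random.default_rng(8)
        c = rng.normal(size=500)
        x = rng.normal(size=500)
        y = 3.0 * c + 0.01 * rng.normal(size=500)
        res = partial_pearson(x, y, covariates=c)
        assert abs(res.r) < 0.15

    def test_planted_partial_correlation_recovered(self):
        # sampling sd of r at n=145 is ~0.063, so individual estimates stay
        # within ~3 sd of the target and their mean is much tighter
        target = 0.5
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 145
            c = rng.normal(size=(n, 2))
            u = rng.normal(size=n)
            v = rng.normal(size=n)
            x = c @ np.array([1.0, -0.5]) + u
            y = c @ np.array([0.3, 0.8]) + target * u + np.sqrt(1 - target**2) * v
            res = partial_pearson(x, y, covariates=c)
            estimates.append(res.r)
            assert 0.30 <= res.r <= 0.70
        assert 0.42 <= np.mean(estimates) <= 0.58

    def test_zero_variance_residuals_flagged(self):
        c = np.arange(10.0)
        res = partial_pearson(c.copy(), np.random.default_rng(0).normal(size=10),
                              covariates=c)
        assert np.isnan(res.r)


class TestRunGroupAnalysis:
    def _analyze(self, cfg, null_m=10):
        from wmnet import build_ensemble

        mats, table = generate_cohort(cfg)
        glob, nodal = {}, {}
        for i, (sid, cm) in enumerate(mats.items()):
            net = threshold_network(cm, 3)
            ens = build_ensemble(net, m=null_m, seed=i) if null_m else None
            gm, nt = compute_all(net, nulls=ens)
            glob[sid] = gm.as_dict()
            nodal[sid] = nt
        gdf = pd.DataFrame.from_dict(glob, orient="index")
        gdf.index.name = "subject_id"
        return run_group_analysis(gdf, nodal, table)

    def test_no_planted_effect_yields_no_bonferroni_hits(self):
        seeds_ok = 0
        for seed in range(5):
            cfg = CohortConfig(
                n_controls=15,
                n_patients=15,
                patient_extra_rewire=0.0,
                patient_edge_loss=0.0,
                planted_deficit_nodes={},
                seed=seed,
            )
            rep = self._analyze(cfg)
            n_sig = int((rep.nodal_comparison["p_bonferroni"] < 0.05).sum())
            seeds_ok += n_sig <= 1
        assert seeds_ok >= 4

    def test_report_is_deterministic_given_cohort_seed(self):
        cfg = CohortConfig(n_controls=8, n_patients=8, seed=12)
        r1 = self._analyze(cfg)
        r2 = self._analyze(cfg)
        pd.testing.assert_frame_equal(r1.global_comparison, r2.global_comparison)
        pd.testing.assert_frame_equal(r1.nodal_comparison, r2.nodal_comparison)
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)

    def test_report_shapes_and_flagging(self):
        cfg = CohortConfig(n_controls=12, n_patients=12, seed=3)
        rep = self._analyze(cfg)
        assert len(rep.global_comparison) == 7
        assert len(rep.nodal_comparison) == 3 * 90
        assert set(rep.flagged_global) <= set(rep.global_comparison["parameter"])
        # demographics includes the chi-square gender row
        assert (rep.demographics["test"] == "chi2").sum() == 1
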