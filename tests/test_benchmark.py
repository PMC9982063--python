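import numpy as np
import pandas as pd
import pytest

from ectnct import (
    PipelineSpec,
    SyntheticConfig,
    build_grid,
    connectome_feature_matrix,
    covariate_baseline,
    generate_cohort,
    nested_loocv,
    run_benchmark,
    spearman_variance_explained,
)


class TestBuildGrid:
    def test_exactly_35_unique_pipelines(self):
        grid = build_grid()
        assert len(grid) == 35
        assert len({s.name for s in grid}) == 35

    def test_contains_both_selection_thresholds_and_all_estimators(self):
        preps = {s.preprocessing for s in build_grid()}
        ests = {s.estimator for s in build_grid()}
        assert {"select5", "select10", "pca95", "pca20", "none"} == preps
        assert len(ests) == 7
        assert {"ols", "ridge", "random_forest"} <= ests


class TestNestedLoocv:
    def test_realizable_linear_target_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = 3.0 * X[:, 1]
        preds = nested_loocv(X, y, PipelineSpec("ols", "none", "ols"))
        from scipy.stats import spearmanr

        assert spearmanr(y, preds).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "spec",
        [
            PipelineSpec("a", "none", "ols"),
            PipelineSpec("b", "select10", "ridge"),
        ],
    )
    def test_held_out_target_cannot_leak(self, spec):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        preds = nested_loocv(X, y, spec, seed=0)
        poisoned = y.copy()
        poisoned[2] += 1000.0
        preds_poisoned = nested_loocv(X, poisoned, spec, seed=0)
        assert preds_poisoned[2] == pytest.approx(preds[2], rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="constant"):
            nested_loocv(X, np.ones(10), PipelineSpec("a", "none", "ols"))
        with pytest.raises(ValueError):
            nested_loocv(X[:, :0], np.arange(10.0), PipelineSpec("a", "none", "ols"))

    def test_inner_selection_runs_when_grid_given(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=12)
        spec = PipelineSpec("tuned", "none", "ridge", {"est__alpha": [0.1, 1.0, 10.0]})
        preds = nested_loocv(X, y, spec, seed=0)
        assert np.all(np.isfinite(preds))


class TestSpearmanVarianceExplained:
    def test_monotone_transform_explains_everything(self):
        y = np.array([3.0, -1.0, 2.0, 0.5, 7.0])
        assert spearman_variance_explained(y, np.exp(y)) == pytest.approx(100.0)

    def test_anti_correlation_clamps_to_zero(self):
        y = np.arange(10.0)
        assert spearman_variance_explained(y, -y) == 0.0

    def test_matches_brute_force_rank_then_pearson(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        rho = np.corrcoef(ra, rb)[0, 1]
        expected = 100 * rho**2 if rho > 0 else 0.0
        assert spearman_variance_explained(a, b) == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_monotone_transforms_of_either_argument(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=15), rng.normal(size=15)
        base = spearman_variance_explained(a, b)
        assert spearman_variance_explained(np.exp(a), b) == pytest.approx(base)
        assert spearman_variance_explained(a, b**3) == pytest.approx(base)

    def test_constant_true_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_variance_explained(np.ones(5), np.arange(5.0))


class TestCovariateBaseline:
    def test_realizable_response_fully_explained(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {
                "age": rng.uniform(20, 70, 30),
                "sex": rng.integers(0, 2, 30).astype(float),
                "hdrs_pre": rng.uniform(15, 35, 30),
            }
        )
        table["response"] = -0.8 * table["hdrs_pre"] + 4.0
        assert covariate_baseline(table) == pytest.approx(100.0)

    def test_pure_noise_explains_little(self):
        ves = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            table = pd.DataFrame(
                {
                    "age": rng.uniform(20, 70, 50),
                    "sex": rng.integers(0, 2, 50).astype(float),
                    "hdrs_pre": rng.uniform(15, 35, 50),
                    "response": rng.normal(size=50),
                }
            )
            ves.append(covariate_baseline(table))
        assert np.mean(ves) < 10.0

    def test_deterministic_on_rerun(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            {
                "age": rng.uniform(20, 70, 20),
                "sex": rng.integers(0, 2, 20).astype(float),
                "hdrs_pre": rng.uniform(15, 35, 20),
                "response": rng.normal(size=20),
            }
        )
        assert covariate_baseline(table) == covariate_baseline(table)


class TestRunBenchmark:
    def test_row_counting_two_modalities(self):
        rng = np.random.default_rng(7)
        n = 10
        mods = {"fa": rng.normal(size=(n, 5)), "md": rng.normal(size=(n, 5))}
        ctrl = pd.DataFrame(
            {"ac_mean": rng.normal(size=n), "mc_mean": rng.normal(size=n)}
        )
        y = rng.normal(size=n)
        res = run_benchmark(mods, ctrl, y, seed=0)
        assert len(res.results) == 2 * 35 + 2
        assert set(res.best_per_modality) == {"fa", "md"}

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(8)
        mods = {"fa": rng.normal(size=(10, 4))}
        ctrl = pd.DataFrame(
            {"ac_mean": rng.normal(size=10), "mc_mean": rng.normal(size=10)}
        )
        y = rng.normal(size=10)
        specs = [PipelineSpec("rf", "none", "random_forest")]
        r1 = run_benchmark(mods, ctrl, y, seed=3, specs=specs)
        r2 = run_benchmark(mods, ctrl, y, seed=3, specs=specs)
        assert r1.results.equals(r2.results)

    def test_planted_controllability_signal_beats_matrix_pipelines(self):
        # response depends on MC-bar only: the single-feature model should
        # outperform every connectome-matrix pipeline
        cfg = SyntheticConfig(
            n_subjects=16,
            n_nodes=24,
            psi_missing_count=0,
            response_noise_sd=0.0,
            age_effect=0.0,
            sex_effect=0.0,
            baseline_effect=0.0,
            path_b=0.0,
            direct_c_mc=5.0,
            seed=9,
        )
        cohort = generate_cohort(cfg, include_eeg=False)
        tab = cohort.table
        X = connectome_feature_matrix(
            [cohort.connectomes[s].weights for s in tab["id"]]
        )
        res = run_benchmark(
            {"streamlines": X},
            tab[["ac_mean", "mc_mean"]],
            tab["response"].to_numpy(),
            seed=0,
        )
        assert res.single_feature["mc_mean"] == pytest.approx(100.0)
        assert res.best_per_modality["streamlines"] < res.single_feature["mc_mean"]

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        mods = {"fa": rng.normal(size=(8, 3))}
        ctrl = pd.DataFrame(
            {"ac_mean": rng.normal(size=9), "mc_mean": rng.normal(size=9)}
        )
        with pytest.raises(ValueError):
            run_benchmark(mods, ctrl, rng.normal(size=9), seed=0)
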