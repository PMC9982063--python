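import numpy as np
import pandas as pd
import pytest

from ectnct import (
    HYPOTHESIS_DIRECTIONS,
    ancova,
    mediate,
    partial_eta_squared,
)


def make_regression_table(n=100, seed=0, beta_x=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    c1 = rng.normal(size=n)
    c2 = rng.integers(0, 2, size=n).astype(float)
    y = beta_x * x + 0.8 * c1 - 0.5 * c2 + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "c1": c1, "c2": c2})


def normal_equations_oracle(df, dependent, predictor, covariates):
    """Explicit matrix-algebra OLS: t, F, eta_p^2 of the predictor."""
    X = np.column_stack(
        [np.ones(len(df)), df[predictor], *[df[c] for c in covariates]]
    )
    y = df[dependent].to_numpy()
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df2 = len(df) - X.shape[1]
    sigma2 = resid @ resid / df2
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = beta[1] / se
    F = t * t
    return F, df2, F / (F + df2)


class TestAncova:
    def test_matches_normal_equations_oracle(self):
        df = make_regression_table()
        res = ancova(df, "y", "x", ["c1", "c2"], +1)
        F, df2, eta = normal_equations_oracle(df, "y", "x", ["c1", "c2"])
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.df2 == df2
        assert res.eta_p_sq == pytest.approx(eta, rel=1e-10)
        assert res.df1 == 1

    def test_df_bookkeeping_with_four_covariates(self):
        rng = np.random.default_rng(1)
        for n, expected_df2 in [(45, 39), (50, 44)]:
            df = pd.DataFrame(
                rng.normal(size=(n, 6)),
                columns=["y", "x", "a", "b", "c", "d"],
            )
            res = ancova(df, "y", "x", ["a", "b", "c", "d"], +1)
            assert (res.df1, res.df2) == (1, expected_df2)

    def test_one_sided_p_depends_on_hypothesized_direction(self):
        df = make_regression_table(beta_x=2.0)
        up = ancova(df, "y", "x", ["c1"], +1)
        down = ancova(df, "y", "x", ["c1"], -1)
        assert up.p_one_sided < 0.05
        assert down.p_one_sided == pytest.approx(1 - up.p_one_sided, abs=1e-12)
        assert up.coefficient_sign == 1

    def test_missing_rows_dropped_and_counted(self):
        df = make_regression_table(n=50)
        df.loc[:4, "y"] = np.nan
        res = ancova(df, "y", "x", ["c1"], +1)
        assert res.n_used == 45 and res.n_dropped == 5
        assert res.df2 == 45 - 2 - 1

    def test_degenerate_inputs_rejected(self):
        df = make_regression_table(n=30)
        with pytest.raises(ValueError, match="constant"):
            ancova(df.assign(x=1.0), "y", "x", ["c1"], +1)
        with pytest.raises(ValueError, match="collinear"):
            ancova(df.assign(c1=df["x"]), "y", "x", ["c1"], +1)
        with pytest.raises(ValueError, match="few"):
            ancova(df.head(4), "y", "x", ["c1", "c2"], +1)

    def test_row_permutation_leaves_estimates_unchanged(self):
        df = make_regression_table(n=60, seed=3)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r1 = ancova(df, "y", "x", ["c1", "c2"], +1)
        r2 = ancova(shuffled, "y", "x", ["c1", "c2"], +1)
        assert r1.F == pytest.approx(r2.F, rel=1e-10)
        assert r1.coefficient == pytest.approx(r2.coefficient, rel=1e-10)


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df2,expected",
        [(7.28, 39, 0.157), (8.15, 44, 0.156), (0.0, 40, 0.0)],
    )
    def test_reported_triples(self, F, df2, expected):
        assert partial_eta_squared(F, 1, df2) == pytest.approx(expected, abs=5e-4)

    def test_identity_with_f(self):
        for F in (0.5, 3.0, 12.0):
            eta = partial_eta_squared(F, 1, 33)
            assert eta * (F + 33) == pytest.approx(F, rel=1e-12)

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)


def make_mediation_table(n=200, seed=0, a=-0.4, b=-0.5, cp=0.3):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    cov = rng.normal(size=n)
    m = a * x + 0.2 * cov + rng.normal(size=n)
    y = b * m + cp * x - 0.3 * cov + rng.normal(size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "cov": cov})


class TestMediate:
    def test_total_effect_decomposition_exact(self):
        df = make_mediation_table()
        res = mediate(df, "x", "m", "y", ["cov"], n_boot=200, n_perm=200, seed=1)
        assert abs(res.c - (res.c_prime + res.ab)) < 1e-10

    def test_seed_determinism(self):
        df = make_mediation_table(seed=5)
        r1 = mediate(df, "x", "m", "y", ["cov"], n_boot=300, n_perm=300, seed=7)
        r2 = mediate(df, "x", "m", "y", ["cov"], n_boot=300, n_perm=300, seed=7)
        assert r1.ab_ci == r2.ab_ci and r1.p_ab_perm == r2.p_ab_perm

    def test_ci_contains_point_estimate_and_detects_effect(self):
        df = make_mediation_table(n=300, seed=2)
        res = mediate(df, "x", "m", "y", ["cov"], n_boot=1000, n_perm=1000, seed=3)
        lo, hi = res.ab_ci
        assert lo <= res.ab <= hi
        assert res.ab > 0  # (-0.4) * (-0.5)
        assert res.p_ab_perm < 0.05

    def test_paths_match_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = make_mediation_table(n=150, seed=8)
        res = mediate(df, "x", "m", "y", ["cov"], n_boot=100, n_perm=100, seed=0)
        pg = pingouin.mediation_analysis(
            data=df, x="x", m="m", y="y", covar=["cov"], n_boot=100, seed=0
        ).set_index("path")["coef"]
        assert res.ab == pytest.approx(pg["Indirect"], rel=1e-6)
        assert res.c == pytest.approx(pg["Total"], rel=1e-6)
        assert res.c_prime == pytest.approx(pg["Direct"], rel=1e-6)

    def test_null_mediator_rarely_significant(self):
        # b = 0 by construction: permutation p should be uniform-ish
        hits = 0
        for rep in range(20):
            df = make_mediation_table(n=200, seed=100 + rep, b=0.0)
            res = mediate(df, "x", "m", "y", ["cov"], n_boot=50, n_perm=500, seed=rep)
            hits += res.p_ab_perm < 0.05
        assert hits <= 3

    def test_constant_mediator_rejected(self):
        df = make_mediation_table(n=50)
        with pytest.raises(ValueError, match="mediator"):
            mediate(df.assign(m=1.0), "x", "m", "y", [], n_boot=10, n_perm=10, seed=0)

    def test_row_permutation_leaves_point_estimates_unchanged(self):
        df = make_mediation_table(n=120, seed=4)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = mediate(df, "x", "m", "y", ["cov"], n_boot=10, n_perm=10, seed=0)
        r2 = mediate(shuffled, "x", "m", "y", ["cov"], n_boot=10, n_perm=10, seed=0)
        assert r1.ab == pytest.approx(r2.ab, rel=1e-10)
        assert r1.c_prime == pytest.approx(r2.c_prime, rel=1e-10)


def test_direction_map_covers_all_five_contrasts():
    assert set(HYPOTHESIS_DIRECTIONS) == {
        ("mc_mean", "psi"),
        ("ac_mean", "psi"),
        ("psi", "response"),
        ("mc_mean", "response"),
        ("ac_mean", "response"),
    }
    assert HYPOTHESIS_DIRECTIONS[("mc_mean", "psi")] == -1
    assert HYPOTHESIS_DIRECTIONS[("mc_mean", "response")] == +1
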