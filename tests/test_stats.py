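"""Agreement and regression statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvi3d.errors import UndefinedValueError, ValidationError
from cvi3d.stats import (
    bland_altman,
    build_report,
    cov_percent,
    f_test_equal_variance,
    group_compare,
    icc_2_1,
    icc_quality,
    multivariable_model,
    quintile_stratified_sample,
    univariate_screen,
)
from cvi3d.synth import CohortSpec, generate_cohort


def brute_force_icc21(x):
    """ICC(2,1) from explicit two-way ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestCov:
    @pytest.mark.parametrize("mean,sd,expected", [
        (62.92, 1.57, 2.50),
        (63.35, 1.72, 2.72),
        (63.53, 2.09, 3.29),
        (288.3, 85.6, 29.69),
    ])
    def test_published_mean_sd_pairs(self, mean, sd, expected):
        assert cov_percent(mean, sd) == expected

    def test_raw_sample(self):
        sample = np.array([10.0, 12.0, 11.0, 13.0])
        expected = 100 * sample.std(ddof=1) / sample.mean()
        assert cov_percent(sample, ndigits=None) == pytest.approx(expected)

    def test_constant_sample_is_zero(self):
        assert cov_percent(np.array([5.0, 5.0, 5.0])) == 0.0

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedValueError):
            cov_percent(0.0, 1.0)


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_2_1(x)
        assert res.value == pytest.approx(1.0)
        assert res.quality == "excellent"

    def test_constant_offset_penalised(self):
        r1 = np.arange(10.0)
        res = icc_2_1(np.column_stack([r1, r1 + 3.0]))
        assert res.value < 1.0

    def test_toy_matrix_matches_brute_force(self):
        x = np.array([[1, 2], [3, 3], [5, 6], [7, 6], [9, 10]], dtype=float)
        assert icc_2_1(x).value == pytest.approx(brute_force_icc21(x), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_random_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        assert icc_2_1(x).value == pytest.approx(brute_force_icc21(x), abs=1e-10)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        n, k = x.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        # absolute-agreement single-measurement row (labelled ICC2 or ICC(A,1)
        # depending on version)
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        res = icc_2_1(x)
        assert res.value == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_quality_bands(self):
        assert icc_quality(0.3) == "poor"
        assert icc_quality(0.6) == "moderate"
        assert icc_quality(0.8) == "good"
        assert icc_quality(0.95) == "excellent"

    def test_missing_cells_rejected(self):
        x = np.ones((5, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            icc_2_1(x)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.loa == (0.0, 0.0)

    def test_hand_arithmetic(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])  # d = [1, 2, 3]
        res = bland_altman(x, y)
        assert res.mean_diff == pytest.approx(2.0)
        assert res.loa[0] == pytest.approx(2 - 1.96, abs=1e-12)
        assert res.loa[1] == pytest.approx(2 + 1.96, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000), n=st.integers(3, 60))
    def test_mean_diff_is_difference_of_means(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(60, 2, size=n), rng.normal(60, 2, size=n)
        res = bland_altman(x, y)
        assert res.mean_diff == pytest.approx(x.mean() - y.mean(), abs=1e-12)
        assert res.loa[0] <= res.mean_diff <= res.loa[1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestFTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        f, p = f_test_equal_variance(x, x)
        assert f == 1.0 and p == pytest.approx(1.0)

    def test_variance_ratio_four(self):
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        x = (x - x.mean()) / x.std(ddof=1) * 2.0  # sample sd exactly 2
        y = rng.normal(size=10)
        y = (y - y.mean()) / y.std(ddof=1)        # sample sd exactly 1
        f, p = f_test_equal_variance(x, y)
        assert f == pytest.approx(4.0, abs=1e-12)
        dist = sps.f(9, 9)
        assert p == pytest.approx(2 * min(dist.cdf(4.0), dist.sf(4.0)), abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 2, 15), rng.normal(0, 1, 12)
        f1, p1 = f_test_equal_variance(x, y)
        f2, p2 = f_test_equal_variance(y, x)
        assert f2 == pytest.approx(1 / f1)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(UndefinedValueError):
            f_test_equal_variance([1.0, 2.0], [3.0, 3.0])


class TestRegression:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2.0 * np.arange(10.0)})
        screen = univariate_screen(df, "y", ["x"])
        assert screen.loc[0, "estimate"] == pytest.approx(2.0)
        assert screen.loc[0, "p"] < 1e-10

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(scale=0.3, size=30)
        screen = univariate_screen(df, "y", ["x"])
        X = np.column_stack([np.ones(30), df["x"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert screen.loc[0, "estimate"] == pytest.approx(beta[1], abs=1e-10)

    def test_ethnicity_reference_is_chinese(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "ethnicity": rng.choice(["Chinese", "Indian", "Malay"], size=60,
                                    p=[0.6, 0.3, 0.1]),
            "y": rng.normal(size=60),
        })
        screen = univariate_screen(df, "y", ["ethnicity"])
        assert sorted(screen["term"]) == ["ethnicity[Indian]", "ethnicity[Malay]"]

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame({"x": np.ones(20), "y": np.random.default_rng(0).normal(size=20)})
        screen = univariate_screen(df, "y", ["x"])
        assert screen.loc[0, "excluded"]

    def test_no_passing_predictor_gives_age_only_model(self):
        df = generate_cohort(CohortSpec(n_eyes=50, seed=7))
        # select predictors that (by construction) carry no signal; if a
        # chance association passes the screen, drop it for this check
        model = multivariable_model(df, "cvi3d_whole", ["age"], screen_alpha=1e-9)
        assert model.predictors == ("age",)

    def test_adjusted_r2_formula(self):
        df = generate_cohort(CohortSpec(n_eyes=40, seed=3,
                                        effects={"bmi": 1.0, "age": 0.2}))
        model = multivariable_model(df, "cvi3d_whole", ["age", "bmi"])
        import statsmodels.api as sm
        X = sm.add_constant(df[list(model.predictors)].to_numpy(dtype=float))
        fit = sm.OLS(df["cvi3d_whole"].to_numpy(), X).fit()
        n, p = X.shape[0], X.shape[1] - 1
        expected = 1 - (1 - fit.rsquared) * (n - 1) / (n - p - 1)
        assert model.adj_r2 == pytest.approx(expected, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"age": rng.normal(50, 5, 30)})
        df["dup"] = df["age"]
        df["y"] = df["age"] * 0.5 + rng.normal(size=30) * 1e-3
        with pytest.raises(ValidationError):
            multivariable_model(df, "y", ["age", "dup"], screen_alpha=0.99)


class TestGroupCompare:
    def test_equal_group_means(self):
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 4),
            "v": np.tile([1.0, 2.0, 3.0, 4.0], 3),
        })
        assert group_compare(df, "g", "v") == pytest.approx(1.0)

    def test_chi_square_diagonal_table(self):
        from scipy import stats as sps
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "v": ["x"] * 10 + ["y"] * 10,
        })
        p = group_compare(df, "g", "v")
        # N(ad-bc)^2 / (row/col products) = 20 for [[10,0],[0,10]]
        assert p == pytest.approx(float(sps.chi2.sf(20.0, 1)), abs=1e-12)

    def test_proportional_rows_give_p_one(self):
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 20,
            "v": (["x"] * 5 + ["y"] * 5) + (["x"] * 10 + ["y"] * 10),
        })
        assert group_compare(df, "g", "v") == pytest.approx(1.0)

    def test_small_group_rejected_for_anova(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            group_compare(df, "g", "v")


class TestQuintileSampling:
    def test_population_of_fifty_fully_selected(self):
        values = pd.Series(np.arange(50.0), index=[f"id{i}" for i in range(50)])
        selected = quintile_stratified_sample(values, 10, seed=0)
        assert sorted(selected) == sorted(values.index)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(280, 80, size=200))
        a = quintile_stratified_sample(values, 10, seed=42)
        b = quintile_stratified_sample(values, 10, seed=42)
        assert a == b
        c = quintile_stratified_sample(values, 10, seed=43)
        assert a != c

    def test_selected_ids_fall_in_their_stratum_range(self):
        rng = np.random.default_rng(9)
        values = pd.Series(rng.normal(280, 80, size=150))
        selected = quintile_stratified_sample(values, 10, seed=1)
        cuts = np.percentile(values, [20, 40, 60, 80])
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        for q in range(5):
            block = values[selected[q * 10:(q + 1) * 10]]
            assert (block > edges[q]).all() or q == 0
            assert (block <= edges[q + 1]).all() or q == 4

    def test_undersized_quintile_rejected(self):
        values = pd.Series(np.arange(20.0))
        with pytest.raises(ValidationError):
            quintile_stratified_sample(values, 10, seed=0)


class TestReport:
    def test_report_shapes_and_determinism(self, tmp_path):
        df = generate_cohort(CohortSpec(n_eyes=50, seed=21))
        covs = ["age", "se", "al", "bmi", "ethnicity"]
        tables = build_report(df, covariates=covs)
        assert len(tables["agreement"]) == 4
        assert len(tables["scanning_volume"]) == 3
        assert set(tables["agreement"]["comparison"]) == {
            "2d_subfoveal_vs_3d_whole", "2d_subfoveal_vs_3d_superior",
            "2d_subfoveal_vs_3d_central", "2d_subfoveal_vs_3d_inferior"}
        # byte-for-byte reproducibility
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        tables["agreement"].to_csv(p1, index=False)
        build_report(df, covariates=covs)["agreement"].to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_columns_is_schema_error(self):
        with pytest.raises(ValidationError):
            build_report(pd.DataFrame({"cvi3d_whole": [1.0, 2.0]}))
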