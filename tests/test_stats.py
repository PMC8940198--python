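"""Cohort statistics: hand-formula oracles, GLM equivalences, pipeline behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from dyadstats import (
    CohortConfig,
    DegenerateInputError,
    fit_glm,
    independent_t,
    oneway_anova,
    paired_t,
    pearson_r,
    run_pipeline,
    simulate_cohort,
)


# -- independent textbook-formula oracles (pure python/math) -----------------

def oracle_paired_t(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    s = math.sqrt(sum((v - m) ** 2 for v in d) / (n - 1))
    return m / (s / math.sqrt(n))


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_pooled_t(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((v - ma) ** 2 for v in a) / (na - 1)
    sb2 = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def oracle_anova_f(groups):
    N = sum(len(g) for g in groups)
    k = len(groups)
    grand = sum(sum(g) for g in groups) / N
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (N - k))


class TestPairedT:
    def test_hand_formula_example(self):
        """d = (1,2,3): t = 2/(1/sqrt 3) = 3.464, df 2."""
        res = paired_t([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-10)
        assert res.statistic == pytest.approx(3.464, abs=5e-4)
        assert res.df == 2

    def test_null_identity_and_degenerate(self, rng):
        x = rng.normal(size=20)
        noise = rng.normal(size=20)
        res = paired_t(x + noise, x)  # differences vary around... their own mean
        assert np.isfinite(res.statistic)
        with pytest.raises(DegenerateInputError):
            paired_t(x, x)  # constant-zero differences

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            x = list(rng.normal(size=8))
            y = list(rng.normal(size=8))
            assert paired_t(x, y).statistic == pytest.approx(oracle_paired_t(x, y), abs=1e-10)


class TestPearson:
    def test_perfect_and_inverse(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]).estimate == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]).estimate == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]).estimate == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_matches_oracle(self, rng):
        for _ in range(20):
            x = list(rng.normal(size=9))
            y = list(rng.normal(size=9))
            assert pearson_r(x, y).estimate == pytest.approx(oracle_pearson(x, y), abs=1e-10)


class TestIndependentT:
    def test_hand_example(self):
        """(1,2,3) vs (4,5,6): pooled t = −3.674, df 4."""
        values = [1, 2, 3, 4, 5, 6]
        group = ["a", "a", "a", "b", "b", "b"]
        res = independent_t(values, group)
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4
        assert res.estimate == pytest.approx(-3.0)

    def test_identical_means_near_zero(self, rng):
        v = np.concatenate([rng.normal(size=50), rng.normal(size=50)])
        res = independent_t(v, ["a"] * 50 + ["b"] * 50)
        assert abs(res.statistic) < 3

    def test_matches_oracle(self, rng):
        for _ in range(20):
            a = list(rng.normal(size=6))
            b = list(rng.normal(size=9))
            res = independent_t(a + b, ["x"] * 6 + ["y"] * 9)
            assert res.statistic == pytest.approx(oracle_pooled_t(a, b), abs=1e-10)


class TestAnova:
    def test_shifted_group_matches_sums_of_squares_oracle(self, rng):
        groups = [list(rng.normal(0, 1, 10)), list(rng.normal(0, 1, 10)), list(rng.normal(2, 1, 10))]
        values = sum(groups, [])
        factor = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = oneway_anova(values, factor)
        assert res.statistic == pytest.approx(oracle_anova_f(groups), abs=1e-10)
        assert res.df == (2, 27)

    def test_identical_groups_f_near_zero(self):
        res = oneway_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)


class TestGlm:
    def test_single_binary_predictor_equals_pooled_t(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "g": ["low"] * 20 + ["high"] * 20}
        )
        glm = fit_glm(df, "y", factors={"g": "low"})
        t = independent_t(df.y, df.g)
        row = glm.params.query("term == 'g' and level == 'high'").iloc[0]
        assert row.coef == pytest.approx(-t.estimate, abs=1e-10)  # low listed first
        assert row.p == pytest.approx(t.p_value, abs=1e-10)

    def test_balanced_two_factor_matches_normal_equations(self, rng):
        """Brute-force normal-equations oracle on an orthogonal balanced design."""
        levels_a = ["a0", "a1"]
        levels_b = ["b0", "b1", "b2"]
        rows = []
        for a in levels_a:
            for b in levels_b:
                for _ in range(4):
                    rows.append((a, b))
        df = pd.DataFrame(rows, columns=["A", "B"])
        df["y"] = rng.normal(size=len(df))
        glm = fit_glm(df, "y", factors={"A": "a0", "B": "b0"})
        # manual dummy design, same coding
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df.A == "a1").astype(float),
                (df.B == "b1").astype(float),
                (df.B == "b2").astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        got = {
            ("Intercept", ""): beta[0],
            ("A", "a1"): beta[1],
            ("B", "b1"): beta[2],
            ("B", "b2"): beta[3],
        }
        for (term, level), expected in got.items():
            row = glm.params.query("term == @term and level == @level").iloc[0]
            assert row.coef == pytest.approx(expected, abs=1e-10)

    def test_reference_rows_fixed_at_zero(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30), "g": ["a", "b", "c"] * 10})
        glm = fit_glm(df, "y", factors={"g": "c"})
        ref = glm.params.query("reference").iloc[0]
        assert ref.level == "c" and ref.coef == 0.0
        nonref = glm.params.query("term == 'g' and not reference")
        assert set(nonref.level) == {"a", "b"}
        assert ((nonref.ci_low <= nonref.coef) & (nonref.coef <= nonref.ci_high)).all()

    def test_rank_deficiency_names_aliased_term(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=20), "g": ["a", "b"] * 10}
        )
        df["g2"] = df["g"]  # perfectly aliased copy
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(df, "y", factors={"g": "a", "g2": "a"})

    def test_planted_class_effect_recovered(self):
        cohort = simulate_cohort(CohortConfig(n_dyads=100_000), rng=12)
        glm = fit_glm(
            cohort,
            "sensitivity_30mo",
            factors={
                "education": "university", "income": ">3500",
                "infant_sex": "girl", "depressive_class": "low",
            },
        )
        row = glm.params.query("term == 'depressive_class' and level == 'high'").iloc[0]
        assert row.coef == pytest.approx(-0.64, abs=0.05)
        assert row.p < 1e-10


class TestTypeIError:
    def test_rejection_rates_near_alpha_and_p_uniform(self, rng):
        """Null data: each test rejects at ~5%; paired-t p-values are uniform."""
        import scipy.stats

        reps = 1000
        rejections = {"paired": 0, "independent": 0, "anova": 0, "pearson": 0}
        pvals = []
        for _ in range(reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            p = paired_t(x, y).p_value
            pvals.append(p)
            rejections["paired"] += p < 0.05
            rejections["independent"] += (
                independent_t(np.concatenate([x, y]), ["a"] * 40 + ["b"] * 40).p_value < 0.05
            )
            z = rng.normal(size=20)
            rejections["anova"] += (
                oneway_anova(np.concatenate([x[:20], y[:20], z]), ["a"] * 20 + ["b"] * 20 + ["c"] * 20).p_value
                < 0.05
            )
            rejections["pearson"] += pearson_r(x, y).p_value < 0.05
        for name, count in rejections.items():
            assert 0.03 <= count / reps <= 0.07, name
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortConfig(n_dyads=5000), rng=99)


class TestPipeline:
    def test_report_structure_and_planted_signs(self, cohort):
        report = run_pipeline(cohort, config={"seed": 99})
        assert set(report.tables) == {
            "covariate_screen", "age_comparison", "correlations",
            "class_comparisons", "diagnostics",
        }
        age = report.tables["age_comparison"].set_index("construct")
        assert age.loc["entropy", "t"] > 0          # unpredictability decreases with age
        assert age.loc["entropy", "mean_8mo"] == pytest.approx(0.87, abs=0.02)
        corr = report.tables["correlations"].set_index("comparison")
        assert corr.loc["entropy 8mo ~ 30mo", "estimate"] > 0.2
        assert corr.loc["entropy ~ sensitivity (8mo)", "estimate"] < -0.2
        cls = report.tables["class_comparisons"].set_index("comparison")
        assert cls.loc["sensitivity_30mo ~ depressive_class", "p"] < 0.001
        glm = report.glms["glm_sensitivity_depressive_class"]
        row = glm.params.query("term == 'depressive_class' and level == 'high'").iloc[0]
        assert row.coef == pytest.approx(-0.64, abs=0.15)

    def test_missing_column_rejected(self, cohort):
        with pytest.raises(ValueError, match="missing column"):
            run_pipeline(cohort.drop(columns=["entropy_8mo"]))

    def test_deterministic_given_same_cohort(self, cohort, tmp_path):
        r1 = run_pipeline(cohort, config={"seed": 99})
        r2 = run_pipeline(cohort, config={"seed": 99})
        assert r1.summary() == r2.summary()
        r1.to_dir(tmp_path / "a")
        r2.to_dir(tmp_path / "b")
        assert (tmp_path / "a" / "summary.txt").read_text() == (
            tmp_path / "b" / "summary.txt"
        ).read_text()

    def test_null_cohort_has_small_effects_and_uniform_p(self):
        """Zero planted effects: estimates near 0, entropy paired-t p uniform."""
        import scipy.stats

        null_cfg = dict(
            entropy_mean=(0.8, 0.8), entropy_sd=(0.15, 0.15), entropy_stability=0.0,
            sensitivity_mean=(5.0, 5.0), sensitivity_sd=(1.0, 1.0),
            sensitivity_stability=0.0, entropy_sensitivity_r=(0.0, 0.0),
            depressive_sensitivity_means=(5.0, 5.0), anxiety_sensitivity_means=(5.0, 5.0),
        )
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            df = simulate_cohort(CohortConfig(n_dyads=60, **null_cfg), rng=rng)
            pvals.append(paired_t(df.entropy_8mo, df.entropy_30mo).p_value)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01
        big = simulate_cohort(CohortConfig(n_dyads=4000, **null_cfg), rng=rng)
        report = run_pipeline(big)
        corr = report.tables["correlations"]
        assert (corr["estimate"].abs() < 0.05).all()
        glm = report.glms["glm_sensitivity_depressive_class"]
        row = glm.params.query("term == 'depressive_class' and level == 'high'").iloc[0]
        assert abs(row.coef) < 0.15

    def test_header_records_provenance(self, cohort):
        report = run_pipeline(cohort, config={"seed": 7})
        assert report.header["n_dyads"] == 5000
        assert report.header["seed"] == 7
        assert "raw p-values" in report.header["multiple_testing"]
        assert len(report.header["config_hash"]) == 12
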