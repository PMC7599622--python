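"""Analysis battery vs independent brute-force oracles and constructed cases."""

import math

import numpy as np
import pandas as pd
import pytest

from gaprunner import (
    ConfigurationError,
    DegenerateDataError,
    SingularDesignError,
    anova_on_correlations,
    bonferroni_pairwise,
    collinearity_table,
    correlation_table,
    generate_cohort,
    metrics_table,
    ols_fit,
    pearson,
    per_block_correlations,
    repeated_validation,
    validation_predictors,
)
from gaprunner.stats import MODEL_SUBSETS, fisher_z_mean

# ---------------------------------------------------------------- oracles


def oracle_pearson(x, y):
    """Direct product-moment formula, no library calls."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_ols(X, y):
    """Normal equations with intercept; coefficients and t statistics."""
    Xd = np.column_stack([np.ones(len(y)), X])
    XtX = Xd.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ y)
    resid = y - Xd @ beta
    dof = len(y) - Xd.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, beta / se


def oracle_anova(groups):
    """Sums-of-squares one-way ANOVA from first principles."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


# ---------------------------------------------------------------- pearson


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson([1, 2, 3], [1, 2, 3]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y).r == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ConfigurationError):
            pearson([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_p_value_from_t_distribution(self, rng):
        import scipy.stats as sps

        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)


# -------------------------------------------------------------------- OLS


class TestOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = ols_fit(2 * x, {"x": x})
        assert res.term("x").coef == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 13))
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            res = ols_fit(y, {"a": X[:, 0], "b": X[:, 1]})
            beta, tvals = oracle_ols(X, y)
            got = [res.term("const").coef, res.term("a").coef, res.term("b").coef]
            got_t = [res.term("const").t, res.term("a").t, res.term("b").t]
            assert np.allclose(got, beta, atol=1e-10)
            assert np.allclose(got_t, tvals, atol=1e-10)

    def test_slope_t_equals_pearson_t(self, rng):
        """Algebraic identity in simple regression, over 100 random instances."""
        for _ in range(100):
            n = int(rng.integers(5, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = ols_fit(y, {"x": x})
            c = pearson(x, y)
            t_r = c.r * math.sqrt((n - 2) / (1 - c.r**2))
            assert res.term("x").t == pytest.approx(t_r, abs=1e-10)
            assert res.term("x").p == pytest.approx(c.p, abs=1e-10)

    def test_duplicated_predictor_is_singular(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(SingularDesignError):
            ols_fit(rng.normal(size=10), {"a": x, "b": x})


# ------------------------------------------------------------ correlation grid


def _cohort_frames(n=40, seed=3):
    cohort = generate_cohort(n=n, seed=seed)
    return cohort, metrics_table(cohort), \
        {k: float(v) for k, v in cohort.swan_totals().items()}


class TestCorrelationTable:
    def test_grid_shape(self):
        _, mtab, swan = _cohort_frames()
        grid = correlation_table(mtab, swan)
        assert len(grid) == 12
        preds = {k[0] for k in grid}
        scopes = {k[1] for k in grid}
        assert preds == {"median", "iqr", "omissions"}
        assert scopes == {"ALL", "SHORT", "MEDIUM", "LONG"}

    def test_swan_equal_to_median_gives_r_one(self):
        _, mtab, _ = _cohort_frames()
        fake = {
            pid: m
            for pid, m in mtab[mtab["scope"] == "ALL"][
                ["participant_id", "median"]].itertuples(index=False)
        }
        grid = correlation_table(mtab, fake)
        assert grid[("median", "ALL")].r == pytest.approx(1.0)

    def test_default_cohort_sign_pattern_all_scope(self):
        """n = 200 synthetic cohort: (+, +, -) for (median, IQR, omissions)."""
        cohort = generate_cohort(n=200, seed=0)
        mtab = metrics_table(cohort)
        grid = correlation_table(
            mtab, {k: float(v) for k, v in cohort.swan_totals().items()})
        assert grid[("median", "ALL")].r > 0
        assert grid[("iqr", "ALL")].r > 0
        assert grid[("omissions", "ALL")].r < 0

    def test_two_participants_degenerate(self):
        _, mtab, swan = _cohort_frames(n=2, seed=1)
        with pytest.raises(DegenerateDataError):
            correlation_table(mtab, swan)


# ------------------------------------------------------------ collinearity


class TestCollinearityTable:
    def test_seven_models_in_order(self):
        _, mtab, swan = _cohort_frames()
        regs = collinearity_table(mtab, swan)
        assert [r.model_label for r in regs] == [
            "median", "iqr", "omissions",
            "median+iqr", "median+omissions", "iqr+omissions",
            "median+iqr+omissions",
        ]
        assert len(MODEL_SUBSETS) == 7

    def test_collinear_predictors_significant_alone_not_jointly(self, rng):
        """Near-duplicate predictors: each strong alone, none in the full model."""
        n = 32
        z = rng.normal(size=n)
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "scope": "ALL",
            "median": z + 0.05 * rng.normal(size=n),
            "iqr": z + 0.05 * rng.normal(size=n),
            "omissions": z + 0.05 * rng.normal(size=n),
        })
        swan = {f"P{i}": z[i] + 0.5 * rng.normal() for i in range(n)}
        regs = {r.model_label: r for r in collinearity_table(df, swan)}
        for name in ("median", "iqr", "omissions"):
            assert regs[name].term(name).p < 0.05
        full = regs["median+iqr+omissions"]
        assert all(full.term(nm).p > 0.05 for nm in ("median", "iqr", "omissions"))

    def test_orthogonal_predictors_stay_significant_jointly(self, rng):
        n = 60
        a, b, c = rng.normal(size=(3, n))
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "scope": "ALL", "median": a, "iqr": b, "omissions": c,
        })
        y = 2 * a + 2 * b + 2 * c + 0.3 * rng.normal(size=n)
        swan = {f"P{i}": y[i] for i in range(n)}
        regs = {r.model_label: r for r in collinearity_table(df, swan)}
        full = regs["median+iqr+omissions"]
        assert all(full.term(nm).p < 0.05 for nm in ("median", "iqr", "omissions"))


# ------------------------------------------------------- per-block profile


class TestPerBlockCorrelations:
    def test_eighteen_blocks_in_order(self, small_cohort):
        out = per_block_correlations(small_cohort)
        assert [bid for bid, _, _ in out] == [f"B{i}" for i in range(1, 19)]
        classes = [cls.value for _, cls, _ in out]
        assert classes.count("SHORT") == classes.count("MEDIUM") == 6

    def test_toy_cohort_matches_direct_formula(self):
        """Hand-built 4-participant toy: per-block r against the formula."""
        from gaprunner import BlockConfig, Schedule, scripted_policy, simulate_session
        from gaprunner.cohort_sim import Cohort, ParticipantProfile, SwanScore

        sched = Schedule(blocks=(
            BlockConfig("B1", 8.0, 2.0, 5.0, n_gaps=2),
            BlockConfig("B2", 13.0, 2.0, 5.0, n_gaps=2),
        ))
        dists = {"P1": [1, 2, 5, 5], "P2": [2, 3, 4, 6], "P3": [3, 3, 3, 3],
                 "P4": [4, 5, 1, 2]}
        totals = {"P1": -10, "P2": 0, "P3": 5, "P4": 20}
        profiles, swans, logs = [], [], []
        for pid, script in dists.items():
            profiles.append(ParticipantProfile(participant_id=pid, lam=0.5))
            swans.append(SwanScore(items=_items_for_total(totals[pid]),
                                   total=totals[pid]))
            logs.append(simulate_session(
                sched, scripted_policy([float(d) for d in script]), pid, 0))
        cohort = Cohort(profiles=profiles, swan=swans, logs=logs)
        out = per_block_correlations(cohort)
        med_b1 = [1.5, 2.5, 3.0, 4.5]
        med_b2 = [5.0, 5.0, 3.0, 1.5]
        sw = [totals[p] for p in ("P1", "P2", "P3", "P4")]
        assert out[0][2].r == pytest.approx(oracle_pearson(med_b1, sw), abs=1e-12)
        assert out[1][2].r == pytest.approx(oracle_pearson(med_b2, sw), abs=1e-12)

    def test_default_cohort_is_gradient(self):
        """Seeded n = 200 cohort: long/medium blocks out-predict short ones."""
        cohort = generate_cohort(n=200, seed=0)
        out = per_block_correlations(cohort)
        by_class = {"SHORT": [], "MEDIUM": [], "LONG": []}
        for _, cls, res in out:
            by_class[cls.value].append(res.r)
        mean_ml = np.mean(by_class["MEDIUM"] + by_class["LONG"])
        assert mean_ml > np.mean(by_class["SHORT"])


def _items_for_total(total):
    """Nine items in [-3, 3] summing to ``total``."""
    items = []
    rest = total
    for _ in range(9):
        v = max(-3, min(3, rest))
        items.append(v)
        rest -= v
    assert rest == 0
    return tuple(items)


# ------------------------------------------------------------------ ANOVA


class TestAnova:
    def test_equal_means_f_near_zero(self):
        rs = [0.1, 0.3, 0.1, 0.3, 0.1, 0.3]
        classes = ["S", "S", "M", "M", "L", "L"]
        res = anova_on_correlations(rs, classes)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.df_between == 2 and res.df_within == 3

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(100):
            sizes = rng.integers(2, 7, size=3)
            groups = [list(rng.normal(size=s)) for s in sizes]
            rs = [v for g in groups for v in g]
            classes = [c for c, g in zip("SML", groups) for _ in g]
            res = anova_on_correlations(rs, classes)
            assert res.F == pytest.approx(oracle_anova(groups), abs=1e-10)

    def test_constructed_separation_significant(self, rng):
        short = 0.1 + 0.01 * rng.normal(size=6)
        med = 0.5 + 0.01 * rng.normal(size=6)
        long_ = 0.5 + 0.01 * rng.normal(size=6)
        rs = np.concatenate([short, med, long_])
        classes = ["SHORT"] * 6 + ["MEDIUM"] * 6 + ["LONG"] * 6
        res = anova_on_correlations(rs, classes)
        assert res.p < 0.05

    def test_undersized_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            anova_on_correlations([0.1, 0.2, 0.3], ["S", "S", "M"])


class TestBonferroniPairwise:
    def test_identical_groups_nothing_significant(self):
        rs = [0.2, 0.3, 0.2, 0.3, 0.2, 0.3]
        classes = ["S", "S", "M", "M", "L", "L"]
        out = bonferroni_pairwise(rs, classes)
        assert len(out) == 3
        assert not any(c.significant for c in out)

    def test_per_test_alpha_is_family_over_three(self):
        rs = [0.2, 0.3, 0.2, 0.3, 0.2, 0.3]
        classes = ["S", "S", "M", "M", "L", "L"]
        out = bonferroni_pairwise(rs, classes, family_alpha=0.05)
        assert all(c.per_test_alpha == pytest.approx(0.05 / 3) for c in out)

    def test_constructed_short_vs_rest_pattern(self, rng):
        """SHORT shifted down, MEDIUM ~ LONG: only the SHORT pairs flag."""
        rs = np.concatenate([
            0.12 + 0.04 * rng.normal(size=6),
            0.50 + 0.04 * rng.normal(size=6),
            0.52 + 0.04 * rng.normal(size=6),
        ])
        classes = ["SHORT"] * 6 + ["MEDIUM"] * 6 + ["LONG"] * 6
        flags = {c.pair: c.significant for c in bonferroni_pairwise(rs, classes)}
        assert flags[("SHORT", "MEDIUM")] and flags[("SHORT", "LONG")]
        assert not flags[("MEDIUM", "LONG")]


# ----------------------------------------------------------- hold-out loop


class TestRepeatedValidation:
    @staticmethod
    def _frame(X, ids=None):
        ids = ids or [f"P{i}" for i in range(len(X))]
        return pd.DataFrame(X, index=ids, columns=["SHORT", "MEDIUM", "LONG"])

    def test_train_test_sizes_match_three_quarters_split(self, rng):
        X = self._frame(rng.normal(size=(32, 3)))
        swan = {p: float(rng.normal()) for p in X.index}
        res = repeated_validation(X, swan, reps=10, seed=0)
        assert res.train_n == 24 and res.test_n == 8

    def test_noise_free_linear_signal_gives_mean_r_one(self, rng):
        X = rng.normal(size=(32, 3))
        y = 1.0 + X @ np.array([2.0, -1.0, 0.5])
        frame = self._frame(X)
        swan = {p: float(v) for p, v in zip(frame.index, y)}
        res = repeated_validation(frame, swan, reps=200, seed=1)
        assert res.mean_r == pytest.approx(1.0, abs=1e-6)

    def test_null_signal_mean_r_near_zero(self, rng):
        """No predictor-response association: the hold-out r averages to ~0.

        A single finite cohort retains whatever chance association its 32
        rows happen to carry (across-cohort SD of the per-cohort mean r is
        about 0.2), so the null calibration averages splits over many
        independent null cohorts.
        """
        means = []
        for c in range(100):
            X = rng.normal(size=(32, 3))
            y = rng.normal(size=32)
            frame = self._frame(X)
            swan = {p: float(v) for p, v in zip(frame.index, y)}
            means.append(repeated_validation(frame, swan, reps=20, seed=c).mean_r)
        assert abs(np.mean(means)) < 0.1

    def test_reproducible_and_label_invariant(self, rng):
        X = rng.normal(size=(16, 3))
        y = X @ np.array([1.0, 1.0, 1.0]) + rng.normal(size=16)
        f1 = self._frame(X)
        swan = {p: float(v) for p, v in zip(f1.index, y)}
        r1 = repeated_validation(f1, swan, reps=50, seed=3)
        r2 = repeated_validation(f1, swan, reps=50, seed=3)
        assert r1.mean_r == r2.mean_r
        relabel = {f"P{i}": f"Q{i}" for i in range(16)}
        f2 = f1.rename(index=relabel)
        swan2 = {relabel[k]: v for k, v in swan.items()}
        r3 = repeated_validation(f2, swan2, reps=50, seed=3)
        assert r3.mean_r == pytest.approx(r1.mean_r, abs=1e-12)

    def test_degenerate_test_sets_excluded(self):
        X = self._frame(np.arange(24.0).reshape(8, 3))
        swan = {p: 1.0 for p in X.index}  # constant response
        with pytest.raises(DegenerateDataError):
            repeated_validation(X, swan, reps=5, seed=0)

    def test_too_small_cohort_rejected(self, rng):
        X = self._frame(rng.normal(size=(6, 3)))
        swan = {p: float(rng.normal()) for p in X.index}
        with pytest.raises(DegenerateDataError):
            repeated_validation(X, swan, reps=5, seed=0)

    def test_validation_predictors_pivot(self, small_cohort):
        mtab = metrics_table(small_cohort)
        wide = validation_predictors(mtab)
        assert list(wide.columns) == ["SHORT", "MEDIUM", "LONG"]
        assert len(wide) <= len(small_cohort)

    def test_fisher_z_mean_bounds(self):
        assert fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5)
        assert -1 < fisher_z_mean([-0.9, 0.9, 0.2]) < 1
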