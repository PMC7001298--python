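"""Split-plot ANOVA, permutation, bootstrap and t-test inference layer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sympy.utilities.iterables import multiset_permutations

from nfds import (
    LineRecord,
    ResponseMatrix,
    UnbalancedDesignError,
    bootstrap_mean_ci,
    global_t_test,
    group_means,
    permutation_test_between,
    response_matrix,
    rm_anova,
)

SF = np.repeat([0.2, 0.8], 6)
ENV = np.tile(np.repeat(["hom", "het"], 3), 2)


def matrix(y, sf=SF, env=ENV, kind="s_I"):
    n = len(sf)
    return ResponseMatrix(
        line_id=tuple(f"L{i:02d}" for i in range(n)),
        start_freq=np.asarray(sf),
        environment=np.asarray(env),
        y=np.asarray(y, dtype=float),
        kind=kind,
    )


def random_matrix(rng, n_per_cell=3, effects=False):
    sf = np.repeat([0.2, 0.8], 2 * n_per_cell)
    env = np.tile(np.repeat(["hom", "het"], n_per_cell), 2)
    y = rng.normal(size=(len(sf), 2))
    if effects:
        y += 0.8 * (sf == 0.2)[:, None] + 0.5 * (env == "hom")[:, None]
        y[:, 1] += 0.4
    return matrix(y, sf, env)


def statsmodels_oracle(data):
    """Independent split-plot F values via OLS on line means and differences.

    Between-stratum F comes from a two-way GLM on per-line means; the
    within stratum from the same GLM on per-line interval differences, the
    generation main effect being the squared intercept t under sum coding.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frame = pd.DataFrame(
        {
            "m": data.y.mean(axis=1),
            "d": data.y[:, 1] - data.y[:, 0],
            "sf": data.start_freq.astype(str),
            "env": data.environment,
        }
    )
    out = {}
    fit_m = smf.ols("m ~ C(sf, Sum) * C(env, Sum)", frame).fit()
    an_m = anova_lm(fit_m, typ=2)
    out["SF"] = an_m.loc["C(sf, Sum)", "F"]
    out["E"] = an_m.loc["C(env, Sum)", "F"]
    out["SF:E"] = an_m.loc["C(sf, Sum):C(env, Sum)", "F"]
    fit_d = smf.ols("d ~ C(sf, Sum) * C(env, Sum)", frame).fit()
    an_d = anova_lm(fit_d, typ=2)
    out["G"] = float(fit_d.tvalues["Intercept"] ** 2)
    out["G:SF"] = an_d.loc["C(sf, Sum)", "F"]
    out["G:E"] = an_d.loc["C(env, Sum)", "F"]
    out["G:SF:E"] = an_d.loc["C(sf, Sum):C(env, Sum)", "F"]
    return out


class TestRmAnova:
    def test_df_structure_of_12_line_design(self, rng):
        table = rm_anova(random_matrix(rng))
        between = table[table.stratum == "between"]
        within = table[table.stratum == "within"]
        assert between["df"].tolist() == [1, 1, 1, 8]
        assert within["df"].tolist() == [1, 1, 1, 1, 8]
        assert table["df"].sum() == 23

    def test_ss_additive_within_strata(self, rng):
        data = random_matrix(rng, effects=True)
        table = rm_anova(data)
        total = ((data.y - data.y.mean()) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(total)

    def test_constant_response_flagged(self):
        table = rm_anova(matrix(np.full((12, 2), 0.7)))
        assert (table["SS"] == pytest.approx(0.0)) is not False
        assert table["SS"].abs().max() < 1e-25
        assert table["F"].isna().all()

    def test_matches_glm_oracle(self, rng):
        for _ in range(10):
            data = random_matrix(rng, effects=True)
            table = rm_anova(data).set_index("term")
            oracle = statsmodels_oracle(data)
            for term, f_expected in oracle.items():
                assert table.loc[term, "F"] == pytest.approx(f_expected, abs=1e-8)

    def test_row_order_invariance(self, rng):
        data = random_matrix(rng, effects=True)
        perm = rng.permutation(data.n_lines)
        shuffled = matrix(data.y[perm], data.start_freq[perm], data.environment[perm])
        a = rm_anova(data).set_index("term")["F"]
        b = rm_anova(shuffled).set_index("term")["F"]
        assert np.allclose(a.dropna(), b.dropna())

    def test_measure_swap_invariance(self, rng):
        """Swapping the two repeated measures flips G's sign, not any F."""
        data = random_matrix(rng, effects=True)
        swapped = matrix(data.y[:, ::-1], data.start_freq, data.environment)
        a = rm_anova(data).set_index("term")["F"].dropna()
        b = rm_anova(swapped).set_index("term")["F"].dropna()
        assert np.allclose(a, b)

    def test_unbalanced_rejected(self):
        with pytest.raises(UnbalancedDesignError, match="unbalanced"):
            rm_anova(
                matrix(
                    np.zeros((12, 2)),
                    sf=np.repeat([0.2, 0.8], [8, 4]),
                    env=ENV,
                )
            )

    def test_three_measures_rejected(self):
        with pytest.raises(UnbalancedDesignError, match="2 repeated measures"):
            matrix(np.zeros((12, 3))).validate()


class TestPermutation:
    def test_matches_exhaustive_enumeration(self, rng):
        """Random-permutation p approximates the exhaustive label-shuffle p."""
        sf = np.repeat([0.2, 0.8], 4)
        env = np.tile(np.repeat(["hom", "het"], 2), 2)
        y = rng.normal(size=(8, 2)) + 0.6 * (sf == 0.2)[:, None]
        data = matrix(y, sf, env)
        obs = rm_anova(data).set_index("term").loc["SF", "F"]

        cells = [0, 0, 1, 1, 2, 2, 3, 3]
        exceed = total = 0
        for assignment in multiset_permutations(cells):
            sf_p = np.array([(0.2, 0.8)[c // 2] for c in assignment])
            env_p = np.array([("hom", "het")[c % 2] for c in assignment])
            f = rm_anova(matrix(y, sf_p, env_p)).set_index("term").loc["SF", "F"]
            exceed += f >= obs
            total += 1
        p_exact = exceed / total

        n_perm = 4999
        p_rand = permutation_test_between(data, "SF", n_perm=n_perm, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_rand - p_exact) < 2 * se + 2 / n_perm

    def test_constant_response_maximal_p(self):
        data = matrix(np.full((12, 2), 0.3))
        assert permutation_test_between(data, "SF", n_perm=99, seed=0) == 1.0

    def test_reproducible_and_term_checked(self, rng):
        data = random_matrix(rng, effects=True)
        p1 = permutation_test_between(data, "E", n_perm=999, seed=7)
        p2 = permutation_test_between(data, "E", n_perm=999, seed=7)
        assert p1 == p2
        with pytest.raises(ValueError, match="term"):
            permutation_test_between(data, "G", seed=0)

    def test_strong_effect_small_p(self, rng):
        y = rng.normal(scale=0.1, size=(12, 2)) + 5.0 * (SF == 0.2)[:, None]
        p = permutation_test_between(matrix(y), "SF", n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000, abs=5e-3)

    def test_agrees_with_parametric_on_null(self, rng):
        """Permutation and F-distribution p-values track on Gaussian nulls."""
        gaps = []
        for _ in range(60):
            data = random_matrix(rng)
            p_param = rm_anova(data).set_index("term").loc["SF", "p"]
            p_perm = permutation_test_between(data, "SF", n_perm=999, seed=rng)
            gaps.append(abs(p_param - p_perm))
        assert np.mean(gaps) < 0.03


class TestBootstrap:
    def test_degenerate_inputs(self):
        ci = bootstrap_mean_ci([0.4] * 6, n_boot=199, seed=0)
        assert (ci.estimate, ci.lower, ci.upper) == pytest.approx((0.4, 0.4, 0.4))
        with pytest.raises(ValueError):
            bootstrap_mean_ci([])
        with pytest.warns(UserWarning, match="single"):
            ci1 = bootstrap_mean_ci([0.2], n_boot=199, seed=0)
        assert ci1.lower == ci1.upper == 0.2

    def test_range_containment(self):
        ci = bootstrap_mean_ci([0.0, 1.0] * 6, n_boot=2999, seed=1)
        assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0
        assert ci.estimate == pytest.approx(0.5)

    def test_reproducible(self):
        a = bootstrap_mean_ci(np.arange(12.0), n_boot=999, seed=3)
        b = bootstrap_mean_ci(np.arange(12.0), n_boot=999, seed=3)
        assert a == b


class TestGlobalT:
    def test_hand_example(self):
        t, df, p = global_t_test([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_all_zero(self):
        t, df, p = global_t_test([0.0] * 5)
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_undefined_inputs_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            global_t_test([0.1, np.nan, 0.2])


class TestGroupMeans:
    def lines(self, s_by_cell, noise, rng, reps=3):
        out = []
        i = 0
        for sf in (0.2, 0.8):
            for env in ("hom", "het"):
                for _ in range(reps):
                    i += 1
                    base = s_by_cell[(sf, env)]
                    y = base + noise * rng.normal(size=2)
                    out.append((f"L{i:02d}", sf, env, y))
        return matrix(
            np.array([r[3] for r in out]),
            np.array([r[1] for r in out]),
            np.array([r[2] for r in out]),
        )

    def test_identical_cells_overlap(self, rng):
        # enough replicate lines per cell for percentile CIs near nominal coverage
        data = self.lines(
            {(a, b): 0.2 for a in (0.2, 0.8) for b in ("hom", "het")}, 0.05, rng, reps=8
        )
        gm = group_means(data, n_boot=999, seed=0)
        assert len(gm) == 4
        for s1, s2 in itertools.combinations(gm.values(), 2):
            assert max(s1.lower, s2.lower) <= min(s1.upper, s2.upper)  # pairwise overlap

    def test_constructed_null_cell_detected(self, rng):
        s_by_cell = {
            (0.2, "hom"): 0.25,
            (0.8, "hom"): 0.25,
            (0.2, "het"): 0.25,
            (0.8, "het"): 0.0,
        }
        data = self.lines(s_by_cell, 0.02, rng)
        gm = group_means(data, n_boot=1999, seed=0)
        assert gm[(0.8, "het")].covers(0.0)
        for key in [(0.2, "hom"), (0.8, "hom"), (0.2, "het")]:
            assert not gm[key].covers(0.0)

    def test_reproducible(self, rng):
        data = self.lines({(a, b): 0.1 for a in (0.2, 0.8) for b in ("hom", "het")}, 0.1, rng)
        assert group_means(data, n_boot=499, seed=9) == group_means(data, n_boot=499, seed=9)


class TestResponseMatrixBuilder:
    @staticmethod
    def twelve_lines():
        return [
            LineRecord(f"L{i:02d}", sf, env, sf, 0.4, 0.45)
            for i, (sf, env, _) in enumerate(
                itertools.product((0.2, 0.8), ("hom", "het"), range(3)), start=1
            )
        ]

    def test_from_line_records(self):
        lines = self.twelve_lines()
        rm_d = response_matrix(lines, kind="delta_f")
        assert rm_d.y.shape == (12, 2)
        assert rm_d.y[0, 0] == pytest.approx((0.4 - 0.2) / 5)
        assert rm_d.y[0, 1] == pytest.approx((0.45 - 0.4) / 5)
        rm_s = response_matrix(lines, kind="s_I")
        assert np.isfinite(rm_s.y).all()

    def test_undefined_estimates_named(self):
        lines = self.twelve_lines()
        bad = lines[4]
        lines[4] = LineRecord("L05", bad.start_freq, bad.environment, bad.f0, 1.0, 1.0)
        with pytest.raises(ValueError, match="L05"):
            response_matrix(lines, kind="s_I")
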