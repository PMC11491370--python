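import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from strepniche import stats

from conftest import make_design, make_profile


def balanced_design(n_per_cell, rng=None, means=None):
    """2x2xn layout with optional cell means (keyed (richness, fungicide))."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for r in ("mono", "poly"):
        for f in ("unt", "trt"):
            mu = 0.0 if means is None else means[(r, f)]
            for _ in range(n_per_cell):
                rows.append({"richness": r, "fungicide": f, "y": rng.normal(mu, 1.0)})
    return pd.DataFrame(rows)


def projection_ss_oracle(y, richness, fungicide):
    """Sequential SS via explicit least-squares projections (independent path)."""
    y = np.asarray(y, float)
    frames = []
    x0 = np.ones((len(y), 1))
    d_r = pd.get_dummies(pd.Series(richness), drop_first=True).to_numpy(float)
    cells = pd.Series([f"{r}|{f}" for r, f in zip(richness, fungicide)])
    d_c = pd.get_dummies(cells, drop_first=True).to_numpy(float)
    x1 = np.hstack([x0, d_r])
    x2 = np.hstack([x0, d_c])  # same span as richness + nested fungicide

    def fit_ss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return float(((x @ beta) ** 2).sum())

    s0, s1, s2 = fit_ss(x0), fit_ss(x1), fit_ss(x2)
    return s1 - s0, s2 - s1, float((y**2).sum()) - s2


class TestNestedAnova:
    def test_no_variance_gives_f_zero_p_one(self):
        df = balanced_design(3)
        res = stats.nested_anova(
            np.full(len(df), 2.5), df.richness.to_numpy(), df.fungicide.to_numpy()
        )
        assert res.f("richness") == 0.0 and res.p("richness") == 1.0
        assert res.f("fungicide(richness)") == 0.0 and res.p("fungicide(richness)") == 1.0

    def test_ss_and_df_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            df = balanced_design(int(rng.integers(2, 8)), rng)
            res = stats.nested_anova(
                df.y.to_numpy(), df.richness.to_numpy(), df.fungicide.to_numpy()
            )
            t = res.table
            parts = t.loc[["richness", "fungicide(richness)", "residual"]]
            assert parts.sum_sq.sum() == pytest.approx(
                t.at["total", "sum_sq"], abs=1e-9
            )
            assert parts.df.sum() == t.at["total", "df"]

    def test_matches_projection_oracle_on_balanced_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            df = balanced_design(
                5, rng, means={("mono", "unt"): 0, ("mono", "trt"): 1,
                               ("poly", "unt"): 0.5, ("poly", "trt"): 0.2}
            )
            res = stats.nested_anova(
                df.y.to_numpy(), df.richness.to_numpy(), df.fungicide.to_numpy()
            )
            ss_r, ss_n, ss_e = projection_ss_oracle(
                df.y.to_numpy(), df.richness.to_numpy(), df.fungicide.to_numpy()
            )
            assert res.table.at["richness", "sum_sq"] == pytest.approx(ss_r, abs=1e-9)
            assert res.table.at["fungicide(richness)", "sum_sq"] == pytest.approx(
                ss_n, abs=1e-9
            )
            assert res.table.at["residual", "sum_sq"] == pytest.approx(ss_e, abs=1e-9)

    def test_matches_statsmodels_sequential_anova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        df = balanced_design(6, rng, means={("mono", "unt"): 0, ("mono", "trt"): 0.8,
                                            ("poly", "unt"): -0.5, ("poly", "trt"): 0})
        res = stats.nested_anova(
            df.y.to_numpy(), df.richness.to_numpy(), df.fungicide.to_numpy()
        )
        ref = anova_lm(
            smf.ols("y ~ C(richness) + C(richness):C(fungicide)", df).fit(), typ=1
        )
        assert res.p("richness") == pytest.approx(ref.loc["C(richness)", "PR(>F)"], abs=1e-12)
        assert res.p("fungicide(richness)") == pytest.approx(
            ref.loc["C(richness):C(fungicide)", "PR(>F)"], abs=1e-12
        )

    def test_rejects_degenerate_layouts(self):
        with pytest.raises(ValueError):
            stats.nested_anova(
                np.arange(4.0),
                np.array(["m", "m", "p", "p"]),
                np.array(["u", "t", "u", "t"]),
            )  # zero residual df
        with pytest.raises(ValueError):
            stats.nested_anova(
                np.arange(8.0),
                np.array(["m"] * 8),
                np.array(["u", "t"] * 4),
            )  # constant richness


class TestTukey:
    def test_two_groups_equal_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 7)
        table, _ = stats.tukey_hsd(
            np.concatenate([a, b]), np.array(["a"] * 9 + ["b"] * 7)
        )
        _, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert table.p.iloc[0] == pytest.approx(p_ref, abs=1e-9)

    def test_identical_groups_share_one_letter(self):
        values = np.tile([1.0, 2.0, 3.0], 4)
        groups = np.repeat(["g1", "g2", "g3", "g4"], 3)
        table, display = stats.tukey_hsd(values, groups)
        assert not table.significant.any()
        assert set(display.letters.values()) == {"a"}

    def test_shifted_group_gets_unique_letter(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(10, 1, 8)]
        )
        groups = np.repeat(["g1", "g2", "g3"], 8)
        _, display = stats.tukey_hsd(values, groups)
        assert display.letters["g1"] == display.letters["g2"]
        assert display.letters["g3"] not in (
            display.letters["g1"],
            display.letters["g2"],
        )

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.normal(m, 1, 6) for m in (0.0, 0.5, 3.0, 3.2)]
        )
        groups = np.repeat(["g1", "g2", "g3", "g4"], 6)
        table, display = stats.tukey_hsd(values, groups)
        for _, row in table.iterrows():
            shared = set(display.letters[row.group1]) & set(display.letters[row.group2])
            assert bool(shared) == (not row.significant)

    def test_singleton_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="lonely"):
            stats.tukey_hsd(
                np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "lonely"])
            )


class TestPearson:
    def test_perfect_line_and_orthogonal_vectors(self):
        x = np.arange(10.0)
        r2, p = stats.pearson_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-12
        y = np.array([1.0, -1.0] * 5)  # orthogonal to a constant-step ramp? no:
        x2 = np.array([1.0, 1.0, -1.0, -1.0])
        y2 = np.array([1.0, -1.0, 1.0, -1.0])
        r2b, _ = stats.pearson_r2(x2, y2)
        assert r2b == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # r = cov/(sx sy) evaluated by hand: r = 0.8, r^2 = 0.64
        sx = x - x.mean()
        sy = y - y.mean()
        r_hand = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        r2, p = stats.pearson_r2(x, y)
        assert r2 == pytest.approx(r_hand**2, abs=1e-12)
        t = r_hand * math.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3), abs=1e-12)

    def test_constant_input_undefined(self):
        r2, p = stats.pearson_r2(np.ones(5), np.arange(5.0))
        assert math.isnan(r2) and math.isnan(p)


def naive_bh(p):
    """Quadratic-time step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    adj = np.empty(m)
    for i, pi in enumerate(p):
        rank_vals = []
        for j, pj in enumerate(p):
            if pj >= pi:
                rank = (p <= pj).sum()
                rank_vals.append(min(1.0, m * pj / rank))
        adj[i] = min(rank_vals)
    return adj


class TestFdr:
    def test_single_p_unchanged(self):
        res = stats.fdr_adjust([0.03])
        assert res.adjusted[0] == pytest.approx(0.03)

    def test_stepup_worked_example(self):
        res = stats.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert res.adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0, width=32), min_size=1, max_size=20))
    def test_matches_naive_oracle_and_by_dominates_bh(self, pvals):
        bh = stats.fdr_adjust(pvals, method="bh")
        by = stats.fdr_adjust(pvals, method="by")
        assert bh.adjusted == pytest.approx(naive_bh(pvals), abs=1e-12)
        assert np.all(by.adjusted >= bh.adjusted - 1e-12)
        assert np.all(bh.adjusted >= bh.raw - 1e-12)
        assert np.all(bh.adjusted <= 1.0 + 1e-12)
        order = np.argsort(bh.raw)
        assert np.all(np.diff(bh.adjusted[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_adjust([0.5, 1.2])


class TestPerSubstrateScreen:
    @staticmethod
    def _profiles_and_design(rng, n_per_cell=5, n_sub=12, shift_subs=(), shift=0.0):
        iso = {}
        profiles = []
        k = 0
        for r in ("mono", "poly"):
            for f in ("unt", "trt"):
                for _ in range(n_per_cell):
                    name = f"I{k}"
                    od = rng.uniform(0.05, 0.5, n_sub)
                    if r == "mono":
                        od[list(shift_subs)] += shift
                    profiles.append(make_profile(name, od))
                    iso[name] = (r, f, f"{r}.{f}.plant")
                    k += 1
        return profiles, make_design(iso)

    def test_identical_groups_give_no_discoveries(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.05, 0.5, 10)
        iso = {}
        profiles = []
        for k, (r, f) in enumerate(
            [(r, f) for r in ("mono", "poly") for f in ("unt", "trt")] * 3
        ):
            name = f"I{k}"
            profiles.append(make_profile(name, base))
            iso[name] = (r, f, f"{r}.{f}.plant")
        table = stats.per_substrate_tests(profiles, make_design(iso))
        assert not table.discovery.any()

    def test_large_injected_effects_are_the_discoveries(self):
        rng = np.random.default_rng(0)
        profiles, design = self._profiles_and_design(
            rng, n_per_cell=6, n_sub=12, shift_subs=(1, 4, 7), shift=5.0
        )
        table = stats.per_substrate_tests(profiles, design)
        hits = table[(table.family == "richness") & table.discovery]
        assert set(hits.substrate) == {"s1", "s4", "s7"}
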