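"""Statistical machinery: Mann-Whitney, two-way ANOVA, Holm-Sidak, summaries."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from arterymech.stats import (
    holm_sidak,
    mann_whitney,
    significance_stars,
    summarize_group_curves,
    two_way_anova_curves,
)


class TestMannWhitney:
    def test_fully_separated_triples(self):
        """{1,2,3} vs {4,5,6}: U=0 and exact two-tailed p = 2/20 = 0.1."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration_without_ties(self, rng):
        """Independent cross-check: for tie-free samples up to 8+8 the
        enumeration agrees with scipy's exact distribution."""
        for _ in range(20):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(2, 9))
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            mine = mann_whitney(x, y, mode="exact")
            _, p_scipy = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            )
            assert mine.p == pytest.approx(p_scipy, abs=1e-12)

    def test_exact_matches_bruteforce_with_ties(self):
        """With ties, enumeration over mid-rank splits is the reference."""
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        res = mann_whitney(x, y, mode="exact")
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        m = len(x)
        mu = m * len(y) / 2.0
        u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
        hits = sum(
            1
            for idx in combinations(range(len(pooled)), m)
            if abs(ranks[list(idx)].sum() - m * (m + 1) / 2.0 - mu)
            >= abs(u_obs - mu) - 1e-12
        )
        assert res.p == pytest.approx(hits / comb(len(pooled), m), abs=1e-12)

    def test_approx_close_to_exact_at_8_vs_8(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.8
        pe = mann_whitney(x, y, mode="exact").p
        pa = mann_whitney(x, y, mode="approx").p
        assert abs(pe - pa) < 0.01

    def test_auto_switches_to_approx_for_large_samples(self, rng):
        res = mann_whitney(rng.normal(size=12), rng.normal(size=12))
        assert "approximation" in res.note

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _balanced_anova_oracle(df):
    """Classic balanced two-way ANOVA from cell/marginal means."""
    g_levels = sorted(df["group"].unique())
    x_levels = sorted(df["x"].unique())
    a, b = len(g_levels), len(x_levels)
    r = len(df) // (a * b)
    grand = df["y"].mean()
    cell = df.groupby(["group", "x"])["y"].mean()
    mg = df.groupby("group")["y"].mean()
    mx = df.groupby("x")["y"].mean()
    ss_a = b * r * sum((mg[g] - grand) ** 2 for g in g_levels)
    ss_b = a * r * sum((mx[x] - grand) ** 2 for x in x_levels)
    ss_ab = r * sum(
        (cell[(g, x)] - mg[g] - mx[x] + grand) ** 2
        for g in g_levels
        for x in x_levels
    )
    ss_e = sum(
        (row["y"] - cell[(row["group"], row["x"])]) ** 2 for _, row in df.iterrows()
    )
    df_e = a * b * (r - 1)
    out = {}
    for name, ss, d in (
        ("group", ss_a, a - 1),
        ("point", ss_b, b - 1),
        ("interaction", ss_ab, (a - 1) * (b - 1)),
    ):
        f = (ss / d) / (ss_e / df_e)
        out[name] = (f, float(sps.f.sf(f, d, df_e)))
    return out


class TestTwoWayAnova:
    def _random_balanced(self, rng, a=2, b=5, r=4, effect=0.0):
        rows = []
        for gi in range(a):
            for xi in range(b):
                for _ in range(r):
                    rows.append(
                        dict(group=f"g{gi}", x=xi, y=rng.normal() + effect * gi)
                    )
        return pd.DataFrame(rows)

    def test_matches_projection_oracle_to_1e8(self, rng):
        """F and p agree with an independent cell-means least-squares
        computation to 1e-8 on random balanced layouts."""
        for _ in range(5):
            df = self._random_balanced(rng, effect=0.4)
            res = two_way_anova_curves(df)
            oracle = _balanced_anova_oracle(df)
            for name, (f, p) in oracle.items():
                assert res.effects[name].f_stat == pytest.approx(f, abs=1e-8, rel=1e-8)
                assert res.effects[name].p == pytest.approx(p, abs=1e-8, rel=1e-8)

    def test_additive_layout_has_zero_interaction(self):
        """Purely additive cell structure: interaction sum of squares is 0."""
        rows = []
        noise = [0.3, -0.1, -0.2]
        for gi, ga in enumerate([0.0, 1.5]):
            for xi, xb in enumerate([0.0, 0.7]):
                for e in noise:
                    rows.append(dict(group=f"g{gi}", x=xi, y=ga + xb + e))
        res = two_way_anova_curves(pd.DataFrame(rows))
        assert res.effects["interaction"].f_stat == pytest.approx(0.0, abs=1e-10)

    def test_invariance_to_shift_and_scale(self, rng):
        df = self._random_balanced(rng, effect=0.5)
        base = two_way_anova_curves(df)
        shifted = df.assign(y=df["y"] + 100.0)
        scaled = df.assign(y=df["y"] * 7.0)
        for other in (shifted, scaled):
            res = two_way_anova_curves(other)
            for name in ("group", "point", "interaction"):
                assert res.effects[name].f_stat == pytest.approx(
                    base.effects[name].f_stat, rel=1e-9
                )

    def test_empty_cell_is_named(self, rng):
        df = self._random_balanced(rng)
        df = df[~((df["group"] == "g1") & (df["x"] == 3))]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova_curves(df)

    def test_single_level_factor_rejected(self, rng):
        df = self._random_balanced(rng)
        with pytest.raises(ValueError):
            two_way_anova_curves(df[df["group"] == "g0"])


class TestHolmSidak:
    def test_hand_evaluated_step_down(self):
        adj = holm_sidak([0.01, 0.04, 0.30])
        expected = [1 - 0.99**3, max(1 - 0.99**3, 1 - 0.96**2), 0.30]
        np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_single_p_unchanged(self):
        assert holm_sidak([0.2])[0] == pytest.approx(0.2)

    def test_zeros_stay_zero(self):
        np.testing.assert_array_equal(holm_sidak([0.0, 0.0, 0.0]), 0.0)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0.0, 1.0, size=12)
        assert np.all(holm_sidak(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


class TestStars:
    @pytest.mark.parametrize(
        "p,stars", [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***")]
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars


class TestSummaries:
    def _curves(self, rng, n=6, noise=1.0):
        rows = []
        xs = np.linspace(0, 140, 15)
        for s in range(n):
            for x in xs:
                rows.append(
                    dict(group="g", sample=f"s{s}", x=x, y=0.1 * x + rng.normal(0, noise))
                )
        return pd.DataFrame(rows)

    def test_se_is_sd_over_sqrt_n(self, rng):
        df = self._curves(rng)
        sd_mode = summarize_group_curves(df, dispersion="sd")
        se_mode = summarize_group_curves(df, dispersion="se")
        np.testing.assert_allclose(
            se_mode["dispersion"], sd_mode["dispersion"] / np.sqrt(sd_mode["n"])
        )

    def test_single_sample_group_flagged(self):
        df = pd.DataFrame([dict(group="g", x=0.0, y=1.0), dict(group="g", x=1.0, y=2.0)])
        out = summarize_group_curves(df)
        assert out["n_lt_2"].all()
        np.testing.assert_allclose(out["mean"], [1.0, 2.0])
        assert out["sd"].isna().all()

    def test_pointwise_sd_consistent_with_known_noise(self, rng):
        """With n=6 samples and noise SD s, the mean pointwise variance is
        an unbiased estimate of s^2 (within chi-square Monte-Carlo error)."""
        s = 2.5
        dfs = [self._curves(rng, n=6, noise=s) for _ in range(30)]
        variances = np.concatenate(
            [summarize_group_curves(d)["sd"].to_numpy() ** 2 for d in dfs]
        )
        k = variances.size  # each with 5 df
        se = s**2 * np.sqrt(2.0 / (5 * k))
        assert abs(variances.mean() - s**2) < 4 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group_curves(pd.DataFrame(columns=["group", "x", "y"]))
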