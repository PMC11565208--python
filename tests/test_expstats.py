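"""Statistical layer: ANOVA decompositions, Tukey HSD, lsmeans, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c4wue.expstats import (
    average_subsamples,
    lsmeans_se,
    one_way_anova,
    per_day_posthoc,
    planned_contrast,
    repeated_measures_anova,
    tukey_hsd,
    two_way_anova,
)


def _two_groups(a, b):
    return pd.DataFrame({"y": list(a) + list(b), "g": ["a"] * len(a) + ["b"] * len(b)})


class TestAverageSubsamples:
    def test_collapses_to_one_row_per_plant(self):
        df = pd.DataFrame({
            "plant_id": ["p1"] * 4 + ["p2"] * 4,
            "genotype": ["WT"] * 8,
            "density": [46.0, 50.0, 53.0, 51.0, 60.0, 62.0, 58.0, 64.0],
        })
        out = average_subsamples(df, ["plant_id", "genotype"], "density")
        assert len(out) == 2
        assert out.loc[out["plant_id"] == "p1", "density"].iloc[0] == pytest.approx(50.0)

    def test_single_subsample_unchanged(self):
        df = pd.DataFrame({"plant_id": ["p1"], "genotype": ["WT"], "density": [42.0]})
        out = average_subsamples(df, ["plant_id", "genotype"], "density")
        assert out["density"].iloc[0] == 42.0

    def test_mixed_subsample_counts_plain_means(self):
        df = pd.DataFrame({"plant_id": ["p1", "p1", "p2"], "y": [1.0, 3.0, 5.0]})
        out = average_subsamples(df, ["plant_id"], "y")
        assert list(out["y"]) == [2.0, 5.0]


class TestOneWay:
    def test_identical_groups(self):
        tab = one_way_anova(_two_groups([1, 2, 3], [1, 2, 3]), "y", "g")
        assert tab.loc["g", "F"] == 0.0
        assert tab.loc["g", "p"] == 1.0

    def test_hand_decomposition(self):
        tab = one_way_anova(_two_groups([1, 2, 3], [7, 8, 9]), "y", "g")
        assert tab.loc["g", "sum_sq"] == pytest.approx(54.0)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(4.0)
        assert tab.loc["g", "F"] == pytest.approx(54.0)
        assert (tab["df"] == [1, 4]).all()

    def test_p_matches_f_quadrature(self):
        """p for F=54, df=(1,4) equals numerical integration of the F density."""
        from scipy.integrate import quad

        tab = one_way_anova(_two_groups([1, 2, 3], [7, 8, 9]), "y", "g")
        p_quad, _ = quad(lambda x: stats.f.pdf(x, 1, 4), 54.0, np.inf)
        assert tab.loc["g", "p"] == pytest.approx(p_quad, abs=1e-6)

    def test_empty_level_rejected(self):
        df = _two_groups([1, 2, 3], [7, 8, 9])
        df["g"] = pd.Categorical(df["g"], categories=["a", "b", "c"])
        with pytest.raises(ValueError, match="0 observations"):
            one_way_anova(df, "y", "g")

    def test_permutation_oracle(self):
        """F-test p agrees with a permutation null within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        df = _two_groups(rng.normal(0.0, 1.0, 8), rng.normal(1.0, 1.0, 8))
        tab = one_way_anova(df, "y", "g")
        p_f, f_obs = tab.loc["g", "p"], tab.loc["g", "F"]
        y = df["y"].to_numpy()
        n1 = (df["g"] == "a").sum()
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(y)
            # direct two-group F: SSB/(SSW/(n-2)) computed from scratch
            m1, m2, grand = perm[:n1].mean(), perm[n1:].mean(), perm.mean()
            ssb = n1 * (m1 - grand) ** 2 + (len(perm) - n1) * (m2 - grand) ** 2
            ssw = ((perm[:n1] - m1) ** 2).sum() + ((perm[n1:] - m2) ** 2).sum()
            if ssb / (ssw / (len(perm) - 2)) >= f_obs:
                count += 1
        assert abs(count / n_perm - p_f) < 0.02


class TestTwoWay:
    @staticmethod
    def _balanced_2x2(delta, n=2, noise=None):
        rows = []
        rng = np.random.default_rng(0)
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                mu = delta if (a, b) == ("a2", "b2") else 0.0
                for _ in range(n):
                    y = mu + (rng.normal(0, 1) if noise else 0.0)
                    rows.append({"A": a, "B": b, "y": y})
        return pd.DataFrame(rows)

    def test_additive_means_zero_interaction(self):
        rows = []
        for a, ea in [("a1", 0.0), ("a2", 2.0)]:
            for b, eb in [("b1", 0.0), ("b2", 3.0)]:
                rows += [{"A": a, "B": b, "y": 10.0 + ea + eb}] * 2
        tab = two_way_anova(pd.DataFrame(rows), "y", "A", "B")
        assert tab.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_interaction_ss_hand_value(self):
        """Pattern {0,0;0,delta}: interaction SS = n*delta^2/4 at delta=4, n=2."""
        tab = two_way_anova(self._balanced_2x2(4.0, n=2), "y", "A", "B")
        # cell deviations +-1: SS_AB = sum n*(dev)^2 = 4 cells * 2 * 1 = 8
        assert tab.loc["A:B", "sum_sq"] == pytest.approx(8.0)
        assert tab.loc["A", "sum_sq"] == pytest.approx(8.0)
        assert tab.loc["B", "sum_sq"] == pytest.approx(8.0)

    def test_empty_cell_rejected(self):
        df = self._balanced_2x2(1.0)
        df = df[~((df["A"] == "a2") & (df["B"] == "b2"))]
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(df, "y", "A", "B")

    def test_balanced_type3_equals_classical_and_sums_to_total(self):
        df = self._balanced_2x2(2.0, n=3, noise=True)
        tab = two_way_anova(df, "y", "A", "B")
        # classical sequential decomposition computed by hand from cell means
        y = df["y"].to_numpy()
        grand = y.mean()
        sst = ((y - grand) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(sst)
        means_a = df.groupby("A")["y"].mean()
        ss_a_classical = sum(6 * (m - grand) ** 2 for m in means_a)
        assert tab.loc["A", "sum_sq"] == pytest.approx(ss_a_classical)


class TestRepeatedMeasures:
    @staticmethod
    def _trajectories(slope_by_group, n_subj=4, n_days=5, noise_sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, slope in slope_by_group.items():
            for s in range(n_subj):
                base = rng.normal(0.0, 0.3)
                for d in range(n_days):
                    rows.append({
                        "g": g, "s": f"{g}{s}", "d": d,
                        "y": base + slope * d + rng.normal(0.0, noise_sd),
                    })
        return pd.DataFrame(rows)

    def test_identical_trajectories_zero_f(self):
        rows = []
        for g in ("wt", "mut"):
            for s in range(3):
                for d in range(4):
                    rows.append({"g": g, "s": f"{g}{s}", "d": d, "y": float(d)})
        tab = repeated_measures_anova(pd.DataFrame(rows), "y", "g", "d", "s")
        assert tab.loc["g", "F"] == 0.0
        assert tab.loc["g:d", "F"] == 0.0

    def test_diverging_trajectories_detected(self):
        df = self._trajectories({"wt": 1.0, "mut": 0.3}, seed=3)
        tab = repeated_measures_anova(df, "y", "g", "d", "s")
        assert tab.loc["g:d", "p"] < 0.05

    def test_missing_day_rejected(self):
        df = self._trajectories({"wt": 1.0, "mut": 0.3})
        df = df.drop(df[(df["s"] == "wt0") & (df["d"] == 2)].index)
        with pytest.raises(ValueError, match="incomplete"):
            repeated_measures_anova(df, "y", "g", "d", "s")

    def test_ss_decomposition_sums_to_total(self):
        df = self._trajectories({"wt": 1.0, "mut": 0.3}, seed=9)
        tab = repeated_measures_anova(df, "y", "g", "d", "s")
        y = df["y"].to_numpy()
        assert tab["sum_sq"].sum() == pytest.approx(((y - y.mean()) ** 2).sum())


class TestTukey:
    def test_two_group_identity_with_t_test(self):
        """q = sqrt(2)*|t| and the adjusted p equals the pooled t-test p."""
        rng = np.random.default_rng(2)
        df = _two_groups(rng.normal(0, 1, 6), rng.normal(1.2, 1, 6))
        tk = tukey_hsd(df, "y", "g")
        t = stats.ttest_ind(df.loc[df["g"] == "a", "y"], df.loc[df["g"] == "b", "y"])
        assert tk.pairwise["q"].iloc[0] == pytest.approx(np.sqrt(2) * abs(t.statistic), rel=1e-9)
        assert tk.pairwise["p_adj"].iloc[0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0] * 3, "g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3})
        tk = tukey_hsd(df, "y", "g")
        assert np.allclose(tk.pairwise["p_adj"], 1.0)
        assert len(set(tk.letters.values())) == 1

    def test_far_shifted_group_distinct_letter(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": np.r_[rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(10, 1, 8)],
            "g": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
        })
        tk = tukey_hsd(df, "y", "g")
        assert set(tk.letters["c"]).isdisjoint(set(tk.letters["a"]) | set(tk.letters["b"]))

    def test_letters_consistent_with_pairwise_flags(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({
            "y": np.r_[rng.normal(0, 1, 6), rng.normal(1.5, 1, 6), rng.normal(3, 1, 6), rng.normal(9, 1, 6)],
            "g": np.repeat(list("abcd"), 6),
        })
        tk = tukey_hsd(df, "y", "g")
        for r in tk.pairwise.itertuples():
            shared = set(tk.letters[r.group1]) & set(tk.letters[r.group2])
            assert bool(shared) == (not r.significant)

    def test_fewer_than_two_groups_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            tukey_hsd(df, "y", "g")


class TestLsMeans:
    def test_balanced_one_way_equals_group_means(self):
        df = _two_groups([1.0, 2.0, 3.0], [7.0, 8.0, 9.0])
        out = lsmeans_se(df, "y", ["g"]).set_index("g")
        assert out.loc["a", "lsmean"] == pytest.approx(2.0)
        assert out.loc["b", "lsmean"] == pytest.approx(8.0)
        # SE = sqrt(MSW/n) with MSW = 1, n = 3
        assert out.loc["a", "se"] == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_unbalanced_two_way_unweighted_cell_means(self):
        rows = (
            [{"A": "a1", "B": "b1", "y": v} for v in (1.0, 3.0)]
            + [{"A": "a1", "B": "b2", "y": v} for v in (10.0, 12.0, 14.0, 16.0)]
            + [{"A": "a2", "B": "b1", "y": v} for v in (0.0, 2.0)]
            + [{"A": "a2", "B": "b2", "y": v} for v in (4.0, 6.0)]
        )
        df = pd.DataFrame(rows)
        out = lsmeans_se(df, "y", ["A", "B"], term="A").set_index("A")
        # lsmean(a1) = (mean(2) + mean(13)) / 2 = 7.5, not the raw marginal 9.33
        assert out.loc["a1", "lsmean"] == pytest.approx((2.0 + 13.0) / 2.0)
        raw_marginal = df.loc[df["A"] == "a1", "y"].mean()
        assert out.loc["a1", "lsmean"] != pytest.approx(raw_marginal)

    def test_empty_cell_inestimable(self):
        df = pd.DataFrame({"A": ["a1", "a1", "a2"], "B": ["b1", "b2", "b1"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="inestimable"):
            lsmeans_se(df, "y", ["A", "B"])


class TestPlannedContrast:
    def test_two_group_reproduces_pooled_t(self):
        rng = np.random.default_rng(8)
        df = _two_groups(rng.normal(0, 1, 7), rng.normal(1, 1, 7))
        res = planned_contrast(df, "y", "g", {"a": 1.0, "b": -1.0})
        t = stats.ttest_ind(df.loc[df["g"] == "a", "y"], df.loc[df["g"] == "b", "y"])
        assert res["t"] == pytest.approx(t.statistic, rel=1e-9)
        assert res["p"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_wt_vs_mean_of_lines(self):
        df = pd.DataFrame({
            "y": [10.0, 12.0, 6.0, 8.0, 4.0, 6.0],
            "g": ["WT", "WT", "12b", "12b", "13a", "13a"],
        })
        res = planned_contrast(df, "y", "g", {"WT": 1.0, "12b": -0.5, "13a": -0.5})
        assert res["estimate"] == pytest.approx(11.0 - 0.5 * (7.0 + 5.0))

    def test_nonzero_weights_rejected(self):
        df = _two_groups([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="sum to zero"):
            planned_contrast(df, "y", "g", {"a": 1.0, "b": 1.0})


class TestPerDayPosthoc:
    def test_flags_days_with_separated_groups(self):
        rng = np.random.default_rng(21)
        rows = []
        for day in (1, 2, 3):
            sep = 0.0 if day == 1 else 8.0
            for g, mu in [("wt", 0.0), ("mut", sep)]:
                for _ in range(5):
                    rows.append({"day": day, "g": g, "y": rng.normal(mu, 1.0)})
        out = per_day_posthoc(pd.DataFrame(rows), "y", "g")
        flags = out.groupby("day")["significant"].any()
        assert not flags.loc[1]
        assert flags.loc[2] and flags.loc[3]
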