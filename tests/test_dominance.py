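import numpy as np
import pandas as pd
import pytest

from phenoprofiles.dominance import (IntersectionTable, dominant_background,
                                     hard_assign, intersections,
                                     typical_profiles)
from phenoprofiles.fcm import FuzzyCMeans


def make_table(counts_dict):
    """counts_dict: {cluster: {background: count}}"""
    return IntersectionTable(pd.DataFrame(counts_dict).T.fillna(0))


class TestHardAssign:
    def _fit(self):
        rng = np.random.default_rng(0)
        data = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        return FuzzyCMeans(data, 2).fit(seed=0)

    def test_max_membership_and_totality(self):
        res = self._fit()
        ids = [f"P{i}" for i in range(40)]
        assignments, ties = hard_assign(res, ids)
        assert set(assignments) == set(ids)
        labels = np.array([assignments[i] for i in ids])
        assert len(np.unique(labels[:20])) == 1
        assert labels[0] != labels[-1]

    def test_tie_goes_to_lowest_index_with_flag(self):
        res = self._fit()
        res.memberships = np.array([[0.5, 0.5], [0.9, 0.1]])
        assignments, ties = hard_assign(res, ["a", "b"])
        assert assignments["a"] == 0 and ties["a"]
        assert assignments["b"] == 0 and not ties["b"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hard_assign(self._fit(), ["only-one"])


class TestIntersections:
    def test_counts_proportions_and_conservation(self):
        assignments = {}
        backgrounds = {}
        spec = {"A": {"TST": 138, "TEM": 30, "mixed": 60},
                "B": {"TST": 34, "TEM": 80, "mixed": 40}}
        k = 0
        for cl, bgs in spec.items():
            for bg, n in bgs.items():
                for _ in range(n):
                    assignments[f"P{k}"] = cl
                    backgrounds[f"P{k}"] = bg
                    k += 1
        table = intersections(assignments, backgrounds)
        assert int(table.counts.to_numpy().sum()) == k
        assert table.ng_total["TST"] == 172
        # the printed worked ratio: 138 of 172 TST profiles in cluster A
        assert table.total_proportion.loc["A", "TST"] == pytest.approx(0.802, abs=5e-4)

    def test_single_cluster_total_proportion_one(self):
        assignments = {f"P{i}": 0 for i in range(9)}
        backgrounds = {f"P{i}": ["x", "y", "z"][i % 3] for i in range(9)}
        table = intersections(assignments, backgrounds)
        assert np.allclose(table.total_proportion.loc[0], 1.0)

    def test_empty_cluster_proportions_missing(self):
        table = make_table({"A": {"x": 5, "y": 5}, "B": {"x": 0, "y": 0}})
        assert table.nc_total["B"] == 0
        assert table.cluster_proportion.loc["B"].isna().all()

    def test_cluster_proportions_sum_to_one(self):
        table = make_table({"A": {"x": 7, "y": 3}, "B": {"x": 2, "y": 8}})
        assert np.allclose(table.cluster_proportion.sum(axis=1), 1.0)

    def test_mismatched_plot_sets_raise(self):
        with pytest.raises(ValueError):
            intersections({"a": 0}, {"b": "x"})


class TestDominantBackground:
    @pytest.mark.parametrize("cp,tp,expect", [
        (0.605, 0.802, True),     # clear dominance
        (0.485, 0.581, False),    # fails the total-proportion bound
        (0.433, 0.802, True),     # cluster share just above one third
    ])
    def test_threshold_combinations(self, cp, tp, expect):
        ng_total = 1000
        in_cluster = int(round(tp * ng_total))
        nc_total = int(round(in_cluster / cp))
        table = make_table({
            "A": {"target": in_cluster, "other": nc_total - in_cluster},
            "B": {"target": ng_total - in_cluster, "other": 10_000},
        })
        out = dominant_background(table)
        assert (out["A"]["dominant"] == "target") is expect

    def test_exact_boundary_qualifies(self):
        # ClusterProportion exactly 1/3 and TotalProportion exactly 2/3;
        # 'other' is spread out so it cannot qualify on total proportion
        table = make_table({"A": {"g": 40, "other": 80},
                            "B": {"g": 20, "other": 200}})
        out = dominant_background(table)
        assert table.cluster_proportion.loc["A", "g"] == pytest.approx(1 / 3)
        assert table.total_proportion.loc["A", "g"] == pytest.approx(2 / 3)
        assert out["A"]["dominant"] == "g"

    def test_dominance_monotone_in_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 60, size=(2, 3))
            table = IntersectionTable(pd.DataFrame(counts, index=["A", "B"],
                                                   columns=["x", "y", "z"]))
            before = dominant_background(table)
            for bg in ["x", "y", "z"]:
                if before["A"]["dominant"] == bg:
                    bumped = counts.copy()
                    bumped[0, ["x", "y", "z"].index(bg)] += 5
                    t2 = IntersectionTable(pd.DataFrame(
                        bumped, index=["A", "B"], columns=["x", "y", "z"]))
                    assert dominant_background(t2)["A"]["dominant"] == bg

    def test_multiple_qualifiers_reported(self):
        table = make_table({"A": {"x": 50, "y": 45}, "B": {"x": 10, "y": 10}})
        out = dominant_background(table)
        assert set(out["A"]["qualifiers"]) == {"x", "y"}
        assert out["A"]["dominant"] == "x"


class TestTypicalProfiles:
    def test_one_polyline_per_cluster(self):
        rng = np.random.default_rng(1)
        data = np.vstack([rng.normal(0, 0.2, (15, 5)), rng.normal(4, 0.2, (15, 5))])
        res = FuzzyCMeans(data, 2).fit(seed=0)
        out = typical_profiles(res, {}, days=(24, 45, 57, 74, 81))
        assert len(out) == 2
        assert all(len(t.centroid) == 5 for t in out)

    def test_identical_profiles_centroid_equals_profile(self):
        base = np.array([10.0, 60.0, 150.0, 230.0, 255.0])
        data = np.tile(base, (12, 1))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = FuzzyCMeans(data, 2).fit(seed=0, n_restarts=1)
        out = typical_profiles(res, {}, days=(24, 45, 57, 74, 81))
        for t in out:
            assert t.centroid == pytest.approx(base, rel=1e-9)

    def test_dominant_annotation(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (10, 4))
        res = FuzzyCMeans(data, 2).fit(seed=0)
        dom = {0: {"dominant": "TST"}, 1: {"dominant": None}}
        out = typical_profiles(res, dom, days=(24, 45, 57, 74))
        assert out[0].dominant_background == "TST"
        assert out[1].dominant_background is None

    def test_day_length_mismatch_raises(self):
        rng = np.random.default_rng(3)
        res = FuzzyCMeans(rng.normal(size=(10, 4)), 2).fit(seed=0)
        with pytest.raises(ValueError):
            typical_profiles(res, {}, days=(24, 45))


class TestPlotting:
    def test_plot_helpers_return_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        from phenoprofiles.plotting import plot_intersections, plot_typical_profiles

        rng = np.random.default_rng(4)
        res = FuzzyCMeans(rng.normal(size=(12, 5)), 2).fit(seed=0)
        profs = typical_profiles(res, {0: {"dominant": "TST"}},
                                 days=(24, 45, 57, 74, 81))
        ax = plot_typical_profiles(profs)
        assert len(ax.lines) == 2
        table = make_table({"A": {"x": 3, "y": 4}, "B": {"x": 1, "y": 2}})
        ax2 = plot_intersections(table)
        assert len(ax2.patches) == 4
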