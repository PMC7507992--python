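"""Median dichotomization, KM/log-rank, Cox, BH, enrichment, centrality."""

import itertools

import numpy as np
import pandas as pd
import pytest

import triprot as tp
from triprot.errors import ConfigurationError, DegenerateDataError


class TestDichotomize:
    def test_even_split(self):
        out = tp.dichotomize_at_median([1.0, 2.0, 3.0, 4.0])
        assert list(out) == ["low", "low", "high", "high"]

    def test_median_element_goes_low(self):
        out = tp.dichotomize_at_median([1.0, 2.0, 3.0])
        assert list(out) == ["low", "low", "high"]

    def test_high_count_at_most_half(self):
        rng = np.random.default_rng(0)
        for n in (5, 10, 17, 40):
            v = rng.normal(size=n)
            out = tp.dichotomize_at_median(v)
            assert (out == "high").sum() <= n // 2

    def test_constant_raises(self):
        with pytest.raises(DegenerateDataError):
            tp.dichotomize_at_median([2.0, 2.0, 2.0])


class TestKaplanMeier:
    def test_single_group_rejected(self):
        with pytest.raises(ConfigurationError):
            tp.kaplan_meier_logrank([1, 2], [1, 1], ["a", "a"])

    def test_identical_groups_logrank_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a"] * 3 + ["b"] * 3
        res = tp.kaplan_meier_logrank(t, e, g)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-9)

    def test_product_limit_by_hand(self):
        res = tp.kaplan_meier_logrank(
            [1.0, 2.0, 3.0, 1.0], [1, 1, 1, 1], ["a", "a", "a", "b"]
        )
        surv = res.curves["a"]
        steps = surv.loc[surv["time"] > 0, "survival"].to_numpy()
        np.testing.assert_allclose(steps, [2 / 3, 1 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, size=50)
        res = tp.kaplan_meier_logrank(
            np.concatenate([t, t + 1]), np.ones(100, int),
            ["a"] * 50 + ["b"] * 50,
        )
        curve = res.curves["a"]
        times = curve["time"].to_numpy()[1:]
        surv = curve["survival"].to_numpy()[1:]
        emp = [(t > x).mean() for x in times]
        np.testing.assert_allclose(surv, emp, atol=1e-12)

    def test_separated_groups_detected(self):
        """True hazard ratio 3 at n=200/group: log-rank p < 0.01."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            ta = rng.exponential(1.0, size=200)
            tb = rng.exponential(3.0, size=200)
            res = tp.kaplan_meier_logrank(
                np.concatenate([ta, tb]), np.ones(400, int),
                ["a"] * 200 + ["b"] * 200,
            )
            hits += res.logrank_p < 0.01
        assert hits >= 9


class TestCox:
    def test_duplicating_subjects_leaves_hr_unchanged(self):
        # exact under Breslow ties; Efron treats the introduced ties
        # differently so it is only approximately invariant
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, size=80).astype(float)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.8 * x)))
        e = np.ones(80, int)
        cov = pd.DataFrame({"x": x})
        hr1 = tp.cox_regression(t, e, cov, ties="breslow").summary.loc["x", "hr"]
        cov2 = pd.concat([cov, cov], ignore_index=True)
        hr2 = tp.cox_regression(
            np.concatenate([t, t]), np.concatenate([e, e]), cov2,
            ties="breslow",
        ).summary.loc["x", "hr"]
        assert hr2 == pytest.approx(hr1, rel=1e-6)
        hr_efron = tp.cox_regression(
            np.concatenate([t, t]), np.concatenate([e, e]), cov2
        ).summary.loc["x", "hr"]
        assert hr_efron == pytest.approx(hr1, rel=0.05)

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        t = rng.exponential(1.0, size=100)
        e = rng.integers(0, 2, size=100)
        e[:10] = 1
        cov = pd.DataFrame({"x": x})
        c1 = tp.cox_regression(t, e, cov).summary.loc["x", "coef"]
        c2 = tp.cox_regression(t * 365.25, e, cov).summary.loc["x", "coef"]
        assert c2 == pytest.approx(c1, rel=1e-6)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=120).astype(float)
        t = rng.exponential(1.0 / (0.3 * np.exp(0.7 * x)))
        e = np.ones(120, int)
        hr = tp.cox_regression(t, e, pd.DataFrame({"x": x})).summary.loc["x", "hr"]
        hr_swapped = tp.cox_regression(
            t, e, pd.DataFrame({"x": 1 - x})
        ).summary.loc["x", "hr"]
        assert hr_swapped == pytest.approx(1.0 / hr, rel=1e-6)

    def test_breslow_close_to_efron_without_ties(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(150, int)
        cov = pd.DataFrame({"x": x})
        efron = tp.cox_regression(t, e, cov, ties="efron").summary.loc["x", "coef"]
        breslow = tp.cox_regression(t, e, cov, ties="breslow").summary.loc["x", "coef"]
        assert breslow == pytest.approx(efron, abs=1e-6)

    def test_too_few_events(self):
        with pytest.raises(DegenerateDataError):
            tp.cox_regression(
                [1.0, 2.0, 3.0], [1, 0, 0],
                pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]}),
            )

    def test_multivariate_reports_global_p(self, small_cohort):
        _, cohort, clinical, _ = small_cohort
        df = clinical.data
        cov = df[["grade", "tumor_size", "age"]].astype(float)
        res = tp.cox_regression(df["rfs_years"], df["relapse"], cov)
        assert res.model_type == "cox_multivariate"
        assert 0.0 <= res.global_p <= 1.0


class TestBh:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.02, 0.02, 0.02], [0.02, 0.02, 0.02]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ],
    )
    def test_step_up(self, p, expected):
        assert tp.bh_correct(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            tp.bh_correct([0.5, 1.5])


class TestEnrichment:
    def _annotations(self):
        universe = {f"P{i}" for i in range(1000)}
        sets = {
            "full": {f"P{i}" for i in range(50)},
            "disjoint": {f"P{i}" for i in range(500, 550)},
        }
        return tp.AnnotationSets(sets, universe)

    def test_hypergeometric_tail_closed_form(self):
        from scipy import stats

        ann = self._annotations()
        fg = {f"P{i}" for i in range(50)}
        res = tp.fisher_enrichment(fg, ann)
        expected = stats.hypergeom.sf(49, 1000, 50, 50)
        assert res.loc["full", "p"] == pytest.approx(expected, rel=1e-12)
        # and identical to the one-sided Fisher exact p
        table = [[50, 0], [0, 950]]
        assert res.loc["full", "p"] == pytest.approx(
            stats.fisher_exact(table, alternative="greater")[1], rel=1e-9
        )

    def test_disjoint_term(self):
        ann = self._annotations()
        res = tp.fisher_enrichment({f"P{i}" for i in range(50)}, ann)
        assert res.loc["disjoint", "odds_ratio"] == 0.0
        assert res.loc["disjoint", "p"] == pytest.approx(1.0)

    def test_null_pass_rate_before_correction(self):
        rng = np.random.default_rng(6)
        universe = {f"P{i}" for i in range(2000)}
        sets = {
            f"T{j}": set(rng.choice(sorted(universe), size=60, replace=False))
            for j in range(100)
        }
        ann = tp.AnnotationSets(sets, universe)
        fg = set(rng.choice(sorted(universe), size=200, replace=False))
        res = tp.fisher_enrichment(fg, ann)
        assert (res["p"] < 0.05).mean() <= 0.12

    def test_empty_foreground_raises(self):
        with pytest.raises(DegenerateDataError):
            tp.fisher_enrichment(set(), self._annotations())

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\tP1\tP2\nT2\tdesc\tP3\n")
        ann = tp.read_gmt(path)
        assert ann.sets == {"T1": {"P1", "P2"}, "T2": {"P3"}}


def naive_betweenness(nodes, edge_set):
    """Exhaustive path-enumeration betweenness (independent of the package)."""
    adj = {v: set() for v in nodes}
    for a, b in edge_set:
        adj[a].add(b)
        adj[b].add(a)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all simple paths s -> t by DFS
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for p in sps:
            for v in p[1:-1]:
                score[v] += 1.0 / len(sps)
    return score


class TestBetweenness:
    def test_path_graph(self):
        edges = pd.DataFrame({"node_a": ["a", "b"], "node_b": ["b", "c"]})
        res = tp.betweenness_centrality(edges)
        assert res.loc["b", "betweenness"] == pytest.approx(1.0)
        assert res.loc["a", "betweenness"] == 0.0

    def test_star_graph(self):
        edges = pd.DataFrame(
            {"node_a": ["c"] * 4, "node_b": ["l1", "l2", "l3", "l4"]}
        )
        res = tp.betweenness_centrality(edges)
        assert res.loc["c", "betweenness"] == pytest.approx(6.0)  # C(4,2) pairs
        assert (res.drop("c")["betweenness"] == 0).all()

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for n in (5, 6, 7):
            for _ in range(20):
                nodes = [f"v{i}" for i in range(n)]
                edge_set = [
                    (a, b)
                    for a, b in itertools.combinations(nodes, 2)
                    if rng.random() < 0.4
                ]
                if not edge_set:
                    continue
                edges = pd.DataFrame(edge_set, columns=["node_a", "node_b"])
                res = tp.betweenness_centrality(edges)
                oracle = naive_betweenness(nodes, edge_set)
                for v in res.index:
                    assert res.loc[v, "betweenness"] == pytest.approx(
                        oracle[v], abs=1e-9
                    )

    def test_top_decile_flags(self):
        edges = tp.simulate_network(60, 0.1, seed=8)
        res = tp.betweenness_centrality(edges, top_fraction=0.1)
        assert res["top"].sum() >= 1
        assert res.loc[res["top"], "betweenness"].min() >= \
            res.loc[~res["top"], "betweenness"].max()
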