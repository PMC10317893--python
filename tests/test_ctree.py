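"""Conditional inference tree: permutation oracle, cutpoint search, growth."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tgtree as tt
from tgtree.ctree import FitParams, find_level_split


def exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force two-sided permutation p-value of the linear statistic.

    Uses the mid-p convention (ties with the observed statistic count
    one half), the discrete analogue comparable with a continuous
    reference distribution.
    """
    n, k = len(y), int(y.sum())
    mu = x.sum() * y.mean()
    obs = abs(float(x @ y) - mu)
    above = ties = total = 0
    for pos in itertools.combinations(range(n), k):
        total += 1
        val = abs(float(x[list(pos)].sum()) - mu)
        if val > obs + 1e-12:
            above += 1
        elif val >= obs - 1e-12:
            ties += 1
    return (above + 0.5 * ties) / total


class TestAssociationTest:
    def test_matches_exact_permutation_oracle(self):
        x = np.arange(1.0, 7.0)
        y = np.array([0, 0, 0, 1, 1, 1.0])
        res = tt.association_test(x, y)
        assert abs(res.p_value - exact_permutation_p(x, y)) < 0.05

    def test_oracle_agreement_on_random_small_instances(self):
        """Asymptotic p within 0.05 of full enumeration at exactly
        enumerable sizes (n = 12..16, at least 3 records per class)."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(12, 17))
            x = rng.normal(size=n)
            y = np.zeros(n)
            y[: int(rng.integers(3, n - 2))] = 1.0
            rng.shuffle(y)
            res = tt.association_test(x, y)
            assert abs(res.p_value - exact_permutation_p(x, y)) < 0.05

    def test_constant_x_gives_p_one(self):
        res = tt.association_test(np.ones(10), np.arange(10) % 2)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_pure_node_gives_p_one(self):
        res = tt.association_test(np.arange(10.0), np.zeros(10))
        assert res.p_value == 1.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tt.association_test(np.arange(4.0), np.array([0, 1, 0, 1.0]),
                                np.array([1.0, -1.0, 1.0, 1.0]))

    def test_nominal_quadratic_form_detects_level_effect(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, 300)
        y = (rng.random(300) < np.where(codes == 2, 0.8, 0.2)).astype(float)
        x = np.eye(3)[codes]
        res = tt.association_test(x, y)
        assert res.df == 2
        assert res.p_value < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-100, 100), b=st.floats(0.01, 100),
           seed=st.integers(0, 10 ** 6))
    def test_invariant_under_affine_transforms(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.4).astype(float)
        if y.min() == y.max():
            return
        base = tt.association_test(x, y)
        trans = tt.association_test(a + b * x, y)
        assert trans.statistic == pytest.approx(base.statistic, rel=1e-6, abs=1e-9)


class TestFindCutpoint:
    def test_perfect_separation(self):
        found = tt.find_cutpoint(np.array([1.0, 1, 2, 2]), np.array([0, 0, 1, 1.0]),
                                 params=FitParams(minsplit=2, minbucket=1))
        assert found[0] == 1.0

    def test_boundary_reported_as_largest_left_value(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        cut, _ = tt.find_cutpoint(x, y, params=FitParams(minsplit=4, minbucket=2))
        assert cut == 4.0

    def test_matches_brute_force_on_random_instances(self):
        """Exhaustive scan equals brute-force maximization over admissible cuts."""
        rng = np.random.default_rng(2)
        params = FitParams(minsplit=6, minbucket=3)
        for _ in range(30):
            n = int(rng.integers(12, 40))
            x = np.round(rng.normal(size=n), 1)  # force ties
            y = (rng.random(n) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            found = tt.find_cutpoint(x, y, params=params)
            # oracle: loop over every unique value
            W, ybar = n, y.mean()
            V = ((y - ybar) ** 2).mean()
            best = None
            for xi in np.unique(x)[:-1]:
                wa = float((x <= xi).sum())
                if wa < 3 or n - wa < 3:
                    continue
                ta = float(y[x <= xi].sum())
                z = abs(ta - wa * ybar) / np.sqrt(V * wa * (n - wa) / (n - 1))
                if best is None or z > best[1] + 1e-12:
                    best = (xi, z)
            assert (found is None) == (best is None)
            if found is not None:
                assert found[0] == best[0]
                assert found[1] == pytest.approx(best[1])

    def test_jump_recovery_near_planted_cutoff(self):
        """Planted jump at 35 is recovered within +-15% in >= 90% of seeds.

        The maximizing cut lands at an observed value on either side of
        the jump; the window matches the recovery tolerance used for the
        node-threshold aggregation downstream.
        """
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 70, 1000)
            y = (rng.random(1000) < np.where(x > 35, 0.563, 0.058)).astype(float)
            cut, _ = tt.find_cutpoint(x, y)
            hits += abs(cut - 35.0) <= 0.15 * 35.0
        assert hits >= 90

    def test_no_admissible_cut_returns_none(self):
        assert tt.find_cutpoint(np.ones(30), np.arange(30) % 2.0) is None
        x = np.array([1.0, 2, 3, 4])
        assert tt.find_cutpoint(x, np.array([0, 1, 0, 1.0]),
                                params=FitParams(minsplit=8, minbucket=4)) is None


class TestFindLevelSplit:
    def test_recovers_outlying_level(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 4, 400)
        y = (rng.random(400) < np.where(codes == 3, 0.9, 0.1)).astype(float)
        subset, _ = find_level_split(codes, ("a", "b", "c", "d"), y)
        assert set(subset) == {"a", "b", "c"}  # level 'd' goes right alone

    def test_enumerates_all_proper_partitions(self):
        # k = 3 levels -> 3 canonical partitions; best must beat the others
        codes = np.array([0] * 10 + [1] * 10 + [2] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10 + [0.0] * 10)
        subset, z = find_level_split(codes, ("a", "b", "c"), y)
        assert set(subset) == {"a", "c"}


class TestSelectSplitVariable:
    def test_bonferroni_arithmetic_single_and_many(self, planted_cohort):
        y = planted_cohort.endpoint.astype(float)
        df = planted_cohort.df
        preds = tt.default_predictors()
        raw = {}
        for p in preds:
            from tgtree.ctree import _encode, _indicator
            e = _encode(df, p)
            x = _indicator(e, len(p.levels)) if p.kind == "nominal" else e
            raw[p.name] = tt.association_test(x, y).p_value
        best = min(raw, key=raw.get)
        sel = tt.select_split_variable(df, y, preds)
        assert sel is not None
        name, p_adj = sel[0].name, sel[1]
        assert name == best
        assert p_adj == pytest.approx(min(1.0, 9 * raw[best]))
        # single-candidate selection applies no adjustment
        single = next(p for p in preds if p.name == best)
        sel1 = tt.select_split_variable(df, y, [single])
        assert sel1[1] == pytest.approx(raw[best])

    def test_stop_signal_when_nothing_significant(self):
        rng = np.random.default_rng(4)
        import pandas as pd

        df = pd.DataFrame({"noise": rng.normal(size=40)})
        y = (rng.random(40) < 0.5).astype(float)
        sel = tt.select_split_variable(df, y, [tt.Predictor("noise", "continuous")],
                                       FitParams(alpha=1e-6))
        assert sel is None

    def test_empty_predictor_list_rejected(self, planted_cohort):
        with pytest.raises(ValueError, match="empty predictor"):
            tt.select_split_variable(planted_cohort.df,
                                     planted_cohort.endpoint.astype(float), [])

    def test_signal_variable_wins_against_noise(self):
        """Tg selected in >= 95% of seeds when only Tg carries signal."""
        from conftest import make_signal_cohort

        wins = 0
        for seed in range(100):
            cohort = make_signal_cohort(np.random.default_rng(seed))
            sel = tt.select_split_variable(cohort.df, cohort.endpoint.astype(float),
                                           tt.default_predictors())
            wins += sel is not None and sel[0].name == "tg"
        assert wins >= 95


class TestGrowTree:
    def test_all_negative_outcome_gives_single_terminal(self, planted_cohort):
        df = planted_cohort.df.copy()
        df["ptwbs"] = "negative"
        tree = tt.grow_tree(tt.Cohort(df))
        assert tree.root.is_terminal
        assert tree.root.risk == 0.0

    def test_terminal_conservation(self, planted_cohort):
        tree = tt.grow_tree(planted_cohort)
        terms = tree.terminals()
        assert sum(t.n for t in terms) == len(planted_cohort)
        pooled = sum(t.n * t.risk for t in terms) / len(planted_cohort)
        assert pooled == pytest.approx(planted_cohort.event_rate, abs=1e-9)

    def test_type_one_error_under_null(self, planted_cohort):
        """With a permuted outcome the tree stays root-only in >= 90% of runs."""
        rng = np.random.default_rng(5)
        y = planted_cohort.endpoint
        splits = 0
        for _ in range(200):
            yperm = rng.permutation(y)
            tree = tt.grow_tree(planted_cohort.df, y=yperm)
            splits += not tree.root.is_terminal
        assert splits / 200 <= 0.05 + 0.03

    def test_minbucket_respected(self, planted_cohort):
        tree = tt.grow_tree(planted_cohort)
        assert min(t.n for t in tree.terminals()) >= tree.params.minbucket

    def test_max_depth_limits_growth(self, planted_cohort):
        tree = tt.grow_tree(planted_cohort, params=FitParams(max_depth=1))
        assert tree.depth <= 1

    def test_empty_cohort_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="empty"):
            tt.grow_tree(tiny_cohort.subset(np.array([], dtype=int)))

    def test_deterministic(self, planted_cohort):
        a = tt.grow_tree(planted_cohort).to_json()
        b = tt.grow_tree(planted_cohort).to_json()
        assert a == b


class TestPredict:
    def test_root_only_tree_maps_everything_to_root(self, planted_cohort):
        df = planted_cohort.df.copy()
        df["ptwbs"] = "negative"
        tree = tt.grow_tree(tt.Cohort(df))
        pred = tree.predict(planted_cohort)
        assert (pred["node_id"] == tree.root.node_id).all()

    def test_value_at_cutpoint_goes_left(self):
        model = tt.published_model()
        nid_left, risk_left = tt.predict_node(model, {"n_stage": 0, "tg": 35.0})
        assert risk_left == 0.152
        nid_right, risk_right = tt.predict_node(model, {"n_stage": 0, "tg": 35.0001})
        assert risk_right == 0.563

    def test_routing_matches_predicate_chain(self, planted_cohort):
        """Vectorized routing equals brute-force predicate evaluation."""
        tree = tt.grow_tree(planted_cohort,
                            [p for p in tt.default_predictors()
                             if p.name in ("tg", "n_stage")])
        rng = np.random.default_rng(6)
        rows = planted_cohort.df.sample(100, random_state=7).reset_index(drop=True)
        pred = tree.predict(rows)

        def route(node, row):
            while not node.is_terminal:
                go_left = row[node.predictor] <= node.cutpoint
                node = node.left if go_left else node.right
            return node

        for i in range(len(rows)):
            term = route(tree.root, rows.iloc[i])
            assert pred.loc[i, "node_id"] == term.node_id

    def test_missing_predictor_value_is_error(self):
        model = tt.published_model()
        with pytest.raises((KeyError, ValueError)):
            tt.predict_node(model, {"tg": 5.0})


class TestSerialization:
    def test_json_round_trip(self, planted_cohort):
        tree = tt.grow_tree(planted_cohort)
        back = tt.FittedTree.from_json(tree.to_json())
        assert back.to_json() == tree.to_json()
        pred_a = tree.predict(planted_cohort)
        pred_b = back.predict(planted_cohort)
        assert (pred_a == pred_b).all().all()

    def test_file_round_trip(self, tmp_path, planted_cohort):
        tree = tt.grow_tree(planted_cohort)
        tree.to_json(tmp_path / "tree.json")
        back = tt.FittedTree.from_json(tmp_path / "tree.json")
        assert back.to_dict() == tree.to_dict()


class TestFitParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FitParams(alpha=0.0)
        with pytest.raises(ValueError):
            FitParams(minbucket=0)
        with pytest.raises(ValueError):
            FitParams(minsplit=10, minbucket=7)
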