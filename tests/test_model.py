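import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidatlas.errors import DegenerateDataError, UnknownTypeError
from capsidatlas.model import (KnockoutFeatures, MutagenesisRecord,
                               TrainingPair, TwoScaleParams, TypeParams,
                               capsid_cruciality, evaluate, fit,
                               first_prediction_scores,
                               interface_break_probability,
                               linear_separability, make_training_pairs,
                               pathway_break_probability, ranking_concordance,
                               ranking_loss, scores, sigmoid,
                               train_test_split_records)

PATHWAYS = [["i1", "i2"], ["i1", "i3"], ["i2", "i3"]]


def feats(mm_mc_by_type):
    return KnockoutFeatures("r", dict(mm_mc_by_type))


class TestInterfaceBreakProbability:
    def test_zero_weights_give_half(self):
        p = TwoScaleParams({"i1": TypeParams(0, 0, 0, 0.5)})
        assert interface_break_probability(feats({"i1": (0.4, 0.9)}), p, "i1") == 0.5

    def test_hand_arithmetic(self):
        p = TwoScaleParams({"i1": TypeParams(-2, -4, 3, 0.5)})
        got = interface_break_probability(feats({"i1": (1.0, 1.0)}), p, "i1")
        assert got == pytest.approx(1 / (1 + np.exp(3)), abs=1e-5)
        assert got == pytest.approx(0.04743, abs=1e-5)

    def test_large_negative_offset_limit(self):
        p = TwoScaleParams({"i1": TypeParams(0, 0, -500, 0.5)})
        assert interface_break_probability(feats({}), p, "i1") == pytest.approx(0.0)

    def test_neutral_features_for_missing_type(self):
        p = TwoScaleParams({"i1": TypeParams(-1, -1, 0, 0.5)})
        f = feats({})  # knockout touches no type: bar-code (1, 1)
        assert interface_break_probability(f, p, "i1") == pytest.approx(
            float(sigmoid(-2.0)))

    def test_unknown_type(self):
        p = TwoScaleParams({"i1": TypeParams(0, 0, 0, 0.5)})
        with pytest.raises(UnknownTypeError):
            interface_break_probability(feats({}), p, "i9")

    def test_w_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TypeParams(0, 0, 0, 1.5)


class TestPathwayBreakProbability:
    def test_zero_weight_vanishes(self):
        P = {"i1": 0.9, "i2": 0.8}
        w = {"i1": 0.0, "i2": 0.0}
        assert pathway_break_probability(P, w, ["i1", "i2"]) == 0.0

    def test_single_type_full_weight(self):
        assert pathway_break_probability({"i1": 0.37}, {"i1": 1.0}, ["i1"]) \
            == pytest.approx(0.37)

    def test_two_types_half(self):
        got = pathway_break_probability(
            {"i1": 0.5, "i2": 0.5}, {"i1": 1.0, "i2": 1.0}, ["i1", "i2"])
        assert got == pytest.approx(0.75)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=4))
    def test_bounds_and_monotonicity(self, pw):
        types = [f"t{k}" for k in range(len(pw))]
        P = {t: p for t, (p, _) in zip(types, pw)}
        w = {t: v for t, (_, v) in zip(types, pw)}
        c = pathway_break_probability(P, w, types)
        assert 0.0 <= c <= 1.0
        bumped = dict(P)
        bumped[types[0]] = min(1.0, P[types[0]] + 0.1)
        assert pathway_break_probability(bumped, w, types) >= c - 1e-12


class TestCapsidCruciality:
    def test_no_pathways_is_zero(self):
        p = TwoScaleParams({"i1": TypeParams(-1, -1, 0, 0.5)})
        assert capsid_cruciality(feats({}), p, []) == 0.0

    def test_single_pathway_equals_its_break_probability(self):
        p = TwoScaleParams({t: TypeParams(-1, -1, 0, 0.5) for t in ("i1", "i2")})
        f = feats({"i1": (0.2, 0.3), "i2": (0.9, 0.1)})
        P = {t: interface_break_probability(f, p, t) for t in ("i1", "i2")}
        w = {t: 0.5 for t in ("i1", "i2")}
        expected = pathway_break_probability(P, w, ["i1", "i2"])
        assert capsid_cruciality(f, p, [["i1", "i2"]]) == pytest.approx(expected)

    def test_duplicate_pathway_doubles(self):
        p = TwoScaleParams({t: TypeParams(-1, -1, 0, 0.5) for t in ("i1", "i2")})
        f = feats({"i1": (0.2, 0.3)})
        one = capsid_cruciality(f, p, [["i1", "i2"]])
        two = capsid_cruciality(f, p, [["i1", "i2"], ["i1", "i2"]])
        assert two == pytest.approx(2 * one)

    def test_bounded_by_pathway_count(self):
        p = TwoScaleParams({t: TypeParams(-9, -9, 9, 1.0) for t in ("i1", "i2", "i3")})
        f = feats({t: (0.0, 0.0) for t in ("i1", "i2", "i3")})
        h = capsid_cruciality(f, p, PATHWAYS)
        assert 0.0 <= h <= len(PATHWAYS)


class TestRankingLoss:
    def test_empty_is_zero(self):
        assert ranking_loss([], {}) == 0.0

    def test_tie_is_half_per_pair(self):
        H = {"x": 1.0, "y": 1.0}
        assert ranking_loss([TrainingPair("x", "y")], H) == pytest.approx(0.5)

    def test_large_margin_vanishes(self):
        H = {"x": 500.0, "y": 0.0}
        assert ranking_loss([TrainingPair("x", "y")], H) == pytest.approx(0.0)

    def test_missing_score_rejected(self):
        with pytest.raises(KeyError):
            ranking_loss([TrainingPair("x", "z")], {"x": 1.0})

    def test_identical_members_rejected(self):
        with pytest.raises(ValueError):
            TrainingPair("x", "x")


class TestFit:
    @pytest.fixture()
    def tiny_data(self):
        rng = np.random.default_rng(4)
        features = {}
        for k in range(12):
            per_type = {t: (float(rng.uniform()), float(rng.uniform()))
                        for t in ("i1", "i2", "i3")}
            features[f"r{k}"] = KnockoutFeatures(f"r{k}", per_type)
        true = TwoScaleParams({t: TypeParams(-6, -6, 6, w)
                               for t, w in [("i1", .9), ("i2", .5), ("i3", .2)]})
        H = scores(features, true, PATHWAYS)
        rs = sorted(H)
        pairs = [TrainingPair(i, j) for i in rs for j in rs if H[i] > H[j]]
        return features, pairs

    def test_zero_iterations_returns_init(self, tiny_data):
        features, pairs = tiny_data
        init = TwoScaleParams.initial(["i1", "i2", "i3"], a=-2.0, w=0.25)
        out = fit(features, pairs, PATHWAYS, init=init, n_iter=0)
        for t in out.types:
            assert out[t].a == init[t].a
            assert out[t].w == pytest.approx(init[t].w, abs=1e-9)

    def test_loss_never_increases(self, tiny_data):
        features, pairs = tiny_data
        H0 = scores(features, TwoScaleParams.initial(["i1", "i2", "i3"]), PATHWAYS)
        fitted = fit(features, pairs, PATHWAYS, n_iter=800, step=0.05)
        H1 = scores(features, fitted, PATHWAYS)
        assert ranking_loss(pairs, H1) <= ranking_loss(pairs, H0)

    def test_weights_stay_in_unit_interval(self, tiny_data):
        features, pairs = tiny_data
        fitted = fit(features, pairs, PATHWAYS, n_iter=500, step=0.5)
        for t in fitted.types:
            assert 0.0 <= fitted[t].w <= 1.0

    def test_no_pairs_rejected(self, tiny_data):
        features, _ = tiny_data
        with pytest.raises(ValueError):
            fit(features, [], PATHWAYS)


class TestEvaluate:
    def test_two_distinct_points_separable(self):
        points = {"a": (0.1, 0.1), "b": (0.9, 0.9)}
        labels = {"a": "disrupt", "b": "non-disrupt"}
        rep = linear_separability(points, labels)
        assert rep["separable"] and not rep["trivial"]
        assert rep["margin"] > 0

    def test_interleaved_collinear_not_separable(self):
        # alternating classes along a line cannot be split by any line
        points = {"a": (0.0, 0.0), "b": (1.0, 1.0),
                  "c": (2.0, 2.0), "d": (3.0, 3.0)}
        labels = {"a": "disrupt", "b": "non-disrupt",
                  "c": "disrupt", "d": "non-disrupt"}
        assert not linear_separability(points, labels)["separable"]

    def test_single_class_trivially_separable(self):
        points = {"a": (0.1, 0.1), "b": (0.9, 0.9)}
        labels = {"a": "disrupt", "b": "disrupt"}
        rep = linear_separability(points, labels)
        assert rep["separable"] and rep["trivial"]

    def test_perfect_ranking_concordance(self):
        H = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5}
        labels = {"a": "disrupt", "b": "disrupt",
                  "c": "non-disrupt", "d": "non-disrupt"}
        assert ranking_concordance(H, labels) == 1.0

    def test_tie_counts_half(self):
        H = {"a": 1.0, "c": 1.0}
        labels = {"a": "disrupt", "c": "non-disrupt"}
        assert ranking_concordance(H, labels) == 0.5

    def test_partial_records_excluded(self):
        H = {"a": 3.0, "b": 9.0, "c": 1.0}
        labels = {"a": "disrupt", "b": "partial", "c": "non-disrupt"}
        assert ranking_concordance(H, labels) == 1.0

    def test_single_labelled_item_rejected(self):
        with pytest.raises(DegenerateDataError):
            evaluate({"a": 1.0}, None, {"a": "disrupt"})

    def test_report_contains_both_views(self):
        H = {"a": 3.0, "c": 1.0}
        points = {"a": (0.1, 0.1), "c": (0.9, 0.9)}
        labels = {"a": "disrupt", "c": "non-disrupt"}
        rep = evaluate(H, points, labels)
        assert rep["concordance"] == 1.0
        assert rep["separability"]["separable"]


class TestPairsAndSplit:
    def test_partial_order_pairing_rules(self):
        labels = {"d1": "disrupt", "d2": "disrupt", "p1": "partial",
                  "p2": "partial", "n1": "non-disrupt"}
        pairs = make_training_pairs(labels)
        as_tuples = {(p.r_more, p.r_less) for p in pairs}
        assert ("d1", "n1") in as_tuples
        assert ("d1", "p1") in as_tuples and ("p1", "n1") in as_tuples
        assert ("p1", "p2") not in as_tuples and ("p2", "p1") not in as_tuples
        assert len(pairs) == 2 * 1 + 2 * 2 + 2 * 1

    def test_split_is_stratified_and_seeded(self):
        records = [MutagenesisRecord("AAV2", r, "disrupt") for r in range(10)]
        records += [MutagenesisRecord("MVM", r, "non-disrupt") for r in range(5)]
        tr1, te1 = train_test_split_records(records, fraction=0.4, seed=3)
        tr2, _ = train_test_split_records(records, fraction=0.4, seed=3)
        assert [r.residue for r in tr1] == [r.residue for r in tr2]
        assert sum(1 for r in tr1 if r.virus == "AAV2") == 4
        assert sum(1 for r in tr1 if r.virus == "MVM") == 2
        assert len(tr1) + len(te1) == len(records)

    def test_first_prediction_scores_order(self):
        features = {
            "crucial": KnockoutFeatures("crucial", {"i1": (0.1, 0.1)}),
            "benign": KnockoutFeatures("benign", {"i1": (0.9, 0.95)}),
        }
        s = first_prediction_scores(features)
        assert s["crucial"] > s["benign"]

    def test_record_label_vocabulary(self):
        with pytest.raises(ValueError):
            MutagenesisRecord("AAV2", 1, "maybe")
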