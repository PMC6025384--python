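"""Rough-set approximations, LEM2 induction, and the rule classifier."""

import numpy as np
import pandas as pd
import pytest

import oracles
from roughmri.roughset import (
    DecisionTable,
    QuantileDiscretizer,
    RoughSetClassifier,
    RuleSet,
    approximate,
    approximation_quality,
    blocks,
    classify,
    lem2,
)


def make_table(rows: dict, labels: dict, attrs: list[str]) -> DecisionTable:
    return DecisionTable(
        conditions=pd.DataFrame.from_dict(rows, orient="index", columns=attrs),
        decision=pd.Series(labels),
    )


# A consistent worked table: temperature/headache determine flu
WORKED_ROWS = {
    "o1": (0, 0), "o2": (0, 1), "o3": (1, 0),
    "o4": (1, 1), "o5": (2, 1), "o6": (2, 0),
}
WORKED_LABELS = {
    "o1": "no", "o2": "no", "o3": "no",
    "o4": "yes", "o5": "yes", "o6": "yes",
}
WORKED_ATTRS = ["temp", "ache"]


def random_table(rng, n=30, p=3, n_vals=3, labels=("a", "b")) -> DecisionTable:
    rows = {f"x{i}": tuple(rng.integers(0, n_vals, size=p)) for i in range(n)}
    labs = {f"x{i}": labels[rng.integers(0, len(labels))] for i in range(n)}
    return make_table(rows, labs, [f"f{j}" for j in range(p)])


class TestDiscretizer:
    def test_equal_frequency_tertiles_of_one_to_nine(self):
        X = np.arange(1, 10, dtype=float).reshape(-1, 1)
        d = QuantileDiscretizer(n_bins=3).fit(X)
        binned = d.transform(X).ravel()
        assert np.array_equal(np.bincount(binned), [3, 3, 3])
        assert np.allclose(d.cuts_[0], np.quantile(X.ravel(), [1 / 3, 2 / 3]))

    def test_constant_column_single_bin(self):
        X = np.full((10, 1), 4.2)
        d = QuantileDiscretizer(n_bins=3).fit(X)
        assert d.cuts_[0].size == 0
        assert not d.transform(X).any()

    def test_out_of_range_values_clamp_to_end_bins(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        d = QuantileDiscretizer(n_bins=3).fit(X)
        assert d.transform([[-100.0]])[0, 0] == 0
        assert d.transform([[+100.0]])[0, 0] == 2

    def test_matches_sort_and_split_oracle(self, rng):
        X = rng.normal(size=(50, 5))
        d = QuantileDiscretizer(n_bins=3).fit(X)
        binned = d.transform(X)
        for j in range(5):
            col = np.sort(X[:, j])
            # sort-and-split: bottom/middle/top thirds by empirical quantile
            lo, hi = np.quantile(col, [1 / 3, 2 / 3])
            want = np.where(X[:, j] < lo, 0, np.where(X[:, j] < hi, 1, 2))
            assert np.array_equal(binned[:, j], want)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            QuantileDiscretizer(n_bins=1).fit(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            QuantileDiscretizer(method="magic").fit(np.zeros((3, 2)))


class TestBlocks:
    def test_no_attributes_single_block(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        assert blocks(t, []) == [frozenset(WORKED_ROWS)]

    def test_all_distinct_singletons(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        got = blocks(t)
        assert sorted(len(b) for b in got) == [1] * 6

    def test_partition_properties_and_pairwise_oracle(self, rng):
        t = random_table(rng, n=20, p=2, n_vals=2)
        got = set(blocks(t))
        rows = {x: tuple(t.conditions.loc[x]) for x in t.objects}
        want = set(oracles.blocks_pairwise(rows))
        assert got == want
        # disjoint and covering
        union = set().union(*got)
        assert union == set(t.objects)
        assert sum(len(b) for b in got) == len(t.objects)

    def test_unknown_attribute_rejected(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        with pytest.raises(ValueError):
            blocks(t, ["nope"])


class TestApproximate:
    def test_consistent_table_exact(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        ap = approximate(t, "yes")
        assert ap.lower == ap.upper == frozenset({"o4", "o5", "o6"})
        assert ap.boundary == frozenset()
        assert ap.accuracy == 1.0

    def test_conflicting_pair_lands_in_both_boundaries(self):
        rows = {"p": (0,), "q": (0,), "r": (1,)}
        labels = {"p": "a", "q": "b", "r": "a"}
        t = make_table(rows, labels, ["f"])
        for concept in ("a", "b"):
            ap = approximate(t, concept)
            assert {"p", "q"} <= ap.boundary
        assert approximation_quality(t) < 1.0

    @pytest.mark.parametrize("trial", range(5))
    def test_laws_and_enum_oracle_on_random_tables(self, trial):
        rng = np.random.default_rng(300 + trial)
        t = random_table(rng, n=30, p=3, n_vals=2)
        rows = {x: tuple(t.conditions.loc[x]) for x in t.objects}
        labs = dict(t.decision)
        consistent = True
        for concept in pd.unique(t.decision):
            ap = approximate(t, concept)
            want_lo, want_up = oracles.approximations_enum(rows, labs, concept)
            assert ap.lower == want_lo and ap.upper == want_up
            concept_set = t.concept(concept)
            assert ap.lower <= concept_set <= ap.upper
            assert ap.boundary == ap.upper - ap.lower
            assert 0.0 <= ap.accuracy <= 1.0
            consistent &= ap.boundary == frozenset()
        assert (approximation_quality(t) == 1.0) == consistent

    def test_unknown_concept_rejected(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        with pytest.raises(ValueError):
            approximate(t, "maybe")


class TestLem2:
    def test_single_determining_attribute_yields_one_rule_per_value(self):
        rows = {f"x{i}": (i % 3,) for i in range(9)}
        labels = {x: f"c{v[0]}" for x, v in rows.items()}
        t = make_table(rows, labels, ["f"])
        rs = lem2(t)
        assert len(rs.rules) == 3
        for r in rs.rules:
            assert r.specificity == 1
            assert r.support == 3
            (a, v) = r.conditions[0]
            assert r.decision == f"c{v}"

    def test_fully_inconsistent_concept_yields_no_rules(self):
        rows = {"p": (0,), "q": (0,)}
        labels = {"p": "a", "q": "b"}
        t = make_table(rows, labels, ["f"])
        with pytest.warns(UserWarning):
            rs = lem2(t)
        assert rs.rules == []

    def test_worked_table_against_exhaustive_minimal_complex_oracle(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        rs = lem2(t)
        rows = {x: tuple(t.conditions.loc[x]) for x in t.objects}
        for concept in ("no", "yes"):
            minimal, lower = oracles.minimal_certain_complexes(
                rows, WORKED_LABELS, concept, WORKED_ATTRS
            )
            minimal_sets = {conds for conds, _ in minimal}
            covered = set()
            for r in rs.for_concept(concept):
                conds = frozenset(r.conditions)
                # every induced rule is one of the exhaustively-found
                # minimal certain complexes
                assert conds in minimal_sets
                blk = {
                    x for x in rows
                    if all(rows[x][WORKED_ATTRS.index(a)] == v
                           for a, v in r.conditions)
                }
                assert frozenset(blk) <= lower
                assert r.support == len(blk)
                covered |= blk
            # local covering: rule blocks union to exactly the lower approx
            assert covered == set(lower)

    @pytest.mark.parametrize("trial", range(4))
    def test_rules_certain_and_covering_on_random_tables(self, trial):
        rng = np.random.default_rng(400 + trial)
        t = random_table(rng, n=25, p=4, n_vals=2)
        rs = lem2(t)
        for concept in pd.unique(t.decision):
            lower = approximate(t, concept).lower
            covered = set()
            for r in rs.for_concept(concept):
                blk = set(t.objects)
                for a, v in r.conditions:
                    blk &= set(t.conditions.index[t.conditions[a] == v])
                assert frozenset(blk) <= lower  # certainty
                covered |= blk
            assert covered == set(lower)  # completeness

    def test_resubstitution_is_perfect_on_consistent_tables(self, rng):
        # continuous features -> discretizer -> LEM2; distinct rows are
        # consistent, so every training object must classify as itself
        X = rng.normal(size=(24, 6))
        y = np.array(["a", "b"] * 12)
        X[y == "b", 0] += 5.0  # make it learnable
        clf = RoughSetClassifier(n_bins=3).fit(X, y)
        assert approximation_quality(clf.decision_table_) == 1.0
        assert np.array_equal(clf.predict(X), y)


class TestClassify:
    def test_case_matching_exactly_one_rule(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        rs = lem2(t)
        for x, vals in WORKED_ROWS.items():
            case = dict(zip(WORKED_ATTRS, vals))
            assert classify(rs, case) == WORKED_LABELS[x]

    def test_partial_matching_hand_computation(self):
        from roughmri.roughset import Rule

        rules = RuleSet(
            rules=[
                Rule((("f1", 0), ("f2", 0)), "a", support=6, strength=0.3),
                Rule((("f1", 1), ("f3", 1)), "b", support=4, strength=0.2),
                Rule((("f2", 2),), "b", support=3, strength=0.15),
            ],
            default_label="a",
        )
        # case matches no rule fully:
        case = {"f1": 0, "f2": 1, "f3": 1}
        # scores: a: (1/2)*6 = 3 ; b: (1/2)*4 + 0*3 = 2  -> "a"
        assert classify(rules, case) == "a"
        case2 = {"f1": 1, "f2": 2, "f3": 0}
        # scores: a: (1/2)*6 = 3 ; b: (1/2)*4 + 1*3 = 5 -> "b"
        # (f2=2 matches rule 3 fully? no: rule 3 IS fully matched -> b)
        assert classify(rules, case2) == "b"

    def test_empty_rule_set_falls_back_to_majority(self):
        rs = RuleSet(rules=[], default_label="normal")
        with pytest.warns(UserWarning):
            assert classify(rs, {"f": 0}) == "normal"


class TestRuleSetSerialization:
    def test_json_round_trip(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        rs = lem2(t)
        back = RuleSet.from_json(rs.to_json())
        assert back.default_label == rs.default_label
        assert [(r.conditions, r.decision, r.support) for r in back.rules] == [
            (r.conditions, r.decision, r.support) for r in rs.rules
        ]

    def test_human_readable_dump(self):
        t = make_table(WORKED_ROWS, WORKED_LABELS, WORKED_ATTRS)
        text = str(lem2(t))
        assert "IF " in text and "THEN class=" in text and "[support " in text


class TestRoughSetClassifierEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone
        from sklearn.exceptions import NotFittedError

        clf = RoughSetClassifier(n_bins=4)
        assert clone(clf).get_params()["n_bins"] == 4
        with pytest.raises(NotFittedError):
            clf.predict(np.zeros((1, 2)))

    def test_fit_predict_on_separable_blobs(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(6, 1, (20, 3))])
        y = np.array(["normal"] * 20 + ["abnormal"] * 20)
        clf = RoughSetClassifier().fit(X, y)
        assert set(clf.classes_) == {"normal", "abnormal"}
        Xt = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(6, 1, (5, 3))])
        yt = np.array(["normal"] * 5 + ["abnormal"] * 5)
        assert clf.score(Xt, yt) == 1.0

    def test_dataframe_input_uses_column_names(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["alpha", "beta"])
        y = np.array(["a", "b"] * 6)
        clf = RoughSetClassifier().fit(X, y)
        assert list(clf.feature_names_in_) == ["alpha", "beta"]
        attrs_in_rules = {a for r in clf.rules_.rules for a, _ in r.conditions}
        assert attrs_in_rules <= {"alpha", "beta"}
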