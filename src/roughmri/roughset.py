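"""Rough-set machinery and the LEM2 rule classifier.

A decision table holds objects described by discrete condition attributes
plus one decision (class) attribute.  Objects indistinguishable on a set
of attributes form indiscernibility blocks; a concept (the set of objects
with one decision value) is approximated from below by the union of
blocks fully inside it (the lower approximation: certainly in) and from
above by the union of blocks intersecting it (the upper approximation:
possibly in).  The boundary is their difference, and the approximation
accuracy is |lower| / |upper| — equal to 1 exactly when the table is
consistent.

LEM2 (Learning from Examples Module 2) induces a local covering of each
concept's LOWER approximation: minimal complexes (conjunctions of
attribute-value pairs) are grown greedily — always adding the pair t
maximizing |[t] ∩ G| over the uncovered goal set G, ties broken by
smaller |[t]|, then attribute column order, then ascending value — then
stripped of redundant conditions, and redundant rules are dropped from
the covering.  Only certain rules are produced, so inconsistent training
data never yields a rule that misclassifies a training object.

Because rough sets need discrete attributes and the texture features are
continuous, a quantile (equal-frequency) discretizer — fitted on training
data only — maps each feature to a small number of ordinal bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DecisionTable",
    "Approximation",
    "Rule",
    "RuleSet",
    "blocks",
    "approximate",
    "approximation_quality",
    "lem2",
    "classify",
    "QuantileDiscretizer",
    "RoughSetClassifier",
]


@dataclass(frozen=True)
class DecisionTable:
    """Objects x discrete condition attributes + one decision attribute."""

    conditions: pd.DataFrame
    decision: pd.Series

    def __post_init__(self):
        if not self.conditions.index.equals(self.decision.index):
            raise ValueError("conditions and decision must share an index")
        if self.decision.isna().any():
            raise ValueError("decision attribute must be present for all objects")
        if self.conditions.index.has_duplicates:
            raise ValueError("object ids must be unique")

    @property
    def objects(self) -> list:
        return list(self.conditions.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.conditions.columns)

    def concept(self, label) -> frozenset:
        return frozenset(self.decision.index[self.decision == label])


@dataclass(frozen=True)
class Approximation:
    concept: object
    lower: frozenset
    upper: frozenset
    boundary: frozenset
    accuracy: float


@dataclass(frozen=True)
class Rule:
    """A certain decision rule: a conjunction of attribute-value pairs."""

    conditions: tuple[tuple[str, object], ...]
    decision: object
    support: int
    strength: float

    @property
    def specificity(self) -> int:
        return len(self.conditions)

    def matches(self, case: dict | pd.Series) -> bool:
        return all(case[a] == v for a, v in self.conditions)

    def match_fraction(self, case: dict | pd.Series) -> float:
        hit = sum(1 for a, v in self.conditions if case[a] == v)
        return hit / len(self.conditions)

    def __str__(self) -> str:
        conj = " AND ".join(f"{a}={v}" for a, v in self.conditions)
        return f"IF {conj} THEN class={self.decision} [support {self.support}]"


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)
    default_label: object = None  # training-majority class

    def for_concept(self, label) -> list[Rule]:
        return [r for r in self.rules if r.decision == label]

    def to_json(self) -> str:
        payload = {
            "default_label": self.default_label,
            "rules": [
                {
                    "conditions": [[a, v] for a, v in r.conditions],
                    "decision": r.decision,
                    "support": r.support,
                    "strength": r.strength,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        payload = json.loads(text)
        rules = [
            Rule(
                conditions=tuple((a, v) for a, v in r["conditions"]),
                decision=r["decision"],
                support=int(r["support"]),
                strength=float(r["strength"]),
            )
            for r in payload["rules"]
        ]
        return cls(rules=rules, default_label=payload.get("default_label"))

    def __str__(self) -> str:
        return "\n".join(str(r) for r in self.rules)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def blocks(table: DecisionTable, attrs: list[str] | None = None) -> list[frozenset]:
    """Indiscernibility partition over the given condition attributes.

    With no attributes every object is indiscernible: one block = U.
    """
    if attrs is None:
        attrs = table.attributes
    unknown = set(attrs) - set(table.attributes)
    if unknown:
        raise ValueError(f"unknown attributes: {sorted(unknown)}")
    if not attrs:
        return [frozenset(table.objects)]
    groups = table.conditions.groupby(list(attrs), sort=False).groups
    return [frozenset(idx) for idx in groups.values()]


def approximate(table: DecisionTable, concept_label) -> Approximation:
    """Lower/upper approximation, boundary and accuracy of one concept."""
    concept = table.concept(concept_label)
    if not concept:
        raise ValueError(f"concept {concept_label!r} absent from decision column")
    lower: set = set()
    upper: set = set()
    for block in blocks(table):
        if block <= concept:
            lower |= block
        if block & concept:
            upper |= block
    boundary = upper - lower
    accuracy = len(lower) / len(upper) if upper else 1.0
    return Approximation(
        concept=concept_label,
        lower=frozenset(lower),
        upper=frozenset(upper),
        boundary=frozenset(boundary),
        accuracy=accuracy,
    )


def approximation_quality(table: DecisionTable) -> float:
    """Ratio of summed lower- to summed upper-approximation cardinalities
    over all concepts; 1 exactly when the table is consistent."""
    lo = hi = 0
    for label in pd.unique(table.decision):
        ap = approximate(table, label)
        lo += len(ap.lower)
        hi += len(ap.upper)
    return lo / hi if hi else 1.0


def _pair_blocks(table: DecisionTable) -> dict[tuple[str, object], frozenset]:
    """Block [(a, v)] for every attribute-value pair present in the table."""
    out: dict[tuple[str, object], frozenset] = {}
    for a in table.attributes:
        col = table.conditions[a]
        for v, idx in col.groupby(col, sort=True).groups.items():
            out[(a, v)] = frozenset(idx)
    return out


def _complex_block(T: list[tuple[str, object]], pair_block, universe: frozenset) -> frozenset:
    b = universe
    for t in T:
        b = b & pair_block[t]
    return b


def lem2(table: DecisionTable) -> RuleSet:
    """Induce a LEM2 local covering (certain rules only) for each concept.

    Rules for a concept cover exactly its lower approximation; a concept
    with an empty lower approximation yields no rules (a warning is
    emitted).  Ties in the greedy pair choice break deterministically:
    larger |[t] ∩ G|, then smaller |[t]|, then attribute column order,
    then ascending value.
    """
    universe = frozenset(table.objects)
    pair_block = _pair_blocks(table)
    attr_order = {a: i for i, a in enumerate(table.attributes)}
    n_train = len(table.objects)
    counts = table.decision.value_counts()
    # training majority; ties -> first label in decision-column order
    default_label = counts.index[0]

    all_rules: list[Rule] = []
    for label in pd.unique(table.decision):
        B = frozenset(approximate(table, label).lower)
        if not B:
            warnings.warn(
                f"concept {label!r} has an empty lower approximation; "
                "no certain rules induced for it",
                stacklevel=2,
            )
            continue
        G = set(B)
        covering: list[list[tuple[str, object]]] = []
        while G:
            T: list[tuple[str, object]] = []
            used_attrs: set[str] = set()
            G_local = set(G)
            while not (T and _complex_block(T, pair_block, universe) <= B):
                # candidate pairs relevant to the uncovered goal objects
                best = None
                best_key = None
                for (a, v), blk in pair_block.items():
                    if a in used_attrs:
                        continue
                    inter = len(blk & G_local)
                    if inter == 0:
                        continue
                    key = (-inter, len(blk), attr_order[a], v)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (a, v)
                assert best is not None, "no candidate pair; inconsistent goal set"
                T.append(best)
                used_attrs.add(best[0])
                G_local &= pair_block[best]
            # drop redundant conditions (in the order they were added)
            for t in list(T):
                if len(T) > 1:
                    trial = [u for u in T if u != t]
                    if _complex_block(trial, pair_block, universe) <= B:
                        T = trial
            covering.append(T)
            covered = set()
            for Tc in covering:
                covered |= _complex_block(Tc, pair_block, universe)
            G = set(B) - covered
        # drop redundant rules
        minimal: list[list[tuple[str, object]]] = list(covering)
        for Tc in list(covering):
            others = [o for o in minimal if o is not Tc]
            covered = set()
            for o in others:
                covered |= _complex_block(o, pair_block, universe)
            if others and covered >= B:
                minimal = others
        for Tc in minimal:
            blk = _complex_block(Tc, pair_block, universe)
            all_rules.append(
                Rule(
                    conditions=tuple(Tc),
                    decision=label,
                    support=len(blk),
                    strength=len(blk) / n_train,
                )
            )
    return RuleSet(rules=all_rules, default_label=default_label)


def classify(rules: RuleSet, case: dict | pd.Series):
    """Classify one discretized case with the rule set.

    Fully matching rules vote with weight = support.  If none match, each
    rule contributes a partial score (matched conditions / specificity) x
    support to its decision class.  Ties, and an empty rule set, fall
    back to the training-majority class.
    """
    if not rules.rules:
        warnings.warn("empty rule set; predicting the majority class", stacklevel=2)
        return rules.default_label
    scores: dict = {}
    full = [r for r in rules.rules if r.matches(case)]
    if full:
        for r in full:
            scores[r.decision] = scores.get(r.decision, 0.0) + r.support
    else:
        for r in rules.rules:
            scores[r.decision] = scores.get(r.decision, 0.0) + (
                r.match_fraction(case) * r.support
            )
    best = max(scores.values())
    winners = [lab for lab, s in scores.items() if s == best]
    if len(winners) == 1:
        return winners[0]
    return rules.default_label if rules.default_label in winners else winners[0]


class QuantileDiscretizer(BaseEstimator, TransformerMixin):
    """Per-column discretization into ordinal bins.

    Equal-frequency cuts sit at the empirical quantiles of the TRAINING
    data (duplicate cuts from ties collapse); equal-width cuts divide the
    training range evenly.  Values beyond the training range clamp into
    the end bins.  A constant column gets no cuts and maps to bin 0.
    """

    def __init__(self, n_bins: int = 3, method: str = "frequency"):
        self.n_bins = n_bins
        self.method = method

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.method not in ("frequency", "width"):
            raise ValueError("method must be 'frequency' or 'width'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training table must be a nonempty 2-D array")
        cuts: list[np.ndarray] = []
        qs = np.arange(1, self.n_bins) / self.n_bins
        for j in range(X.shape[1]):
            col = X[:, j]
            if self.method == "frequency":
                c = np.quantile(col, qs)
            else:
                c = col.min() + qs * (col.max() - col.min())
            c = np.unique(c)
            if col.min() == col.max():
                c = np.array([])  # constant column: single bin
            cuts.append(c)
        self.cuts_ = cuts
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "cuts_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted table")
        out = np.empty(X.shape, dtype=np.int64)
        for j, c in enumerate(self.cuts_):
            out[:, j] = np.searchsorted(c, X[:, j], side="left") if c.size else 0
        return out


class RoughSetClassifier(BaseEstimator, ClassifierMixin):
    """Rough-set LEM2 rule classifier over continuous features.

    ``fit`` discretizes the training features (quantile bins learned on
    the training fold only), induces certain LEM2 rules from the lower
    approximations, and stores the rule set; ``predict`` discretizes with
    the SAME cuts and applies support-weighted rule voting with partial
    matching for uncovered cases.

    Parameters
    ----------
    n_bins : int, default 3
        Number of discretization bins per feature.
    method : {'frequency', 'width'}, default 'frequency'
        Cut-point placement.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    rules_ : RuleSet
        Induced certain rules with support counts.
    discretizer_ : QuantileDiscretizer
        Fitted cut points.
    """

    def __init__(self, n_bins: int = 3, method: str = "frequency"):
        self.n_bins = n_bins
        self.method = method

    def _columns(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        return [f"f{j}" for j in range(np.asarray(X).shape[1])]

    def fit(self, X, y):
        cols = self._columns(X)
        Xa = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if Xa.ndim != 2:
            raise ValueError("X must be 2-D")
        if Xa.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if Xa.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        self.feature_names_in_ = np.asarray(cols)
        self.n_features_in_ = Xa.shape[1]
        self.discretizer_ = QuantileDiscretizer(self.n_bins, self.method).fit(Xa)
        binned = self.discretizer_.transform(Xa)
        table = DecisionTable(
            conditions=pd.DataFrame(binned, columns=cols),
            decision=pd.Series(y, name="label"),
        )
        self.decision_table_ = table
        self.rules_ = lem2(table)
        return self

    def predict(self, X):
        check_is_fitted(self, "rules_")
        Xa = np.asarray(X, dtype=float)
        binned = self.discretizer_.transform(Xa)
        cols = list(self.feature_names_in_)
        out = [
            classify(self.rules_, dict(zip(cols, row)))
            for row in binned
        ]
        return np.asarray(out)
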