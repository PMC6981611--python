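"""Interpretable if-then rules extracted from a random forest.

A rule is a conjunction of threshold conditions on standardized property
features with a predicted class, e.g.::

    GRAR740101 <= 0.9055 & MANP780101 > 0.7495  =>  QSP

Candidate rules are the root-to-leaf decision paths of a 100-tree forest;
each is greedily pruned (a condition is dropped when dropping it does not
increase the rule's training misclassification count), deduplicated, and
ranked by accuracy, then cover, then brevity.  A query peptide is classified
positive when it satisfies every condition of at least one positive rule; the
default class when nothing fires is negative — a conservative choice for a
screening task whose positive class is the minority in nature.

The bundled IR-QSP rule set (``irqsp_rules.tsv``) is the published 8-rule set
for quorum-sensing peptides, with thresholds on the standardized feature
scale; ``<=`` is inclusive and ``>`` exclusive, exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .featurize import FeatureMatrix

__all__ = [
    "Condition",
    "Rule",
    "RuleStats",
    "RankedRule",
    "rule_matches",
    "rule_stats",
    "classify_by_ruleset",
    "extract_rules",
    "parse_rules_tsv",
    "rules_to_tsv",
    "load_irqsp_rules",
]


@dataclass(frozen=True)
class Condition:
    """One threshold test on a named feature: ``feature <= t`` or ``feature > t``."""

    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">"):
            raise ValueError(f"op must be '<=' or '>', got {self.op!r}")
        t = float(self.threshold)
        if t != t or t in (float("inf"), float("-inf")):
            raise ValueError(f"{self.feature}: threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions with a predicted class (+1 or -1).

    Redundant conditions (same feature and op) are collapsed to the tightest:
    the smallest threshold for ``<=``, the largest for ``>``.
    """

    conditions: tuple[Condition, ...]
    predicted_class: int

    def __post_init__(self) -> None:
        if self.predicted_class not in (1, -1):
            raise ValueError("predicted_class must be +1 or -1")
        conds = tuple(self.conditions)
        if not conds:
            raise ValueError("rule needs at least one condition")
        tight: dict[tuple[str, str], Condition] = {}
        order: list[tuple[str, str]] = []
        for c in conds:
            key = (c.feature, c.op)
            if key not in tight:
                tight[key] = c
                order.append(key)
            else:
                old = tight[key]
                if (c.op == "<=" and c.threshold < old.threshold) or (
                    c.op == ">" and c.threshold > old.threshold
                ):
                    tight[key] = c
        object.__setattr__(
            self, "conditions", tuple(tight[k] for k in order)
        )

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(c.feature for c in self.conditions)

    def __str__(self) -> str:
        return " & ".join(str(c) for c in self.conditions)


@dataclass(frozen=True)
class RuleStats:
    """Cover / misclassification statistics of a rule on a labeled matrix."""

    cover: int
    misclassified: int

    def __post_init__(self) -> None:
        if self.cover < 0 or not (0 <= self.misclassified <= max(self.cover, 0)):
            raise ValueError("need 0 <= misclassified <= cover")

    @property
    def accuracy_pct(self) -> float:
        """Exact percent accuracy; display-rounds to 2 decimals."""
        if self.cover == 0:
            return 0.0
        return 100.0 * (self.cover - self.misclassified) / self.cover


@dataclass(frozen=True)
class RankedRule:
    rule_id: int
    rule: Rule
    stats: RuleStats


def _feature_index(matrix_names: Sequence[str], rule: Rule) -> dict[str, int]:
    idx = {}
    for feat in rule.features:
        try:
            idx[feat] = list(matrix_names).index(feat)
        except ValueError:
            raise KeyError(
                f"rule references feature {feat!r} absent from the matrix"
            ) from None
    return idx


def rule_matches(rule: Rule, x: Sequence[float] | dict[str, float],
                 feature_names: Sequence[str] | None = None) -> bool:
    """True iff *x* satisfies every condition (conjunction only).

    *x* may be a mapping feature->value, or a vector accompanied by
    *feature_names*.  Missing features raise ``KeyError``.
    """
    if isinstance(x, dict):
        values = x
    else:
        if feature_names is None:
            raise ValueError("feature_names required when x is a vector")
        values = dict(zip(feature_names, np.asarray(x, dtype=float)))
    for cond in rule.conditions:
        if cond.feature not in values:
            raise KeyError(f"missing feature {cond.feature!r}")
        if not cond.holds(float(values[cond.feature])):
            return False
    return True


def _match_matrix(rule: Rule, matrix: FeatureMatrix) -> np.ndarray:
    """Boolean row mask of samples matching *rule* (vectorized row scan)."""
    idx = _feature_index(matrix.feature_names, rule)
    ok = np.ones(matrix.n_samples, dtype=bool)
    for cond in rule.conditions:
        col = matrix.values[:, idx[cond.feature]]
        ok &= (col <= cond.threshold) if cond.op == "<=" else (col > cond.threshold)
    return ok


def rule_stats(rule: Rule, matrix: FeatureMatrix, y: Sequence[int]) -> RuleStats:
    """Cover and misclassification of *rule* on a standardized labeled matrix."""
    yv = np.asarray(y, dtype=int)
    hits = _match_matrix(rule, matrix)
    cover = int(hits.sum())
    mis = int(np.sum(hits & (yv != rule.predicted_class)))
    return RuleStats(cover, mis)


def classify_by_ruleset(
    rules: Sequence[RankedRule | Rule],
    x: Sequence[float] | dict[str, float],
    feature_names: Sequence[str] | None = None,
) -> tuple[int, list[int]]:
    """Disjunction-of-conjunctions classification.

    Returns (+1, fired ids) when at least one positive rule fires, else
    (-1, fired ids).  Fired ids list every matching rule (1-based for plain
    ``Rule`` inputs, the ``rule_id`` for ranked rules) for interpretability.
    """
    if not rules:
        raise ValueError("empty rule set")
    fired: list[int] = []
    positive = False
    for i, entry in enumerate(rules, start=1):
        rule = entry.rule if isinstance(entry, RankedRule) else entry
        rid = entry.rule_id if isinstance(entry, RankedRule) else i
        if rule_matches(rule, x, feature_names):
            fired.append(rid)
            if rule.predicted_class == 1:
                positive = True
    return (1 if positive else -1), fired


def _paths_of_tree(tree, feature_names: Sequence[str], classes) -> list[Rule]:
    """Every root-to-leaf path of a fitted sklearn tree as a candidate rule."""
    t = tree.tree_
    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            cls = int(classes[int(np.argmax(counts))])
            if conds:
                rules.append(Rule(tuple(conds), cls))
            return
        feat = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [Condition(feat, "<=", thr)])
        walk(t.children_right[node], conds + [Condition(feat, ">", thr)])

    walk(0, [])
    return rules


def _prune(rule: Rule, matrix: FeatureMatrix, y: Sequence[int]) -> Rule:
    """Greedily drop conditions that do not increase training misclassification."""
    current = rule
    mis = rule_stats(current, matrix, y).misclassified
    improved = True
    while improved and len(current.conditions) > 1:
        improved = False
        for i in range(len(current.conditions)):
            conds = current.conditions[:i] + current.conditions[i + 1:]
            cand = Rule(conds, current.predicted_class)
            cand_mis = rule_stats(cand, matrix, y).misclassified
            if cand_mis <= mis:
                current, mis = cand, cand_mis
                improved = True
                break
    return current


def extract_rules(
    matrix: FeatureMatrix,
    y: Sequence[int],
    n_trees: int = 100,
    seed: int = 0,
    max_depth: int | None = None,
) -> list[RankedRule]:
    """Fit an ``n_trees`` forest, harvest and prune its decision paths.

    Returns deduplicated rules ranked by accuracy desc, cover desc, then
    fewer conditions, with stats recomputed on (matrix, y).
    """
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("rule extraction needs both classes present")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, max_depth=max_depth, n_jobs=1
    )
    forest.fit(matrix.values, yv)
    seen: set[tuple] = set()
    ranked: list[tuple] = []
    for tree in forest.estimators_:
        for rule in _paths_of_tree(tree, matrix.feature_names, forest.classes_):
            pruned = _prune(rule, matrix, yv)
            key = (pruned.predicted_class, frozenset(pruned.conditions))
            if key in seen:
                continue
            seen.add(key)
            stats = rule_stats(pruned, matrix, yv)
            if stats.cover == 0:
                continue
            ranked.append((pruned, stats))
    ranked.sort(
        key=lambda rs: (-rs[1].accuracy_pct, -rs[1].cover, len(rs[0].conditions))
    )
    return [
        RankedRule(i, rule, stats)
        for i, (rule, stats) in enumerate(ranked, start=1)
    ]


def _parse_conditions(text: str) -> tuple[Condition, ...]:
    conds = []
    for part in text.split("&"):
        tokens = part.split()
        if len(tokens) != 3 or tokens[1] not in ("<=", ">"):
            raise ValueError(f"bad condition {part.strip()!r}")
        conds.append(Condition(tokens[0], tokens[1], float(tokens[2])))
    return tuple(conds)


def parse_rules_tsv(text: str) -> list[RankedRule]:
    """Parse the TSV rule format (lossless round-trip with rules_to_tsv)."""
    out: list[RankedRule] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("rule_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns")
        rid, cls, conds, cover, mis, _acc = fields
        label = 1 if cls.strip() in ("QSP", "+1", "1") else -1
        rule = Rule(_parse_conditions(conds), label)
        out.append(RankedRule(int(rid), rule, RuleStats(int(cover), int(mis))))
    return out


def rules_to_tsv(rules: Iterable[RankedRule]) -> str:
    lines = ["rule_id\tclass\tconditions\tcover\tmisclassified\taccuracy_pct"]
    for rr in rules:
        cls = "QSP" if rr.rule.predicted_class == 1 else "Non-QSP"
        lines.append(
            f"{rr.rule_id}\t{cls}\t{rr.rule}\t{rr.stats.cover}\t"
            f"{rr.stats.misclassified}\t{rr.stats.accuracy_pct:.2f}"
        )
    return "\n".join(lines) + "\n"


def load_irqsp_rules() -> list[RankedRule]:
    """The published 8-rule IR-QSP set with its printed cover statistics.

    Thresholds live on the standardized feature scale of the featurize
    module; apply them only to z-scored feature vectors.
    """
    text = resources.files("iqsp.data").joinpath("irqsp_rules.tsv").read_text(
        encoding="utf-8"
    )
    return parse_rules_tsv(text)
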