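"""Root-to-leaf decision rules extracted from a CART model.

Every leaf becomes one rule: the conjunction of threshold conditions along
its path, simplified per feature to the tightest lower ("> a") and upper
("<= b") bound. The rules partition the feature space — exactly one rule
fires for any sample — and applying them reproduces the tree's predictions
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cart import DecisionTreeModel, TreeNode

__all__ = [
    "RuleCondition",
    "DecisionRule",
    "RuleSet",
    "extract_rules",
    "apply_rules",
    "summarize_rules",
]


@dataclass(frozen=True)
class RuleCondition:
    feature_index: int
    relation: str  # "<=" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.relation not in ("<=", ">"):
            raise ValueError(f"relation must be '<=' or '>', got {self.relation!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, sample: np.ndarray) -> bool:
        v = sample[self.feature_index]
        return v <= self.threshold if self.relation == "<=" else v > self.threshold


@dataclass(frozen=True)
class DecisionRule:
    conditions: tuple[RuleCondition, ...]
    label: int
    support: tuple[int, int]  # (negatives, positives) at the source leaf

    def matches(self, sample: np.ndarray) -> bool:
        return all(c.holds(sample) for c in self.conditions)


@dataclass
class RuleSet:
    rules: list[DecisionRule]
    feature_ids: list[str]

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def n_positive_rules(self) -> int:
        return sum(1 for r in self.rules if r.label == 1)

    @property
    def n_negative_rules(self) -> int:
        return sum(1 for r in self.rules if r.label == 0)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "feature_ids": self.feature_ids,
            "rules": [
                {
                    "conditions": [
                        {
                            "feature_id": self.feature_ids[c.feature_index],
                            "feature_index": c.feature_index,
                            "relation": c.relation,
                            "threshold": c.threshold,
                        }
                        for c in r.conditions
                    ],
                    "label": r.label,
                    "support": list(r.support),
                }
                for r in self.rules
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


def _simplify(path: list[RuleCondition]) -> tuple[RuleCondition, ...]:
    """Keep only the tightest lower and upper bound per feature."""
    lower: dict[int, float] = {}  # feature -> max threshold among ">"
    upper: dict[int, float] = {}  # feature -> min threshold among "<="
    for c in path:
        if c.relation == ">":
            lower[c.feature_index] = max(lower.get(c.feature_index, -np.inf), c.threshold)
        else:
            upper[c.feature_index] = min(upper.get(c.feature_index, np.inf), c.threshold)
    out: list[RuleCondition] = []
    for f in sorted(set(lower) | set(upper)):
        lo = lower.get(f)
        hi = upper.get(f)
        if lo is not None and hi is not None and lo >= hi:
            raise ValueError(f"unsatisfiable path conditions on feature {f}")
        if lo is not None:
            out.append(RuleCondition(f, ">", lo))
        if hi is not None:
            out.append(RuleCondition(f, "<=", hi))
    return tuple(out)


def extract_rules(model: DecisionTreeModel) -> RuleSet:
    """One rule per leaf, conditions read along the root-to-leaf path."""
    rules: list[DecisionRule] = []
    stack: list[tuple[TreeNode, list[RuleCondition]]] = [(model.root, [])]
    while stack:
        node, path = stack.pop()
        if node.is_leaf:
            rules.append(
                DecisionRule(
                    conditions=_simplify(path),
                    label=node.prediction,
                    support=node.counts,
                )
            )
            continue
        stack.append((node.right, path + [RuleCondition(node.feature, ">", node.threshold)]))
        stack.append((node.left, path + [RuleCondition(node.feature, "<=", node.threshold)]))
    return RuleSet(rules=rules, feature_ids=list(model.feature_ids))


def apply_rules(ruleset: RuleSet, sample: np.ndarray) -> tuple[int, int]:
    """Return (label, rule index) for the unique matching rule.

    Zero or multiple matches indicate a corrupted rule set and raise.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(ruleset.feature_ids),):
        raise ValueError(
            f"sample has {sample.shape} values, rules expect {len(ruleset.feature_ids)}"
        )
    hits = [i for i, r in enumerate(ruleset.rules) if r.matches(sample)]
    if len(hits) != 1:
        raise RuntimeError(
            f"rule set is not a partition: {len(hits)} rules matched (expected 1)"
        )
    i = hits[0]
    return ruleset.rules[i].label, i


def _render_rule(rule: DecisionRule, feature_ids: Sequence[str],
                 metadata: Mapping[str, str] | None) -> str:
    if not rule.conditions:
        body = "TRUE"
    else:
        parts = []
        for c in rule.conditions:
            fid = feature_ids[c.feature_index]
            name = metadata.get(fid, fid) if metadata else fid
            parts.append(f"score({name}) {c.relation} {c.threshold:.4g}")
        body = " AND ".join(parts)
    outcome = "cancer-related" if rule.label == 1 else "not cancer-related"
    n0, n1 = rule.support
    return f"IF {body} THEN {outcome}  [support: {n1} positive / {n0} negative]"


def summarize_rules(
    ruleset: RuleSet, term_metadata: Mapping[str, str] | None = None
) -> str:
    """Human-readable report: identifying rules first, sorted by positive support."""
    if not ruleset.rules:
        raise ValueError("empty rule set")
    pos = [r for r in ruleset.rules if r.label == 1]
    neg = [r for r in ruleset.rules if r.label == 0]
    pos.sort(key=lambda r: -r.support[1])
    neg.sort(key=lambda r: -r.support[1])
    lines = [f"{len(pos)} identifying / {len(neg)} excluding"]
    if pos:
        lines.append("")
        lines.append("# Identifying rules (predict positive)")
        for r in pos:
            lines.append(_render_rule(r, ruleset.feature_ids, term_metadata))
    if neg:
        lines.append("")
        lines.append("# Excluding rules (predict negative)")
        for r in neg:
            lines.append(_render_rule(r, ruleset.feature_ids, term_metadata))
    return "\n".join(lines) + "\n"
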