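"""Fast-and-frugal tree representation, classification and serialization.

A fast-and-frugal tree (FFT) is an ordered list of split rules.  Every
non-final node carries exactly one *exit*: if its rule fires on a patient,
classification stops immediately with the node's exit decision; otherwise the
next cue is inspected.  The final node has both exits (rule fires -> positive,
else negative).  Classification therefore uses between 1 and ``depth`` cue
lookups per patient, which is what makes these trees cheap to apply at the
bedside.

Rules are numeric threshold comparisons (``cue > t`` or ``cue <= t``) on the
cue's coded scale; ordinal and binary cues are thresholded on their integer
codes (e.g. ``surgery_site > 2`` selects peripheral surgery, ``frailty <= 0``
selects robust patients).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .metrics import PerfStats, perf_from_predictions

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "BOTH",
    "SplitRule",
    "Node",
    "FFTree",
    "ClassificationTrace",
    "classify",
    "classify_table",
    "evaluate",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

POSITIVE = "positive"
NEGATIVE = "negative"
BOTH = "both"

_GT = ">"
_LE = "<="


@dataclass(frozen=True)
class SplitRule:
    """A threshold comparison on one cue; firing points toward the node's exit."""

    cue: str
    direction: str  # ">" or "<="
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in (_GT, _LE):
            raise ValueError(f"direction must be '>' or '<=', got {self.direction!r}")

    def fires(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.direction == _GT:
            return v > self.threshold
        return v <= self.threshold

    def negate(self) -> "SplitRule":
        """The complementary rule (exact: not(v > t) == v <= t)."""
        other = _LE if self.direction == _GT else _GT
        return SplitRule(self.cue, other, self.threshold)

    def describe(self) -> str:
        return f"{self.cue} {self.direction} {self.threshold:g}"


@dataclass(frozen=True)
class Node:
    """One tree level: a rule plus the side on which classification exits."""

    rule: SplitRule
    exit_side: str

    def __post_init__(self) -> None:
        if self.exit_side not in (POSITIVE, NEGATIVE, BOTH):
            raise ValueError(f"bad exit side {self.exit_side!r}")


@dataclass(frozen=True)
class FFTree:
    """An ordered fast-and-frugal tree.

    Invariants: depth >= 1, every non-final node exits on exactly one side,
    the final node exits on both, and no cue appears twice.  ``goal_value``
    records the balanced accuracy the tree achieved on its training set (or
    ``None`` for hand-specified trees).
    """

    nodes: tuple[Node, ...]
    goal_value: float | None = None

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(nodes) < 1:
            raise ValueError("a tree needs at least one node")
        for node in nodes[:-1]:
            if node.exit_side not in (POSITIVE, NEGATIVE):
                raise ValueError("non-final nodes must exit on exactly one side")
        if nodes[-1].exit_side != BOTH:
            raise ValueError("the final node must exit on both sides")
        cues = [n.rule.cue for n in nodes]
        if len(set(cues)) != len(cues):
            raise ValueError("a cue may appear only once per tree")

    @property
    def depth(self) -> int:
        return len(self.nodes)

    @property
    def cues(self) -> list[str]:
        return [n.rule.cue for n in self.nodes]

    def describe(self) -> str:
        lines = []
        for i, node in enumerate(self.nodes, start=1):
            if node.exit_side == BOTH:
                lines.append(f"{i}. if {node.rule.describe()}: POSITIVE else NEGATIVE")
            else:
                lines.append(f"{i}. if {node.rule.describe()}: exit {node.exit_side.upper()}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ClassificationTrace:
    """Decision for one patient plus how many cues were looked up."""

    decision: int
    cues_used: int
    exit_depth: int


def classify_table(tree: FFTree, frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cascade classification.

    Returns ``(decisions, depths)`` as boolean / integer arrays.  Missing
    values in any tree cue are fatal: imputation must precede classification.
    """
    missing_cols = [c for c in tree.cues if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"table is missing tree cues {missing_cols}")
    n = len(frame)
    decisions = np.zeros(n, dtype=bool)
    depths = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for i, node in enumerate(tree.nodes):
        values = frame[node.rule.cue].to_numpy(dtype=float)
        if np.isnan(values[active]).any():
            raise ValueError(
                f"missing values in cue {node.rule.cue!r}: impute before classifying")
        fires = node.rule.fires(values)
        if node.exit_side == BOTH:
            decisions[active] = fires[active]
            depths[active] = i + 1
            active = np.zeros(n, dtype=bool)
        else:
            exiting = active & fires
            decisions[exiting] = node.exit_side == POSITIVE
            depths[exiting] = i + 1
            active &= ~fires
    return decisions, depths


def classify(tree: FFTree, record: Mapping[str, float]) -> ClassificationTrace:
    """Classify one patient record, reporting the exit depth."""
    frame = pd.DataFrame([dict(record)])
    decisions, depths = classify_table(tree, frame)
    d = int(depths[0])
    return ClassificationTrace(decision=int(decisions[0]), cues_used=d, exit_depth=d)


def evaluate(tree: FFTree, table: CohortTable,
             n_cues_available: int | None = None) -> PerfStats:
    """Confusion counts and derived metrics of a tree on a labelled cohort.

    ``pci`` uses the number of cue columns available in the supplied table as
    its denominator unless overridden.
    """
    if table.n == 0:
        raise ValueError("cannot evaluate on an empty table")
    table.require_outcome()
    decisions, depths = classify_table(tree, table.cue_frame)
    if n_cues_available is None:
        n_cues_available = len(table.cue_names)
    return perf_from_predictions(table.outcome, decisions, cues_used=depths,
                                 n_cues_available=n_cues_available)


# ---------------------------------------------------------------------------
# Serialization (YAML/JSON, round-trip stable)
# ---------------------------------------------------------------------------

def tree_to_dict(tree: FFTree) -> dict:
    return {
        "nodes": [
            {"cue": n.rule.cue, "direction": n.rule.direction,
             "threshold": float(n.rule.threshold), "exit": n.exit_side}
            for n in tree.nodes
        ],
        "goal_value": None if tree.goal_value is None else float(tree.goal_value),
    }


def tree_from_dict(doc: Mapping) -> FFTree:
    nodes = tuple(
        Node(SplitRule(d["cue"], d["direction"], float(d["threshold"])), d["exit"])
        for d in doc["nodes"]
    )
    return FFTree(nodes, goal_value=doc.get("goal_value"))


def save_tree(tree: FFTree, path: str | Path) -> None:
    path = Path(path)
    doc = tree_to_dict(tree)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=False))


def load_tree(path: str | Path) -> FFTree:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return tree_from_dict(doc)
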