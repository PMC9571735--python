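"""Fast-and-frugal tree induction: the ifan and dfan construction algorithms.

Both algorithms optimise a weighted mean of sensitivity and specificity on the
training set; with the default weight 0.5 this is balanced accuracy.

*ifan* ("independent fan") scores every cue marginally -- the best single-cue
threshold rule over all unique observed values and both directions -- ranks
cues by that marginal score, truncates the ranking at ``max_levels``, and then
searches the *fan*: for each depth ``k`` every one of the ``2**(k-1)``
assignments of exit sides to the non-final nodes.  The candidate maximising
the training goal wins; ties prefer the shallower tree, then the first
candidate in enumeration order.

*dfan* ("dependent fan") re-selects the best cue *conditionally*: at each node
it re-evaluates the best single-cue rule for every unused cue on the cases
still undecided at that node, takes the best, and branches over the two
possible exit sides.  Completed candidate trees are scored on the full
training set; if no deeper tree strictly improves on the best shallower one,
the shallower (truncated) tree is returned.

Tie-breaking everywhere is deterministic: higher goal, then higher
sensitivity, then lower threshold, then direction ``>`` before ``<=``, then
alphabetical cue name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .metrics import PerfStats
from .tree import BOTH, NEGATIVE, POSITIVE, FFTree, Node, SplitRule, classify_table, evaluate

__all__ = [
    "CueScore",
    "best_split_for_cue",
    "rank_cues",
    "build_ifan",
    "build_dfan",
    "FastFrugalTreeModel",
    "FastFrugalTreeResults",
]

_DIRECTIONS = (">", "<=")


@dataclass(frozen=True)
class CueScore:
    """Marginal (or conditional) single-cue performance: rule plus its goal."""

    cue: str
    rule: SplitRule
    goal: float
    sens: float
    spec: float


def best_split_for_cue(values, labels, weight: float = 0.5, cue: str = "cue") -> CueScore:
    """Best threshold rule for one cue under the weighted sens/spec goal.

    Candidate thresholds are all unique observed values, crossed with the two
    directions; a rule's predictions are positive where it fires.  Requires at
    least one case of each class.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if np.isnan(v).any():
        raise ValueError(f"cue {cue!r} has missing values; impute first")
    pos = int(y.sum())
    neg = int(len(y) - pos)
    if pos == 0 or neg == 0:
        raise ValueError("goal undefined: labels contain a single class")
    u, inverse = np.unique(v, return_inverse=True)
    pos_at = np.bincount(inverse, weights=y, minlength=len(u))
    tot_at = np.bincount(inverse, minlength=len(u))
    cpos = np.cumsum(pos_at)
    cneg = np.cumsum(tot_at - pos_at)
    # direction ">": positive iff v > u[i];  "<=": positive iff v <= u[i]
    sens = np.concatenate([(pos - cpos) / pos, cpos / pos])
    spec = np.concatenate([cneg / neg, (neg - cneg) / neg])
    thr = np.concatenate([u, u])
    dir_rank = np.concatenate([np.zeros(len(u)), np.ones(len(u))])  # ">" preferred
    goal = weight * sens + (1.0 - weight) * spec
    # lexsort: last key is primary
    order = np.lexsort((dir_rank, thr, -sens, -goal))
    i = order[0]
    direction = _DIRECTIONS[int(dir_rank[i])]
    rule = SplitRule(cue, direction, float(thr[i]))
    return CueScore(cue, rule, float(goal[i]), float(sens[i]), float(spec[i]))


def _score_key(score: CueScore):
    # sort key for ranking cue scores (descending goal, then sens, low threshold,
    # ">" first, alphabetical cue)
    return (-score.goal, -score.sens, score.rule.threshold,
            _DIRECTIONS.index(score.rule.direction), score.cue)


def rank_cues(table: CohortTable, cues: Sequence[str] | None = None,
              weight: float = 0.5) -> list[CueScore]:
    """Score every cue marginally and sort by decreasing goal (deterministic ties)."""
    table.require_outcome()
    if cues is None:
        cues = table.cue_names
    y = table.outcome
    scores = [best_split_for_cue(table.data[c].to_numpy(), y, weight=weight, cue=c)
              for c in cues]
    return sorted(scores, key=_score_key)


def _exit_node(rule: SplitRule, side: str) -> Node:
    """Node whose rule fires exactly for the cases exiting on ``side``.

    Marginal rules point toward the positive class; a negative exit therefore
    uses the complementary rule, so that firing always means "decide now".
    """
    if side == NEGATIVE:
        return Node(rule.negate(), NEGATIVE)
    return Node(rule, side)


@dataclass
class _Candidate:
    tree: FFTree
    score: float
    perf: PerfStats
    order: int


def _evaluate_candidates(candidates: list[tuple[int, tuple[Node, ...]]],
                         table: CohortTable, weight: float) -> tuple[FFTree, list[_Candidate]]:
    """Score candidate node lists on the training table and pick the winner.

    Candidates are visited sorted by (depth, enumeration order); only a
    strictly better goal displaces the incumbent, so ties resolve toward the
    shallower, earlier-enumerated tree and a deeper tree is kept only when it
    strictly improves on every shallower one (truncation-on-no-improvement).
    """
    scored: list[_Candidate] = []
    for order, nodes in sorted(candidates, key=lambda c: (len(c[1]), c[0])):
        tree = FFTree(nodes)
        perf = evaluate(tree, table)
        score = weight * perf.sens + (1.0 - weight) * perf.spec
        scored.append(_Candidate(tree, score, perf, order))
    best = scored[0]
    for cand in scored[1:]:
        if cand.score > best.score:
            best = cand
    winner = FFTree(best.tree.nodes, goal_value=best.perf.bacc)
    return winner, scored


def _ifan_candidates(ranked: list[CueScore], max_levels: int):
    candidates = []
    order = 0
    top = ranked[:max_levels]
    for k in range(1, len(top) + 1):
        for exits in itertools.product((POSITIVE, NEGATIVE), repeat=k - 1):
            nodes = tuple(_exit_node(top[i].rule, exits[i]) for i in range(k - 1))
            nodes += (Node(top[k - 1].rule, BOTH),)
            candidates.append((order, nodes))
            order += 1
    return candidates


def build_ifan(table: CohortTable, max_levels: int = 5, weight: float = 0.5,
               cues: Sequence[str] | None = None) -> FFTree:
    """Construct a fast-and-frugal tree with the ifan algorithm (default depth cap 5)."""
    tree, _ = _build_ifan(table, max_levels, weight, cues)
    return tree


def _build_ifan(table, max_levels, weight, cues=None):
    if max_levels < 1:
        raise ValueError("max_levels must be at least 1")
    ranked = rank_cues(table, cues=cues, weight=weight)
    candidates = _ifan_candidates(ranked, max_levels)
    return _evaluate_candidates(candidates, table, weight)


def build_dfan(table: CohortTable, max_levels: int = 4, weight: float = 0.5,
               cues: Sequence[str] | None = None) -> FFTree:
    """Construct a fast-and-frugal tree with the dfan algorithm (default depth cap 4)."""
    tree, _ = _build_dfan(table, max_levels, weight, cues)
    return tree


def _build_dfan(table, max_levels, weight, cues=None):
    if max_levels < 1:
        raise ValueError("max_levels must be at least 1")
    table.require_outcome()
    if cues is None:
        cues = table.cue_names
    y = table.outcome.astype(bool)
    values = {c: table.data[c].to_numpy(dtype=float) for c in cues}
    candidates: list[tuple[int, tuple[Node, ...]]] = []
    counter = itertools.count()

    def best_conditional(mask: np.ndarray, unused: list[str]) -> CueScore:
        scores = [best_split_for_cue(values[c][mask], y[mask], weight=weight, cue=c)
                  for c in unused]
        return sorted(scores, key=_score_key)[0]

    def recurse(prefix: tuple[Node, ...], mask: np.ndarray, unused: list[str]) -> None:
        pick = best_conditional(mask, unused)
        candidates.append((next(counter), prefix + (Node(pick.rule, BOTH),)))
        depth = len(prefix) + 1
        if depth >= max_levels or len(unused) <= 1:
            return
        remaining_cues = [c for c in unused if c != pick.cue]
        for side in (POSITIVE, NEGATIVE):
            node = _exit_node(pick.rule, side)
            exits = node.rule.fires(values[pick.cue]) & mask
            remaining = mask & ~exits
            ym = y[remaining]
            if remaining.any() and ym.any() and not ym.all():
                recurse(prefix + (node,), remaining, remaining_cues)

    recurse((), np.ones(table.n, dtype=bool), list(cues))
    return _evaluate_candidates(candidates, table, weight)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class FastFrugalTreeModel:
    """Fast-and-frugal tree model for a binary risk outcome.

    Parameters
    ----------
    cohort : CohortTable
        Training data (imputed; construction is fatal on missing cue values).
    algorithm : {"ifan", "dfan"}
        Construction algorithm.
    max_levels : int, optional
        Depth cap; defaults to 5 for ifan and 4 for dfan.
    weight : float
        Sensitivity weight of the goal ``weight*sens + (1-weight)*spec``.
        The default 0.5 is balanced accuracy; other values exist for
        sensitivity analyses only.
    cues : sequence of str, optional
        Cue subset to search (default: all cues in the cohort).
    """

    def __init__(self, cohort: CohortTable, algorithm: str = "ifan",
                 max_levels: int | None = None, weight: float = 0.5,
                 cues: Sequence[str] | None = None) -> None:
        if algorithm not in ("ifan", "dfan"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        cohort.require_outcome()
        self.cohort = cohort
        self.algorithm = algorithm
        self.max_levels = max_levels if max_levels is not None else (5 if algorithm == "ifan" else 4)
        self.weight = weight
        self.cues = list(cues) if cues is not None else cohort.cue_names

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, outcome: str = "pod",
                       **kwargs) -> "FastFrugalTreeModel":
        df = frame.rename(columns={outcome: "pod"}) if outcome != "pod" else frame
        return cls(CohortTable(df), **kwargs)

    def fit(self) -> "FastFrugalTreeResults":
        builder = _build_ifan if self.algorithm == "ifan" else _build_dfan
        tree, fan = builder(self.cohort, self.max_levels, self.weight, self.cues)
        return FastFrugalTreeResults(self, tree, fan)


class FastFrugalTreeResults:
    """Fitted fast-and-frugal tree: the tree, its training fit and the fan.

    ``fan_`` lists every candidate tree examined during construction with its
    depth, goal, hit rate and false-alarm rate (the points of the fan's ROC
    cloud).
    """

    def __init__(self, model: FastFrugalTreeModel, tree: FFTree,
                 fan: list[_Candidate]) -> None:
        self.model = model
        self.tree = tree
        self.train_perf: PerfStats = evaluate(tree, model.cohort)
        self.fan_: pd.DataFrame = pd.DataFrame(
            [{"depth": c.tree.depth, "goal": c.score, "hr": c.perf.sens,
              "far": 1.0 - c.perf.spec,
              "exits": "".join("+" if n.exit_side == POSITIVE else "-"
                               for n in c.tree.nodes[:-1])}
             for c in fan]
        )

    def predict(self, table: CohortTable | pd.DataFrame) -> np.ndarray:
        frame = table.cue_frame if isinstance(table, CohortTable) else table
        decisions, _ = classify_table(self.tree, frame)
        return decisions.astype(np.int64)

    def evaluate(self, table: CohortTable) -> PerfStats:
        return evaluate(self.tree, table)

    def summary(self) -> str:
        m = self.model
        p = self.train_perf
        lines = [
            "Fast-and-frugal tree results",
            "=" * 60,
            f"algorithm: {m.algorithm}    max levels: {m.max_levels}    "
            f"sensitivity weight: {m.weight:g}",
            f"n train: {m.cohort.n}    cues searched: {len(m.cues)}    "
            f"candidates examined: {len(self.fan_)}",
            "-" * 60,
            self.tree.describe(),
            "-" * 60,
            f"training: sens {p.sens:.3f}  spec {p.spec:.3f}  bacc {p.bacc:.3f}  "
            f"acc {p.acc:.3f}",
            f"frugality: mcu {p.mcu:.2f}  pci {100 * p.pci:.0f}%",
        ]
        return "\n".join(lines)
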