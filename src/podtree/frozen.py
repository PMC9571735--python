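"""The two published screening trees, ready to apply to a cohort.

The *pre-operative* tree asks up to four questions, in this order:

1. Charlson Comorbidity Index > 1  -> flag POSITIVE (at risk)
2. surgery site > 2 (peripheral)   -> flag NEGATIVE
3. ASA physical status > 2         -> flag POSITIVE
4. frailty > 0 (pre-frail/frail)   -> POSITIVE, robust (<= 0) -> NEGATIVE

Only the first node's rule and the cue order are anchored in the published
text; the exit directions and thresholds of nodes 2-3 are defaults inferred
from the published cohort marginals (peripheral surgery and ASA 1-2 are far
more common among patients who stayed delirium-free) and can be overridden
per node.

The *postoperative* tree uses duration of anesthesia, then age, then CCI, in
that order, but its numeric cut points were published only graphically; this
module therefore refuses to build it without explicit thresholds rather than
inventing defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cohort import CohortTable
from .metrics import PerfStats, perf_from_predictions
from .tree import BOTH, NEGATIVE, POSITIVE, FFTree, Node, SplitRule, classify_table

__all__ = [
    "FrozenTreeConfig",
    "preoperative_tree",
    "postoperative_tree",
    "screen",
    "ScreeningReport",
    "PREOPERATIVE_TREE_CUES",
    "POSTOPERATIVE_TREE_CUES",
]

PREOPERATIVE_TREE_CUES = ("cci", "surgery_site", "asa_ps", "frailty")
POSTOPERATIVE_TREE_CUES = ("anesthesia_duration", "age", "cci")


@dataclass(frozen=True)
class FrozenTreeConfig:
    """Per-node overrides for the under-specified elements of a frozen tree."""

    thresholds: Mapping[str, float] = field(default_factory=dict)
    exit_sides: Mapping[str, str] = field(default_factory=dict)


def _check_overrides(config: FrozenTreeConfig, cues: tuple[str, ...]) -> None:
    for mapping, what in ((config.thresholds, "threshold"),
                          (config.exit_sides, "exit side")):
        foreign = [c for c in mapping if c not in cues]
        if foreign:
            raise ValueError(f"{what} override references foreign cues {foreign}; "
                             f"this tree uses {list(cues)}")


def _build(defaults, config: FrozenTreeConfig, cues) -> FFTree:
    _check_overrides(config, cues)
    nodes = []
    for cue, direction, threshold, side in defaults:
        threshold = config.thresholds.get(cue, threshold)
        side = config.exit_sides.get(cue, side) if side != BOTH else BOTH
        nodes.append(Node(SplitRule(cue, direction, threshold), side))
    return FFTree(tuple(nodes))


def preoperative_tree(config: FrozenTreeConfig | None = None) -> FFTree:
    """The published four-cue pre-operative screening tree (defaults overridable)."""
    config = config or FrozenTreeConfig()
    defaults = (
        ("cci", ">", 1.0, POSITIVE),
        ("surgery_site", ">", 2.0, NEGATIVE),
        ("asa_ps", ">", 2.0, POSITIVE),
        ("frailty", ">", 0.0, BOTH),
    )
    return _build(defaults, config, PREOPERATIVE_TREE_CUES)


def postoperative_tree(config: FrozenTreeConfig) -> FFTree:
    """The published three-cue postoperative tree; thresholds are mandatory.

    The published figure prints no numeric cut points for duration of
    anesthesia, age or CCI, so all three thresholds must be supplied
    explicitly via ``config.thresholds``.
    """
    missing = [c for c in POSTOPERATIVE_TREE_CUES if c not in config.thresholds]
    if missing:
        raise ValueError(
            f"postoperative tree thresholds for {missing} must be supplied: the "
            "published cut points are not printed in the source text")
    t = config.thresholds
    defaults = (
        ("anesthesia_duration", ">", float(t["anesthesia_duration"]), POSITIVE),
        ("age", ">", float(t["age"]), POSITIVE),
        ("cci", ">", float(t["cci"]), BOTH),
    )
    return _build(defaults, config, POSTOPERATIVE_TREE_CUES)


@dataclass
class ScreeningReport:
    """Per-patient decisions plus performance when outcomes are available."""

    decisions: pd.DataFrame  # columns: decision, cues_used
    perf: PerfStats | None

    @property
    def flagged(self) -> pd.DataFrame:
        """The subset of patients flagged as at risk of POD."""
        return self.decisions[self.decisions["decision"] == 1]


def screen(tree: FFTree, cohort: CohortTable) -> ScreeningReport:
    """Apply a screening tree to an (imputed) cohort.

    Returns the per-patient flag report; performance statistics are attached
    when the cohort carries outcomes.
    """
    missing_cols = [c for c in tree.cues if c not in cohort.data.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing tree cues {missing_cols}")
    if cohort.n == 0:
        return ScreeningReport(
            decisions=pd.DataFrame(columns=["decision", "cues_used"]), perf=None)
    decisions, depths = classify_table(tree, cohort.cue_frame)
    report = pd.DataFrame({"decision": decisions.astype(int), "cues_used": depths})
    perf = None
    if cohort.has_outcome:
        perf = perf_from_predictions(cohort.outcome, decisions, cues_used=depths,
                                     n_cues_available=len(cohort.cue_names))
    return ScreeningReport(decisions=report, perf=perf)
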