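"""Naive brute-force oracles for the tree builders.

Deliberately slow, loop-based and independent of the package's vectorised
construction code: candidate rules are enumerated with plain Python loops and
candidate trees are scored by walking each record through the cascade one
node at a time.  Used only on tiny instances.
"""

from __future__ import annotations

import itertools
from math import inf


def naive_metrics(decisions, labels, weight=0.5):
    hi = sum(1 for d, y in zip(decisions, labels) if d and y)
    mi = sum(1 for d, y in zip(decisions, labels) if not d and y)
    fa = sum(1 for d, y in zip(decisions, labels) if d and not y)
    cr = sum(1 for d, y in zip(decisions, labels) if not d and not y)
    sens = hi / (hi + mi)
    spec = cr / (cr + fa)
    return weight * sens + (1 - weight) * spec, sens, spec


def naive_best_rule(values, labels, weight=0.5):
    """Best (direction, threshold) over unique observed values, naive loops.

    Tie rule mirrors the implementation contract: higher goal, higher
    sensitivity, lower threshold, '>' before '<='.
    """
    best = None
    for threshold in sorted(set(values)):
        for direction in (">", "<="):
            decisions = [v > threshold if direction == ">" else v <= threshold
                         for v in values]
            goal, sens, _ = naive_metrics(decisions, labels, weight)
            key = (-goal, -sens, threshold, 0 if direction == ">" else 1)
            if best is None or key < best[0]:
                best = (key, direction, threshold, goal, sens)
    _, direction, threshold, goal, sens = best
    return direction, threshold, goal, sens


def walk_tree(nodes, row):
    """nodes: list of (cue, direction, threshold, exit_side); row: dict."""
    for i, (cue, direction, threshold, exit_side) in enumerate(nodes):
        v = row[cue]
        fired = v > threshold if direction == ">" else v <= threshold
        if exit_side == "both":
            return 1 if fired else 0
        if fired:
            return 1 if exit_side == "positive" else 0
    raise AssertionError("final node must decide")


def tree_goal(nodes, rows, labels, weight=0.5):
    decisions = [walk_tree(nodes, r) for r in rows]
    goal, _, _ = naive_metrics(decisions, labels, weight)
    return goal


def _as_exit_nodes(cue, direction, threshold, side):
    """The stored rule fires exactly for the cases exiting on `side`."""
    if side == "negative":
        flipped = "<=" if direction == ">" else ">"
        return (cue, flipped, threshold, "negative")
    return (cue, direction, threshold, side)


def ifan_oracle_goal(rows, labels, max_levels, weight=0.5):
    """Exhaustive search over rank-ordered cue prefixes x exit structures."""
    cues = sorted(rows[0].keys())
    ranked = []
    for cue in cues:
        values = [r[cue] for r in rows]
        direction, threshold, goal, sens = naive_best_rule(values, labels, weight)
        ranked.append(((-goal, -sens, threshold, 0 if direction == ">" else 1, cue),
                       cue, direction, threshold))
    ranked.sort(key=lambda x: x[0])
    top = ranked[:max_levels]
    best = -inf
    for k in range(1, len(top) + 1):
        for exits in itertools.product(("positive", "negative"), repeat=k - 1):
            nodes = [_as_exit_nodes(c, d, t, e)
                     for (_, c, d, t), e in zip(top[:k - 1], exits)]
            _, c, d, t = top[k - 1]
            nodes.append((c, d, t, "both"))
            best = max(best, tree_goal(nodes, rows, labels, weight))
    return best


def dfan_oracle_goal(rows, labels, max_levels, weight=0.5):
    """Exhaustive search over all cue orders x exit structures, with each
    node's threshold chosen conditionally on the cases remaining there."""
    cues = sorted(rows[0].keys())
    best = -inf
    for k in range(1, min(max_levels, len(cues)) + 1):
        for order in itertools.permutations(cues, k):
            for exits in itertools.product(("positive", "negative"), repeat=k - 1):
                nodes = []
                idx = list(range(len(rows)))
                ok = True
                for level, cue in enumerate(order):
                    sub_labels = [labels[i] for i in idx]
                    if not any(sub_labels) or all(sub_labels):
                        ok = False
                        break
                    values = [rows[i][cue] for i in idx]
                    direction, threshold, _, _ = naive_best_rule(
                        values, sub_labels, weight)
                    if level == k - 1:
                        nodes.append((cue, direction, threshold, "both"))
                    else:
                        node = _as_exit_nodes(cue, direction, threshold,
                                              exits[level])
                        nodes.append(node)
                        c, d, t, _ = node
                        idx = [i for i in idx
                               if not (rows[i][c] > t if d == ">" else rows[i][c] <= t)]
                if ok:
                    best = max(best, tree_goal(nodes, rows, labels, weight))
    return best


def dfan_greedy_goal(rows, labels, max_levels, weight=0.5):
    """Independent naive reimplementation of the conditional (dfan) builder.

    Mirrors the normative algorithm with plain loops: at each node the best
    unused cue on the remaining cases (same tie rule), branching over exit
    sides, candidates scored on the full data, ties resolved toward the
    shallower, earlier-enumerated tree.
    """
    cues = sorted(rows[0].keys())
    candidates = []  # (generation order, nodes)
    counter = itertools.count()

    def best_cue(idx, unused):
        best = None
        for cue in unused:
            values = [rows[i][cue] for i in idx]
            sub = [labels[i] for i in idx]
            direction, threshold, goal, sens = naive_best_rule(values, sub, weight)
            key = (-goal, -sens, threshold, 0 if direction == ">" else 1, cue)
            if best is None or key < best[0]:
                best = (key, cue, direction, threshold)
        return best[1], best[2], best[3]

    def recurse(prefix, idx, unused):
        cue, direction, threshold = best_cue(idx, unused)
        candidates.append((next(counter), prefix + [(cue, direction, threshold, "both")]))
        if len(prefix) + 1 >= max_levels or len(unused) <= 1:
            return
        rest = [c for c in unused if c != cue]
        for side in ("positive", "negative"):
            node = _as_exit_nodes(cue, direction, threshold, side)
            c, d, t, _ = node
            remaining = [i for i in idx
                         if not (rows[i][c] > t if d == ">" else rows[i][c] <= t)]
            sub = [labels[i] for i in remaining]
            if remaining and any(sub) and not all(sub):
                recurse(prefix + [node], remaining, rest)

    recurse([], list(range(len(rows))), cues)
    best_goal = None
    for _, nodes in sorted(candidates, key=lambda c: (len(c[1]), c[0])):
        goal = tree_goal(nodes, rows, labels, weight)
        if best_goal is None or goal > best_goal:
            best_goal = goal
    return best_goal
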