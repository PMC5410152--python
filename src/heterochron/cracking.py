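"""Event-pair cracking: from pair-character changes to per-event shifts.

A branch's event-pair character changes say how pairs reordered, not
which member of a pair actually moved.  Cracking decomposes them: each
changed pair (i, j) contributes its signed degree of change (+ means
event i shifted later relative to j) positively to event i and
negatively to event j; an event's total relative change (TRC) is the
average contribution over the changed pairs it participates in.  Events
whose TRC lies beyond the two-tailed 95% t interval around the node's
mean TRC are flagged heterochronic (strictly beyond — boundary values
are not flagged).

Branches supported by too few interacting pairs cannot separate signal
from the background pattern: a node is "crackable" only if some event
participates in at least two usable changes.  Set-valued reconstruction
endpoints are averaged when every consistent difference agrees in sign
(0 -> {1,2} gives +1.5) and excluded as direction-ambiguous otherwise
(1 -> {0,2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import t as student_t

from .report import HeterochronyRecord, HeterochronyReport

__all__ = [
    "PairChange",
    "CrackResult",
    "extract_branch_changes",
    "node_is_crackable",
    "crack_node",
    "flag_heterochronic_events",
    "crack_tree",
]


@dataclass(frozen=True)
class PairChange:
    node: str
    pair: tuple[int, int]
    parent_states: frozenset
    child_states: frozenset
    magnitude: float  # signed; + = first event of the pair shifts later
    excluded: bool = False
    reason: str = ""


def _parse_pair(char_id: str) -> tuple[int, int]:
    try:
        i, j = char_id.split("v")
        return int(i), int(j)
    except ValueError:
        raise ValueError(
            f"character id {char_id!r} is not an event-pair id ('<i>v<j>')"
        ) from None


def extract_branch_changes(reconstruction, node: str) -> list[PairChange]:
    """Convert a branch's reconstructed character changes into PairChanges.

    ``reconstruction`` is an MP or ML reconstruction of event-pair
    characters (anything with ``changes_at(node)`` yielding records with
    ``char_id``, ``parent_states`` and ``child_states``).
    """
    out: list[PairChange] = []
    for ch in reconstruction.changes_at(node):
        pair = _parse_pair(ch.char_id)
        diffs = sorted({c - p for c in ch.child_states for p in ch.parent_states})
        if diffs[0] < 0 < diffs[-1]:
            out.append(
                PairChange(node, pair, ch.parent_states, ch.child_states,
                           0.0, excluded=True, reason="direction-ambiguous")
            )
            continue
        out.append(
            PairChange(node, pair, ch.parent_states, ch.child_states,
                       float(np.mean(diffs)))
        )
    return out


def node_is_crackable(changes: list[PairChange]) -> bool:
    """True iff some event participates in >= 2 usable (non-excluded) changes."""
    seen: dict[int, int] = {}
    for ch in changes:
        if ch.excluded:
            continue
        for e in ch.pair:
            seen[e] = seen.get(e, 0) + 1
            if seen[e] >= 2:
                return True
    return False


@dataclass
class CrackResult:
    node: str
    trc: dict[int, float]  # event -> total relative change
    pair_counts: dict[int, int]  # event -> number of contributing changes
    mean_trc: float
    ci_lower: float  # nan when < 3 participating events
    ci_upper: float
    n_excluded: int = 0

    @property
    def ci_defined(self) -> bool:
        return not math.isnan(self.ci_lower)


def crack_node(changes: list[PairChange], level: float = 0.95) -> CrackResult:
    """Per-event TRC with a t interval over the participating events."""
    if not node_is_crackable(changes):
        raise ValueError("node is not crackable (insufficient interacting pairs)")
    node = changes[0].node
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_excluded = 0
    for ch in changes:
        if ch.excluded:
            n_excluded += 1
            continue
        i, j = ch.pair
        sums[i] = sums.get(i, 0.0) + ch.magnitude
        counts[i] = counts.get(i, 0) + 1
        sums[j] = sums.get(j, 0.0) - ch.magnitude
        counts[j] = counts.get(j, 0) + 1
    trc = {e: sums[e] / counts[e] for e in sorted(sums)}
    vals = np.array([trc[e] for e in sorted(trc)])
    mean = float(vals.mean())
    if len(vals) < 3:
        return CrackResult(node, trc, counts, mean, math.nan, math.nan, n_excluded)
    sd = float(vals.std(ddof=1))
    tq = float(student_t.ppf(0.5 + level / 2, len(vals) - 1))
    half = tq * sd / math.sqrt(len(vals))
    return CrackResult(node, trc, counts, mean, mean - half, mean + half, n_excluded)


def flag_heterochronic_events(result: CrackResult, method: str = "cracking") -> HeterochronyReport:
    """Flag events whose TRC lies strictly beyond the node's CI."""
    report = HeterochronyReport()
    if not result.ci_defined:
        return report
    for e in sorted(result.trc):
        v = result.trc[e]
        if v > result.ci_upper:
            direction = "later"
        elif v < result.ci_lower:
            direction = "earlier"
        else:
            continue
        report.records.append(
            HeterochronyRecord(result.node, str(e), direction, v,
                               result.ci_lower, result.ci_upper, method=method)
        )
    return report


def crack_tree(reconstruction, level: float = 0.95, method: str = "cracking"):
    """Crack every branch with enough signal; returns (results, report).

    Branches whose change set is not crackable are silently skipped, as
    are branches with no changes at all.
    """
    results: list[CrackResult] = []
    report = HeterochronyReport()
    for n in reconstruction.tree.preorder():
        if n.parent is None:
            continue
        changes = extract_branch_changes(reconstruction, n.label)
        if not changes or not node_is_crackable(changes):
            continue
        res = crack_node(changes, level=level)
        results.append(res)
        report.records.extend(flag_heterochronic_events(res, method=method))
    return results, report
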