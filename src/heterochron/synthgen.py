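"""Simulated developmental-sequence evolution with known heterochronies.

The neutral model is a Kendall walk: starting from the identity event
order at the root, each branch applies Poisson(swap_rate x length)
random adjacent transpositions.  Injected shifts — an event moved by a
stated signed number of positions on a stated branch — ride on top, so
detection effect size is controlled in sequence positions.  Ties
(simultaneous events), random missingness and inapplicable limb events
in designated limbless tips emulate the structure of real organogenesis
tables.  Every realized per-branch event displacement is logged so
detector output can be scored for precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .report import HeterochronyReport
from .seqdata import (
    INAPP_CODE,
    MISSING_CODE,
    Event,
    Phylogeny,
    TimelineMatrix,
)

__all__ = [
    "SimConfig",
    "Move",
    "TruthLog",
    "simulate_timelines",
    "apply_missingness",
    "evaluate_recovery",
    "RecoverySummary",
]


@dataclass(frozen=True)
class Move:
    event: int  # 1-based event index
    direction: str  # 'earlier' | 'later'
    magnitude: float  # positions moved


@dataclass
class SimConfig:
    tree: Phylogeny
    n_events: int = 10
    swap_rate: float = 0.5  # adjacent transpositions per unit branch length
    shifts: list[tuple[str, int, int]] = field(default_factory=list)  # (branch, event, +/- positions)
    tie_rate: float = 0.0
    missing_rate: float = 0.0
    limbless_tips: list[str] = field(default_factory=list)
    limb_events: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for r, name in ((self.swap_rate, "swap_rate"),):
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        for r, name in ((self.tie_rate, "tie_rate"), (self.missing_rate, "missing_rate")):
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for (_, ev, _) in self.shifts:
            if not 1 <= ev <= self.n_events:
                raise ValueError(f"shift event {ev} outside 1..{self.n_events}")


@dataclass
class TruthLog:
    """Realized per-branch moves, keyed by the branch's child-node label."""

    moves: dict[str, list[Move]] = field(default_factory=dict)
    injected: list[tuple[str, int, int]] = field(default_factory=list)

    def moves_at(self, branch: str) -> list[Move]:
        return self.moves.get(branch, [])


def _branch_moves(parent_seq: list[int], child_seq: list[int]) -> list[Move]:
    ppos = {e: i for i, e in enumerate(parent_seq)}
    out = []
    for i, e in enumerate(child_seq):
        d = i - ppos[e]
        if d:
            out.append(Move(e, "later" if d > 0 else "earlier", float(abs(d))))
    return out


def simulate_timelines(config: SimConfig) -> tuple[TimelineMatrix, TruthLog]:
    """Evolve event orders down the tree; returns timelines + truth log.

    Positions are 1..E at each tip before tie merging; with ``tie_rate``
    each inter-event boundary independently collapses, making the two
    neighbours simultaneous.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    E = config.n_events
    tree = config.tree
    shifts_by_branch: dict[str, list[tuple[int, int]]] = {}
    labels = {n.label for n in tree.preorder()}
    for (br, ev, d) in config.shifts:
        if br not in labels:
            raise KeyError(f"shift branch {br!r} not in tree")
        shifts_by_branch.setdefault(br, []).append((ev, d))

    seqs: dict[int, list[int]] = {id(tree.root): list(range(1, E + 1))}
    truth = TruthLog(injected=list(config.shifts))
    tip_seqs: dict[str, list[int]] = {}
    for n in tree.preorder():
        if n.parent is None:
            continue
        seq = list(seqs[id(n.parent)])
        ell = n.length if n.length is not None else 1.0
        for _ in range(rng.poisson(config.swap_rate * ell)):
            p = int(rng.integers(0, E - 1))
            seq[p], seq[p + 1] = seq[p + 1], seq[p]
        for (ev, d) in shifts_by_branch.get(n.label, []):
            i = seq.index(ev)
            j = int(np.clip(i + d, 0, E - 1))
            seq.pop(i)
            seq.insert(j, ev)
        seqs[id(n)] = seq
        mv = _branch_moves(seqs[id(n.parent)], seq)
        if mv:
            truth.moves[n.label] = mv
        if n.is_tip:
            tip_seqs[n.label] = seq

    species = tree.tip_labels()
    positions = np.zeros((len(species), E), dtype=np.int64)
    for si, sp in enumerate(species):
        seq = tip_seqs[sp]
        rank = np.empty(E, dtype=np.int64)
        merged = rng.random(E - 1) < config.tie_rate
        r = 1
        for i, ev in enumerate(seq):
            if i > 0 and not merged[i - 1]:
                r += 1
            rank[ev - 1] = r
        positions[si] = rank
    events = [Event(i + 1, f"E{i + 1}") for i in range(E)]
    return TimelineMatrix(species, events, positions), truth


def apply_missingness(timelines: TimelineMatrix, config: SimConfig) -> TimelineMatrix:
    """Knock out cells at ``missing_rate`` and blank limb events in
    limbless tips as inapplicable (seeded independently of the walk)."""
    rng = np.random.default_rng((config.seed, 1))
    out = timelines.copy()
    if config.missing_rate > 0:
        mask = rng.random(out.positions.shape) < config.missing_rate
        out.positions[mask] = MISSING_CODE
    for sp in config.limbless_tips:
        i = out.species.index(sp)
        for ev in config.limb_events:
            out.positions[i, ev - 1] = INAPP_CODE
    return out


@dataclass
class RecoverySummary:
    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    per_event: dict[int, tuple[int, int, int]]  # event -> (tp, fp, fn)


def evaluate_recovery(
    report: HeterochronyReport,
    truth: TruthLog,
    tolerance: float = 1.0,
    tree: Phylogeny | None = None,
    event_labels: list[str] | None = None,
) -> RecoverySummary:
    """Score a detector's flags against the truth log.

    A flag (where, event, direction) matches a truth move of magnitude
    >= ``tolerance`` on that branch in that direction.  If ``tree`` is
    given, a move on an internal branch is also credited to flags at its
    descendant tips (the continuous criterion flags terminal taxa).
    Empty report against empty truth scores precision = recall = 1.
    """
    label_to_idx = {}
    if event_labels:
        label_to_idx = {lbl: i + 1 for i, lbl in enumerate(event_labels)}

    def event_index(s: str) -> int | None:
        if s in label_to_idx:
            return label_to_idx[s]
        digits = "".join(ch for ch in s if ch.isdigit())
        return int(digits) if digits else None

    descendants: dict[str, set[str]] = {}
    if tree is not None:
        for n in tree.postorder():
            if n.is_tip:
                descendants[n.label] = {n.label}
            else:
                descendants[n.label] = set().union(
                    *(descendants[c.label] for c in n.children)
                )

    truth_keys = []  # (branch, event, direction)
    for br, moves in truth.moves.items():
        for m in moves:
            if m.magnitude >= tolerance:
                truth_keys.append((br, m.event, m.direction))

    def flag_matches(where: str, ev: int, direction: str, tk) -> bool:
        br, tev, tdir = tk
        if ev != tev or direction != tdir:
            return False
        if where == br:
            return True
        return tree is not None and where in descendants.get(br, ())

    tp = fp = 0
    matched = [False] * len(truth_keys)
    per_event: dict[int, list[int]] = {}
    for rec in report:
        ev = event_index(rec.event)
        hit = False
        for ti, tk in enumerate(truth_keys):
            if ev is not None and flag_matches(rec.where, ev, rec.direction, tk):
                matched[ti] = True
                hit = True
        bucket = per_event.setdefault(ev if ev is not None else -1, [0, 0, 0])
        if hit:
            tp += 1
            bucket[0] += 1
        else:
            fp += 1
            bucket[1] += 1
    fn = 0
    for ti, tk in enumerate(truth_keys):
        if not matched[ti]:
            fn += 1
            per_event.setdefault(tk[1], [0, 0, 0])[2] += 1
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if len(truth_keys) == 0 else sum(matched) / len(truth_keys)
    return RecoverySummary(
        precision, recall, tp, fp, fn,
        {e: tuple(v) for e, v in per_event.items()},
    )
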