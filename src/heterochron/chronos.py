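"""Branch-length assignment: unit lengths or fossil-calibrated node ages.

Calibrated analyses date nodes with the oldest fossil of a *total group*
(a lineage plus everything closer to it than to its sister), so a
calibration row naturally dates the **stem** of the named clade — the
node where that lineage splits from its sister.  Rows are therefore
resolved as the parent of the MRCA of the supplied tip set by default
(``stem=False`` selects the MRCA itself; a row whose resolved node is
the root dates the root).  Nodes without a calibration are aged bottom-up
as the oldest descendant age plus a fixed step (default 3 Ma) per
intervening branch; extant tips sit at age 0.  Branch lengths are then
parent age minus child age, which makes the tree ultrametric over tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqdata import Node, Phylogeny

__all__ = [
    "Calibration",
    "CalibrationTable",
    "CalibrationConflictError",
    "read_calibration_table",
    "unit_branch_lengths",
    "calibrate_branch_lengths",
]


class CalibrationConflictError(ValueError):
    """A calibrated node is no older than one of its (effective) children."""


@dataclass(frozen=True)
class Calibration:
    clade: str
    tips: tuple[str, ...]
    age_ma: float
    stem: bool = True
    note: str = ""

    def __post_init__(self):
        if self.age_ma <= 0:
            raise ValueError(f"calibration age must be positive ({self.clade})")
        if not self.tips:
            raise ValueError(f"calibration {self.clade} has no tips")


@dataclass
class CalibrationTable:
    rows: list[Calibration] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def read_calibration_table(path) -> CalibrationTable:
    """Load a CSV with columns clade, tips (;-separated), age_ma, [stem], [note]."""
    df = pd.read_csv(path, comment="#")
    rows = []
    for _, r in df.iterrows():
        tips = tuple(t.strip() for t in str(r["tips"]).split(";") if t.strip())
        stem = bool(r["stem"]) if "stem" in df.columns and not pd.isna(r.get("stem")) else True
        note = "" if "note" not in df.columns or pd.isna(r.get("note")) else str(r["note"])
        rows.append(Calibration(str(r["clade"]), tips, float(r["age_ma"]), stem, note))
    return CalibrationTable(rows)


def unit_branch_lengths(tree: Phylogeny) -> Phylogeny:
    """Return a copy with every branch length set to 1 (ages cleared)."""
    out = tree.copy()
    for n in out.preorder():
        n.age = None
        n.length = None if n.parent is None else 1.0
    return out


def _resolve_node(tree: Phylogeny, cal: Calibration) -> Node:
    missing = set(cal.tips) - set(tree.tip_labels())
    if missing:
        raise KeyError(f"calibration {cal.clade}: taxa not in tree: {sorted(missing)}")
    if len(cal.tips) == 1:
        node = tree.find(cal.tips[0])
    else:
        node = tree.mrca(list(cal.tips))
    if cal.stem:
        node = node.parent if node.parent is not None else node
    return node


def calibrate_branch_lengths(
    tree: Phylogeny,
    calibrations: CalibrationTable,
    default_step: float = 3.0,
    on_conflict: str = "error",
) -> Phylogeny:
    """Assign node ages from fossil calibrations and derive branch lengths.

    Calibrated node ages are used exactly (no smoothing).  Uncalibrated
    node age = max over children of (child age + ``default_step``), tips
    at age 0.  If several calibrations resolve to one node the oldest is
    kept with a warning.  A calibrated node that ends up no older than a
    child raises :class:`CalibrationConflictError`; ``on_conflict=
    'drop_younger'`` instead discards the younger conflicting calibration
    and retries (each drop is warned).
    """
    if on_conflict not in ("error", "drop_younger"):
        raise ValueError("on_conflict must be 'error' or 'drop_younger'")
    active = list(calibrations.rows)
    while True:
        try:
            return _calibrate(tree, active, default_step)
        except CalibrationConflictError as err:
            if on_conflict == "error" or err.drop_candidate is None:  # type: ignore[attr-defined]
                raise
            cand = err.drop_candidate  # type: ignore[attr-defined]
            warnings.warn(
                f"dropping conflicting calibration {cand.clade} ({cand.age_ma} Ma): {err}",
                stacklevel=2,
            )
            active = [c for c in active if c is not cand]


def _calibrate(tree: Phylogeny, cals: list[Calibration], step: float) -> Phylogeny:
    out = tree.copy()
    fixed: dict[int, tuple[float, Calibration]] = {}
    for cal in cals:
        node = _resolve_node(out, cal)
        if node.is_tip:
            raise ValueError(
                f"calibration {cal.clade} resolves to extant tip {node.label}; "
                "tips have age 0"
            )
        key = id(node)
        if key in fixed:
            old_age, old_cal = fixed[key]
            keep = cal if cal.age_ma > old_age else old_cal
            warnings.warn(
                f"calibrations {old_cal.clade} ({old_age} Ma) and {cal.clade} "
                f"({cal.age_ma} Ma) resolve to the same node; keeping the oldest",
                stacklevel=3,
            )
            fixed[key] = (keep.age_ma, keep)
        else:
            fixed[key] = (cal.age_ma, cal)

    # `source` tracks which calibration an age (possibly propagated upward
    # through +step increments) ultimately derives from, so a conflict can
    # name — and optionally drop — the responsible row.
    source: dict[int, Calibration | None] = {}
    for n in out.postorder():
        if n.is_tip:
            n.age = 0.0
            source[id(n)] = None
            continue
        oldest_child = max(n.children, key=lambda c: c.age)
        floor_age = oldest_child.age + step
        if id(n) in fixed:
            age, cal = fixed[id(n)]
            if age <= oldest_child.age:
                child_src = source[id(oldest_child)]
                err = CalibrationConflictError(
                    f"calibrated node {cal.clade} ({age} Ma) is not older than "
                    f"descendant aged {oldest_child.age} Ma"
                    + (f" (from {child_src.clade})" if child_src else "")
                )
                # drop whichever conflicting calibration is younger; a tie
                # drops the descendant (its +step propagation caused the clash)
                if child_src is not None and child_src.age_ma <= cal.age_ma:
                    err.drop_candidate = child_src  # type: ignore[attr-defined]
                else:
                    err.drop_candidate = cal  # type: ignore[attr-defined]
                raise err
            n.age = float(age)
            source[id(n)] = cal
        else:
            n.age = floor_age
            source[id(n)] = source[id(oldest_child)]
    for n in out.preorder():
        if n.parent is not None and n.parent.age <= n.age:
            # parent was calibrated below its children's propagated floor
            parent_src = source[id(n.parent)]
            child_src = source[id(n)]
            err = CalibrationConflictError(
                f"node {n.parent.label} ({n.parent.age} Ma) is not older than "
                f"child {n.label} ({n.age} Ma)"
            )
            cands = [c for c in (parent_src, child_src) if c is not None]
            err.drop_candidate = (  # type: ignore[attr-defined]
                min(cands, key=lambda c: c.age_ma) if cands else None
            )
            raise err
        n.length = None if n.parent is None else n.parent.age - n.age
    return out
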