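"""Domain types and I/O: developmental timelines, character matrices, trees.

A developmental timeline records, for each species, the ordinal stage at
which each organogenesis event (limb ridge, otic placode, ...) first
appears.  Equal stage numbers denote simultaneous events; ``?`` marks an
unobserved event and ``-`` an inapplicable one (e.g. limb events in
limbless taxa).  Timelines are encoded into discrete character matrices
downstream (:mod:`heterochron.encode`) and analysed on rooted phylogenies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "INAPPLICABLE",
    "MISSING_CODE",
    "INAPP_CODE",
    "Event",
    "TimelineMatrix",
    "CharacterMatrix",
    "Node",
    "Phylogeny",
    "read_timeline_table",
    "read_newick_tree",
    "write_character_matrix",
    "read_character_matrix",
    "prune_taxa",
]

UNKNOWN = "?"
INAPPLICABLE = "-"

# integer cell codes used throughout the package
MISSING_CODE = -1
INAPP_CODE = -2


@dataclass(frozen=True)
class Event:
    """A named developmental event with a 1-based index."""

    index: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"event index must be >= 1, got {self.index}")


class TimelineMatrix:
    """Species x event table of ordinal stage positions.

    Cells hold a positive integer position, ``?`` (unknown) or ``-``
    (inapplicable).  Internally positions are an int array with
    :data:`MISSING_CODE` / :data:`INAPP_CODE` sentinels.
    """

    def __init__(self, species: list[str], events: list[Event], positions: np.ndarray):
        if len(set(species)) != len(species):
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise ValueError(f"duplicate species labels: {dupes}")
        idx = [e.index for e in events]
        if idx != list(range(1, len(events) + 1)):
            raise ValueError("event indices must be contiguous from 1")
        positions = np.asarray(positions, dtype=np.int64)
        if positions.shape != (len(species), len(events)):
            raise ValueError(
                f"positions shape {positions.shape} != ({len(species)}, {len(events)})"
            )
        bad = (positions < 1) & (positions != MISSING_CODE) & (positions != INAPP_CODE)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid position {positions[i, j]} for species "
                f"{species[i]!r}, event {events[j].index}"
            )
        self.species = list(species)
        self.events = list(events)
        self.positions = positions

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def position(self, species: str, event_index: int):
        """Return the recorded position, ``'?'`` or ``'-'`` for one cell."""
        v = int(self.positions[self.species.index(species), event_index - 1])
        if v == MISSING_CODE:
            return UNKNOWN
        if v == INAPP_CODE:
            return INAPPLICABLE
        return v

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame of strings (the on-disk dialect)."""
        cells = np.empty(self.positions.shape, dtype=object)
        for i in range(self.n_species):
            for j in range(self.n_events):
                v = self.positions[i, j]
                cells[i, j] = UNKNOWN if v == MISSING_CODE else (
                    INAPPLICABLE if v == INAPP_CODE else str(int(v))
                )
        return pd.DataFrame(
            cells, index=self.species, columns=[e.label or f"event_{e.index}" for e in self.events]
        )

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="species")

    def copy(self) -> "TimelineMatrix":
        return TimelineMatrix(self.species, self.events, self.positions.copy())


def read_timeline_table(path, dialect: str = "auto") -> TimelineMatrix:
    """Load a delimited timeline table (rows = species, columns = events).

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``"auto"`` (sniff from the
    extension, falling back to comma).  Cells must be positive integers,
    ``?`` or ``-``; anything else raises with the offending coordinates.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    species = [str(s) for s in df.index]
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(f"duplicate species label(s) in {path}: {dupes}")
    events = [Event(j + 1, str(c)) for j, c in enumerate(df.columns)]
    pos = np.empty(df.shape, dtype=np.int64)
    for i, sp in enumerate(species):
        for j, col in enumerate(df.columns):
            raw = str(df.iat[i, j]).strip()
            if raw == UNKNOWN or raw.lower() == "nan":
                pos[i, j] = MISSING_CODE
            elif raw == INAPPLICABLE:
                pos[i, j] = INAPP_CODE
            else:
                try:
                    pos[i, j] = int(raw)
                except ValueError:
                    raise ValueError(
                        f"non-integer cell {raw!r} at species {sp!r}, column {col!r}"
                    ) from None
    return TimelineMatrix(species, events, pos)


class CharacterMatrix:
    """Taxa x discrete characters with states 0-9, ``?`` and ``-``.

    ``states`` is an int8 array using :data:`MISSING_CODE` / :data:`INAPP_CODE`.
    """

    SYMBOLS = "0123456789"

    def __init__(
        self,
        taxa: list[str],
        char_ids: list[str],
        states: np.ndarray,
        ordered: bool = False,
    ):
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(taxa), len(char_ids)):
            raise ValueError("states shape mismatch")
        if ((states > 9) | ((states < 0) & (states != MISSING_CODE) & (states != INAPP_CODE))).any():
            raise ValueError("states must be 0..9, '?' or '-'")
        self.taxa = list(taxa)
        self.char_ids = [str(c) for c in char_ids]
        self.states = states
        self.ordered = bool(ordered)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.char_ids)

    def row_string(self, i: int) -> str:
        out = []
        for v in self.states[i]:
            out.append(UNKNOWN if v == MISSING_CODE else (INAPPLICABLE if v == INAPP_CODE else str(int(v))))
        return "".join(out)

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        rows = [self.taxa.index(t) for t in keep]
        return CharacterMatrix(keep, self.char_ids, self.states[rows], self.ordered)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.char_ids == other.char_ids
            and np.array_equal(self.states, other.states)
        )


def _sanitize(label: str) -> str:
    return label.replace(" ", "_")


def write_character_matrix(matrix: CharacterMatrix, format: str = "tnt") -> str:
    """Serialise a matrix as a TNT ``xread`` or NEXUS ``data`` block.

    Round-trip safe with :func:`read_character_matrix`, including ``?``
    and ``-`` cells.  States above 9 are rejected (single-symbol blocks).
    """
    fmt = format.lower()
    if (matrix.states > 9).any():
        raise ValueError("states > 9 not representable in a single-symbol block")
    name_w = max(len(_sanitize(t)) for t in matrix.taxa) + 2
    rows = [
        f"{_sanitize(t):<{name_w}}{matrix.row_string(i)}" for i, t in enumerate(matrix.taxa)
    ]
    if fmt == "tnt":
        lines = [
            "xread",
            f"'{matrix.n_chars} characters, {matrix.n_taxa} taxa'",
            f"{matrix.n_chars} {matrix.n_taxa}",
            *rows,
            ";",
        ]
        # additivity declaration: ccode + = ordered (additive), - = unordered
        sign = "+" if matrix.ordered else "-"
        lines.append(f"ccode {sign} 0.{matrix.n_chars - 1};")
        lines.append("proc /;")
        return "\n".join(lines) + "\n"
    if fmt == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
            "    MATRIX",
            *("        " + r for r in rows),
            "    ;",
            "END;",
            "BEGIN ASSUMPTIONS;",
            "    TYPESET * default = {}: 1-{};".format(
                "ord" if matrix.ordered else "unord", matrix.n_chars
            ),
            "END;",
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r} (expected 'tnt' or 'nexus')")


def _parse_rows(row_lines: list[str]) -> tuple[list[str], np.ndarray]:
    taxa, rows = [], []
    for ln in row_lines:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"malformed matrix row: {ln!r}")
        name, seq = parts
        taxa.append(name)
        row = []
        for ch in seq:
            if ch == UNKNOWN:
                row.append(MISSING_CODE)
            elif ch == INAPPLICABLE:
                row.append(INAPP_CODE)
            elif ch.isdigit():
                row.append(int(ch))
            else:
                raise ValueError(f"unexpected state symbol {ch!r} in row for {name}")
        rows.append(row)
    return taxa, np.array(rows, dtype=np.int8)


def read_character_matrix(text: str) -> CharacterMatrix:
    """Parse a TNT or NEXUS block produced by :func:`write_character_matrix`."""
    stripped = text.strip()
    if stripped.lower().startswith("#nexus"):
        lines = [ln.strip() for ln in stripped.splitlines()]
        try:
            start = next(i for i, ln in enumerate(lines) if ln.upper() == "MATRIX") + 1
        except StopIteration:
            raise ValueError("no MATRIX section found") from None
        end = next(i for i in range(start, len(lines)) if lines[i] == ";")
        taxa, states = _parse_rows([ln for ln in lines[start:end] if ln])
        ordered = "default = ord" in stripped
    elif stripped.lower().startswith("xread"):
        lines = [ln.strip() for ln in stripped.splitlines()]
        body = [ln for ln in lines[1:] if ln and not ln.startswith("'")]
        dims = body[0].split()
        nchar, ntax = int(dims[0]), int(dims[1])
        row_lines = []
        for ln in body[1:]:
            if ln == ";" or ln.startswith("ccode") or ln.startswith("proc"):
                break
            row_lines.append(ln)
        taxa, states = _parse_rows(row_lines)
        if len(taxa) != ntax or states.shape[1] != nchar:
            raise ValueError("declared dimensions do not match matrix body")
        ordered = "ccode +" in stripped
    else:
        raise ValueError("unrecognised character matrix format")
    char_ids = [str(i + 1) for i in range(states.shape[1])]
    return CharacterMatrix(taxa, char_ids, states, ordered)


# ---------------------------------------------------------------------------
# Trees


class Node:
    """One node of a rooted :class:`Phylogeny`."""

    __slots__ = ("label", "length", "age", "children", "parent")

    def __init__(self, label: str = "", length: float | None = None):
        self.label = label
        self.length = length
        self.age: float | None = None
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with optional branch lengths and node ages.

    Unlabeled internal nodes are auto-named ``N<preorder index>`` so
    reconstructions are addressable across runs.
    """

    def __init__(self, root: Node, outgroup: str | None = None):
        self.root = root
        self.outgroup = outgroup
        self._autoname()
        tips = self.tip_labels()
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels in tree")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def postorder(self) -> list[Node]:
        return list(reversed([n for n in self._preorder_rl()]))

    def _preorder_rl(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def find(self, label: str) -> Node:
        for n in self.preorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def mrca(self, labels: list[str]) -> Node:
        want = set(labels)
        missing = want - set(self.tip_labels())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        # smallest node whose tip set covers `want`
        cover: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_tip:
                cover[id(n)] = {n.label}
            else:
                cover[id(n)] = set().union(*(cover[id(c)] for c in n.children))
        best = self.root
        for n in self.postorder():
            if want <= cover[id(n)]:
                return n
        return best

    def _autoname(self) -> None:
        for i, n in enumerate(self.preorder()):
            if not n.is_tip and not n.label:
                n.label = f"N{i}"

    # -- construction / serialisation --------------------------------------
    @classmethod
    def from_newick(cls, text: str, outgroup: str | None = None) -> "Phylogeny":
        dt = dendropy.Tree.get(data=text, schema="newick")

        def conv(dn) -> Node:
            lbl = ""
            if dn.taxon is not None:
                lbl = dn.taxon.label.replace(" ", "_")
            elif dn.label:
                lbl = str(dn.label).replace(" ", "_")
            node = Node(lbl, dn.edge.length)
            for ch in dn.child_nodes():
                node.add_child(conv(ch))
            return node

        return cls(conv(dt.seed_node), outgroup=outgroup)

    def to_newick(self, lengths: bool = True, internal_labels: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_tip:
                s = n.label
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if internal_labels:
                    s += n.label
            if lengths and n.length is not None and n.parent is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Phylogeny":
        def dup(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.age = n.age
            for c in n.children:
                m.add_child(dup(c))
            return m

        return Phylogeny(dup(self.root), outgroup=self.outgroup)

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())


def read_newick_tree(path, companion_taxa: list[str] | None = None,
                     outgroup: str | None = None) -> tuple[Phylogeny, list[str]]:
    """Read a rooted newick tree; returns ``(tree, warnings)``.

    If ``companion_taxa`` is given, tree tips absent from it are listed in
    the warnings rather than raising.
    """
    with open(path) as fh:
        text = fh.read()
    tree = Phylogeny.from_newick(text, outgroup=outgroup)
    warnings: list[str] = []
    if companion_taxa is not None:
        extra = sorted(set(tree.tip_labels()) - set(companion_taxa))
        warnings = [f"tree taxon {t!r} absent from companion matrix" for t in extra]
    return tree, warnings


def prune_taxa(tree: Phylogeny, drop: list[str]) -> Phylogeny:
    """Remove the named tips, suppressing degree-2 nodes (lengths summed).

    If the root is left with one child, that child becomes the root (its
    own edge length is discarded, as a root has no incoming branch).
    """
    present = set(tree.tip_labels())
    missing = set(drop) - present
    if missing:
        raise KeyError(f"cannot prune absent taxa: {sorted(missing)}")
    if len(present) - len(set(drop)) < 2:
        raise ValueError("pruning would leave fewer than 2 tips")
    out = tree.copy()
    dropset = set(drop)

    def rec(n: Node) -> Node | None:
        if n.is_tip:
            return None if n.label in dropset else n
        kept = []
        for c in n.children:
            r = rec(c)
            if r is not None:
                kept.append(r)
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            # splice this node out, summing branch lengths
            if child.length is not None and n.length is not None:
                child.length = child.length + n.length
            elif n.length is not None and child.length is None:
                child.length = n.length
            return child
        n.children = []
        for c in kept:
            n.add_child(c)
        return n

    new_root = rec(out.root)
    assert new_root is not None
    if len(new_root.children) == 1:  # pruning collapsed the root
        new_root = new_root.children[0]
    new_root.parent = None
    new_root.length = None
    og = out.outgroup if out.outgroup not in dropset else None
    return Phylogeny(new_root, outgroup=og)
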