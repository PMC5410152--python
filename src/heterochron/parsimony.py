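"""Parsimony analysis: tree lengths, reconstructions, search, topology tests.

Unordered (non-additive) characters are scored by Fitch's algorithm;
ordered (additive) characters by Sankoff dynamic programming with
|a - b| step costs (equivalently Farris intervals inside the search).
``?`` and ``-`` are both treated as full ambiguity.  Ensemble consistency
(CI) and retention (RI) indices follow the standard definitions
CI = sum(m_i)/sum(s_i) and RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i)),
where m_i is the minimum conceivable steps of character i, s_i its steps
on the tree and g_i its maximum steps on a star tree.

The heuristic search mirrors a "traditional search": seeded
random-addition Wagner builds followed by tree bisection-reconnection
(TBR) to a local optimum, holding a bounded number of equally short
trees per replicate and pooling unique topologies at the global best
length.  An exhaustive enumerator over all unrooted topologies is
provided as an oracle for small taxon sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .seqdata import INAPP_CODE, MISSING_CODE, CharacterMatrix, Node, Phylogeny

__all__ = [
    "TreeScore",
    "SearchConfig",
    "SearchResult",
    "TempletonResult",
    "BranchChange",
    "MPReconstruction",
    "tree_length",
    "fitch_lengths",
    "sankoff_lengths",
    "per_character_lengths",
    "mp_reconstruct",
    "heuristic_search",
    "exhaustive_search",
    "consensus",
    "templeton_test",
    "wilcoxon_signed_rank",
]

_K = 10  # global state alphabet 0..9
_INF = np.float64(1e18)


# ---------------------------------------------------------------------------
# scores


@dataclass
class TreeScore:
    total_length: int
    per_character: np.ndarray
    ci: float
    ri: float

    def __post_init__(self):
        assert self.total_length == int(self.per_character.sum())


def _check_tips(matrix: CharacterMatrix, tree: Phylogeny) -> list[str]:
    tips = tree.tip_labels()
    missing = [t for t in tips if t not in matrix.taxa]
    if missing:
        raise KeyError(f"tree tips missing from matrix: {missing}")
    return tips


def _tip_rows(matrix: CharacterMatrix, tips: list[str]) -> np.ndarray:
    return matrix.states[[matrix.taxa.index(t) for t in tips]]


def sankoff_lengths(matrix: CharacterMatrix, tree: Phylogeny, ordered: bool) -> np.ndarray:
    """Per-character minimum steps by Sankoff DP (handles polytomies)."""
    tips = _check_tips(matrix, tree)
    states = _tip_rows(matrix, tips)  # (n_tips, n_chars)
    tip_idx = {t: i for i, t in enumerate(tips)}
    C = matrix.n_chars
    # cost[s] per node, vectorised over characters: shape (C, K)
    cost: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_tip:
            s = states[tip_idx[n.label]]
            m = np.full((C, _K), _INF)
            amb = (s == MISSING_CODE) | (s == INAPP_CODE)
            m[amb] = 0.0
            obs = ~amb
            m[np.where(obs)[0], s[obs].astype(int)] = 0.0
            cost[id(n)] = m
        else:
            acc = np.zeros((C, _K))
            for c in n.children:
                acc += _min_transition(cost.pop(id(c)), ordered)
            cost[id(n)] = acc
    root = cost[id(tree.root)]
    return root.min(axis=1).astype(np.int64)


def _min_transition(child_cost: np.ndarray, ordered: bool) -> np.ndarray:
    """min over child state s' of cost[s'] + w(s, s') for each parent state s."""
    if not ordered:
        overall = child_cost.min(axis=1, keepdims=True)
        return np.minimum(child_cost, overall + 1.0)
    # |a-b| cost: distance transform along the state axis
    out = child_cost.copy()
    for s in range(1, _K):
        np.minimum(out[:, s], out[:, s - 1] + 1.0, out=out[:, s])
    for s in range(_K - 2, -1, -1):
        np.minimum(out[:, s], out[:, s + 1] + 1.0, out=out[:, s])
    return out


def fitch_lengths(matrix: CharacterMatrix, tree: Phylogeny) -> np.ndarray:
    """Per-character Fitch steps (unordered); requires a binary tree."""
    if not tree.is_binary():
        raise ValueError("Fitch pass requires a fully bifurcating tree")
    tips = _check_tips(matrix, tree)
    states = _tip_rows(matrix, tips)
    tip_idx = {t: i for i, t in enumerate(tips)}
    C = matrix.n_chars
    full = np.uint16((1 << _K) - 1)
    steps = np.zeros(C, dtype=np.int64)
    mask: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_tip:
            s = states[tip_idx[n.label]]
            m = np.where(s >= 0, (1 << s.clip(min=0).astype(np.uint16)), full).astype(np.uint16)
            mask[id(n)] = m
        else:
            a = mask.pop(id(n.children[0]))
            b = mask.pop(id(n.children[1]))
            inter = a & b
            empty = inter == 0
            steps += empty
            mask[id(n)] = np.where(empty, a | b, inter)
    return steps


def per_character_lengths(matrix: CharacterMatrix, tree: Phylogeny, ordered: bool) -> np.ndarray:
    """Dispatch: Fitch for unordered binary trees, Sankoff otherwise."""
    if not ordered and tree.is_binary():
        return fitch_lengths(matrix, tree)
    return sankoff_lengths(matrix, tree, ordered)


def _char_min_steps(states: np.ndarray, ordered: bool) -> np.ndarray:
    """m_i: minimum conceivable steps per character (star-free lower bound)."""
    C = states.shape[1]
    m = np.zeros(C, dtype=np.int64)
    for c in range(C):
        col = states[:, c]
        obs = col[col >= 0]
        if obs.size == 0:
            continue
        m[c] = (obs.max() - obs.min()) if ordered else (len(np.unique(obs)) - 1)
    return m


def _char_max_steps_star(states: np.ndarray, ordered: bool) -> np.ndarray:
    """g_i: steps on a star tree with the best single root state."""
    C = states.shape[1]
    g = np.zeros(C, dtype=np.int64)
    for c in range(C):
        col = states[:, c]
        obs = col[col >= 0]
        if obs.size == 0:
            continue
        if ordered:
            g[c] = min(int(np.abs(obs - r).sum()) for r in range(obs.min(), obs.max() + 1))
        else:
            _, counts = np.unique(obs, return_counts=True)
            g[c] = int(obs.size - counts.max())
    return g


def tree_length(matrix: CharacterMatrix, tree: Phylogeny, ordered: bool | None = None) -> TreeScore:
    """Total parsimony length plus ensemble CI and RI on the given tree."""
    if ordered is None:
        ordered = matrix.ordered
    per_char = per_character_lengths(matrix, tree, ordered)
    tips = tree.tip_labels()
    states = _tip_rows(matrix, tips)
    m = _char_min_steps(states, ordered)
    g = _char_max_steps_star(states, ordered)
    s_sum, m_sum, g_sum = int(per_char.sum()), int(m.sum()), int(g.sum())
    ci = 1.0 if s_sum == 0 else m_sum / s_sum
    ri = 1.0 if g_sum == m_sum else (g_sum - s_sum) / (g_sum - m_sum)
    return TreeScore(s_sum, per_char, ci, ri)


# ---------------------------------------------------------------------------
# most-parsimonious reconstruction


@dataclass(frozen=True)
class BranchChange:
    """A character change on the branch into ``node`` (child end)."""

    node: str
    char_index: int
    char_id: str
    parent_states: frozenset
    child_states: frozenset


@dataclass
class MPReconstruction:
    """Per-node most-parsimonious state sets and the implied branch changes.

    ``node_states[label][c]`` is the set of states at that node that occur
    in at least one most-parsimonious reconstruction of character ``c``
    (the MPR set).  A change is listed for a branch only when the parent
    and child MPR sets are disjoint, i.e. every most-parsimonious
    reconstruction implies a change there — the conservative
    ACCTRAN/DELTRAN intersection.
    """

    tree: Phylogeny
    ordered: bool
    char_ids: list[str]
    node_states: dict[str, list[frozenset]]
    changes: list[BranchChange]
    char_lengths: np.ndarray

    def changes_at(self, node_label: str) -> list[BranchChange]:
        return [ch for ch in self.changes if ch.node == node_label]


def mp_reconstruct(matrix: CharacterMatrix, tree: Phylogeny, ordered: bool | None = None) -> MPReconstruction:
    """Sankoff down/up pass giving exact MPR sets per node and character."""
    if ordered is None:
        ordered = matrix.ordered
    tips = _check_tips(matrix, tree)
    states = _tip_rows(matrix, tips)
    tip_idx = {t: i for i, t in enumerate(tips)}
    C = matrix.n_chars
    post = tree.postorder()
    pre = tree.preorder()

    def w(a: np.ndarray) -> np.ndarray:
        return _min_transition(a, ordered)

    down: dict[int, np.ndarray] = {}
    for n in post:
        if n.is_tip:
            s = states[tip_idx[n.label]]
            m = np.full((C, _K), _INF)
            amb = (s == MISSING_CODE) | (s == INAPP_CODE)
            m[amb] = 0.0
            obs = ~amb
            m[np.where(obs)[0], s[obs].astype(int)] = 0.0
            down[id(n)] = m
        else:
            down[id(n)] = sum(w(down[id(c)]) for c in n.children)

    # Root preference: among equally parsimonious root states, keep those
    # matching the outgroup tip's state (standard outgroup rooting); the
    # up pass is then conditioned on that restricted root set.
    root_u = np.zeros((C, _K))
    if tree.outgroup is not None and tree.outgroup in tip_idx:
        og = states[tip_idx[tree.outgroup]]
        droot = down[id(tree.root)]
        best = droot.min(axis=1, keepdims=True)
        mpr_root = droot <= best + 1e-9
        for c in range(C):
            s = int(og[c])
            if s >= 0 and mpr_root[c, s]:
                root_u[c, :] = _INF
                root_u[c, s] = 0.0

    up: dict[int, np.ndarray] = {id(tree.root): root_u}
    for n in pre:
        if not n.children:
            continue
        contribs = {id(c): w(down[id(c)]) for c in n.children}
        total = sum(contribs.values())
        base = up[id(n)]
        for c in n.children:
            # parent-state cost of everything except subtree c
            rest = base + total - contribs[id(c)]
            up[id(c)] = w(rest)  # symmetric costs: same transform

    lengths = (down[id(tree.root)] + up[id(tree.root)]).min(axis=1)
    # per-character admissible states: observed set (unordered) or the
    # observed min..max range (ordered); keeps tie states inside the alphabet
    allowed = np.zeros((C, _K), dtype=bool)
    for c in range(C):
        col = states[:, c]
        obs = col[col >= 0]
        if obs.size == 0:
            allowed[c, :] = True
        elif ordered:
            allowed[c, obs.min(): obs.max() + 1] = True
        else:
            allowed[c, np.unique(obs)] = True
    node_states: dict[str, list[frozenset]] = {}
    for n in pre:
        tot = down[id(n)] + up[id(n)]
        best = tot.min(axis=1)
        sets = []
        for c in range(C):
            ok = (tot[c] <= best[c] + 1e-9) & allowed[c]
            if not ok.any():
                ok = tot[c] <= best[c] + 1e-9
            sets.append(frozenset(int(s) for s in np.where(ok)[0]))
        node_states[n.label] = sets

    changes: list[BranchChange] = []
    for n in pre:
        if n.parent is None:
            continue
        ps, cs = node_states[n.parent.label], node_states[n.label]
        for c in range(C):
            if not (ps[c] & cs[c]):
                changes.append(
                    BranchChange(n.label, c, matrix.char_ids[c], ps[c], cs[c])
                )
    return MPReconstruction(
        tree, ordered, list(matrix.char_ids), node_states, changes,
        lengths.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# adjacency-based heuristic search

# Unrooted trees are held as adjacency lists over node ids: tips are matrix
# row indices 0..n-1, internal nodes n..2n-3.  Scoring roots the tree at
# tip 0 (all internal nodes then have exactly two children).


class _SearchData:
    def __init__(self, matrix: CharacterMatrix, ordered: bool):
        self.n = matrix.n_taxa
        self.ordered = ordered
        s = matrix.states
        if ordered:
            lo = np.where(s >= 0, s, 0).astype(np.int16)
            hi = np.where(s >= 0, s, _K - 1).astype(np.int16)
            self.lo, self.hi = lo, hi
        else:
            full = np.uint16((1 << _K) - 1)
            self.masks = np.where(
                s >= 0, (1 << s.clip(min=0).astype(np.uint16)), full
            ).astype(np.uint16)

    def score(self, adj: list[list[int]]) -> int:
        root_tip = next(i for i in range(self.n) if adj[i])
        order, kids = _postorder_from_tip(adj, root_tip)
        if self.ordered:
            return self._score_farris(order, kids, root_tip)
        return self._score_fitch(order, kids, root_tip)

    def _score_fitch(self, order, kids, root_tip) -> int:
        mask: dict[int, np.ndarray] = {}
        steps = 0
        for v in order:
            ch = kids[v]
            if not ch:
                mask[v] = self.masks[v]
                continue
            a, b = mask[ch[0]], mask[ch[1]]
            inter = a & b
            empty = inter == 0
            steps += int(empty.sum())
            mask[v] = np.where(empty, a | b, inter)
        # join the root tip itself
        a, b = mask[order[-1]], self.masks[root_tip]
        steps += int(((a & b) == 0).sum())
        return steps

    def _score_farris(self, order, kids, root_tip) -> int:
        lo: dict[int, np.ndarray] = {}
        hi: dict[int, np.ndarray] = {}
        steps = 0
        for v in order:
            ch = kids[v]
            if not ch:
                lo[v], hi[v] = self.lo[v], self.hi[v]
                continue
            l1, h1, l2, h2 = lo[ch[0]], hi[ch[0]], lo[ch[1]], hi[ch[1]]
            mlo = np.maximum(l1, l2)
            mhi = np.minimum(h1, h2)
            gap = mlo - mhi
            sep = gap > 0
            steps += int(gap[sep].sum())
            lo[v] = np.where(sep, mhi, mlo)
            hi[v] = np.where(sep, mlo, mhi)
        l1, h1 = lo[order[-1]], hi[order[-1]]
        l2, h2 = self.lo[root_tip], self.hi[root_tip]
        gap = np.maximum(l1, l2) - np.minimum(h1, h2)
        steps += int(gap[gap > 0].sum())
        return steps


def _postorder_from_tip(adj: list[list[int]], root_tip: int):
    """Postorder node list (excluding the root tip) and children map."""
    start = adj[root_tip][0]
    parent = {start: root_tip}
    order = []
    stack = [start]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in adj[v]:
            if u != parent[v]:
                parent[u] = v
                stack.append(u)
    order.reverse()
    kids = {v: [u for u in adj[v] if u != parent[v]] for v in order}
    return order, kids


def _edges(adj: list[list[int]], nodes=None) -> list[tuple[int, int]]:
    src = range(len(adj)) if nodes is None else nodes
    out = []
    for a in src:
        for b in adj[a]:
            if a < b and (nodes is None or b in nodes):
                out.append((a, b))
    return sorted(out)


def _component(adj: list[list[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _splits_key(adj: list[list[int]], n_taxa: int) -> frozenset:
    """Canonical topology key: the set of tip bipartition sides without tip 0."""
    order, kids = _postorder_from_tip(adj, 0)
    below: dict[int, frozenset] = {}
    splits = set()
    for v in order:
        if not kids[v]:
            below[v] = frozenset([v])
        else:
            below[v] = frozenset().union(*(below[c] for c in kids[v]))
            if 1 < len(below[v]) < n_taxa - 1:
                splits.add(below[v])
    return frozenset(splits)


def _copy_adj(adj: list[list[int]]) -> list[list[int]]:
    return [list(v) for v in adj]


def _insert_tip(adj, tip, edge, new_internal):
    a, b = edge
    adj[a].remove(b)
    adj[b].remove(a)
    adj[a].append(new_internal)
    adj[b].append(new_internal)
    adj[new_internal] = [a, b, tip]
    adj[tip] = [new_internal]


def _remove_tip(adj, tip, new_internal, edge):
    a, b = edge
    adj[a].remove(new_internal)
    adj[b].remove(new_internal)
    adj[a].append(b)
    adj[b].append(a)
    adj[new_internal] = []
    adj[tip] = []


def _wagner_build(order: np.ndarray, data: _SearchData) -> list[list[int]]:
    """Greedy stepwise addition in the given taxon order."""
    n = data.n
    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
    t0, t1, t2 = (int(x) for x in order[:3])
    first_internal = n
    adj[first_internal] = [t0, t1, t2]
    for t in (t0, t1, t2):
        adj[t] = [first_internal]
    next_internal = n + 1
    for k in range(3, n):
        t = int(order[k])
        best, best_edge = None, None
        for e in _edges(adj):
            _insert_tip(adj, t, e, next_internal)
            L = data.score(adj)
            _remove_tip(adj, t, next_internal, e)
            if best is None or L < best:
                best, best_edge = L, e
        _insert_tip(adj, t, best_edge, next_internal)
        next_internal += 1
    return adj


def _tbr_neighbors(adj: list[list[int]]):
    """Yield all tree bisection-reconnection neighbours (as fresh copies)."""
    for (u, v) in _edges(adj):
        base = _copy_adj(adj)
        base[u].remove(v)
        base[v].remove(u)

        def _prep(side: int):
            # -> (attach-point-or-None, reusable node id, component member)
            if not base[side]:  # isolated tip
                return ("node", side), None, side
            a, b = base[side]  # degree-2 internal: splice out
            base[a].remove(side)
            base[b].remove(side)
            base[a].append(b)
            base[b].append(a)
            base[side] = []
            return None, side, a

        pt_u, free_u, rep_u = _prep(u)
        pt_v, free_v, rep_v = _prep(v)
        pts_u = [pt_u] if pt_u else [
            ("edge", e) for e in _edges(base, _component(base, rep_u))
        ]
        pts_v = [pt_v] if pt_v else [
            ("edge", e) for e in _edges(base, _component(base, rep_v))
        ]
        for p1 in pts_u:
            for p2 in pts_v:
                cand = _copy_adj(base)
                r1 = _attach(cand, p1, free_u)
                r2 = _attach(cand, p2, free_v)
                cand[r1].append(r2)
                cand[r2].append(r1)
                yield cand


def _attach(adj, point, free_id) -> int:
    kind, val = point
    if kind == "node":
        return val
    a, b = val
    adj[a].remove(b)
    adj[b].remove(a)
    adj[a].append(free_id)
    adj[b].append(free_id)
    adj[free_id] = [a, b]
    return free_id


@dataclass
class SearchConfig:
    replicates: int = 10
    hold: int = 10
    seed: int = 0
    ordered: bool = False
    outgroup: str | None = None

    def __post_init__(self):
        if self.replicates < 1 or self.hold < 1:
            raise ValueError("replicates and hold must be >= 1")


@dataclass
class SearchResult:
    best_length: int
    trees: list[Phylogeny]
    score: TreeScore
    log: list[int] = field(default_factory=list)


def _adj_to_phylogeny(adj: list[list[int]], taxa: list[str], outgroup: str | None) -> Phylogeny:
    n = len(taxa)
    root_tip = taxa.index(outgroup) if outgroup else 0
    order, kids = _postorder_from_tip(adj, root_tip)

    def build(v: int) -> Node:
        node = Node(taxa[v] if v < n else "")
        for c in kids[v]:
            node.add_child(build(c))
        return node

    root = Node("")
    root.add_child(Node(taxa[root_tip]))
    root.add_child(build(order[-1]))
    return Phylogeny(root, outgroup=taxa[root_tip] if outgroup else None)


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig | None = None) -> SearchResult:
    """Random-addition Wagner builds + TBR, pooled best trees (seeded)."""
    config = config or SearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    data = _SearchData(matrix, config.ordered)
    global_best: int | None = None
    pool: dict[frozenset, list[list[int]]] = {}
    log: list[int] = []
    for rep in range(config.replicates):
        rng = np.random.default_rng([config.seed % (2**31), rep])
        order = rng.permutation(matrix.n_taxa)
        adj = _wagner_build(order, data)
        best, held = _tbr_to_optimum(adj, data, config.hold)
        log.append(best)
        if global_best is None or best < global_best:
            global_best = best
            pool = dict(held)
        elif best == global_best:
            for k, t in held.items():
                pool.setdefault(k, t)
    trees = [
        _adj_to_phylogeny(a, matrix.taxa, config.outgroup)
        for _, a in sorted(pool.items(), key=lambda kv: sorted(map(sorted, kv[0])))
    ]
    score = tree_length(matrix, trees[0], config.ordered)
    assert score.total_length == global_best
    return SearchResult(int(global_best), trees, score, log)


def _tbr_to_optimum(adj, data: _SearchData, hold: int):
    n = data.n
    best = data.score(adj)
    held = {_splits_key(adj, n): _copy_adj(adj)}
    improved = True
    while improved:
        improved = False
        for cand in _tbr_neighbors(adj):
            L = data.score(cand)
            if L < best:
                adj, best = cand, L
                held = {_splits_key(cand, n): _copy_adj(cand)}
                improved = True
                break
            if L == best and len(held) < hold:
                k = _splits_key(cand, n)
                if k not in held:
                    held[k] = _copy_adj(cand)
    return best, held


def exhaustive_search(matrix: CharacterMatrix, ordered: bool = False,
                      outgroup: str | None = None) -> SearchResult:
    """Score every unrooted topology (oracle; limited to <= 10 taxa)."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if n > 10:
        raise ValueError("exhaustive enumeration limited to 10 taxa")
    data = _SearchData(matrix, ordered)
    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
    adj[n] = [0, 1, 2]
    for t in (0, 1, 2):
        adj[t] = [n]
    best: list = [None, {}]

    def rec(k: int):
        if k == n:
            L = data.score(adj)
            if best[0] is None or L < best[0]:
                best[0] = L
                best[1] = {_splits_key(adj, n): _copy_adj(adj)}
            elif L == best[0]:
                key = _splits_key(adj, n)
                if key not in best[1]:
                    best[1][key] = _copy_adj(adj)
            return
        w = n + k - 2
        for e in list(_edges(adj)):
            _insert_tip(adj, k, e, w)
            rec(k + 1)
            _remove_tip(adj, k, w, e)

    rec(3)
    trees = [
        _adj_to_phylogeny(a, matrix.taxa, outgroup)
        for _, a in sorted(best[1].items(), key=lambda kv: sorted(map(sorted, kv[0])))
    ]
    score = tree_length(matrix, trees[0], ordered)
    return SearchResult(int(best[0]), trees, score, [int(best[0])])


# ---------------------------------------------------------------------------
# consensus


def consensus(trees: list[Phylogeny], kind: str = "strict") -> Phylogeny:
    """Strict or 50%-majority-rule consensus of rooted trees."""
    if not trees:
        raise ValueError("need at least one tree")
    tipsets = {frozenset(t.tip_labels()) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("trees have mixed tip sets")
    all_tips = tipsets.pop()
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in _clades(t):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    if kind == "strict":
        keep = [c for c, k in counts.items() if k == n]
    elif kind in ("majority50", "majority"):
        keep = [c for c, k in counts.items() if k > n / 2]
    else:
        raise ValueError(f"unknown consensus kind {kind!r}")
    keep = [c for c in keep if 1 < len(c) < len(all_tips)]
    keep.sort(key=lambda c: (-len(c), sorted(c)))
    root = Node("")
    nodes: list[tuple[frozenset, Node]] = [(frozenset(all_tips), root)]
    for clade in keep:
        parent = min(
            (c for c in nodes if clade < c[0]), key=lambda cn: len(cn[0])
        )[1]
        nd = parent.add_child(Node(""))
        nodes.append((clade, nd))
    for tip in sorted(all_tips):
        parent = min(
            (c for c in nodes if tip in c[0]), key=lambda cn: len(cn[0])
        )[1]
        parent.add_child(Node(tip))
    return Phylogeny(root, outgroup=trees[0].outgroup)


def _clades(tree: Phylogeny):
    below: dict[int, frozenset] = {}
    for n in tree.postorder():
        if n.is_tip:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            yield below[id(n)]


# ---------------------------------------------------------------------------
# Templeton (Wilcoxon signed-rank) topology test


@dataclass
class TempletonResult:
    n_nonzero: int
    statistic: float  # W = min(W+, W-)
    p: float
    degenerate: bool = False


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> tuple[float, float, int]:
    """Two-tailed Wilcoxon signed-rank test with average ranks for ties.

    Zero differences are dropped.  For n <= ``exact_max_n`` the null
    distribution is enumerated exactly (dynamic programming over doubled
    ranks); otherwise a normal approximation with continuity correction
    is used.  Returns ``(W, p, n_nonzero)`` with W = min(W+, W-).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    if n <= exact_max_n:
        t = np.rint(2 * ranks).astype(np.int64)
        total = int(t.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for ti in t:
            # out-of-place add: each difference's sign enters exactly once
            counts[ti:] = counts[ti:] + counts[: total + 1 - ti]
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        p_low = float(counts[: w2 + 1].sum())
        p_high = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = float(2.0 * norm.sf(z))
    return W, min(p, 1.0), n


def templeton_test(
    matrix: CharacterMatrix,
    tree_a: Phylogeny,
    tree_b: Phylogeny,
    ordered: bool | None = None,
) -> TempletonResult:
    """Compare two topologies by per-character parsimony length differences."""
    if ordered is None:
        ordered = matrix.ordered
    la = per_character_lengths(matrix, tree_a, ordered)
    lb = per_character_lengths(matrix, tree_b, ordered)
    d = (la - lb).astype(float)
    if (d == 0).all():
        return TempletonResult(0, 0.0, 1.0, degenerate=True)
    W, p, n = wilcoxon_signed_rank(d)
    return TempletonResult(n, W, p)
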