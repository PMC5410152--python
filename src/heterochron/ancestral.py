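"""Ancestral state reconstruction and the continuous heterochrony criterion.

Continuous characters are reconstructed by squared-change parsimony:
internal values minimise the sum over branches of (Delta x)^2 / l (the
branch-length-weighted criterion; with unit lengths this reduces to the
plain criterion).  The minimiser is the exact solution of the tree's
weighted-Laplacian linear system.  Root uncertainty comes from
phylogenetically independent contrasts: the Brownian rate is estimated
from the n-1 standardised contrasts, the root variance from the pruning
recursion, and a Student-t interval around the GLS root estimate.  A
terminal taxon whose character value falls outside the root's 95% CI is
flagged as a heterochronic shift ('earlier' below, 'later' above).

Discrete (event-pair) characters get marginal maximum-likelihood
reconstruction under a one-rate symmetric Mk model whose state space is
the character's observed alphabet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import t as student_t

from .encode import ContinuousMatrix
from .parsimony import BranchChange
from .report import HeterochronyRecord, HeterochronyReport
from .seqdata import CharacterMatrix, Node, Phylogeny, prune_taxa

__all__ = [
    "NodeValues",
    "RootReconstruction",
    "MkCharacter",
    "MkReconstruction",
    "squared_change_reconstruct",
    "pic_root_ci",
    "flag_continuous_heterochrony",
    "ml_mk_reconstruct",
]


@dataclass
class NodeValues:
    """Internal-node values minimising the (weighted) squared-change score."""

    values: dict[str, float]
    score: float


@dataclass
class RootReconstruction:
    char_id: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    df: int

    def __post_init__(self):
        assert self.ci_lower <= self.estimate <= self.ci_upper


def _branch_weights(tree: Phylogeny, use_lengths: bool) -> dict[int, float]:
    w = {}
    for n in tree.preorder():
        if n.parent is None:
            continue
        if use_lengths:
            if n.length is None:
                raise ValueError(f"branch into {n.label!r} has no length")
            if n.length <= 0:
                raise ValueError(
                    f"branch into {n.label!r} has non-positive length; "
                    "calibrate the tree or use unit lengths"
                )
            w[id(n)] = 1.0 / n.length
        else:
            w[id(n)] = 1.0
    return w


def _prune_to_known(tree: Phylogeny, values: dict[str, float]) -> Phylogeny:
    known = [t for t in tree.tip_labels() if t in values and np.isfinite(values[t])]
    drop = [t for t in tree.tip_labels() if t not in known]
    return prune_taxa(tree, drop) if drop else tree.copy()


def squared_change_reconstruct(
    values: dict[str, float], tree: Phylogeny, use_branch_lengths: bool = True
) -> NodeValues:
    """Exact weighted squared-change parsimony via the tree linear system.

    Tips absent from ``values`` (or non-finite) are pruned first.  The
    returned ``score`` is the minimised sum of (Delta)^2 / l over
    branches — the "steps" of a continuous character mapping.
    """
    sub = _prune_to_known(tree, values)
    tips = sub.tip_labels()
    if len(tips) < 2:
        raise ValueError("need at least 2 tips with values")
    w = _branch_weights(sub, use_branch_lengths)
    internals = sub.internal_nodes()
    index = {id(n): i for i, n in enumerate(internals)}
    m = len(internals)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for n in sub.preorder():
        if n.parent is None:
            continue
        wij = w[id(n)]
        pi = index[id(n.parent)]
        if n.is_tip:
            A[pi, pi] += wij
            b[pi] += wij * values[n.label]
        else:
            ci = index[id(n)]
            A[pi, pi] += wij
            A[ci, ci] += wij
            A[pi, ci] -= wij
            A[ci, pi] -= wij
    x = np.linalg.solve(A, b)
    out = {internals[i].label: float(x[i]) for i in range(m)}
    score = 0.0
    for n in sub.preorder():
        if n.parent is None:
            continue
        xc = values[n.label] if n.is_tip else out[n.label]
        xp = out[n.parent.label]
        score += w[id(n)] * (xc - xp) ** 2
    return NodeValues(out, float(score))


def _pic_prune(node: Node, values: dict[str, float], use_lengths: bool,
               contrasts: list[float]) -> tuple[float, float]:
    """Return (value, variance) seen from above `node`; collect contrasts."""
    edge = (node.length if use_lengths else 1.0) if node.parent is not None else 0.0
    if node.is_tip:
        return values[node.label], edge
    parts = [_pic_prune(c, values, use_lengths, contrasts) for c in node.children]
    x, v = parts[0]
    for (x2, v2) in parts[1:]:  # polytomies combined pairwise in child order
        contrasts.append((x - x2) / math.sqrt(v + v2))
        x = (x / v + x2 / v2) / (1 / v + 1 / v2)
        v = (v * v2) / (v + v2)
    return x, v + edge


def pic_root_ci(
    values: dict[str, float],
    tree: Phylogeny,
    level: float = 0.95,
    use_branch_lengths: bool = True,
    df_mode: str = "contrasts",
    char_id: str = "",
) -> RootReconstruction:
    """Root estimate with a t confidence interval from independent contrasts.

    ``df_mode='contrasts'`` uses n-1 degrees of freedom (the number of
    contrasts); ``'n-2'`` is selectable for compatibility with other
    conventions.
    """
    sub = _prune_to_known(tree, values)
    tips = sub.tip_labels()
    n = len(tips)
    if n < 3:
        raise ValueError("root CI needs at least 3 tips with values")
    _branch_weights(sub, use_branch_lengths)  # validates lengths
    contrasts: list[float] = []
    est, v_root = _pic_prune(sub.root, values, use_branch_lengths, contrasts)
    df = len(contrasts) - 1 if df_mode == "n-2" else len(contrasts)
    rate = float(np.sum(np.square(contrasts)) / df)
    se = math.sqrt(rate * v_root)
    if se == 0.0:
        return RootReconstruction(char_id, est, 0.0, est, est, df)
    tq = float(student_t.ppf(0.5 + level / 2, df))
    return RootReconstruction(char_id, est, se, est - tq * se, est + tq * se, df)


def flag_continuous_heterochrony(
    continuous: ContinuousMatrix,
    tree: Phylogeny,
    reference: str = "lepidosaur",
    outgroup: str = "Sphenodon_punctatus",
    use_branch_lengths: bool = True,
    level: float = 0.95,
) -> tuple[HeterochronyReport, list[RootReconstruction]]:
    """Flag taxa whose continuous value lies beyond the ancestral root CI.

    ``reference='squamate'`` prunes the outgroup before reconstruction
    (the root then estimates the ancestral ingroup member); every taxon
    with a recorded value — including the outgroup — is still compared
    against the interval.
    """
    if reference not in ("lepidosaur", "squamate"):
        raise ValueError("reference must be 'lepidosaur' or 'squamate'")
    ref_tree = tree
    if reference == "squamate":
        ref_tree = prune_taxa(tree, [outgroup])
    report = HeterochronyReport()
    roots: list[RootReconstruction] = []
    rec_mask = continuous.recorded_mask()
    for j, ev in enumerate(continuous.event_labels):
        vals = {
            sp: float(continuous.values[i, j])
            for i, sp in enumerate(continuous.species)
            if rec_mask[i, j]
        }
        usable = [t for t in ref_tree.tip_labels() if t in vals]
        if len(usable) < 3:
            continue
        rr = pic_root_ci(
            vals, ref_tree, level=level, use_branch_lengths=use_branch_lengths,
            char_id=ev,
        )
        roots.append(rr)
        for sp, v in vals.items():
            if v < rr.ci_lower:
                direction = "earlier"
            elif v > rr.ci_upper:
                direction = "later"
            else:
                continue
            report.records.append(
                HeterochronyRecord(
                    sp, ev, direction, v, rr.ci_lower, rr.ci_upper,
                    method=f"continuous/{reference}",
                )
            )
    return report, roots


# ---------------------------------------------------------------------------
# Mk maximum likelihood


@dataclass
class MkCharacter:
    """Marginal ML reconstruction of one discrete character."""

    char_id: str
    states: tuple[int, ...]  # observed alphabet, original state values
    rate: float
    log_likelihood: float
    probs: dict[str, np.ndarray]  # node label -> marginal over `states`
    skipped: bool = False
    at_bound: bool = False


@dataclass
class MkReconstruction:
    """Per-character Mk reconstructions plus MP-style change records.

    ``node_states`` holds, per node and character, the set of
    highest-marginal-probability states, so event-pair cracking can
    consume ML reconstructions through the same interface as parsimony.
    """

    tree: Phylogeny
    char_ids: list[str]
    chars: list[MkCharacter]
    node_states: dict[str, list[frozenset]]
    changes: list[BranchChange]

    def changes_at(self, node_label: str) -> list[BranchChange]:
        return [ch for ch in self.changes if ch.node == node_label]


def _mk_pmatrix(k: int, rate: float, t: float) -> np.ndarray:
    """Transition probabilities of the k-state symmetric Mk model."""
    e = math.exp(-k * rate * t)
    same = 1.0 / k + (k - 1) / k * e
    diff = 1.0 / k * (1.0 - e)
    P = np.full((k, k), diff)
    np.fill_diagonal(P, same)
    return P


def _mk_down(tree: Phylogeny, tipvec: dict[str, np.ndarray], k: int, rate: float):
    """Conditional likelihoods from below, with log-scale factors."""
    down: dict[int, np.ndarray] = {}
    logf = 0.0
    for n in tree.postorder():
        if n.is_tip:
            down[id(n)] = tipvec[n.label]
            continue
        L = np.ones(k)
        for c in n.children:
            t = c.length if c.length is not None else 1.0
            L = L * (_mk_pmatrix(k, rate, t) @ down[id(c)])
        mx = L.max()
        if mx > 0:
            L = L / mx
            logf += math.log(mx)
        down[id(n)] = L
    return down, logf


def _mk_loglik(tree, tipvec, k, rate) -> float:
    down, logf = _mk_down(tree, tipvec, k, rate)
    lik = float(down[id(tree.root)].sum() / k)
    return -np.inf if lik <= 0 else math.log(lik) + logf


RATE_BOUNDS = (1e-8, 100.0)


def ml_mk_reconstruct(matrix: CharacterMatrix, tree: Phylogeny) -> MkReconstruction:
    """Fit a one-rate symmetric Mk model per character and reconstruct nodes.

    The state space of each character is its observed alphabet (constant
    characters are skipped).  The rate is fitted by bounded 1-D
    likelihood maximisation; marginal node probabilities come from the
    standard down/up pruning passes with a flat root prior.
    """
    tips = tree.tip_labels()
    missing = [t for t in tips if t not in matrix.taxa]
    if missing:
        raise KeyError(f"tree tips missing from matrix: {missing}")
    rows = {t: matrix.states[matrix.taxa.index(t)] for t in tips}
    pre = tree.preorder()
    chars: list[MkCharacter] = []
    node_states: dict[str, list[frozenset]] = {n.label: [] for n in pre}
    changes: list[BranchChange] = []

    for c, cid in enumerate(matrix.char_ids):
        col = {t: int(rows[t][c]) for t in tips}
        observed = sorted({v for v in col.values() if v >= 0})
        k = len(observed)
        if k < 2:
            mk = MkCharacter(cid, tuple(observed), 0.0, 0.0, {}, skipped=True)
            chars.append(mk)
            st = frozenset(observed) if observed else frozenset()
            for n in pre:
                node_states[n.label].append(st)
            continue
        smap = {s: i for i, s in enumerate(observed)}
        tipvec = {}
        for t_label in tips:
            v = np.zeros(k)
            s = col[t_label]
            if s < 0:
                v[:] = 1.0
            else:
                v[smap[s]] = 1.0
            tipvec[t_label] = v

        # optimise log10(rate): the likelihood basin is narrow near zero on
        # the raw scale but well conditioned in log space
        res = minimize_scalar(
            lambda x: -_mk_loglik(tree, tipvec, k, 10.0**x),
            bounds=(math.log10(RATE_BOUNDS[0]), math.log10(RATE_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rate = float(10.0 ** res.x)
        loglik = -float(res.fun)
        at_bound = rate <= RATE_BOUNDS[0] * 1.01 or rate >= RATE_BOUNDS[1] * 0.99
        if at_bound:
            warnings.warn(
                f"character {cid}: fitted rate {rate:g} at bound {RATE_BOUNDS}",
                stacklevel=2,
            )
        down, _ = _mk_down(tree, tipvec, k, rate)
        up: dict[int, np.ndarray] = {id(tree.root): np.full(k, 1.0 / k)}
        for n in pre:
            if not n.children:
                continue
            below = {}
            for ch in n.children:
                t = ch.length if ch.length is not None else 1.0
                below[id(ch)] = _mk_pmatrix(k, rate, t) @ down[id(ch)]
            for ch in n.children:
                rest = up[id(n)].copy()
                for other in n.children:
                    if other is not ch:
                        rest = rest * below[id(other)]
                t = ch.length if ch.length is not None else 1.0
                u = _mk_pmatrix(k, rate, t).T @ rest
                mx = u.max()
                up[id(ch)] = u / mx if mx > 0 else u
        probs = {}
        for n in pre:
            m = down[id(n)] * up[id(n)]
            s = m.sum()
            probs[n.label] = m / s if s > 0 else np.full(k, 1.0 / k)
        mk = MkCharacter(cid, tuple(observed), rate, loglik, probs, at_bound=at_bound)
        chars.append(mk)
        for n in pre:
            p = probs[n.label]
            best = p.max()
            node_states[n.label].append(
                frozenset(observed[i] for i in range(k) if p[i] >= best - 1e-12)
            )

    for n in pre:
        if n.parent is None:
            continue
        for c, cid in enumerate(matrix.char_ids):
            ps = node_states[n.parent.label][c]
            cs = node_states[n.label][c]
            if ps and cs and not (ps & cs):
                changes.append(BranchChange(n.label, c, cid, ps, cs))
    return MkReconstruction(tree, list(matrix.char_ids), chars, node_states, changes)
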