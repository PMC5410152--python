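import numpy as np
import pytest

from heterochron.seqdata import CharacterMatrix, Node, Phylogeny


def make_matrix(taxa, cols, ordered=False):
    cols = np.asarray(cols, dtype=np.int8)
    return CharacterMatrix(
        taxa, [str(i + 1) for i in range(cols.shape[1])], cols, ordered
    )


def random_binary_tree(n, rng, lengths=False):
    """Random binary tree over tips t0..t{n-1} by sequential joining."""
    nodes = [Node(f"t{i}", float(rng.exponential(1.0) + 0.05) if lengths else None)
             for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = Node("", float(rng.exponential(1.0) + 0.05) if lengths else None)
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    nodes[0].length = None
    return Phylogeny(nodes[0])


def random_matrix(n_taxa, n_chars, max_state, rng, missing=0.0):
    states = rng.integers(0, max_state + 1, size=(n_taxa, n_chars)).astype(np.int8)
    if missing:
        states[rng.random(states.shape) < missing] = -1
    return make_matrix([f"t{i}" for i in range(n_taxa)], states)


def brute_force_lengths(matrix, tree, ordered):
    """Exhaustive internal-labeling parsimony oracle (tiny trees only).

    Internal states are drawn from each character's observed states
    (unordered) or the observed min..max range (ordered); restricting to
    these cannot increase the optimum for unit or linear costs.
    """
    import itertools

    internals = tree.internal_nodes()
    assert len(internals) <= 6
    tips = tree.tip_labels()
    rows = {t: matrix.states[matrix.taxa.index(t)] for t in tips}
    out = []
    for c in range(matrix.n_chars):
        obs = sorted({int(rows[t][c]) for t in tips if rows[t][c] >= 0})
        if not obs:
            out.append(0)
            continue
        space = list(range(obs[0], obs[-1] + 1)) if ordered else obs
        idx = {id(n): i for i, n in enumerate(internals)}
        best = None
        for combo in itertools.product(space, repeat=len(internals)):
            cost = 0
            for n in tree.preorder():
                if n.parent is None:
                    continue
                sp = combo[idx[id(n.parent)]]
                if n.is_tip:
                    sc = int(rows[n.label][c])
                    if sc < 0:
                        continue  # ambiguous tip: zero-cost choice exists
                else:
                    sc = combo[idx[id(n)]]
                cost += abs(sp - sc) if ordered else int(sp != sc)
            best = cost if best is None else min(best, cost)
        out.append(best)
    return np.array(out, dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
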