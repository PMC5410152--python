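import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from heterochron.parsimony import (
    consensus,
    fitch_lengths,
    mp_reconstruct,
    per_character_lengths,
    sankoff_lengths,
    templeton_test,
    tree_length,
    wilcoxon_signed_rank,
)
from heterochron.seqdata import Phylogeny

from conftest import brute_force_lengths, make_matrix, random_binary_tree, random_matrix


class TestTreeLength:
    def test_clean_split_costs_one(self):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        m = make_matrix(list("ABCD"), [[0], [0], [1], [1]])
        assert tree_length(m, t, False).total_length == 1

    def test_conflicting_split_costs_two(self):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        m = make_matrix(list("ABCD"), [[0], [1], [0], [1]])
        assert tree_length(m, t, False).total_length == 2

    def test_linear_vs_unit_cost(self):
        t = Phylogeny.from_newick("(A,B);")
        m = make_matrix(list("AB"), [[0], [2]])
        assert tree_length(m, t, True).total_length == 2
        assert tree_length(m, t, False).total_length == 1

    def test_missing_tip_in_matrix_errors(self):
        t = Phylogeny.from_newick("((A,B),Z);")
        m = make_matrix(list("AB"), [[0], [1]])
        with pytest.raises(KeyError):
            tree_length(m, t, False)

    def test_fitch_equals_unit_sankoff(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 9))
            t = random_binary_tree(n, rng)
            m = random_matrix(n, 6, 3, rng, missing=0.15)
            assert (fitch_lengths(m, t) == sankoff_lengths(m, t, False)).all()

    def test_brute_force_oracle_small_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 7))
            t = random_binary_tree(n, rng)
            m = random_matrix(n, 4, 3, rng, missing=0.1)
            for ordered in (False, True):
                got = per_character_lengths(m, t, ordered)
                want = brute_force_lengths(m, t, ordered)
                assert (got == want).all()

    def test_length_invariant_under_rerooting(self, rng):
        # same unrooted tree, three rootings
        trees = [
            "((A,B),((C,D),(E,F)));",
            "(((A,B),(C,D)),(E,F));",
            "(A,(B,((C,D),(E,F))));",
        ]
        m = random_matrix(6, 8, 4, rng)
        m.taxa = list("ABCDEF")
        lens = {tree_length(m, Phylogeny.from_newick(s), o).total_length
                for s in trees for o in (False,)}
        assert len(lens) == 1

    def test_ensemble_index_bounds(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 9))
            t = random_binary_tree(n, rng)
            m = random_matrix(n, 10, 4, rng, missing=0.1)
            sc = tree_length(m, t, False)
            assert 0 < sc.ci <= 1.0
            assert 0 <= sc.ri <= 1.0

    def test_homoplasy_free_has_ci_one(self):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        m = make_matrix(list("ABCD"), [[0, 0], [0, 1], [1, 1], [1, 1]])
        assert tree_length(m, t, False).ci == 1.0


class TestMPReconstruct:
    def test_outgroup_roots_the_change(self):
        t = Phylogeny.from_newick("((A,B),C);", outgroup="C")
        m = make_matrix(list("ABC"), [[1], [1], [0]])
        r = mp_reconstruct(m, t, False)
        assert len(r.changes) == 1
        ch = r.changes[0]
        assert ch.parent_states == frozenset({0})
        assert ch.child_states == frozenset({1})

    def test_invariant_character_has_no_changes(self):
        t = Phylogeny.from_newick("((A,B),C);", outgroup="C")
        m = make_matrix(list("ABC"), [[2], [2], [2]])
        assert mp_reconstruct(m, t, False).changes == []

    def test_mpr_sets_match_exhaustive_labelings(self, rng):
        """Node MPR sets equal the states used by >=1 optimal labeling."""
        import itertools

        for _ in range(10):
            n = int(rng.integers(4, 7))
            t = random_binary_tree(n, rng)
            m = random_matrix(n, 3, 2, rng)
            r = mp_reconstruct(m, t, False)
            internals = t.internal_nodes()
            rows = {lbl: m.states[m.taxa.index(lbl)] for lbl in t.tip_labels()}
            for c in range(m.n_chars):
                obs = sorted({int(v[c]) for v in rows.values() if v[c] >= 0})
                best, used = None, {}
                for combo in itertools.product(obs, repeat=len(internals)):
                    assign = {nd.label: s for nd, s in zip(internals, combo)}
                    cost = 0
                    for nd in t.preorder():
                        if nd.parent is None:
                            continue
                        sp = assign[nd.parent.label]
                        sc = int(rows[nd.label][c]) if nd.is_tip else assign[nd.label]
                        cost += int(sp != sc)
                    if best is None or cost < best:
                        best, used = cost, {k: {v} for k, v in assign.items()}
                    elif cost == best:
                        for k, v in assign.items():
                            used[k].add(v)
                assert r.char_lengths[c] == best
                for nd in internals:
                    assert r.node_states[nd.label][c] == frozenset(used[nd.label])


class TestConsensus:
    def test_identical_trees(self):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        c = consensus([t, t.copy(), t.copy()], "strict")
        assert {frozenset(x) for x in _clades(c)} == {frozenset(x) for x in _clades(t)}

    def test_partial_agreement(self):
        a = Phylogeny.from_newick("(((A,B),C),D);")
        b = Phylogeny.from_newick("(((A,B),D),C);")
        c = consensus([a, b], "strict")
        clades = {frozenset(x) for x in _clades(c)}
        assert frozenset({"A", "B"}) in clades
        assert len([x for x in clades if 1 < len(x) < 4]) == 1

    def test_majority_rule(self):
        a = Phylogeny.from_newick("(((A,B),C),D);")
        b = Phylogeny.from_newick("(((A,B),C),D);")
        c3 = Phylogeny.from_newick("(((A,C),B),D);")
        maj = consensus([a, b, c3], "majority50")
        clades = {frozenset(x) for x in _clades(maj)}
        assert frozenset({"A", "B"}) in clades
        assert frozenset({"A", "B", "C"}) in clades

    def test_strict_clades_occur_in_every_input(self, rng):
        from heterochron.parsimony import SearchConfig, heuristic_search

        m = random_matrix(7, 5, 2, rng)
        res = heuristic_search(m, SearchConfig(replicates=4, hold=10, seed=5))
        cons = consensus(res.trees, "strict")
        for clade in _clades(cons):
            if 1 < len(clade) < 7:
                for t in res.trees:
                    assert clade in set(_clades(t))

    def test_mixed_tip_sets_rejected(self):
        a = Phylogeny.from_newick("((A,B),C);")
        b = Phylogeny.from_newick("((A,B),D);")
        with pytest.raises(ValueError):
            consensus([a, b])


def _clades(tree):
    out = []
    below = {}
    for n in tree.postorder():
        if n.is_tip:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            out.append(below[id(n)])
    return out


class TestWilcoxon:
    def test_all_positive_five(self):
        W, p, n = wilcoxon_signed_rank(np.array([1.0, 1, 1, 1, 1]))
        assert n == 5 and p == pytest.approx(2 / 32)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 14))
            d = rng.normal(size=n) * np.exp(rng.normal(size=n))
            d = d[np.abs(d) > 1e-12]
            if len(set(np.abs(d))) != len(d):
                continue
            _, p, _ = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_full_sign_enumeration(self, rng):
        """DP null distribution equals brute-force 2^n enumeration (n<=12)."""
        import itertools

        from scipy.stats import rankdata

        for trial in range(8):
            n = int(rng.integers(4, 13))
            d = np.round(rng.normal(size=n) * 3, 0)
            d = d[d != 0]
            if d.size < 3:
                continue
            ranks = rankdata(np.abs(d), method="average")
            w_obs = ranks[d > 0].sum()
            count_le = count_ge = 0
            for signs in itertools.product([0, 1], repeat=d.size):
                w = sum(r for s, r in zip(signs, ranks) if s)
                count_le += w <= w_obs + 1e-9
                count_ge += w >= w_obs - 1e-9
            total = 2 ** d.size
            expected = min(1.0, 2 * min(count_le / total, count_ge / total))
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_for_large_n(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        W, p, n = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestTempleton:
    def test_identical_trees_degenerate(self, rng):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        m = random_matrix(4, 6, 2, rng)
        m.taxa = list("ABCD")
        r = templeton_test(m, t, t.copy(), False)
        assert r.degenerate and r.p == 1.0 and r.n_nonzero == 0

    def test_study_shaped_synthetic_data(self):
        from heterochron import datasets
        from heterochron.chronos import unit_branch_lengths
        from heterochron.encode import discretize, event_pair_encode, to_continuous
        from heterochron.synthgen import apply_missingness, simulate_timelines

        cfg = datasets.study_sim_config(seed=0)
        tl, _ = simulate_timelines(cfg)
        tl = apply_missingness(tl, cfg)
        mol = unit_branch_lengths(datasets.load_hypothesis("molecular"))
        mor = unit_branch_lengths(datasets.load_hypothesis("morphological"))
        pairs = event_pair_encode(tl)
        r = templeton_test(pairs, mol, mor, False)
        assert 0 <= r.p <= 1
        assert r.n_nonzero < pairs.n_chars
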