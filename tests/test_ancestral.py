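import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from heterochron.ancestral import (
    _mk_pmatrix,
    flag_continuous_heterochrony,
    ml_mk_reconstruct,
    pic_root_ci,
    squared_change_reconstruct,
)
from heterochron.encode import ContinuousMatrix
from heterochron.seqdata import Phylogeny

from conftest import make_matrix, random_binary_tree


class TestSquaredChange:
    def test_star_mean(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1);")
        nv = squared_change_reconstruct({"A": 0, "B": 0.5, "C": 1}, t)
        assert nv.values[t.root.label] == pytest.approx(0.5)
        assert nv.score == pytest.approx(0.5)

    def test_two_tip_weighting(self):
        # minimise r^2/1 + (r-1)^2/3: the 1/length weights pull the root
        # toward the short-branch tip
        t = Phylogeny.from_newick("(A:1,B:3);")
        nv = squared_change_reconstruct({"A": 0, "B": 1}, t)
        assert nv.values[t.root.label] == pytest.approx(0.25)
        assert nv.score == pytest.approx(0.25)

    def test_constant_tips_zero_score(self):
        t = Phylogeny.from_newick("((A:1,B:2):1,C:3);")
        nv = squared_change_reconstruct({"A": 0.3, "B": 0.3, "C": 0.3}, t)
        assert all(v == pytest.approx(0.3) for v in nv.values.values())
        assert nv.score == pytest.approx(0.0)

    def test_zero_length_branch_rejected(self):
        t = Phylogeny.from_newick("((A:0,B:2):1,C:3);")
        with pytest.raises(ValueError, match="non-positive"):
            squared_change_reconstruct({"A": 0, "B": 1, "C": 0.5}, t)

    def test_matches_generic_minimizer(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            t = random_binary_tree(n, rng, lengths=True)
            vals = {f"t{i}": float(rng.random()) for i in range(n)}
            nv = squared_change_reconstruct(vals, t)
            internals = [nd.label for nd in t.internal_nodes()]

            def objective(x):
                m = dict(zip(internals, x))
                s = 0.0
                for nd in t.preorder():
                    if nd.parent is None:
                        continue
                    xc = vals[nd.label] if nd.is_tip else m[nd.label]
                    s += (xc - m[nd.parent.label]) ** 2 / nd.length
                return s

            res = minimize(objective, np.full(len(internals), 0.5), tol=1e-14)
            assert nv.score == pytest.approx(res.fun, abs=1e-8)

    def test_root_equals_recursive_weighted_mean(self, rng):
        """The linear-system root equals the pruning-recursion mean."""
        for lengths in (False, True):
            t = random_binary_tree(7, rng, lengths=True)
            if not lengths:
                for nd in t.preorder():
                    if nd.parent is not None:
                        nd.length = 1.0
            vals = {f"t{i}": float(rng.random()) for i in range(7)}

            def prune(nd):
                if nd.is_tip:
                    return vals[nd.label], nd.length
                (x1, v1), (x2, v2) = (prune(c) for c in nd.children)
                x = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
                v = v1 * v2 / (v1 + v2)
                return x, v + (nd.length or 0.0)

            root_mean, _ = prune(t.root)
            nv = squared_change_reconstruct(vals, t)
            assert nv.values[t.root.label] == pytest.approx(root_mean)

    def test_missing_tips_pruned(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        nv = squared_change_reconstruct({"A": 0, "B": 1, "C": 0.5}, t)
        assert t.root.label in nv.values


class TestPicRootCI:
    def test_equal_tips_degenerate(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rr = pic_root_ci({"A": 1, "B": 1, "C": 1, "D": 1}, t)
        assert rr.se == 0.0 and rr.ci_lower == rr.ci_upper == 1.0

    def test_hand_computed_symmetric_case(self):
        # contrasts: (A-B)/sqrt2 = 0, (C-D)/sqrt2 = 0, (0-1)/sqrt3
        # sigma^2 = (1/3)/3; v_root = 0.75; se = sqrt(0.75/9)
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rr = pic_root_ci({"A": 0, "B": 0, "C": 1, "D": 1}, t)
        assert rr.estimate == pytest.approx(0.5)
        assert rr.se == pytest.approx(math.sqrt(0.75 / 9))
        assert rr.df == 3
        from scipy.stats import t as student_t

        half = student_t.ppf(0.975, 3) * rr.se
        assert rr.ci_upper == pytest.approx(0.5 + half)

    def test_too_few_tips_rejected(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            pic_root_ci({"A": 0, "B": 1}, t)

    def test_alternative_df_convention(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rr = pic_root_ci({"A": 0, "B": 0.2, "C": 1, "D": 1}, t, df_mode="n-2")
        assert rr.df == 2


class TestContinuousCriterion:
    def _matrix(self, species, values):
        return ContinuousMatrix(species, ["E1"], np.array(values)[:, None])

    def test_flags_are_exactly_the_out_of_interval_taxa(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
        values = [0.4, 0.45, 0.5, 0.55, 0.5, 0.45]
        cont = self._matrix(list("ABCDEF"), values)
        report, roots = flag_continuous_heterochrony(cont, t, outgroup="A")
        assert len(roots) == 1
        lo, hi = roots[0].ci_lower, roots[0].ci_upper
        flagged = {r.where for r in report}
        for sp, v in zip("ABCDEF", values):
            assert (sp in flagged) == (v < lo or v > hi)
        for r in report:
            assert r.direction == ("earlier" if r.statistic < lo else "later")

    def test_extreme_taxon_flagged_later(self):
        t = Phylogeny.from_newick(
            "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
        )
        cont = self._matrix(list("ABCDEF"), [0.5, 0.5, 0.5, 0.5, 0.5, 0.99])
        report, _ = flag_continuous_heterochrony(cont, t, outgroup="A")
        assert any(r.where == "F" and r.direction == "later" for r in report)

    def test_squamate_reference_prunes_outgroup(self):
        t = Phylogeny.from_newick(
            "(Out:1,((C:1,D:1):1,(E:1,F:1):1):1);"
        )
        cont = self._matrix(["Out", "C", "D", "E", "F"], [0.9, 0.5, 0.5, 0.5, 0.5])
        rep_all, roots_all = flag_continuous_heterochrony(
            cont, t, reference="lepidosaur", outgroup="Out")
        rep_sq, roots_sq = flag_continuous_heterochrony(
            cont, t, reference="squamate", outgroup="Out")
        # outgroup still compared against the ingroup interval
        assert any(r.where == "Out" for r in rep_sq)
        assert roots_sq[0].se <= roots_all[0].se + 1e-12


class TestMkModel:
    def test_identical_tips_concentrate_root(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = make_matrix(list("ABCD"), [[1, 0], [1, 1], [1, 0], [1, 1]])
        rec = ml_mk_reconstruct(m, t)
        assert rec.chars[0].skipped  # constant character
        p = rec.chars[1].probs
        assert abs(sum(p[t.root.label]) - 1) < 1e-9

    def test_two_tip_symmetry(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        m = make_matrix(list("AB"), [[0], [1]])
        rec = ml_mk_reconstruct(m, t)
        p = rec.chars[0].probs[t.root.label]
        assert p[0] == pytest.approx(p[1], abs=1e-9)

    def test_marginals_match_brute_force_sum(self, rng):
        """Pruning marginals equal direct summation over internal states."""
        t = Phylogeny.from_newick("((A:0.3,B:0.9):0.4,(C:0.2,D:1.1):0.7);")
        m = make_matrix(list("ABCD"), [[0], [0], [1], [2]])
        rec = ml_mk_reconstruct(m, t)
        ch = rec.chars[0]
        k = len(ch.states)
        tipstate = {"A": 0, "B": 0, "C": 1, "D": 2}
        internals = t.internal_nodes()
        labels = [n.label for n in internals]
        margs = {lbl: np.zeros(k) for lbl in labels}
        for combo in itertools.product(range(k), repeat=len(internals)):
            assign = dict(zip(labels, combo))
            lik = 1.0 / k
            for n in t.preorder():
                if n.parent is None:
                    continue
                sp = assign[n.parent.label]
                sc = assign[n.label] if not n.is_tip else tipstate[n.label]
                lik *= _mk_pmatrix(k, ch.rate, n.length)[sp, sc]
            for lbl, s in assign.items():
                margs[lbl][s] += lik
        for lbl in labels:
            want = margs[lbl] / margs[lbl].sum()
            assert np.abs(ch.probs[lbl] - want).max() < 1e-9

    def test_loglik_invariant_under_rerooting(self):
        from heterochron.ancestral import _mk_loglik

        a = Phylogeny.from_newick("((A:1,B:2):0.5,(C:1.5,D:1):0.5);")
        # same unrooted metric tree rooted along the A edge
        c = Phylogeny.from_newick("(A:1,(B:2,(C:1.5,D:1):1):0);")
        m = make_matrix(list("ABCD"), [[0], [1], [0], [2]])
        ra = ml_mk_reconstruct(m, a)
        k = len(ra.chars[0].states)
        tipvec = {lbl: np.eye(k)[s] for lbl, s in zip("ABCD", [0, 1, 0, 2])}
        la = _mk_loglik(a, tipvec, k, ra.chars[0].rate)
        lc = _mk_loglik(c, tipvec, k, ra.chars[0].rate)
        assert la == pytest.approx(lc, abs=1e-9)

    def test_missing_states_uninformative(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = make_matrix(list("ABCD"), [[0], [-1], [1], [-2]])
        rec = ml_mk_reconstruct(m, t)
        p = rec.chars[0].probs
        for lbl in p:
            assert abs(p[lbl].sum() - 1) < 1e-9
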