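import numpy as np
import pytest

from heterochron import datasets
from heterochron.encode import event_pair_encode
from heterochron.seqdata import (
    Event,
    Phylogeny,
    TimelineMatrix,
    prune_taxa,
    read_character_matrix,
    read_newick_tree,
    read_timeline_table,
    write_character_matrix,
)
from heterochron.synthgen import apply_missingness, simulate_timelines

from conftest import make_matrix


class TestTimelineIO:
    def test_study_shaped_round_trip(self, tmp_path):
        """A 29-species x 20-event table reads back with full shape."""
        cfg = datasets.study_sim_config(seed=1)
        tl, _ = simulate_timelines(cfg)
        tl = apply_missingness(tl, cfg)
        path = tmp_path / "timelines.csv"
        tl.write(path)
        back = read_timeline_table(path)
        assert back.n_species == 29 and back.n_events == 20
        assert np.array_equal(back.positions, tl.positions)

    def test_minimal_one_by_one(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,E1\nX,1\n")
        tl = read_timeline_table(p)
        assert tl.n_species == 1 and tl.n_events == 1
        assert tl.position("X", 1) == 1

    def test_non_integer_cell_names_coordinates(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,E1,E2\nX,1,1.5\n")
        with pytest.raises(ValueError, match="1.5.*'X'.*E2|'X'.*E2"):
            read_timeline_table(p)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,E1\nX,1\nX,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_timeline_table(p)

    def test_unknown_and_inapplicable_cells(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,E1,E2,E3\nX,1,?,-\n")
        tl = read_timeline_table(p)
        assert tl.position("X", 2) == "?"
        assert tl.position("X", 3) == "-"


class TestNewick:
    def test_three_tip_topology(self):
        t = Phylogeny.from_newick("((A,B),C);")
        assert sorted(t.tip_labels()) == ["A", "B", "C"]
        assert len(t.internal_nodes()) == 2

    def test_branch_lengths_preserved(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        lengths = {n.label: n.length for n in t.preorder() if n.is_tip}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_internal_names_deterministic(self):
        a = Phylogeny.from_newick("((A,B),(C,D));")
        b = Phylogeny.from_newick("((A,B),(C,D));")
        assert [n.label for n in a.preorder()] == [n.label for n in b.preorder()]

    def test_hypothesis_trees_match_species_table(self):
        species = set(datasets.load_species()["species"])
        for which in ("molecular", "morphological"):
            tree = datasets.load_hypothesis(which)
            assert set(tree.tip_labels()) == species
            assert len(tree.tip_labels()) == 29

    def test_companion_warning(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),C);")
        _, warn = read_newick_tree(p, companion_taxa=["A", "B"])
        assert len(warn) == 1 and "C" in warn[0]


class TestCharacterMatrixIO:
    @pytest.mark.parametrize("fmt", ["tnt", "nexus"])
    def test_round_trip_identity(self, fmt):
        m = make_matrix(
            ["Taxon_a", "Taxon_b", "Taxon_c"],
            [[0, 9, -1], [1, -2, 2], [3, 3, -2]],
            ordered=True,
        )
        text = write_character_matrix(m, fmt)
        back = read_character_matrix(text)
        assert back == m
        assert back.ordered == m.ordered

    @pytest.mark.parametrize("fmt", ["tnt", "nexus"])
    def test_inapplicable_preserved(self, fmt):
        m = make_matrix(["a", "b"], [[-2], [1]])
        back = read_character_matrix(write_character_matrix(m, fmt))
        assert back.row_string(0) == "-"

    def test_event_pair_matrix_declares_190_characters(self):
        cfg = datasets.study_sim_config(seed=2)
        tl, _ = simulate_timelines(cfg)
        pairs = event_pair_encode(tl)
        text = write_character_matrix(pairs, "tnt")
        assert "190 29" in text
        assert read_character_matrix(text).n_chars == 190

    def test_state_above_nine_rejected(self):
        m = make_matrix(["a", "b"], [[0], [9]])
        m.states[0, 0] = 9  # fine
        write_character_matrix(m, "tnt")
        with pytest.raises(ValueError):
            bad = make_matrix(["a", "b"], [[0], [9]])
            bad.states[0, 0] = 10
            write_character_matrix(bad, "tnt")


class TestPrune:
    def test_drop_one_keeps_lengths(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        p = prune_taxa(t, ["C"])
        assert sorted(p.tip_labels()) == ["A", "B"]
        assert p.to_newick() == "(A:1,B:1);"

    def test_study_tree_minus_outgroup(self):
        tree = datasets.load_hypothesis("molecular")
        p = prune_taxa(tree, [datasets.OUTGROUP])
        assert len(p.tip_labels()) == 28
        assert datasets.OUTGROUP not in p.tip_labels()

    def test_unknown_taxon_errors(self):
        t = Phylogeny.from_newick("((A,B),C);")
        with pytest.raises(KeyError):
            prune_taxa(t, ["Z"])

    def test_too_few_tips_errors(self):
        t = Phylogeny.from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            prune_taxa(t, ["A", "B"])

    def test_path_lengths_preserved_through_suppressed_nodes(self, rng):
        t = Phylogeny.from_newick(
            "((A:1,(B:2,(C:1,D:3):0.5):0.25):2,(E:1,F:4):0.5);"
        )

        def depths(tree):
            out = {}
            for tip in tree.tips():
                d, n = 0.0, tip
                while n.parent is not None:
                    d += n.length
                    n = n.parent
                out[tip.label] = d
            return out

        before = depths(t)
        # drop tips so the root keeps two children: internal paths must be summed
        p = prune_taxa(t, ["B", "C"])
        after = depths(p)
        for tip, d in after.items():
            assert d == pytest.approx(before[tip])
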