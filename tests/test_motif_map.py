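import pytest
from oracles import parsimony_oracle, random_tree

from motifshift import synthetic_data as sd
from motifshift.align_anchor import LiftedRegion
from motifshift.motif_map import extract_signature, parsimony_states, tally_by_clade
from motifshift.seq_io import tree_from_string


def lifted(seq_id, subseq, status="complete", start=64):
    return LiftedRegion(seq_id, "signature", start, start + len(subseq) - 1,
                        status, subseq)


class TestExtractSignature:
    @pytest.mark.parametrize(
        "motif, label",
        [("YDG", "YDG"), ("FDG", "FDG"), ("LDG", "LDG"), ("VDG", "VDG"),
         ("WDG", "other"), ("ydg", "YDG")],
    )
    def test_classification(self, motif, label):
        a = extract_signature(lifted("s1", motif))
        assert a.class_label == label and not a.missing

    def test_incomplete_window_flagged_missing(self):
        a = extract_signature(lifted("s1", "Y", status="partial"))
        assert a.class_label == "other" and a.missing

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="length"):
            extract_signature(lifted("s1", "YDGA"))


class TestTallyByClade:
    TREE = "(((a,b)X,(c,d,e)Y)XY,f)root;"

    def assignments(self, motifs):
        out = []
        for sp, motif in motifs.items():
            a = extract_signature(lifted(sp, motif))
            a.species = sp
            out.append(a)
        return out

    def test_counts_per_clade(self):
        tree = tree_from_string(self.TREE)
        table = tally_by_clade(
            self.assignments({"a": "YDG", "b": "YDG", "c": "FDG", "d": "FDG", "e": "YDG"}),
            tree, ["X", "Y"],
        )
        assert table.loc["X", "YDG"] == 2
        assert table.loc["Y", "FDG"] == 2 and table.loc["Y", "YDG"] == 1

    def test_nested_clades_count_in_both(self):
        tree = tree_from_string(self.TREE)
        table = tally_by_clade(
            self.assignments({"a": "YDG", "b": "FDG"}), tree, ["X", "XY"]
        )
        assert table.loc["X"].sum() == 2 and table.loc["XY"].sum() == 2

    def test_row_sums_equal_species_counts(self):
        tree = tree_from_string(self.TREE)
        motifs = {s: "YDG" for s in "abcdef"}
        table = tally_by_clade(self.assignments(motifs), tree, ["X", "Y", "XY"])
        assert table.sum(axis=1).tolist() == [2, 3, 5]

    def test_unknown_species_is_an_error_listing_it(self):
        tree = tree_from_string(self.TREE)
        with pytest.raises(ValueError, match="ghost"):
            tally_by_clade(self.assignments({"ghost": "YDG"}), tree, ["X"])

    def test_unknown_clade_is_an_error(self):
        tree = tree_from_string(self.TREE)
        with pytest.raises(ValueError, match="Z"):
            tally_by_clade(self.assignments({"a": "YDG"}), tree, ["Z"])


class TestParsimony:
    def test_single_forced_change(self):
        tree = tree_from_string("((A,B)ab,(C,D)cd)root;")
        res = parsimony_states(
            tree, {"A": "YDG", "B": "YDG", "C": "FDG", "D": "FDG"}
        )
        assert res.min_changes == 1
        (t,) = res.transitions
        assert t.child == "cd" and (t.from_state, t.to_state) == ("YDG", "FDG")

    def test_uniform_leaves_no_changes(self):
        tree = tree_from_string("((A,B),(C,D));")
        res = parsimony_states(tree, {s: "YDG" for s in "ABCD"})
        assert res.min_changes == 0 and res.transitions == [] and res.is_unique

    def test_unlabeled_leaf_rejected(self):
        tree = tree_from_string("((A,B),(C,D));")
        with pytest.raises(ValueError, match="D"):
            parsimony_states(tree, {"A": "x", "B": "x", "C": "x"})

    def test_min_changes_matches_enumeration_on_random_trees(self, rng):
        """Exact agreement with exhaustive internal-labeling enumeration on
        50 random 6-leaf (possibly multifurcating) trees, 3 states."""
        states = ["YDG", "FDG", "LDG"]
        for _ in range(50):
            newick, children, _root = random_tree(rng, 6)
            leaf_states = {
                f"L{i}": states[int(rng.integers(0, 3))] for i in range(6)
            }
            tree = tree_from_string(newick)
            res = parsimony_states(tree, leaf_states)
            assert res.min_changes == parsimony_oracle(children, _root, leaf_states)
            # reported labeling must itself realize min_changes
            changes = sum(
                1
                for parent, kids in children.items()
                for k in kids
                if res.labeling[parent] != res.labeling[k]
            )
            assert changes == res.min_changes

    def test_min_changes_at_least_states_minus_one(self, rng):
        for _ in range(20):
            newick, children, _root = random_tree(rng, 8)
            leaf_states = {
                f"L{i}": "SFLV"[int(rng.integers(0, 4))] for i in range(8)
            }
            res = parsimony_states(tree_from_string(newick), leaf_states)
            assert res.min_changes >= len(set(leaf_states.values())) - 1

    def test_invariant_to_leaf_order(self):
        states = {"A": "Y", "B": "F", "C": "F", "D": "Y", "E": "L"}
        t1 = parsimony_states(
            tree_from_string("((A,B)p,(C,(D,E)q)r)root;"), states
        )
        t2 = parsimony_states(
            tree_from_string("(((E,D)q,C)r,(B,A)p)root;"), states
        )
        assert t1.min_changes == t2.min_changes
        assert t1.n_optimal_labelings == t2.n_optimal_labelings

    def test_uniqueness_count_matches_enumeration(self, rng):
        import itertools

        for _ in range(20):
            newick, children, root = random_tree(rng, 5)
            leaf_states = {
                f"L{i}": "YF"[int(rng.integers(0, 2))] for i in range(5)
            }
            res = parsimony_states(tree_from_string(newick), leaf_states)
            internal = list(children)
            states = sorted(set(leaf_states.values()))
            n_opt = 0
            for combo in itertools.product(states, repeat=len(internal)):
                labels = dict(zip(internal, combo))
                labels.update(leaf_states)
                changes = sum(
                    1
                    for parent, kids in children.items()
                    for k in kids
                    if labels[parent] != labels[k]
                )
                if changes == res.min_changes:
                    n_opt += 1
            assert res.n_optimal_labelings == n_opt
            assert res.is_unique == (n_opt == 1)


class TestPlantedTransitionRecovery:
    def test_nested_bird_history_recovered_exactly(self, bird_families):
        records, truth, config = bird_families["IRF5"]
        tree = tree_from_string(config.newick)
        leaf_states = {
            r.species: truth.leaf_windows[r.species]["signature"]["subsequence"]
            for r in records
        }
        res = parsimony_states(tree, leaf_states)
        planted = {
            (t.child_label, t.from_motif, t.to_motif)
            for t in truth.applied_transitions
        }
        found = {(t.child, t.from_state, t.to_state) for t in res.transitions}
        assert res.min_changes == len(planted) == 3
        assert found == planted

    def test_recovery_across_seeded_replicates(self):
        """Homoplasy-free planted transitions are recovered exactly in every
        one of 30 seeded replicates."""
        for seed in range(30):
            config = sd.default_bird_config(seed=seed)
            records, truth = sd.simulate_family(config)
            tree = tree_from_string(config.newick)
            leaf_states = {
                r.species: truth.leaf_windows[r.species]["signature"]["subsequence"]
                for r in records
            }
            res = parsimony_states(tree, leaf_states)
            planted = {
                (t.child_label, t.from_motif, t.to_motif)
                for t in truth.applied_transitions
            }
            found = {(t.child, t.from_state, t.to_state) for t in res.transitions}
            assert found == planted, seed

    def test_cuckoo_homoplasy_adds_one_change(self):
        config = sd.default_bird_config(seed=1, include_cuckoo_homoplasy=True)
        records, truth = sd.simulate_family(config)
        tree = tree_from_string(config.newick)
        leaf_states = {
            r.species: truth.leaf_windows[r.species]["signature"]["subsequence"]
            for r in records
        }
        res = parsimony_states(tree, leaf_states)
        assert res.min_changes == 4
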