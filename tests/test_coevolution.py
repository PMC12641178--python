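import dendropy
import numpy as np
import pandas as pd
import pytest

import rbfcoevo as rc
from rbfcoevo import synth
from rbfcoevo.coevolution import (ancestral_triplet_states,
                                  class_state_proportions, clade_trajectory,
                                  decode_triplet, encode_triplet,
                                  encode_triplets, fitch_reconstruct,
                                  modal_state_per_class,
                                  per_class_conservation, trajectory_graph,
                                  triplet_mi)
from conftest import brute_force_parsimony


def _tree(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    t.is_rooted = True
    from rbfcoevo.coevolution import _assign_node_ids
    _assign_node_ids(t)
    return t


class TestFitch:
    def test_uniform_states_no_events(self):
        tree = _tree("((a,b),(c,d));")
        hist = fitch_reconstruct(tree, {x: 1 for x in "abcd"})
        assert hist.score == 0
        assert hist.events == []
        assert all(s == 1 for s in hist.node_states.values())

    def test_single_clade_transition(self):
        tree = _tree("((a,b),(c,d));")
        hist = fitch_reconstruct(tree, {"a": 1, "b": 1, "c": 0, "d": 0})
        assert hist.score == 1
        assert len(hist.events) == 1
        # root resolved toward presence, so the event is a loss
        assert hist.events[0].kind == "loss"

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(7)
        for rep in range(40):
            n = int(rng.integers(4, 9))
            tree = synth.gen_tree(n, seed=int(rng.integers(2**31)))
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            states = {l: int(rng.integers(0, 2)) for l in leaves}
            hist = fitch_reconstruct(tree, states)
            assert hist.score == brute_force_parsimony(tree, states)

    def test_events_replay_to_leaf_states(self):
        rng = np.random.default_rng(3)
        tree = synth.gen_tree(12, seed=9)
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        states = {l: int(rng.integers(0, 2)) for l in leaves}
        hist = fitch_reconstruct(tree, states)
        # replay: child state flips exactly at event branches
        flips = {(e.parent, e.child) for e in hist.events}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_s = hist.node_states[node.parent_node.node_id]
            child_s = hist.node_states[node.node_id]
            expected_flip = (node.parent_node.node_id,
                             node.node_id) in flips
            assert (parent_s != child_s) == expected_flip
        for l in leaves:
            assert hist.node_states[l] == states[l]

    def test_score_invariant_under_leaf_relabeling(self):
        tree1 = _tree("((a,b),(c,(d,e)));")
        states = {"a": 1, "b": 0, "c": 1, "d": 0, "e": 1}
        s1 = fitch_reconstruct(tree1, states).score
        # same topology written with children swapped
        tree2 = _tree("(((e,d),c),(b,a));")
        assert fitch_reconstruct(tree2, states).score == s1

    def test_agrees_with_phangorn_small_parsimony(self, tmp_path):
        """Independent cross-check against R phangorn's parsimony score."""
        import shutil, subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        newick = "((a,b),((c,d),(e,f)));"
        states = {"a": 1, "b": 1, "c": 0, "d": 1, "e": 0, "f": 0}
        tree = _tree(newick)
        ours = fitch_reconstruct(tree, states).score
        script = tmp_path / "pars.R"
        script.write_text(
            'suppressMessages(library(phangorn))\n'
            f'tree <- read.tree(text="{newick}")\n'
            'states <- c(a=1, b=1, c=0, d=1, e=0, f=0)\n'
            'dat <- phyDat(matrix(states, ncol=1,'
            ' dimnames=list(names(states), NULL)),'
            ' type="USER", levels=c(0,1))\n'
            'cat(fitch(tree, dat))\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert ours == int(out.stdout.strip())

    def test_unlabeled_leaf_errors(self):
        tree = _tree("((a,b),c);")
        with pytest.raises(ValueError, match="no state"):
            fitch_reconstruct(tree, {"a": 1, "b": 0})

    def test_unrooted_tree_errors(self):
        tree = _tree("((a,b),c);")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            fitch_reconstruct(tree, {"a": 1, "b": 0, "c": 1})


class TestPerClassConservation:
    def test_simple_ratio(self, catalog):
        from rbfcoevo.synth import MatrixConfig, gen_matrix
        cfg = MatrixConfig(class_sizes={"x": 10}, default_retention=1.0,
                           base_retention={"der": 0.0})
        m, _ = gen_matrix(cfg, catalog, seed=0)
        m.values.loc[m.genomes[:7], "der"] = 1
        table = per_class_conservation(m, ["der"])
        assert table.loc[0, "ratio"] == pytest.approx(0.7)
        assert table.loc[0, "n"] == 10

    def test_single_genome_class_ratio_binary(self, catalog):
        from rbfcoevo.synth import MatrixConfig, gen_matrix
        cfg = MatrixConfig(class_sizes={"x": 1}, default_retention=1.0)
        m, _ = gen_matrix(cfg, catalog, seed=0)
        table = per_class_conservation(m)
        assert set(table["ratio"]) <= {0.0, 1.0}

    def test_class_knockouts_detected(self, paper_like):
        matrix, truth = paper_like
        table = per_class_conservation(matrix, ["der"])
        ko = set(synth.FOCAL_KNOCKOUTS["der"])
        in_ko = table["taxon_class"].isin(ko)
        assert (table.loc[in_ko, "ratio"] < 0.1).all()
        assert (table.loc[~in_ko, "ratio"] > 0.9).all()


class TestTriplets:
    @pytest.mark.parametrize("bits,state", [
        ((1, 1, 1), 7), ((0, 0, 0), 0), ((0, 1, 1), 3), ((1, 0, 0), 4),
    ])
    def test_encoding_convention(self, bits, state):
        assert encode_triplet(*bits) == state
        assert decode_triplet(state) == bits

    def test_encode_triplets_excludes_missing_calls(self, paper_like):
        matrix, _ = paper_like
        calls = synth.gen_h78_calls(synth.CPR_CLASS_SIZES, seed=12)
        partial = calls.iloc[:-10]
        states, n_excluded = encode_triplets(matrix, partial)
        assert n_excluded == 10
        assert len(states) == matrix.shape[0] - 10
        assert states["state"].between(0, 7).all()

    def test_class_proportions_sum_to_one(self):
        states, _ = synth.gen_triplet_states(seed=4)
        props = class_state_proportions(states)
        sums = props.groupby("taxon_class")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_trivial_proportions(self):
        states = pd.DataFrame({"taxon_class": ["x", "x"], "state": [7, 0],
                               "der": 1, "rplA": 1, "H78": 1})
        props = class_state_proportions(states)
        assert sorted(props["proportion"]) == [0.5, 0.5]

    def test_modal_states_match_generation(self):
        states, truth = synth.gen_triplet_states(seed=4)
        modal = modal_state_per_class(states)
        for cls, expected in truth["modal_states"].items():
            assert modal[cls] == expected


class TestTrajectory:
    def test_no_changes_single_node(self):
        tree = synth.gen_tree({"A": 3, "B": 3}, seed=1)
        node_states = {nid: 7 for nid in
                       (nd.node_id for nd in tree.preorder_node_iter())}
        g = trajectory_graph(tree, node_states, synth.leaf_class_map(tree))
        assert set(g.nodes) == {7}
        assert g.number_of_edges() == 0

    def test_simulated_single_loss_edge(self):
        """A clade losing H78 only produces the 7 -> 6 transition there."""
        tree = synth.gen_tree({"A": 4, "B": 4}, seed=2)
        classes = synth.leaf_class_map(tree)
        states = pd.DataFrame({
            "der": 1, "rplA": 1,
            "H78": [0 if classes[l] == "A" else 1 for l in classes],
        }, index=pd.Index(list(classes), name="genome_id"))
        anc = ancestral_triplet_states(tree, states)
        g = trajectory_graph(tree, anc, classes)
        assert set(g.edges()) == {(7, 6)}
        (_, _, data), = g.edges(data=True)
        assert data["clades"] == frozenset({"A"})

    def test_two_clades_lose_different_bits(self):
        tree = synth.gen_tree({"A": 4, "B": 4, "C": 4}, seed=3)
        classes = synth.leaf_class_map(tree)
        states = pd.DataFrame({
            "der": [0 if classes[l] == "A" else 1 for l in classes],
            "rplA": [0 if classes[l] == "B" else 1 for l in classes],
            "H78": 1,
        }, index=pd.Index(list(classes), name="genome_id"))
        anc = ancestral_triplet_states(tree, states)
        g = trajectory_graph(tree, anc, classes)
        assert set(g.edges()) == {(7, 3), (7, 5)}

    def test_clade_trajectory_orders_transitions(self):
        tree = synth.gen_tree({"A": 4, "B": 4}, seed=2)
        classes = synth.leaf_class_map(tree)
        states = pd.DataFrame({
            "der": 1, "rplA": 1,
            "H78": [0 if classes[l] == "A" else 1 for l in classes],
        }, index=pd.Index(list(classes), name="genome_id"))
        anc = ancestral_triplet_states(tree, states)
        assert clade_trajectory(tree, anc, ["A"], classes) == [(7, 6)]
        assert clade_trajectory(tree, anc, ["B"], classes) == []

    def test_missing_states_error(self):
        tree = synth.gen_tree({"A": 2}, seed=0)
        with pytest.raises(ValueError, match="missing"):
            trajectory_graph(tree, {}, {})


class TestTripletMI:
    def test_identical_bits_equal_entropy(self):
        from rbfcoevo.minetwork import marginal_entropy
        der = np.array([1, 0, 1, 1, 0, 0])
        states = pd.DataFrame({"der": der, "rplA": der,
                               "H78": [1, 1, 0, 0, 1, 0]})
        mi = triplet_mi(states)
        assert mi["der~rplA"] == pytest.approx(marginal_entropy(der))

    def test_independent_bits_near_zero(self):
        rng = np.random.default_rng(8)
        states = pd.DataFrame(rng.integers(0, 2, size=(4000, 3)),
                              columns=["der", "rplA", "H78"])
        mi = triplet_mi(states)
        assert all(v < 0.02 for v in mi.values())

    def test_coupling_strength_orders_mi(self):
        """Strong der-rplA coupling and weak der-H78 coupling must rank
        MI(der,rplA) above MI(der,H78)."""
        rng = np.random.default_rng(9)
        n = 2000
        der = rng.integers(0, 2, n)
        rpla = np.where(rng.random(n) < 0.9, der, rng.integers(0, 2, n))
        h78 = np.where(rng.random(n) < 0.2, der, rng.integers(0, 2, n))
        states = pd.DataFrame({"der": der, "rplA": rpla, "H78": h78})
        mi = triplet_mi(states)
        assert mi["der~rplA"] > mi["der~H78"]
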