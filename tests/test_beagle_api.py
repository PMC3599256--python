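"""API-layer tests: instance lifecycle, eigen-system transition matrices,
traversal-driven partials updates, pattern compression, newick handling."""

import numpy as np
import pytest

from plfpipe import beagle_api as api
from plfpipe.plf_kernel import NumericMode, ValidationError

NEWICK4 = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);"
NEWICK3 = "((A:0.1,B:0.2):0.05,C:0.3);"


class TestInstanceLifecycle:
    def test_buffer_allocation(self):
        inst = api.create_instance(4, 128)
        assert inst.n_buffers == 7  # 4 tips + 3 internal
        assert len(inst.partials) == 7
        assert np.all(inst.scale.lnScaler == 0)

    def test_degenerate_dimensions(self):
        with pytest.raises(ValidationError):
            api.create_instance(1, 10)
        with pytest.raises(ValidationError):
            api.create_instance(4, 0)

    def test_state_code_expansion(self):
        inst = api.create_instance(2, 2)
        api.set_instance_data(inst, ["AN", "T-"], np.full(4, 0.25), [1, 1])
        np.testing.assert_array_equal(inst.partials[0].values,
                                      [[1, 0, 0, 0], [1, 1, 1, 1]])
        np.testing.assert_array_equal(inst.partials[1].values,
                                      [[0, 0, 0, 1], [1, 1, 1, 1]])

    def test_frequencies_must_normalise(self):
        inst = api.create_instance(2, 1)
        with pytest.raises(ValidationError):
            api.set_instance_data(inst, ["A", "C"], (0.3, 0.3, 0.3, 0.3), [1])

    def test_dump_text_round_info(self):
        inst = api.create_instance(2, 1)
        api.set_instance_data(inst, ["A", "C"], np.full(4, 0.25), [1])
        text = inst.dump_text()
        assert "n_tips=2" in text and "pi\t" in text


class TestTransitionMatrices:
    def test_zero_branch_is_identity(self):
        m = api.transition_probability(api.jc69_eigen_system(), 0.0)
        np.testing.assert_allclose(m.p, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 2.0])
    def test_jc69_closed_form(self, t):
        m = api.transition_probability(api.jc69_eigen_system(), t)
        diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        off = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        expected = np.full((4, 4), off)
        np.fill_diagonal(expected, diag)
        np.testing.assert_allclose(m.p, expected, atol=1e-10)

    def test_random_reversible_rows_stochastic(self, rng):
        from plfpipe.workbench import random_reversible_eigen_system
        for _ in range(5):
            eigen, pi = random_reversible_eigen_system(rng)
            for t in (0.05, 0.3, 1.0):
                m = api.transition_probability(eigen, t)
                np.testing.assert_allclose(m.p.sum(axis=1), np.ones(4), atol=1e-9)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValidationError):
            api.transition_probability(api.jc69_eigen_system(), -0.1)


def _ready_instance(newick, seqs, mode=NumericMode.EXACT):
    tree = api.parse_newick(newick)
    patterns, weights = api.compress_patterns([seqs[n] for n in tree.tip_names()])
    inst = api.create_instance(tree.n_tips, len(weights.w), mode)
    api.set_instance_data(inst, patterns, np.full(4, 0.25), weights.w)
    api.update_all_transition_matrices(inst, api.jc69_eigen_system(), tree)
    return tree, inst


class TestUpdatePartials:
    def test_two_tip_tree_single_invocation(self):
        tree = api.parse_newick("(A:0.1,B:0.2);")
        assert len(tree.postorder_ops) == 1

    def test_four_tip_balanced_three_postorder_ops(self):
        tree = api.parse_newick(NEWICK4)
        assert len(tree.postorder_ops) == 3
        computed = set(tree.tip_ids)
        for parent, left, right in tree.postorder_ops:
            assert left in computed and right in computed
            computed.add(parent)

    def test_lnscaler_accumulates_per_node_scp(self):
        tree, inst = _ready_instance(NEWICK4, {"A": "ACGT", "B": "ACGA",
                                               "C": "GCGT", "D": "ACTT"})
        total = np.zeros(inst.n_patterns)
        inst.reset_scale_factors()
        import plfpipe.plf_kernel as pk
        for parent, left, right in tree.postorder_ops:
            inst.partials[parent] = pk.update_partials_node(
                inst.matrices[left], inst.matrices[right],
                inst.partials[left], inst.partials[right], inst.scale, inst.mode)
            total += inst.scale.scP
        np.testing.assert_allclose(inst.scale.lnScaler, total, atol=1e-12)

    def test_update_partials_requires_matrices(self):
        tree = api.parse_newick("(A:0.1,B:0.2);")
        inst = api.create_instance(2, 1)
        api.set_instance_data(inst, ["A", "C"], np.full(4, 0.25), [1])
        with pytest.raises(ValidationError):
            api.update_partials(inst, tree)


class TestRootLogLikelihood:
    def test_two_tip_all_ambiguous_hand_computation(self):
        # every tip N: partials all ones; clP[s] = (sum_x P) * (sum_y P) = 1,
        # condLike = 1, so lnL = 0 per site
        tree, inst = _ready_instance("(A:0.1,B:0.2);", {"A": "NNN", "B": "NNN"})
        api.update_partials(inst, tree)
        lnl = api.calculate_root_log_likelihood(inst, tree)
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_loglikelihood_nonpositive(self):
        tree, inst = _ready_instance(NEWICK4, {"A": "ACGTAC", "B": "ACGAAC",
                                               "C": "GCGTTT", "D": "ACTTAC"})
        api.update_partials(inst, tree)
        assert api.calculate_root_log_likelihood(inst, tree) <= 0

    def test_pulley_principle(self):
        # re-rooting along the same edge leaves the likelihood unchanged
        # for a reversible model: split the 0.05+0.07 internal edge
        seqs = {"A": "ACGTACGTAA", "B": "ACGAACGTAT",
                "C": "GCGTACATAA", "D": "ACTTACGGAA"}
        t1, i1 = _ready_instance("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);", seqs)
        t2, i2 = _ready_instance("((A:0.1,B:0.2):0.02,(C:0.3,D:0.15):0.10);", seqs)
        t3, i3 = _ready_instance("((A:0.1,B:0.2):0.12,(C:0.3,D:0.15):0.00);", seqs)
        api.update_partials(i1, t1)
        api.update_partials(i2, t2)
        api.update_partials(i3, t3)
        l1 = api.calculate_root_log_likelihood(i1, t1)
        l2 = api.calculate_root_log_likelihood(i2, t2)
        l3 = api.calculate_root_log_likelihood(i3, t3)
        assert l1 == pytest.approx(l2, rel=1e-9)
        assert l1 == pytest.approx(l3, rel=1e-9)

    def test_rerun_after_reset_is_deterministic(self):
        tree, inst = _ready_instance(NEWICK4, {"A": "ACGTAC", "B": "ACGAAC",
                                               "C": "GCGTTT", "D": "ACTTAC"})
        api.update_partials(inst, tree)
        l1 = api.calculate_root_log_likelihood(inst, tree)
        api.update_partials(inst, tree)  # resets scale factors internally
        l2 = api.calculate_root_log_likelihood(inst, tree)
        assert l1 == l2


class TestCompressPatterns:
    def test_identical_columns(self):
        patterns, w = api.compress_patterns(["A" * 100, "C" * 100])
        assert patterns == ["A", "C"]
        assert list(w.w) == [100]

    def test_all_distinct_columns(self):
        patterns, w = api.compress_patterns(["ACGT", "CGTA"])
        assert len(w.w) == 4 and np.all(w.w == 1)

    def test_weights_conserve_length(self, rng):
        rows = ["".join(rng.choice(list("ACGTN"), 57)) for _ in range(5)]
        patterns, w = api.compress_patterns(rows)
        assert int(w.w.sum()) == 57
        assert all(len(p) == len(w.w) for p in patterns)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValidationError):
            api.compress_patterns(["ACGT", "ACG"])


class TestNewick:
    def test_three_tip_parse(self):
        tree = api.parse_newick(NEWICK3)
        assert tree.n_tips == 3
        assert len(tree.postorder_ops) == 2
        assert tree.tip_names() == ["A", "B", "C"]

    def test_missing_lengths_rejected(self):
        with pytest.raises(api.TreeParseError):
            api.parse_newick("(A,B);")

    def test_polytomy_rejected(self):
        with pytest.raises(api.TreeParseError):
            api.parse_newick("(A:0.1,B:0.2,C:0.3);")

    def test_write_parse_round_trip(self):
        tree = api.parse_newick(NEWICK4)
        back = api.parse_newick(api.write_newick(tree))
        assert back.tip_names() == tree.tip_names()
        for nid in back.nodes:
            a, b = back.nodes[nid], tree.nodes[nid]
            assert a.children == b.children
            if b.length is not None:
                assert a.length == pytest.approx(b.length, rel=1e-9)
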