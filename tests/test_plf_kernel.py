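"""Likelihood-kernel unit tests: per-site columns, rescaling, scaler
bookkeeping, root accumulation, and the brute-force pruning oracle."""

import numpy as np
import pytest

from plfpipe import plf_kernel as pk
from plfpipe.plf_kernel import (DegenerateSiteError, NumericMode,
                                PartialsTable, PatternWeights, ScaleBuffers,
                                StateFrequencies, TransitionMatrix)

from conftest import random_partials, random_stochastic_matrix

I4 = np.eye(4)
U4 = np.full((4, 4), 0.25)


def brute_force_site_likelihood(tree_ops, tip_partials, matrices, pi, site):
    """Independent oracle: enumerate every assignment of states to the
    internal nodes and sum pi(root state) x product of edge transition
    probabilities x tip partials.  Exponential in internal-node count —
    usable only on small trees, which is the point."""
    internals = [op[0] for op in tree_ops]
    n_int = len(internals)
    total = 0.0
    for assign in np.ndindex(*(4,) * n_int):
        states = dict(zip(internals, assign))
        # root prior
        prob = pi[states[internals[-1]]]
        for parent, left, right in tree_ops:
            s = states[parent]
            for child in (left, right):
                p_edge = matrices[child].p
                if child in states:  # internal child
                    prob *= p_edge[s, states[child]]
                else:  # tip child: marginalise over its partials
                    prob *= float(p_edge[s] @ tip_partials[child][site])
        total += prob
    return total


class TestComputeSitePartials:
    def test_identity_preserves_one_hot(self):
        out = pk.compute_site_partials(TransitionMatrix(I4), TransitionMatrix(I4),
                                       (1, 0, 0, 0), (1, 0, 0, 0))
        np.testing.assert_array_equal(out, [1, 0, 0, 0])

    def test_uniform_matrix_all_ones(self):
        out = pk.compute_site_partials(TransitionMatrix(U4), TransitionMatrix(U4),
                                       (1, 1, 1, 1), (1, 1, 1, 1))
        np.testing.assert_allclose(out, [1, 1, 1, 1])

    def test_matches_direct_double_evaluation(self, rng):
        for _ in range(25):
            pl, pr = random_stochastic_matrix(rng), random_stochastic_matrix(rng)
            clL = rng.uniform(0, 1, 4).astype(np.float32)
            clR = rng.uniform(0, 1, 4).astype(np.float32)
            dev = pk.compute_site_partials(TransitionMatrix(pl), TransitionMatrix(pr),
                                           clL, clR, NumericMode.DEVICE)
            oracle = (pl @ clL.astype(np.float64)) * (pr @ clR.astype(np.float64))
            np.testing.assert_allclose(dev, oracle, rtol=1e-5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(pk.ValidationError):
            pk.compute_site_partials(TransitionMatrix(I4), TransitionMatrix(I4),
                                     (np.nan, 0, 0, 0), (1, 0, 0, 0))
        with pytest.raises(pk.ValidationError):
            pk.compute_site_partials(TransitionMatrix(I4), TransitionMatrix(I4),
                                     (-1, 0, 0, 0), (1, 0, 0, 0))

    def test_conservation_in_unit_interval(self, rng):
        # row-stochastic matrices and tip partials in [0,1] keep all
        # partials in [0,1] before rescaling
        for _ in range(10):
            pl, pr = random_stochastic_matrix(rng), random_stochastic_matrix(rng)
            out = pk.compute_site_partials(TransitionMatrix(pl), TransitionMatrix(pr),
                                           rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
            assert np.all(out >= 0) and np.all(out <= 1)


class TestRescaleSite:
    def test_max_normalisation(self):
        norm, scaler = pk.rescale_site((0.5, 0.25, 0.1, 0.05))
        assert scaler == 0.5
        np.testing.assert_allclose(norm, [1, 0.5, 0.2, 0.1])

    def test_already_normalised(self):
        norm, scaler = pk.rescale_site((1, 1, 1, 1))
        assert scaler == 1
        np.testing.assert_array_equal(norm, [1, 1, 1, 1])

    def test_all_zero_site_raises(self):
        with pytest.raises(DegenerateSiteError):
            pk.rescale_site((0, 0, 0, 0))


class TestUpdatePartialsNode:
    def _children(self, rng, n):
        return (PartialsTable(random_partials(rng, n), role="tip"),
                PartialsTable(random_partials(rng, n), role="tip"))

    def test_fresh_buffers_lnscaler_equals_scp(self, rng):
        clL, clR = self._children(rng, 16)
        scale = ScaleBuffers.zeros(16)
        pk.update_partials_node(TransitionMatrix(random_stochastic_matrix(rng)),
                                TransitionMatrix(random_stochastic_matrix(rng)),
                                clL, clR, scale)
        np.testing.assert_array_equal(scale.lnScaler, scale.scP)

    def test_cascaded_updates_accumulate(self, rng):
        clL, clR = self._children(rng, 16)
        scale = ScaleBuffers.zeros(16)
        m = TransitionMatrix(random_stochastic_matrix(rng))
        out1 = pk.update_partials_node(m, m, clL, clR, scale)
        scp1 = scale.scP.copy()
        pk.update_partials_node(m, m, out1, out1, scale)
        np.testing.assert_allclose(scale.lnScaler, scp1 + scale.scP, atol=1e-12)

    def test_every_row_max_is_one(self, rng):
        clL, clR = self._children(rng, 64)
        scale = ScaleBuffers.zeros(64)
        out = pk.update_partials_node(TransitionMatrix(random_stochastic_matrix(rng)),
                                      TransitionMatrix(random_stochastic_matrix(rng)),
                                      clL, clR, scale)
        np.testing.assert_array_equal(out.values.max(axis=1), np.ones(64))

    def test_degenerate_site_reports_index(self):
        z = PartialsTable(np.array([[1.0, 0, 0, 0], [0, 0, 0, 0.0]]), role="tip")
        m = TransitionMatrix(I4)
        with pytest.raises(DegenerateSiteError, match="site 1"):
            pk.update_partials_node(m, m, z, z, ScaleBuffers.zeros(2))


class TestRootLogLikelihood:
    def test_all_ones_gives_zero(self):
        root = PartialsTable(np.ones((5, 4)), role="root")
        lnl = pk.root_log_likelihood(root, StateFrequencies(np.full(4, 0.25)),
                                     ScaleBuffers.zeros(5),
                                     PatternWeights(np.ones(5, dtype=int)))
        assert lnl == 0.0

    def test_single_one_hot_site(self):
        root = PartialsTable(np.array([[1.0, 0, 0, 0]]), role="root")
        lnl = pk.root_log_likelihood(root, StateFrequencies(np.full(4, 0.25)),
                                     ScaleBuffers.zeros(1),
                                     PatternWeights(np.array([2])))
        assert lnl == pytest.approx(2 * np.log(0.25), rel=1e-12)

    def test_degenerate_root_raises(self):
        root = PartialsTable(np.array([[0.0, 0, 1, 0]]), role="root")
        with pytest.raises(DegenerateSiteError):
            pk.root_log_likelihood(root, StateFrequencies((1.0, 0, 0, 0)),
                                   ScaleBuffers.zeros(1),
                                   PatternWeights(np.array([1])))


def _random_tree_ops(rng, n_tips):
    """Random postorder op list over tip ids 0..n_tips-1."""
    avail = list(range(n_tips))
    next_id = n_tips
    ops = []
    while len(avail) > 1:
        i, j = sorted(rng.choice(len(avail), 2, replace=False))
        right = avail.pop(j)
        left = avail.pop(i)
        ops.append((next_id, left, right))
        avail.append(next_id)
        next_id += 1
    return ops


class TestPruningOracle:
    @pytest.mark.parametrize("n_tips", [3, 4, 5])
    def test_exact_mode_matches_state_enumeration(self, rng, n_tips):
        n_sites = 6
        ops = _random_tree_ops(rng, n_tips)
        tips = {i: random_partials(rng, n_sites) for i in range(n_tips)}
        matrices = {nid: TransitionMatrix(random_stochastic_matrix(rng))
                    for nid in range(2 * n_tips - 2)}  # every non-root node
        pi = rng.dirichlet(np.ones(4))
        # kernel path with rescaling at every internal node
        scale = ScaleBuffers.zeros(n_sites)
        bufs = {i: PartialsTable(tips[i], role="tip") for i in range(n_tips)}
        for parent, left, right in ops:
            bufs[parent] = pk.update_partials_node(
                matrices[left], matrices[right], bufs[left], bufs[right], scale)
        lnl = pk.root_log_likelihood(bufs[ops[-1][0]], StateFrequencies(pi),
                                     scale, PatternWeights(np.ones(n_sites, int)))
        oracle = sum(np.log(brute_force_site_likelihood(ops, tips, matrices, pi, k))
                     for k in range(n_sites))
        assert lnl == pytest.approx(oracle, rel=1e-9)

    def test_scaling_invariance(self, rng):
        # exact-mode lnL is identical with per-node rescaling on or off
        n_tips, n_sites = 5, 32
        ops = _random_tree_ops(rng, n_tips)
        tips = {i: random_partials(rng, n_sites) for i in range(n_tips)}
        matrices = {nid: TransitionMatrix(random_stochastic_matrix(rng))
                    for nid in range(2 * n_tips - 2)}
        pi = rng.dirichlet(np.ones(4))
        scale = ScaleBuffers.zeros(n_sites)
        bufs = {i: PartialsTable(tips[i], role="tip") for i in range(n_tips)}
        for parent, left, right in ops:
            bufs[parent] = pk.update_partials_node(
                matrices[left], matrices[right], bufs[left], bufs[right], scale)
        lnl_scaled = pk.root_log_likelihood(bufs[ops[-1][0]], StateFrequencies(pi),
                                            scale, PatternWeights(np.ones(n_sites, int)))
        # unscaled pruning, pure double precision
        unbufs = {i: tips[i] for i in range(n_tips)}
        for parent, left, right in ops:
            unbufs[parent] = (unbufs[left] @ matrices[left].p.T) * \
                             (unbufs[right] @ matrices[right].p.T)
        lnl_plain = float(np.log(unbufs[ops[-1][0]] @ pi).sum())
        assert lnl_scaled == pytest.approx(lnl_plain, rel=1e-9)


class TestPartialsIO:
    def test_round_trip(self, rng, tmp_path):
        table = PartialsTable(random_partials(rng, 8), role="root")
        w = PatternWeights(rng.integers(1, 20, 8))
        path = tmp_path / "partials.tsv"
        pk.write_partials(table, path, w)
        back, wback = pk.read_partials(path)
        np.testing.assert_array_equal(back.values, table.values)
        assert back.role == "root"
        np.testing.assert_array_equal(wback.w, w.w)
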