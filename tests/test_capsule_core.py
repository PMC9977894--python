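"""Capsule primitives: squashing, voting, routing, grouping, vote counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groupcapsnet.autodiff import Tensor
from groupcapsnet.capsule_core import (
    CapsuleField, ConfigurationError, GroupPartition, RoutingConfig,
    WeightBank, count_votes, deconv_capsule_layer, grouped_capsule_layer,
    grouped_fusion_layer, modified_squash, route_cluster, squash,
    squash_flops, vote,
)
from conftest import make_bank, make_field

R3 = RoutingConfig(3)


# ---------------------------------------------------------------------------
# Squashing nonlinearities
# ---------------------------------------------------------------------------

class TestSquashing:
    @pytest.mark.parametrize("fn", [squash, modified_squash])
    def test_zero_maps_to_zero(self, fn):
        np.testing.assert_allclose(fn(np.zeros(4)), np.zeros(4))

    def test_unit_norm_values_match_closed_forms(self):
        # both length maps equal 1/2 at unit norm
        np.testing.assert_allclose(squash(np.array([1.0, 0.0])),
                                   [0.5, 0.0], atol=1e-7)
        np.testing.assert_allclose(modified_squash(np.array([0.0, 1.0])),
                                   [0.0, 0.5], atol=1e-7)

    def test_printed_closed_forms_at_3_4(self):
        # |v| = 5: squash -> (25/26) * v/5 ; modified -> v/6
        v = np.array([3.0, 4.0])
        np.testing.assert_allclose(squash(v), 25 / 26 * np.array([0.6, 0.8]),
                                   atol=1e-7)
        np.testing.assert_allclose(modified_squash(v), v / 6.0, atol=1e-9)

    @pytest.mark.parametrize("fn", [squash, modified_squash])
    @given(v=st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_norm_bound_and_direction(self, fn, v):
        v = np.asarray(v, dtype=float)
        out = fn(v)
        nv, no = np.linalg.norm(v), np.linalg.norm(out)
        assert no < 1.0
        if nv > 1e-6:
            # direction preserved exactly: cosine between v and out is 1
            assert np.dot(out, v) == pytest.approx(no * nv, rel=1e-9)

    @pytest.mark.parametrize("fn", [squash, modified_squash])
    def test_length_map_strictly_increasing(self, fn):
        xs = np.linspace(0.01, 30, 300)
        lens = [np.linalg.norm(fn(np.array([x, 0.0]))) for x in xs]
        assert np.all(np.diff(lens) > 0)

    def test_maps_agree_exactly_at_zero_and_one(self):
        # x^2/(1+x^2) and x/(1+x) coincide at x = 0 and x = 1 only
        for v in (np.zeros(3), np.array([0.6, 0.8, 0.0])):
            np.testing.assert_allclose(squash(v), modified_squash(v),
                                       atol=1e-7)
        v = np.array([2.0, 0.0])
        assert not np.allclose(squash(v), modified_squash(v))

    def test_modified_variant_needs_fewer_flops(self):
        for dim in (2, 4, 8, 16, 64):
            assert squash_flops(dim, "modified_squash") < \
                squash_flops(dim, "squash")

    def test_tensor_and_array_paths_agree(self):
        v = np.random.default_rng(0).normal(size=(3, 5))
        np.testing.assert_allclose(squash(Tensor(v)).data, squash(v))


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

class TestVote:
    def _single_vote(self, W, v):
        """Route a 1x1 spatial, 1-in-type instance through vote()."""
        field = CapsuleField(v.reshape(1, 1, 1, 1, -1))
        bank = WeightBank(1, 1, v.size, W.shape[0], (1, 1),
                          GroupPartition(1, 1), rng=None, dtype=float)
        bank.matrices.data[0, 0, 0, 0] = W
        vs = vote(field, bank, padding=0)
        return vs.votes.data.reshape(W.shape[0])

    def test_identity_matrix_returns_input(self):
        u = self._single_vote(np.eye(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(u, [1.0, 0.0])

    def test_scalar_scaling(self):
        u = self._single_vote(2 * np.eye(2), np.array([0.3, -0.4]))
        np.testing.assert_allclose(u, [0.6, -0.8])

    def test_matches_dense_per_pair_oracle(self, rng):
        # 1x1 spatial, 2 in-types dim 2, 1 out-type dim 3
        field = make_field(1, 1, 1, 2, 2, seed=3)
        bank = make_bank(2, 1, 2, 3, g=1, kernel=(1, 1), seed=4)
        vs = vote(field, bank, padding=0)
        # oracle: independent matrix-vector products per (t', t)
        expected = np.zeros((2, 3))
        for t in range(2):
            W = bank.matrices.data[0, 0, t, 0]
            expected[t] = W @ field.values.data[0, 0, 0, t]
        got = vs.votes.data.reshape(2, 1, 3)[:, 0, :]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_dimension_mismatch_names_layer(self):
        field = make_field(1, 2, 2, 2, 5)
        bank = make_bank(2, 2, 4, 4, g=1)
        with pytest.raises(ConfigurationError, match="test"):
            vote(field, bank)

    def test_empty_receptive_field_rejected(self):
        field = make_field(1, 1, 1, 2, 4)
        bank = make_bank(2, 2, 4, 4, g=1, kernel=(2, 2))
        with pytest.raises(ConfigurationError, match="receptive field"):
            vote(field, bank, stride=2, padding=0)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def routing_transcript(u, iterations, nonlin):
    """Independent scalar implementation of the routing recurrence.

    u: (out_types, n_votes, dim) votes for a single group and position.
    Logits start at zero; couplings soft-max across output types per vote;
    the squashed output feeds the agreement update.
    """
    to, c, d = u.shape
    b = np.zeros((to, c))
    for it in range(iterations):
        e = np.exp(b - b.max(axis=0, keepdims=True))
        coup = e / e.sum(axis=0, keepdims=True)
        v_hat = np.zeros((to, d))
        for o in range(to):
            for j in range(c):
                v_hat[o] += coup[o, j] * u[o, j]
        if it + 1 < iterations:
            for o in range(to):
                a = nonlin(v_hat[o])
                for j in range(c):
                    b[o, j] += float(u[o, j] @ a)
    return v_hat, coup


class TestRouting:
    def _vote_set(self, u):
        """Wrap (out_types, C, dim) votes for a single position/group."""
        to, c, d = u.shape
        from groupcapsnet.capsule_core import VoteSet
        votes = u.transpose(1, 0, 2).reshape(1, c, 1, to, d)
        return VoteSet(Tensor(np.ascontiguousarray(votes)), batch=1,
                       height=1, width=1)

    def test_single_vote_preserves_direction(self):
        u = np.array([[[3.0, 4.0]]])                 # 1 out type, 1 vote
        out = route_cluster(self._vote_set(u), R3, squash)
        v = out.values.data.reshape(2)
        cos = v @ u[0, 0] / (np.linalg.norm(v) * 5)
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_identical_votes_sum_with_uniform_couplings(self):
        # 1 iteration, k identical votes, uniform couplings (softmax of 0)
        k = 4
        u = np.tile(np.array([0.5, -0.2]), (1, k, 1))
        out = route_cluster(self._vote_set(u), RoutingConfig(1), squash)
        # single output type -> each coupling is 1 -> v_hat = k * u
        np.testing.assert_allclose(out.values.data.reshape(2),
                                   k * u[0, 0], atol=1e-12)

    def test_three_iteration_hand_transcript(self):
        # 3 votes, 2 output types, dim 2 -- against the scalar transcript
        rng = np.random.default_rng(7)
        u = rng.normal(0, 1.0, (2, 3, 2))
        for nonlin, npfn in ((squash, squash), (modified_squash,
                                                modified_squash)):
            out = route_cluster(self._vote_set(u), R3, nonlin)
            expected, coup = routing_transcript(u, 3, npfn)
            np.testing.assert_allclose(
                out.values.data.reshape(2, 2), expected, atol=1e-10)

    def test_couplings_nonnegative_convex_cone(self, rng):
        field = make_field(1, 4, 4, 4, 6, seed=9)
        bank = make_bank(4, 4, 6, 6, g=2, seed=10)
        vs = vote(field, bank)
        route_cluster(vs, R3, squash)
        assert np.all(vs.couplings >= 0)
        assert np.isfinite(vs.couplings).all()

    def test_nan_votes_raise_numeric_error(self):
        from groupcapsnet.capsule_core import NumericError
        u = np.full((2, 3, 2), np.nan)
        with pytest.raises(NumericError):
            route_cluster(self._vote_set(u), R3, squash)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            RoutingConfig(0)


# ---------------------------------------------------------------------------
# Grouped layers
# ---------------------------------------------------------------------------

def sub_bank(bank, group):
    """Extract group `group` of a grouped bank as an independent g=1 bank."""
    ti = bank.in_types // bank.partition.g
    to = bank.out_types // bank.partition.g
    sb = WeightBank(ti, to, bank.in_dim, bank.out_dim, bank.kernel,
                    GroupPartition(1, ti), bank.kernel_shared,
                    rng=None, dtype=bank.matrices.dtype)
    sb.matrices.data[0] = bank.matrices.data[group]
    return sb


class TestGroupedLayer:
    @pytest.mark.parametrize("t,g", [(4, 1), (4, 2), (8, 2), (8, 4),
                                     (16, 2), (16, 4)])
    def test_group_equivalence_oracle(self, t, g):
        """Grouped layer == concatenation of independent per-group layers."""
        field = make_field(2, 5, 5, t, 4, seed=t * 10 + g)
        bank = make_bank(t, t, 4, 6, g=g, seed=t + g)
        out = grouped_capsule_layer(field, bank, GroupPartition(g, t), R3,
                                    squash)
        blk = t // g
        parts = []
        for i in range(g):
            sub_field = CapsuleField(
                field.values.data[:, :, :, i * blk:(i + 1) * blk, :])
            parts.append(grouped_capsule_layer(
                sub_field, sub_bank(bank, i), GroupPartition(1, blk), R3,
                squash).values.data)
        expected = np.concatenate(parts, axis=3)
        assert np.abs(out.values.data - expected).max() < 1e-6

    def test_g1_equals_nongrouped(self):
        field = make_field(1, 4, 4, 4, 4, seed=2)
        bank = make_bank(4, 4, 4, 4, g=1, seed=3)
        out1 = grouped_capsule_layer(field, bank, GroupPartition(1, 4), R3,
                                     modified_squash)
        # non-grouped reference: vote + route + squash composition
        vs = vote(field, bank)
        ref = modified_squash(route_cluster(vs, R3, modified_squash).values)
        assert np.abs(out1.values.data - ref.data).max() < 1e-6

    def test_single_output_type_fast_path_matches_general(self):
        field = make_field(2, 6, 6, 4, 8, seed=5)
        bank = make_bank(4, 2, 8, 16, g=2, seed=6)
        fast = grouped_capsule_layer(field, bank, GroupPartition(2, 4), R3,
                                     modified_squash)
        vs = vote(field, bank)
        slow = modified_squash(
            route_cluster(vs, R3, modified_squash).values)
        assert np.abs(fast.values.data - slow.data).max() < 1e-10

    def test_indivisible_types_rejected(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            make_bank(6, 6, 4, 4, g=4)

    def test_output_lengths_strictly_below_one(self):
        field = make_field(1, 4, 4, 4, 4, seed=11)
        field = CapsuleField(field.values.data * 100)
        bank = make_bank(4, 4, 4, 4, g=2, seed=12)
        out = grouped_capsule_layer(field, bank, GroupPartition(2, 4), R3,
                                    squash)
        assert out.lengths().max() < 1.0

    def test_type_permutation_within_group_equivariance(self):
        """Permuting in-group input types together with the matching weight
        slices leaves the output unchanged (grouping is the only cross-type
        structure)."""
        field = make_field(1, 4, 4, 4, 4, seed=21)
        bank = make_bank(4, 4, 4, 4, g=2, seed=22)
        out = grouped_capsule_layer(field, bank, GroupPartition(2, 4), R3,
                                    squash).values.data
        # swap the two types inside group 0 (types 0 and 1)
        perm = [1, 0, 2, 3]
        field2 = CapsuleField(field.values.data[:, :, :, perm, :])
        bank2 = make_bank(4, 4, 4, 4, g=2, seed=22)
        bank2.matrices.data[0] = bank.matrices.data[0][:, [1, 0]]
        out2 = grouped_capsule_layer(field2, bank2, GroupPartition(2, 4), R3,
                                     squash).values.data
        assert np.abs(out - out2).max() < 1e-10


class TestDeconvLayer:
    def test_doubles_spatial_extent(self):
        field = make_field(1, 8, 8, 4, 4, seed=1)
        bank = make_bank(4, 2, 4, 8, g=2, kernel=(2, 2), seed=2)
        out = deconv_capsule_layer(field, bank, GroupPartition(2, 4), R3,
                                   squash)
        assert (out.height, out.width) == (16, 16)
        assert (out.n_types, out.dim) == (2, 8)

    def test_scatter_oracle_nonshared(self):
        """g=1 deconv == explicit per-position vote scattering + routing."""
        field = make_field(1, 3, 3, 2, 3, seed=4)
        bank = make_bank(2, 2, 3, 4, g=1, kernel=(2, 2), seed=5)
        out = deconv_capsule_layer(field, bank, GroupPartition(1, 2), R3,
                                   squash).values.data
        W = bank.matrices.data[0]               # (To, Ti, 4, do, di)
        x = field.values.data[0]
        expected = np.zeros((6, 6, 2, 4))
        for i in range(3):
            for j in range(3):
                for a in range(2):
                    for b in range(2):
                        u = np.zeros((2, 2, 4))   # (out type, in type, do)
                        for to in range(2):
                            for ti in range(2):
                                u[to, ti] = W[to, ti, a * 2 + b] @ x[i, j, ti]
                        vh, _ = routing_transcript(u, 3, squash)
                        expected[2 * i + a, 2 * j + b] = vh
        expected = squash(expected)
        assert np.abs(out[0] - expected).max() < 1e-8

    def test_constant_field_gives_constant_output(self):
        vals = np.tile(np.array([0.3, -0.1, 0.2, 0.4]), (1, 4, 4, 2, 1))
        field = CapsuleField(vals)
        bank = make_bank(2, 2, 4, 4, g=1, kernel=(2, 2), kernel_shared=True,
                         seed=7)
        out = deconv_capsule_layer(field, bank, GroupPartition(1, 2), R3,
                                   squash).values.data
        # kernel-shared deconv of a constant field is constant everywhere
        assert np.abs(out - out[:, :1, :1]).max() < 1e-12

    def test_shared_matches_manual_upsample(self):
        field = make_field(1, 4, 4, 2, 4, seed=8)
        bank = make_bank(2, 2, 4, 4, g=1, kernel=(2, 2), kernel_shared=True,
                         seed=9)
        out = deconv_capsule_layer(field, bank, GroupPartition(1, 2), R3,
                                   squash).values.data
        for a in range(2):
            for b in range(2):
                np.testing.assert_allclose(out[:, a::2, b::2], out[:, ::2, ::2])


class TestFusionLayer:
    def test_matches_concatenated_vote_routing(self):
        f1 = make_field(1, 4, 4, 2, 4, seed=30)
        f2 = make_field(1, 4, 4, 2, 6, seed=31)     # different dims
        b1 = make_bank(2, 2, 4, 8, g=2, seed=32)
        b2 = make_bank(2, 2, 6, 8, g=2, seed=33)
        out = grouped_fusion_layer([f1, f2], [b1, b2], R3, squash)
        # oracle: votes computed separately and pooled before routing
        from groupcapsnet.capsule_core import VoteSet
        import groupcapsnet.autodiff as ad
        v1, v2 = vote(f1, b1), vote(f2, b2)
        u = np.concatenate([v1.votes.data, v2.votes.data], axis=1)
        fused = VoteSet(Tensor(u), batch=1, height=4, width=4)
        ref = squash(route_cluster(fused, R3, squash).values)
        assert np.abs(out.values.data - ref.data).max() < 1e-10

    def test_bank_count_mismatch_rejected(self):
        f1 = make_field(1, 4, 4, 2, 4)
        b1 = make_bank(2, 2, 4, 8, g=2)
        with pytest.raises(ConfigurationError):
            grouped_fusion_layer([f1], [b1, b1], R3, squash)


# ---------------------------------------------------------------------------
# Vote counting
# ---------------------------------------------------------------------------

class TestCountVotes:
    @pytest.mark.parametrize("g,expected", [(1, 16), (2, 8), (4, 4)])
    def test_all_pairs_1x1(self, g, expected):
        assert count_votes(4, 4, 1, 1, 1, g) == expected

    @pytest.mark.parametrize("t", [4, 8, 16])
    @pytest.mark.parametrize("g", [1, 2, 4])
    @pytest.mark.parametrize("karea,hw", [(1, 1), (9, 8), (4, 16)])
    def test_vote_count_law(self, t, g, karea, hw):
        """count(g) * g == count(1), exactly, across a config grid."""
        assert count_votes(t, t, karea, hw, hw, g) * g == \
            count_votes(t, t, karea, hw, hw, 1)

    def test_materialized_votes_match_analytic_count(self):
        field = make_field(2, 6, 6, 4, 4, seed=40)
        bank = make_bank(4, 4, 4, 4, g=2, seed=41)
        vs = vote(field, bank)
        assert vs.votes_per_sample == count_votes(4, 4, 9, 6, 6, 2)

    def test_indivisible_rejected(self):
        with pytest.raises(ConfigurationError):
            count_votes(6, 6, 1, 1, 1, 4)
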