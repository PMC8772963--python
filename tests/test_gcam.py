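"""GCAM primitives, chain composition, shape law and parameter accounting."""

import itertools

import numpy as np
import pytest

from oracles import mlp_weight_tally
from pemnet.gcam import (GCAMChain, GCAMConfig, RefinementMLP,
                         apply_to_features, budget_chain, count_params,
                         gcam_forward, hidden_width, make_refinement_mlps,
                         pool_concat, propagate, refine)
from pemnet.nn import Tensor


class OnesStub:
    """Refiner stub emitting an all-ones vector (identity for propagate)."""

    def __init__(self, in_dim, out_dim):
        self.in_dim, self.out_dim = in_dim, out_dim

    def refine_vector(self, v):
        return np.ones(self.out_dim)


class TestPoolConcat:
    def test_constant_map(self):
        out = pool_concat(np.full((3, 2, 2), 7.0))
        np.testing.assert_array_equal(out, [7, 7, 7, 7, 7, 7])

    def test_single_channel_max_then_mean(self):
        np.testing.assert_allclose(pool_concat(np.array([[[1., 2.], [3., 4.]]])),
                                   [4.0, 2.5])

    def test_spatial_permutation_invariance(self, rng):
        m = rng.normal(size=(4, 3, 5))
        perm = rng.permutation(15)
        m2 = m.reshape(4, 15)[:, perm].reshape(4, 3, 5)
        np.testing.assert_allclose(pool_concat(m), pool_concat(m2))


class TestRefine:
    def test_zero_weights_sigmoid_gives_half(self):
        mlp = RefinementMLP(4, 6, r=2)
        mlp.W2.data[:] = 0
        np.testing.assert_allclose(refine(np.zeros(4), mlp), 0.5)

    def test_hand_set_2_1_2_identity_activations(self):
        mlp = RefinementMLP(2, 2, r=2, hidden_activation="identity",
                            output_activation="identity")
        mlp.W2.data = np.array([[1., 1.]], np.float32)
        mlp.W1.data = np.array([[1.], [-1.]], np.float32)
        np.testing.assert_allclose(refine(np.array([2., 3.]), mlp), [5., -5.])

    def test_sigmoid_output_strictly_inside_unit_interval(self, rng):
        mlp = RefinementMLP(8, 16, r=4, rng=rng)
        mlp.W1.data = rng.normal(size=mlp.W1.data.shape).astype(np.float32)
        out = refine(rng.normal(size=8), mlp)
        assert np.all(out > 0) and np.all(out < 1)

    def test_dimension_mismatch_names_dims(self):
        mlp = RefinementMLP(4, 8)
        with pytest.raises(ValueError, match="in_dim=4"):
            refine(np.zeros(6), mlp)


class TestPropagateApply:
    def test_identity_annihilator_product(self):
        b = np.array([4.0, 3.0])
        np.testing.assert_allclose(propagate(np.ones(2), b), b)
        np.testing.assert_allclose(propagate(np.zeros(2), b), 0)
        np.testing.assert_allclose(propagate(np.array([0.5, 2.0]), b), [2.0, 6.0])
        with pytest.raises(ValueError):
            propagate(np.ones(3), b)

    def test_apply_scales_channels(self, rng):
        m = rng.normal(size=(2, 3, 3))
        out = apply_to_features(m, np.array([2.0, 0.0]))
        np.testing.assert_allclose(out[0], 2 * m[0])
        np.testing.assert_allclose(out[1], 0)
        np.testing.assert_allclose(apply_to_features(m, np.ones(2)), m)
        # homogeneity
        a = rng.normal(size=2)
        np.testing.assert_allclose(apply_to_features(m, 3.0 * a),
                                   3.0 * apply_to_features(m, a))

    def test_sigmoid_attention_never_amplifies(self, rng):
        m = rng.normal(size=(4, 5, 5))
        mlp = RefinementMLP(4, 4, r=2, rng=rng)
        mlp.W1.data = rng.normal(size=mlp.W1.data.shape).astype(np.float32)
        attn = refine(rng.normal(size=4), mlp)
        out = apply_to_features(m, attn)
        assert np.all(np.abs(out) <= np.abs(m))

    def test_shape_mismatch_and_projection(self, rng):
        m = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError):
            apply_to_features(m, np.ones(4))
        out = apply_to_features(m, np.array([1.0, 3.0, 2.0, 1.0]),
                                final_projection="allow")
        np.testing.assert_allclose(out, m * np.array([1.5, 2.0])[:, None, None])


class TestChain:
    def test_two_levels_equals_primitive_composition(self, rng):
        cfg = GCAMConfig((2, 4))
        maps = [rng.normal(size=(2, 1, 1)), rng.normal(size=(4, 1, 1))]
        np.testing.assert_allclose(gcam_forward(maps, cfg, []),
                                   apply_to_features(maps[1], pool_concat(maps[0])))

    def test_three_levels_equals_hand_composition(self, rng):
        cfg = GCAMConfig((2, 4, 8), r=2)
        mlps = make_refinement_mlps(cfg, rng)
        for m in mlps:
            m.W1.data = rng.normal(size=m.W1.data.shape).astype(np.float32)
        maps = [rng.normal(size=(2, 2, 3)), rng.normal(size=(4, 2, 2)),
                rng.normal(size=(8, 1, 1))]
        v = pool_concat(maps[0])
        v = refine(v, mlps[0])
        v = propagate(v, pool_concat(maps[1]))
        expect = apply_to_features(maps[2], v)
        np.testing.assert_allclose(gcam_forward(maps, cfg, mlps), expect)

    def test_ones_stubs_make_chain_identity(self, rng):
        cfg = GCAMConfig((2, 4, 8, 16), r=2)
        stubs = [OnesStub(2 * c, 2 * cn)
                 for c, cn in zip(cfg.tap_channels, cfg.tap_channels[1:])][:2]
        maps = [rng.normal(size=(c, 2, 2)) for c in (2, 4, 8)]
        final = rng.normal(size=(16, 2, 2))
        # ones from the last stub times pooled stats of the last tapped map
        out = gcam_forward(maps + [final], cfg, stubs)
        expect = apply_to_features(final, pool_concat(maps[2]))
        np.testing.assert_allclose(out, expect)

    def test_shape_law(self):
        GCAMConfig((8, 16, 32)).validate_chain()
        with pytest.raises(ValueError, match="double"):
            GCAMConfig((8, 16, 20)).validate_chain()
        GCAMConfig((8, 16, 20), final_projection="allow").validate_chain()

    def test_wrong_mlp_count_rejected_before_compute(self, rng):
        cfg = GCAMConfig((2, 4, 8), r=2)
        maps = [rng.normal(size=(c, 1, 1)) for c in (2, 4, 8)]
        with pytest.raises(ValueError, match="refinement MLPs"):
            gcam_forward(maps, cfg, [])

    def test_spatial_permutation_of_nonfinal_maps(self, rng):
        cfg = GCAMConfig((2, 4), r=2)
        m0 = rng.normal(size=(2, 2, 3))
        perm = rng.permutation(6)
        m0p = m0.reshape(2, 6)[:, perm].reshape(2, 2, 3)
        final = rng.normal(size=(4, 2, 2))
        np.testing.assert_allclose(gcam_forward([m0, final], cfg, []),
                                   gcam_forward([m0p, final], cfg, []))

    def test_tensor_chain_matches_numpy_chain(self, rng):
        for normalize in (False, True):
            cfg = GCAMConfig((2, 4, 8), r=2, normalize_taps=normalize)
            chain = GCAMChain(cfg, rng)
            for m in chain.mlps:
                m.W1.data = rng.normal(size=m.W1.data.shape).astype(np.float32)
            maps = [rng.normal(size=(c, 2, 2)).astype(np.float32) for c in (2, 4, 8)]
            out_np = gcam_forward(maps, cfg, chain.mlps)
            out_t = chain([Tensor(m[None]) for m in maps]).data[0]
            np.testing.assert_allclose(out_t, out_np, atol=1e-5)

    def test_force_identity_returns_last_map(self, rng):
        chain = GCAMChain(GCAMConfig((2, 4), r=2), rng)
        maps = [Tensor(rng.normal(size=(1, 2, 2, 2))),
                Tensor(rng.normal(size=(1, 4, 2, 2)))]
        np.testing.assert_array_equal(chain(maps, force_identity=True).data,
                                      maps[1].data)


class TestBudget:
    def test_closed_form_examples(self):
        assert count_params(64, 128, 8) == 8 * 64 + 128 * 8 == 1536
        for c, cp in [(4, 4), (16, 128)]:
            assert count_params(c, cp, c) == c + cp   # h = 1
        assert budget_chain(GCAMConfig((4, 8))) == 0
        assert budget_chain(GCAMConfig((4, 8, 16), r=2)) == 96

    def test_formula_equals_weight_tally(self):
        for c, cp, r in itertools.product([4, 8, 64], [4, 16, 128], [1, 2, 8]):
            for policy in ("none", "both"):
                mlp = RefinementMLP(c, cp, r=r, bias_policy=policy)
                assert count_params(c, cp, r, policy) == mlp_weight_tally(mlp)
                assert mlp.hidden_dim == hidden_width(c, r)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            count_params(0, 4, 2)
        with pytest.raises(ValueError):
            count_params(4, 4, 0)
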