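"""Network assembly: parameter accounting, bypass equivalence, training."""

import dataclasses

import numpy as np
import pytest

from pemnet.gcam import GCAMConfig, budget_chain
from pemnet.model import (ASPPConfig, BackboneSpec, PeMNetConfig, TrainConfig,
                          build_model, load_model, predict_mask, predict_proba,
                          save_model)
from pemnet.phantom import DEFAULT_MLO_RANGES, PhantomSpec, generate_dataset
from pemnet.train import evaluate_model, repeat_experiment, to_arrays, train

# a deliberately small preset so unit tests stay fast
TINY = PeMNetConfig(
    backbone=BackboneSpec(stage_channels=(4, 8, 16), stage_strides=(1, 2, 1)),
    gcam=GCAMConfig(tap_channels=(4, 8, 16), r=2, normalize_taps=True),
    aspp=ASPPConfig(branch_channels=8, dilation_rates=(2, 4)),
    input_size=64, low_level_channels=4, decoder_channels=8)

PRESETS = [
    TINY,
    PeMNetConfig(backbone=BackboneSpec(stage_channels=(8, 16), stage_strides=(1, 2)),
                 gcam=GCAMConfig(tap_channels=(8, 16), r=4),
                 aspp=ASPPConfig(branch_channels=8, dilation_rates=(2,)),
                 input_size=32, low_level_channels=4, decoder_channels=8),
    PeMNetConfig(aspp=ASPPConfig(branch_channels=16)),  # default 4-stage backbone
]


@pytest.mark.parametrize("cfg", PRESETS, ids=["3stage", "2stage", "4stage"])
def test_parameter_difference_equals_gcam_budget(cfg):
    with_gcam = build_model(cfg, seed=0)
    without = build_model(dataclasses.replace(cfg, gcam=None), seed=0)
    assert with_gcam.parameter_count() - without.parameter_count() \
        == budget_chain(cfg.gcam)


def test_identity_bypass_equals_baseline_forward(rng):
    cfg = TINY
    m = build_model(cfg, seed=4)
    b = build_model(dataclasses.replace(cfg, gcam=None), seed=4)
    x = rng.uniform(0, 255, size=(2, 1, 64, 64)).astype(np.float32)
    diff = np.abs(m.forward(x, force_identity_attention=True).data
                  - b.forward(x).data).max()
    assert diff < 1e-5


def test_forward_shape_and_probability_normalisation(rng):
    m = build_model(TINY, seed=1)
    img = rng.uniform(0, 255, size=(64, 64))
    p = predict_proba(m, img)
    assert p.shape == (2, 64, 64)
    np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-6)


def test_seeded_initialisation_is_identical():
    a, b = build_model(TINY, seed=9), build_model(TINY, seed=9)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)
    c = build_model(TINY, seed=10)
    assert any(not np.array_equal(pa.data, pc.data)
               for (_, pa), (_, pc) in zip(a.named_parameters(), c.named_parameters()))


def test_untrained_model_predicts_empty_mask(rng):
    # zero-initialised head -> constant logits -> ties -> class 0
    m = build_model(TINY, seed=2)
    assert predict_mask(m, rng.uniform(0, 255, size=(64, 64))).sum() == 0


def test_input_divisibility_error(rng):
    m = build_model(TINY, seed=2)
    with pytest.raises(ValueError, match="pad"):
        predict_mask(m, rng.uniform(0, 255, size=(60, 60)))


def test_incompatible_gcam_chain_rejected():
    with pytest.raises(ValueError, match="tap channels"):
        PeMNetConfig(backbone=BackboneSpec(stage_channels=(4, 8, 16),
                                           stage_strides=(1, 2, 1)),
                     gcam=GCAMConfig(tap_channels=(4, 8, 12)))


def _phantom_pairs(n, seed, size=64):
    base = PhantomSpec(width=size, height=size, margin=4)
    samples, _ = generate_dataset(n, DEFAULT_MLO_RANGES, seed=seed, base_spec=base)
    return samples


class TestTraining:
    def test_one_epoch_smoke_history(self):
        m = build_model(TINY, seed=0)
        hist = train(m, _phantom_pairs(8, seed=1),
                     TrainConfig(max_epochs=1, minibatch_size=4, seed=0))
        assert len(hist) == 1 and np.isfinite(hist[0]["loss"])
        assert hist[0]["lr"] == pytest.approx(1e-4)

    def test_loss_decreases_and_training_is_deterministic(self):
        data = _phantom_pairs(16, seed=2)
        tc = TrainConfig(max_epochs=4, minibatch_size=8, seed=3, initial_lr=1e-3)
        hists = []
        for _ in range(2):
            m = build_model(TINY, seed=5)
            hists.append(train(m, data, tc))
        assert hists[0] == hists[1]
        assert hists[0][-1]["loss"] < hists[0][0]["loss"]

    def test_validation_errors(self):
        m = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(m, [], TrainConfig(max_epochs=1))
        bad = [(np.zeros((64, 64)), np.zeros((32, 32), np.uint8))]
        with pytest.raises(ValueError, match="disagree"):
            to_arrays(bad)
        nonbinary = [(np.zeros((64, 64)), np.full((64, 64), 2, np.uint8))]
        with pytest.raises(ValueError, match="0,1"):
            to_arrays(nonbinary)


def test_repeat_experiment_bookkeeping():
    data = _phantom_pairs(6, seed=4)
    tc = TrainConfig(max_epochs=1, minibatch_size=6, seed=0)
    res = repeat_experiment(TINY, tc, 3, data, data[:3], base_seed=1)
    assert len(set(res.seeds)) == 3 and len(res.runs) == 3
    single = repeat_experiment(TINY, tc, 1, data, data[:3], base_seed=1)
    assert all(v == 0.0 for v in single.report.std.values())
    # mean of per-run means equals pooled mean at equal eval-set sizes
    flat = [ms.jaccard for run in res.runs for ms in run]
    assert res.report.mean["jaccard"] == pytest.approx(np.mean(flat))


def test_checkpoint_roundtrip(tmp_path, rng):
    m = build_model(TINY, seed=6)
    img = rng.uniform(0, 255, size=(64, 64))
    save_model(m, tmp_path / "ck.npz")
    m2 = load_model(tmp_path / "ck.npz")
    np.testing.assert_array_equal(predict_mask(m, img), predict_mask(m2, img))
    assert m2.cfg == m.cfg
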