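"""Loss masking, label smoothing, schedules and training mechanics."""

import numpy as np
import pytest

from spliceml.datasets import EncodedBlock
from spliceml.errors import DataError
from spliceml.junctions import TISSUES
from spliceml.model import ModelConfig, SpliceNet
from spliceml.training import (MINI_SCHEDULE, TrainingSchedule, fine_tune,
                               masked_loss, smoothed_targets, train,
                               train_protocol)

CFG = ModelConfig(n_residual_blocks=2, channels=8, kernels=(5, 5),
                  dilations=(1, 2), skip_taps=(1,))


def make_blocks(rng, n=10, with_sites=True):
    """Small random blocks matching CFG's context (= 12)."""
    c = CFG.context
    step = 40
    blocks = []
    for i in range(n):
        x = np.zeros((step + 2 * c, 4), np.float32)
        x[np.arange(step + 2 * c), rng.integers(0, 4, step + 2 * c)] = 1
        y = np.zeros((step, 12), np.float32)
        y[:, 0::3] = 1.0
        if with_sites and i % 2 == 0:
            pos = int(rng.integers(0, step))
            for t in range(4):
                y[pos, 3 * t: 3 * t + 3] = (0, 1, rng.uniform(0.2, 1.0))
        blocks.append(EncodedBlock("g%d" % i, 0, x, y, 0))
    return blocks


class TestMaskedLoss:
    def test_all_masked_gives_zero(self, rng):
        raw = rng.normal(size=(2, 9, 12)).astype(np.float32)
        labels = np.zeros_like(raw)
        loss, grad = masked_loss(raw, labels)
        assert loss == 0.0
        assert np.all(grad == 0.0)

    def test_perfect_predictions_give_near_zero(self):
        raw = np.zeros((1, 4, 12), np.float32)
        labels = np.zeros_like(raw)
        labels[..., 0::3] = 1.0          # unspliced everywhere, usage 0
        raw[..., 0::3] = 30.0            # softmax -> (1, 0)
        raw[..., 2::3] = -60.0           # sigmoid -> 0
        loss, _ = masked_loss(raw, labels)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_masked_labels_never_affect_loss(self, rng):
        raw = rng.normal(size=(2, 7, 12)).astype(np.float32)
        labels = np.zeros_like(raw)
        labels[0, 2, 0:3] = (0, 1, 0.5)
        base, _ = masked_loss(raw, labels)
        tampered = labels.copy()
        tampered[1, 3, 2] = 0.9   # usage under a [0,0] pair: masked
        loss2, _ = masked_loss(raw, tampered)
        assert loss2 == base

    def test_smoothing_targets_exact(self):
        assert smoothed_targets(True) == (0.05, 0.95)
        assert smoothed_targets(False) == (0.95, 0.05)

    def test_smoothed_optimum_is_smoothed_target(self):
        """With label smoothing the CE-minimizing probability is 0.95."""
        labels = np.zeros((1, 1, 12), np.float32)
        labels[..., 0::3] = 1.0
        grid = np.linspace(-6, 6, 400)
        losses = []
        for z in grid:
            raw = np.zeros((1, 1, 12), np.float32)
            raw[..., 0::3] = z / 2
            raw[..., 1::3] = -z / 2
            loss, _ = masked_loss(raw, labels, label_types=("probability",),
                                  label_smoothing=0.05, with_grad=False)
            losses.append(loss)
        zstar = grid[int(np.argmin(losses))]
        p_unspliced = 1 / (1 + np.exp(-zstar))
        assert p_unspliced == pytest.approx(0.95, abs=0.01)

    def test_single_tissue_restriction(self, rng):
        raw = rng.normal(size=(1, 5, 12)).astype(np.float32)
        labels = np.zeros_like(raw)
        labels[..., 0::3] = 1.0
        loss_h, grad = masked_loss(raw, labels, tissues=("heart",))
        # gradients flow only into heart's three output channels
        assert np.all(grad[..., 3:] == 0.0)
        tampered = labels.copy()
        tampered[..., 3:6] = 0.0  # change liver labels
        loss2, _ = masked_loss(raw, tampered, tissues=("heart",))
        assert loss2 == loss_h

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(DataError):
            masked_loss(np.zeros((1, 3, 12)), np.zeros((1, 4, 12)))


class TestTrain:
    def test_reduces_heldout_loss_and_is_deterministic(self, rng):
        blocks = make_blocks(rng, n=16)
        sched = TrainingSchedule(pretrain_cycles=(2,), batch_size=4,
                                 holdout_fraction=0.25, patience=99)
        log1, log2 = [], []
        net1 = train(blocks, CFG, sched, seed=3, log=log1)
        net2 = train(blocks, CFG, sched, seed=3, log=log2)
        strip = lambda rows: [{k: v for k, v in r.items() if k != "seconds"}
                              for r in rows]
        assert strip(log1) == strip(log2)  # bitwise-reproducible given the seed
        w1, w2 = net1.copy_weights(), net2.copy_weights()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)

    def test_lr_log_hits_cycle_boundaries(self, rng):
        blocks = make_blocks(rng, n=12)
        log = []
        sched = TrainingSchedule(pretrain_cycles=(1, 2), batch_size=4,
                                 holdout_fraction=0.0, patience=99)
        train(blocks, CFG, sched, seed=0, log=log)
        assert log[0]["lr_start"] == pytest.approx(5e-4)
        assert log[0]["lr_end"] == pytest.approx(0.0)   # end of cycle 1
        assert log[1]["lr_start"] == pytest.approx(5e-4)  # restart
        assert log[-1]["lr_end"] == pytest.approx(0.0)  # end of cycle 2

    def test_empty_training_set_errors(self):
        with pytest.raises(DataError):
            train([], CFG)

    def test_all_masked_dataset_errors(self, rng):
        blocks = make_blocks(rng, n=4)
        for b in blocks:
            b.y[...] = 0.0
        with pytest.raises(DataError):
            train(blocks, CFG)


class TestFineTune:
    def test_only_selected_outputs_move(self, rng):
        blocks = make_blocks(rng, n=8)
        base = train(blocks, CFG, TrainingSchedule(pretrain_cycles=(1,),
                                                   batch_size=4,
                                                   holdout_fraction=0.0),
                     seed=1)
        tuned = fine_tune(base, blocks, "heart", "usage", epochs=1, lr=5e-4,
                          batch_size=4, seed=2, weight_decay=0.0)
        w0, w1 = base.state_arrays(), tuned.state_arrays()
        # the output convolution only changes in heart's usage column
        d_out = np.abs(w1["out.W"] - w0["out.W"])[0]  # (channels, 12)
        moved = d_out.max(axis=0) > 0
        assert moved[2] and not moved[3:].any() and not moved[0]

    def test_splice_free_removal(self, rng):
        blocks = make_blocks(rng, n=8)   # odd blocks have no sites
        base = train(blocks, CFG, TrainingSchedule(pretrain_cycles=(1,),
                                                   batch_size=4,
                                                   holdout_fraction=0.0),
                     seed=1)
        with_sites = [b for b in blocks if b.y[:, 1].sum() > 0]
        assert 0 < len(with_sites) < len(blocks)
        tuned = fine_tune(base, blocks, "heart", "probability", epochs=1,
                          lr=5e-5, remove_splice_free=True, batch_size=4,
                          seed=2, label_smoothing=0.05)
        assert tuned is not base

    def test_unknown_tissue_errors(self, rng, tiny_net):
        with pytest.raises(DataError):
            fine_tune(tiny_net, make_blocks(rng), "kidney", "usage",
                      epochs=1, lr=1e-4)


def test_protocol_produces_all_combinations(rng):
    blocks = make_blocks(rng, n=8)
    sched = TrainingSchedule(pretrain_cycles=(1,), tissue_epochs=1,
                             finetune_epochs=1, batch_size=4,
                             holdout_fraction=0.0, ensemble_size=1,
                             finetune_ensemble_size=1)
    combos = (("heart", "probability"), ("heart", "usage"))
    bundle = train_protocol(blocks, CFG, sched, seed=0, combos=combos)
    assert len(bundle.probability("heart")) == 1
    assert len(bundle.usage("heart")) == 1
    phases = set(bundle.log["phase"])
    assert {"pretrain", "heart-probability", "heart-usage"} <= phases
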