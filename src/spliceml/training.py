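"""Masked multi-task losses and the three-phase training protocol.

Phase 1 (joint pre-training) trains all four tissues and both label types
at once with AdamW under a cosine-annealed warm-restart schedule (cycle
lengths in epochs, learning rate 5e-4 at each cycle start decaying to 0 at
the cycle end); 10% of the blocks are held out to pick the early-stopping
epoch.  Phase 2 trains each (tissue, label type) combination separately for
a few epochs at 5e-4.  Phase 3 fine-tunes each combination with label
smoothing (spliced/unspliced targets [0.05, 0.95] / [0.95, 0.05]) at 5e-5,
after removing blocks that contain no splice site for the tissue.

Losses: categorical cross-entropy on each tissue's softmax probability
pair, binary cross-entropy on each tissue's sigmoid usage output, summed
over tissues.  A position whose probability pair is labeled [0, 0]
(padding, unknown, or a spliced site failing the coverage rule) contributes
zero to both losses.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import EncodedBlock
from .errors import DataError
from .junctions import TISSUES
from .model import ModelConfig, SpliceNet
from .nn import AdamW, cycle_step_lrs, sigmoid, softmax_pairs

ALL_COMBOS = tuple((t, lt) for t in TISSUES for lt in ("probability", "usage"))


@dataclass(frozen=True)
class TrainingSchedule:
    """Epochs, learning rates and sizes for the three training phases."""

    pretrain_cycles: tuple[int, ...] = (2, 4)
    pretrain_lr: float = 5e-4
    tissue_epochs: int = 4
    tissue_lr: float = 5e-4
    finetune_epochs: int = 4
    finetune_lr: float = 5e-5
    label_smoothing: float = 0.05
    batch_size: int = 8
    holdout_fraction: float = 0.1
    #: epochs without held-out improvement before halting; None = run all
    #: epochs (the best-held-out weights are restored in either case)
    patience: int | None = 1
    weight_decay: float = 0.01
    ensemble_size: int = 5
    finetune_ensemble_size: int = 3


#: reduced protocol matched to the miniature model and synthetic genomes
MINI_SCHEDULE = TrainingSchedule(pretrain_cycles=(4, 8), tissue_epochs=3,
                                 finetune_epochs=1, batch_size=2,
                                 ensemble_size=1, finetune_ensemble_size=1,
                                 patience=None)


def masked_loss(raw: np.ndarray, labels: np.ndarray,
                tissues: Sequence[str] = TISSUES,
                label_types: Sequence[str] = ("probability", "usage"),
                label_smoothing: float = 0.0,
                with_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Summed masked loss and its gradient w.r.t. the raw outputs.

    ``raw`` are the *unactivated* model outputs for the labeled positions,
    shape (B, L, 12); ``labels`` has the same shape.  The loss is averaged
    over B*L positions (masked positions contribute 0) and summed over the
    selected tissues and label types.
    """
    if raw.shape != labels.shape:
        raise DataError(f"prediction shape {raw.shape} != labels {labels.shape}")
    B, L, _ = raw.shape
    norm = 1.0 / (B * L)
    grad = np.zeros_like(raw) if with_grad else None
    total = 0.0
    eps = 1e-9
    for t_name in tissues:
        t = TISSUES.index(t_name)
        pair = raw[..., 3 * t: 3 * t + 2]
        target = labels[..., 3 * t: 3 * t + 2]
        mask = target.sum(axis=-1) > 0  # [0,0] marks excluded positions
        if "probability" in label_types:
            if label_smoothing:
                s = label_smoothing
                target = np.where(mask[..., None],
                                  target * (1 - 2 * s) + s, 0.0)
            p = softmax_pairs(pair)
            ce = -(target * np.log(p + eps)).sum(axis=-1) * mask
            total += ce.sum() * norm
            if with_grad:
                grad[..., 3 * t: 3 * t + 2] = (
                    (p * target.sum(axis=-1, keepdims=True) - target)
                    * mask[..., None] * norm)
        if "usage" in label_types:
            z = raw[..., 3 * t + 2]
            u = labels[..., 3 * t + 2]
            p = sigmoid(z)
            bce = -(u * np.log(p + eps) + (1 - u) * np.log(1 - p + eps)) * mask
            total += bce.sum() * norm
            if with_grad:
                grad[..., 3 * t + 2] = (p - u) * mask * norm
    return float(total), grad


def smoothed_targets(spliced: bool, smoothing: float = 0.05) -> tuple[float, float]:
    """Label-smoothed probability-pair target for a (un)spliced site."""
    return (smoothing, 1 - smoothing) if spliced else (1 - smoothing, smoothing)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i: i + batch_size]


def _stack(blocks: Sequence[EncodedBlock], idx) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([blocks[i].x for i in idx])
    y = np.stack([blocks[i].y for i in idx])
    return x, y


def _heldout_loss(net: SpliceNet, blocks: Sequence[EncodedBlock],
                  batch_size: int, tissues, label_types,
                  label_smoothing: float = 0.0) -> float:
    c = net.config.context
    losses = []
    for i in range(0, len(blocks), batch_size):
        x, y = _stack(blocks, range(i, min(i + batch_size, len(blocks))))
        raw = net.forward_raw(x, train=False)
        raw = raw[:, c: x.shape[1] - c, :]
        loss, _ = masked_loss(raw, y, tissues, label_types,
                              label_smoothing, with_grad=False)
        losses.append(loss * len(x))
    return float(np.sum(losses) / len(blocks))


def _run_epochs(net: SpliceNet, opt: AdamW, train_blocks, heldout_blocks,
                step_lrs: np.ndarray, steps_per_epoch: int, batch_size: int,
                rng: np.random.Generator, tissues, label_types,
                label_smoothing: float, log: list, phase: str,
                patience: int | None = None, track_best: bool = False) -> None:
    """Run len(step_lrs)/steps_per_epoch epochs; early-stop on held-out loss.

    With held-out blocks and ``track_best``, the weights giving the lowest
    held-out loss are restored at the end; training halts early after
    ``patience`` consecutive epochs without improvement (None = never).
    """
    c = net.config.context
    n_epochs = len(step_lrs) // max(steps_per_epoch, 1)
    best = (np.inf, None)
    bad_epochs = 0
    step = 0
    for epoch in range(n_epochs):
        t0 = time.time()
        epoch_losses = []
        lr_start = step_lrs[step] if step < len(step_lrs) else 0.0
        for idx in _batches(len(train_blocks), batch_size, rng):
            lr = float(step_lrs[min(step, len(step_lrs) - 1)])
            x, y = _stack(train_blocks, idx)
            raw = net.forward_raw(x, train=True)
            mid = raw[:, c: x.shape[1] - c, :]
            loss, grad_mid = masked_loss(mid, y, tissues, label_types,
                                         label_smoothing)
            grad = np.zeros_like(raw)
            grad[:, c: x.shape[1] - c, :] = grad_mid
            opt.zero_grad()
            net.backward_raw(grad)
            opt.step(lr)
            epoch_losses.append(loss)
            step += 1
        lr_end = float(step_lrs[step - 1])
        held = (np.nan if not heldout_blocks else
                _heldout_loss(net, heldout_blocks, batch_size, tissues,
                              label_types, label_smoothing))
        log.append({"phase": phase, "epoch": epoch,
                    "train_loss": float(np.mean(epoch_losses)),
                    "heldout_loss": held, "lr_start": float(lr_start),
                    "lr_end": lr_end, "seconds": time.time() - t0})
        if track_best and heldout_blocks:
            if held < best[0] - 1e-9:
                best = (held, net.copy_weights())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if patience is not None and bad_epochs >= patience:
                    break
    if best[1] is not None:
        net.load_weights(best[1])


def train(blocks: Sequence[EncodedBlock], config: ModelConfig,
          schedule: TrainingSchedule = TrainingSchedule(), seed: int = 0,
          log: list | None = None) -> SpliceNet:
    """Phase-1 joint pre-training with warm restarts and early stopping."""
    if not blocks:
        raise DataError("empty training set")
    if not any(b.y[:, 0::3].sum() + b.y[:, 1::3].sum() > 0 for b in blocks):
        raise DataError("no unmasked labels in any block")
    rng = np.random.default_rng(seed)
    net = SpliceNet(config, seed=int(rng.integers(2 ** 31)))
    opt = AdamW(net.params(), weight_decay=schedule.weight_decay)
    order = rng.permutation(len(blocks))
    n_held = int(round(schedule.holdout_fraction * len(blocks)))
    held = [blocks[i] for i in order[:n_held]]
    tr = [blocks[i] for i in order[n_held:]]
    steps_per_epoch = -(-len(tr) // schedule.batch_size)
    step_lrs = np.concatenate([
        cycle_step_lrs(c, steps_per_epoch, schedule.pretrain_lr)
        for c in schedule.pretrain_cycles])
    if log is None:
        log = []
    _run_epochs(net, opt, tr, held, step_lrs, steps_per_epoch,
                schedule.batch_size, rng, TISSUES, ("probability", "usage"),
                0.0, log, phase="pretrain", patience=schedule.patience,
                track_best=True)
    net._log = log  # noqa: SLF001 - convenience handle for callers
    return net


def _has_splice_site(block: EncodedBlock, tissue: str) -> bool:
    t = TISSUES.index(tissue)
    return bool(block.y[:, 3 * t + 1].sum() > 0)


def fine_tune(net: SpliceNet, blocks: Sequence[EncodedBlock], tissue: str,
              label_type: str, epochs: int, lr: float,
              label_smoothing: float = 0.0, remove_splice_free: bool = False,
              batch_size: int = 8, weight_decay: float = 0.01,
              seed: int = 0, log: list | None = None) -> SpliceNet:
    """Continue training with the loss restricted to one tissue/label type.

    Returns a new network; the input network is left untouched.  With
    ``remove_splice_free`` blocks containing no spliced position for the
    tissue are dropped (the smoothed fine-tuning phase).
    """
    if tissue not in TISSUES:
        raise DataError(f"unknown tissue {tissue!r}")
    if label_type not in ("probability", "usage"):
        raise DataError(f"unknown label type {label_type!r}")
    tuned = SpliceNet(net.config)
    tuned.load_weights(net.copy_weights())
    use = [b for b in blocks if not remove_splice_free
           or _has_splice_site(b, tissue)]
    if not use:
        raise DataError("no blocks left after removing splice-free sequences")
    rng = np.random.default_rng(seed)
    opt = AdamW(tuned.params(), weight_decay=weight_decay)
    steps_per_epoch = -(-len(use) // batch_size)
    step_lrs = cycle_step_lrs(epochs, steps_per_epoch, lr)
    if log is None:
        log = []
    _run_epochs(tuned, opt, use, [], step_lrs, steps_per_epoch, batch_size,
                rng, (tissue,), (label_type,), label_smoothing, log,
                phase=f"{tissue}-{label_type}")
    tuned._log = log  # noqa: SLF001
    return tuned


@dataclass
class ModelBundle:
    """Fine-tuned ensembles per (tissue, label type)."""

    members: dict = field(default_factory=dict)
    log: pd.DataFrame | None = None

    def ensemble(self, tissue: str, label_type: str) -> list[SpliceNet]:
        return self.members[(tissue, label_type)]

    def probability(self, tissue: str) -> list[SpliceNet]:
        return self.members[(tissue, "probability")]

    def usage(self, tissue: str) -> list[SpliceNet]:
        return self.members[(tissue, "usage")]


def train_protocol(blocks: Sequence[EncodedBlock], config: ModelConfig,
                   schedule: TrainingSchedule = TrainingSchedule(),
                   seed: int = 0, smoothed: bool = True,
                   combos: Sequence[tuple[str, str]] = ALL_COMBOS,
                   ) -> ModelBundle:
    """The full three-phase protocol with ensembling.

    ``ensemble_size`` independent runs of pre-training + per-combination
    training are performed; with ``smoothed`` the label-smoothed fine-tuning
    phase is applied on top (its ensemble size may differ).  Returns the
    per-combination ensembles of the last phase run.
    """
    rng = np.random.default_rng(seed)
    log: list = []
    members: dict = {combo: [] for combo in combos}
    n_runs = max(schedule.ensemble_size,
                 schedule.finetune_ensemble_size if smoothed else 0)
    for run in range(n_runs):
        base = train(blocks, config, schedule,
                     seed=int(rng.integers(2 ** 31)), log=log)
        for tissue, label_type in combos:
            stage2 = fine_tune(
                base, blocks, tissue, label_type,
                epochs=schedule.tissue_epochs, lr=schedule.tissue_lr,
                batch_size=schedule.batch_size,
                weight_decay=schedule.weight_decay,
                seed=int(rng.integers(2 ** 31)), log=log)
            model = stage2
            if smoothed and run < schedule.finetune_ensemble_size:
                model = fine_tune(
                    stage2, blocks, tissue, label_type,
                    epochs=schedule.finetune_epochs, lr=schedule.finetune_lr,
                    label_smoothing=schedule.label_smoothing,
                    remove_splice_free=True,
                    batch_size=schedule.batch_size,
                    weight_decay=schedule.weight_decay,
                    seed=int(rng.integers(2 ** 31)), log=log)
            if run < (schedule.finetune_ensemble_size if smoothed
                      else schedule.ensemble_size):
                members[(tissue, label_type)].append(model)
    return ModelBundle(members=members, log=pd.DataFrame(log))
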