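"""The dilated-residual splice network.

The network maps a one-hot DNA sequence of length ``N >= 2*context + 1`` to
12 outputs per position for the middle ``N - 2*context`` positions: for
each of the four tissues (heart, liver, brain, testis) a softmax pair
(P_unspliced, P_spliced) and a sigmoid usage value.

Architecture: an input 1x1 convolution lifts the 4-channel one-hot input to
the working width; a stack of pre-activation residual blocks (each two
BN -> ReLU -> dilated-conv units with an identity shortcut) grows the
receptive field; skip connections tap the activations entering selected
residual blocks (and the stack's output) with 1x1 convolutions and sum them
into the input of the penultimate 1x1 convolution, which produces the 12
output channels.  The receptive half-width equals the sum over residual
blocks of ``dilation * (kernel - 1)``, and the flank positions whose
receptive field leaves the input are cropped from the output.

The full-scale configuration (16 blocks in four groups with kernels
11/11/21/41 and dilations 1/4/10/25, skip taps before blocks 1, 5, 9 and
13) has a receptive half-width of 5,000 bases; the miniature configuration
used by the synthetic fixtures (4 blocks, kernel 11, dilations 1/2/6/16)
has a half-width of 250.

A single network carries both output heads; the *probability* and *usage*
model variants differ only in which outputs are trained and read out.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import BlockGeometry, one_hot_encode
from .errors import DataError
from .junctions import TISSUES
from .nn import Conv1d, Param, ResidualBlock, sigmoid, softmax_pairs

N_OUT = 12
PROB_COLS = np.array([3 * t + i for t in range(4) for i in (0, 1)])
SPLICED_COLS = np.array([3 * t + 1 for t in range(4)])
USAGE_COLS = np.array([3 * t + 2 for t in range(4)])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``kernels``/``dilations`` give one entry per residual block (each block
    applies two convolutions with that kernel and dilation).  ``skip_taps``
    are 1-based block indices whose *input* activations are tapped into the
    skip sum; the stack output is always tapped as well.
    """

    n_residual_blocks: int = 16
    channels: int = 32
    kernels: tuple[int, ...] = (11,) * 4 + (11,) * 4 + (21,) * 4 + (41,) * 4
    dilations: tuple[int, ...] = (1,) * 4 + (4,) * 4 + (10,) * 4 + (25,) * 4
    skip_taps: tuple[int, ...] = (1, 5, 9, 13)
    head_type: str = "combined"  # combined | probability | usage

    def __post_init__(self) -> None:
        if len(self.kernels) != self.n_residual_blocks or \
                len(self.dilations) != self.n_residual_blocks:
            raise DataError("kernels/dilations must list one entry per block")
        if any(t < 1 or t > self.n_residual_blocks for t in self.skip_taps):
            raise DataError("skip_taps must lie in 1..n_residual_blocks")

    @property
    def context(self) -> int:
        return receptive_half_width(self)


MINI_CONFIG = ModelConfig(n_residual_blocks=4, channels=32,
                          kernels=(11, 11, 11, 11), dilations=(1, 2, 6, 16),
                          skip_taps=(1, 3))


def receptive_half_width(config: ModelConfig) -> int:
    """Bases of context on each side: sum of dilation*(kernel-1) per block."""
    return int(sum(d * (k - 1) for k, d in
                   zip(config.kernels, config.dilations)))


class SpliceNet:
    """Forward/backward network over channel-last one-hot input."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        C = config.channels
        self.conv_in = Conv1d(4, C, 1, 1, rng, "in")
        self.blocks = [
            ResidualBlock(C, k, d, rng, f"rb{i + 1}")
            for i, (k, d) in enumerate(zip(config.kernels, config.dilations))]
        self.taps = {i: Conv1d(C, C, 1, 1, rng, f"tap{i}")
                     for i in sorted(config.skip_taps)}
        self.tap_out = Conv1d(C, C, 1, 1, rng, "tap_out")
        self.conv_out = Conv1d(C, N_OUT, 1, 1, rng, "out")

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.conv_in.params()
        for b in self.blocks:
            ps += b.params()
        for t in sorted(self.taps):
            ps += self.taps[t].params()
        ps += self.tap_out.params() + self.conv_out.params()
        return ps

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {p.name: p.data for p in self.params()}
        for i, b in enumerate(self.blocks):
            for j, u in enumerate((b.u1, b.u2)):
                arrays[f"rb{i + 1}.u{j + 1}.bn.rm"] = u.bn.running_mean
                arrays[f"rb{i + 1}.u{j + 1}.bn.rv"] = u.bn.running_var
        return arrays

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.state_arrays().items():
            v[...] = weights[k]

    # -- computation -------------------------------------------------------
    def forward_raw(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Uncropped, unactivated outputs, shape (B, L, 12)."""
        h = self.conv_in.forward(x.astype(np.float32, copy=False), train)
        skip = None
        for i, block in enumerate(self.blocks, start=1):
            if i in self.taps:
                t = self.taps[i].forward(h, train)
                skip = t if skip is None else skip + t
            h = block.forward(h, train)
        t = self.tap_out.forward(h, train)
        skip = t if skip is None else skip + t
        return self.conv_out.forward(skip, train)

    def backward_raw(self, dout: np.ndarray) -> None:
        dskip = self.conv_out.backward(dout)
        dh = self.tap_out.backward(dskip)
        dtaps = {i: self.taps[i].backward(dskip) for i in self.taps}
        for i in range(len(self.blocks), 0, -1):
            dh = self.blocks[i - 1].backward(dh)
            if i in dtaps:
                dh = dh + dtaps[i]
        self.conv_in.backward(dh)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Activated predictions for the middle N - 2*context positions.

        Per tissue ``t`` the output columns are ``(3t, 3t+1)`` = softmax
        (P_unspliced, P_spliced) and ``3t+2`` = sigmoid usage.
        """
        c = self.config.context
        if x.shape[1] < 2 * c + 1:
            raise DataError(
                f"input length {x.shape[1]} < 2*context+1 = {2 * c + 1}")
        raw = self.forward_raw(x, train)
        raw = raw[:, c: x.shape[1] - c, :]
        return activate(raw)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def activate(raw: np.ndarray) -> np.ndarray:
    """Apply the output heads: softmax on probability pairs, sigmoid usage."""
    out = np.empty_like(raw)
    out[..., PROB_COLS] = softmax_pairs(raw[..., PROB_COLS])
    out[..., USAGE_COLS] = sigmoid(raw[..., USAGE_COLS])
    return out


def ensemble_predict(models: Sequence[SpliceNet], x: np.ndarray) -> np.ndarray:
    """Elementwise mean of member predictions."""
    if not models:
        raise DataError("ensemble_predict requires at least one model")
    out = models[0].predict(x)
    for m in models[1:]:
        out += m.predict(x)
    return out / len(models)


def predict_sequence(models: Sequence[SpliceNet], sequence: str,
                     geometry: BlockGeometry | None = None,
                     batch_size: int = 16) -> np.ndarray:
    """Stitched predictions over a whole gene sequence, shape (len, 12).

    The sequence is padded with ``flank`` Ns, tiled into overlapping blocks,
    predicted block-wise and stitched from the block middles; the result is
    identical (to float roundoff) to one forward pass over the whole padded
    sequence.  ``geometry.flank`` must be >= the models' context (default: a
    geometry with flank = context and step = 4*context).
    """
    if not models:
        raise DataError("predict_sequence requires at least one model")
    c = models[0].config.context
    if geometry is None:
        geometry = BlockGeometry(flank=c, step=4 * c)
    if geometry.flank < c:
        raise DataError("geometry flank smaller than model context")
    from .datasets import pad_and_tile  # local import to avoid cycle
    blocks = pad_and_tile(sequence, geometry)
    xs = np.stack([b.x for b in blocks])
    outs = []
    extra = geometry.flank - c  # positions to trim beyond the middle
    for i in range(0, len(xs), batch_size):
        out = ensemble_predict(models, xs[i: i + batch_size])
        outs.append(out[:, extra: out.shape[1] - extra, :])
    track = np.concatenate(outs, axis=0).reshape(-1, N_OUT)
    return track[: len(sequence)]


def predict_site(models: Sequence[SpliceNet], window: str) -> np.ndarray:
    """Predictions (12,) for the center position of a 2*context+1 window."""
    x = one_hot_encode(window)[None]
    return ensemble_predict(models, x)[0, 0]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def save_checkpoint(model: SpliceNet, path: str | Path,
                    meta: dict | None = None) -> None:
    payload = dict(model.state_arrays())
    header = {"schema": SCHEMA_VERSION, "config": asdict(model.config),
              "meta": meta or {}}
    payload["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[SpliceNet, dict]:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]))
        if header["schema"] != SCHEMA_VERSION:
            raise DataError(f"unsupported checkpoint schema {header['schema']}")
        cfg = header["config"]
        for key in ("kernels", "dilations", "skip_taps"):
            cfg[key] = tuple(cfg[key])
        model = SpliceNet(ModelConfig(**cfg))
        model.load_weights({k: npz[k] for k in npz.files if k != "__header__"})
    return model, header["meta"]
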