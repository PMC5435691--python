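"""Encoder-decoder fully convolutional network for slicewise kidney segmentation.

The encoder follows the first 10 convolution layers of the VGG-16 layout —
blocks of (2, 64), (2, 128), (3, 256), (3, 512) 3x3/pad-1 convolutions, each
convolution followed by batch normalization and ReLU, with 2x2/stride-2
max-pooling between blocks that records the argmax locations.  The decoder
mirrors the encoder: index-driven unpooling restores spatial resolution and
deconvolution stacks (3x3, stride 1, pad 1) refine it, finishing in a 1x1
convolution that maps the final feature maps to the two classes (kidney /
non-kidney).  A per-pixel softmax yields foreground probabilities and the
network is trained with mean multinomial cross-entropy under AdaGrad.

A ``width_multiplier`` scales every channel count so the same architecture
runs as a desk-scale profile (e.g. 64x64 input at 0.25 width) for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (AdaGrad, BatchNorm2d, Conv2d, MaxPool2d, MaxUnpool2d, ReLU,
                 softmax, softmax_cross_entropy)

DEFAULT_ENCODER_BLOCKS: tuple[tuple[int, int], ...] = ((2, 64), (2, 128), (3, 256), (3, 512))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    ``encoder_blocks`` is a sequence of (n_conv_layers, n_channels); the
    default totals 10 convolution layers.  The decoder always mirrors the
    encoder, so output spatial size equals input spatial size.
    """

    input_size: tuple[int, int] = (224, 224)
    encoder_blocks: tuple[tuple[int, int], ...] = DEFAULT_ENCODER_BLOCKS
    kernel_size: int = 3
    n_classes: int = 2
    batch_norm: bool = True
    width_multiplier: float = 1.0
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        n_pools = len(self.encoder_blocks)
        div = 2 ** n_pools
        for d in self.input_size:
            if d % div:
                raise ValueError(
                    f"input size {self.input_size} not divisible by 2^{n_pools}")

    def channels(self) -> list[int]:
        """Per-block channel counts after applying the width multiplier."""
        return [max(1, int(round(c * self.width_multiplier)))
                for _, c in self.encoder_blocks]


@dataclass
class TrainingConfig:
    """Optimization recipe: AdaGrad, lr 1e-4, weight decay 5e-4, batch size 8."""

    optimizer: str = "adagrad"
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    batch_size: int = 8
    n_iterations: int = 500
    seed: int = 0
    log_every: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adagrad":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class SegNet:
    """The assembled network: ordered layer graph with pool-index routing."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels()
        k = spec.kernel_size

        def conv_block(cin: int, cout: int) -> list:
            layers: list = [Conv2d(cin, cout, k, rng)]
            if spec.batch_norm:
                layers.append(BatchNorm2d(cout))
            layers.append(ReLU())
            return layers

        self.enc_stages: list[list] = []
        cin = spec.in_channels
        for (n_conv, _), cout in zip(spec.encoder_blocks, ch):
            stage: list = []
            for _ in range(n_conv):
                stage.extend(conv_block(cin, cout))
                cin = cout
            self.enc_stages.append(stage)
        self.pools = [MaxPool2d() for _ in self.enc_stages]

        # Decoder mirrors the encoder: the last deconvolution of each stage
        # steps the width down to the next-shallower block.
        self.unpools = [MaxUnpool2d() for _ in self.enc_stages]
        self.dec_stages: list[list] = []
        for i in reversed(range(len(ch))):
            n_conv = spec.encoder_blocks[i][0]
            cout_next = ch[i - 1] if i > 0 else ch[0]
            stage = []
            for j in range(n_conv):
                cout = ch[i] if j < n_conv - 1 else cout_next
                stage.extend(conv_block(cin, cout))
                cin = cout
            self.dec_stages.append(stage)
        self.head = Conv2d(cin, spec.n_classes, 1, rng)
        self._tape: list | None = None

    # -- plumbing -------------------------------------------------------

    def layers(self) -> list:
        out: list = []
        for s in self.enc_stages:
            out.extend(s)
        out.extend(self.pools)
        out.extend(self.unpools)
        for s in self.dec_stages:
            out.extend(s)
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    # -- forward / backward --------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != tuple(self.spec.input_size):
            raise ValueError(
                f"input spatial size {x.shape[2:]} != spec {self.spec.input_size}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        tape: list = []
        indices: list[np.ndarray] = []
        for stage, pool in zip(self.enc_stages, self.pools):
            for layer in stage:
                x = layer.forward(x, train)
                tape.append(layer)
            x, idx = pool.forward(x, train)
            tape.append(pool)
            indices.append(idx)
        for unpool, stage in zip(self.unpools, self.dec_stages):
            x = unpool.forward(x, indices.pop(), train)
            tape.append(unpool)
            for layer in stage:
                x = layer.forward(x, train)
                tape.append(layer)
        x = self.head.forward(x, train)
        tape.append(self.head)
        self._tape = tape if train else None
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, n_classes, H, W), evaluation mode."""
        return softmax(self.forward_logits(x, train=False), axis=1)

    def backward(self, grad: np.ndarray) -> None:
        assert self._tape is not None, "call forward_logits(train=True) first"
        for layer in reversed(self._tape):
            grad = layer.backward(grad)
        self._tape = None

    # -- persistence ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def recalibrate_batchnorm(self, images: np.ndarray, batch_size: int = 8,
                              max_batches: int = 50) -> None:
        """Replace batch-norm running statistics by the average batch
        statistics over a sweep of the training set.

        The exponential running estimates lag behind the parameters during
        short training runs; one deterministic sweep (first ``max_batches``
        consecutive batches) re-anchors them before evaluation.
        """
        if images.ndim == 3:
            images = images[:, None]
        bns = [l for l in self.layers() if isinstance(l, BatchNorm2d)]
        if not bns:
            return
        sums: list[list[np.ndarray] | None] = [None] * len(bns)
        n_batches = 0
        for start in range(0, len(images), batch_size):
            if n_batches >= max_batches:
                break
            batch = np.ascontiguousarray(images[start:start + batch_size],
                                         dtype=np.float32)
            if len(batch) < 2:
                continue
            for bn in bns:
                bn.capture_stats = []
            try:
                self.forward_logits(batch, train=False)
                for i, bn in enumerate(bns):
                    (m, v), = bn.capture_stats
                    if sums[i] is None:
                        sums[i] = [m.astype(np.float64), v.astype(np.float64)]
                    else:
                        sums[i][0] += m
                        sums[i][1] += v
            finally:
                for bn in bns:
                    bn.capture_stats = None
            n_batches += 1
        if n_batches == 0:
            return
        for bn, s in zip(bns, sums):
            bn.running_mean[...] = (s[0] / n_batches).astype(np.float32)
            bn.running_var[...] = (s[1] / n_batches).astype(np.float32)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


def build_network(spec: NetworkSpec, seed: int = 0) -> SegNet:
    """Construct a SegNet with Xavier-initialized weights (deterministic per seed)."""
    return SegNet(spec, seed=seed)


def loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-pixel cross-entropy of probability maps against {0,1} labels."""
    p = np.asarray(probabilities, dtype=np.float64)
    lab = np.asarray(labels)
    if p.shape[0] != lab.shape[0] or p.shape[2:] != lab.shape[1:]:
        raise ValueError(f"shape mismatch: {p.shape} vs {lab.shape}")
    eps = 1e-12
    flat = p.transpose(0, 2, 3, 1).reshape(-1, p.shape[1])
    idx = lab.astype(np.int64).ravel()
    return float(-np.log(flat[np.arange(flat.shape[0]), idx] + eps).mean())


def train(net: SegNet, images: np.ndarray, labels: np.ndarray,
          cfg: TrainingConfig, callback=None) -> list[float]:
    """Train in place; returns the per-iteration loss history.

    ``images``: (n_slices, H, W) mean-subtracted intensities;
    ``labels``: (n_slices, H, W) in {0, 1}.  Slices are reshuffled every
    epoch; each iteration consumes one batch of ``cfg.batch_size``.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty training set")
    if images.shape != labels.shape:
        raise ValueError("image/label shape mismatch")
    rng = np.random.default_rng(cfg.seed)
    opt = AdaGrad(net.layers(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    history: list[float] = []
    order = rng.permutation(len(images))
    pos = 0
    for it in range(cfg.n_iterations):
        if pos + cfg.batch_size > len(order):
            order = rng.permutation(len(images))
            pos = 0
        take = order[pos:pos + cfg.batch_size]
        if len(take) == 0:  # fewer slices than one batch: sample with replacement
            take = rng.integers(0, len(images), size=cfg.batch_size)
        pos += cfg.batch_size
        xb = images[take][:, None]
        yb = labels[take]
        logits = net.forward_logits(xb, train=True)
        l, grad = softmax_cross_entropy(logits, yb)
        if not np.isfinite(l):
            raise FloatingPointError(
                f"training loss diverged (non-finite) at iteration {it}")
        net.backward(grad)
        opt.step()
        history.append(l)
        if callback is not None:
            callback(it, l)
    net.recalibrate_batchnorm(images, batch_size=cfg.batch_size)
    return history


def save_checkpoint(path: str | Path, net: SegNet, mean_value: float,
                    extra: dict | None = None) -> None:
    """Persist spec + parameters + the training-set mean used for centering."""
    meta = dict(asdict(net.spec))
    meta["encoder_blocks"] = list(map(list, meta["encoder_blocks"]))
    np.savez(path, __meta__=np.array([repr(meta)], dtype=object),
             __mean__=np.array([mean_value], dtype=np.float64),
             **net.state_dict())


def load_checkpoint(path: str | Path) -> tuple[SegNet, float]:
    with np.load(path, allow_pickle=True) as f:
        meta = eval(str(f["__meta__"][0]))  # noqa: S307 - own trusted format
        meta["input_size"] = tuple(meta["input_size"])
        meta["encoder_blocks"] = tuple(tuple(b) for b in meta["encoder_blocks"])
        spec = NetworkSpec(**meta)
        net = SegNet(spec)
        net.load_state_dict({k: f[k] for k in f.files
                             if not k.startswith("__")})
        mean = float(f["__mean__"][0])
    return net, mean
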