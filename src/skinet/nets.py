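"""Bayesian segmentation and classification networks.

The segmenter is a MultiResUNet — a U-Net whose convolutional blocks
approximate parallel 3x3/5x5/7x7 filtering by chaining three 3x3
convolutions (channel split 1/6, 1/3, 1/2 of W = alpha*U) with a 1x1
residual, and whose skip connections pass through "Res paths" (4, 3, 2, 1
residual conv blocks at increasing depth). Dropout layers after every
pooling and upsampling step make it Bayesian in the Monte-Carlo-dropout
sense: keeping them active at inference draws approximate posterior
samples over the weights.

The classifier is a width-scalable conv/pool CNN with the same
Bayesian-dropout contract (configurable dropout insertion points, softmax
head). Batch-norm always uses frozen running statistics during stochastic
sampling so that dropout is the only source of randomness.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import core
from .nn.core import Tensor


class InvalidSpecError(ValueError):
    """An architecture spec violates its invariants."""


class CapabilityError(RuntimeError):
    """The model cannot honour the requested mode (e.g. no dropout)."""


@dataclasses.dataclass
class MultiResBlockSpec:
    input_channels: int
    U: int
    alpha: float = 1.67
    split_fractions: tuple[float, float, float] = (1 / 6, 1 / 3, 1 / 2)


@dataclasses.dataclass
class ResPathSpec:
    n_blocks: tuple[int, ...] = (4, 3, 2, 1)
    filters: tuple[int, ...] = (32, 64, 128, 256)


@dataclasses.dataclass
class BayesianNetSpec:
    kind: str  # "segmenter" | "classifier"
    input_size: tuple[int, int] = (224, 224)
    n_classes: int = 7
    dropout_rate: float = 0.5
    dropout_positions: tuple[str, ...] | None = None
    base_filters: int = 32
    alpha: float = 1.67
    seed: int = 0


def _split_channels(U: int, alpha: float, fractions) -> tuple[int, int, int]:
    W = alpha * U
    chans = tuple(int(np.floor(W * f)) for f in fractions)
    if W <= 0 or min(chans) < 1:
        raise InvalidSpecError(f"W = alpha*U = {W:.2f} too small: splits {chans}")
    return chans


class MultiResBlock(nn.Module):
    """Three chained 3x3 conv(+BN+ReLU) branches concatenated, with a
    1x1-convolved residual of the input added before the final ReLU/BN."""

    def __init__(self, spec: MultiResBlockSpec, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = _split_channels(spec.U, spec.alpha, spec.split_fractions)
        self.out_channels = c1 + c2 + c3
        cin = spec.input_channels
        self.conv1 = nn.Conv2d(cin, c1, 3, rng)
        self.bn1 = nn.BatchNorm2d(c1)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng)
        self.bn2 = nn.BatchNorm2d(c2)
        self.conv3 = nn.Conv2d(c2, c3, 3, rng)
        self.bn3 = nn.BatchNorm2d(c3)
        self.bn_cat = nn.BatchNorm2d(self.out_channels)
        self.shortcut = nn.Conv2d(cin, self.out_channels, 1, rng)
        self.bn_short = nn.BatchNorm2d(self.out_channels)
        self.bn_out = nn.BatchNorm2d(self.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        a = core.relu(self.bn1(self.conv1(x)))
        b = core.relu(self.bn2(self.conv2(a)))
        c = core.relu(self.bn3(self.conv3(b)))
        cat = self.bn_cat(core.concat_channels([a, b, c]))
        res = self.bn_short(self.shortcut(x))
        return self.bn_out(core.relu(cat + res))


class ResPath(nn.Module):
    """Chain of residual conv blocks bridging an encoder-decoder skip."""

    def __init__(self, in_channels: int, filters: int, n_blocks: int,
                 rng: np.random.Generator):
        super().__init__()
        if n_blocks < 1:
            raise InvalidSpecError("Res path needs at least one block")
        self.out_channels = filters
        self.blocks = []
        cin = in_channels
        for i in range(n_blocks):
            conv = nn.Conv2d(cin, filters, 3, rng)
            bn = nn.BatchNorm2d(filters)
            short = nn.Conv2d(cin, filters, 1, rng)
            bn_s = nn.BatchNorm2d(filters)
            bn_o = nn.BatchNorm2d(filters)
            for j, m in enumerate((conv, bn, short, bn_s, bn_o)):
                setattr(self, f"b{i}_{j}", m)
            self.blocks.append((conv, bn, short, bn_s, bn_o))
            cin = filters

    def forward(self, x: Tensor) -> Tensor:
        for conv, bn, short, bn_s, bn_o in self.blocks:
            x = bn_o(core.relu(bn(conv(x)) + bn_s(short(x))))
        return x


def build_multires_block(spec: MultiResBlockSpec,
                         seed: int = 0) -> MultiResBlock:
    return MultiResBlock(spec, np.random.default_rng(seed))


def build_res_path(spec: ResPathSpec, depth_index: int,
                   in_channels: int | None = None,
                   seed: int = 0) -> ResPath:
    """Res path for ``depth_index`` in 1..4 (shallowest to deepest)."""
    if not 1 <= depth_index <= len(spec.n_blocks):
        raise ValueError(f"depth_index {depth_index} out of range 1..{len(spec.n_blocks)}")
    filters = spec.filters[depth_index - 1]
    n_blocks = spec.n_blocks[depth_index - 1]
    if in_channels is None:
        in_channels = filters
    return ResPath(in_channels, filters, n_blocks, np.random.default_rng(seed))


class BayesianMultiResUNet(nn.Module):
    """Encoder-decoder lesion segmenter with MC-dropout sampling.

    Four MultiRes+pool(+dropout) encoder stages, a fifth MultiRes bridge,
    and four transposed-conv(+dropout)+MultiRes decoder stages whose skip
    inputs come through Res paths; final 1x1 conv + sigmoid yields an
    HxW probability map.
    """

    def __init__(self, spec: BayesianNetSpec):
        super().__init__()
        h, w = spec.input_size
        if h % 16 or w % 16:
            raise InvalidSpecError(f"input size {spec.input_size} not divisible by 16")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        base, alpha = spec.base_filters, spec.alpha
        u = [base * 2 ** i for i in range(5)]
        cin = 3
        self.enc = []
        self.paths = []
        for i in range(4):
            mb = MultiResBlock(MultiResBlockSpec(cin, u[i], alpha), rng)
            drop = nn.Dropout(spec.dropout_rate)
            path = ResPath(mb.out_channels, u[i], 4 - i, rng)
            setattr(self, f"enc{i}", mb)
            setattr(self, f"enc_drop{i}", drop)
            setattr(self, f"respath{i}", path)
            self.enc.append((mb, drop))
            self.paths.append(path)
            cin = mb.out_channels
        self.bridge = MultiResBlock(MultiResBlockSpec(cin, u[4], alpha), rng)
        cin = self.bridge.out_channels
        self.dec = []
        for i in range(3, -1, -1):
            up = nn.ConvTranspose2x2(cin, u[i], rng)
            drop = nn.Dropout(spec.dropout_rate)
            mb = MultiResBlock(MultiResBlockSpec(u[i] + self.paths[i].out_channels,
                                                 u[i], alpha), rng)
            setattr(self, f"up{i}", up)
            setattr(self, f"dec_drop{i}", drop)
            setattr(self, f"dec{i}", mb)
            self.dec.append((i, up, drop, mb))
            cin = mb.out_channels
        self.head = nn.Conv2d(cin, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for mb, drop in self.enc:
            feat = mb(x)
            skips.append(feat)
            x = drop(core.maxpool2x2(feat))
        x = self.bridge(x)
        for i, up, drop, mb in self.dec:
            x = drop(up(x))
            x = mb(core.concat_channels([x, self.paths[i](skips[i])]))
        return core.sigmoid(self.head(x))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probability maps for a batch of HxWx3 images (returns N,H,W)."""
        x = Tensor(_to_nchw(images))
        return self.forward(x).data[:, 0]


class BayesianCNNClassifier(nn.Module):
    """Conv/pool backbone + global average pooling + softmax head, with
    dropout inserted at configurable positions for MC sampling.

    ``dropout_positions`` names insertion points: ``"stage<k>"`` (after
    conv stage k's pooling) and ``"head"`` (before the final dense layer).
    Default: after the last two conv stages and before the head.
    """

    def __init__(self, spec: BayesianNetSpec, n_stages: int = 4):
        super().__init__()
        h, w = spec.input_size
        if h % 2 ** n_stages or w % 2 ** n_stages:
            raise InvalidSpecError(
                f"input size {spec.input_size} not divisible by {2 ** n_stages}")
        if spec.n_classes < 2:
            raise InvalidSpecError("classifier needs n_classes >= 2")
        self.spec = spec
        self.n_stages = n_stages
        positions = spec.dropout_positions
        if positions is None:
            positions = (f"stage{n_stages - 2}", f"stage{n_stages - 1}", "head")
        self.positions = tuple(positions)
        rng = np.random.default_rng(spec.seed)
        cin = 3
        self.stages = []
        for i in range(n_stages):
            cout = spec.base_filters * 2 ** i
            conv = nn.Conv2d(cin, cout, 3, rng)
            bn = nn.BatchNorm2d(cout)
            drop = nn.Dropout(spec.dropout_rate) if f"stage{i}" in self.positions else None
            setattr(self, f"conv{i}", conv)
            setattr(self, f"bn{i}", bn)
            if drop is not None:
                setattr(self, f"drop{i}", drop)
            self.stages.append((conv, bn, drop))
            cin = cout
        self.head_drop = nn.Dropout(spec.dropout_rate) if "head" in self.positions else None
        self.fc = nn.Dense(cin, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Pre-softmax class scores (N, n_classes)."""
        return self.forward_with_activations(x)[0]

    def forward_with_activations(self, x: Tensor) -> tuple[Tensor, dict[str, Tensor]]:
        """Logits plus each stage's post-ReLU conv activation (for Grad-CAM)."""
        acts: dict[str, Tensor] = {}
        for i, (conv, bn, drop) in enumerate(self.stages):
            a = core.relu(bn(conv(x)))
            acts[f"stage{i}"] = a
            x = core.maxpool2x2(a)
            if drop is not None:
                x = drop(x)
        x = core.global_avg_pool(x)
        if self.head_drop is not None:
            x = self.head_drop(x)
        return self.fc(x), acts

    def forward_proba(self, x: Tensor) -> Tensor:
        return core.softmax(self.forward(x), axis=1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class-probability vectors for a batch of HxWx3 images."""
        return self.forward_proba(Tensor(_to_nchw(images))).data


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    return images.transpose(0, 3, 1, 2)


def build_bayesian_multiresunet(spec: BayesianNetSpec) -> BayesianMultiResUNet:
    if spec.kind != "segmenter":
        raise InvalidSpecError("spec.kind must be 'segmenter'")
    return BayesianMultiResUNet(spec).eval_mode()


def build_bayesian_classifier(spec: BayesianNetSpec,
                              n_stages: int = 4) -> BayesianCNNClassifier:
    if spec.kind != "classifier":
        raise InvalidSpecError("spec.kind must be 'classifier'")
    return BayesianCNNClassifier(spec, n_stages=n_stages).eval_mode()


def set_stochastic_mode(model: nn.Module, enabled: bool,
                        rng: np.random.Generator | None = None) -> nn.Module:
    """Toggle test-time dropout sampling; batch-norm stays in eval mode."""
    drops = [m for m in model.modules() if isinstance(m, nn.Dropout)]
    if enabled and not drops:
        raise CapabilityError("model has no dropout layers to sample")
    for d in drops:
        d.stochastic = enabled
        if rng is not None:
            d.rng = rng
    return model


def save_checkpoint(model: nn.Module, path: str | Path) -> None:
    """Weights as NPZ next to the architecture spec as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    spec = getattr(model, "spec", None)
    if spec is not None:
        meta = dataclasses.asdict(spec)
        meta["n_stages"] = getattr(model, "n_stages", None)
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)


def load_checkpoint(path: str | Path) -> nn.Module:
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    n_stages = meta.pop("n_stages", None)
    for key in ("input_size", "dropout_positions"):
        if isinstance(meta.get(key), list):
            meta[key] = tuple(meta[key])
    spec = BayesianNetSpec(**meta)
    if spec.kind == "segmenter":
        model = build_bayesian_multiresunet(spec)
    else:
        model = build_bayesian_classifier(spec, n_stages=n_stages or 4)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model.eval_mode()
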