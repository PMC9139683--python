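"""Multiscale Average Pooling Network (MAPNet) for optic disc / cup segmentation.

The network couples two feature extractors over a square RGB region of
interest:

* **DNFE** — a DenseNet-121-style encoder tapped at three spatial scales
  (input/4, input/8, input/16). At default width the taps carry 128, 256 and
  1024 channels.
* **APFE** — an Average-Pooling-based Feature Extractor that, for each tap,
  average-pools at three window sizes, projects each pooled map to a third of
  the APFE width by 1x1 convolution, upsamples back bilinearly and
  concatenates (384 channels at defaults).

Each scale's concatenated (tap + APFE) tensor — 128x128x512, 64x64x640 and
32x32x1408 at defaults — feeds a single transposed-convolution decoder head
producing a full-resolution two-channel score map. A final 1x1 convolution
over the three stacked head outputs acts as an embedded ensemble, combining
them into the network output (input_side x input_side x 2).

Two independent networks are trained in practice, one for the optic disc and
one for the cup. Training is per-pixel softmax cross-entropy with Adam, an
80/20 train/validation split, and best-validation-checkpoint selection.

:class:`MapNetSegmenter` wraps construction, training and inference as a
scikit-learn estimator (``fit`` / ``predict`` / ``score``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor, no_grad
from .preprocess import normalize_image

__all__ = [
    "MapNetConfig", "MapNet", "TrainingRun", "MapNetSegmenter",
    "build_model", "apfe_features", "train", "predict_mask",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MapNetConfig:
    """Architecture and training hyper-parameters.

    The encoder is parameterised by ``growth_rate`` and ``block_layers``;
    the default (32, (6, 12, 24)) reproduces the first three dense blocks of
    DenseNet-121 and yields tap widths (128, 256, 1024). ``reduced()`` gives
    a narrow encoder with the same channel arithmetic for desk-scale runs.
    """

    input_side: int = 512
    num_output_channels: int = 2
    growth_rate: int = 32
    block_layers: tuple[int, int, int] = (6, 12, 24)
    apfe_channels: int = 384
    apfe_pool_sizes: tuple[int, int, int] = (2, 4, 8)
    head_upsample_factors: tuple[int, int, int] = (4, 8, 16)
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    decay: float = 0.0
    max_epochs: int = 100
    batch_size: int = 20
    val_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def reduced(cls, **overrides) -> "MapNetConfig":
        """Narrow configuration (input 128) for CPU-scale training runs."""
        base = dict(input_side=128, growth_rate=8, block_layers=(2, 2, 4),
                    apfe_channels=24, max_epochs=10, batch_size=4)
        base.update(overrides)
        return cls(**base)

    @property
    def dnfe_tap_channels(self) -> tuple[int, int, int]:
        """Channel widths of the three encoder taps.

        Scales 1-2 are tapped after the transition layer's 2x channel
        compression (before pooling); scale 3 is the raw third-block output.
        """
        c = 2 * self.growth_rate  # stem width
        taps = []
        for i, n_layers in enumerate(self.block_layers):
            c += n_layers * self.growth_rate
            if i < 2:
                c //= 2
            taps.append(c)
        return tuple(taps)

    @property
    def combined_channels(self) -> tuple[int, int, int]:
        return tuple(t + self.apfe_channels for t in self.dnfe_tap_channels)

    @property
    def tap_sides(self) -> tuple[int, int, int]:
        return (self.input_side // 4, self.input_side // 8, self.input_side // 16)

    def validate(self) -> None:
        if self.input_side % 16:
            raise ValueError("input_side must be divisible by 16")
        if self.apfe_channels % 3:
            raise ValueError("apfe_channels must be divisible by 3")
        for side, f in zip(self.tap_sides, self.head_upsample_factors):
            if side * f != self.input_side:
                raise ValueError(
                    f"head upsample factor {f} does not restore input side "
                    f"{self.input_side} from tap side {side}")
        for side in self.tap_sides:
            for w in self.apfe_pool_sizes:
                if side % w:
                    raise ValueError(f"APFE pool window {w} must divide tap side {side}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MapNetConfig":
        d = json.loads(text)
        for key in ("block_layers", "apfe_pool_sizes", "head_upsample_factors"):
            d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks


class _DenseLayer(nn.Module):
    """BN-ReLU-1x1(4g) bottleneck, BN-ReLU-3x3(g); output concatenated to input."""

    def __init__(self, cin: int, growth: int, rng):
        self.bn1 = nn.BatchNorm2d(cin)
        self.conv1 = nn.Conv2d(cin, 4 * growth, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(4 * growth)
        self.conv2 = nn.Conv2d(4 * growth, growth, 3, pad=1, bias=False, rng=rng)

    def forward(self, x):
        y = self.conv1(F.relu(self.bn1(x)))
        y = self.conv2(F.relu(self.bn2(y)))
        return F.concat([x, y])


class _DenseBlock(nn.Module):
    def __init__(self, cin: int, n_layers: int, growth: int, rng):
        self.layers = [_DenseLayer(cin + i * growth, growth, rng) for i in range(n_layers)]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class _Transition(nn.Module):
    """BN-ReLU-1x1 channel compression (pooling is applied after the tap)."""

    def __init__(self, cin: int, cout: int, rng):
        self.bn = nn.BatchNorm2d(cin)
        self.conv = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)

    def forward(self, x):
        return self.conv(F.relu(self.bn(x)))


class APFE(nn.Module):
    """Average-Pooling-based Feature Extractor.

    Three branches, one per pool window: average-pool, project to
    ``out_channels/3`` by 1x1 convolution (BN + ReLU), bilinearly upsample
    back to the tap's spatial size, then concatenate.
    """

    def __init__(self, cin: int, out_channels: int, pool_sizes: tuple[int, int, int], rng):
        if out_channels % 3:
            raise ValueError("APFE out_channels must be divisible by 3")
        self.pool_sizes = tuple(pool_sizes)
        branch_c = out_channels // 3
        self.projs = [nn.Conv2d(cin, branch_c, 1, bias=False, rng=rng) for _ in self.pool_sizes]
        self.bns = [nn.BatchNorm2d(branch_c) for _ in self.pool_sizes]

    def forward(self, x):
        outs = []
        for w, proj, bn in zip(self.pool_sizes, self.projs, self.bns):
            y = F.avg_pool2d(x, w) if w > 1 else x
            y = F.relu(bn(proj(y)))
            if w > 1:
                y = F.upsample_bilinear(y, w)
            outs.append(y)
        return F.concat(outs)


class MapNet(nn.Module):
    """The full network; ``forward(x, capture=True)`` also returns intermediates."""

    def __init__(self, config: MapNetConfig | None = None):
        config = config or MapNetConfig()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        stem_c = 2 * g

        self.stem_conv = nn.Conv2d(3, stem_c, 7, stride=2, pad=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)
        self.stem_pool = nn.MaxPool2d(3, stride=2, pad=1)

        taps = config.dnfe_tap_channels
        c = stem_c
        self.blocks, self.transitions = [], []
        for i, n_layers in enumerate(config.block_layers):
            self.blocks.append(_DenseBlock(c, n_layers, g, rng))
            c += n_layers * g
            if i < 2:
                self.transitions.append(_Transition(c, c // 2, rng))
                c //= 2
            assert c == taps[i]

        self.apfes = [APFE(t, config.apfe_channels, config.apfe_pool_sizes, rng)
                      for t in taps]
        k_out = config.num_output_channels
        self.heads = [
            nn.ConvTranspose2d(t + config.apfe_channels, k_out, 2 * f, stride=f,
                               pad=f // 2, rng=rng)
            for t, f in zip(taps, config.head_upsample_factors)
        ]
        self.ensemble = nn.Conv2d(3 * k_out, k_out, 1, rng=rng)

    def encoder_taps(self, x):
        y = self.stem_pool(F.relu(self.stem_bn(self.stem_conv(x))))
        taps = []
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i < 2:
                y = self.transitions[i](y)
                taps.append(y)
                y = F.avg_pool2d(y, 2)
            else:
                taps.append(y)
        return taps

    def forward(self, x, capture: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if c != 3 or h != self.config.input_side or w != self.config.input_side:
            raise ValueError(
                f"expected (N, 3, {self.config.input_side}, {self.config.input_side}) "
                f"input, got {x.shape}")
        taps = self.encoder_taps(x)
        apfe_outs = [apfe(t) for apfe, t in zip(self.apfes, taps)]
        combined = [F.concat([t, a]) for t, a in zip(taps, apfe_outs)]
        heads = [head(z) for head, z in zip(self.heads, combined)]
        out = self.ensemble(F.concat(heads))
        if capture:
            info = {
                "taps": taps,
                "apfe": apfe_outs,
                "combined": combined,
                "heads": heads,
                "output": out,
            }
            return out, info
        return out

    def shape_summary(self, x=None) -> dict:
        """Shapes (H, W, C) of every stage, measured from a real forward pass."""
        if x is None:
            s = self.config.input_side
            x = np.zeros((1, 3, s, s), np.float32)
        self.eval()
        with no_grad():
            _, info = self.forward(x, capture=True)

        def hwc(t):
            _, c, h, w = t.shape
            return (h, w, c)

        return {key: [hwc(t) for t in val] if isinstance(val, list) else hwc(val)
                for key, val in info.items()}


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingRun:
    """Loss curves and best-checkpoint bookkeeping for one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0
    config: MapNetConfig | None = None

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss"]
        for i, (tr, va) in enumerate(zip(self.train_loss, self.val_loss)):
            lines.append(f"{i},{tr:.6f},{va:.6f}")
        return "\n".join(lines) + "\n"


def _to_nchw(images) -> np.ndarray:
    """Stack HWC images to a normalized (per-image, per-channel z-score) NCHW batch."""
    batch = [normalize_image(img).data.transpose(2, 0, 1) for img in images]
    return np.stack(batch).astype(np.float32)


def _epoch_losses(model, x, y, idx, batch_size, optimizer=None):
    losses = []
    for lo in range(0, len(idx), batch_size):
        sel = idx[lo:lo + batch_size]
        if optimizer is None:
            with no_grad():
                loss = F.softmax_cross_entropy(model(Tensor(x[sel])), y[sel])
        else:
            optimizer.zero_grad()
            loss = F.softmax_cross_entropy(model(Tensor(x[sel])), y[sel])
            loss.backward()
            optimizer.step()
        losses.append(float(loss.data) * len(sel))
    return sum(losses) / len(idx)


def train(model: MapNet, dataset, config: MapNetConfig | None = None,
          verbose: int = 0) -> TrainingRun:
    """Train ``model`` on (image, mask) pairs with Adam and best-epoch selection.

    ``dataset`` is a sequence of (HWC RGB image, binary mask) pairs. The data
    is split 80/20 into train/validation (``config.val_fraction``); the
    checkpoint with minimum validation loss is restored into ``model`` before
    returning.
    """
    config = config or model.config
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    x = _to_nchw([img for img, _ in dataset])
    y = np.stack([np.asarray(m) > 0 for _, m in dataset]).astype(np.int8)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(config.val_fraction * len(x)))) if len(x) > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order

    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2,
                        eps=config.epsilon, decay=config.decay)
    run = TrainingRun(seed=config.seed, config=config)
    best_state, best_val = None, np.inf
    for epoch in range(config.max_epochs):
        model.train()
        perm = train_idx[rng.permutation(len(train_idx))]
        tr_loss = _epoch_losses(model, x, y, perm, config.batch_size, optimizer)
        model.eval()
        va_loss = _epoch_losses(model, x, y, val_idx, config.batch_size)
        run.train_loss.append(tr_loss)
        run.val_loss.append(va_loss)
        if va_loss < best_val:
            best_val, run.best_epoch = va_loss, epoch
            best_state = model.get_state()
        if verbose:
            print(f"epoch {epoch}: train {tr_loss:.4f}  val {va_loss:.4f}")
    if best_state is not None:
        model.set_state(best_state)
    return run


def predict_mask(model: MapNet, roi_image: np.ndarray) -> np.ndarray:
    """Segment one RGB ROI image (HWC, already at the model's input side).

    The image is z-score normalized per channel and the per-pixel class is
    the argmax over the two output channels; returns a uint8 0/1 mask.
    """
    model.eval()
    x = _to_nchw([roi_image])
    with no_grad():
        out = model(Tensor(x))
    return out.data.argmax(axis=1)[0].astype(np.uint8)


def build_model(config: MapNetConfig | None = None) -> MapNet:
    """Construct a MAPNet from a config (validated); weights are seeded."""
    return MapNet(config)


def apfe_features(feature_map: np.ndarray, pool_sizes=(2, 4, 8),
                  out_channels: int = 384, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised APFE to one NCHW (or CHW) feature map."""
    x = np.asarray(feature_map, np.float32)
    if x.ndim == 3:
        x = x[None]
    apfe = APFE(x.shape[1], out_channels, tuple(pool_sizes), np.random.default_rng(seed))
    apfe.eval()
    with no_grad():
        y = apfe(Tensor(x))
    return y.data


# ---------------------------------------------------------------------------
# sklearn estimator


class MapNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper: one binary segmentation network.

    Parameters
    ----------
    preset : {"reduced", "full"}
        Base architecture. "reduced" is a narrow 128-pixel-input variant
        with the same channel arithmetic as the full 512-pixel network.
    epochs, batch_size, learning_rate, seed
        Override the preset's training hyper-parameters when not None.
    config : MapNetConfig, optional
        Full explicit configuration; takes precedence over ``preset``.

    Attributes
    ----------
    model_ : MapNet
        The trained network (best validation checkpoint restored).
    training_run_ : TrainingRun
        Loss curves and best epoch.
    config_ : MapNetConfig
        The resolved configuration.
    """

    def __init__(self, preset: str = "reduced", epochs: int | None = None,
                 batch_size: int | None = None, learning_rate: float | None = None,
                 seed: int = 0, config: MapNetConfig | None = None, verbose: int = 0):
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.config = config
        self.verbose = verbose

    def _resolve_config(self) -> MapNetConfig:
        if self.config is not None:
            cfg = dataclasses.replace(self.config)
        elif self.preset == "reduced":
            cfg = MapNetConfig.reduced()
        elif self.preset == "full":
            cfg = MapNetConfig()
        else:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.epochs is not None:
            cfg.max_epochs = self.epochs
        if self.batch_size is not None:
            cfg.batch_size = self.batch_size
        if self.learning_rate is not None:
            cfg.learning_rate = self.learning_rate
        cfg.seed = self.seed
        cfg.validate()
        return cfg

    def fit(self, X, y):
        """Fit on images ``X`` (n, S, S, 3) and binary masks ``y`` (n, S, S)."""
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n, side, side, 3) RGB images")
        if y.shape != X.shape[:3]:
            raise ValueError("y must be (n, side, side) masks matching X")
        cfg = self._resolve_config()
        if X.shape[1] != cfg.input_side:
            raise ValueError(
                f"images are {X.shape[1]} px but the configuration expects "
                f"{cfg.input_side} px; resize first (preprocess.resize_pair)")
        self.config_ = cfg
        self.model_ = MapNet(cfg)
        self.training_run_ = train(self.model_, list(zip(X, y)), cfg,
                                   verbose=self.verbose)
        return self

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, S, S) uint8 by per-pixel argmax."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X)
        self.model_.eval()
        out = []
        bs = max(1, self.config_.batch_size)
        for lo in range(0, len(X), bs):
            batch = _to_nchw(X[lo:lo + bs])
            with no_grad():
                scores = self.model_(Tensor(batch))
            out.append(scores.data.argmax(axis=1).astype(np.uint8))
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        """Foreground probability maps (n, S, S) via softmax over channels."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X)
        self.model_.eval()
        out = []
        bs = max(1, self.config_.batch_size)
        for lo in range(0, len(X), bs):
            batch = _to_nchw(X[lo:lo + bs])
            with no_grad():
                scores = self.model_(Tensor(batch))
            out.append(F.softmax(scores.data, axis=1)[:, 1])
        return np.concatenate(out)

    def score(self, X, y) -> float:
        """Mean Jaccard index of predicted vs. true masks."""
        pred = self.predict(X)
        y = np.asarray(y) > 0
        scores = []
        for p, t in zip(pred > 0, y):
            union = np.logical_or(p, t).sum()
            scores.append(np.logical_and(p, t).sum() / union if union else 1.0)
        return float(np.mean(scores))
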