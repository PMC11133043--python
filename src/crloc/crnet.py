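"""CNN regressor for sub-pixel CR center localization, trained on
synthetic images only.

The canonical architecture is a VGG-style stack of seven 3x3
convolutional layers whose filter counts grow from 64 to 512, each of the
first six followed by 2x2 max pooling, feeding two dense layers that
regress the (x, y) CR center in absolute patch pixels.  Training follows a
two-stage regime:

* **Stage 1** trains the full network with Adam (lr 1e-4), MSE loss and
  batch size 4 on a stream of unique synthetic images whose CR center may
  lie anywhere in the patch, for up to 700 epochs with early stopping on a
  fixed 300-image validation set.
* **Stage 2** fine-tunes from the stage-1 weights at lr 1e-6 with the
  first two convolutional blocks frozen, on images whose centers lie
  within 1.5 px of the patch center ([89.25, 90.75]) — the condition the
  network meets at inference, where a coarse detector has already centered
  the CR in the cutout.

Because every training image is freshly generated, an "epoch" is defined
here as a fixed number of new images (``epoch_size``, default 512).
Validation error is the mean Euclidean distance in pixels, logged per
epoch alongside the MSE training loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from .localizers import LocalizationResult, Method
from .synthcr import PATCH_SIZE, ImagePatch, make_patch, sample_spec

__all__ = [
    "ModelConfig",
    "TrainHistory",
    "CRNet",
    "build_model",
    "stage_sampler",
    "train_stage1",
    "train_stage2",
    "predict_center",
    "predict_batch",
    "overfit_harness",
    "save_weights",
    "load_weights",
]

SampleFn = Callable[[int, np.random.Generator], Tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    The defaults are the canonical full-scale settings; reduced filter
    counts / epoch sizes are accepted for small-scale runs and tests.
    """

    input_size: int = PATCH_SIZE
    conv_filters: Tuple[int, ...] = (64, 64, 128, 128, 256, 256, 512)
    dense_widths: Tuple[int, ...] = (256, 2)
    lr_stage1: float = 1e-4
    lr_stage2: float = 1e-6
    batch_size: int = 4
    max_epochs: int = 700
    frozen_blocks_stage2: int = 2
    epoch_size: int = 512
    n_val: int = 300
    patience: int = 30

    def __post_init__(self) -> None:
        if not self.conv_filters or any(f <= 0 for f in self.conv_filters):
            raise ValueError("conv_filters must be a non-empty positive sequence")
        if any(
            a > b for a, b in zip(self.conv_filters, self.conv_filters[1:])
        ):
            raise ValueError("conv_filters must be non-decreasing")
        if len(self.dense_widths) != 2 or self.dense_widths[-1] != 2:
            raise ValueError("dense_widths must be two entries ending in 2 (x, y)")
        size = self.input_size
        for _ in range(len(self.conv_filters) - 1):
            size //= 2
        if size < 1:
            raise ValueError(
                "input_size too small for the number of pooling stages"
            )


@dataclass
class TrainHistory:
    """Per-epoch training log."""

    epoch: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)  # MSE, px^2
    val_error: List[float] = field(default_factory=list)  # mean Euclidean, px
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_error: float = float("inf")
    init_val_error: float = float("inf")  # validation error of the starting weights


class CRNet:
    """Convolutional CR center regressor: 180x180 grayscale patch -> (x, y)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers: List[_nn.Layer] = []
        self.conv_layers: List[_nn.Conv2D] = []
        c_in = 1
        size = cfg.input_size
        n_conv = len(cfg.conv_filters)
        for i, f in enumerate(cfg.conv_filters):
            conv = _nn.Conv2D(c_in, f, rng)
            self.conv_layers.append(conv)
            layers.append(conv)
            layers.append(_nn.ReLU())
            if i < n_conv - 1:
                layers.append(_nn.MaxPool2())
                size //= 2
            c_in = f
        layers.append(_nn.Flatten())
        n_flat = size * size * c_in
        # the final bias starts at the patch center so an untrained network
        # already predicts the geometrically sensible point
        center = cfg.input_size / 2.0
        layers.append(_nn.Dense(n_flat, cfg.dense_widths[0], rng))
        layers.append(_nn.ReLU())
        layers.append(
            _nn.Dense(cfg.dense_widths[0], 2, rng, bias_init=(center, center))
        )
        self.net = _nn.Sequential(layers)

    # -- inference ---------------------------------------------------------
    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predict (x, y) for a batch; returns (N, 2) in patch pixels."""
        x = self._as_batch(images)
        return self.net.forward(x, train=False).astype(float)

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=_nn.F32)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[:, :, :, None]
        if x.ndim != 4 or x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} patches, got {x.shape}"
            )
        return x

    # -- training plumbing -------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray, opt: _nn.Adam) -> float:
        pred = self.net.forward(self._as_batch(x), train=True)
        loss, grad = _nn.mse_loss(pred, np.asarray(y, dtype=_nn.F32))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss ({loss}) at Adam step {opt.t + 1}"
            )
        self.net.backward(grad)
        opt.step(*self.net.trainable_params())
        return loss

    def freeze_blocks(self, n_blocks: int) -> None:
        """Freeze the first ``n_blocks`` convolutional blocks (conv+pool)."""
        for conv in self.conv_layers[:n_blocks]:
            conv.trainable = False

    def frozen_weights(self) -> List[np.ndarray]:
        return [
            p.copy()
            for conv in self.conv_layers
            if not conv.trainable
            for p in conv.params()
        ]

    def get_weights(self) -> List[np.ndarray]:
        return self.net.get_weights()

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        self.net.set_weights(weights)


def build_model(cfg: ModelConfig = ModelConfig(), seed: int = 0) -> CRNet:
    """Construct a (deterministically initialized) CR regressor."""
    return CRNet(cfg, seed=seed)


# --------------------------------------------------------------------------
# data generation


def stage_sampler(stage: int, size: int = PATCH_SIZE) -> SampleFn:
    """Sampler of unique synthetic training images for one stage.

    Returns ``sample_fn(n, rng) -> (images (n, s, s), targets (n, 2))``
    with targets in absolute patch pixels (x, y).  Every call draws fresh
    parameter sets, so the model never sees an image twice.
    """

    def sample_fn(n: int, rng: np.random.Generator):
        images = np.empty((n, size, size), dtype=_nn.F32)
        targets = np.empty((n, 2), dtype=_nn.F32)
        for i in range(n):
            cr, bg, noise = sample_spec(stage, rng)
            images[i] = make_patch(cr, bg, noise, size=size).pixels
            targets[i] = (cr.x_c, cr.y_c)
        return images, targets

    return sample_fn


def _validation_error(model: CRNet, images: np.ndarray, targets: np.ndarray) -> float:
    preds = []
    for start in range(0, len(images), 32):
        preds.append(model.predict(images[start : start + 32]))
    pred = np.concatenate(preds, axis=0)
    return float(np.mean(np.linalg.norm(pred - targets, axis=1)))


def _train_loop(
    model: CRNet,
    sample_fn: SampleFn,
    cfg: ModelConfig,
    seed: int,
    lr: float,
) -> Tuple[List[np.ndarray], TrainHistory]:
    ss = np.random.SeedSequence(seed)
    val_rng, train_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    val_images, val_targets = sample_fn(cfg.n_val, val_rng)

    opt = _nn.Adam(lr=lr)
    history = TrainHistory()
    init_val = _validation_error(model, val_images, val_targets)
    best = {"weights": model.get_weights(), "val": init_val, "epoch": 0}
    steps_per_epoch = max(1, cfg.epoch_size // cfg.batch_size)
    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for _ in range(steps_per_epoch):
            x, y = sample_fn(cfg.batch_size, train_rng)
            losses.append(model.train_step(x, y, opt))
        val = _validation_error(model, val_images, val_targets)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_error.append(val)
        if val < best["val"]:
            best = {"weights": model.get_weights(), "val": val, "epoch": epoch}
        elif epoch - best["epoch"] >= cfg.patience:
            break
    history.stopped_epoch = history.epoch[-1] if history.epoch else 0
    history.best_epoch = best["epoch"]
    history.best_val_error = best["val"]
    history.init_val_error = init_val
    model.set_weights(best["weights"])
    return best["weights"], history


def train_stage1(
    model: CRNet,
    sample_fn: Optional[SampleFn] = None,
    cfg: Optional[ModelConfig] = None,
    seed: int = 0,
) -> Tuple[List[np.ndarray], TrainHistory]:
    """Stage-1 training: full network, broad CR-center distribution."""
    cfg = cfg or model.cfg
    sample_fn = sample_fn or stage_sampler(1, size=cfg.input_size)
    return _train_loop(model, sample_fn, cfg, seed, lr=cfg.lr_stage1)


def train_stage2(
    model: CRNet,
    stage1_weights: Sequence[np.ndarray],
    sample_fn: Optional[SampleFn] = None,
    cfg: Optional[ModelConfig] = None,
    seed: int = 0,
) -> Tuple[List[np.ndarray], TrainHistory]:
    """Stage-2 fine-tuning: frozen early blocks, near-centered targets.

    Initializes from the stage-1 weights, freezes the first
    ``cfg.frozen_blocks_stage2`` convolutional blocks and trains the rest
    at the reduced learning rate.  Early stopping keeps the best weights,
    including the stage-1 starting point, so the returned weights are
    never worse than the initialization on the stage-2 validation set.
    """
    if stage1_weights is None:
        raise ValueError("stage-2 fine-tuning requires stage-1 weights")
    cfg = cfg or model.cfg
    model.set_weights(stage1_weights)
    model.freeze_blocks(cfg.frozen_blocks_stage2)
    sample_fn = sample_fn or stage_sampler(2, size=cfg.input_size)
    return _train_loop(model, sample_fn, cfg, seed, lr=cfg.lr_stage2)


# --------------------------------------------------------------------------
# inference helpers


def predict_center(model: CRNet, patch) -> LocalizationResult:
    """Predict the CR center of a single patch."""
    pixels = patch.pixels if isinstance(patch, ImagePatch) else np.asarray(patch)
    xy = model.predict(pixels)[0]
    return LocalizationResult(x=float(xy[0]), y=float(xy[1]), method=Method.CNN)


def predict_batch(model: CRNet, patches: Sequence) -> List[LocalizationResult]:
    """Predict CR centers for a sequence of patches, order preserved."""
    if len(patches) == 0:
        return []
    stack = np.stack(
        [p.pixels if isinstance(p, ImagePatch) else np.asarray(p) for p in patches]
    )
    xy = model.predict(stack)
    return [
        LocalizationResult(x=float(r[0]), y=float(r[1]), method=Method.CNN)
        for r in xy
    ]


# --------------------------------------------------------------------------
# sanity harness


def overfit_harness(
    cfg: Optional[ModelConfig] = None,
    n_images: int = 10,
    max_steps: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    stage: int = 1,
    sample_fn: Optional[SampleFn] = None,
) -> Tuple[float, List[float]]:
    """Memorization check: can the architecture fit a tiny fixed set?

    Builds a fresh model, draws ``n_images`` fixed synthetic images and
    runs Adam steps over them (batch-sized slices, cycling).  Returns the
    final full-set MSE (px^2) and the per-check loss trace.  The harness
    uses its own, larger learning rate: it probes trainability of the
    architecture, not the staged training schedule.
    """
    cfg = cfg or ModelConfig()
    model = build_model(cfg, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    sample_fn = sample_fn or stage_sampler(stage, size=cfg.input_size)
    images, targets = sample_fn(n_images, rng)
    opt = _nn.Adam(lr=lr)
    trace: List[float] = []
    b = cfg.batch_size
    idx = 0
    for step in range(max_steps):
        sel = [(idx + j) % n_images for j in range(b)]
        idx = (idx + b) % n_images
        model.train_step(images[sel], targets[sel], opt)
        if (step + 1) % 25 == 0 or step == max_steps - 1:
            pred = model.predict(images)
            full = float(np.mean((pred - targets) ** 2))
            trace.append(full)
            if full < 0.05:
                break
    return trace[-1], trace


# --------------------------------------------------------------------------
# serialization


def save_weights(path, model: CRNet) -> None:
    """Save weights and config to a single portable .npz archive."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_weights(path) -> CRNet:
    """Rebuild a model from a .npz archive written by :func:`save_weights`."""
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
    cfg_dict["dense_widths"] = tuple(cfg_dict["dense_widths"])
    model = build_model(ModelConfig(**cfg_dict))
    n = len([k for k in data.files if k.startswith("w")])
    model.set_weights([data[f"w{i}"] for i in range(n)])
    return model
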