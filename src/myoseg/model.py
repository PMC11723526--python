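"""Three-headed residual encoder-decoder for simultaneous myotube/nuclei
segmentation, its binary-cross-entropy objective, and the training loop.

The network maps a 2-channel fluorescence patch x through a shared
generator G (two stride-2 downsampling blocks, a stack of residual blocks,
two stride-2 transposed-conv upsampling blocks) and three class heads
C_k (5x5 conv + sigmoid), producing per-pixel probabilities for the
myotube mask, the nuclei mask and the nuclei-centroid map:

    yhat_k = C_k(G(x)),   k in {myotube, nuclei, centroid}

Training minimises the weighted sum of per-class mean BCE losses with
Adam (lr 1e-3, beta1 0.5, beta2 0.999).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _nn
from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    ReLU,
    ResidualBlock,
    Sequential,
    sigmoid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SegOutputs",
    "TrainHistory",
    "MyotubeNet",
    "build_model",
    "forward",
    "bce_loss",
    "total_loss",
    "train",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "ablate_residual_depth",
]

BCE_EPS = 1e-7  # clamp for log() stability; probabilities live in [eps, 1-eps]


@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    ``base_channels`` is the channel width after the first downsampling
    block (64 in the reference architecture); downsampling doubles it,
    the residual stack runs at 4x (via a 1x1 projection) and upsampling
    halves it back. ``strict_128`` instead keeps the residual stack at
    2x base, with no projection.
    """

    in_channels: int = 2
    base_channels: int = 64
    n_down: int = 2
    n_residual_blocks: int = 5
    n_heads: int = 3
    head_kernel: int = 5
    strict_128: bool = False
    lr: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 20
    batch_size: int = 4
    lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    val_fraction: float = 0.0
    seed: int = 0
    allow_nonstandard_down: bool = False

    def __post_init__(self):
        if self.n_residual_blocks < 1:
            raise ValueError("n_residual_blocks must be >= 1")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError(f"loss weights must be strictly positive, got {self.lambdas}")
        if self.n_down != 2 and not self.allow_nonstandard_down:
            raise ValueError(
                "the reference architecture uses exactly 2 downsampling stages; "
                "set allow_nonstandard_down=True to deviate"
            )
        if self.n_heads != 3:
            raise ValueError("the model produces exactly 3 outputs (myotube, nuclei, centroid)")


@dataclass
class SegOutputs:
    """Sigmoid probability maps aligned to the input grid, each (1, H, W)."""

    p_myotube: np.ndarray
    p_nuclei: np.ndarray
    p_centroid: np.ndarray

    def as_tuple(self):
        return (self.p_myotube, self.p_nuclei, self.p_centroid)

    @property
    def shape(self):
        return self.p_myotube.shape


@dataclass
class TrainHistory:
    total: list = field(default_factory=list)
    cls1: list = field(default_factory=list)
    cls2: list = field(default_factory=list)
    cls3: list = field(default_factory=list)
    val_total: list = field(default_factory=list)
    wall_time_s: float = 0.0
    config: dict = field(default_factory=dict)


class MyotubeNet:
    """The generator G plus the three class heads C_k."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        b = cfg.base_channels
        rng = np.random.default_rng(cfg.seed)
        self.down1 = Sequential(
            Conv2d(cfg.in_channels, b, 3, stride=2, rng=rng), InstanceNorm2d(), ReLU()
        )
        self.down2 = Sequential(Conv2d(b, 2 * b, 3, stride=2, rng=rng), InstanceNorm2d(), ReLU())
        if cfg.strict_128:
            res_c = 2 * b
            self.proj = None
        else:
            res_c = 4 * b
            self.proj = Conv2d(2 * b, res_c, 1, rng=rng)
        self.res = Sequential(*[ResidualBlock(res_c, rng) for _ in range(cfg.n_residual_blocks)])
        self.up1 = Sequential(ConvTranspose2d(res_c, res_c // 2, rng=rng), InstanceNorm2d(), LeakyReLU())
        self.up2 = Sequential(
            ConvTranspose2d(res_c // 2, res_c // 4, rng=rng), InstanceNorm2d(), LeakyReLU()
        )
        self.heads = [
            Conv2d(res_c // 4, 1, cfg.head_kernel, rng=rng) for _ in range(cfg.n_heads)
        ]
        self._trunk = Sequential(
            self.down1, self.down2, *( [self.proj] if self.proj else [] ), self.res, self.up1, self.up2
        )

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        yield from self._trunk.iter_layers()
        yield from self.heads

    def check_input(self, x: np.ndarray):
        h, w = x.shape[-2:]
        if h % 4 or w % 4:
            raise ValueError(
                f"spatial dims ({h}, {w}) must be divisible by 4: the two stride-2 "
                "downsampling stages each halve the grid"
            )

    # -- forward paths -----------------------------------------------------
    def trunk_forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self._trunk.forward(x, training)

    def head_logits(self, feat: np.ndarray, training: bool) -> list[np.ndarray]:
        return [h.forward(feat, training) for h in self.heads]

    def forward_features(self, x: np.ndarray) -> dict:
        """Run a forward pass recording each block's output shape (per sample)."""
        self.check_input(x)
        x = np.atleast_3d(x)
        if x.ndim == 3:
            x = x[None]
        shapes = {}
        h = self.down1.forward(x, False)
        shapes["down1"] = h.shape[1:]
        h = self.down2.forward(h, False)
        shapes["down2"] = h.shape[1:]
        if self.proj is not None:
            h = self.proj.forward(h, False)
        h = self.res.forward(h, False)
        shapes["residual"] = h.shape[1:]
        h = self.up1.forward(h, False)
        shapes["up1"] = h.shape[1:]
        h = self.up2.forward(h, False)
        shapes["up2"] = h.shape[1:]
        for i, head in enumerate(self.heads, 1):
            shapes[f"head{i}"] = head.forward(h, False).shape[1:]
        return shapes

    # -- state -------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, lay in enumerate(self.layers()):
            for k, v in lay.params.items():
                state[f"L{i}.{k}"] = v
            if isinstance(lay, BatchNorm2d):
                state[f"L{i}.running_mean"] = lay.running_mean
                state[f"L{i}.running_var"] = lay.running_var
        return state

    def load_state(self, state: dict[str, np.ndarray]):
        for i, lay in enumerate(self.layers()):
            for k in lay.params:
                lay.params[k] = state[f"L{i}.{k}"].copy()
            if isinstance(lay, BatchNorm2d):
                lay.running_mean = state[f"L{i}.running_mean"].copy()
                lay.running_var = state[f"L{i}.running_var"].copy()

    def astype(self, dtype):
        for lay in self.layers():
            for k in lay.params:
                lay.params[k] = lay.params[k].astype(dtype)
            lay.zero_grad()
        return self


def build_model(cfg: ModelConfig | None = None) -> MyotubeNet:
    return MyotubeNet(cfg or ModelConfig())


def count_parameters(model: MyotubeNet) -> int:
    return int(sum(p.size for lay in model.layers() for p in lay.params.values()))


def forward(model: MyotubeNet, x: np.ndarray) -> SegOutputs:
    """Eval-mode forward pass; accepts (2, H, W) or (N, 2, H, W)."""
    model.check_input(x)
    squeeze = x.ndim == 3
    xb = x[None] if squeeze else x
    feat = model.trunk_forward(np.asarray(xb, dtype=np.float32), False)
    probs = [sigmoid(z) for z in model.head_logits(feat, False)]
    if squeeze:
        probs = [p[0] for p in probs]
    return SegOutputs(*probs)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy over all N pixels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def total_loss(outputs: SegOutputs, targets, lambdas=(1.0, 1.0, 1.0)) -> float:
    """Weighted sum of the three per-class BCE losses."""
    if any(l <= 0 for l in lambdas):
        raise ValueError(f"loss weights must be strictly positive, got {lambdas}")
    ts = targets.as_tuple() if hasattr(targets, "as_tuple") else tuple(targets)
    return float(sum(l * bce_loss(p, t) for l, p, t in zip(lambdas, outputs.as_tuple(), ts)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_arrays(dataset):
    """Accept (X, Y) arrays or a sequence of (patch, (t1,t2,t3)) pairs."""
    if isinstance(dataset, tuple) and len(dataset) == 2 and hasattr(dataset[0], "ndim"):
        X, Y = dataset
        return np.asarray(X, np.float32), np.asarray(Y, np.float32)
    xs, ys = [], []
    for x, t in dataset:
        px = x.pixels if hasattr(x, "pixels") else x
        ts = t.as_tuple() if hasattr(t, "as_tuple") else tuple(t)
        xs.append(np.asarray(px, np.float32))
        ys.append(np.stack([np.asarray(m, np.float32) for m in ts]))
    return np.stack(xs), np.stack(ys)


def train(model: MyotubeNet, dataset, cfg: ModelConfig | None = None):
    """Seeded mini-batch training loop; returns (model, TrainHistory).

    Keeps the weights with the best (validation, else training) total loss
    and restores them before returning.
    """
    cfg = cfg or model.cfg
    X, Y = _as_arrays(dataset)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(X)
    n_val = int(round(cfg.val_fraction * n))
    order0 = rng.permutation(n)
    val_idx, tr_idx = order0[:n_val], order0[n_val:]
    opt = Adam(list(model.layers()), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    hist = TrainHistory(config=asdict(cfg))
    best = (np.inf, None)
    t0 = time.perf_counter()
    lam = cfg.lambdas
    for epoch in range(cfg.epochs):
        perm = tr_idx[rng.permutation(len(tr_idx))]
        sums = np.zeros(3)
        nb = 0
        for s in range(0, len(perm), cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            opt.zero_grad()
            feat = model.trunk_forward(xb, True)
            gfeat = np.zeros_like(feat)
            losses = []
            for k, head in enumerate(model.heads):
                z = head.forward(feat, True)
                p = sigmoid(z)
                t = yb[:, k : k + 1]
                losses.append(bce_loss(p, t))
                gz = (lam[k] * (p - t) / t.size).astype(np.float32)
                gfeat += head.backward(gz)
            model._trunk.backward(gfeat)
            lt = sum(l * w for l, w in zip(losses, lam))
            if not np.isfinite(lt):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {nb} (lr={cfg.lr}): {losses}"
                )
            opt.step()
            sums += losses
            nb += 1
        mean = sums / max(nb, 1)
        lt = float(np.dot(mean, lam))
        hist.cls1.append(float(mean[0]))
        hist.cls2.append(float(mean[1]))
        hist.cls3.append(float(mean[2]))
        hist.total.append(lt)
        score = lt
        if n_val:
            vl = _eval_loss(model, X[val_idx], Y[val_idx], cfg)
            hist.val_total.append(vl)
            score = vl
        if score < best[0]:
            best = (score, {k: v.copy() for k, v in model.state_arrays().items()})
        logger.info("epoch %d: Ltotal=%.4f (cls %.4f/%.4f/%.4f)", epoch, lt, *mean)
    hist.wall_time_s = time.perf_counter() - t0
    if best[1] is not None:
        model.load_state(best[1])
    return model, hist


def _eval_loss(model, X, Y, cfg):
    tot = 0.0
    for s in range(0, len(X), cfg.batch_size):
        xb, yb = X[s : s + cfg.batch_size], Y[s : s + cfg.batch_size]
        out = forward(model, xb)
        tot += total_loss(out, (yb[:, 0:1], yb[:, 1:2], yb[:, 2:3]), cfg.lambdas) * len(xb)
    return tot / len(X)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MyotubeNet, path):
    state = model.state_arrays()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> MyotubeNet:
    with np.load(path) as z:
        cfg_d = json.loads(bytes(z["__config__"].tobytes()).decode())
        cfg_d["lambdas"] = tuple(cfg_d["lambdas"])
        model = build_model(ModelConfig(**cfg_d))
        model.load_state({k: z[k] for k in z.files if k != "__config__"})
    return model


# ---------------------------------------------------------------------------
# residual-depth ablation harness
# ---------------------------------------------------------------------------

def ablate_residual_depth(depths, dataset, cfg: ModelConfig, eval_set=None, segment_fn=None):
    """Sweep the residual-stack depth, reporting size, accuracy and test time.

    ``eval_set`` is an (X, Y) pair used both for IoU/Dice and for timing the
    forward pass; with ``cfg.epochs == 0`` the sweep reports untrained models
    (size/time only). ``segment_fn`` may replace the built-in binarisation.
    Returns a pandas DataFrame with one row per depth.
    """
    import pandas as pd

    from .metrics import confusion, dice, iou

    rows = []
    for d in depths:
        dcfg = replace(cfg, n_residual_blocks=int(d))
        model = build_model(dcfg)
        if cfg.epochs > 0:
            model, _ = train(model, dataset, dcfg)
        row = {"depth": int(d), "n_params": count_parameters(model)}
        if eval_set is not None:
            Xe, Ye = _as_arrays(eval_set)
            t0 = time.perf_counter()
            out = forward(model, Xe)
            row["test_time_s"] = time.perf_counter() - t0
            for k, name in enumerate(("myotube", "nuclei", "centroid")):
                pred = (out.as_tuple()[k][:, 0] >= 0.5).astype(np.uint8)
                cc = confusion(pred, (Ye[:, k] >= 0.5).astype(np.uint8))
                row[f"iou_{name}"] = iou(cc)
                row[f"dice_{name}"] = dice(cc)
        rows.append(row)
    return pd.DataFrame(rows)
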