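"""Modified U-net for multi-class tissue segmentation.

The encoder is ``depth`` blocks of [same-padding 3x3 conv -> batchnorm ->
ReLU -> 2x2 max-pool], the bottleneck one further conv block without pooling,
and the decoder mirrors the encoder with [nearest x2 upsample -> concatenate
the pre-pool encoder features -> conv -> batchnorm -> ReLU]; a final 1x1
convolution projects to per-class logits. Dropout is applied after each
max-pool during training only. Optimization is Adam on the avoid-masked
categorical cross-entropy, batch size 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np

from . import nn
from .legend import LabelMap, RoiSample
from .metrics import masked_cross_entropy
from .preprocessing import DatasetStats, standardize

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "forward",
    "train",
    "predict_proba",
    "predict_tissue_map",
    "save_model",
    "load_model",
]


class ShapeError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``base_channels`` sets the first encoder width; widths double per level
    (32 -> 64 -> 128 -> 256 with a 512-channel bottleneck at the default).
    ``dropout_rate`` is the drop probability applied after each max-pool
    during training.
    """

    n_classes: int = 11
    depth: int = 4
    base_channels: int = 32
    kernel_size: int = 3
    dropout_rate: float = 0.8
    upsample_mode: str = "nearest"
    convs_per_block: int = 1

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def divisor(self) -> int:
        return 2**self.depth


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the full-scale protocol."""

    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 1
    seed: int = 0
    optimizer_name: str = "adam"
    validation_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.batch_size != 1:
            raise ValueError("only batch_size=1 is supported")
        self.validation_ids = frozenset(self.validation_ids)


@dataclass
class TrainedModel:
    spec: ModelSpec
    params: dict
    train_history: list = field(default_factory=list)  # (train_loss, val_loss) per epoch
    version_tag: str = "C0"
    seed: int = 0


def _channel_plan(spec: ModelSpec):
    enc = [spec.base_channels * 2**l for l in range(spec.depth)]
    bottleneck = spec.base_channels * 2**spec.depth
    return enc, bottleneck


def build_model(spec: ModelSpec, seed: int, version_tag: str = "C0") -> TrainedModel:
    """He-initialized parameters, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    params: dict = {}
    k = spec.kernel_size

    def add_block(prefix: str, c_in: int, c_out: int):
        for j in range(spec.convs_per_block):
            ci = c_in if j == 0 else c_out
            fan_in = ci * k * k
            params[f"{prefix}_conv{j}_W"] = (
                rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, ci, k, k))
            ).astype(np.float32)
            params[f"{prefix}_conv{j}_b"] = np.zeros(c_out, dtype=np.float32)
            params[f"{prefix}_bn{j}_gamma"] = np.ones(c_out, dtype=np.float32)
            params[f"{prefix}_bn{j}_beta"] = np.zeros(c_out, dtype=np.float32)

    enc, bottleneck = _channel_plan(spec)
    c_prev = 3
    for l, c in enumerate(enc):
        add_block(f"enc{l}", c_prev, c)
        c_prev = c
    add_block("bot", c_prev, bottleneck)
    c_prev = bottleneck
    for l in reversed(range(spec.depth)):
        add_block(f"dec{l}", c_prev + enc[l], enc[l])
        c_prev = enc[l]
    params["out_W"] = (
        rng.normal(0, np.sqrt(2.0 / c_prev), (spec.n_classes, c_prev, 1, 1))
    ).astype(np.float32)
    params["out_b"] = np.zeros(spec.n_classes, dtype=np.float32)
    return TrainedModel(spec=spec, params=params, version_tag=version_tag, seed=seed)


def _block_forward(x, params, prefix, n_convs, cache):
    for j in range(n_convs):
        W = params[f"{prefix}_conv{j}_W"]
        y, cols = nn.conv2d(x, W, params[f"{prefix}_conv{j}_b"])
        g = params[f"{prefix}_bn{j}_gamma"]
        y, bn_cache = nn.batchnorm(y, g, params[f"{prefix}_bn{j}_beta"])
        y = nn.relu(y)
        cache.append((prefix, j, cols, bn_cache, y))
        x = y
    return x


def _block_backward(dy, params, cache_slice, grads):
    for prefix, j, cols, bn_cache, y in reversed(cache_slice):
        dy = nn.relu_backward(dy, y)
        g = params[f"{prefix}_bn{j}_gamma"]
        dy, dgamma, dbeta = nn.batchnorm_backward(dy, bn_cache, g)
        grads[f"{prefix}_bn{j}_gamma"] = dgamma
        grads[f"{prefix}_bn{j}_beta"] = dbeta
        W = params[f"{prefix}_conv{j}_W"]
        dy, dW, db = nn.conv2d_backward(dy, cols, W)
        grads[f"{prefix}_conv{j}_W"] = dW
        grads[f"{prefix}_conv{j}_b"] = db
    return dy


def forward(model: TrainedModel, x: np.ndarray, train: bool = False, rng=None):
    """Run the network on a standardized ``(3, H, W)`` input.

    Returns per-pixel class probabilities ``(n_classes, H, W)``; with
    ``train=True`` additionally returns logits and the backward cache.
    Dropout is active only in training mode.
    """
    spec = model.spec
    c, h, w = x.shape
    d = spec.divisor
    if h % d or w % d:
        raise ShapeError(
            f"spatial dims {h}x{w} must be divisible by 2^depth = {d}"
        )
    params = model.params
    nb = spec.convs_per_block
    p_drop = spec.dropout_rate if train else 0.0

    caches = {"blocks": [], "pools": [], "drops": []}
    skips = []
    h_cur = x.astype(np.float32)
    for l in range(spec.depth):
        blk: list = []
        h_cur = _block_forward(h_cur, params, f"enc{l}", nb, blk)
        caches["blocks"].append(blk)
        skips.append(h_cur)
        h_cur, pc = nn.maxpool2(h_cur)
        caches["pools"].append(pc)
        h_cur, mask = nn.dropout(h_cur, p_drop, rng) if train else (h_cur, None)
        caches["drops"].append(mask)
    blk = []
    h_cur = _block_forward(h_cur, params, "bot", nb, blk)
    caches["blocks"].append(blk)
    dec_concat_ch = []
    for l in reversed(range(spec.depth)):
        h_cur = nn.upsample2(h_cur)
        dec_concat_ch.append(h_cur.shape[0])
        h_cur = np.concatenate([h_cur, skips[l]], axis=0)
        blk = []
        h_cur = _block_forward(h_cur, params, f"dec{l}", nb, blk)
        caches["blocks"].append(blk)
    logits, out_cols = nn.conv2d(h_cur, params["out_W"], params["out_b"])
    caches["out_cols"] = out_cols
    caches["dec_concat_ch"] = dec_concat_ch
    probs = nn.softmax(logits, axis=0)
    if train:
        return probs, logits, caches
    return probs


def _backward(model: TrainedModel, dlogits: np.ndarray, caches) -> dict:
    spec = model.spec
    params = model.params
    grads: dict = {}
    dy, dW, db = nn.conv2d_backward(dlogits, caches["out_cols"], params["out_W"])
    grads["out_W"], grads["out_b"] = dW, db

    blocks = caches["blocks"]
    # decoder blocks occupy the tail of the cache list, shallow level last
    dskips = [None] * spec.depth
    bi = len(blocks) - 1
    for i, l in enumerate(range(spec.depth)):  # l = 0 .. depth-1, shallow first
        dy = _block_backward(dy, params, blocks[bi], grads)
        up_ch = caches["dec_concat_ch"][spec.depth - 1 - i]
        dup, dskip = dy[:up_ch], dy[up_ch:]
        dskips[l] = dskip
        dy = nn.upsample2_backward(dup)
        bi -= 1
    dy = _block_backward(dy, params, blocks[bi], grads)  # bottleneck
    bi -= 1
    for l in reversed(range(spec.depth)):
        dy = nn.dropout_backward(dy, caches["drops"][l])
        dy = nn.maxpool2_backward(dy, caches["pools"][l])
        dy = dy + dskips[l]
        dy = _block_backward(dy, params, blocks[bi], grads)
        bi -= 1
    return grads


def _loss_and_grad(probs, logits, labels: np.ndarray, avoid_index: int):
    mask = labels != avoid_index
    n = int(mask.sum())
    loss = masked_cross_entropy(probs, labels, avoid_index)
    onehot = np.zeros_like(probs)
    safe = np.where(mask, labels, 0)
    np.put_along_axis(onehot, safe[None], 1.0, axis=0)
    dlogits = (probs - onehot) * mask[None].astype(np.float32) / n
    return loss, dlogits.astype(np.float32)


def train(
    model: TrainedModel,
    train_set: list,
    config: TrainConfig,
    stats: DatasetStats,
    avoid_index: int | None = None,
) -> TrainedModel:
    """Train in place for ``config.epochs`` epochs (batch size 1, Adam).

    Samples whose roi_id is in ``config.validation_ids`` are held out from
    gradient updates; their mean loss is recorded per epoch alongside the
    training loss. Avoid-class pixels never contribute gradient.
    """
    if not train_set:
        raise ValueError("empty training set")
    val = [s for s in train_set if s.roi_id in config.validation_ids]
    fit = [s for s in train_set if s.roi_id not in config.validation_ids]
    if not fit:
        raise ValueError("validation_ids exclude every training sample")
    avoid = train_set[0].labels.legend.avoid_index if avoid_index is None else avoid_index
    usable = []
    for s in fit:
        if not (s.labels.indices != avoid).any():
            import warnings

            warnings.warn(
                f"ROI {s.roi_id} is entirely avoid-class: no gradient signal; skipped"
            )
        else:
            usable.append(s)
    fit = usable
    if not fit:
        raise ValueError("no training sample has labeled pixels")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    xs = {s.roi_id: np.ascontiguousarray(standardize(s.image, stats).transpose(2, 0, 1)) for s in train_set}
    ys = {s.roi_id: s.labels.indices for s in train_set}

    history = []
    order = [s.roi_id for s in fit]
    for _ in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for rid in order:
            probs, logits, caches = forward(model, xs[rid], train=True, rng=rng)
            loss, dlogits = _loss_and_grad(probs, logits, ys[rid], avoid)
            grads = _backward(model, dlogits, caches)
            opt.step(model.params, grads)
            losses.append(loss)
        val_losses = [
            masked_cross_entropy(forward(model, xs[s.roi_id]), ys[s.roi_id], avoid)
            for s in val
        ]
        history.append(
            (float(np.mean(losses)), float(np.mean(val_losses)) if val_losses else float("nan"))
        )
    model.train_history = history
    return model


def predict_proba(model: TrainedModel, sample: RoiSample, stats: DatasetStats) -> np.ndarray:
    x = np.ascontiguousarray(standardize(sample.image, stats).transpose(2, 0, 1))
    return forward(model, x)


def predict_tissue_map(model: TrainedModel, sample: RoiSample, stats: DatasetStats) -> LabelMap:
    """Argmax tissue map; ties break to the lowest class index, never avoid."""
    probs = predict_proba(model, sample, stats)
    return LabelMap(probs.argmax(axis=0).astype(np.int16), sample.labels.legend)


def save_model(model: TrainedModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / f"{model.version_tag}.npz", **model.params)
    sidecar = {
        "spec": asdict(model.spec),
        "version_tag": model.version_tag,
        "seed": model.seed,
        "train_history": model.train_history,
    }
    (out / f"{model.version_tag}.json").write_text(json.dumps(sidecar, indent=1))
    lines = ["epoch,train_loss,val_loss"] + [
        f"{e},{t},{v}" for e, (t, v) in enumerate(model.train_history)
    ]
    (out / f"{model.version_tag}_history.csv").write_text("\n".join(lines) + "\n")
    return out / f"{model.version_tag}.npz"


def load_model(npz_path) -> TrainedModel:
    npz_path = Path(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    with np.load(npz_path) as z:
        params = {k: z[k] for k in z.files}
    return TrainedModel(
        spec=ModelSpec(**sidecar["spec"]),
        params=params,
        train_history=[tuple(t) for t in sidecar["train_history"]],
        version_tag=sidecar["version_tag"],
        seed=sidecar["seed"],
    )
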