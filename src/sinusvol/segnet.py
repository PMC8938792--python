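"""Encoder–decoder semantic segmentation network for sinus CT slices.

The architecture combines three ideas from efficient segmentation
networks: depthwise-separable convolutions (a depthwise spatial filter
followed by a 1x1 pointwise mix) keep the parameter count low;
squeeze-and-excitation (SE) blocks with a Mish-activated bottleneck
recalibrate channels using global context; and residual additive skips
stabilise optimisation.  The bottleneck applies atrous spatial pyramid
pooling (ASPP) — parallel dilated convolutions plus an image-level
pooled branch — to enlarge the receptive field, and the decoder
upsamples bilinearly, concatenating encoder features at each scale
before a final 1x1 classification head at input resolution.

Everything is sized by :class:`SegConfig` so a tiny instance trains on
a single CPU in minutes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import mish  # re-exported: the SE activation  # noqa: F401
from .regions import N_CLASSES

__all__ = [
    "SegConfig",
    "TrainConfig",
    "DepthwiseSeparableBlock",
    "SEBlock",
    "Residual",
    "ASPP",
    "SegModel",
    "build_model",
    "predict_slice",
    "train_supervised",
    "mean_foreground_dice",
    "save_checkpoint",
    "load_checkpoint",
    "mish",
]


@dataclass
class SegConfig:
    """Hyper-parameters of the segmentation model.

    Attributes
    ----------
    in_channels:
        Input channels per slice.  The phantom pipeline feeds intensity
        plus three normalised coordinate ramps (4 channels) so the
        network can tell left from right structures of identical
        density.
    n_classes:
        Background + labelled regions (default 13).
    base_width:
        Channels of the first encoder stage; stage ``i`` has
        ``base_width * 2**i`` channels.
    depth:
        Number of encoder stages; each stage after the first halves the
        spatial resolution, so the bottleneck sits at ``1/2**(depth-1)``.
    se_reduction:
        Bottleneck ratio ``r`` of the SE excitation transform; clamped
        so the reduced width is at least 1.
    atrous_rates:
        Dilation rates of the ASPP branches; strictly increasing,
        starting at 1.
    decoder_skip_stages:
        Encoder stages whose features are concatenated into the
        decoder (default: every stage before the bottleneck).
    """

    in_channels: int = 4
    n_classes: int = N_CLASSES
    base_width: int = 8
    depth: int = 3
    se_reduction: int = 16
    atrous_rates: tuple[int, ...] = (1, 6, 12, 18)
    decoder_skip_stages: tuple[int, ...] | None = None
    dice_weight: float = 0.0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        rates = tuple(self.atrous_rates)
        if not rates:
            raise ValueError("atrous_rates must be non-empty")
        if rates[0] != 1 or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("atrous_rates must be strictly increasing and start at 1")
        self.atrous_rates = rates
        if self.decoder_skip_stages is None:
            self.decoder_skip_stages = tuple(range(self.depth - 1))
        else:
            self.decoder_skip_stages = tuple(sorted(self.decoder_skip_stages))
            if any(s < 0 or s >= self.depth - 1 for s in self.decoder_skip_stages):
                raise ValueError("decoder_skip_stages must index stages before the bottleneck")

    def stage_width(self, i: int) -> int:
        return self.base_width * (2 ** i)


class DepthwiseSeparableBlock(nn.Module):
    """Depthwise 3x3 filter + pointwise 1x1 mix, each with BN and ReLU."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng=None,
                 dtype=np.float32):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.dw = nn.Conv2d(cin, cin, 3, stride=stride, groups=cin, bias=False,
                            rng=rng, dtype=dtype)
        self.pw = nn.Conv2d(cin, cout, 1, bias=False, rng=rng, dtype=dtype)
        self.body = nn.Sequential(
            self.dw, nn.BatchNorm2d(cin, dtype=dtype), nn.ReLU(),
            self.pw, nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU(),
        )

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def conv_weight_count(self) -> int:
        """Weights in the two convolutions (k^2*Cin + Cin*Cout)."""
        return int(self.dw.weight.value.size + self.pw.weight.value.size)


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gating.

    Squeeze: per-channel global average pooling.  Excitation: a C->C/r
    linear map, Mish, a C/r->C map, and a logistic gate in (0,1) that
    rescales each channel multiplicatively.
    """

    def __init__(self, channels: int, reduction: int = 16, rng=None,
                 dtype=np.float32):
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng, dtype=dtype)
        self.act = nn.Mish()
        self.fc2 = nn.Linear(hidden, channels, rng=rng, dtype=dtype)
        self.gate = nn.Sigmoid()

    def squeeze(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(2, 3))

    def excitation(self, z: np.ndarray) -> np.ndarray:
        return self.gate.forward(self.fc2.forward(self.act.forward(self.fc1.forward(z))))

    def forward(self, x):
        self._x = x
        self._s = self.excitation(self.squeeze(x))
        return x * self._s[:, :, None, None]

    def backward(self, grad):
        x, s = self._x, self._s
        gs = np.einsum("bchw,bchw->bc", grad, x, optimize=True)
        gz = self.fc1.backward(self.act.backward(self.fc2.backward(self.gate.backward(gs))))
        hw = x.shape[2] * x.shape[3]
        return grad * s[:, :, None, None] + gz[:, :, None, None] / hw


class Residual(nn.Module):
    """y = body(x) + shortcut(x); shortcut defaults to the identity.

    Raises if the body changes the feature shape and no projection is
    supplied.
    """

    def __init__(self, body: nn.Module, shortcut: nn.Module | None = None):
        self.res_body = body
        self.shortcut = shortcut or nn.Identity()

    def forward(self, x):
        y = self.res_body.forward(x)
        sc = self.shortcut.forward(x)
        if y.shape != sc.shape:
            raise ValueError(
                f"residual shape mismatch {y.shape} vs {sc.shape}: "
                "configure a projection shortcut")
        return y + sc

    def backward(self, grad):
        return self.res_body.backward(grad) + self.shortcut.backward(grad)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling.

    One 3x3 convolution per dilation rate, in parallel with an
    image-level branch (global average pool -> 1x1 conv -> broadcast),
    concatenated and fused by a 1x1 convolution.  Spatial dims are
    preserved.
    """

    def __init__(self, cin: int, cout: int, rates: tuple[int, ...], rng=None,
                 dtype=np.float32):
        if not rates:
            raise ValueError("atrous rate list must be non-empty")
        self.rates = tuple(rates)
        self.branches = [
            nn.Sequential(nn.Conv2d(cin, cout, 3, dilation=r, bias=False,
                                    rng=rng, dtype=dtype),
                          nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU())
            for r in self.rates
        ]
        self.pool_conv = nn.Conv2d(cin, cout, 1, rng=rng, dtype=dtype)
        self.pool_act = nn.ReLU()
        self.fuse = nn.Sequential(
            nn.Conv2d(cout * (len(self.rates) + 1), cout, 1, bias=False,
                      rng=rng, dtype=dtype),
            nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU())
        self.cout = cout

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        self._hw = (h, w)
        outs = [b.forward(x) for b in self.branches]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        pooled = self.pool_act.forward(self.pool_conv.forward(pooled))
        outs.append(np.broadcast_to(pooled, (x.shape[0], self.cout, h, w)).copy())
        return self.fuse.forward(np.concatenate(outs, axis=1))

    def backward(self, grad):
        h, w = self._hw
        g = self.fuse.backward(grad)
        c = self.cout
        gx = None
        for i, b in enumerate(self.branches):
            gb = b.backward(g[:, i * c:(i + 1) * c])
            gx = gb if gx is None else gx + gb
        gp = g[:, len(self.branches) * c:].sum(axis=(2, 3), keepdims=True)
        gp = self.pool_conv.backward(self.pool_act.backward(gp))
        return gx + gp / (h * w)


class _EncoderStage(nn.Module):
    """DS block + SE gating wrapped in a residual with projection."""

    def __init__(self, cin: int, cout: int, stride: int, reduction: int,
                 rng=None, dtype=np.float32):
        body = nn.Sequential(
            DepthwiseSeparableBlock(cin, cout, stride=stride, rng=rng, dtype=dtype),
            SEBlock(cout, reduction, rng=rng, dtype=dtype),
        )
        if cin != cout or stride != 1:
            proj = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng,
                          dtype=dtype),
                nn.BatchNorm2d(cout, dtype=dtype))
        else:
            proj = None
        self.res = Residual(body, proj)

    def forward(self, x):
        return self.res.forward(x)

    def backward(self, grad):
        return self.res.backward(grad)


class SegModel(nn.Module):
    """The full encoder–ASPP–decoder network (see module docstring)."""

    def __init__(self, config: SegConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.config = config
        c = config
        self.encoder = []
        cin = c.in_channels
        for i in range(c.depth):
            w = c.stage_width(i)
            stride = 1 if i == 0 else 2
            self.encoder.append(_EncoderStage(cin, w, stride, c.se_reduction,
                                              rng=rng, dtype=dtype))
            cin = w
        bott_w = c.stage_width(c.depth - 1)
        self.aspp = ASPP(bott_w, bott_w, c.atrous_rates, rng=rng, dtype=dtype)
        self.decoder = []
        self.resizers = []
        cur = bott_w
        for i in sorted(c.decoder_skip_stages, reverse=True):
            w = c.stage_width(i)
            self.resizers.append(nn.BilinearResize())
            self.decoder.append(DepthwiseSeparableBlock(cur + w, w, rng=rng,
                                                        dtype=dtype))
            cur = w
        self.final_resize = nn.BilinearResize()
        self.head = nn.Conv2d(cur, c.n_classes, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        if x.ndim != 4:
            raise ValueError("expected (batch, channel, H, W) input")
        self._in_hw = (x.shape[2], x.shape[3])
        feats = []
        cur = x
        for stage in self.encoder:
            cur = stage.forward(cur)
            feats.append(cur)
        cur = self.aspp.forward(feats[-1])
        self._skip_order = sorted(self.config.decoder_skip_stages, reverse=True)
        self._skip_widths = []
        for rz, dec, i in zip(self.resizers, self.decoder, self._skip_order):
            skip = feats[i]
            cur = rz.forward(cur, (skip.shape[2], skip.shape[3]))
            cur = dec.forward(np.concatenate([cur, skip], axis=1))
            self._skip_widths.append((cur.shape[1], skip.shape[1]))
        cur = self.final_resize.forward(cur, self._in_hw)
        return self.head.forward(cur)

    def backward(self, grad):
        g = self.head.backward(grad)
        g = self.final_resize.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for rz, dec, i in zip(reversed(self.resizers), reversed(self.decoder),
                              reversed(self._skip_order)):
            g = dec.backward(g)
            w_skip = self.config.stage_width(i)
            skip_grads[i] = g[:, -w_skip:]
            g = rz.backward(g[:, :-w_skip])
        g = self.aspp.backward(g)
        for i in range(self.config.depth - 1, -1, -1):
            if i in skip_grads:
                g = g + skip_grads[i]
            g = self.encoder[i].backward(g)
        return g


def build_model(config: SegConfig, seed: int | None = None,
                dtype=np.float32) -> SegModel:
    """Instantiate a :class:`SegModel` with seeded He initialisation."""
    rng = np.random.default_rng(seed)
    return SegModel(config, rng=rng, dtype=dtype)


def predict_slice(model: SegModel, slice_2d: np.ndarray):
    """Segment one slice; returns (label map, class-probability map).

    Accepts ``(H, W)`` (single-channel models) or ``(C, H, W)`` arrays.
    Inference is deterministic: eval mode, no stochastic layers.
    """
    x = np.asarray(slice_2d)
    if x.ndim == 2:
        x = x[None, :, :]
    if x.ndim != 3:
        raise ValueError(f"expected a 2D slice or (C,H,W) array, got ndim={x.ndim}")
    if x.shape[0] != model.config.in_channels:
        raise ValueError(
            f"slice has {x.shape[0]} channels, model expects {model.config.in_channels}")
    was_training = model.training
    model.eval()
    logits = model.forward(x[None].astype(np.float32, copy=False))
    model.train(was_training)
    probs = nn.softmax(logits, axis=1)[0]
    labels = probs.argmax(axis=0)
    return labels, probs


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    lr: float = 2e-3
    seed: int = 0
    weight_decay: float = 0.0
    dice_weight: float = 0.0
    ignore_index: int = -1
    #: median-frequency class balancing of the cross-entropy, so the
    #: small cavities (ethmoids, OMC) are not swamped by background.
    balance_classes: bool = True
    log_csv: str | None = None


def _soft_dice_grad(logits: np.ndarray, labels: np.ndarray, ignore_index: int):
    """Soft Dice loss over foreground classes and its logit gradient."""
    p = nn.softmax(logits, axis=1)
    k = logits.shape[1]
    valid = (labels != ignore_index).astype(p.dtype)
    onehot = np.zeros_like(p)
    safe = np.where(labels == ignore_index, 0, labels)
    np.put_along_axis(onehot, safe[:, None], 1.0, axis=1)
    onehot *= valid[:, None]
    pv = p * valid[:, None]
    inter = (pv * onehot).sum(axis=(0, 2, 3))
    denom = pv.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + 1e-7
    dice = 2.0 * inter / denom
    loss = 1.0 - float(dice[1:].mean())  # foreground classes only
    dLdp = np.zeros_like(p)
    nfg = k - 1
    for c in range(1, k):
        dLdp[:, c] = -(2.0 * onehot[:, c] * denom[c] - 2.0 * inter[c]) / (
            denom[c] ** 2 * nfg)
    dLdp *= valid[:, None]
    inner = (dLdp * p).sum(axis=1, keepdims=True)
    return loss, p * (dLdp - inner)


def train_step(model: SegModel, opt: nn.Adam, xb: np.ndarray, yb: np.ndarray,
               cfg: TrainConfig, class_weights: np.ndarray | None = None) -> float:
    model.zero_grad()
    logits = model.forward(xb)
    loss, dlogits = nn.softmax_cross_entropy(logits, yb, cfg.ignore_index,
                                             class_weights=class_weights)
    if cfg.dice_weight > 0:
        dloss, ddl = _soft_dice_grad(logits, yb, cfg.ignore_index)
        loss += cfg.dice_weight * dloss
        dlogits = dlogits + cfg.dice_weight * ddl.astype(dlogits.dtype)
    model.backward(dlogits)
    opt.step()
    return loss


def per_sample_losses(model: SegModel, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 32, ignore_index: int = -1) -> np.ndarray:
    """Mean cross-entropy of each slice under the current model (eval mode)."""
    was_training = model.training
    model.eval()
    out = np.empty(len(x), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size])
        _, _, per = nn.softmax_cross_entropy(logits, y[i:i + batch_size],
                                             ignore_index, per_sample=True)
        out[i:i + batch_size] = per
    model.train(was_training)
    return out


def mean_foreground_dice(model: SegModel, x: np.ndarray, y: np.ndarray,
                         batch_size: int = 32) -> float:
    """Mean Dice over foreground classes present in the reference labels."""
    from .evalstats import seg_metrics

    was_training = model.training
    model.eval()
    preds = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size])
        preds.append(logits.argmax(axis=1))
    model.train(was_training)
    pred = np.concatenate(preds)
    m = seg_metrics(pred, y)
    fg = [c for c in m.per_class_dice if c != 0]
    return float(np.mean([m.per_class_dice[c] for c in fg])) if fg else float("nan")


def train_supervised(
    model: SegModel,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    opt: nn.Adam | None = None,
) -> list[dict]:
    """Supervised training loop; returns a per-epoch history.

    ``x`` is (N, C, H, W) float32, ``y`` is (N, H, W) int labels with
    ``cfg.ignore_index`` marking pixels excluded from the loss.
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = opt or nn.Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    weights = None
    if cfg.balance_classes:
        weights = nn.median_frequency_weights(
            y, model.config.n_classes, cfg.ignore_index)
    history: list[dict] = []
    model.train(True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs >=2 samples
            losses.append(train_step(model, opt, x[idx], y[idx], cfg, weights))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val is not None:
            rec["val_dice"] = mean_foreground_dice(model, val[0], val[1])
            model.train(True)
        history.append(rec)
    if cfg.log_csv:
        path = Path(cfg.log_csv)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return history


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    """Write weights as .npz with a JSON sidecar of the SegConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = asdict(model.config)
    cfg["atrous_rates"] = list(cfg["atrous_rates"])
    cfg["decoder_skip_stages"] = list(cfg["decoder_skip_stages"])
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(cfg, fh, indent=2)


def load_checkpoint(path: str | Path) -> SegModel:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        raw = json.load(fh)
    raw["atrous_rates"] = tuple(raw["atrous_rates"])
    raw["decoder_skip_stages"] = tuple(raw["decoder_skip_stages"])
    model = SegModel(SegConfig(**raw))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict(dict(data))
    return model
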