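"""The two convolutional networks of the hybrid segmentation model.

* A U-Net (4 encoding stages, bridge, 4 decoding stages; 5x5 kernels,
  8 initial feature channels doubling per stage, "same" zero padding,
  batch normalization between convolution and ReLU in the encoder)
  that semantically labels 256x32 B-scan patches into 5 region classes.
* A sliding-window (SW) classifier (3 convolutions, 3 max-poolings,
  4 ReLUs, 2 fully connected layers, softmax; 33x33 input, 32 initial
  channels) that decides whether the centre pixel of a tiny patch lies
  on one of the 5 boundary lines (classes 1..5) or in background (0).

Whole-B-scan segmentation tiles the image into 256x32 windows, averages
overlapping class scores and takes an argmax (ties resolve to the lower
class index).  Training follows a fixed schedule: batch 128, up to 45
epochs, learning rate divided by 10 every 10 epochs, SGD with momentum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .patches import PatchSet

UNET_DOWN_FACTOR = 16


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the semantic-segmentation U-Net."""

    input_height: int = 256
    input_width: int = 32
    n_stages: int = 4
    kernel: int = 5
    initial_channels: int = 8
    n_classes: int = 5


@dataclass(frozen=True)
class SWConfig:
    """Architecture of the sliding-window boundary-pixel classifier."""

    patch_size: int = 33
    kernel: int = 5
    initial_channels: int = 32
    n_classes: int = 6


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule; defaults follow the published recipe."""

    batch_size: int = 128
    epochs: int = 45
    initial_lr: float = 0.01   # 0.05 for the SW model
    lr_decay_every: int = 10
    lr_decay_factor: float = 10.0
    momentum: float = 0.9
    seed: int = 0
    # optional early exit once validation accuracy reaches a target
    # (still within the <=45-epoch schedule); None trains all epochs.
    # stop_min_class_recall additionally requires every class present in
    # the validation labels to reach that recall before stopping —
    # overall pixel accuracy alone can be high while a thin class (the
    # EZ-pRPE band) is still entirely missed.
    stop_at_val_accuracy: float | None = None
    stop_min_class_recall: float | None = None
    # None = plain cross-entropy; "balanced" = inverse-frequency class
    # weights from the training labels (rescues classes occupying only a
    # few percent of pixels, like the EZ-pRPE band)
    class_weights: str | None = None

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for 1-based ``epoch``: lr0 / 10^floor((e-1)/10)."""
        if epoch < 1:
            raise ValueError("epochs are 1-based")
        return self.initial_lr / self.lr_decay_factor ** ((epoch - 1) // self.lr_decay_every)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A network plus its configuration and training history."""

    flavor: str                      # "unet" | "sw"
    config: UNetConfig | SWConfig
    net: nn.Layer
    trained: bool = False
    history: list[dict] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return nn.count_params(self.net)

    def describe(self) -> dict:
        return {"flavor": self.flavor, "config": asdict(self.config),
                "n_params": self.n_params, "trained": self.trained,
                "epochs_trained": len(self.history)}


def _conv_bn_relu(c_in, c_out, k, rng):
    return [nn.Conv2d(c_in, c_out, k, rng), nn.BatchNorm(c_out), nn.ReLU()]


def _conv_relu(c_in, c_out, k, rng):
    return [nn.Conv2d(c_in, c_out, k, rng), nn.ReLU()]


class _UNet(nn.Layer):
    """U-Net graph with skip connections (batch norm in the encoder only)."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        k, c0 = cfg.kernel, cfg.initial_channels
        chans = [c0 * 2 ** s for s in range(cfg.n_stages)]        # 8,16,32,64
        bridge_c = c0 * 2 ** cfg.n_stages                          # 128
        self.enc: list[nn.Sequential] = []
        c_in = 1
        for c in chans:
            self.enc.append(nn.Sequential(_conv_bn_relu(c_in, c, k, rng)
                                          + _conv_bn_relu(c, c, k, rng)))
            c_in = c
        self.pools = [nn.MaxPool2d() for _ in chans]
        self.bridge = nn.Sequential(_conv_bn_relu(c_in, bridge_c, k, rng)
                                    + _conv_bn_relu(bridge_c, bridge_c, k, rng))
        self.ups: list[nn.ConvTranspose2x2] = []
        self.dec: list[nn.Sequential] = []
        c_in = bridge_c
        for c in reversed(chans):
            self.ups.append(nn.ConvTranspose2x2(c_in, c, rng))
            self.dec.append(nn.Sequential(_conv_relu(2 * c, c, k, rng)
                                          + _conv_relu(c, c, k, rng)))
            c_in = c
        self.head = nn.Conv2d(c_in, cfg.n_classes, 1, rng)

    def params(self):
        ps = []
        for block in (*self.enc, self.bridge, *self.ups, *self.dec, self.head):
            ps.extend(block.params())
        return ps

    def forward(self, x, train):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bridge.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dy):
        dy = self.head.backward(dy)
        dskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            dy = dec.backward(dy)
            c = dy.shape[-1] // 2
            dskips.append(dy[..., :c])
            dy = up.backward(np.ascontiguousarray(dy[..., c:]))
        dy = self.bridge.backward(dy)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)
        return dy


def build_unet(cfg: UNetConfig = UNetConfig(), seed: int = 0) -> TrainedModel:
    """Construct an untrained U-Net; identical seeds give identical weights."""
    rng = np.random.default_rng(seed)
    return TrainedModel("unet", cfg, _UNet(cfg, rng))


def build_sw(cfg: SWConfig = SWConfig(), seed: int = 0) -> TrainedModel:
    """Construct the untrained sliding-window classifier.

    Layer inventory: 3 convolutions (32, 32, 64 channels), 3 max poolings,
    4 ReLUs (one after each convolution, one after the first fully
    connected layer), 2 fully connected layers, softmax applied by the
    loss / :func:`classify_pixels`.
    """
    rng = np.random.default_rng(seed)
    k, c0 = cfg.kernel, cfg.initial_channels
    s = cfg.patch_size
    # spatial sizes after the three pools (same-padded convolutions)
    for _ in range(3):
        s //= 2
    flat = s * s * (2 * c0)
    net = nn.Sequential(
        _conv_bn_relu(1, c0, k, rng) + [nn.MaxPool2d()]
        + _conv_bn_relu(c0, c0, k, rng) + [nn.MaxPool2d()]
        + _conv_bn_relu(c0, 2 * c0, k, rng) + [nn.MaxPool2d()]
        + [nn.Flatten(), nn.Linear(flat, 64, rng), nn.ReLU(),
           nn.Linear(64, cfg.n_classes, rng)]
    )
    return TrainedModel("sw", cfg, net)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_batch(model: TrainedModel, xb: np.ndarray, train: bool) -> np.ndarray:
    return model.net.forward(xb[..., None].astype(nn.F32), train)


def finalize_batchnorm(model: TrainedModel, images: np.ndarray,
                       batch_size: int = 128, max_batches: int = 4) -> None:
    """Replace EMA batch-norm statistics with population estimates.

    Runs a few inference passes over training images while the norm
    layers accumulate their input statistics; after this, evaluation
    uses population mean/variance instead of a lagging running average
    (the convention of the training framework this recipe comes from).
    """
    bns = [l for l in _iter_layers(model.net) if isinstance(l, nn.BatchNorm)]
    if not bns:
        return
    for b in bns:
        b.begin_stats()
    for i in range(0, min(len(images), max_batches * batch_size), batch_size):
        _forward_batch(model, images[i:i + batch_size], train=False)
    for b in bns:
        b.end_stats()


def _iter_layers(layer: nn.Layer):
    yield layer
    for child in vars(layer).values():
        items = child if isinstance(child, list) else [child]
        for it in items:
            if isinstance(it, nn.Layer):
                yield from _iter_layers(it)


def _accuracy(model: TrainedModel, images: np.ndarray, labels: np.ndarray,
              batch_size: int = 128) -> tuple[float, np.ndarray]:
    """Validation accuracy and per-class recall.

    Accuracy is per-pixel (U-Net) or per-patch (SW); recall is returned
    per class, NaN for classes absent from ``labels``.
    """
    n_classes = model.config.n_classes
    hits = np.zeros(n_classes)
    counts = np.zeros(n_classes)
    correct = total = 0
    for i in range(0, len(images), batch_size):
        logits = _forward_batch(model, images[i:i + batch_size], train=False)
        pred = logits.argmax(axis=-1)
        lab = labels[i:i + batch_size]
        correct += int((pred == lab).sum())
        total += pred.size
        for k in range(n_classes):
            mask = lab == k
            counts[k] += mask.sum()
            hits[k] += (pred[mask] == k).sum()
    with np.errstate(invalid="ignore"):
        recall = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return correct / max(total, 1), recall


def train(model: TrainedModel, train_set: PatchSet, val_set: PatchSet,
          tcfg: TrainConfig = TrainConfig(), verbose: bool = False) -> TrainedModel:
    """Train ``model`` in place and return it.

    U-Net models take ``flavor == "unet"`` patch sets (dense label
    patches); the SW model takes ``flavor == "sw"`` sets (integer patch
    labels).  The learning-rate schedule, batch size and epoch budget
    come from ``tcfg``; history gains one record per epoch.
    """
    if train_set.flavor != model.flavor:
        raise ValueError(f"patch flavor {train_set.flavor!r} does not match "
                         f"model flavor {model.flavor!r}")
    if len(train_set) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.SGD(model.net.params(), lr=tcfg.initial_lr, momentum=tcfg.momentum)
    x_tr, y_tr = train_set.images, train_set.labels
    weights = None
    if tcfg.class_weights == "balanced":
        counts = np.bincount(y_tr.reshape(-1),
                             minlength=model.config.n_classes).astype(np.float64)
        weights = np.where(counts > 0, counts.sum()
                           / (np.count_nonzero(counts) * np.maximum(counts, 1)),
                           0.0)
    elif tcfg.class_weights is not None:
        raise ValueError(f"unknown class_weights {tcfg.class_weights!r}")
    for epoch in range(1, tcfg.epochs + 1):
        opt.lr = tcfg.learning_rate(epoch)
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), tcfg.batch_size):
            sel = order[i:i + tcfg.batch_size]
            logits = _forward_batch(model, x_tr[sel], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_tr[sel], weights)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        finalize_batchnorm(model, x_tr, tcfg.batch_size, max_batches=2)
        if len(val_set):
            val_acc, recall = _accuracy(model, val_set.images, val_set.labels,
                                        tcfg.batch_size)
        else:
            val_acc, recall = float("nan"), np.array([])
        min_recall = float(np.nanmin(recall)) if recall.size else float("nan")
        model.history.append({"epoch": epoch, "lr": opt.lr,
                              "loss": float(np.mean(losses)),
                              "val_accuracy": val_acc,
                              "val_class_recall": recall.tolist()})
        if verbose:
            print(f"epoch {epoch:2d}  lr {opt.lr:.2g}  loss {np.mean(losses):.4f}"
                  f"  val acc {val_acc:.4f}  min recall {min_recall:.3f}")
        if tcfg.stop_at_val_accuracy is not None:
            reached = val_acc >= tcfg.stop_at_val_accuracy
            if tcfg.stop_min_class_recall is not None and recall.size:
                reached = reached and min_recall >= tcfg.stop_min_class_recall
            if reached:
                break
    model.trained = True
    return model


def validation_accuracy(model: TrainedModel, val_set: PatchSet) -> float:
    return _accuracy(model, val_set.images, val_set.labels)[0]


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _mirror_pad_to(image: np.ndarray, h: int, w: int) -> np.ndarray:
    ph, pw = h - image.shape[0], w - image.shape[1]
    return np.pad(image, ((0, ph), (0, pw)), mode="reflect")


def _tile_positions(extent: int, tile: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent) with a final flush tile."""
    if extent <= tile:
        return [0]
    pos = list(range(0, extent - tile + 1, stride))
    if pos[-1] != extent - tile:
        pos.append(extent - tile)
    return pos


def segment_bscan(model: TrainedModel, image: np.ndarray,
                  h_stride: int = 16, v_stride: int = 128,
                  batch_size: int = 64) -> np.ndarray:
    """Segment a whole B-scan with the U-Net by tiling and stitching.

    256x32 tiles are laid with the given strides (the image is
    mirror-padded up to tile multiples and cropped back), softmax class
    scores of overlapping tiles are averaged, and the per-pixel argmax
    taken; ties break toward the lower class index.  Returns an integer
    label map with the shape of ``image``.
    """
    if model.flavor != "unet":
        raise ValueError("segment_bscan requires a U-Net model")
    if not model.trained and not getattr(model, "allow_untrained", False):
        raise RuntimeError("model is untrained; train() it first")
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    cfg: UNetConfig = model.config
    th, tw = cfg.input_height, cfg.input_width
    h, w = image.shape
    work = _mirror_pad_to(image, max(h, th), max(w, tw))
    hw, ww = work.shape
    rows = _tile_positions(hw, th, v_stride)
    cols = _tile_positions(ww, tw, h_stride)
    scores = np.zeros((hw, ww, cfg.n_classes), dtype=np.float64)
    weight = np.zeros((hw, ww, 1), dtype=np.float64)
    tiles, spans = [], []
    for r in rows:
        for c in cols:
            tiles.append(work[r:r + th, c:c + tw])
            spans.append((r, c))
    tiles = np.asarray(tiles, dtype=nn.F32)
    for i in range(0, len(tiles), batch_size):
        logits = _forward_batch(model, tiles[i:i + batch_size], train=False)
        probs = nn.softmax(logits)
        for j, (r, c) in enumerate(spans[i:i + batch_size]):
            scores[r:r + th, c:c + tw] += probs[j]
            weight[r:r + th, c:c + tw] += 1.0
    scores /= weight
    return scores.argmax(axis=-1)[:h, :w].astype(np.int8)


def classify_pixels(model: TrainedModel, image: np.ndarray,
                    coords: Sequence[tuple[int, int]],
                    batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Classify pixels with the SW model.

    Extracts a 33x33 patch centred at each (row, col) of ``coords``
    (mirror padding at the borders) and returns ``(classes, probs)`` —
    integer classes in {0..5} and the softmax probability vectors.
    """
    if model.flavor != "sw":
        raise ValueError("classify_pixels requires a SW model")
    if not model.trained and not getattr(model, "allow_untrained", False):
        raise RuntimeError("model is untrained; train() it first")
    coords = list(coords)
    cfg: SWConfig = model.config
    half = cfg.patch_size // 2
    h, w = image.shape
    for r, c in coords:
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(f"coordinate {(r, c)} outside image {image.shape}")
    if not coords:
        return (np.zeros(0, dtype=np.int8),
                np.zeros((0, cfg.n_classes), dtype=nn.F32))
    padded = np.pad(image, half, mode="reflect")
    patches = np.asarray([padded[r:r + cfg.patch_size, c:c + cfg.patch_size]
                          for r, c in coords], dtype=nn.F32)
    probs = np.empty((len(coords), cfg.n_classes), dtype=nn.F32)
    for i in range(0, len(patches), batch_size):
        logits = _forward_batch(model, patches[i:i + batch_size], train=False)
        probs[i:i + batch_size] = nn.softmax(logits)
    return probs.argmax(axis=-1).astype(np.int8), probs
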