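"""3-class U-net nuclei segmentation: background / boundary / inside.

Plain semantic segmentation of nuclei merges touching instances.  Training
the network to predict a third *boundary* class — the 2-px band just inside
each singular nucleus contour — keeps the *inside* regions of touching
nuclei separated; connected components of the inside map, dilated back by
the boundary halfwidth, recover per-nucleus instance masks.  Only singular
(untruncated, non-overlapping) nuclei are labelled as targets, so the
network learns to suppress clumps and border fragments directly.

The encoder-decoder (depth 4, base 16 filters by default) runs on the
nuclei-dye density image normalised to [0, 1] by the color module's fixed
ceiling.  Training uses Adam, categorical cross-entropy, batch
normalisation, a softmax head, and on-the-fly augmentation (horizontal and
vertical flips, random zoom in [1.0, 1.1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from cishquant import nn

__all__ = [
    "TrainConfig",
    "UNet",
    "build_model",
    "train",
    "predict",
    "classmap_to_instances",
    "evaluate_iou",
    "save_checkpoint",
    "load_checkpoint",
]

BACKGROUND, BOUNDARY, INSIDE = 0, 1, 2


@dataclass
class TrainConfig:
    """Hyperparameters of the segmentation model and its training run."""

    epochs: int = 30
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"
    batch_size: int = 1
    depth: int = 4
    base_filters: int = 16
    flip_vertical: bool = True
    flip_horizontal: bool = True
    zoom_range: tuple[float, float] = (1.0, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.depth, self.base_filters) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        lo, hi = self.zoom_range
        if not (1.0 <= lo <= hi <= 1.1):
            raise ValueError("zoom range must lie within [1.0, 1.1]")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimiser is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")


class UNet:
    """Encoder-decoder with skip connections and a 3-class softmax head."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, f = config.depth, config.base_filters
        self.enc: list[tuple[nn.ConvBlock, nn.ConvBlock]] = []
        self.pools = [nn.MaxPool2() for _ in range(d)]
        c_in = 1
        for i in range(d):
            c = f * 2**i
            self.enc.append((nn.ConvBlock(c_in, c, rng), nn.ConvBlock(c, c, rng)))
            c_in = c
        cb = f * 2**d
        self.bottleneck = (nn.ConvBlock(c_in, cb, rng), nn.ConvBlock(cb, cb, rng))
        self.ups = [nn.Upsample2() for _ in range(d)]
        self.dec: list[tuple[nn.ConvBlock, nn.ConvBlock]] = []
        c_in = cb
        for i in reversed(range(d)):
            c = f * 2**i
            self.dec.append((nn.ConvBlock(c_in + c, c, rng), nn.ConvBlock(c, c, rng)))
            c_in = c
        self.head = nn.Conv1x1(f, 3, rng)
        self._skip_channels = [f * 2**i for i in range(d)]

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for a, b in self.enc:
            out += a.params() + b.params()
        out += self.bottleneck[0].params() + self.bottleneck[1].params()
        for a, b in self.dec:
            out += a.params() + b.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2**self.config.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input height/width must be divisible by {div}, got {x.shape[1:3]}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, H, W, 1) float input -> (N, H, W, 3) logits."""
        self._check_shape(x)
        skips = []
        for (blk1, blk2), pool in zip(self.enc, self.pools):
            x = blk2.forward(blk1.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x, train), train)
        for (blk1, blk2), up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = np.concatenate([up.forward(x, train), skip], axis=-1)
            x = blk2.forward(blk1.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        # reversed(dec) walks from the finest level (i=0) down to the deepest;
        # dskips therefore accumulates skip gradients in level order 0..d-1
        dskips = []
        for (blk1, blk2), up in zip(reversed(self.dec), reversed(self.ups)):
            dy = blk1.backward(blk2.backward(dy))
            c_up = dy.shape[-1] - self._skip_channels[len(dskips)]
            dskips.append(dy[..., c_up:])
            dy = up.backward(dy[..., :c_up])
        dy = self.bottleneck[0].backward(self.bottleneck[1].backward(dy))
        for (blk1, blk2), pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            dy = blk1.backward(blk2.backward(dy))


def build_model(config: TrainConfig) -> UNet:
    """Construct a freshly initialised segmentation model."""
    return UNet(config)


def _augment(
    image: np.ndarray, labels: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if config.flip_horizontal and rng.random() < 0.5:
        image, labels = image[:, ::-1], labels[:, ::-1]
    if config.flip_vertical and rng.random() < 0.5:
        image, labels = image[::-1, :], labels[::-1, :]
    lo, hi = config.zoom_range
    zoom = rng.uniform(lo, hi)
    if zoom > 1.0:
        h, w = image.shape
        zi = ndi.zoom(image, zoom, order=1)
        zl = ndi.zoom(labels, zoom, order=0)
        r0 = (zi.shape[0] - h) // 2
        c0 = (zi.shape[1] - w) // 2
        image = zi[r0 : r0 + h, c0 : c0 + w]
        labels = zl[r0 : r0 + h, c0 : c0 + w]
    return np.ascontiguousarray(image), np.ascontiguousarray(labels)


def train(
    model: UNet,
    images: list[np.ndarray],
    labels: list[np.ndarray],
    config: TrainConfig | None = None,
    augment: bool = True,
) -> list[float]:
    """Train in place; returns the per-epoch mean loss history.

    ``images`` are single-channel float arrays already normalised to [0, 1]
    (the nuclei-density channel); ``labels`` are integer 3-class maps of the
    same shape.  One seed drives shuffling and augmentation draws.
    """
    config = config or model.config
    if len(images) != len(labels) or not images:
        raise ValueError("images and labels must be aligned and nonempty")
    present = np.unique(np.concatenate([np.unique(l) for l in labels]))
    if len(present) < 3:
        import warnings

        warnings.warn(f"only classes {present.tolist()} present in labels; loss may degenerate")
    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(model.params(), lr=config.learning_rate)
    history: list[float] = []
    n = len(images)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                img, lab = images[i], labels[i]
                if augment:
                    img, lab = _augment(img, lab, config, rng)
                xs.append(img.astype(np.float32)[..., None])
                ys.append(lab)
            x = np.stack(xs)
            y = np.stack(ys)
            logits = model.forward(x, train=True)
            loss, _, dlogits = nn.softmax_cross_entropy(logits, y)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities, shape (H, W, 3); deterministic."""
    x = np.asarray(image, dtype=np.float32)[None, ..., None]
    logits = model.forward(x, train=False)
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return (ez / ez.sum(axis=-1, keepdims=True))[0]


def classmap_to_instances(
    classmap: np.ndarray, dilation_radius_px: int = 2
) -> list[np.ndarray]:
    """Instance masks from a class-probability map.

    Argmax per pixel (ties go to the lowest class index, i.e. background
    over boundary over inside), binarise the inside class, take 8-connected
    components, and dilate each component by a disk to restore the band the
    boundary class removed.  Dilated masks may touch; they stay separate.
    """
    from skimage.morphology import disk

    labels = np.argmax(classmap, axis=-1)
    inside = labels == INSIDE
    comp_labels, n = ndi.label(inside, structure=ndi.generate_binary_structure(2, 2))
    struct = disk(dilation_radius_px) if dilation_radius_px > 0 else None
    masks = []
    for i in range(1, n + 1):
        mask = comp_labels == i
        if struct is not None:
            mask = ndi.binary_dilation(mask, structure=struct)
        masks.append(mask)
    return masks


def evaluate_iou(
    predicted: list[np.ndarray], annotated: list[np.ndarray]
) -> tuple[float, list[tuple[int, int, float]]]:
    """Pixel IoU of the unions plus greedily matched per-instance IoUs.

    Returns ``(union_iou, matches)`` where each match is
    ``(predicted_index, annotated_index, iou)``; matching pairs the highest
    remaining-overlap couple first, each instance used at most once.
    """
    if not predicted and not annotated:
        return 1.0, []
    shape = (predicted or annotated)[0].shape
    pred_union = np.zeros(shape, dtype=bool)
    for m in predicted:
        pred_union |= m
    ann_union = np.zeros(shape, dtype=bool)
    for m in annotated:
        ann_union |= m
    union = (pred_union | ann_union).sum()
    union_iou = float((pred_union & ann_union).sum() / union) if union else 1.0

    pairs = []
    for i, p in enumerate(predicted):
        for j, a in enumerate(annotated):
            inter = (p & a).sum()
            if inter:
                pairs.append((float(inter / ((p | a).sum())), i, j))
    pairs.sort(reverse=True)
    used_p: set[int] = set()
    used_a: set[int] = set()
    matches = []
    for iou, i, j in pairs:
        if i in used_p or j in used_a:
            continue
        used_p.add(i)
        used_a.add(j)
        matches.append((i, j, iou))
    return union_iou, matches


def save_checkpoint(model: UNet, path, density_ceiling: float | None = None) -> None:
    """Persist weights plus the training config (and normalisation ceiling)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    bn_stats = {}
    for j, bn in enumerate(_iter_batchnorms(model)):
        bn_stats[f"bn{j}_mean"] = bn.running_mean
        bn_stats[f"bn{j}_var"] = bn.running_var
    meta = dict(asdict(model.config))
    meta["zoom_range"] = list(meta["zoom_range"])
    if density_ceiling is not None:
        meta["density_ceiling"] = density_ceiling
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays, **bn_stats)


def load_checkpoint(path) -> tuple[UNet, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        ceiling = meta.pop("density_ceiling", None)
        meta["zoom_range"] = tuple(meta["zoom_range"])
        config = TrainConfig(**meta)
        model = UNet(config)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for j, bn in enumerate(_iter_batchnorms(model)):
            bn.running_mean = data[f"bn{j}_mean"]
            bn.running_var = data[f"bn{j}_var"]
    extra = {"density_ceiling": ceiling} if ceiling is not None else {}
    return model, extra


def _iter_batchnorms(model: UNet):
    for a, b in model.enc:
        yield a.bn
        yield b.bn
    yield model.bottleneck[0].bn
    yield model.bottleneck[1].bn
    for a, b in model.dec:
        yield a.bn
        yield b.bn
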