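"""Stage One: per-slice U-shaped lesion segmentation.

A 2D encoder-decoder with skip connections segments each transverse DWI
slice; the per-slice probability maps are thresholded and stacked in slice
order to compose the patient's SegMap. Three scaled-down backbone block
types are available — plain convolutional, residual, and densely
connected — standing in for the full-scale VGG/ResNet/DenseNet U-Net
variants at desk scale. Training minimizes the Focal Tversky loss with
Adam under a cosine-annealed learning rate, and the parameter state with
the best validation Dice is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .imageio import AugmentParams, DwiVolume, SegMap, augment
from .losses import EPS, TverskyParams
from .metrics import dice
from .nn import Adam, Conv2d, Module, Tensor, concat, cosine_lr

__all__ = ["S1Config", "TrainedS1", "build_s1", "train_s1", "predict_segmap",
           "threshold_segmap", "save_s1", "load_s1"]

BACKBONES = ("plain", "residual", "dense")


@dataclass(frozen=True)
class S1Config:
    """Architecture and training hyperparameters of the slice segmenter."""

    backbone: str = "plain"
    depth: int = 3
    base_width: int = 8
    epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 16
    loss: TverskyParams = field(default_factory=TverskyParams)
    seed: int = 0
    binarization_threshold: float = 0.5
    augment_params: AugmentParams | None = field(
        default_factory=lambda: AugmentParams(
            rotate_deg=10.0, hflip_prob=0.5, shift_frac=0.05,
            scale_delta=0.05, ssr_rotate_deg=10.0))

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.binarization_threshold < 1:
            raise ValueError("binarization_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Blocks and network
# ---------------------------------------------------------------------------

class _PlainBlock(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x):
        return self.c2(self.c1(x).relu()).relu()


class _ResidualBlock(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.proj = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x):
        y = self.c2(self.c1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class _DenseBlock(Module):
    def __init__(self, in_ch, out_ch, rng):
        growth = max(out_ch // 2, 2)
        self.c1 = Conv2d(in_ch, growth, 3, rng)
        self.c2 = Conv2d(in_ch + growth, growth, 3, rng)
        self.squeeze = Conv2d(in_ch + 2 * growth, out_ch, 1, rng)

    def __call__(self, x):
        y1 = self.c1(x).relu()
        x1 = concat([x, y1], axis=1)
        y2 = self.c2(x1).relu()
        return self.squeeze(concat([x1, y2], axis=1)).relu()


_BLOCKS = {"plain": _PlainBlock, "residual": _ResidualBlock,
           "dense": _DenseBlock}


class UNet2D(Module):
    """U-shaped encoder-decoder over single-channel slices."""

    def __init__(self, config: S1Config):
        rng = np.random.default_rng(config.seed)
        block = _BLOCKS[config.backbone]
        d, w = config.depth, config.base_width
        widths = [w * 2 ** i for i in range(d)]
        self.enc = []
        in_ch = 1
        for width in widths:
            self.enc.append(block(in_ch, width, rng))
            in_ch = width
        self.dec = []
        for i in range(d - 2, -1, -1):
            self.dec.append(block(widths[i + 1] + widths[i], widths[i], rng))
        self.head = Conv2d(widths[0], 1, 1, rng)
        self.depth = d

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk(x)
            if i < self.depth - 1:
                skips.append(x)
                x = x.maxpool2d()
        for blk, skip in zip(self.dec, reversed(skips)):
            x = blk(concat([x.upsample2d(), skip], axis=1))
        return self.head(x).sigmoid()


@dataclass
class TrainedS1:
    """Segmenter parameters plus config and training history."""

    model: UNet2D
    config: S1Config
    history: list[dict] = field(default_factory=list)
    best_val_dice: float = float("nan")
    val_patient_ids: list[str] = field(default_factory=list)
    trained: bool = False

    @property
    def input_multiple(self) -> int:
        return 2 ** (self.config.depth - 1)


def build_s1(config: S1Config) -> TrainedS1:
    """Construct an untrained slice segmenter from its config."""
    return TrainedS1(model=UNet2D(config), config=config)


def _check_dims(shape, depth):
    mult = 2 ** (depth - 1)
    if shape[0] % mult or shape[1] % mult:
        raise ValueError(
            f"slice dims {shape[:2]} must be divisible by {mult} "
            f"(2**(depth-1))")


def _focal_tversky_graph(probs: Tensor, truth: np.ndarray,
                         params: TverskyParams) -> Tensor:
    t = truth.astype(np.float64)
    tp = (probs * t).sum()
    fn = ((1.0 - probs) * t).sum()
    fp = (probs * (1.0 - t)).sum()
    ti = (tp + EPS) / (tp + params.alpha * fn + params.beta * fp + EPS)
    return (1.0 - ti).pow(params.gamma)


def _case_slices(case) -> tuple[np.ndarray, np.ndarray]:
    vol = case.volume.data
    msk = case.truth_mask.data
    imgs = np.moveaxis(vol, 2, 0)[:, None, :, :]
    msks = np.moveaxis(msk, 2, 0)[:, None, :, :]
    return imgs, msks


def train_s1(model: TrainedS1, cases: list, config: S1Config | None = None,
             val_fraction: float = 0.2) -> TrainedS1:
    """Train the segmenter on preprocessed phantom/patient cases.

    ``cases`` must already be padded and z-score normalized. Patients are
    split into training and internal validation (last ``val_fraction`` of a
    seeded shuffle); augmentation applies to training slices only. Returns
    the model holding the parameter state with the best validation Dice.
    Fully deterministic given ``config.seed``.
    """
    config = config or model.config
    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    _check_dims(cases[0].volume.data.shape, config.depth)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(cases))
    n_val = max(1, int(round(val_fraction * len(cases))))
    val_cases = [cases[i] for i in order[len(cases) - n_val:]]
    train_cases = [cases[i] for i in order[:len(cases) - n_val]]

    imgs_list, msks_list = zip(*(_case_slices(c) for c in train_cases))
    imgs = np.concatenate(imgs_list)
    msks = np.concatenate(msks_list)
    if not np.any(msks):
        raise ValueError("no lesion-positive slice in training set")

    net = model.model
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = []
    best_state, best_dice = None, -1.0
    n = len(imgs)
    for epoch in range(config.epochs):
        lr = cosine_lr(config.learning_rate, epoch, config.epochs)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = imgs[idx]
            yb = msks[idx]
            if config.augment_params is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    aug_seed = int((config.seed * 1000003 + epoch * 8191
                                    + int(idx[j])) % 2**31)
                    xb[j, 0], yb[j, 0] = augment(
                        xb[j, 0], yb[j, 0], config.augment_params, aug_seed)
            probs = net(Tensor(xb))
            loss = _focal_tversky_graph(probs, yb, config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            losses.append(float(loss.data))
        val_dice = _validation_dice(model, val_cases)
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": float(np.mean(losses)),
                        "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = net.state()
    net.load_state(best_state)
    model.history = history
    model.best_val_dice = best_dice
    model.val_patient_ids = [c.patient_id for c in val_cases]
    model.trained = True
    return model


def _validation_dice(model: TrainedS1, cases: list) -> float:
    scores = []
    for case in cases:
        pred = predict_segmap(model, case.volume, _check_trained=False)
        try:
            scores.append(dice(pred, case.truth_mask))
        except ValueError:  # both empty
            scores.append(1.0)
    return float(np.mean(scores)) if scores else float("nan")


def predict_segmap(model: TrainedS1, volume: DwiVolume,
                   _check_trained: bool = True) -> SegMap:
    """Segment every slice and compose the patient's 3D SegMap.

    Blank (all-zero) slices — the padding convention — bypass the network
    and yield defined-zero output. Per-slice probabilities are thresholded
    at ``binarization_threshold`` and stacked in slice order on the
    volume's grid.
    """
    if _check_trained and not model.trained:
        raise ValueError("model is untrained; call train_s1 first")
    _check_dims(volume.data.shape, model.config.depth)
    imgs = np.moveaxis(volume.data, 2, 0)[:, None, :, :]
    nonblank = np.array([np.any(s) for s in imgs[:, 0]])
    probs = np.zeros(imgs.shape)
    if nonblank.any():
        out = model.model(Tensor(imgs[nonblank]))
        probs[nonblank] = out.data
    binary = (probs[:, 0] >= model.config.binarization_threshold)
    data = np.moveaxis(binary, 0, 2).astype(np.uint8)
    return SegMap(data, volume.spacing_mm, volume.affine, volume.patient_id)


def predict_probabilities(model: TrainedS1, volume: DwiVolume) -> np.ndarray:
    """Per-voxel lesion probabilities (same grid as the volume)."""
    _check_dims(volume.data.shape, model.config.depth)
    imgs = np.moveaxis(volume.data, 2, 0)[:, None, :, :]
    nonblank = np.array([np.any(s) for s in imgs[:, 0]])
    probs = np.zeros(imgs.shape)
    if nonblank.any():
        probs[nonblank] = model.model(Tensor(imgs[nonblank])).data
    return np.moveaxis(probs[:, 0], 0, 2)


def threshold_segmap(volume: DwiVolume, z_threshold: float = 2.5) -> SegMap:
    """Plain intensity-threshold segmenter (a learned model's oracle).

    On a z-score normalized volume the background is ~N(0, 1), so voxels at
    or above ``z_threshold`` standard scores are marked lesion. Used as a
    reference baseline: on high-contrast phantoms this simple rule is near
    ceiling, so a trained segmenter should track it closely.
    """
    data = (volume.data >= z_threshold).astype(np.uint8)
    return SegMap(data, volume.spacing_mm, volume.affine, volume.patient_id)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_s1(model: TrainedS1, path) -> None:
    import dataclasses

    state = {f"p{i}": arr for i, arr in enumerate(model.model.state())}
    meta = {"config": dataclasses.asdict(model.config),
            "history": model.history,
            "best_val_dice": model.best_val_dice,
            "val_patient_ids": model.val_patient_ids,
            "trained": model.trained}
    np.savez(Path(path), meta=json.dumps(meta), **state)


def load_s1(path) -> TrainedS1:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        keys = sorted((k for k in archive.files if k != "meta"),
                      key=lambda k: int(k[1:]))
        arrays = [archive[k] for k in keys]
    cfg = meta["config"]
    cfg["loss"] = TverskyParams(**cfg["loss"])
    if cfg["augment_params"] is not None:
        cfg["augment_params"] = AugmentParams(**cfg["augment_params"])
    config = S1Config(**cfg)
    model = build_s1(config)
    model.model.load_state(arrays)
    model.history = meta["history"]
    model.best_val_dice = meta["best_val_dice"]
    model.val_patient_ids = meta.get("val_patient_ids", [])
    model.trained = meta["trained"]
    return model
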