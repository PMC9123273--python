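"""Stage Two: SegMap-guided 3D classification, plus a one-stage baseline.

The two-stage classifier sees the lesion through the SegMap — by default
the voxelwise product of DWI volume and mask ("extracted stroke area"),
optionally the mask alone or a two-channel stack — so it learns from the
segmented lesion's 3D geometry rather than from the whole brain. The
one-stage baseline is the traditional design: the same 3D network applied
to the full preprocessed volume. Both train under the focal loss with Adam
and cosine annealing; each model's decision threshold is set by Youden's
index on its internal validation predictions.

Binary conventions: the positive class is *non-lacune* for the size task
and *posterior* for the territory task. Patients whose lesions span both
territories are excluded from the territory task before training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imageio import DwiVolume, SegMap
from .losses import FocalParams
from .metrics import RankedPredictions, auroc, youden_threshold
from .nn import Adam, Conv3d, Dense, Module, Tensor, cosine_lr

__all__ = [
    "S2Config",
    "ClassPrediction",
    "TrainedS2",
    "make_s2_input",
    "train_s2",
    "train_one_stage",
    "predict_class",
    "save_s2",
    "load_s2",
    "POSITIVE_CLASS",
]

logger = logging.getLogger(__name__)

BACKBONES_3D = ("plain3d", "res3d_small", "res3d_large")
INPUT_MODES = ("masked_dwi", "mask_only", "two_channel")
TASKS = ("size", "territory")

# positive class per task: arbitrary but fixed
POSITIVE_CLASS = {"size": "non_lacune", "territory": "posterior"}
NEGATIVE_CLASS = {"size": "lacune", "territory": "anterior"}


@dataclass(frozen=True)
class S2Config:
    """Architecture and training hyperparameters of the 3D classifier."""

    backbone: str = "plain3d"
    input_mode: str = "masked_dwi"
    task: str = "size"
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 8
    loss: FocalParams = field(default_factory=FocalParams)
    seed: int = 0
    decision_threshold: float | None = None  # None -> Youden on validation
    downsample_inplane: int = 2
    weight_decay: float = 1e-4
    augment_flips: bool = True
    augment_shift_vox: int = 2
    tta_flip: bool = True  # average predictions over the left-right flip
    n_ensemble: int = 1  # independently initialized members, shared split

    def __post_init__(self):
        if self.backbone not in BACKBONES_3D:
            raise ValueError(f"backbone must be one of {BACKBONES_3D}")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.downsample_inplane < 1:
            raise ValueError("downsample_inplane must be >= 1")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")


@dataclass(frozen=True)
class ClassPrediction:
    patient_id: str
    probability: float
    predicted_class: str
    threshold_used: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def make_s2_input(volume: DwiVolume, segmap: SegMap, mode: str) -> np.ndarray:
    """Build the classifier input from volume and SegMap (channel-first).

    masked_dwi: voxelwise product volume*mask; mask_only: the mask;
    two_channel: both stacked along a leading channel axis.
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"input_mode must be one of {INPUT_MODES}")
    if volume.data.shape != segmap.data.shape:
        raise ValueError(
            f"grid mismatch: {volume.data.shape} vs {segmap.data.shape}")
    mask = segmap.data.astype(np.float64)
    if mode == "masked_dwi":
        return (volume.data * mask)[None]
    if mode == "mask_only":
        return mask[None]
    return np.stack([volume.data * mask, mask])


def _downsample_inplane(x: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean in-plane downsampling of a (C, X, Y, Z) array."""
    if factor == 1:
        return x
    c, nx, ny, nz = x.shape
    tx, ty = (nx // factor) * factor, (ny // factor) * factor
    x = x[:, :tx, :ty, :]
    return x.reshape(c, tx // factor, factor, ty // factor, factor, nz).mean(
        axis=(2, 4))


def _downsample_batch(x: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean in-plane downsampling of a (N, C, X, Y, Z) batch."""
    if factor == 1:
        return x
    n, c, nx, ny, nz = x.shape
    tx, ty = (nx // factor) * factor, (ny // factor) * factor
    x = x[:, :, :tx, :ty, :]
    return x.reshape(n, c, tx // factor, factor, ty // factor, factor,
                     nz).mean(axis=(3, 5))


# ---------------------------------------------------------------------------
# 3D networks
# ---------------------------------------------------------------------------

class _Plain3dBlock(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv3d(in_ch, out_ch, 3, rng)

    def __call__(self, x):
        return self.c1(x).relu()


class _Res3dBlock(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv3d(in_ch, out_ch, 3, rng)
        self.c2 = Conv3d(out_ch, out_ch, 3, rng)
        self.proj = Conv3d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x):
        y = self.c2(self.c1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class Net3D(Module):
    """Small 3D conv net: three conv/pool stages, then a dense head.

    The head flattens the pooled 4x4x2-ish grid (rather than global
    pooling) so the classifier keeps coarse spatial location — needed for
    the territory task — while staying small enough not to memorize
    desk-scale cohorts.
    """

    def __init__(self, config: S2Config, in_channels: int,
                 input_shape: tuple[int, int, int]):
        rng = np.random.default_rng(config.seed)
        block = _Res3dBlock if config.backbone.startswith("res3d") else _Plain3dBlock
        w1, w2, w3 = (12, 24, 24) if config.backbone == "res3d_large" else (8, 16, 16)
        self.b1 = block(in_channels, w1, rng)
        self.b2 = block(w1, w2, rng)
        self.b3 = block(w2, w3, rng)
        nx, ny, nz = input_shape
        if nx % 8 or ny % 8 or nz % 4:
            raise ValueError(
                "classifier input dims must be divisible by (8, 8, 4)")
        flat = (nx // 8) * (ny // 8) * (nz // 4) * w3
        self.fc1 = Dense(flat, 32, rng)
        self.fc2 = Dense(32, 1, rng)
        self._flat = flat

    def __call__(self, x: Tensor) -> Tensor:
        x = self.b1(x).maxpool3d((2, 2, 2))
        x = self.b2(x).maxpool3d((2, 2, 2))
        x = self.b3(x).maxpool3d((2, 2, 1))
        x = x.reshape(x.shape[0], self._flat)
        return self.fc2(self.fc1(x).relu())  # logits


@dataclass
class TrainedS2:
    """Classifier parameters, config, threshold, and validation predictions.

    ``models`` holds ``config.n_ensemble`` members trained on the same
    train/validation split from independent initializations; predictions
    average the members' probabilities.
    """

    models: list[Net3D]
    config: S2Config
    two_stage: bool
    input_shape: tuple[int, int, int]
    in_channels: int
    threshold: float = 0.5
    val_probs: np.ndarray = None  # type: ignore[assignment]
    val_labels: np.ndarray = None  # type: ignore[assignment]
    history: list = field(default_factory=list)  # per-member epoch records
    n_excluded_both: int = 0
    trained: bool = False


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _focal_graph(logits: Tensor, y: np.ndarray, params: FocalParams) -> Tensor:
    p = logits.sigmoid()
    y = y.reshape(-1, 1).astype(np.float64)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    eps = 1e-7
    return (-(params.alpha) * (1.0 - p_t).pow(params.gamma)
            * (p_t + eps).log()).mean()


def _label_value(case, task: str) -> int:
    lab = case.size_label if task == "size" else case.territory_label
    return int(lab == POSITIVE_CLASS[task])


def _augment_batch(x: np.ndarray, config: S2Config,
                   rng: np.random.Generator) -> np.ndarray:
    """Random in-plane isometries and small integer translations (zero fill).

    The size label is invariant to every in-plane isometry, so the size
    task draws from the full dihedral group (x/y flips and, on square
    grids, transposition) — an eightfold effective enlargement of the
    training set. The territory task only flips the x (left-right) axis:
    the brain is left-right symmetric, but flipping the
    anterior-posterior axis would relabel territory.
    """
    out = x.copy()
    s = config.augment_shift_vox
    full_group = config.task == "size"
    square = x.shape[2] == x.shape[3]
    for i in range(len(out)):
        if config.augment_flips and rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if config.augment_flips and full_group:
            if rng.random() < 0.5:
                out[i] = out[i, :, :, ::-1]
            if square and rng.random() < 0.5:
                out[i] = out[i].transpose(0, 2, 1, 3)
        if s:
            dx, dy = rng.integers(-s, s + 1, size=2)
            shifted = np.zeros_like(out[i])
            src_x = slice(max(0, -dx), out.shape[2] - max(0, dx))
            dst_x = slice(max(0, dx), out.shape[2] - max(0, -dx))
            src_y = slice(max(0, -dy), out.shape[3] - max(0, dy))
            dst_y = slice(max(0, dy), out.shape[3] - max(0, -dy))
            shifted[:, dst_x, dst_y] = out[i][:, src_x, src_y]
            out[i] = shifted
    return out


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _fit_member(x_tr, y_tr, x_va, y_va, config: S2Config, seed: int):
    """Train one ensemble member; returns (net, val_probs, history).

    Training sees full-resolution inputs; augmentation happens at full
    resolution and the in-plane downsampling is applied per batch, so
    integer shifts present fine structure (e.g. the gap between scattered
    components) at many phases of the downsampling blocks."""
    member_cfg = S2Config(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(seed + 1)
    net = Net3D(member_cfg, in_channels=x_tr.shape[1],
                input_shape=x_va.shape[2:])
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = []
    best_state, best_loss = None, float("inf")
    n = len(x_tr)
    for epoch in range(config.epochs):
        lr = cosine_lr(config.learning_rate, epoch, config.epochs)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = _downsample_batch(_augment_batch(x_tr[idx], config, rng),
                                   config.downsample_inplane)
            logits = net(Tensor(xb))
            loss = _focal_graph(logits, y_tr[idx], config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr, weight_decay=config.weight_decay)
            losses.append(float(loss.data))
        val_probs = _forward_probs(net, x_va, config.batch_size,
                                   tta=config.tta_flip,
                                   full_group=config.task == "size")
        try:
            val_auc = auroc(RankedPredictions(val_probs, y_va))
        except ValueError:
            val_auc = float("nan")
        val_loss = _focal_numpy(val_probs, y_va, config.loss)
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_auroc": val_auc})
        # select on validation focal loss: smoother than a small-sample AUROC
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = net.state()
    if best_state is not None:
        net.load_state(best_state)
    val_probs = _forward_probs(net, x_va, config.batch_size,
                               tta=config.tta_flip,
                               full_group=config.task == "size")
    return net, val_probs, history


def _fit(inputs: np.ndarray, labels: np.ndarray, config: S2Config,
         two_stage: bool, val_fraction: float = 0.25) -> TrainedS2:
    """Split once, then train ``config.n_ensemble`` members on that split."""
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 patients of each class")
    rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _stratified_split(labels, val_fraction, rng)
    x_tr, y_tr = inputs[train_idx], labels[train_idx]
    x_va = _downsample_batch(inputs[val_idx], config.downsample_inplane)
    y_va = labels[val_idx]

    nets, member_probs, history = [], [], []
    for k in range(config.n_ensemble):
        net, probs, hist = _fit_member(x_tr, y_tr, x_va, y_va, config,
                                       seed=config.seed + 1000 * k)
        nets.append(net)
        member_probs.append(probs)
        history.append(hist)
    val_probs = np.mean(member_probs, axis=0)

    if config.decision_threshold is not None:
        thr = float(config.decision_threshold)
    else:
        thr, _ = youden_threshold(RankedPredictions(val_probs, y_va))
    return TrainedS2(models=nets, config=config, two_stage=two_stage,
                     input_shape=inputs.shape[2:], in_channels=inputs.shape[1],
                     threshold=thr, val_probs=val_probs, val_labels=y_va,
                     history=history, trained=True)


def _forward_probs(net: Net3D, x: np.ndarray, batch_size: int,
                   tta: bool = False, full_group: bool = False) -> np.ndarray:
    """Sigmoid probabilities, optionally averaging logits over flips.

    With ``tta`` the left-right flip is always included; ``full_group``
    (size task) additionally averages the anterior-posterior flip and the
    combined flip — the orientations the size label is invariant to.
    """
    out = []
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        views = [xb]
        if tta:
            views.append(xb[:, :, ::-1])
            if full_group:
                views.append(xb[:, :, :, ::-1])
                views.append(xb[:, :, ::-1, ::-1])
        logits = np.mean(
            [net(Tensor(v)).data[:, 0].astype(np.float64) for v in views],
            axis=0)
        out.append(1.0 / (1.0 + np.exp(-logits)))
    return np.concatenate(out) if out else np.empty(0)


def _focal_numpy(probs: np.ndarray, y: np.ndarray,
                 params: FocalParams) -> float:
    p_t = np.where(y == 1, probs, 1.0 - probs)
    return float(np.mean(-params.alpha * (1.0 - p_t) ** params.gamma
                         * np.log(p_t + 1e-7)))


def _exclude_both(cases: list, segmaps: list | None, task: str):
    if task != "territory":
        return cases, segmaps, 0
    keep = [i for i, c in enumerate(cases) if c.territory_label != "both"]
    n_excl = len(cases) - len(keep)
    if n_excl:
        logger.info("territory task: excluded %d both-territory patients",
                    n_excl)
    cases = [cases[i] for i in keep]
    if segmaps is not None:
        segmaps = [segmaps[i] for i in keep]
    return cases, segmaps, n_excl


def train_s2(cases: list, segmaps: list, task: str,
             config: S2Config | None = None) -> TrainedS2:
    """Train the two-stage classifier on SegMap-guided inputs.

    ``segmaps`` are the per-patient SegMaps (ground truth or S1
    predictions) on the same grids as the case volumes. Both-territory
    patients are excluded from the territory task. Deterministic given
    ``config.seed``; the decision threshold is set by Youden's index on
    the internal validation predictions.
    """
    config = config or S2Config(task=task)
    if config.task != task:
        config = S2Config(**{**config.__dict__, "task": task})
    cases, segmaps, n_excl = _exclude_both(cases, segmaps, task)
    inputs = np.stack([make_s2_input(c.volume, m, config.input_mode)
                       for c, m in zip(cases, segmaps, strict=True)])
    labels = np.array([_label_value(c, task) for c in cases])
    trained = _fit(inputs, labels, config, two_stage=True)
    trained.n_excluded_both = n_excl
    return trained


def train_one_stage(cases: list, task: str,
                    config: S2Config | None = None) -> TrainedS2:
    """Train the traditional one-stage baseline on full volumes."""
    config = config or S2Config(task=task)
    if config.task != task:
        config = S2Config(**{**config.__dict__, "task": task})
    cases, _, n_excl = _exclude_both(cases, None, task)
    inputs = np.stack([c.volume.data[None] for c in cases])
    labels = np.array([_label_value(c, task) for c in cases])
    trained = _fit(inputs, labels, config, two_stage=False)
    trained.n_excluded_both = n_excl
    return trained


def save_s2(classifier: TrainedS2, path) -> None:
    import dataclasses
    import json
    from pathlib import Path

    state = {f"m{k}p{i}": arr
             for k, net in enumerate(classifier.models)
             for i, arr in enumerate(net.state())}
    cfg = dataclasses.asdict(classifier.config)
    cfg["loss"] = dataclasses.asdict(classifier.config.loss)
    meta = {"config": cfg,
            "two_stage": classifier.two_stage,
            "input_shape": list(classifier.input_shape),
            "in_channels": classifier.in_channels,
            "threshold": classifier.threshold,
            "history": classifier.history,
            "n_excluded_both": classifier.n_excluded_both,
            "trained": classifier.trained}
    np.savez(Path(path), meta=json.dumps(meta), **state,
             val_probs=classifier.val_probs, val_labels=classifier.val_labels)


def load_s2(path) -> TrainedS2:
    import json

    import re

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        member_arrays: dict[int, list] = {}
        for key in archive.files:
            m = re.fullmatch(r"m(\d+)p(\d+)", key)
            if m:
                member_arrays.setdefault(int(m.group(1)), []).append(
                    (int(m.group(2)), archive[key]))
        val_probs = archive["val_probs"]
        val_labels = archive["val_labels"]
    cfg = meta["config"]
    cfg["loss"] = FocalParams(**cfg["loss"])
    config = S2Config(**cfg)
    nets = []
    f = config.downsample_inplane
    nx, ny, nz = meta["input_shape"]
    net_shape = (nx // f, ny // f, nz)  # nets operate on the training grid
    for k in sorted(member_arrays):
        member_cfg = S2Config(**{**config.__dict__,
                                 "seed": config.seed + 1000 * k})
        net = Net3D(member_cfg, in_channels=meta["in_channels"],
                    input_shape=net_shape)
        net.load_state([a for _, a in sorted(member_arrays[k])])
        nets.append(net)
    return TrainedS2(models=nets, config=config, two_stage=meta["two_stage"],
                     input_shape=tuple(meta["input_shape"]),
                     in_channels=meta["in_channels"],
                     threshold=meta["threshold"], val_probs=val_probs,
                     val_labels=val_labels, history=meta["history"],
                     n_excluded_both=meta["n_excluded_both"],
                     trained=meta["trained"])


def predict_class(classifier: TrainedS2, volume: DwiVolume,
                  segmap: SegMap | None = None) -> ClassPrediction:
    """Classify one patient; positive iff probability >= threshold."""
    if not classifier.trained:
        raise ValueError("classifier is untrained")
    config = classifier.config
    if classifier.two_stage:
        if segmap is None:
            raise ValueError("two-stage classifier requires a SegMap")
        x = make_s2_input(volume, segmap, config.input_mode)
    else:
        x = volume.data[None]
    if x.shape[1:] != tuple(classifier.input_shape):
        raise ValueError(f"input grid {x.shape[1:]} does not match "
                         f"trained shape {tuple(classifier.input_shape)}")
    x = _downsample_inplane(x, config.downsample_inplane)[None]
    prob = float(np.mean([
        _forward_probs(net, x, 1, tta=config.tta_flip,
                       full_group=config.task == "size")[0]
        for net in classifier.models]))
    task = config.task
    pred = (POSITIVE_CLASS[task] if prob >= classifier.threshold
            else NEGATIVE_CLASS[task])
    return ClassPrediction(patient_id=volume.patient_id, probability=prob,
                           predicted_class=pred,
                           threshold_used=classifier.threshold)
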