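"""Brain/object localization back-ends.

Two localizers are provided, mirroring the deployed feedback pipeline:

* :func:`segment_intensity` -- thresholding (Otsu by default), largest
  6-connected component, hole filling; the phantom path.
* a 3D U-Net (:func:`build_localizer_network`) trained with the generalized
  Dice loss and Adam; the fetal path, trainable at desk scale on synthetic
  scenes.

The generalized Dice loss over ``M`` tissue classes is

.. math::

    L = 1 - 2 \\frac{\\sum_k w_k \\sum_n p_{kn} t_{kn}}
                  {\\sum_k w_k \\sum_n (p_{kn} + t_{kn})},
    \\qquad w_k = 1 / (\\textstyle\\sum_n t_{kn})^2,

where ``p`` is the predicted per-class probability map and ``t`` the one-hot
target.  Classes absent from the target make ``w_k`` diverge; their weight is
clamped at ``1/eps**2`` with ``eps = 1e-5`` voxels, which keeps the loss
finite and leaves present-class behaviour untouched.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import BinaryMask, GridGeometry, VolumeGrid
from .nn import Adam, UNet3d

_ABSENT_CLASS_EPS = 1e-5

# 6-connectivity (faces only) for component analysis
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# Probabilistic / label maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProbabilityMap:
    """Per-voxel class probabilities, channel-first ``(M, X, Y, Z)``."""

    geometry: GridGeometry
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4 or self.probs.shape[1:] != self.geometry.shape:
            raise ValueError("probs must be (M, X, Y, Z) matching the geometry")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-voxel class probabilities must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]


@dataclasses.dataclass
class LabelMap:
    """One-hot target map, channel-first ``(M, X, Y, Z)``."""

    geometry: GridGeometry
    onehot: np.ndarray

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot, dtype=np.float32)
        if self.onehot.ndim != 4 or self.onehot.shape[1:] != self.geometry.shape:
            raise ValueError("onehot must be (M, X, Y, Z) matching the geometry")
        if not np.array_equal(self.onehot, self.onehot.astype(bool)):
            raise ValueError("onehot entries must be 0/1")
        if not np.array_equal(
            self.onehot.sum(axis=0), np.ones(self.geometry.shape, dtype=np.float32)
        ):
            raise ValueError("exactly one class per voxel required")

    @staticmethod
    def from_mask(mask: BinaryMask) -> "LabelMap":
        fg = mask.values.astype(np.float32)
        return LabelMap(mask.geometry, np.stack([1.0 - fg, fg], axis=0))

    @property
    def n_classes(self) -> int:
        return self.onehot.shape[0]


def class_weights(onehot: np.ndarray) -> np.ndarray:
    """Inverse-squared-volume class weights ``w_k = 1/(sum_n t_kn)^2`` with
    absent classes clamped at ``1/eps^2``."""
    t = onehot.reshape(onehot.shape[0], -1)
    sums = np.maximum(t.sum(axis=1, dtype=np.float64), _ABSENT_CLASS_EPS)
    return 1.0 / sums**2


def _gdl_core(p: np.ndarray, t: np.ndarray):
    """Loss and intermediates on flattened (M, N) float64 arrays."""
    w = class_weights(t)
    inter = (p * t).sum(axis=1)
    total = (p + t).sum(axis=1)
    num = float((w * inter).sum())
    den = float((w * total).sum())
    loss = 1.0 - 2.0 * num / den
    return loss, w, num, den


def generalized_dice_loss(pred: ProbabilityMap, target: LabelMap) -> float:
    """Generalized Dice loss between a probability map and a one-hot target."""
    if pred.geometry != target.geometry or pred.n_classes != target.n_classes:
        raise ValueError("prediction and target must share geometry and classes")
    p = pred.probs.reshape(pred.n_classes, -1).astype(np.float64)
    t = target.onehot.reshape(target.n_classes, -1).astype(np.float64)
    loss, *_ = _gdl_core(p, t)
    return loss


def gdl_value_and_grad(probs: np.ndarray, onehot: np.ndarray):
    """GDL and its gradient w.r.t. the probabilities (arrays ``(M, ...)``)."""
    shape = probs.shape
    p = probs.reshape(shape[0], -1).astype(np.float64)
    t = onehot.reshape(shape[0], -1).astype(np.float64)
    loss, w, num, den = _gdl_core(p, t)
    # dL/dp_kn = -2 (w_k t_kn den - num w_k) / den^2
    grad = -2.0 * (w[:, None] * t * den - num * w[:, None]) / den**2
    return loss, grad.reshape(shape)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Network construction and inference
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of the localization U-Net.

    The default is the deployed configuration: five encoder-decoder levels
    with (32, 64, 128, 256, 512) channels, two 3x3x3 stride-1 conv blocks per
    stage with instance normalization and LeakyReLU, 2x2x2 average pooling at
    the first two downsamplings and 2x2x2 max pooling at the remaining two,
    a mirrored decoder with upsampling, and N = 2 output classes.
    ``small()`` is a reduced desk-scale profile for CPU training.
    """

    channels: tuple = (32, 64, 128, 256, 512)
    levels: int = 5
    n_classes: int = 2
    input_edge: int = 128

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        if len(self.channels) != self.levels:
            raise ValueError(
                f"need {self.levels} channel widths, got {len(self.channels)}"
            )
        if any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channel widths must be strictly increasing")
        if self.n_classes != 2:
            raise ValueError("the localizer is a 2-class (background/brain) network")
        if self.input_edge % 2 ** (self.levels - 1):
            raise ValueError(
                f"input edge {self.input_edge} not divisible by "
                f"2**(levels-1) = {2 ** (self.levels - 1)}"
            )

    @staticmethod
    def small(input_edge: int = 64) -> "NetworkSpec":
        """Reduced profile (same family, 4x fewer channels) for CPU budgets."""
        return NetworkSpec(channels=(8, 16, 32, 64, 128), input_edge=input_edge)


def build_localizer_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> UNet3d:
    """Instantiate the localization U-Net for a given :class:`NetworkSpec`."""
    return UNet3d(channels=spec.channels, in_channels=1,
                  n_classes=spec.n_classes, seed=seed)


def normalize_volume(values: np.ndarray, lo_pct=1.0, hi_pct=99.0) -> np.ndarray:
    """Per-volume robust percentile normalization to [0, 1]."""
    v = np.asarray(values, dtype=np.float32)
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(v)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def predict_mask(model: UNet3d, volume: VolumeGrid, normalize: bool = True):
    """Run the network on one (preprocessed) volume.

    Returns ``(BinaryMask, ProbabilityMap)``.  The mask is the foreground
    argmax; exact ties go to background.  An all-background outcome is not an
    error -- the caller checks ``mask.empty``.
    """
    values = volume.values
    if normalize:
        values = normalize_volume(values)
    logits = model.forward(values[None])
    probs = softmax_channels(logits)
    mask = BinaryMask(volume.geometry, probs[1] > probs[0])
    return mask, ProbabilityMap(volume.geometry, probs)


# ---------------------------------------------------------------------------
# Intensity-based segmentation (phantom path)
# ---------------------------------------------------------------------------

def segment_intensity(volume: VolumeGrid, threshold="auto") -> BinaryMask:
    """Threshold (Otsu for ``"auto"``), keep the largest 6-connected
    component, and fill internal holes.  Invariant to global positive
    intensity scaling when the threshold is automatic."""
    values = np.asarray(volume.values)
    if not np.all(np.isfinite(values)):
        raise ValueError("volume contains non-finite values")
    if values.max() <= 0:
        return BinaryMask(volume.geometry, np.zeros(volume.geometry.shape, bool))
    if threshold == "auto":
        thr = float(threshold_otsu(values))
    else:
        thr = float(threshold)
    binary = values > thr
    if not binary.any():
        return BinaryMask(volume.geometry, binary)
    labels, n = ndimage.label(binary, structure=_STRUCT_6)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = binary & (labels == int(counts.argmax()))
    filled = ndimage.binary_fill_holes(largest, structure=_STRUCT_6)
    return BinaryMask(volume.geometry, filled)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``beta1``/``beta2`` are the Adam defaults used by the deployed model; the
    learning rate, epoch count, batch size and augmentation settings are
    free parameters exposed here.  ``patch_edge`` enables random patch-based
    training (a standard 3D-segmentation strategy that keeps CPU training
    tractable); ``None`` trains on full volumes.
    """

    epochs: int = 4
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1
    seed: int = 0
    augment_flips: bool = False
    augment_noise_sigma: float = 0.0
    patch_edge: Optional[int] = 32
    lr_schedule: str = "constant"  # "constant" | "cosine"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


def _sample_patch(values, onehot, edge, rng):
    """Random cubic patch: half the draws are centered near the foreground
    (so the target is well represented), half uniformly anywhere (so distant
    structures -- notably the confounder -- supply negative supervision)."""
    shape = values.shape
    center = None
    if rng.random() < 0.5:
        fg = np.argwhere(onehot[1] > 0)
        if fg.size:
            center = fg.mean(axis=0) + rng.integers(-edge // 4, edge // 4 + 1, size=3)
    lo = []
    for a in range(3):
        if shape[a] <= edge:
            lo.append(0)
            continue
        if center is None:
            c = int(rng.integers(edge // 2, shape[a] - edge // 2 + 1))
        else:
            c = int(np.clip(center[a], edge // 2, shape[a] - edge // 2))
        lo.append(c - edge // 2)
    sl = tuple(slice(lo[a], lo[a] + min(edge, shape[a])) for a in range(3))
    return values[sl], onehot[(slice(None),) + sl]


def _augment(values, onehot, config: TrainConfig, rng):
    if config.augment_flips:
        for a in range(3):
            if rng.random() < 0.5:
                values = np.flip(values, axis=a)
                onehot = np.flip(onehot, axis=a + 1)
    if config.augment_noise_sigma > 0:
        values = values + rng.normal(0, config.augment_noise_sigma, values.shape)
    return np.ascontiguousarray(values), np.ascontiguousarray(onehot)


def train_localizer(
    train_set: Sequence,
    val_set: Sequence,
    config: TrainConfig = TrainConfig(),
    model: Optional[UNet3d] = None,
    spec: Optional[NetworkSpec] = None,
):
    """Train the localizer with Adam on the generalized Dice loss.

    ``train_set``/``val_set`` are sequences of ``(VolumeGrid, LabelMap)``.
    Deterministic for a fixed config seed.  Returns ``(model, history)``
    where history rows carry per-epoch mean training GDL and validation DSC.
    """
    from .evaluation import dice  # local import to avoid a cycle

    if not train_set:
        raise ValueError("empty training set")
    if spec is None:
        edge = train_set[0][0].geometry.shape[0]
        spec = NetworkSpec.small(input_edge=edge)
    if model is None:
        model = build_localizer_network(spec, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate,
               betas=(config.beta1, config.beta2))

    # pre-normalize once
    prepared = [
        (normalize_volume(vol.values), lab.onehot.astype(np.float32))
        for vol, lab in train_set
    ]
    history = []
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / config.epochs)
            )
        order = rng.permutation(len(prepared))
        losses = []
        opt.zero_grad()
        in_batch = 0
        for step, idx in enumerate(order):
            values, onehot = prepared[idx]
            if config.patch_edge and config.patch_edge < values.shape[0]:
                values, onehot = _sample_patch(values, onehot, config.patch_edge, rng)
            values, onehot = _augment(values, onehot, config, rng)
            logits = model.forward(values.astype(np.float32)[None])
            probs = softmax_channels(logits)
            loss, gprob = gdl_value_and_grad(probs, onehot)
            # chain through softmax: dL/dz = p * (g - sum_k g_k p_k)
            gz = probs * (gprob - (gprob * probs).sum(axis=0, keepdims=True))
            model.backward(gz.astype(np.float32))
            losses.append(loss)
            in_batch += 1
            if in_batch == config.batch_size or step == len(order) - 1:
                if in_batch > 1:
                    for p in opt.params:
                        p.grad /= in_batch
                opt.step()
                opt.zero_grad()
                in_batch = 0
        val_dscs = []
        for vol, lab in val_set:
            mask, _ = predict_mask(model, vol)
            truth = BinaryMask(lab.geometry, lab.onehot[1] > 0.5)
            val_dscs.append(dice(mask, truth))
        history.append(
            {
                "epoch": epoch,
                "train_gdl": float(np.mean(losses)),
                "val_dsc": float(np.mean(val_dscs)) if val_dscs else float("nan"),
            }
        )
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet3d, spec: NetworkSpec, path, seed: int = 0) -> None:
    """Single-file checkpoint: architecture spec + weights + seed provenance."""
    path = Path(path)
    meta = {
        "channels": list(spec.channels),
        "levels": spec.levels,
        "n_classes": spec.n_classes,
        "input_edge": spec.input_edge,
        "seed": seed,
    }
    arrays = {f"w{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(model, spec, seed)``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such checkpoint: {path}")
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    spec = NetworkSpec(
        channels=tuple(meta["channels"]),
        levels=meta["levels"],
        n_classes=meta["n_classes"],
        input_edge=meta["input_edge"],
    )
    model = build_localizer_network(spec, seed=meta["seed"])
    model.load_state_arrays(arrays)
    return model, spec, meta["seed"]
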