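"""Randomized synthetic training scenes for the localization network.

Each scene is a fetal-head-like ellipsoid with randomized size, position and
relaxation parameters, a fluid-bright confounder blob (the stomach failure
mode) and dim maternal background, acquired at TE 90 ms with additive
Gaussian noise.  Parameter ranges bracket mid-gestation head sizes at the
3 mm acquisition resolution; the confounder's signal is drawn to overlap the
head's, so the network must learn shape/size, not a threshold.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .grid import VolumeGrid
from .localizer import LabelMap
from .phantom import (
    AcquisitionConfig,
    SceneComponent,
    Trajectory,
    WorldScene,
    acquire_repetition,
    analytic_target_mask,
)


def held_out_dice_experiment(
    seed: int,
    n_train: int = 32,
    n_val: int = 8,
    edge: int = 64,
    epochs: int = 16,
    learning_rate: float = 3e-3,
) -> float:
    """Parameter-recovery experiment: train the reduced localizer on randomly
    generated head scenes and return the mean held-out Dice coefficient.

    Training uses 32-voxel patches with flip augmentation and a cosine
    learning-rate schedule; evaluation runs the trained network on full
    held-out volumes.
    """
    from .evaluation import dice
    from .grid import BinaryMask
    from .localizer import NetworkSpec, TrainConfig, predict_mask, train_localizer

    train = make_training_scenes(n_train, edge=edge, seed=seed)
    val = make_training_scenes(n_val, edge=edge, seed=seed + 1000)
    cfg = TrainConfig(
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
        patch_edge=32,
        augment_flips=True,
        lr_schedule="cosine",
    )
    model, _ = train_localizer(train, [], cfg, spec=NetworkSpec.small(edge))
    scores = [
        dice(predict_mask(model, vol)[0], BinaryMask(lab.geometry, lab.onehot[1] > 0.5))
        for vol, lab in val
    ]
    return float(np.mean(scores))


def random_fetal_scene(rng: np.random.Generator) -> WorldScene:
    """One randomized head + confounder + background scene."""
    head_radii = rng.uniform(20.0, 32.0, size=3)
    head_center = rng.uniform(-24.0, 24.0, size=3)
    head = SceneComponent(
        "ellipsoid",
        tuple(head_center),
        tuple(head_radii),
        s0=float(rng.uniform(90.0, 110.0)),
        t2star_ms=float(rng.uniform(50.0, 70.0)),
    )
    # stomach-like blob: smaller, fluid-bright (long T2*), placed well clear
    # of the head but inside the FOV
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    dist = rng.uniform(55.0, 80.0)
    conf_center = np.clip(head_center + direction * dist, -80.0, 80.0)
    confounder = SceneComponent(
        "sphere",
        tuple(conf_center),
        (float(rng.uniform(10.0, 18.0)),) * 3,
        s0=float(rng.uniform(40.0, 60.0)),
        t2star_ms=float(rng.uniform(100.0, 140.0)),
    )
    return WorldScene(
        (head, confounder),
        target_index=0,
        background_s0=float(rng.uniform(15.0, 25.0)),
        background_t2star_ms=float(rng.uniform(25.0, 35.0)),
    )


def make_training_scenes(
    n: int,
    edge: int = 64,
    spacing: float = 3.0,
    te_ms: float = 90.0,
    noise_sigma: float = 1.0,
    seed: int = 0,
) -> List[Tuple[VolumeGrid, LabelMap]]:
    """Generate ``n`` (volume, label-map) pairs on an ``edge**3`` grid."""
    rng = np.random.default_rng(seed)
    out = []
    static = Trajectory(np.zeros((1, 3)))
    for i in range(n):
        scene = random_fetal_scene(rng)
        acq = AcquisitionConfig(
            shape=(edge,) * 3,
            spacing=spacing,
            te_list_ms=(te_ms,),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fov = acq.geometry()
        vol = acquire_repetition(scene, static, fov, 0, te_ms, acq)
        mask = analytic_target_mask(scene, static, fov, 0)
        out.append((vol, LabelMap.from_mask(mask)))
    return out
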