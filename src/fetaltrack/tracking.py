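"""Closed-loop prospective FOV control.

Each repetition is acquired at the controller's current FOV, localized, and
reduced to a world-frame center of mass (CoM).  The reported motion signal is
the CoM displacement between time points ``n`` and ``n-2`` (the feedback path
has a two-repetition latency: a step first visible in the image at repetition
``r`` changes the FOV of the image acquired at repetition ``r + 2``).

The shift actually queued is the pending-aware recentering correction
``com(n) - fov_center(n) - (queued, not-yet-applied shifts)``: feeding the raw
n/n-2 displacement back at every repetition would double-correct, since a
step stays visible in the displacement signal for two frames.  Both
quantities are recorded per repetition.

Safety gates: corrections from masks whose volume falls outside configurable
bounds are suppressed and flagged (mis-segmentation protection); per-axis
shifts are clipped to ``max_shift_mm``; an empty mask holds the current FOV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from typing import Callable, List, Optional, Sequence

import numpy as np

from .grid import BinaryMask, GridGeometry, VolumeGrid, WorldPoint, voxel_to_world
from .localizer import predict_mask, segment_intensity
from .phantom import AcquisitionConfig, Trajectory, WorldScene, acquire_repetition


@dataclasses.dataclass(frozen=True)
class Displacement:
    """World-frame CoM displacement between two repetitions (mm)."""

    d: tuple
    from_repetition: int
    to_repetition: int

    def __post_init__(self):
        object.__setattr__(self, "d", tuple(float(v) for v in self.d))


@dataclasses.dataclass
class FOVState:
    """Per-repetition FOV centers plus the queue of pending shifts."""

    centers: List[np.ndarray] = dataclasses.field(default_factory=list)
    pending: List[tuple] = dataclasses.field(default_factory=list)  # (apply_at, shift)

    def pending_sum(self) -> np.ndarray:
        if not self.pending:
            return np.zeros(3)
        return np.sum([s for _, s in self.pending], axis=0)

    def next_center(self, repetition: int, previous: np.ndarray) -> np.ndarray:
        """Center for ``repetition``: previous center plus all shifts due."""
        due = [s for at, s in self.pending if at <= repetition]
        self.pending = [(at, s) for at, s in self.pending if at > repetition]
        center = np.asarray(previous, dtype=float)
        if due:
            center = center + np.sum(due, axis=0)
        return center


@dataclasses.dataclass
class RepetitionRecord:
    """Audit-trail entry for one repetition."""

    repetition: int
    fov_center: tuple
    com_world: Optional[tuple]
    mask_voxels: int
    displacement: Optional[Displacement]
    shift_applied: tuple = (0.0, 0.0, 0.0)
    empty_flag: bool = False
    implausible_flag: bool = False

    def __post_init__(self):
        if (self.com_world is None) != self.empty_flag:
            raise ValueError("com_world must be absent exactly when empty_flag is set")


@dataclasses.dataclass(frozen=True)
class LoopConfig:
    """Controller configuration.

    ``latency_repetitions`` is the feedback delay (2 in the deployed system);
    ``min_volume_ml``/``max_volume_ml`` bound plausible mask volumes (None
    disables the gate); ``max_shift_mm`` clips each correction per axis
    (None: half the FOV extent).
    """

    latency_repetitions: int = 2
    localizer: str = "intensity"
    min_volume_ml: Optional[float] = None
    max_volume_ml: Optional[float] = None
    max_shift_mm: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.latency_repetitions < 1:
            raise ValueError("latency_repetitions must be >= 1")


def center_of_mass(mask: BinaryMask) -> Optional[WorldPoint]:
    """Unweighted world-frame mean of the foreground voxel indices; ``None``
    for an empty mask (the loop treats that as a missing sample, never as an
    error)."""
    if mask.empty:
        return None
    idx = np.argwhere(mask.values).mean(axis=0)
    return voxel_to_world(idx, mask.geometry)


def estimate_displacement(
    records: Sequence[RepetitionRecord], n: int, lag: int = 2
) -> Optional[Displacement]:
    """CoM displacement between repetitions ``n`` and ``n - lag`` in the world
    frame (each CoM under its own repetition's FOV geometry); ``None`` during
    warm-up or when either CoM is missing."""
    if n < lag:
        return None
    a, b = records[n - lag], records[n]
    if a.com_world is None or b.com_world is None:
        return None
    d = np.asarray(b.com_world) - np.asarray(a.com_world)
    return Displacement(tuple(d), from_repetition=n - lag, to_repetition=n)


def compute_correction(
    records: Sequence[RepetitionRecord],
    fov_state: FOVState,
    n: int,
    max_shift_mm: Optional[float] = None,
) -> np.ndarray:
    """Pending-aware recentering correction at repetition ``n``.

    ``(com(n) - fov_center(n)) - sum(pending shifts)``, clipped per axis.
    Subtracting the queued-but-unapplied shifts prevents the same motion from
    being corrected twice while the loop waits out its latency.
    """
    rec = records[n]
    if rec.com_world is None:
        return np.zeros(3)
    corr = (
        np.asarray(rec.com_world)
        - np.asarray(rec.fov_center)
        - fov_state.pending_sum()
    )
    if max_shift_mm is not None:
        corr = np.clip(corr, -max_shift_mm, max_shift_mm)
    return corr


def apply_fov_update(
    fov_state: FOVState, correction: np.ndarray, computed_at: int, latency: int = 2
) -> FOVState:
    """Queue a correction computed from repetition ``computed_at`` to take
    effect at repetition ``computed_at + latency``."""
    correction = np.asarray(correction, dtype=float)
    if not np.all(np.isfinite(correction)):
        raise ValueError("correction must be finite")
    if np.any(correction != 0.0):
        fov_state.pending.append((computed_at + latency, correction))
    return fov_state


class IntensityLocalizer:
    """Otsu + largest-component segmentation (phantom path)."""

    def __call__(self, volume: VolumeGrid) -> BinaryMask:
        return segment_intensity(volume)


class NetworkLocalizer:
    """U-Net segmentation (fetal path)."""

    def __init__(self, model, normalize: bool = True):
        self.model = model
        self.normalize = normalize

    def __call__(self, volume: VolumeGrid) -> BinaryMask:
        mask, _ = predict_mask(self.model, volume, normalize=self.normalize)
        return mask


def run_closed_loop(
    scene: WorldScene,
    trajectory: Trajectory,
    acq: AcquisitionConfig,
    loop: LoopConfig = LoopConfig(),
    localizer: Optional[Callable[[VolumeGrid], BinaryMask]] = None,
    initial_center=(0.0, 0.0, 0.0),
    collect_volumes: Optional[list] = None,
) -> List[RepetitionRecord]:
    """Simulate the full acquire -> localize -> CoM -> feedback loop.

    A localizer failure (exception or empty mask) flags the repetition and
    holds the current FOV; the loop always completes all repetitions.  Pass a
    list as ``collect_volumes`` to also receive the acquired series.
    """
    if localizer is None:
        localizer = IntensityLocalizer()
    max_shift = loop.max_shift_mm
    if max_shift is None:
        max_shift = float(np.max(acq.geometry().fov_extent_mm) / 2.0)
    te = acq.te_list_ms[0]
    state = FOVState()
    records: List[RepetitionRecord] = []
    center = np.asarray(initial_center, dtype=float)
    for n in range(trajectory.n_repetitions):
        prev = center
        center = state.next_center(n, center)
        shift_applied = tuple(center - prev)
        fov = acq.geometry(tuple(center))
        volume = acquire_repetition(scene, trajectory, fov, n, te, acq)
        if collect_volumes is not None:
            collect_volumes.append(volume)
        try:
            mask = localizer(volume)
        except Exception:
            mask = BinaryMask(fov, np.zeros(fov.shape, bool))
        com = center_of_mass(mask)
        implausible = False
        if com is not None:
            vol_ml = mask.volume_ml
            if loop.min_volume_ml is not None and vol_ml < loop.min_volume_ml:
                implausible = True
            if loop.max_volume_ml is not None and vol_ml > loop.max_volume_ml:
                implausible = True
        rec = RepetitionRecord(
            repetition=n,
            fov_center=tuple(center),
            com_world=None if com is None else tuple(com),
            mask_voxels=mask.voxel_count,
            displacement=None,
            shift_applied=shift_applied,
            empty_flag=com is None,
            implausible_flag=implausible,
        )
        records.append(rec)
        rec.displacement = estimate_displacement(records, n, lag=2)
        if com is not None and not implausible:
            corr = compute_correction(records, state, n, max_shift)
            apply_fov_update(state, corr, n, loop.latency_repetitions)
    return records


# ---------------------------------------------------------------------------
# Audit-trail output
# ---------------------------------------------------------------------------

def _record_row(rec: RepetitionRecord) -> dict:
    d = rec.displacement.d if rec.displacement is not None else (None,) * 3
    com = rec.com_world if rec.com_world is not None else (None,) * 3
    return {
        "repetition": rec.repetition,
        "fov_x_mm": rec.fov_center[0], "fov_y_mm": rec.fov_center[1],
        "fov_z_mm": rec.fov_center[2],
        "com_x_mm": com[0], "com_y_mm": com[1], "com_z_mm": com[2],
        "mask_voxels": rec.mask_voxels,
        "disp_x_mm": d[0], "disp_y_mm": d[1], "disp_z_mm": d[2],
        "shift_x_mm": rec.shift_applied[0], "shift_y_mm": rec.shift_applied[1],
        "shift_z_mm": rec.shift_applied[2],
        "empty_flag": rec.empty_flag,
        "implausible_flag": rec.implausible_flag,
    }


def write_audit_csv(records: Sequence[RepetitionRecord], path) -> None:
    rows = [_record_row(r) for r in records]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def write_audit_json(records: Sequence[RepetitionRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([_record_row(r) for r in records], fh, indent=1)
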