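"""Synthetic scenes and EPI-like acquisition simulation.

This module stands in for the scanner: analytic phantoms (sphere phantom,
fetal-head-like ellipsoid scene with a confounding fluid blob), piecewise
constant translational motion, a mono-exponential T2* signal model, and
per-repetition image formation at the controller's current field of view.

Image formation is purely geometric rasterization plus ``S0*exp(-TE/T2*)``
decay and optional additive Gaussian noise; k-space effects (distortion,
ghosting) are not modelled, and motion is instantaneous between repetitions
(single-shot readouts freeze intra-volume motion).
"""

from __future__ import annotations

import csv
import dataclasses
from typing import Optional, Sequence

import numpy as np

from .grid import BinaryMask, GridGeometry, VolumeGrid, WorldPoint

_KINDS = ("sphere", "ellipsoid", "box")


def signal_te(s0: float, t2star_ms: float, te_ms: float) -> float:
    """Mono-exponential gradient-echo signal ``s0 * exp(-TE / T2*)``."""
    if np.any(np.asarray(t2star_ms) <= 0):
        raise ValueError("t2star_ms must be > 0")
    if np.any(np.asarray(s0) < 0) or np.any(np.asarray(te_ms) < 0):
        raise ValueError("s0 and te_ms must be >= 0")
    return s0 * float(np.exp(-te_ms / t2star_ms))


@dataclasses.dataclass(frozen=True)
class SceneComponent:
    """A homogeneous geometric object with its own S0 and T2* (ms)."""

    kind: str
    center: tuple
    radii: tuple
    s0: float
    t2star_ms: float

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        r = tuple(float(v) for v in np.atleast_1d(np.asarray(self.radii, dtype=float)))
        if len(r) == 1:
            r = r * 3
        object.__setattr__(self, "radii", r)
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be 3-vectors")
        if any(v <= 0 for v in self.radii):
            raise ValueError("radii must be > 0")
        if self.s0 <= 0 or self.t2star_ms <= 0:
            raise ValueError("s0 and t2star_ms must be > 0")

    def contains(self, points: np.ndarray, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Membership of world points (...,3) in this component displaced by
        ``offset``."""
        rel = np.asarray(points, dtype=float) - (
            np.asarray(self.center) + np.asarray(offset, dtype=float)
        )
        if self.kind == "box":
            return np.all(np.abs(rel) <= np.asarray(self.radii), axis=-1)
        return np.sum((rel / np.asarray(self.radii)) ** 2, axis=-1) <= 1.0


@dataclasses.dataclass(frozen=True)
class WorldScene:
    """An analytic scene: ordered components (later ones overwrite earlier
    where they overlap), the index of the tracked target, and a background
    signal level.  The background, like tissue, decays with TE when a
    background T2* is given; otherwise it is TE-independent."""

    components: tuple
    target_index: int = 0
    background_s0: float = 0.0
    background_t2star_ms: Optional[float] = None

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise ValueError("scene needs at least one component")
        object.__setattr__(self, "components", comps)
        if not (0 <= self.target_index < len(comps)):
            raise ValueError("target_index out of range")
        if self.background_s0 < 0:
            raise ValueError("background_s0 must be >= 0")

    @property
    def target(self) -> SceneComponent:
        return self.components[self.target_index]

    def background_signal(self, te_ms: float) -> float:
        if self.background_s0 == 0.0:
            return 0.0
        if self.background_t2star_ms is None:
            return self.background_s0
        return signal_te(self.background_s0, self.background_t2star_ms, te_ms)


def make_sphere_world(
    radius_mm: float = 40.0, s0: float = 100.0, t2star_ms: float = 60.0
) -> WorldScene:
    """Agarose-sphere-like phantom: one sphere at the world origin.

    Defaults give a bright, homogeneous object against zero (air) background,
    the configuration used for controlled-motion tracking runs.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    comp = SceneComponent("sphere", (0.0, 0.0, 0.0), (radius_mm,) * 3, s0, t2star_ms)
    return WorldScene((comp,), target_index=0, background_s0=0.0)


def make_fetal_world(
    head_radii_mm: Sequence[float] = (30.0, 25.0, 25.0),
    head_center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    confounder: Optional[SceneComponent] = "default",
    background_s0: float = 20.0,
    background_t2star_ms: float = 30.0,
    head_s0: float = 100.0,
    head_t2star_ms: float = 60.0,
) -> WorldScene:
    """Fetal-head-like scene: ellipsoidal "brain" target inside dim maternal
    background, plus (by default) a fluid-filled confounder blob emulating the
    stomach, whose signal at long TE matches the brain's.

    At TE = 90 ms the defaults give brain ~= 22, confounder ~= 24,
    background ~= 1 (arbitrary units), so intensity alone cannot separate
    brain from confounder -- the failure mode the localizer must handle.
    """
    if confounder == "default":
        confounder = SceneComponent(
            "sphere", (60.0, -45.0, 10.0), (15.0,) * 3, s0=50.0, t2star_ms=120.0
        )
    head = SceneComponent(
        "ellipsoid",
        tuple(head_center_mm),
        tuple(head_radii_mm),
        s0=head_s0,
        t2star_ms=head_t2star_ms,
    )
    comps = (head,) if confounder is None else (head, confounder)
    return WorldScene(
        comps,
        target_index=0,
        background_s0=background_s0,
        background_t2star_ms=background_t2star_ms,
    )


@dataclasses.dataclass(frozen=True)
class MotionEvent:
    """A step translation of the target, first visible in the image acquired
    at ``first_visible_repetition`` (0-based)."""

    first_visible_repetition: int
    delta: tuple

    def __post_init__(self):
        if self.first_visible_repetition < 0:
            raise ValueError("first_visible_repetition must be >= 0")
        object.__setattr__(self, "delta", tuple(float(d) for d in self.delta))
        if len(self.delta) != 3:
            raise ValueError("delta must be a 3-vector (mm)")


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Per-repetition world offset of the target (piecewise constant)."""

    offsets_mm: np.ndarray  # (n_repetitions, 3)

    def __post_init__(self):
        arr = np.atleast_2d(np.asarray(self.offsets_mm, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValueError("offsets_mm must have shape (n_repetitions, 3)")
        object.__setattr__(self, "offsets_mm", arr)

    @property
    def n_repetitions(self) -> int:
        return self.offsets_mm.shape[0]

    def offset(self, repetition: int) -> np.ndarray:
        if not (0 <= repetition < self.n_repetitions):
            raise ValueError(
                f"repetition {repetition} out of range [0, {self.n_repetitions})"
            )
        return self.offsets_mm[repetition]


def step_trajectory(events: Sequence[MotionEvent], n_repetitions: int) -> Trajectory:
    """Cumulative piecewise-constant trajectory: the offset at repetition r is
    the sum of deltas of all events with ``first_visible_repetition <= r``."""
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    offsets = np.zeros((n_repetitions, 3))
    for ev in events:
        if ev.first_visible_repetition >= n_repetitions:
            raise ValueError(
                f"event at repetition {ev.first_visible_repetition} outside a "
                f"{n_repetitions}-repetition series"
            )
        offsets[ev.first_visible_repetition :] += np.asarray(ev.delta)
    return Trajectory(offsets)


@dataclasses.dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition template: grid shape/spacing, echo times, noise, seed.

    Defaults mirror the controlled phantom protocol (isotropic 3.0 mm voxels,
    TE = 90 ms) on a desk-scale 64^3 grid.
    """

    shape: tuple = (64, 64, 64)
    spacing: float = 3.0
    te_list_ms: tuple = (90.0,)
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "te_list_ms", tuple(float(t) for t in self.te_list_ms))
        if not self.te_list_ms or any(t <= 0 for t in self.te_list_ms):
            raise ValueError("te_list_ms must be non-empty positive echo times")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def geometry(self, fov_center=(0.0, 0.0, 0.0)) -> GridGeometry:
        return GridGeometry(self.shape, self.spacing, fov_center)


def _world_coordinate_grid(fov: GridGeometry) -> np.ndarray:
    axes = [
        fov.fov_center[a]
        + fov.spacing[a] * (np.arange(fov.shape[a], dtype=float) - fov.midpoint_index[a])
        for a in range(3)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=-1)  # (X, Y, Z, 3)


def _scene_values(
    scene: WorldScene, target_offset: np.ndarray, fov: GridGeometry, te_ms: float
) -> np.ndarray:
    pts = _world_coordinate_grid(fov)
    out = np.full(fov.shape, scene.background_signal(te_ms), dtype=np.float32)
    for i, comp in enumerate(scene.components):
        off = target_offset if i == scene.target_index else (0.0, 0.0, 0.0)
        inside = comp.contains(pts, off)
        out[inside] = signal_te(comp.s0, comp.t2star_ms, te_ms)
    return out


def acquire_repetition(
    scene: WorldScene,
    trajectory: Trajectory,
    fov: GridGeometry,
    repetition: int,
    te_ms: float,
    config: AcquisitionConfig,
) -> VolumeGrid:
    """Rasterize the (displaced) scene at the current FOV and echo time.

    Deterministic for fixed ``(config.seed, repetition, te_ms)``: the noise
    stream is derived from the base seed plus the repetition index, with the
    echo time folded in so multi-echo frames get independent noise.
    """
    offset = trajectory.offset(repetition)  # validates the repetition index
    values = _scene_values(scene, offset, fov, te_ms)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(
            [(config.seed + repetition) % 2**31, int(round(te_ms * 1000))]
        )
        values = values + rng.normal(
            0.0, config.noise_sigma, size=values.shape
        ).astype(np.float32)
        np.clip(values, 0.0, None, out=values)  # magnitude images are >= 0
    return VolumeGrid(fov, values, repetition_index=repetition, te_ms=te_ms)


def analytic_target_mask(
    scene: WorldScene, trajectory: Trajectory, fov: GridGeometry, repetition: int
) -> BinaryMask:
    """Ground-truth mask: voxel centers inside the displaced target."""
    offset = trajectory.offset(repetition)
    pts = _world_coordinate_grid(fov)
    return BinaryMask(fov, scene.target.contains(pts, offset))


def analytic_target_com(
    scene: WorldScene, trajectory: Trajectory, repetition: int
) -> WorldPoint:
    """Analytic world CoM of the (symmetric) target at a repetition."""
    c = np.asarray(scene.target.center) + trajectory.offset(repetition)
    return WorldPoint.from_array(c)


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["repetition", "dx_mm", "dy_mm", "dz_mm"])
        for r in range(trajectory.n_repetitions):
            writer.writerow([r] + [f"{v:.6g}" for v in trajectory.offsets_mm[r]])


# ---------------------------------------------------------------------------
# Config-file construction (used by the CLI)
# ---------------------------------------------------------------------------

def scene_from_dict(cfg: dict) -> WorldScene:
    """Build a scene from a plain dict (parsed YAML/JSON).

    Recognized forms: ``{"preset": "sphere", ...}``, ``{"preset": "fetal",
    ...}`` or an explicit ``{"components": [...], "target_index": ...}``.
    """
    preset = cfg.get("preset")
    if preset == "sphere":
        keys = {k: cfg[k] for k in ("radius_mm", "s0", "t2star_ms") if k in cfg}
        return make_sphere_world(**keys)
    if preset == "fetal":
        keys = {
            k: cfg[k]
            for k in (
                "head_radii_mm",
                "head_center_mm",
                "background_s0",
                "background_t2star_ms",
                "head_s0",
                "head_t2star_ms",
            )
            if k in cfg
        }
        if cfg.get("confounder") is False:
            keys["confounder"] = None
        return make_fetal_world(**keys)
    if "components" not in cfg:
        raise ValueError("scene config needs 'preset' or 'components'")
    comps = tuple(
        SceneComponent(
            c["kind"], tuple(c["center"]), tuple(np.atleast_1d(c["radii"])),
            float(c["s0"]), float(c["t2star_ms"])
        )
        for c in cfg["components"]
    )
    return WorldScene(
        comps,
        target_index=int(cfg.get("target_index", 0)),
        background_s0=float(cfg.get("background_s0", 0.0)),
        background_t2star_ms=cfg.get("background_t2star_ms"),
    )


def trajectory_from_dict(cfg: dict) -> Trajectory:
    """Build a trajectory from ``{"n_repetitions": N, "events": [...]}``."""
    events = [
        MotionEvent(int(e["first_visible_repetition"]), tuple(e["delta"]))
        for e in cfg.get("events", [])
    ]
    return step_trajectory(events, int(cfg["n_repetitions"]))
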