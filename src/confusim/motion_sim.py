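"""Bounded-arena random-walk motion for tracking stimuli.

Each object moves at constant retinal speed.  On every frame its heading is
redrawn from a wrapped normal centred on the previous heading ("circular
Gaussian"): draw a normal increment with standard deviation sigma, add,
wrap to [0, 2pi).  At the sigma levels used here (<= pi/8) the wrapped
normal and the von Mises of matched dispersion are practically
indistinguishable, and the wrapped normal is parameterised directly by the
SD the design manipulates.

Positions are continuous (sub-pixel); at the default speed of 6.67 deg/s,
2 minarc/px and 100 Hz the per-frame step is 2.001 px, so integer positions
would alias the speed.  The whole object is kept inside the arena: the
admissible region for object *centres* is the arena inset by half the
object side.  A step that would leave the region is resolved by specular
reflection of the heading off the violated wall with the position clamped
inside (a "resample" alternative redraws the heading increment until the
step is legal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units_design import ArenaSpec, MINARC_PER_DEG

TWO_PI = 2.0 * np.pi
DEFAULT_OBJECT_SIDE_PX = 32


@dataclass(frozen=True)
class MotionParams:
    """Kinematic and timing parameters of one trial.

    speed is in degrees of visual angle per second; sigma is the SD (rad)
    of the per-frame heading increment; durations are in ms (1000 ms
    highlighted target + 4000 ms tracking by default).
    """

    speed: float = 6.67
    sigma: float = np.pi / 2**4
    frame_rate: float = 100.0
    highlight_duration: float = 1000.0
    track_duration: float = 4000.0
    object_side_px: int = DEFAULT_OBJECT_SIDE_PX
    boundary: str = "reflect"  # or "resample"

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.highlight_duration <= 0 or self.track_duration <= 0:
            raise ValueError("durations must be positive")
        if self.boundary not in ("reflect", "resample"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")

    @property
    def n_frames(self) -> int:
        return int(round((self.highlight_duration + self.track_duration) * self.frame_rate / 1000.0))

    @property
    def n_highlight_frames(self) -> int:
        return int(round(self.highlight_duration * self.frame_rate / 1000.0))

    def step_px(self, pixel_pitch: float) -> float:
        """Per-frame displacement in pixels: speed converted through the pitch."""
        return self.speed * MINARC_PER_DEG / pixel_pitch / self.frame_rate


@dataclass
class TrajectorySet:
    """Per-frame positions and headings of all objects in one trial.

    positions has shape (n_frames, n_objects, 2) in continuous pixels
    (object centres, x then y); headings has shape (n_frames, n_objects)
    in radians wrapped to [0, 2pi).
    """

    positions: np.ndarray
    headings: np.ndarray
    target_index: int
    arena: ArenaSpec
    object_side_px: int = DEFAULT_OBJECT_SIDE_PX
    n_highlight_frames: int = 100
    rng_seed: int | None = None
    params: MotionParams | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_objects(self) -> int:
        return self.positions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, object_id, x, y, heading, is_target."""
        f, n = self.n_frames, self.n_objects
        frame_idx = np.repeat(np.arange(f), n)
        obj_idx = np.tile(np.arange(n), f)
        return pd.DataFrame(
            {
                "frame": frame_idx,
                "object_id": obj_idx,
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "heading": self.headings.ravel(),
                "is_target": (obj_idx == self.target_index).astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def admissible_bounds(arena: ArenaSpec, object_side_px: int = DEFAULT_OBJECT_SIDE_PX):
    """(lo_x, hi_x, lo_y, hi_y) bounds for object centres (object fully inside)."""
    half = object_side_px / 2.0
    lo_x, hi_x = half, arena.width_px - half
    lo_y, hi_y = half, arena.height_px - half
    if lo_x > hi_x or lo_y > hi_y:
        raise ValueError("object does not fit inside the arena")
    return lo_x, hi_x, lo_y, hi_y


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def init_positions(
    n: int,
    arena: ArenaSpec,
    object_side_px: int = DEFAULT_OBJECT_SIDE_PX,
    rng_seed=None,
) -> np.ndarray:
    """Uniform random centres over the admissible region; overlap allowed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    lo_x, hi_x, lo_y, hi_y = admissible_bounds(arena, object_side_px)
    rng = _as_rng(rng_seed)
    xy = np.empty((n, 2), dtype=float)
    xy[:, 0] = rng.uniform(lo_x, hi_x, size=n)
    xy[:, 1] = rng.uniform(lo_y, hi_y, size=n)
    return xy


def wrap_angle(theta):
    """Wrap angles to [0, 2pi)."""
    return np.mod(theta, TWO_PI)


def step_heading(theta, sigma: float, rng) -> np.ndarray | float:
    """New heading: wrapped-normal step centred on the previous heading."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _as_rng(rng)
    theta = np.asarray(theta, dtype=float)
    eps = rng.normal(0.0, sigma, size=theta.shape)
    out = wrap_angle(theta + eps)
    return float(out) if out.ndim == 0 else out


def _advance_arrays(pos, head, arena, params, rng, pitch=None):
    """One motion step for all objects; returns (new_pos, new_head, reflected_mask)."""
    rng = _as_rng(rng)
    pitch = arena.pixel_pitch if pitch is None else pitch
    step = params.step_px(pitch)
    lo_x, hi_x, lo_y, hi_y = admissible_bounds(arena, params.object_side_px)

    new_head = step_heading(head, params.sigma, rng)
    cand = pos + step * np.stack([np.cos(new_head), np.sin(new_head)], axis=-1)
    out_x = (cand[:, 0] < lo_x) | (cand[:, 0] > hi_x)
    out_y = (cand[:, 1] < lo_y) | (cand[:, 1] > hi_y)
    violated = out_x | out_y

    if params.boundary == "resample" and np.any(violated):
        idx = np.flatnonzero(violated)
        for _ in range(100):
            new_head[idx] = step_heading(head[idx], params.sigma, rng)
            cand[idx] = pos[idx] + step * np.stack(
                [np.cos(new_head[idx]), np.sin(new_head[idx])], axis=-1
            )
            bad = (
                (cand[idx, 0] < lo_x)
                | (cand[idx, 0] > hi_x)
                | (cand[idx, 1] < lo_y)
                | (cand[idx, 1] > hi_y)
            )
            idx = idx[bad]
            if idx.size == 0:
                break
        out_x = (cand[:, 0] < lo_x) | (cand[:, 0] > hi_x)
        out_y = (cand[:, 1] < lo_y) | (cand[:, 1] > hi_y)
        violated = out_x | out_y
        # whatever still violates after resampling falls through to reflection

    if np.any(violated):
        # specular reflection: vertical wall flips the x-component
        # (theta -> pi - theta), horizontal wall flips the y-component
        # (theta -> -theta); a corner hit composes both (theta + pi)
        new_head = np.where(out_x, np.pi - new_head, new_head)
        new_head = np.where(out_y, -new_head, new_head)
        new_head = wrap_angle(new_head)
        cand[:, 0] = np.clip(cand[:, 0], lo_x, hi_x)
        cand[:, 1] = np.clip(cand[:, 1], lo_y, hi_y)
    return cand, new_head, violated


def advance(traj: TrajectorySet, t: int, params: MotionParams, rng) -> None:
    """Fill frame t+1 of ``traj`` from frame t."""
    if not 0 <= t < traj.n_frames - 1:
        raise IndexError("frame out of range")
    pos, head, _ = _advance_arrays(
        traj.positions[t], traj.headings[t], traj.arena, params, rng
    )
    traj.positions[t + 1] = pos
    traj.headings[t + 1] = head


def simulate_trial_motion(
    n_items: int,
    arena: ArenaSpec,
    params: MotionParams | None = None,
    rng_seed=None,
    init_xy: np.ndarray | None = None,
    init_headings: np.ndarray | None = None,
    target_index: int | None = None,
) -> TrajectorySet:
    """Simulate one full trial of object motion.

    The target is drawn uniformly among the objects unless given.  Initial
    positions are uniform over the admissible region and initial headings
    uniform over [0, 2pi) unless supplied.  Fully reproducible from
    ``rng_seed``.
    """
    if params is None:
        params = MotionParams()
    rng = _as_rng(rng_seed)
    n_frames = params.n_frames

    positions = np.empty((n_frames, n_items, 2), dtype=float)
    headings = np.empty((n_frames, n_items), dtype=float)
    if target_index is None:
        target_index = int(rng.integers(n_items)) if n_items else 0
    positions[0] = (
        init_positions(n_items, arena, params.object_side_px, rng)
        if init_xy is None
        else np.asarray(init_xy, dtype=float)
    )
    headings[0] = (
        rng.uniform(0.0, TWO_PI, size=n_items)
        if init_headings is None
        else wrap_angle(np.asarray(init_headings, dtype=float))
    )
    traj = TrajectorySet(
        positions=positions,
        headings=headings,
        target_index=target_index,
        arena=arena,
        object_side_px=params.object_side_px,
        n_highlight_frames=params.n_highlight_frames,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
        params=params,
    )
    for t in range(n_frames - 1):
        advance(traj, t, params, rng)
    return traj
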