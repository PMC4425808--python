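"""Rendering trials as image sequences.

Objects and background share the same trinary noise statistics — each pixel
takes one of three luminances (32.75, 65.5 or 98.25 cd/m^2) with equal
probability — so a stationary, unbordered object is perfectly background
matching: only motion (and the borders at trial start and end) reveals it.

Textures are frozen per trial: the background and each object's 32x32
patch are drawn once at trial start (a per-frame background refresh is
available behind ``dynamic_background``).  Objects are blitted at
nearest-integer centre positions with no anti-aliasing, so every rendered
pixel stays exactly on the three-level value set; borders are drawn as
rings *outside* the object footprint, which keeps the target's own 32x32
texture fully visible on every frame (the target is always drawn last,
in front of all distractors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .motion_sim import TrajectorySet, _as_rng

#: border luminances (cd/m^2); white clips to the top of the 8-bit export
BLACK = 0.0
WHITE = 131.0

HIGHLIGHT_BORDER_PX = 2  # black/white double border around the target
END_BORDER_PX = 1        # black border around every object at trial end


@dataclass(frozen=True)
class NoiseModel:
    """Three-point luminance distribution of the trinary noise."""

    levels: tuple = (32.75, 65.5, 98.25)
    probabilities: tuple = (1.0 / 3, 1.0 / 3, 1.0 / 3)

    def __post_init__(self) -> None:
        if len(self.levels) != 3 or len(self.probabilities) != 3:
            raise ValueError("trinary noise needs exactly three levels")
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def mean_luminance(self) -> float:
        return float(np.dot(self.levels, self.probabilities))


@dataclass
class FrameImage:
    """One rendered frame: a luminance raster (cd/m^2) plus 8-bit export."""

    luminance: np.ndarray  # (height, width)

    @property
    def shape(self):
        return self.luminance.shape

    def to_uint8(self) -> np.ndarray:
        """Linear 8-bit mapping: 32.75/65.5/98.25 cd/m^2 -> 64/128/192."""
        return np.clip(np.rint(self.luminance * 128.0 / 65.5), 0, 255).astype(np.uint8)


def trinary_texture(shape, noise: NoiseModel | None = None, rng_seed=None) -> np.ndarray:
    """i.i.d. draws from the three-point luminance distribution."""
    if noise is None:
        noise = NoiseModel()
    shape = tuple(int(s) for s in (shape if np.iterable(shape) else (shape, shape)))
    if any(s <= 0 for s in shape):
        raise ValueError("texture dimensions must be positive")
    rng = _as_rng(rng_seed)
    return rng.choice(np.asarray(noise.levels, dtype=float), size=shape, p=noise.probabilities)


@dataclass
class TrialScene:
    """Frozen per-trial textures and draw order for rendering one trial."""

    traj: TrajectorySet
    noise: NoiseModel
    background: np.ndarray            # (H, W)
    object_textures: np.ndarray       # (n_objects, side, side)
    draw_order: np.ndarray            # distractors in seed-stable order, target last
    dynamic_background: bool = False
    rng_seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.traj.n_frames


def make_scene(
    traj: TrajectorySet,
    noise: NoiseModel | None = None,
    rng_seed=None,
    dynamic_background: bool = False,
) -> TrialScene:
    """Draw the frozen background and per-object textures for a trial."""
    if noise is None:
        noise = NoiseModel()
    rng = _as_rng(rng_seed)
    side = traj.object_side_px
    background = trinary_texture((traj.arena.height_px, traj.arena.width_px), noise, rng)
    textures = trinary_texture((traj.n_objects, side, side), noise, rng) if traj.n_objects else (
        np.empty((0, side, side))
    )
    distractors = np.setdiff1d(np.arange(traj.n_objects), [traj.target_index])
    order = np.concatenate([rng.permutation(distractors), [traj.target_index]]).astype(int)
    return TrialScene(
        traj=traj,
        noise=noise,
        background=background,
        object_textures=np.asarray(textures),
        draw_order=order,
        dynamic_background=dynamic_background,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
    )


def phase_of(traj: TrajectorySet, t: int) -> str:
    """Trial phase at frame t: highlight, track or end."""
    if t == traj.n_frames - 1:
        return "end"
    return "highlight" if t < traj.n_highlight_frames else "track"


def _blit(img: np.ndarray, tex: np.ndarray, cx: int, cy: int) -> None:
    side = tex.shape[0]
    half = side // 2
    x0, y0 = cx - half, cy - half
    h, w = img.shape
    sx0, sy0 = max(0, -x0), max(0, -y0)
    sx1 = side - max(0, x0 + side - w)
    sy1 = side - max(0, y0 + side - h)
    if sx1 <= sx0 or sy1 <= sy0:
        return
    img[y0 + sy0 : y0 + sy1, x0 + sx0 : x0 + sx1] = tex[sy0:sy1, sx0:sx1]


def _draw_ring(img: np.ndarray, cx: int, cy: int, inner_half: int, width: int, value: float) -> None:
    """Square ring of ``width`` px immediately outside a (2*inner_half)^2 footprint."""
    h, w = img.shape
    o = inner_half + width
    y0, y1 = max(0, cy - o), min(h, cy + o)
    x0, x1 = max(0, cx - o), min(w, cx + o)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # footprint covers [c-inner_half, c+inner_half) per axis, centre c-0.5;
    # the ring is the Chebyshev shell just outside it
    cheb = np.maximum(np.abs(xx - (cx - 0.5)), np.abs(yy - (cy - 0.5)))
    mask = (cheb > inner_half - 0.25) & (cheb < inner_half + width - 0.25)
    img[y0:y1, x0:x1][mask] = value


def render_frame(
    scene: TrialScene, t: int, phase: str | None = None, rng=None
) -> FrameImage:
    """Render frame t: background, distractors, target last, phase borders."""
    traj = scene.traj
    if not 0 <= t < traj.n_frames:
        raise IndexError(f"frame {t} out of range [0, {traj.n_frames})")
    if phase is None:
        phase = phase_of(traj, t)
    if phase not in ("highlight", "track", "end"):
        raise ValueError(f"unknown phase {phase!r}")

    if scene.dynamic_background:
        img = trinary_texture(scene.background.shape, scene.noise, _as_rng(rng))
    else:
        img = scene.background.copy()
    centres = np.rint(traj.positions[t]).astype(int)
    half = traj.object_side_px // 2
    for i in scene.draw_order:
        _blit(img, scene.object_textures[i], centres[i, 0], centres[i, 1])
    if phase == "highlight":
        cx, cy = centres[traj.target_index]
        # inner white ring then outer black ring around the target
        _draw_ring(img, cx, cy, half, HIGHLIGHT_BORDER_PX, WHITE)
        _draw_ring(img, cx, cy, half + HIGHLIGHT_BORDER_PX, HIGHLIGHT_BORDER_PX, BLACK)
    elif phase == "end":
        for i in scene.draw_order:
            _draw_ring(img, centres[i, 0], centres[i, 1], half, END_BORDER_PX, BLACK)
    return FrameImage(luminance=img)


def export_trial(
    traj: TrajectorySet,
    noise: NoiseModel | None = None,
    out_path=None,
    format: str = "png",
    rng_seed=0,
    dynamic_background: bool = False,
) -> dict:
    """Export a trial as numbered frames plus a JSON manifest.

    ``format`` is "png" (one file per frame) or "gif" (animated, 8-bit).
    Returns a manifest dict (also written to ``manifest.json``).
    """
    if format not in ("png", "gif"):
        raise ValueError(f"unknown export format {format!r}")
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    scene = make_scene(traj, noise, rng_seed, dynamic_background)
    files = []
    if format == "png":
        width = len(str(traj.n_frames - 1))
        for t in range(traj.n_frames):
            frame = render_frame(scene, t)
            name = f"frame_{t:0{width}d}.png"
            iio.imwrite(out / name, frame.to_uint8())
            files.append(name)
    else:
        stack = np.stack([render_frame(scene, t).to_uint8() for t in range(traj.n_frames)])
        name = "trial.gif"
        iio.imwrite(out / name, stack, duration=1000.0 / traj.arena.frame_rate, loop=0)
        files.append(name)
    manifest = {
        "format": format,
        "n_frames": traj.n_frames,
        "n_objects": traj.n_objects,
        "target_index": int(traj.target_index),
        "arena": {"width_px": traj.arena.width_px, "height_px": traj.arena.height_px},
        "object_side_px": traj.object_side_px,
        "motion_seed": traj.rng_seed,
        "texture_seed": scene.rng_seed,
        "dynamic_background": dynamic_background,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
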