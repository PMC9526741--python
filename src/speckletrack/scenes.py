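"""Synthetic hidden-plane scenes: static backgrounds plus moving sub-objects.

The hidden object is modelled as a nonnegative intensity map O(x_o) on the
object plane, decomposed into sub-objects, O = Σ_j o_j, each of which may
translate, rotate, or change apparent size independently over a sequence of
frames.  The generators here emulate the programmable scenes used in the
reference experiments: a handful of simple shapes with one mover, or a field
of static dots with a single moving star.

Coordinate convention (used package-wide): grids are indexed (row, col) with
the origin at index ``N // 2`` on each axis; positions and displacements are
(row, col) vectors in mm, ``mm = (index − N//2) · pixel_pitch``.  In reported
outputs, +x is +col and +y is −row (y up).

Rigid motion is applied by re-rasterising the sub-object sprite each frame
(bilinear resampling, renormalised so the sprite's total intensity is
conserved exactly) rather than by shifting rasterised pixels, so sub-pixel
translations and rotations are supported.  Conserving total intensity is what
makes the differential correlation of a moving object zero-mean.
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Motion",
    "SubObject",
    "SceneComponent",
    "ObjectScene",
    "SceneSequence",
    "ScenePlacementError",
    "disk_sprite",
    "star_sprite",
    "rect_sprite",
    "ring_sprite",
    "make_dotfield_scene",
    "make_multishape_scene",
    "apply_motion",
    "linear_motion",
    "square_path_motion",
    "save_sequence",
    "load_sequence",
]


class ScenePlacementError(ValueError):
    """A sub-object cannot be placed (grid too crowded or motion exits it)."""


@dataclass(frozen=True)
class Motion:
    """Rigid transform of a sub-object in one frame.

    translation in mm (row, col); rotation counter-clockwise in degrees about
    the sprite centre; scale multiplies the sprite's linear size (apparent
    size, e.g. motion toward the medium).
    """

    translation: tuple = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale: float = 1.0

    def key(self) -> tuple:
        return (
            round(float(self.translation[0]), 12),
            round(float(self.translation[1]), 12),
            round(float(self.rotation_deg), 12),
            round(float(self.scale), 12),
        )

    @property
    def is_identity(self) -> bool:
        return self.key() == (0.0, 0.0, 0.0, 1.0)


@dataclass
class SubObject:
    """A sprite (nonnegative intensity patch) anchored on the object plane."""

    sprite: np.ndarray
    anchor: tuple  # (row, col) mm
    mobile: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.sprite = np.asarray(self.sprite, dtype=float)
        if self.sprite.ndim != 2 or np.any(self.sprite < 0):
            raise ValueError("sprite must be a 2-D nonnegative array")
        if self.sprite.sum() <= 0:
            raise ValueError("sprite must carry positive total intensity")


@dataclass(frozen=True)
class SceneComponent:
    """A rasterised sub-object in one frame: full-grid intensity + anchor."""

    raster: np.ndarray  # full object-grid intensity of this sub-object alone
    anchor: tuple  # current (row, col) anchor in mm
    cache_key: tuple  # stable identity for simulator-side caching


@dataclass(frozen=True)
class ObjectScene:
    """One frame of the hidden plane: total intensity plus its components."""

    intensity: np.ndarray
    pixel_pitch: float
    components: tuple = ()

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("scene intensity must be nonnegative and finite")


def _grid_center(n: int) -> int:
    return n // 2


def _transformed_sprite(sprite: np.ndarray, rotation_deg: float, scale: float) -> np.ndarray:
    """Rotate/scale a sprite about its centre, conserving total intensity."""
    if rotation_deg == 0.0 and scale == 1.0:
        return sprite
    if scale <= 0:
        raise ValueError("scale must be > 0")
    h, w = sprite.shape
    out_size = int(np.ceil(np.hypot(h, w) * max(scale, 1.0))) + 4
    out_shape = (out_size, out_size)
    theta = np.deg2rad(rotation_deg)
    # inverse map: output -> input, rotation about the centres
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    matrix = rot.T / scale
    in_center = (np.array(sprite.shape) - 1) / 2.0
    out_center = (np.array(out_shape) - 1) / 2.0
    offset = in_center - matrix @ out_center
    out = ndimage.affine_transform(
        sprite, matrix, offset=offset, output_shape=out_shape, order=1, mode="constant"
    )
    np.clip(out, 0.0, None, out=out)
    total = out.sum()
    if total <= 0:
        raise ScenePlacementError("sprite vanished under the requested transform")
    out *= sprite.sum() / total
    return out


def _place_sprite(canvas: np.ndarray, sprite: np.ndarray, center_px) -> None:
    """Add ``sprite`` to ``canvas`` with its centre at float (row, col) px.

    Bilinear sub-pixel placement; raises if any sprite support would leave
    the canvas.
    """
    padded = np.pad(sprite, 1)
    frac, base = np.modf(np.asarray(center_px, dtype=float))
    shifted = ndimage.shift(padded, frac, order=1, mode="constant", cval=0.0)
    np.clip(shifted, 0.0, None, out=shifted)
    if shifted.sum() > 0:
        shifted *= sprite.sum() / shifted.sum()
    h, w = shifted.shape
    r0 = int(base[0]) - (h - 1) // 2
    c0 = int(base[1]) - (w - 1) // 2
    if r0 < 0 or c0 < 0 or r0 + h > canvas.shape[0] or c0 + w > canvas.shape[1]:
        raise ScenePlacementError(
            f"sprite centred at {tuple(np.asarray(center_px))} px leaves the grid"
        )
    canvas[r0 : r0 + h, c0 : c0 + w] += shifted


@dataclass
class SceneSequence:
    """Time-ordered scene: shared grid plus per-frame, per-object motions.

    ``motions[j]`` is the list of :class:`Motion` of sub-object ``j`` over
    frames; static sub-objects keep identity motion and rasterise to
    bit-identical arrays in every frame (rasters are cached by transform).
    """

    grid_shape: tuple
    pixel_pitch: float
    sub_objects: list
    motions: list  # motions[sub][frame]
    frame_interval: float = 1.0
    token: str = field(default_factory=lambda: uuid.uuid4().hex)
    _raster_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n_frames = {len(m) for m in self.motions}
        if len(n_frames) != 1:
            raise ValueError("all sub-objects need the same number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.motions[0])

    def _raster(self, sub_idx: int, motion: Motion) -> np.ndarray:
        key = (sub_idx, motion.key())
        cached = self._raster_cache.get(key)
        if cached is not None:
            return cached
        sub = self.sub_objects[sub_idx]
        sprite = _transformed_sprite(sub.sprite, motion.rotation_deg, motion.scale)
        canvas = np.zeros(self.grid_shape, dtype=float)
        anchor_mm = np.asarray(sub.anchor, dtype=float) + np.asarray(
            motion.translation, dtype=float
        )
        center_px = anchor_mm / self.pixel_pitch + np.array(
            [_grid_center(self.grid_shape[0]), _grid_center(self.grid_shape[1])]
        )
        _place_sprite(canvas, sprite, center_px)
        self._raster_cache[key] = canvas
        return canvas

    def frame(self, index: int) -> ObjectScene:
        components = []
        total = np.zeros(self.grid_shape, dtype=float)
        for j, sub in enumerate(self.sub_objects):
            motion = self.motions[j][index]
            raster = self._raster(j, motion)
            anchor = tuple(
                np.asarray(sub.anchor, dtype=float)
                + np.asarray(motion.translation, dtype=float)
            )
            components.append(
                SceneComponent(
                    raster=raster,
                    anchor=anchor,
                    cache_key=(self.token, j, motion.key()),
                )
            )
            total = total + raster
        return ObjectScene(
            intensity=total, pixel_pitch=self.pixel_pitch, components=tuple(components)
        )

    def frames(self) -> list:
        return [self.frame(i) for i in range(self.n_frames)]


# ---------------------------------------------------------------------------
# Sprites


def disk_sprite(radius_px: float, value: float = 1.0) -> np.ndarray:
    """Antialiased filled disk."""
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    half = int(np.ceil(radius_px)) + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(rr, cc)
    return value * np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


def star_sprite(size_px: float, n_points: int = 5, value: float = 1.0) -> np.ndarray:
    """Filled n-pointed star of overall diameter ``size_px``."""
    from skimage.draw import polygon

    if size_px < 4:
        raise ValueError("size_px must be >= 4")
    outer = size_px / 2.0
    inner = 0.45 * outer
    half = int(np.ceil(outer)) + 1
    angles = -np.pi / 2 + np.arange(2 * n_points) * np.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, outer, inner)
    rows = half + radii * np.sin(angles)
    cols = half + radii * np.cos(angles)
    sprite = np.zeros((2 * half + 1, 2 * half + 1), dtype=float)
    rr, cc = polygon(rows, cols, sprite.shape)
    sprite[rr, cc] = value
    return sprite


def rect_sprite(height_px: int, width_px: int, value: float = 1.0) -> np.ndarray:
    return np.full((int(height_px), int(width_px)), float(value))


def ring_sprite(outer_px: float, inner_px: float, value: float = 1.0) -> np.ndarray:
    if not 0 < inner_px < outer_px:
        raise ValueError("need 0 < inner_px < outer_px")
    half = int(np.ceil(outer_px)) + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(rr, cc)
    outer_mask = np.clip(outer_px + 0.5 - dist, 0.0, 1.0)
    inner_mask = np.clip(inner_px + 0.5 - dist, 0.0, 1.0)
    return value * np.clip(outer_mask - inner_mask, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Scene builders


def _sprite_radius(sprite: np.ndarray) -> float:
    return max(sprite.shape) / 2.0


def make_dotfield_scene(
    n_dots: int,
    dot_radius: float = 2.0,
    star_size: float = 14.0,
    grid=(256, 256),
    seed: int = 0,
    pixel_pitch: float = 3.75e-3 * 430.0 / 50.0,
    star_anchor_px=(0.0, 0.0),
    margin_px: float = 20.0,
    max_tries_per_dot: int = 500,
) -> SceneSequence:
    """Many static dots plus one mobile star (single-frame template).

    Dot positions are drawn uniformly (seeded) with non-overlapping supports;
    placement fails with :class:`ScenePlacementError` after bounded retries
    when the grid is too crowded.  The star (the last sub-object, flagged
    ``mobile``) sits at ``star_anchor_px`` relative to the grid centre.
    """
    if n_dots < 0:
        raise ValueError("n_dots must be >= 0")
    rng = np.random.default_rng(seed)
    star = star_sprite(star_size)
    star_anchor = (
        float(star_anchor_px[0]) * pixel_pitch,
        float(star_anchor_px[1]) * pixel_pitch,
    )
    placed = [(np.asarray(star_anchor_px, dtype=float), _sprite_radius(star))]
    subs = []
    dot = disk_sprite(dot_radius)
    dot_r = _sprite_radius(dot)
    lo_r, hi_r = margin_px, grid[0] - 1 - margin_px
    lo_c, hi_c = margin_px, grid[1] - 1 - margin_px
    cr, cc = _grid_center(grid[0]), _grid_center(grid[1])
    for i in range(n_dots):
        for _ in range(max_tries_per_dot):
            pos = rng.uniform((lo_r, lo_c), (hi_r, hi_c)) - np.array([cr, cc])
            if all(
                np.hypot(*(pos - other)) > dot_r + other_r + 2.0
                for other, other_r in placed
            ):
                break
        else:
            raise ScenePlacementError(
                f"could not place dot {i + 1}/{n_dots}: grid too crowded"
            )
        placed.append((pos, dot_r))
        subs.append(
            SubObject(
                sprite=dot,
                anchor=(pos[0] * pixel_pitch, pos[1] * pixel_pitch),
                mobile=False,
                name=f"dot{i}",
            )
        )
    subs.append(SubObject(sprite=star, anchor=star_anchor, mobile=True, name="star"))
    motions = [[Motion()] for _ in subs]
    return SceneSequence(
        grid_shape=tuple(grid), pixel_pitch=pixel_pitch, sub_objects=subs, motions=motions
    )


def make_multishape_scene(
    shapes: Sequence[SubObject],
    grid=(256, 256),
    pixel_pitch: float = 3.75e-3 * 430.0 / 50.0,
) -> SceneSequence:
    """Scene from explicit sub-objects; errors if supports collide at t0."""
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    seq = SceneSequence(
        grid_shape=tuple(grid),
        pixel_pitch=pixel_pitch,
        sub_objects=list(shapes),
        motions=[[Motion()] for _ in shapes],
    )
    scene = seq.frame(0)
    rasters = [c.raster for c in scene.components]
    for a in range(len(rasters)):
        for b in range(a + 1, len(rasters)):
            if np.any((rasters[a] > 0) & (rasters[b] > 0)):
                raise ScenePlacementError(f"shapes {a} and {b} overlap at t0")
    return seq


def apply_motion(seq: SceneSequence, sub_index: int, motions: Sequence[Motion]) -> SceneSequence:
    """Animate one sub-object; all others stay bit-identical across frames.

    ``motions`` must have one entry per output frame.  A single-frame
    template is expanded; otherwise the length must match ``seq.n_frames``.
    """
    n = len(motions)
    if n < 1:
        raise ValueError("motion list must be nonempty")
    if not 0 <= sub_index < len(seq.sub_objects):
        raise IndexError("sub_index out of range")
    new_motions = []
    for j, existing in enumerate(seq.motions):
        if j == sub_index:
            new_motions.append(list(motions))
        elif seq.n_frames == n:
            new_motions.append(list(existing))
        elif seq.n_frames == 1:
            new_motions.append([existing[0]] * n)
        else:
            raise ValueError(
                f"motion list length {n} does not match sequence length {seq.n_frames}"
            )
    out = SceneSequence(
        grid_shape=seq.grid_shape,
        pixel_pitch=seq.pixel_pitch,
        sub_objects=seq.sub_objects,
        motions=new_motions,
        frame_interval=seq.frame_interval,
        token=seq.token,
    )
    out._raster_cache = seq._raster_cache  # transforms are content-addressed
    for i in range(out.n_frames):  # fail fast if motion exits the grid
        out.frame(i)
    return out


def linear_motion(step_px, n_frames: int, pixel_pitch: float) -> list:
    """Constant-velocity translation: ``step_px`` (row, col) px per frame."""
    step = np.asarray(step_px, dtype=float) * pixel_pitch
    return [Motion(translation=tuple(step * i)) for i in range(n_frames)]


def square_path_motion(leg_px: float, steps_per_leg: int, pixel_pitch: float) -> list:
    """Closed square path (right, down, left, up), returning to the origin."""
    directions = [(0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0)]
    pos = np.zeros(2)
    out = [Motion()]
    step = leg_px / steps_per_leg
    for d in directions:
        for _ in range(steps_per_leg):
            pos = pos + np.asarray(d) * step
            out.append(Motion(translation=tuple(pos * pixel_pitch)))
    return out


# ---------------------------------------------------------------------------
# TIFF round-trip


def save_sequence(seq: SceneSequence, path) -> None:
    """Write frames as multi-page float32 TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    stack = np.stack([seq.frame(i).intensity for i in range(seq.n_frames)]).astype(
        np.float32
    )
    tifffile.imwrite(path, stack, photometric='minisblack')
    meta = {
        "pixel_pitch_mm": seq.pixel_pitch,
        "frame_interval": seq.frame_interval,
        "n_frames": seq.n_frames,
        "sub_objects": [
            {"name": s.name, "mobile": s.mobile, "anchor_mm": list(map(float, s.anchor))}
            for s in seq.sub_objects
        ],
        "motions": [
            [
                {
                    "translation_mm": list(map(float, m.translation)),
                    "rotation_deg": float(m.rotation_deg),
                    "scale": float(m.scale),
                }
                for m in per_sub
            ]
            for per_sub in seq.motions
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_sequence(path):
    """Read back (frames, pixel_pitch, metadata) written by :func:`save_sequence`."""
    import tifffile

    path = Path(path)
    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    frames = [
        ObjectScene(intensity=np.asarray(page, dtype=np.float32), pixel_pitch=meta["pixel_pitch_mm"])
        for page in stack
    ]
    return frames, meta["pixel_pitch_mm"], meta
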