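"""Forward model: detector-plane speckle from incoherently emitting scenes.

With spatially incoherent, narrow-band illumination the speckle patterns of
individual object points add in intensity, I(x_d) = ∫ O(x_o) S(x_o, x_d) d²x_o,
with no interference cross-terms, and the pairwise correlation between the
point speckles S follows the memory-effect kernel of
:mod:`speckletrack.optics_model`.

Two backends:

``physical``
    A single thin random-phase screen illuminated by a paraxial spherical
    wave from each object point, propagated to the detector with a
    band-limited angular-spectrum transfer function.  Fully developed speckle
    with an essentially unlimited memory range (a thin screen does not
    decorrelate with tilt), used as the ground-truth oracle for speckle
    statistics and for the geometric shift law.

``statistical``
    Directly synthesises circular-Gaussian speckle *fields* with the target
    pairwise correlations.  Each sub-object (or requested source position)
    gets one field node; a new node is conditioned on all existing nodes
    (solve R w = r, fresh residual) so that field correlations match
    √C — the Siegert relation then gives intensity correlations C.  Fields
    are periodic by construction (filtered white noise on the FFT grid), so
    geometric shifts and convolutions are circular and exact.  This is the
    backend that realises a *finite* memory range and is used by the
    beyond-memory tracking studies.

All randomness is drawn from seeds derived from a per-screen master seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .optics_model import (
    MemoryKernel,
    OpticalConfig,
    UndersampledError,
    object_to_detector_shift,
)
from .util import substream_seed

__all__ = [
    "ScatteringScreen",
    "SpeckleFrame",
    "CorrelatedFieldBank",
    "simulate_point_speckle",
    "render_frame",
    "render_sequence",
    "correlated_stack",
    "realized_pairwise_correlation",
    "add_camera_noise",
]

BACKENDS = ("physical", "statistical")


@dataclass(frozen=True)
class SpeckleFrame:
    """Detector-plane intensity I(x_d): the only observable of the method."""

    intensity: np.ndarray
    pitch: float  # mm / detector pixel
    exposure_s: float = 3.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite intensity in speckle frame")
        if np.any(arr < 0):
            raise ValueError("negative intensity in speckle frame")
        object.__setattr__(self, "intensity", arr)


class CorrelatedFieldBank:
    """Joint synthesis of speckle fields with memory-effect correlations.

    One complex field per requested object-plane position ("node"), all on
    the detector FFT grid.  Node fields are unit-power, zero-lag aligned;
    the target field correlation between nodes a, b is
    √(envelope(k·|a−b|·L/L_o)).  New nodes are generated by exact Gaussian
    conditioning on every existing node.  If the requested correlation
    matrix is not positive semi-definite the residual variance is clipped at
    zero (nearest feasible field) and a warning is emitted.
    """

    def __init__(self, config: OpticalConfig, shape, seed: int):
        self.config = config
        self.shape = tuple(shape)
        self.kernel = MemoryKernel(config)
        self.rng = np.random.default_rng(substream_seed(seed, "bank"))
        n_r, n_c = self.shape
        fr = np.fft.fftfreq(n_r, d=config.detector_pixel_pitch)[:, None]
        fc = np.fft.fftfreq(n_c, d=config.detector_pixel_pitch)[None, :]
        # Gaussian field spectrum -> field autocorrelation exp(-Δ²/(2 w²)),
        # w = L_s/(kσ); the intensity correlation is its square (Siegert),
        # matching the kernel's grain factor exp(-k²σ²|Δx_d/L_s|²).
        w = config.grain_field_width
        power = np.exp(-2.0 * np.pi**2 * w**2 * (fr**2 + fc**2))
        self._amplitude = np.sqrt(power)
        self._norm = (n_r * n_c) / math.sqrt(power.sum())
        self._positions: list = []
        self._fields: list = []
        self._corr: Optional[np.ndarray] = None  # target R among nodes
        self._cache: dict = {}
        self._warned = False

    def _fresh_field(self) -> np.ndarray:
        white = self.rng.normal(size=(2, *self.shape))
        noise = (white[0] + 1j * white[1]) / math.sqrt(2.0)
        return self._norm * np.fft.ifft2(self._amplitude * noise)

    @property
    def n_nodes(self) -> int:
        return len(self._fields)

    def field_at(self, pos_mm) -> tuple:
        """Return (complex field, node index) for an object-plane position."""
        pos = np.asarray(pos_mm, dtype=float)
        key = (round(float(pos[0]), 9), round(float(pos[1]), 9))
        hit = self._cache.get(key)
        if hit is not None:
            return self._fields[hit], hit
        if not self._positions:
            fld = self._fresh_field()
        else:
            existing = np.asarray(self._positions)
            r = np.asarray(
                self.kernel.field_correlation_matched(existing - pos[None, :])
            )
            weights, *_ = np.linalg.lstsq(self._corr, r, rcond=None)
            resid = 1.0 - float(r @ weights)
            if resid < -1e-8 and not self._warned:
                warnings.warn(
                    "requested correlation structure is not positive "
                    "semi-definite; using nearest feasible field",
                    RuntimeWarning,
                    stacklevel=2,
                )
                self._warned = True
            fld = math.sqrt(max(resid, 0.0)) * self._fresh_field()
            for w_i, f_i in zip(weights, self._fields):
                if w_i != 0.0:
                    fld = fld + w_i * f_i
        idx = len(self._fields)
        self._fields.append(fld)
        self._positions.append(pos)
        n = idx + 1
        corr = np.eye(n)
        if idx:
            corr[:idx, :idx] = self._corr
            row = np.asarray(
                self.kernel.field_correlation_matched(np.asarray(self._positions[:idx]) - pos[None, :])
            )
            corr[idx, :idx] = row
            corr[:idx, idx] = row
        self._corr = corr
        self._cache[key] = idx
        return fld, idx


@dataclass
class ScatteringScreen:
    """The scattering layer: a seeded random-phase screen.

    The ``physical`` backend uses the explicit phase grid; the
    ``statistical`` backend uses the screen's seed to drive a
    :class:`CorrelatedFieldBank` (lazily built per optical config) plus a
    cache of per-sub-object intensity contributions, so static sub-objects
    render bit-identically across frames.
    """

    seed: int
    shape: tuple = (256, 256)
    amplitude_mask: Optional[np.ndarray] = None
    _phase: Optional[np.ndarray] = field(default=None, repr=False)
    _bank: Optional[CorrelatedFieldBank] = field(default=None, repr=False)
    _point_cache: dict = field(default_factory=dict, repr=False)
    _contrib_cache: dict = field(default_factory=dict, repr=False)

    @property
    def phase(self) -> np.ndarray:
        if self._phase is None:
            rng = np.random.default_rng(substream_seed(self.seed, "phase"))
            self._phase = rng.uniform(0.0, 2.0 * np.pi, size=self.shape)
        return self._phase

    def bank(self, config: OpticalConfig) -> CorrelatedFieldBank:
        if self._bank is None:
            self._bank = CorrelatedFieldBank(config, self.shape, self.seed)
        return self._bank


# ---------------------------------------------------------------------------
# Physical backend


def _angular_spectrum_tf(shape, pitch: float, wavelength: float, distance: float):
    """Band-limited angular-spectrum transfer function exp(ikz√(1−λ²f²))."""
    n_r, n_c = shape
    fr = np.fft.fftfreq(n_r, d=pitch)[:, None]
    fc = np.fft.fftfreq(n_c, d=pitch)[None, :]
    arg = 1.0 - wavelength**2 * (fr**2 + fc**2)
    prop = arg > 0
    tf = np.where(
        prop,
        np.exp(2j * np.pi / wavelength * distance * np.sqrt(np.clip(arg, 0.0, None))),
        0.0,
    )
    # Matsushima band limit against transfer-function aliasing
    f_lim_r = 1.0 / (wavelength * math.sqrt((2.0 * distance / (n_r * pitch)) ** 2 + 1.0))
    f_lim_c = 1.0 / (wavelength * math.sqrt((2.0 * distance / (n_c * pitch)) ** 2 + 1.0))
    tf = np.where((np.abs(fr) <= f_lim_r) & (np.abs(fc) <= f_lim_c), tf, 0.0)
    return tf


def simulate_point_speckle(
    x_o, screen: ScatteringScreen, config: OpticalConfig
) -> SpeckleFrame:
    """Speckle of a single object point through the thin screen (physical).

    Paraxial spherical wave from lateral position ``x_o`` (mm) at distance
    L_o illuminates the screen within a Gaussian spot of width σ, picks up
    the screen's random phase, and propagates L_s to the detector; the frame
    is |field|².  The screen plane is sampled at the detector pitch.
    """
    key = (round(float(x_o[0]), 9), round(float(x_o[1]), 9))
    cached = screen._point_cache.get(("phys", key))
    if cached is not None:
        return cached
    n_r, n_c = screen.shape
    pitch = config.detector_pixel_pitch
    window = min(n_r, n_c) * pitch
    illuminated = min(4.0 * config.sigma, window)
    from .optics_model import expected_grain_diameter  # sampling guard

    expected_grain_diameter(config, illuminated)
    rows = (np.arange(n_r) - n_r // 2)[:, None] * pitch
    cols = (np.arange(n_c) - n_c // 2)[None, :] * pitch
    r2 = (rows - float(x_o[0])) ** 2 + (cols - float(x_o[1])) ** 2
    incident = np.exp(1j * config.k / (2.0 * config.L_o) * r2)
    envelope = np.exp(-(rows**2 + cols**2) / (4.0 * config.sigma**2))
    fld = incident * envelope * np.exp(1j * screen.phase)
    if screen.amplitude_mask is not None:
        fld = fld * screen.amplitude_mask
    tf = _angular_spectrum_tf(screen.shape, pitch, config.wavelength, config.L_s)
    out = np.fft.ifft2(np.fft.fft2(fld) * tf)
    intensity = np.abs(out) ** 2
    if not np.all(np.isfinite(intensity)):
        raise FloatingPointError("non-finite field in point-speckle propagation")
    mean = intensity.mean()
    if mean > 0:
        intensity = intensity / mean
    frame = SpeckleFrame(intensity=intensity, pitch=pitch, meta={"backend": "physical"})
    screen._point_cache[("phys", key)] = frame
    return frame


# ---------------------------------------------------------------------------
# Statistical backend helpers


def _circular_point_reflect(arr: np.ndarray) -> np.ndarray:
    """Point reflection about index (N//2, M//2) on the periodic grid."""
    out = arr[::-1, ::-1]
    return np.roll(out, ((arr.shape[0] + 1) % 2, (arr.shape[1] + 1) % 2), axis=(0, 1))


def _map_raster_to_detector(
    raster: np.ndarray, object_pitch: float, config: OpticalConfig, det_shape
) -> np.ndarray:
    """Rasterise an object-plane intensity patch onto the detector grid.

    Applies the geometric scale L_s/L_o (a 1:1 fast path when the pitches
    are coupled) and the pinhole point reflection when ``flip_axes``; total
    intensity is conserved.
    """
    from scipy import ndimage

    scale = object_pitch * config.magnification / config.detector_pixel_pitch
    if abs(scale - 1.0) > 1e-9:
        zoomed = ndimage.zoom(raster, scale, order=1, mode="grid-constant", grid_mode=True)
        np.clip(zoomed, 0.0, None, out=zoomed)
        if zoomed.sum() > 0:
            zoomed *= raster.sum() / zoomed.sum()
        raster = zoomed
    out = np.zeros(det_shape, dtype=float)
    # paste centred: object centre index -> detector centre index
    r_off = det_shape[0] // 2 - raster.shape[0] // 2
    c_off = det_shape[1] // 2 - raster.shape[1] // 2
    rr = np.arange(raster.shape[0]) + r_off
    cc = np.arange(raster.shape[1]) + c_off
    np.add.at(out, (rr[:, None] % det_shape[0], cc[None, :] % det_shape[1]), raster)
    if config.flip_axes:
        out = _circular_point_reflect(out)
    return out


def _fourier_shift(arr: np.ndarray, shift_px) -> np.ndarray:
    """Exact circular sub-pixel shift of a periodic array."""
    from scipy.ndimage import fourier_shift

    spectrum = np.fft.fft2(arr)
    shifted = fourier_shift(spectrum, shift_px)
    return np.fft.ifft2(shifted)


# ---------------------------------------------------------------------------
# Rendering


def render_frame(
    scene,
    screen: ScatteringScreen,
    config: OpticalConfig,
    backend: str = "statistical",
) -> SpeckleFrame:
    """Incoherent forward model for one scene frame.

    The frame is the intensity-weighted sum of per-point speckles, linear in
    the scene with no interference cross-terms.  The ``physical`` backend
    loops over lit object pixels (exact, slow; for oracle-grade tests); the
    ``statistical`` backend assigns one correlated field node per sub-object
    and convolves the node's speckle intensity with the geometrically mapped
    sub-object footprint (memory effect taken as locally rigid across each
    small sprite).
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
    intensity_map = scene.intensity
    if intensity_map.sum() <= 0:
        raise ValueError("scene is empty")
    if backend == "physical":
        return _render_physical(scene, screen, config)
    return _render_statistical(scene, screen, config)


def _render_physical(scene, screen, config) -> SpeckleFrame:
    n_r, n_c = scene.intensity.shape
    cr, cc = n_r // 2, n_c // 2
    total = np.zeros(screen.shape, dtype=float)
    rows, cols = np.nonzero(scene.intensity)
    for r, c in zip(rows, cols):
        pos = ((r - cr) * scene.pixel_pitch, (c - cc) * scene.pixel_pitch)
        point = simulate_point_speckle(pos, screen, config)
        total = total + scene.intensity[r, c] * point.intensity
    return SpeckleFrame(intensity=total, pitch=config.detector_pixel_pitch, meta={"backend": "physical"})


def _render_statistical(scene, screen, config) -> SpeckleFrame:
    components = getattr(scene, "components", ())
    if not components:
        raise ValueError(
            "statistical backend needs scene components (render from a SceneSequence frame)"
        )
    bank = screen.bank(config)
    total = np.zeros(screen.shape, dtype=float)
    for comp in components:
        fld, node = bank.field_at(comp.anchor)
        cache_key = (node, comp.cache_key)
        contrib = screen._contrib_cache.get(cache_key)
        if contrib is None:
            point_intensity = np.abs(fld) ** 2
            mapped = _map_raster_to_detector(
                comp.raster, scene.pixel_pitch, config, screen.shape
            )
            contrib = np.fft.irfft2(
                np.fft.rfft2(point_intensity) * np.fft.rfft2(mapped), s=screen.shape
            )
            np.clip(contrib, 0.0, None, out=contrib)
            screen._contrib_cache[cache_key] = contrib
        total = total + contrib
    return SpeckleFrame(
        intensity=total, pitch=config.detector_pixel_pitch, meta={"backend": "statistical"}
    )


def render_sequence(
    seq,
    screen: ScatteringScreen,
    config: OpticalConfig,
    backend: str = "statistical",
) -> list:
    """Render every frame of a scene sequence against one (static) screen."""
    return [render_frame(seq.frame(i), screen, config, backend) for i in range(seq.n_frames)]


def correlated_stack(
    positions: Sequence, screen: ScatteringScreen, config: OpticalConfig
) -> list:
    """One speckle frame per object-plane point, with Eq.-style correlations.

    Each frame is |field|² of the point's correlated node, shifted to the
    geometrically mapped detector position (exact periodic Fourier shift).
    The realised pairwise intensity correlations approximate the kernel at
    the matched lag; measure them with
    :func:`realized_pairwise_correlation`.
    """
    if len(positions) == 0:
        raise ValueError("need at least one position")
    bank = screen.bank(config)
    frames = []
    for pos in positions:
        fld, _ = bank.field_at(pos)
        shift_mm = object_to_detector_shift(pos, config)
        shift_px = np.asarray(shift_mm) / config.detector_pixel_pitch
        shifted = _fourier_shift(fld, shift_px)
        frames.append(
            SpeckleFrame(
                intensity=np.abs(shifted) ** 2,
                pitch=config.detector_pixel_pitch,
                meta={"backend": "statistical", "position_mm": tuple(map(float, pos))},
            )
        )
    return frames


def realized_pairwise_correlation(frames, positions, config: OpticalConfig) -> np.ndarray:
    """Sample Pearson correlation between stack frames at the matched lag.

    Frames are un-shifted back to zero lag (inverting the geometric mapping)
    before correlating, so the result is directly comparable with the
    memory-envelope prediction.
    """
    aligned = []
    for frame, pos in zip(frames, positions):
        shift_mm = object_to_detector_shift(pos, config)
        shift_px = -np.asarray(shift_mm) / config.detector_pixel_pitch
        arr = np.fft.ifft2(
            np.fft.fft2(frame.intensity)
            * np.exp(
                -2j
                * np.pi
                * (
                    np.fft.fftfreq(frame.intensity.shape[0])[:, None] * shift_px[0]
                    + np.fft.fftfreq(frame.intensity.shape[1])[None, :] * shift_px[1]
                )
            )
        ).real
        aligned.append(arr - arr.mean())
    n = len(aligned)
    corr = np.eye(n)
    norms = [np.sqrt((a**2).sum()) for a in aligned]
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = float(
                (aligned[i] * aligned[j]).sum() / (norms[i] * norms[j])
            )
    return corr


# ---------------------------------------------------------------------------
# Camera noise


def add_camera_noise(
    frame: SpeckleFrame,
    shot: bool = True,
    read_sigma: float = 2.0,
    bit_depth: int = 16,
    seed: int = 0,
    mean_counts: float = 1000.0,
) -> SpeckleFrame:
    """Poisson shot noise + Gaussian read noise + quantisation/clipping.

    The clean frame is scaled so its mean lands at ``mean_counts`` detector
    counts, then Poisson shot noise (optional), additive Gaussian read noise
    of ``read_sigma`` counts, rounding, and clipping to the bit depth are
    applied.  Deterministic given ``seed``.
    """
    if read_sigma < 0:
        raise ValueError("read_sigma must be >= 0")
    if bit_depth not in (8, 12, 16):
        raise ValueError("bit_depth must be one of 8, 12, 16")
    rng = np.random.default_rng(substream_seed(seed, "noise"))
    scale = mean_counts / frame.intensity.mean() if frame.intensity.mean() > 0 else 1.0
    counts = frame.intensity * scale
    if shot:
        counts = rng.poisson(counts).astype(float)
    if read_sigma > 0:
        counts = counts + rng.normal(0.0, read_sigma, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, 2**bit_depth - 1)
    meta = dict(frame.meta)
    meta.update({"noise_scale": scale, "bit_depth": bit_depth})
    return SpeckleFrame(
        intensity=counts, pitch=frame.pitch, exposure_s=frame.exposure_s, meta=meta
    )
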