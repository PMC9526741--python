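"""Speckle correlations: the computation at the heart of the method.

The autocorrelation of a single speckle frame reveals the hidden object's
autocorrelation, ⟨I ⋆ I⟩ ∝ [O ⋆ O] ⊗ C, with the memory-effect kernel C
acting as the point spread function.  Cross-correlating frames taken at two
times shows how the scene moved, and the differential combination

    I(t1) ⋆ I(t0) − I(t1) ⋆ I(t1)

cancels every static-background term exactly, leaving a zero-mean map with
paired positive/negative lobes: positive at lags the moving object *vacated*
relative to its static neighbours, negative at lags it now occupies.

Conventions
-----------
* [a ⋆ b](Δ) = Σ_x a(x) · b(x + Δ): linear (zero-padded) correlation, never
  circular — speckle frames are not periodic and wrap-around would create
  false lobes.  An N×M input yields a (2N−1)×(2M−1) map with zero lag at
  index (N−1, M−1).
* Intensities are mean-subtracted before correlating (the δS = S − S̄
  convention); without this the enormous DC term swamps all structure.
* ``window``: "none" (default for identity/oracle work) or "tukey"
  (α = 0.25) to tame edge artefacts on real data.
* ``normalize``: "raw" (plain sums) or "coeff" (divided by the product of
  input norms, so values live in [−1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import tukey

from .optics_model import MemoryKernel, memory_envelope

__all__ = [
    "CorrelationMap",
    "DegenerateFrameError",
    "autocorrelate",
    "cross_correlate",
    "differential_correlation",
    "predicted_autocorrelation",
    "ensemble_autocorrelation",
    "map_similarity",
]

WINDOWS = ("none", "tukey")
NORMALIZATIONS = ("raw", "coeff")
KINDS = ("auto", "cross", "differential")


class DegenerateFrameError(ValueError):
    """Raised for constant (zero-variance) frames, which carry no signal."""


@dataclass(frozen=True)
class CorrelationMap:
    """Real-valued lag map over detector-plane lag Δx_d.

    ``values`` has odd shape (2N−1, 2M−1) with zero lag at the central index
    (N−1, M−1); ``lag_pitch`` converts lag pixels to mm.
    """

    values: np.ndarray
    lag_pitch: float
    kind: str
    window: str = "none"
    normalization: str = "coeff"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    @property
    def center(self) -> tuple:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    def lag_mm(self, index) -> np.ndarray:
        """Lag vector (mm) of a (row, col) map index."""
        c = self.center
        return (np.asarray(index, dtype=float) - np.asarray(c)) * self.lag_pitch

    def rot180(self) -> np.ndarray:
        """Map values under 180° rotation about zero lag."""
        return self.values[::-1, ::-1]

    def central_crop(self, half_px: int) -> np.ndarray:
        cr, cc = self.center
        return self.values[
            cr - half_px : cr + half_px + 1, cc - half_px : cc + half_px + 1
        ]


def _as_array(frame) -> np.ndarray:
    return np.asarray(getattr(frame, "intensity", frame), dtype=float)


def _pitch_of(frame, default=1.0) -> float:
    return float(getattr(frame, "pitch", default))


def _prepare(arr: np.ndarray, window: str) -> np.ndarray:
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    out = arr - arr.mean()
    if window == "tukey":
        out = out * np.outer(tukey(arr.shape[0], 0.25), tukey(arr.shape[1], 0.25))
    return out


def _corr_raw(a_prep: np.ndarray, b_prep: np.ndarray) -> np.ndarray:
    """[a ⋆ b](Δ) = Σ a(x) b(x+Δ) on the full (2N−1) linear lag grid."""
    return fftconvolve(b_prep, a_prep[::-1, ::-1], mode="full")


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("frames must be at least 2x2")
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")


def cross_correlate(frame_a, frame_b, window: str = "none", normalize: str = "coeff") -> CorrelationMap:
    """Mean-subtracted cross-correlation [I_a ⋆ I_b](Δ) (a at t1, b at t0).

    For a scene with one moving sub-object the map decomposes into a static
    part (all static-pair correlations, identical to the autocorrelation's)
    and a moving part that follows the mover — the decomposition exploited
    by :func:`differential_correlation`.
    """
    if normalize not in NORMALIZATIONS:
        raise ValueError(f"normalize must be one of {NORMALIZATIONS}")
    a, b = _as_array(frame_a), _as_array(frame_b)
    _check_pair(a, b)
    pa, pb = _prepare(a, window), _prepare(b, window)
    na, nb = np.sqrt((pa**2).sum()), np.sqrt((pb**2).sum())
    if na == 0.0 or nb == 0.0:
        raise DegenerateFrameError("constant frame has no correlation structure")
    values = _corr_raw(pa, pb)
    if normalize == "coeff":
        values = values / (na * nb)
    kind = "auto" if frame_a is frame_b else "cross"
    return CorrelationMap(
        values=values,
        lag_pitch=_pitch_of(frame_a),
        kind=kind,
        window=window,
        normalization=normalize,
    )


def autocorrelate(frame, window: str = "none", normalize: str = "coeff") -> CorrelationMap:
    """Mean-subtracted autocorrelation of one frame (centrosymmetric)."""
    out = cross_correlate(frame, frame, window=window, normalize=normalize)
    return CorrelationMap(
        values=out.values,
        lag_pitch=out.lag_pitch,
        kind="auto",
        window=window,
        normalization=normalize,
    )


def differential_correlation(
    frame_t1, frame_t0, window: str = "none", normalize: str = "coeff"
) -> CorrelationMap:
    """Background-cancelling map XC(t1, t0) − AC(t1).

    Static scene content cancels exactly (identical terms in both maps, same
    computational path — identical frames give bit-exact zeros).  For one
    intensity-conserving mover the map is ∝ [(o_k(t0) − o_k(t1)) ⋆ I(t1)] ⊗ C:
    zero-mean, with + lobes at the mover's old relative lags and − lobes at
    its new ones.  Both maps share the common scale ‖Ĩ1‖·‖Ĩ0‖ under
    "coeff" so the subtraction stays meaningful.
    """
    if normalize not in NORMALIZATIONS:
        raise ValueError(f"normalize must be one of {NORMALIZATIONS}")
    a1, a0 = _as_array(frame_t1), _as_array(frame_t0)
    _check_pair(a1, a0)
    p1, p0 = _prepare(a1, window), _prepare(a0, window)
    n1, n0 = np.sqrt((p1**2).sum()), np.sqrt((p0**2).sum())
    if n1 == 0.0 or n0 == 0.0:
        raise DegenerateFrameError("constant frame has no correlation structure")
    xc = _corr_raw(p1, p0)
    ac = _corr_raw(p1, p1)
    values = xc - ac
    if normalize == "coeff":
        values = values / (n1 * n0)
    return CorrelationMap(
        values=values,
        lag_pitch=_pitch_of(frame_t1),
        kind="differential",
        window=window,
        normalization=normalize,
    )


def ensemble_autocorrelation(frames, window: str = "none", normalize: str = "coeff") -> CorrelationMap:
    """Mean of per-frame autocorrelations over independent screens ⟨I ⋆ I⟩.

    Off-peak speckle fluctuations shrink like 1/√N; the limit is the
    prediction [O ⋆ O] ⊗ C of :func:`predicted_autocorrelation`.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    maps = [autocorrelate(f, window=window, normalize=normalize) for f in frames]
    shape = maps[0].values.shape
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError("ensemble frames have mismatched shapes")
    values = np.mean([m.values for m in maps], axis=0)
    return CorrelationMap(
        values=values,
        lag_pitch=maps[0].lag_pitch,
        kind="auto",
        window=window,
        normalization=normalize,
        meta={"ensemble_n": len(frames)},
    )


def predicted_autocorrelation(scene, kernel: MemoryKernel, out_shape=None) -> CorrelationMap:
    """Closed-form prediction [O ⋆ O] ⊗ C on the detector lag grid.

    The object autocorrelation is weighted by the memory envelope at each
    object-plane lag, rescaled by L_s/L_o onto detector lag pixels, then
    blurred with the kernel's grain profile.  Defined up to an arbitrary
    positive scale (normalised to peak 1); compare with measurements via
    :func:`map_similarity`.
    """
    from scipy import ndimage

    config = kernel.config
    intensity = _as_array(scene)
    if intensity.sum() <= 0:
        raise ValueError("scene is empty")
    pitch_o = float(getattr(scene, "pixel_pitch", config.object_pixel_pitch))
    ac_obj = fftconvolve(intensity, intensity[::-1, ::-1], mode="full")
    h, w = ac_obj.shape
    lag_r = (np.arange(h) - h // 2)[:, None] * pitch_o
    lag_c = (np.arange(w) - w // 2)[None, :] * pitch_o
    x = config.k * np.hypot(lag_r, lag_c) * config.L / config.L_o
    ac_obj = ac_obj * memory_envelope(x)

    scale = pitch_o * config.magnification / config.detector_pixel_pitch
    if abs(scale - 1.0) > 1e-9:
        ac_obj = ndimage.zoom(ac_obj, scale, order=1, mode="grid-constant", grid_mode=True)
        np.clip(ac_obj, 0.0, None, out=ac_obj)

    if out_shape is None:
        out_shape = ac_obj.shape
    out = np.zeros(out_shape, dtype=float)
    cr, cc = out_shape[0] // 2, out_shape[1] // 2
    sr, sc = ac_obj.shape[0] // 2, ac_obj.shape[1] // 2
    r_lo, c_lo = min(cr, sr), min(cc, sc)
    r_hi = min(out_shape[0] - cr, ac_obj.shape[0] - sr)
    c_hi = min(out_shape[1] - cc, ac_obj.shape[1] - sc)
    out[cr - r_lo : cr + r_hi, cc - c_lo : cc + c_hi] = ac_obj[
        sr - r_lo : sr + r_hi, sc - c_lo : sc + c_hi
    ]

    # grain blur: the kernel's on-diagonal intensity-correlation profile
    w_field = config.grain_field_width
    half = max(3, int(np.ceil(4.0 * w_field / config.detector_pixel_pitch)))
    gr = (np.arange(-half, half + 1))[:, None] * config.detector_pixel_pitch
    gc = (np.arange(-half, half + 1))[None, :] * config.detector_pixel_pitch
    grain = np.exp(-(gr**2 + gc**2) / w_field**2)
    grain /= grain.sum()
    out = fftconvolve(out, grain, mode="same")
    peak = out.max()
    if peak > 0:
        out = out / peak
    return CorrelationMap(
        values=out,
        lag_pitch=config.detector_pixel_pitch,
        kind="auto",
        window="none",
        normalization="raw",
        meta={"predicted": True},
    )


def map_similarity(map_a: CorrelationMap, map_b: CorrelationMap, crop_half_px: Optional[int] = None) -> float:
    """Pearson r between two lag maps after an optional central crop.

    Both maps are compared up to an affine scale, which is exactly what the
    proportionality in the autocorrelation prediction leaves undetermined.
    """
    a, b = map_a.values, map_b.values
    if a.shape != b.shape:
        raise ValueError("maps must share a lag grid")
    if crop_half_px is not None:
        a = map_a.central_crop(crop_half_px)
        b = map_b.central_crop(crop_half_px)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("degenerate map in similarity computation")
    return float((a * b).sum() / denom)
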