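"""Optical-memory-effect kernel and object/detector geometry.

A thin, strongly scattering layer scrambles light from a hidden scene into a
speckle pattern, but the scrambling is shift-correlated: tilting the
illumination of the layer by a small angle shifts the transmitted speckle
while largely preserving its structure (the optical memory effect).  For an
incoherently emitting point at lateral position ``x_o`` a distance ``L_o``
behind the layer, and a detector a distance ``L_s`` in front of it, the
intensity correlation between the speckles of two points separated by
``Δx_o`` evaluated at detector lag ``Δx_d`` is modelled as

    C(Δx_o, Δx_d) = exp(−k² |Δθ_o − Δθ_d|² σ²) · (x / sinh x)²,
    x = k |Δθ_o| L,   Δθ_o = Δx_o / L_o,   Δθ_d = Δx_d / L_s,

with ``k = 2π/λ`` the wavenumber, ``σ`` the Gaussian width of the beam
illuminating the layer, and ``L`` the layer thickness.  The first factor is
sharply peaked where the detector lag matches the geometrically scaled
object lag (it sets the speckle grain, i.e. the resolution); the second is
the memory-effect envelope that decays with the angular separation of the
two source points and defines the isoplanatic patch.

Geometry is pinhole-like: an object-plane displacement ``d`` maps to a
detector-plane displacement ``−d · L_s/L_o`` (axes reversed).  The sign
reversal is carried by the ``flip_axes`` convention flag.

Units: lengths in mm throughout; angles dimensionless (radians).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "OpticalConfig",
    "MemoryKernel",
    "UndersampledError",
    "memory_envelope",
    "kernel_value",
    "object_to_detector_shift",
    "detector_to_object_shift",
    "expected_grain_diameter",
    "load_config",
    "save_config",
]

#: sinh overflows float64 near x ~ 710; the envelope there is < 1e-300.
_SINH_GUARD = 700.0


class UndersampledError(ValueError):
    """Raised when the detector pixel pitch cannot resolve a speckle grain."""


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and illumination of the scattering experiment.

    Defaults reproduce the reference transmission geometry: a He-Ne source
    (λ = 632.8 nm), object plane 430 mm behind the scattering layer, camera
    50 mm in front of it, ~0.1 mm thick layer, 1 mm illumination width.
    ``object_pixel_pitch`` defaults to ``detector_pixel_pitch · L_o/L_s`` so
    one object-plane pixel maps onto exactly one detector pixel.

    All lengths in mm.
    """

    wavelength: float = 632.8e-6
    sigma: float = 1.0
    L: float = 0.1
    L_o: float = 430.0
    L_s: float = 50.0
    detector_pixel_pitch: float = 3.75e-3
    object_pixel_pitch: float = 3.75e-3 * 430.0 / 50.0
    flip_axes: bool = True

    def __post_init__(self) -> None:
        for name in (
            "wavelength",
            "sigma",
            "L",
            "L_o",
            "L_s",
            "detector_pixel_pitch",
            "object_pixel_pitch",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def k(self) -> float:
        """Wavenumber 2π/λ (1/mm)."""
        return 2.0 * math.pi / self.wavelength

    @property
    def magnification(self) -> float:
        """|detector shift| / |object shift| = L_s / L_o."""
        return self.L_s / self.L_o

    @property
    def shift_sign(self) -> int:
        """−1 under the pinhole axis reversal, +1 otherwise."""
        return -1 if self.flip_axes else 1

    @property
    def grain_field_width(self) -> float:
        """1/e half-width (mm) of the speckle *field* correlation on the
        detector, L_s/(kσ); the intensity correlation is its square."""
        return self.L_s / (self.k * self.sigma)

    def with_coupled_pitches(self) -> "OpticalConfig":
        """Return a copy whose object pitch maps 1:1 onto detector pixels."""
        return replace(
            self, object_pixel_pitch=self.detector_pixel_pitch * self.L_o / self.L_s
        )


def memory_envelope(x):
    """Memory-effect envelope (x/sinh x)² for x = k·|Δθ|·L.

    Continuous at 0 (value 1), strictly decreasing, and 0 beyond the sinh
    overflow guard where the true value is below 1e-300.  Accepts scalars or
    arrays; the absolute value of the input is taken.
    """
    x = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    ok = x < _SINH_GUARD
    xs = np.where(ok, x, 1.0)
    ratio = np.divide(xs, np.sinh(xs), out=np.ones_like(xs), where=xs > 0)
    out[ok] = (ratio**2)[ok]
    out[x == 0] = 1.0
    if out.ndim == 0:
        return float(out)
    return out


def kernel_value(dx_o, dx_d, config: OpticalConfig):
    """Speckle intensity correlation C(Δx_o, Δx_d) ∈ [0, 1].

    ``dx_o`` and ``dx_d`` are lag vectors (mm) whose last axis has length 2;
    broadcasting over leading axes is supported.  Normalised so
    C(0, 0) = 1; maximal over ``dx_d`` at the matched lag
    ``dx_d = dx_o · L_s/L_o``.
    """
    dx_o = np.asarray(dx_o, dtype=float)
    dx_d = np.asarray(dx_d, dtype=float)
    theta_o = dx_o / config.L_o
    theta_d = dx_d / config.L_s
    dtheta2 = np.sum((theta_o - theta_d) ** 2, axis=-1)
    gauss = np.exp(-((config.k * config.sigma) ** 2) * dtheta2)
    x = config.k * np.sqrt(np.sum(theta_o**2, axis=-1)) * config.L
    value = gauss * memory_envelope(x)
    if np.ndim(value) == 0:
        return float(value)
    return value


def object_to_detector_shift(d_obj, config: OpticalConfig) -> np.ndarray:
    """Map an object-plane displacement (mm) to the detector plane.

    Exact linear map s · d · L_s/L_o with s = −1 when ``flip_axes``.
    """
    return np.asarray(d_obj, dtype=float) * (config.shift_sign * config.magnification)


def detector_to_object_shift(d_det, config: OpticalConfig) -> np.ndarray:
    """Inverse of :func:`object_to_detector_shift` (includes the un-flip)."""
    return np.asarray(d_det, dtype=float) * (config.shift_sign / config.magnification)


def expected_grain_diameter(config: OpticalConfig, illuminated_diameter: float) -> float:
    """Characteristic speckle grain λ·L_s/D for illuminated spot diameter D (mm).

    Raises :class:`UndersampledError` when the grain spans fewer than two
    detector pixels, i.e. the simulation cannot resolve the speckle.
    """
    if illuminated_diameter <= 0:
        raise ValueError("illuminated_diameter must be > 0")
    grain = config.wavelength * config.L_s / illuminated_diameter
    if grain < 2.0 * config.detector_pixel_pitch:
        raise UndersampledError(
            f"speckle grain {grain:.3g} mm < 2 detector pixels "
            f"({2 * config.detector_pixel_pitch:.3g} mm): undersampled"
        )
    return grain


@dataclass(frozen=True)
class MemoryKernel:
    """Closed-form correlation kernel bound to a geometry.

    Convenience wrapper around the module-level functions; also exposes the
    Siegert link between field and intensity correlations used by the
    statistical speckle synthesiser (intensity correlation = |field
    correlation|² for circular Gaussian fields), and the on-diagonal grain
    profile used when predicting autocorrelations.  Correlations follow the
    mean-subtracted convention δS = S − S̄ normalised to C(0, 0) = 1.
    """

    config: OpticalConfig

    def envelope(self, x):
        return memory_envelope(x)

    def value(self, dx_o, dx_d):
        return kernel_value(dx_o, dx_d, self.config)

    def matched(self, dx_o):
        """C at the matched detector lag: the pure memory envelope of Δx_o."""
        dx_o = np.asarray(dx_o, dtype=float)
        x = (
            self.config.k
            * np.sqrt(np.sum(dx_o**2, axis=-1))
            * self.config.L
            / self.config.L_o
        )
        return memory_envelope(x)

    def field_correlation_matched(self, dx_o):
        """Field correlation at matched lag, √C (Siegert relation)."""
        return np.sqrt(self.matched(dx_o))

    def grain_profile(self, dx_d):
        """Intensity-correlation profile vs detector lag at Δx_o = 0."""
        dx_d = np.asarray(dx_d, dtype=float)
        dtheta2 = np.sum((dx_d / self.config.L_s) ** 2, axis=-1)
        return np.exp(-((self.config.k * self.config.sigma) ** 2) * dtheta2)

    def half_range_object_mm(self) -> float:
        """Object-plane separation where the envelope drops to 1/2.

        Solves (x/sinh x)² = 1/2 numerically once; a practical definition of
        the memory range used by the tracking fixtures.
        """
        from scipy.optimize import brentq

        x_half = brentq(lambda x: memory_envelope(x) - 0.5, 1e-9, 10.0)
        return x_half * self.config.L_o / (self.config.k * self.config.L)


# ---------------------------------------------------------------------------
# Flat key-value config files

_CONFIG_KEYS = {
    "wavelength_mm": ("wavelength", float),
    "sigma_mm": ("sigma", float),
    "L_mm": ("L", float),
    "L_o_mm": ("L_o", float),
    "L_s_mm": ("L_s", float),
    "object_pitch_mm": ("object_pixel_pitch", float),
    "detector_pitch_mm": ("detector_pixel_pitch", float),
    "flip_axes": ("flip_axes", None),  # parsed as bool
}

_FIELD_TO_KEY = {field: key for key, (field, _) in _CONFIG_KEYS.items()}


def _parse_bool(text: str) -> bool:
    lowered = text.strip().lower()
    if lowered in {"true", "1", "yes", "on"}:
        return True
    if lowered in {"false", "0", "no", "off"}:
        return False
    raise ValueError(f"cannot parse boolean from {text!r}")


def load_config(path) -> OpticalConfig:
    """Read an :class:`OpticalConfig` from a flat ``key = value`` text file.

    Recognised keys: wavelength_mm, sigma_mm, L_mm, L_o_mm, L_s_mm,
    object_pitch_mm, detector_pitch_mm, flip_axes.  Unknown keys are an
    error; missing keys keep their defaults.  Lines starting with ``#`` are
    comments.
    """
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        field, caster = _CONFIG_KEYS[key]
        kwargs[field] = _parse_bool(raw) if caster is None else caster(raw)
    return OpticalConfig(**kwargs)


def save_config(config: OpticalConfig, path) -> None:
    """Write the flat key-value representation of ``config``."""
    lines = ["# speckletrack optical geometry (lengths in mm)"]
    for field, key in _FIELD_TO_KEY.items():
        value = getattr(config, field)
        if isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")
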