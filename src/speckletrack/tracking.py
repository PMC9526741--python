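"""Turn differential correlation maps into object-plane trajectories.

A differential map ``XC(t1, t0) − AC(t1)`` shows motion from the moving
object's own frame of reference: for every static neighbour within the
memory range there is a positive lobe at the lag the mover occupied relative
to that neighbour at t0 and a negative lobe at the lag it occupies at t1.
The vector from a paired positive lobe to its negative partner is therefore
the detector-plane displacement of the mover; mapped back through the
pinhole geometry it is the object-plane step.  Because the autocorrelation
of a real image is centrosymmetric only *relative* motion is observable;
chaining per-step displacements — each referenced to whatever static objects
are currently nearby — tracks total motion far beyond the memory range
("mosaicing" it).

Robustness choices: noise is estimated as 1.4826 × MAD outside a central
exclusion disk (the residual self-term region), lobes are paired by nearest
neighbour with an amplitude-ratio gate, per-step displacement is the
component-wise median over accepted lobe pairs, and the reference frame for
each step is chosen among candidate lags to maximise the top-feature SNR
(small motions show up better against an older reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .correlations import CorrelationMap, differential_correlation
from .optics_model import OpticalConfig, detector_to_object_shift

__all__ = [
    "MotionFeature",
    "Trajectory",
    "TrackingParams",
    "robust_noise",
    "extract_motion_features",
    "estimate_displacement",
    "choose_reference_lag",
    "build_trajectory",
    "estimate_rotation",
    "save_trajectory",
]


@dataclass(frozen=True)
class MotionFeature:
    """A paired +/− lobe in a differential map.

    Lobe positions are (row, col) lags in map pixels relative to zero lag,
    sub-pixel refined where possible; ``displacement_det`` is the
    negative-lobe position minus the positive-lobe position, in mm.
    """

    positive_lobe_px: tuple
    negative_lobe_px: tuple
    positive_amplitude: float
    negative_amplitude: float
    displacement_det: tuple  # mm, detector plane
    snr: float
    refined: bool = True

    def __post_init__(self) -> None:
        if not (self.positive_amplitude > 0 > self.negative_amplitude):
            raise ValueError("lobe amplitudes must straddle zero")


@dataclass
class TrackingParams:
    """Knobs of the lobe detector and trajectory builder."""

    threshold_sigma: float = 5.0
    max_features: int = 6
    exclusion_radius_px: float = 6.0  # ~3 speckle grains: residual self-term
    search_radius_px: float | None = None  # default: quarter of the frame size
    max_pair_px: float = 25.0
    amplitude_ratio_gate: tuple = (1.0 / 3.0, 3.0)
    candidate_lags: tuple = (1, 2, 5)
    min_snr: float = 5.0
    window: str = "none"
    normalize: str = "coeff"


@dataclass(frozen=True)
class Trajectory:
    """Chained per-step object-plane displacements.

    ``steps[i]`` is the displacement (row, col mm) from frame i to frame
    i+1; ``cumulative`` is its exact prefix sum (N rows, starting at zero).
    ``reference_lags[i]`` records which earlier frame step i was measured
    against (None = no motion detected), ``quality`` the step SNR.
    """

    times: tuple
    steps: np.ndarray
    cumulative: np.ndarray
    reference_lags: tuple
    quality: tuple
    valid: tuple

    def __post_init__(self) -> None:
        expected = np.vstack([np.zeros(2), np.cumsum(self.steps, axis=0)])
        if not np.array_equal(expected, self.cumulative):
            raise ValueError("cumulative must be the exact prefix sum of steps")


def _search_radius(cmap: CorrelationMap, search_radius_px) -> float:
    if search_radius_px is not None:
        return float(search_radius_px)
    frame_n = (min(cmap.values.shape) + 1) // 2
    return frame_n / 4.0


def _annulus_mask(cmap: CorrelationMap, r_in: float, r_out: float) -> np.ndarray:
    cr, cc = cmap.center
    rr = np.arange(cmap.values.shape[0])[:, None] - cr
    cc_ = np.arange(cmap.values.shape[1])[None, :] - cc
    d2 = rr**2 + cc_**2
    return (d2 > r_in**2) & (d2 <= r_out**2)


def robust_noise(
    cmap: CorrelationMap,
    exclusion_radius_px: float = 6.0,
    search_radius_px: float | None = None,
) -> float:
    """1.4826 × median absolute deviation of the lag annulus searched for
    lobes (central exclusion disk removed).

    Restricting the sample to the search region matters because the linear
    correlation's overlap taper shrinks values toward the map edges; a
    whole-map MAD would understate the noise where the lobes actually live.
    """
    mask = _annulus_mask(cmap, exclusion_radius_px, _search_radius(cmap, search_radius_px))
    sample = cmap.values[mask]
    med = np.median(sample)
    return float(1.4826 * np.median(np.abs(sample - med)))


def _local_extrema(values: np.ndarray, threshold: float, mask: np.ndarray, size: int = 5):
    """(row, col, amplitude) of local maxima above threshold inside mask."""
    peak = (values == ndimage.maximum_filter(values, size=size)) & mask
    peak &= values > threshold
    rows, cols = np.nonzero(peak)
    amps = values[rows, cols]
    order = np.argsort(amps)[::-1]
    return [(int(rows[i]), int(cols[i]), float(amps[i])) for i in order]


def _parabolic_refine(values: np.ndarray, row: int, col: int):
    """3-point parabolic sub-pixel peak refinement per axis.

    Returns ((row, col) float, refined?) — falls back to the integer peak at
    map borders or when the local curvature is degenerate.
    """
    h, w = values.shape
    if not (0 < row < h - 1 and 0 < col < w - 1):
        return (float(row), float(col)), False
    out = [float(row), float(col)]
    ok = True
    for axis, idx in ((0, row), (1, col)):
        if axis == 0:
            y0, y1, y2 = values[row - 1, col], values[row, col], values[row + 1, col]
        else:
            y0, y1, y2 = values[row, col - 1], values[row, col], values[row, col + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom == 0.0:
            ok = False
            continue
        delta = 0.5 * (y0 - y2) / denom
        if abs(delta) <= 1.0:
            out[axis] = float(idx + delta)
        else:
            ok = False
    return (out[0], out[1]), ok


def extract_motion_features(
    cmap: CorrelationMap,
    threshold_sigma: float = 5.0,
    max_features: int = 6,
    exclusion_radius_px: float = 6.0,
    max_pair_px: float = 25.0,
    amplitude_ratio_gate: tuple = (1.0 / 3.0, 3.0),
    search_radius_px: float | None = None,
) -> list:
    """Detect and pair ± lobes in a differential map.

    Local extrema above ``threshold_sigma`` × robust noise (outside the
    central exclusion disk) are paired greedily: each negative lobe, in
    decreasing strength, takes the nearest unused positive lobe within
    ``max_pair_px`` whose amplitude magnitude is within the ratio gate.
    Returns at most ``max_features`` features sorted by strength; an empty
    list when nothing exceeds threshold.
    """
    if cmap.kind != "differential":
        raise ValueError(f"expected a differential map, got kind={cmap.kind!r}")
    sigma = robust_noise(cmap, exclusion_radius_px, search_radius_px)
    if sigma <= 0:
        return []
    values = cmap.values
    cr, cc = cmap.center
    mask = _annulus_mask(cmap, exclusion_radius_px, _search_radius(cmap, search_radius_px))
    thr = threshold_sigma * sigma
    pos = _local_extrema(values, thr, mask)
    neg = _local_extrema(-values, thr, mask)
    lo_gate, hi_gate = amplitude_ratio_gate
    features = []
    used_pos = set()
    for n_row, n_col, n_amp in neg:  # n_amp = |negative amplitude|
        best = None
        best_dist = max_pair_px
        for i, (p_row, p_col, p_amp) in enumerate(pos):
            if i in used_pos:
                continue
            ratio = p_amp / n_amp
            if not (lo_gate <= ratio <= hi_gate):
                continue
            dist = np.hypot(p_row - n_row, p_col - n_col)
            if dist <= best_dist:
                best_dist = dist
                best = i
        if best is None:
            continue
        used_pos.add(best)
        p_row, p_col, p_amp = pos[best]
        (prf, pcf), ok_p = _parabolic_refine(values, p_row, p_col)
        (nrf, ncf), ok_n = _parabolic_refine(-values, n_row, n_col)
        disp_px = (nrf - prf, ncf - pcf)
        features.append(
            MotionFeature(
                positive_lobe_px=(prf - cr, pcf - cc),
                negative_lobe_px=(nrf - cr, ncf - cc),
                positive_amplitude=p_amp,
                negative_amplitude=-n_amp,
                displacement_det=(
                    disp_px[0] * cmap.lag_pitch,
                    disp_px[1] * cmap.lag_pitch,
                ),
                snr=min(p_amp, n_amp) / sigma,
                refined=ok_p and ok_n,
            )
        )
        if len(features) >= max_features:
            break
    features.sort(key=lambda f: min(f.positive_amplitude, -f.negative_amplitude), reverse=True)
    return features


def estimate_displacement(feature: MotionFeature, config: OpticalConfig) -> np.ndarray:
    """Object-plane step (row, col mm) of the mover, relative motion only.

    The detector-plane lobe separation maps back through the pinhole
    geometry (scale L_o/L_s, axes un-flipped).  Absolute position is
    unobservable — centrosymmetry of autocorrelations only ever exposes
    motion relative to the static background at the reference time.
    """
    return detector_to_object_shift(np.asarray(feature.displacement_det), config)


@dataclass(frozen=True)
class StepEstimate:
    """Consensus object-plane step extracted from one differential map."""

    step_mm: np.ndarray
    snr: float
    n_support: int
    features: list


def estimate_step(
    cmap: CorrelationMap,
    config: OpticalConfig,
    params: Optional[TrackingParams] = None,
) -> Optional[StepEstimate]:
    """Robust single-mover step estimate from a differential map.

    Combines two kinds of evidence, each a hypothesis for the object-plane
    step: (a) every paired ± lobe (displacement = negative minus positive
    lobe position, mapped through the geometry) and (b) the strongest
    unpaired positive lobe — the mover's own t0⋆t1 cross-term, which sits at
    exactly the step lag (its negative partner is the excluded zero-lag
    well).  Hypotheses vote in displacement space; the SNR-weighted mean of
    the largest cluster wins.  Returns None when nothing exceeds threshold.
    """
    params = params or TrackingParams()
    features = extract_motion_features(
        cmap,
        threshold_sigma=params.threshold_sigma,
        max_features=params.max_features,
        exclusion_radius_px=params.exclusion_radius_px,
        max_pair_px=params.max_pair_px,
        amplitude_ratio_gate=params.amplitude_ratio_gate,
        search_radius_px=params.search_radius_px,
    )
    hypotheses = [
        (estimate_displacement(f, config), f.snr) for f in features
    ]
    self_hyp = _self_lobe_hypothesis(cmap, config, params)
    if self_hyp is not None:
        hypotheses.append(self_hyp)
    if not hypotheses:
        return None
    tol = 3.0 * config.object_pixel_pitch
    points = np.array([h[0] for h in hypotheses])
    weights = np.array([h[1] for h in hypotheses])
    best_score, best_idx = -1.0, 0
    for i in range(len(points)):
        inliers = np.linalg.norm(points - points[i], axis=1) <= tol
        score = weights[inliers].sum()
        if score > best_score:
            best_score, best_idx = score, i
    inliers = np.linalg.norm(points - points[best_idx], axis=1) <= tol
    step = (points[inliers] * weights[inliers, None]).sum(axis=0) / weights[
        inliers
    ].sum()
    return StepEstimate(
        step_mm=step,
        snr=float(weights[inliers].max()),
        n_support=int(inliers.sum()),
        features=features,
    )


def _self_lobe_hypothesis(
    cmap: CorrelationMap, config: OpticalConfig, params: TrackingParams
):
    """Step hypothesis from the mover's own t0⋆t1 positive lobe.

    The differential map's strongest positive extremum outside the central
    exclusion disk lies at detector lag (L_s/L_o)·step; no un-flip applies
    because the pinhole reversal acts on both frames alike.
    """
    sigma = robust_noise(cmap, params.exclusion_radius_px, params.search_radius_px)
    if sigma <= 0:
        return None
    values = cmap.values
    cr, cc = cmap.center
    mask = _annulus_mask(
        cmap, params.exclusion_radius_px, _search_radius(cmap, params.search_radius_px)
    )
    peaks = _local_extrema(values, params.threshold_sigma * sigma, mask)
    if not peaks:
        return None
    row, col, amp = peaks[0]
    (rf, cf), _ = _parabolic_refine(values, row, col)
    lag_mm = np.array([rf - cr, cf - cc]) * cmap.lag_pitch
    step = -detector_to_object_shift(lag_mm, config)
    return step, float(amp / sigma)


@dataclass(frozen=True)
class ReferenceChoice:
    lag: Optional[int]
    features: list
    snr: float
    estimate: Optional[StepEstimate] = None


def choose_reference_lag(
    history: Sequence,
    current_index: int,
    candidate_lags: Sequence[int],
    min_snr: float = 5.0,
    config: Optional[OpticalConfig] = None,
    params: Optional[TrackingParams] = None,
) -> ReferenceChoice:
    """Pick the past frame whose differential map shows motion best.

    Computes the differential map of the current frame against each
    candidate lag and returns the lag with the strongest top feature; a
    ``lag=None`` choice flags that nothing moved detectably (all candidates
    below ``min_snr``).
    """
    params = params or TrackingParams()
    feasible = [lag for lag in candidate_lags if 1 <= lag <= current_index]
    if not feasible:
        raise ValueError("no candidate lag fits inside the history")
    best = ReferenceChoice(lag=None, features=[], snr=0.0)
    for lag in feasible:
        dmap = differential_correlation(
            history[current_index],
            history[current_index - lag],
            window=params.window,
            normalize=params.normalize,
        )
        est = estimate_step(dmap, config or OpticalConfig(), params)
        if est is not None and est.snr >= min_snr and est.snr > best.snr:
            best = ReferenceChoice(
                lag=lag, features=est.features, snr=est.snr, estimate=est
            )
    return best


def build_trajectory(
    frames: Sequence,
    config: OpticalConfig,
    params: Optional[TrackingParams] = None,
) -> Trajectory:
    """Chain per-step displacements across a frame stack.

    Each frame is compared against the adaptive reference lag; the step
    estimate is the component-wise median over the accepted lobe pairs
    (robust to an occasional mis-paired self-lobe).  Steps with no feature
    above threshold contribute zero displacement; failing steps are marked
    invalid without aborting the track.  The cumulative track may exceed the
    memory range even though every individual step stays within it.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    params = params or TrackingParams()
    n = len(frames)
    cumulative = np.zeros((n, 2))
    steps = np.zeros((n - 1, 2))
    lags: list = []
    quality: list = []
    valid: list = []
    for i in range(1, n):
        try:
            choice = choose_reference_lag(
                frames, i, params.candidate_lags, params.min_snr, config, params
            )
        except Exception:
            lags.append(None)
            quality.append(0.0)
            valid.append(False)
            cumulative[i] = cumulative[i - 1]
            steps[i - 1] = 0.0
            continue
        if choice.lag is None or choice.estimate is None:
            cumulative[i] = cumulative[i - 1]
            steps[i - 1] = 0.0
            lags.append(None)
            quality.append(choice.snr)
            valid.append(True)
            continue
        step_total = choice.estimate.step_mm
        cumulative[i] = cumulative[i - choice.lag] + step_total
        steps[i - 1] = cumulative[i] - cumulative[i - 1]
        lags.append(choice.lag)
        quality.append(choice.snr)
        valid.append(True)
    # rebuild cumulative as the exact prefix sum (guards float bookkeeping)
    cumulative = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return Trajectory(
        times=tuple(range(n)),
        steps=steps,
        cumulative=cumulative,
        reference_lags=tuple(lags),
        quality=tuple(quality),
        valid=tuple(valid),
    )


def estimate_rotation(
    map_a: CorrelationMap,
    map_b: CorrelationMap,
    max_deg: float = 45.0,
    r_in_px: float = 5.0,
    r_out_px: float = 30.0,
    highpass_px: float = 2.5,
    dphi_deg: float = 0.5,
) -> float:
    """Rotation angle (deg, CCW) that best maps map_b onto map_a.

    A rotating sub-object rotates its own autocorrelation features about
    zero lag.  Both maps are high-pass filtered (difference of Gaussians,
    scale ``highpass_px``) to isolate the sharp object-correlation copy from
    the smooth speckle pedestal that the two frames share, unwrapped onto a
    polar (radius, azimuth) grid over the annulus [r_in_px, r_out_px], and
    circularly cross-correlated along azimuth with per-radius mean removal;
    the summed correlation peak, parabolically refined, is the angle.
    Centrosymmetry makes the angle meaningful modulo 180°; keep ``max_deg``
    well inside ±90°.
    """
    from scipy.ndimage import gaussian_filter, map_coordinates

    va = map_a.values - gaussian_filter(map_a.values, highpass_px)
    vb = map_b.values - gaussian_filter(map_b.values, highpass_px)
    radii = np.arange(r_in_px, r_out_px + 1.0)
    phis = np.deg2rad(np.arange(0.0, 360.0, dphi_deg))
    rows_a = map_a.center[0] + radii[:, None] * np.sin(phis[None, :])
    cols_a = map_a.center[1] + radii[:, None] * np.cos(phis[None, :])
    A = map_coordinates(va, [rows_a, cols_a], order=1)
    B = map_coordinates(vb, [rows_a, cols_a], order=1)
    A -= A.mean(axis=1, keepdims=True)
    B -= B.mean(axis=1, keepdims=True)
    fa = np.fft.rfft(A, axis=1)
    fb = np.fft.rfft(B, axis=1)
    score = np.fft.irfft(np.conj(fa) * fb, n=A.shape[1], axis=1).sum(axis=0)
    shifts = np.arange(A.shape[1]) * dphi_deg
    shifts = np.where(shifts > 180.0, shifts - 360.0, shifts)
    allowed = np.abs(shifts) <= max_deg
    idx = int(np.argmax(np.where(allowed, score, -np.inf)))
    best = float(shifts[idx])
    y0, y1, y2 = score[idx - 1], score[idx], score[(idx + 1) % len(score)]
    denom = y0 - 2.0 * y1 + y2
    if denom != 0.0:
        best += 0.5 * float(y0 - y2) / float(denom) * dphi_deg
    return best


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a delimited-text trajectory table.

    Columns: frame, dx_mm, dy_mm, cum_x_mm, cum_y_mm, ref_lag, snr — with
    x = +col and y = −row (y up), one row per tracked step.
    """
    lines = ["frame\tdx_mm\tdy_mm\tcum_x_mm\tcum_y_mm\tref_lag\tsnr"]
    for i in range(1, len(traj.times)):
        step = traj.steps[i - 1]
        cum = traj.cumulative[i]
        lag = traj.reference_lags[i - 1]
        lines.append(
            "\t".join(
                [
                    str(traj.times[i]),
                    f"{step[1]:.6g}",
                    f"{-step[0]:.6g}",
                    f"{cum[1]:.6g}",
                    f"{-cum[0]:.6g}",
                    "" if lag is None else str(lag),
                    f"{traj.quality[i - 1]:.3g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
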