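# Methods

## Model

A hidden scene on an object plane a distance `L_o` behind a thin, strongly
scattering layer emits (or reflects) spatially incoherent, narrow-band
light; a bare detector sits `L_s` in front of the layer. Each object point
produces a fully developed speckle pattern on the detector, and with low
spatial coherence the per-point patterns add in intensity with no
interference cross-terms, so the forward model is linear in the scene
intensity `O(x_o)`.

Two object points separated by `Δx_o` produce correlated speckles. We model
the intensity correlation as

    C(Δx_o, Δx_d) = exp(−k² |Δθ_o − Δθ_d|² σ²) · (x / sinh x)²,
    x = k |Δθ_o| L,  Δθ_o = Δx_o/L_o,  Δθ_d = Δx_d/L_s,

normalised to `C(0,0) = 1`. The Gaussian factor is the speckle grain (set by
the width `σ` of the illumination on the layer — the diffraction limit of
the measurement); the `(x/sinh x)²` factor is the memory-effect envelope,
decaying with the *angular* separation of the sources and the layer
thickness `L`, and defines the isoplanatic patch. The argument of the
Gaussian factor is interpreted in angular coordinates (`Δθ_o − Δθ_d`); this
makes the exponent dimensionless and puts the correlation peak at the
matched lag `Δx_d = Δx_o·L_s/L_o`, consistent with the geometric scale
factor between planes. That unit convention is a documented modelling
choice. Geometry is pinhole-like: displacements map with scale `L_s/L_o`
and reversed axes (`flip_axes=True` by default); all proportionality
constants are absorbed into one fitted scale when comparing maps.

## Forward simulation

**Physical backend.** A point source illuminates a single random-phase
screen (paraxial spherical wave within a Gaussian spot), and the field is
propagated to the detector by a band-limited angular-spectrum transfer
function. This produces fully developed speckle (contrast ≈ 1) whose
memory shift obeys `−d·L_s/L_o` essentially exactly — a thin screen barely
decorrelates with tilt — so it serves as the oracle for speckle statistics
and the geometric shift law, not for finite-memory studies. Scenes render
as explicit per-lit-pixel sums (exact linearity).

**Statistical backend.** To emulate a *finite* memory range the synthesiser
imposes the kernel directly. Speckle *fields* are zero-mean circular
Gaussian arrays generated as spectrally filtered white noise on the FFT
grid (Gaussian spectrum chosen so the intensity autocorrelation equals the
kernel's grain factor; fields are periodic, making shifts and convolutions
circular and exact). Intensity correlations follow from field correlations
by the Siegert relation `C = ρ²`, so the target field correlation between
two source positions is `√envelope`. Each *sub-object anchor position*
gets one field node; a new node is drawn by exact Gaussian conditioning on
all existing nodes (solve `R w = r`, add a fresh residual field of variance
`1 − rᵀw`). If the requested structure is not positive semi-definite the
residual is clipped at zero and a warning is emitted (nearest feasible
field). A sub-object's detector contribution is the circular convolution
of its node's speckle intensity with its geometrically mapped footprint —
i.e. the memory effect is taken as exactly rigid *across* one small sprite,
while decorrelation between sub-objects (and between a mover's successive
positions) follows the envelope of their anchor separation. This costs one
`O(n_nodes)` solve per node and three FFTs per sub-object per frame, and
makes static sub-objects render bit-identically across frames, as a static
scene behind a static screen should. Realised pairwise correlations are
measured, not assumed; on a 10-point separation sweep they match the
envelope to ~0.01 (tested against a ±0.1 bound).

**Camera noise** is Poisson shot noise on scaled counts plus Gaussian read
noise, rounded and clipped to the bit depth (8/12/16), deterministic per
seed. Exposure metadata defaults to 3 s; intra-frame motion blur is not
simulated.

## Correlation pipeline

All correlations are linear (zero-padded to `2N−1`, zero lag at the centre
index `(N−1, N−1)`), never circular — frames are not periodic and circular
wrap-around would fabricate lobes. Intensities are mean-subtracted first
(the `δS = S − S̄` convention); without this the DC term swamps everything.
An optional Tukey window (α = 0.25) tames edge artefacts; all identity- and
oracle-based tests run unwindowed. Normalisation is either raw sums or
"coeff" (divide by the product of input norms). The differential map is
computed as `XC − AC` through one shared code path, so identical frames
cancel bit-exactly, and under "coeff" both terms share the denominator
`‖Ĩ₁‖·‖Ĩ₀‖` so the static-background cancellation survives normalisation.

The prediction `[O⋆O]⊗C` is computed by weighting the object
autocorrelation with the memory envelope at each object-plane lag,
rescaling by `L_s/L_o` onto detector lag pixels, and blurring with the
grain profile; it is defined up to a positive scale and compared to
measurements by Pearson correlation over a central crop.

## Tracking

Lobes are local extrema above `threshold_sigma` × robust noise, where the
noise is 1.4826 × MAD over the *searched central annulus* (default outer
radius: a quarter of the frame; inner exclusion disk: 6 px ≈ 3 grains for
the residual self-term). Restricting the noise sample to the search region
matters: the linear correlation's overlap taper shrinks values toward the
map edges, and a whole-map MAD would understate the noise where lobes live
(enough to produce false 5σ detections on static scenes). Negative lobes
are paired greedily with the nearest unused positive lobe within
`max_pair_px`, gated by amplitude ratio (|A⁺/A⁻| ∈ [1/3, 3], as
intensity-conserving motion makes paired lobes comparable).

The per-step displacement is a consensus estimate: every lobe pair
contributes a hypothesis (negative minus positive position, mapped through
the geometry), and so does the strongest unpaired positive lobe — the
mover's own `o(t₀)⋆o(t₁)` cross-term, which sits exactly at the step lag
(its partner is the excluded zero-lag well). Hypotheses vote within a 3-px
radius; the SNR-weighted mean of the winning cluster is the step. This
consensus-of-modes rule replaces a plain median over pairs, which proved
fragile against occasional mis-paired noise lobes; the median is recovered
when all pairs agree. Sub-pixel lobe positions come from a 3-point
parabolic fit per axis (integer fallback at map borders, flagged). A
caveat of peak-reading: when the step is comparable to the lobe width the
overlapping ± lobes bias each other's extrema; fixtures therefore use
steps larger than the lobe width, and the self-lobe hypothesis (whose
partner is excluded) is unbiased for translation.

The reference frame for each step is chosen among candidate lags
({1, 2, 5} by default) to maximise the consensus SNR — an object that
barely moved since the last frame shows up better against an older
reference. Steps with nothing above `min_snr` contribute zero displacement
(no-motion flag); the trajectory is the exact prefix sum of steps. Only
*relative* motion is observable (autocorrelations are centrosymmetric), so
trajectories are displacement chains, not absolute positions.

Rotation is estimated separately: both maps are high-pass filtered
(difference of Gaussians, 2.5 px) to isolate the sharp object-correlation
copy from the smooth speckle pedestal that two frames of the same screen
share, unwrapped to polar coordinates, and circularly correlated along
azimuth with per-radius mean removal; the refined peak is the angle
(defined modulo 180° by centrosymmetry). Without the high-pass the shared
pedestal drags the estimate toward zero.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `wavelength` | 632.8e-6 mm | He-Ne line |
| `L_o`, `L_s` | 430 mm, 50 mm | object/detector distances (scale factor 50/430) |
| `sigma` | 1 mm | illumination width → grain ≈ 2.2 px FWHM on the detector |
| `L` | 0.1 mm | layer thickness; memory half-range ≈ 20 object px at the default pitch |
| `detector_pixel_pitch` | 3.75e-3 mm | camera pixel |
| `object_pixel_pitch` | pitch·L_o/L_s | couples object px 1:1 to detector px |
| `threshold_sigma`, `min_snr` | 5 | detection thresholds in robust-noise units |
| `exclusion_radius_px` | 6 | central self-term exclusion (~3 grains) |

Tracking studies use `L = 0.065 mm` (memory half-range ≈ 31 px on a 256²
grid, about an eighth of the field of view — the regime of a couple of
sellotape layers) with a star moving 12 px/frame: each step is well inside
the memory range while ten steps (108 px) exceed 3× of it. The
displacement-recovery study uses `L = 0.01 mm` (wide isoplanatic patch) so
that random 15–40 px motions stay within range. The memory half-range is
*defined* throughout as the object-plane separation where the envelope
drops to 1/2.

## What the synthetic scenes do and do not emulate

The generators reproduce the structure of programmable test scenes: binary
sprites (disks, stars, rectangles) on a dark background, one or a few
movers over a static field, rigid sub-pixel motion with conserved total
intensity (required for the differential map's zero mean). They do not
model photometric calibration of a real display, parallax or volumetric
depth (depth enters only as apparent-size change), time-varying media, or
polarisation. Passing tests therefore demonstrate the correlation
machinery and its scaling laws under the stated statistical model of the
medium — not detector-specific artefacts of any particular experiment.

## Numerical choices and degenerate inputs

- Constant (zero-variance) frames raise a `DegenerateFrameError` rather
  than returning NaN maps.
- `memory_envelope` returns the analytic limit 1 at `x = 0` and exactly 0
  beyond the sinh overflow guard (`x > 700`, true value < 1e-300).
- Sprite resampling (rotation/scale/sub-pixel placement) is bilinear with
  renormalisation to the sprite's total intensity; frame sums are conserved
  to well under 1%.
- The undersampling guard rejects configurations whose expected grain
  `λL_s/D` spans fewer than two detector pixels.
- All randomness flows from one master seed through named substreams
  (scene, screen, noise), so components can be re-seeded independently and
  whole pipelines re-run bit-identically.

## Problem sizes

Studies run on 256² frames: 50-screen ensembles for the autocorrelation
prediction, 20 trials for displacement recovery, 10-frame tracks and
13-frame closed squares for trajectory chaining, and 20 noisy static
sequences for the false-positive rate. These sizes give speckle-noise
floors comfortably below the tested tolerances (e.g. realised correlations
within ~0.01 of target against a ±0.1 bound) while keeping any single
study in the tens of seconds.

## Known limitations

- The statistical backend treats each sub-object as rigid under the memory
  effect; very large objects spanning a substantial fraction of the memory
  range would need per-region nodes.
- Two movers with equal and opposite displacements can alias their lobe
  pairs; the consensus step estimator then reports the dominant cluster.
- Peak-reading displacement estimates degrade when the per-step motion is
  smaller than the lobe width (overlapping ± lobes); choose the reference
  lag (or frame rate) so steps exceed the lobe width.
- Absolute localisation is impossible in principle; only displacement
  chains relative to the static background are reported.
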