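# Methods

`sepmap` analyzes stimulus-evoked field potentials recorded by a dense
epidural electrode grid over sensory cortex, together with depth-resolved
laminar probe recordings, and ships a synthetic session generator so the
whole pipeline is testable with known ground truth. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic tests do and do not establish about real data.

## The evoked-response model

A surface evoked response is modeled as a sum of stereotyped components.
Each component (the early positive **P** and the delayed negative **N**,
developmental precursors of the adult P1/N1) is separable in space and time:

    v_c(x, t) = s · A · g(x) · p(t − L − j)

with polarity `s ∈ {+1, −1}`, peak amplitude `A` (μV), latency `L` (ms),
per-trial Gaussian latency jitter `j` (truncated at ±3 SD so P always
precedes N), a Gaussian temporal pulse `p` parameterized by its half-duration
at half maximum, and a spatial footprint `g` that is either an isotropic
Gaussian `exp(−d²/2σ²)` (optionally elongated along a chosen axis) or a
flat-top disk indicator `1{d ≤ R}`. White Gaussian sensor noise is added
per sample (a 1/f surrogate is available but off by default; nothing in the
analyses depends on noise color). Pulses are evaluated analytically at
sample times, so latencies and centers are placed with sub-sample /
sub-pixel precision.

This is deliberately not a volume-conductor model: it emulates the
*statistical geometry* of evoked maps (localized footprints, their areas,
relative displacements, trial noise), not biophysical voltages. Absolute
amplitudes are arbitrary (defaults 40 μV for P, 60 μV for N), since surface
amplitudes depend on electrode impedance and reference in ways the model
does not attempt to capture.

### Coordinate and angle conventions

The grid (default 6 rows × 10 columns, 400 μm pitch; hull 2.0 × 3.6 mm) is
mapped to a planar frame with **x increasing caudally and y increasing
medially**. Polar displacements between peaks use `r = √(x² + y²)`,
`θ = atan2(y, x)`: 0° is caudal, +90° medial, −90° lateral. The laminar
probe (default 16 sites, 50 μm spacing) is indexed from the most superficial
site, depths in μm below the surface.

### Default scenario calibration

The default bone-conduction (BC) scenario is keyed to the group-mean
geometry the analysis should recover: the N footprint center sits 339 μm
from the P center at −35° (caudolateral), the N half-maximum area is
1.11 mm², and the P area is set so that the P/N half-maximum disks at that
separation intersect in 76% of the P area and 48% of the N area
(P area = 1.11 · 0.48/0.76 ≈ 0.70 mm²).

The footprint scale is **not** set by the naive inversion
`σ = √(A / 2π ln 2)`. The pipeline applies a common average reference, which
subtracts the footprint's mean electrode gain `ḡ(σ)` from every channel; the
mapped field is then `G(x) − ḡ` and its half-maximum region is
`{G ≥ (1+ḡ)/2}`, with area `2πσ² ln(2/(1+ḡ))`. For σ ≈ 500 μm on this grid
`ḡ ≈ 0.16`, a ~22% area shrinkage — far from negligible. The generator
therefore inverts the reference-aware model by 1-D root finding
(`sigma_for_measured_area`), so the *measured* area equals the target; the
naive closed form remains available (`sigma_from_area`) and is exact for
un-referenced maps. The same reasoning is why disk footprints are used for
the overlap-fraction checks: a flat-top disk's half-maximum region is the
disk itself regardless of any constant offset, so disk radii can be solved
exactly from the circle-lens closed form (with `R_N/R_P = √(0.76/0.48)`
fixed, one radius determines both target fractions simultaneously).

The ASW (air-conducted shock wave) scenario displaces the P center 184 μm
from the BC P center. The group data show no preferred direction for that
offset, so the generator fixes an arbitrary one (55°); only the distance is
meaningful. ASW latencies are delayed 6.7 ms relative to BC. The ablation
scenario zeroes all component amplitudes before synthesis, leaving noise.

Developmental latencies follow `L(age) = a·e^{−b·(age − age₀)} + c`,
anchored at P8 (P: 42 ms, N: 62 ms; defaults a=30/42, b=0.25, c=12/20,
age₀=8) and relaxing toward near-adult values by P15–16. The functional form
matches the exponential trend the fitting stage estimates, so cohort
parameter-recovery tests are exact in the noise-free limit.

## Preprocessing

Fixed order, recorded in provenance: anti-aliased downsampling to 2 kHz
(zero-phase 8th-order Butterworth at 0.4 × target rate, so evoked latencies
are not biased by filter delay; DC is preserved) → epoching into 1.5 s
windows (0.5 s pre / 1.0 s post stimulus; 3000 samples at 2 kHz; events
without a full window are dropped and counted) → bad-channel replacement →
common average reference → per-trial baseline correction → trial average.

Bad channels are replaced *before* the average reference so a noisy channel
cannot contaminate the reference; replacement is the per-sample mean of the
channel's good 4-neighbors (edge and corner channels use the 2–3 neighbors
they have). Bad channels are user-declared; an optional automatic flagger
(per-channel RMS z-score > 5) exists but is off by default because no
principled universal criterion exists. Stimulus onsets from a trigger trace
are detected by threshold crossing with a refractory period to suppress
ringing.

## Topographic mapping

1. **Peak search.** P is the largest positive extremum across channels in
   its search window (default 10–80 ms); N is the most negative extremum
   after the P latency (default up to 300 ms). Latencies are refined by
   3-point parabolic interpolation (0.5 ms sampling cannot otherwise express
   sub-millisecond latency differences). A component must exceed
   `k × SD` of the pre-stimulus baseline of the averaged trace on its best
   channel, else the result is a legal "no response" (youngest ages,
   post-ablation). The default `k = 5` accounts for the extremum being the
   maximum over ~60 channels × a wide window (~10⁴ samples), whose expected
   pure-noise maximum is ≈ 4 SD; a 3-SD floor would flag noise as a response.
2. **Window maps.** Per channel, the mean amplitude in a ±1 ms window around
   the component latency. The window mean under-reads the peak by the
   analytic window-mean factor of the pulse — intentional and harmless,
   since maps are thresholded relative to their own peak.
3. **Interpolation.** A bicubic interpolating (not smoothing) spline over
   the electrode lattice, evaluated on the hull at a configurable step
   (default 10 μm; 1 μm as in the original workflow is supported but ~100×
   more pixels than needed — peak and area estimates converge far above it).
4. **Peak location.** The extremal pixel (argmax for P, argmin for N; ties
   broken row-major and logged) provides the peak amplitude. Reported
   coordinates are refined to the amplitude-weighted centroid of the
   half-maximum region around that pixel. The refinement matters: the
   interpolation error of any practical spline on 400-μm-sampled Gaussian
   fields (~0.2% of amplitude) exceeds the field's own curvature over the
   ±40 μm flat top, biasing the raw argmax by ~10 μm, while the centroid of
   the half-maximum contour is accurate to a few μm for symmetric footprints
   — the spatial analogue of the parabolic latency refinement. The raw
   argmax is available via `refine=False`.
5. **Half-width area.** Threshold at half the signed peak amplitude; keep
   the 4-connected component containing the peak pixel (disconnected
   satellite lobes are excluded — they are not part of the component's
   footprint); area = pixel count × step², in mm². Regions touching the map
   border are flagged truncated (area is then a lower bound).
6. **Overlap and displacement.** Pixel-set intersection of two regions on
   the same grid, reported as fractions of each area; polar (r, θ) offsets
   between refined peak locations. Coincident peaks give r = 0 with θ
   reported missing and excluded from circular statistics.

## Laminar analysis

The multiunit branch band-passes 0.25–4 kHz (zero-phase 4th-order
Butterworth), detects spikes as troughs below −k × robust SD (MAD/0.6745;
default k = 4.5, 1 ms refractory) and accumulates PSTHs in 5 ms half-open
bins `[left, right)`. Amplitude thresholding is a deliberate simplification
of template-based sorting: only multiunit activity is analyzed, not units.
At k = 4.5 the false-trigger rate on band-limited Gaussian noise is ~0.05/s
per channel — acceptable for PSTHs with hundreds of true spikes, but not
"zero"; raise k where purity matters.

The LFP branch low-passes and downsamples to 2 kHz (same path as the grid),
epochs, baseline-corrects and averages, then computes the one-dimensional
current source density as the negative second spatial difference
`CSD_i = −(φ_{i−1} − 2φ_i + φ_{i+1})/h²` at interior sites, dropping the two
edge sites (no Vaknin padding) and using unit conductivity (arbitrary output
units). Sinks are negative. Linear depth profiles map to zero, and any
depth-constant (volume-conducted) signal cancels exactly — the purpose of
the transform.

The synthetic laminar session uses a Ricker (Mexican-hat) depth profile for
the LFP — negative at the sink depth (default 450 μm, the thalamorecipient
layer), positive flanks — times the Gaussian pulse (latency 42 ms, matching
the surface P component), plus inhomogeneous-Poisson evoked spiking whose
rate peaks at the sink depth (σ = 120 μm, peak 120 Hz over 1 Hz baseline)
with a biphasic extracellular waveform and 1.5 ms refractory.

## Statistics

* **Rayleigh test** of circular uniformity: `R̄ = |Σe^{iθ}|/n`, `Z = nR̄²`,
  p from the standard series approximation
  `e^{−Z}[1 + (2Z − Z²)/4n − (24Z − 132Z² + 76Z³ − 9Z⁴)/288n²]`, clipped to
  (0, 1]. Validated against a 10⁵-draw Monte-Carlo uniform null at n = 23
  and cross-checked against an independent implementation.
* **Circular mean ± SEM** via Fisher's dispersion estimate
  `δ̂ = (1 − ρ̂₂)/2ρ̂₁²`, `SEM = √(δ̂/n)`.
* **Spearman** rank correlation with mid-rank ties; two-sided p by the
  t-approximation, replaced by exact permutation enumeration for n ≤ 9.
* **Wilcoxon rank-sum**, one-sided by default (designed for the
  high- vs low-threshold hearing-age group comparison): exact enumeration
  when n_A + n_B ≤ 20 without ties, else normal approximation with tie and
  continuity corrections.
* **Exponential trend fits** by least squares with a multi-start grid over
  the decay rate b (log-spaced 0.01–2/day plus b = 0), keeping the best SSE.
* Group summaries are mean ± SEM. All p-values are reported raw; the 0.05
  convention is never used to gate pipeline outputs, and no multiple-testing
  correction is applied.

## Problem sizes and numerical choices

Tests and the acceptance script simulate at 4 kHz with 4–10 trials per
noise-free scenario (averaging is only load-bearing under noise, where 44
trials — the typical real session — is the default), interpolate at 10 μm
(20 μm for disk-overlap checks), and run end to end in well under a minute.
Determinism: every stochastic element draws from a single `numpy` Generator
seeded from the scenario config, so identical configs give bit-identical
recordings and reports.

## What the synthetic tests do not show

The generator's footprints are unimodal and (by default) isotropic; real
N components spread anisotropically (caudolaterally) and real maps contain
correlated, non-Gaussian noise, electrode artifacts, and overlapping
components. Parameter recovery on these synthetic sessions validates the
*analysis machinery* — that peaks, areas, overlaps, angles and statistics
are computed correctly at the claimed precision — not that the pipeline's
biological estimates from real recordings are unbiased. The window-mean
amplitude bias, the reference-induced area shrinkage, and the ~10 μm
argmax interpolation bias quantified above apply equally to real data and
are worth keeping in mind when comparing absolute areas across studies.

## Known limitations

No artifact/trial rejection, no line-noise filtering, no spike sorting into
units, no biophysical forward model, no anisotropy calibration (supported in
the generator, unparameterized), and the CSD uses unit conductivity without
edge padding, so its absolute scale is arbitrary.
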