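# Methods

## Scene geometry and the size–distance problem

A single tilted camera cannot separate an animal's physical size from its
distance using one detection alone: apparent area scales like r²/d².  What
makes the problem solvable over a video is that (i) every animal moves on
the *same* plane, whose geometry (tilt α, offset y₀, focal length f) is
shared across all tracks and frames, and (ii) each animal's apparent size
must remain consistent with a single radius as it moves through depth.  The
camera is placed at the origin looking along (−1, 0, 0); the plane is
y = −x·tan α − y₀ with 0 < α < π/2 and y₀ > 0.

Monocular scale is fundamentally unidentifiable, so y₀ only sets units: all
3D outputs are in multiples of y₀ unless a physical camera height is
supplied.  Throughout the synthetic scenes we use y₀ = 5; reading that as a
camera ~1.5 m above the ground makes one scene unit ≈ 0.3 m, a sphere
radius of 0.2–0.5 units a rat-sized body, and the default step scale
(below) a foraging walk of ~0.3 m/s.  Only *relative* sizes (normalized to
mean 1) are reported.

The sphere-silhouette area is computed in closed form,

    A = π f² r² √(d² − r²) / (x_c² − r²)^{3/2},

derived from the image conic of the tangent cone (a ray with direction
(−1, −v/f, u/f) is tangent when (dir·c)² = cos²θ |dir|² d², sin θ = r/d;
the determinant identities of the resulting 3×3 conic give the area).  The
tests verify this form against the numeric conic ellipse to ~1e−12 and
against a Monte-Carlo ray-counting oracle to < 1 %.  A `bbox` mode returns
the axis-aligned bounding-box area of the same ellipse instead, for
detector exports that report box rather than mask areas; the default is the
ellipse (mask-like) area.

Two printed conventions in the source material disagree on the order of
the in-plane coordinates (z first vs y/sin α first); both are isometries,
so `ground_coords` exposes an explicit `order` flag, defaulting to the
lateral-first order.

## The generative model and MAP inference

Latent per-animal paths follow a Gaussian random walk in (x, z) with
per-axis step sd σ₁ (a 2-vector; an isotropic choice is just equal
components); y is tied to the plane exactly.  Observations are the
projected pixel position plus N(0, σ₂² I₂) noise and the silhouette area
plus N(0, σ₃²) noise.  Hyperpriors: σ₁ ~ logNormal([0.5, 0.5], 0.3),
σ₂, σ₃ ~ logNormal(0.01, 0.01), where logNormal(m, s) here means the log
of the variable is N(m, s) — the convention is configurable because the
notation is ambiguous.  Note the σ₂, σ₃ hyperprior is *tight* (sd 0.01 in
log space, pinning the observation noises near e^0.01 ≈ 1.0 px / px²);
this is load-bearing: the joint MAP over paths and variances would
otherwise collapse σ₂ → 0 by interpolating the pixel observations exactly.

The remaining priors are this package's own defaults, chosen weakly
informative at the documented scene scale and fully overridable:
α ~ N(0.4, 0.2) rad, y₀ ~ N(5, 2), f ~ N(800, 300) px, sizes
Sᵢ ~ N(1, 1) (positive via log-parameterization), initial positions
x₀ ~ N(−15, 30), z₀ ~ N(0, 30).

MAP estimation maximizes the exact joint log-density with analytically
derived gradients (the projection and area derivatives are short closed
forms; the random-walk block is tridiagonal).  Positivity is enforced by
optimizing log tan α, log y₀, log f, log Sᵢ, log σ and log(−x); the
optimum is reported in the original parameterization without Jacobian
terms, i.e. a constrained-space MAP.  The optimizer is L-BFGS-B
(memory 50, up to 10⁴ iterations, paths initialized by back-projecting
the observed pixels under the prior-mean camera, sizes by inverting the
far-field area law).  L-BFGS is deterministic, so a fit is bit-reproducible
given its inputs; the `seed` only drives optional init jitter (default
off).  Convergence is flagged from the loss-trace tail (relative drop
< 1e−5 over the final window); long fits may report `converged=False`
while all recovered quantities are already stable — the flag is
deliberately strict.  Occlusion gaps are marginalized exactly: a
transition across g missing frames has variance g·σ₁².

Sizes Sᵢ are sphere radii in scene units.  The source conventions are
ambiguous between radius-like and area-like "size"; radii are used
consistently in both the generator and the fit, and relative sizes are
radius ratios with mean 1 (`normalize_sizes`, with an optional
outlier-exclusion rule so a single squirrel-sized intruder does not shift
"the average rat").

## Synthetic study conditions

`simulate_tracks` is the model's own forward process, with defaults fixed
at the study scale: 8 animals, 600 frames at 30 fps, camera
(α = 0.35 rad, y₀ = 5, f = 800 px), occlusion dropout 5 %, entries/exits
off by default (a per-frame exit probability and Poisson re-entry emulate
"more tracklets than true animals" when enabled).  Noise: σ₂ = σ₃ = 1.0
(the scale the σ hyperpriors center on).  The true step sd σ₁ is not
something the hyperprior pins down — its median e^0.5 ≈ 1.65 units/frame
would be ~15 m/s at the documented scale — so the generator uses
σ₁ = 0.03 units/frame (~0.3 m/s), a realistic foraging speed, chosen once
and documented here.  Sizes come from a two-mode lognormal mixture (small
rats ~0.22, large rats ~0.42 units, log-sd 0.12) plus one outlier at 2.5×
the mean of the others, mimicking a squirrel wandering through.  An
optional `speed_size_exponent` scales each animal's σ₁ by
(Sᵢ/mean S)^exponent to emulate size-dependent speed; it is 0 by default
(the bare model has no such coupling) and is switched on only in the demo
analysis.

What the generator does *not* emulate: non-Gaussian tracker glitches and
identity switches, pose-dependent (non-spherical) area fluctuations, lens
distortion, non-planar terrain.  Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real detector pathologies.

Recovery, measured over five seeded scenes in the acceptance checks:
Spearman rank correlation of relative sizes ≥ 0.9, median relative size
error ≤ 15 % and tilt error ≤ 0.1 rad in at least 4 of 5 seeds (typical
values: ρ ≈ 0.95, error ≈ 6 %, tilt error ≈ 0.05 rad, with the tilt
estimate partly anchored by its prior).

## Tracklet statistics

Tracklets split a track at observation gaps > 1 s (configurable) and drop
fragments spanning < 5 s (strict inequality: a 150-frame fragment at
30 fps is kept, 147 frames is not).  A tracklet's summary speed is the
median per-frame ground displacement × frame rate; instantaneous speeds
use central differences after a 5-frame median position filter.  When
per-frame back-projection jitter rivals the step size (it does at the
default noise scales: ~1 px of pixel noise maps to 0.03–0.1 scene units at
typical depths), an optional median-smoothing window before differencing
(`smooth_window`) restores the speed signal; the demo analysis uses a
9-frame (0.3 s) window, chosen once.

Coordination epochs: per frame, count tracklets whose instantaneous speed
exceeds a threshold (default: the 75th percentile of all per-frame speeds;
the demo uses the 90th); maximal runs with count ≥ 3, merged across gaps
< 1 s, are epochs, and participants are the ids that were fast during the
epoch (an alternative "present during" rule is available).  All three
thresholds are package choices — the underlying field observations do not
pin them down — and are configurable.

The two-sample KS test is self-contained.  D is the exact sup-distance of
the ECDFs (computed in integer arithmetic).  The p-value is exact whenever
there are no cross-sample ties and n₁·n₂ ≤ 10⁶: under H₀ all C(n₁+n₂, n₁)
interleavings are equally likely, and the number with max |i·m − j·n| < h
is counted by dynamic programming over the lattice (exact integers).
Otherwise the asymptotic Kolmogorov distribution with the Stephens
small-sample correction is used.  Tests verify the exact path against
brute-force permutation enumeration for all sample sizes ≤ 8 and against
scipy's exact method, and verify null calibration of the quartile
comparison (~4.7 % exact attainable level at 60 vs 60, within the binomial
band over 500 simulations).

## Vocal analyses

Bouts: greedy left-to-right grouping; a silent gap ≥ 250 ms starts a new
bout, a strictly shorter gap joins (strict reading of "less than 250 ms").
Segmentation is exactly invertible on the generator's output because the
generator draws within-bout gaps from (0.05, 0.20) s and between-bout gaps
from (0.40, 1.20) s, respecting the rule's threshold by construction.

F0 is tracked as the frequency of maximum spectral magnitude within an
analysis band, per spectrogram frame (Hann window, NFFT 2048, overlap 256,
Fs 192 kHz ⇒ 93.75 Hz bins); a frame is voiced when its band peak exceeds
the median band magnitude by 6 dB (configurable).  This is a deliberately
simple, fully-tested estimator: on pure tones its error is bounded by one
bin for any configuration, and on a 40→60 kHz chirp at 10 dB SNR the
median is within 2 % — adequate for band-scale call classification
(22 kHz vs 50 kHz vs audible squeaks), not for fine harmonic analysis.
Bout summaries take the median over syllable median-F0 values (pooling all
voiced frames is available as an option) and the sample (n−1) standard
deviation, zero for singleton sets.

Loudness differences are 20·log₁₀ of the RMS ratio; a 4× amplitude ratio
is 12.04 dB.  The duration–frequency projection places each syllable at
(duration, median F0) and tests membership in user-supplied closed polygon
regions; the packaged `illustrative_regions.csv` is a synthetic
illustration of lab-literature call envelopes (a long-duration ~22 kHz box
and a short-duration 35–80 kHz box), *not* digitized from any published
meta-analysis, and real comparisons must supply their own region file.

## Shelter metric

Splat centers are binned on the two non-up axes into square cells
(default up-axis z; exporters differ, so it is configurable) and each
cell's statistic is the population (no n−1) standard deviation of the
up-axis coordinate, unweighted, with an optional per-point weight hook for
opacity- or scale-weighted variants.  Cells with fewer than 3 points are
flagged empty.  Pooling the per-cell means and sds by the law of total
variance reproduces the unbinned global sd exactly, which the tests check
at 1e−9 for several cell sizes; axis-aligned 90° rotations permute but do
not alter the sd multiset.  The constructed oracle scene (uniform ground
with 0.05 jitter, a canopy slab at height 2 over half the footprint)
separates canopy from open cells by a factor ~20.

## Numerical choices and degenerate inputs

* Horizon guard: back-projection raises a specific error when
  |v + f·tan α| < 1e−8·f (scale-free threshold); reconstruction reports
  the offending track and frame.
* The silhouette formula guards x² − r² and d² − r² with a 1e−12 floor
  inside the optimizer; the public `apparent_size` raises on spheres that
  touch the camera or poke behind it.
* Exact-KS integer heights avoid float comparisons of D entirely.
* WAV I/O is float32; integer PCM is normalized to [−1, 1] on read.
* Pipeline outputs are plain CSVs with full-precision floats plus a
  provenance sidecar (config hash excluding output location, seed,
  library versions), making a rerun with the same config and seed
  byte-identical.

## Known limitations

Single camera, single plane, fixed tilt — no lens distortion, no 6-DOF
extrinsics, no terrain relief.  MAP only: no posterior uncertainty on
sizes or camera parameters.  Tracklets are not re-linked across exits, so
per-animal statistics conflate multiple tracklets of one animal.  The F0
tracker follows the strongest in-band partial, which can be a harmonic for
broadband squeaks.  The shelter metric measures vertical spread, not
traversability or cover semantics.
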