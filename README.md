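# urbanrat

Computational ethology of free-ranging urban rats: monocular inference of
animal size and position from thermal-video tracks, multi-animal movement
statistics, ultrasonic-vocalization analysis, and 3D-scene shelter metrics.

Field recordings of rats foraging in cities are cheap to collect (a thermal
camera on a tripod, an ultrasonic logger, a phone camera for 3D scans) but
awkward to quantify: the camera views a tilted ground plane, so a rat's
apparent pixel size confounds its true size with its distance; animals enter
and leave the frame constantly; calls are buried in street noise.  This
package provides the analysis chain for such recordings, for researchers in
urban ecology, collective behavior and bioacoustics — together with
seed-deterministic synthetic generators for every input modality, so the
whole chain is testable without any field data.

## The model

A pinhole camera with focal length *f* (pixels) sits at the origin looking
along (−1, 0, 0).  Animals move on a tilted ground plane
*y = −x·tan α − y₀* and are approximated by spheres of radius *Sᵢ*.  A point
(x, y, z) images at

    u = −f·z/x,   v = f·y/x

and a sphere's silhouette is an ellipse (the quadric projection) with area

    s = π f² Sᵢ² √(d² − Sᵢ²) / (x² − Sᵢ²)^{3/2},   d = ‖(x, y, z)‖,

which reduces on the optical axis to the familiar π f² r²/(d² − r²).
Each animal's in-plane position follows a Gaussian random walk,

    (x_{t+1}, z_{t+1}) = (x_t, z_t) + δ_t,   δ_t ~ N(0, diag σ₁²),

and observations carry pixel noise ε ~ N(0, σ₂² I₂) and size noise
η ~ N(0, σ₃²), with log-normal hyperpriors σ₁ ~ logNormal([0.5, 0.5], 0.3)
and σ₂, σ₃ ~ logNormal(0.01, 0.01), plus Gaussian priors on
Q = (α, y₀, f), initial positions and sizes.  MAP estimates of Q, {Sᵢ},
the noise scales and the latent paths are found by maximizing the joint
log-density (analytic gradients, L-BFGS); ground-plane trajectories follow
by back-projecting pixels through the fitted Q.  Downstream, tracklets
(≥ 5 s trajectory fragments) feed size-quartile speed comparisons,
coordinated-movement detection and participant/non-participant contrasts,
each scored with a two-sample Kolmogorov–Smirnov test whose p-value is
computed exactly (lattice-path counting) whenever feasible.

The audio side groups syllables into bouts (silent gaps < 250 ms), tracks
the fundamental frequency F0 as the band-limited spectral peak
(NFFT = 2048, Fs = 192 kHz), and projects calls into the duration–frequency
plane of the 22 kHz / 50 kHz call-type literature.  The scene side grids
gaussian-splat centers top-down and maps the per-cell height standard
deviation — high under canopy or cover, near zero on open ground.

## Worked example

```bash
python analysis/01_simulate_data.py      # synthetic tracks, audio, splat cloud
python analysis/02_fit_sizes.py          # MAP fit + ground-track reconstruction
python analysis/03_movement_statistics.py
python analysis/04_vocalizations.py
python analysis/05_shelter_map.py
```

prints, for the default seed:

```
camera: tilt 0.3981 rad, plane offset 4.970, focal length 799.4 px, ...
50 tracklets of >= 5 s (from 100 raw tracks)
speed, lower vs upper size quartile: D = 0.615, p = 0.0126  (exact, n = 13/13)
22 coordination epochs (>= 3 animals above the 90th-percentile speed, 0.92 units/s)
size, participants vs non-participants: D = 0.533, p = 0.00135
subway vs park level difference: +12.04 dB (~4.0x amplitude)
5 bouts; median bout F0 51.4 kHz
canopy cells spread 21x more in height than open ground
```

The generating scene had tilt 0.35 rad, plane offset 5 and focal length
800 px, with larger animals walking faster: the fit recovers the camera to
within ~0.05 rad / 1 % focal length, the tracklet statistics detect the
size–speed coupling and the resulting over-representation of large animals
in coordinated bursts, the audio stage recovers the constructed 12 dB
(4× amplitude) environment difference, and the shelter map separates the
canopy strip from open ground by a factor ~20 in height sd.

The same stages are scriptable via the `urbanrat` CLI
(`simulate-tracks`, `fit`, `analyze-audio`, `shelter-map`, `run-all` with a
YAML config) with distinct exit codes for config, data and numeric errors.

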