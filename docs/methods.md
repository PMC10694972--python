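# Methods

This note records the models, assumptions, parameter choices and numerical
decisions behind each stage of the pipeline, and its known limitations.

## 1. Geometry (`ecgikit.geometry`)

**Surface meshes.** Triangulated surfaces with optional vertex-label sets
(e.g. `valve_plane`). Consistency checks: Euler characteristic 2 and
watertightness for closed surfaces. Per-vertex area weights are one third of
each incident triangle's area.

**Closest point on a mesh.** A vectorised closest-point-on-triangle routine
(barycentric region classification: vertex, edge and interior regions) applied
brute-force over all triangles in memory-bounded chunks. It underpins
electrode snapping, virtual-vest projection, BEM electrode interpolation and
ICP. No spatial index is used; for the mesh sizes in scope (≤ a few thousand
triangles) the chunked dense computation is fast and exact.

**Virtual vest.** Each 8×16 electrode panel is reconstructed from its four
imaged corner markers by bilinear interpolation in the corner patch, followed
by projection of every grid point onto the torso surface. This is exact on
planar panels; on an elliptic-cylinder torso the RMS position error stays
below half the 25 mm grid spacing. Corners farther than 20 mm from the torso,
or degenerate (duplicated) corners, are rejected.

**Registration.** Rigid ICP: closest-point correspondences, Kabsch SVD
rotation with determinant-sign correction, iterated to convergence. Intended
for the small residual motions between repeated scans, not for global
alignment from arbitrary poses.

**Paired sites.** Scan–rescan analyses pair each non-valve node of mesh A with
its nearest non-valve node of mesh B; pair distances are retained so callers
can filter distant pairs.

## 2. Synthetic ground truth (`ecgikit.synthgen`)

* **Heart mesh**: star-shaped perturbed ellipsoid (Fibonacci directions,
  smooth radial modulation), triangulated by a star-shaped hull about the
  centroid; the basal cap is labelled `valve_plane`.
* **Activation**: geodesic-like wavefront from a breakthrough node at constant
  conduction velocity (default 1.5 mm/ms) over the mesh edge graph
  (Dijkstra). AT at the breakthrough is exactly 0.
* **Repolarisation**: RT = AT + APD, with APD = 235 ms base, a linear
  apico-basal gradient of 0.25 ms/mm along z, and optional Gaussian APD noise.
* **Electrograms**: template action potential (sigmoid depolarisation at AT,
  sigmoid repolarisation at RT); the unipolar electrogram at a node is
  `farfield_weight × (area-weighted global mean) − (local action potential)`.
  `farfield_weight = 0.4` keeps the local solid-angle contribution dominant,
  as for a contact unipolar electrode; equal weighting was found to bias the
  Wyatt RT estimate away from the true RT even on noise-free signals.
* **Forward projection**: beats with Gaussian RR variability (default
  950 ± 30 ms, floored at 400 ms) are projected through the transfer matrix;
  noise adds broadband Gaussian, baseline wander and powerline components, or
  broadband-only calibrated to a requested SNR (RMS-based). Signals clip at
  ±10 mV.

## 3. Signal processing (`ecgikit.sigproc`)

* **Lead QC**: a channel is excluded as `flat` (SD < 1 µV), `clipping`
  (> 1% of samples at the ±10 mV rails) or `artifact` (SD > 3 mV), in that
  priority. If more than half the channels fail, the recording is rejected.
* **Beat detection**: RMS over included leads of the smoothed derivative
  (60 ms window), peak picking with a 250 ms refractory period. At least 5
  beats and 10 s of signal are required.
* **Signal averaging**: beats are windowed (−150…+600 ms around each onset),
  aligned by cross-correlation against the median template (±50 ms search),
  and the worst `reject_fraction` (default 10%) by template correlation is
  discarded before averaging. RR is the median of the differences of **all**
  detected onsets (robust to rejected beats). Averaging N beats reduces
  uncorrelated noise by 1/√N.
* **Fiducial windows**: the QRS window is located from the peak of the
  derivative-RMS envelope (5 ms Savitzky–Golay frame) with a 15% threshold and
  8 ms padding; the T-wave window is found the same way in the post-QRS region
  using a 25 ms frame and 40 ms padding. Both windows are data-driven; fixed
  windows were found to let late baseline fluctuations capture the RT argmax.

## 4. Forward/inverse solution (`ecgikit.inverse`)

* **Monopole kernel**: `A[i, j] = vertex_area[j] / (4π d_ij)`, then Wilson
  re-referencing (subtract the column mean over electrodes). Fast, and
  accurate enough for marker *sequences*; it is not a physical torso model.
* **BEM kernel**: homogeneous-torso boundary-element transfer with an
  insulated outer boundary, constant-potential row-sum calibration, and
  electrode interpolation by barycentric coordinates on the torso surface.
  Validated against the analytic concentric-spheres solution (relative error
  0.23% on the dipole gain; constant potentials transfer exactly).
* **Tikhonov solve**: thin SVD of the (included-lead) transfer matrix; the
  solution applies filter factors `σᵢ/(σᵢ² + λ²)`. Excluded leads are dropped,
  never interpolated. λ = 0 requires full rank.
* **CRESO λ**: the first local maximum of
  `C(λ) = Σ βᵢ² σᵢ² (σᵢ² − 3λ²)/(σᵢ² + λ²)³` on an ascending 200-point
  log grid spanning `[σ₁×10⁻⁸, σ₁×10]`, evaluated at the time sample of
  maximum torso RMS (one λ per averaged beat). If no interior maximum exists,
  the solver falls back to the L-curve maximum-curvature point.

## 5. Markers (`ecgikit.markers`)

* **AT**: time of steepest negative slope inside the QRS window.
* **RT**: time of steepest positive T-wave slope (Wyatt criterion) inside the
  T window. Derivatives are Savitzky–Golay (order 2): 5 ms frame for the QRS,
  25 ms frame for the much slower T upslope — a short frame materially
  degrades RT under noise.
* **ARI** = RT − AT, enforced as an exact identity on included nodes.
* **Rate correction**: Bazett, `x_c = x / √(RR/1000)`.
* **Amplitude**: QRS peak-to-trough. **Fractionation**: count of distinct
  smoothed negative deflections (≥ 2 ms wide, prominence ≥ 5% of the segment
  range, below the pre-QRS baseline) in the QRS window.
* **Marker QC**: nodes are excluded when AT falls outside the QRS window, RT
  outside the T window, ARI is non-positive, or amplitude is below the floor
  (default 0.05 mV); exclusion above 30% triggers a warning.

## 6. Statistics (`ecgikit.epstats`, `ecgikit.repeatability`)

* **Participant summaries**: means of AT/RTc/ARIc, max–min dispersions, mean
  local gradients (mean |Δvalue|/edge-length over mesh neighbours), amplitude,
  fractionation, RR, after valve-plane exclusion.
* **Group comparison**: Shapiro–Wilk on pooled group residuals (α = 0.05)
  gates Welch-t vs Mann–Whitney; categorical variables use χ² without
  continuity correction; zero-variance variables are reported untested.
* **ICC(2,1)**: two-way random effects, absolute agreement, single measure,
  from the two-way ANOVA mean squares; matches `pingouin`'s ICC(A,1) to
  machine precision. Requires ≥ 5 sites and ≥ 2 raters.
* **Non-parametric Bland–Altman**: per-case median and 5th/95th percentiles
  of paired differences (linear-interpolation quantiles), summarised across
  cases by medians; on standard-normal differences the limits sit at ±1.645.
* **Reliability report**: per-node UEG Pearson correlations (median and IQR),
  Spearman sequence correlations and ICC for AT/RT/ARI, absolute and
  percentage differences, and Bland–Altman limits, over included paired sites.

## 7. Determinism and provenance

Every stochastic routine takes an explicit seed (NumPy `default_rng`); the
full pipeline is bit-reproducible from a seed. `run_pipeline` writes a
manifest with the package version, the configuration, SHA-256 hashes of the
inputs and per-stage timings; failures leave a `FAILED` marker naming the
stage.

## Limitations

* The torso is electrically homogeneous; no lungs, blood masses or
  conductivity inhomogeneities. Absolute potential amplitudes from the
  monopole kernel are not physical — only marker timings and sequences are
  meaningful with it.
* Geodesic wavefront activation ignores fibre orientation, anisotropy and
  transmural propagation; the epicardium is modelled as a single closed
  surface without distinct ventricular cavities.
* The Wyatt RT criterion is used exclusively; alternative repolarisation
  markers (e.g. T-peak based) are not implemented.
* Bazett rate correction is known to over-correct at fast rates; it is kept
  for comparability with standard practice.
* The beat detector assumes reasonably regular rhythm (a 250 ms refractory
  period, no arrhythmia handling); atrial activity is not modelled or removed.
* Quantile-based Bland–Altman limits need many sites per case (≥ 20 enforced)
  and are reported without case-level weighting.
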