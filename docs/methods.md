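# Methods

This note documents the models and numerical choices behind `temporalign`:
what each stage computes, the parameters that matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## 1. Edge-enhancing diffusion filtering (`temporalign.diffusion`)

Anatomical volumes are prepared for segmentation by an iterative
structure-tensor filter.  Per iteration: the image is Gaussian-smoothed
(`sigma`, default 1 voxel); the per-voxel structure tensor `S = g g'` is
formed from the central-difference gradient of the smoothed image;
eigenvalues (sorted descending) give the features

```
intensity = l1 + l2 + l3          (gradient energy)
range     = (l1 - l3) / intensity (1 for sheet-like "surfel" tensors)
W         = |(|range - 0.5| + 0.5) - intensity|
```

and the diffusion tensor is the scalar weight times the eigenvector frame,
`D = W * sum_k e_k e_k' = W * I`, smoothed component-wise with a Gaussian
(`rho`, default 1 voxel).  The update is the explicit unit step
`v <- v + div(D_hat . grad v_hat)`, where the flux gradient is the same
smoothed gradient that built the tensor.  Defaults: 40 iterations.

Three numerical choices deserve explanation:

* **Intensity normalization.** `intensity` is rescaled by the 90th
  percentile of the positive gradient energies and clipped to [0, 1].  With
  this, the entire strong-edge population saturates at `W = 0` (no
  diffusion), and just below the saturation knee the flux `W(g) * g` is a
  *decreasing* function of gradient magnitude.  The filter is therefore a
  Perona–Malik-type process: tissue interiors flatten, and partial-volume
  boundary profiles actively steepen.  Normalizing by the global maximum
  instead leaves typical edges with substantial diffusivity and the filter
  degenerates into near-uniform smoothing that erodes boundaries — we
  measured a monotone interface-gradient loss under that variant, against
  the filter's purpose.
* **Smoothed-gradient flux.** Building the flux from the pre-smoothed
  gradient is also what makes the printed unit time step stable: the
  explicit symbol is bounded by the Gaussian factor at high spatial
  frequencies (with a raw gradient and diffusivities up to 1 per axis, the
  unit step is marginally unstable).
* **Zero-flux boundaries.** The discrete divergence uses odd-reflected
  ghost fluxes, which makes the total image intensity *exactly* conserved
  each iteration (discrete divergence theorem) — a per-iteration invariant
  the tests assert at 1e-6 relative and which holds to machine precision.

Degenerate voxels (gradient energy below `eps_degenerate` relative to the
normalization constant, default 1e-12) get `range = W = 0`; they carry no
gradient, so this is a bookkeeping convention, not a dynamics choice.
Hard step edges cannot become sharper under any positive-semidefinite
diffusion; the boundary-contrast gain is real only for boundaries wider
than one voxel (see §6 on the phantom's point-spread blur).

An optional trilinear upsampling pre-step (`volume.upsample`) mirrors the
practice of filtering coarse acquisitions on a finer grid.

## 2. Histogram segmentation (`temporalign.segment`)

White matter is selected in the joint (intensity, gradient-magnitude)
histogram.  Bin edges run linearly between the 0.5th and 99.5th percentiles
by default (robust to tails); out-of-range voxels are clipped into the edge
bins so counts conserve the voxel total.  Selection regions are explicit
serializable boxes or polygons — reproducible replacements for interactive
histogram tools.  Masks from disjoint regions tile the voxel set exactly.

## 3. Surfaces (`temporalign.surface`, `temporalign.decimate`)

Meshes come from marching cubes at the 0.5 iso-level of the binary mask,
with one voxel of zero padding so surfaces close at the volume border, and
are mapped to world mm through the NIfTI affine.  Every surface must pass
the topology gate `V - E + F = 2` before inflation.

* **Decimation** is quadric edge collapse to the midpoint, ordered by
  squared edge length plus quadric error (short edges collapse first, which
  drives edge lengths toward equality), guarded by the link condition and a
  normal-flip check, followed by 20 rounds of tangential Laplacian
  relaxation.  On reconstructed surfaces the edge-length coefficient of
  variation *decreases*; a perfectly uniform lattice (e.g. a raw icosphere)
  is the one input whose CV cannot be preserved, because collapse
  necessarily creates irregular valences — a known limitation.
* **Curvature** is the umbrella estimator: the displacement toward the
  one-ring mean projected on the outward vertex normal, optionally smoothed
  by neighbor averaging; the sign convention is sulci positive / gyri
  negative, binarized at zero.
* **Inflation** is iterative Laplacian smoothing with per-step centroid
  re-centering and projection to the unit sphere (default 500 steps,
  repeated up to three times if any spherical triangle is still flipped).
  Vertex order is preserved so per-vertex maps carry over.
* **Resampling** to the standard icosphere (level L has `10*4^L + 2`
  vertices; level 7 = 163842) locates each standard direction in its
  containing spherical triangle by central (gnomonic) projection and
  transports scalars barycentrically (exact for constants, range-bounded)
  and labels by nearest source vertex.  Directions that numerically hit no
  triangle fall back to the nearest vertex and are counted.

## 4. Alignment (`temporalign.align`)

All registration happens on the standard icosphere.  The rigid stage
searches SO(3) with ~1200 seeded quasi-uniform candidate rotations scored
by nearest-vertex curvature mismatch on a vertex subsample, then refines by
Nelder–Mead on the rotation vector; constant (no-signal) maps return the
identity with a warning.

CBA/CBA+ optimize per-vertex warps by projected gradient descent on

```
mean_v (c_s(w(v)) - t(v))^2
+ w_lm * mean_lm mean_v (m_s,lm(w(v)) - t_lm(v))^2
+ lambda_reg * mean_e ((|w_i - w_j| - L0_ij) / L0_ij)^2
```

with curvature and landmark maps neighbor-average smoothed per level and
variance-normalized so the two data terms are commensurate
(`w_lm` default 1, `lambda_reg` default 1).  The four-level schedule
defaults to smoothing rounds (120, 60, 20, 5), iterations
(200, 200, 150, 100), and a step of 0.1 mean edge lengths halving per
level; the descent direction is normalized to unit maximum vertex
displacement so the step has that geometric meaning.  Steps are accepted
only if they lower the cost *and* flip no spherical triangle (rejected
steps halve the step size), so the recorded cost is non-increasing and
warps stay valid at every level's end; a level stops early once ten
accepted steps improve the cost by less than 1e-7 relative.  The group
template is refreshed from the currently warped subjects at each level
boundary (dynamic group averaging), starting from the mean of the
rigid-aligned maps.  Landmark polylines are shortest edge-paths between
ordered anchors (Dijkstra with chord-length weights); their indicator maps
are smoothed alongside curvature.  Hemispheres are never mixed in one run.

Warps map each template vertex to a position on the subject sphere; scalars
transport by barycentric interpolation, labels by nearest vertex; the rigid
rotation composes with the nonlinear warp by a matrix product.

## 5. Atlas statistics (`temporalign.atlas`)

Probabilistic maps count, per vertex and area, the subjects labeling that
vertex.  Overlap histograms normalize the level-k counts by the area's
union support (the only convention under which one area's bars sum to 1)
and report the left-skew statistic (mass at level 1 minus mass at level N).
Leave-one-out DICE builds the training atlas region at `min_overlap >= 4`
of the remaining subjects by default; DICE of two empty sets is defined as
0 with a warning, matching the zero cells that occur when an area has no
atlas support.  All three statistics are tested against exhaustive set
enumeration on toy meshes.

## 6. Synthetic data (`temporalign.synthdata`)

* **Volume phantom**: white matter below a sinusoidally folded interface
  (means 100/60, noise sd 10), blurred by a 2-voxel Gaussian point spread
  before noise — the partial-volume transition of a coarse acquisition
  resampled to a finer grid, which is the regime the filter targets
  (`psf_sigma=0` gives the ideal two-valued phantom).  Truth masks and the
  analytic interface normal are exact.
* **Cohort**: one template curvature field (band-limited random background,
  gyral ridges along STG/MTG and a deliberately weaker one along the
  anterior Heschl's gyrus, a sulcal valley along STS) with eight area
  labels tied to the landmark strips; Heschl-band areas subdivide *along*
  the gyrus.  Each subject is the template pulled back through a smooth
  random tangent deformation (RMS amplitude 0.10 rad ≈ one ridge width)
  plus a random *slide along the Heschl ridge* (sd 0.12 rad) and a global
  rotation up to 10°.  The slide is the crux of the design: sliding along a
  ridge barely changes the curvature pattern, so curvature alone cannot
  correct it — only the landmark term can, which is exactly the mechanism
  the method comparison is meant to expose.  The forward correspondence is
  stored (sampling the template there reproduces the subject map to
  machine precision); its numerically inverted composition with the
  rotation is the ground-truth warp (perfect alignment gives DICE 1 by
  construction).  What the cohort does *not* emulate: real gyral geometry,
  Heschl-duplication morphotypes, per-subject area-boundary variability
  independent of geometry, and measurement noise beyond a small curvature
  jitter — so passing tests show the methods' ordering under controlled
  deformations, not their absolute accuracy on real brains.
* **Sound experiment**: 168 sounds in 24 runs, four cross-validation splits
  of 18 training / 6 test runs (126/42 sounds), volume time 2.6 s, a
  9-sample double-gamma response, band-energy features with a localized
  spectral bump per sound covering all 128 bands, one-hot frequency tuning
  per vertex, and white noise at amplitude SNR 2 by default (sd of signal
  over sd of noise, per vertex).

## 7. In-vivo maps (`temporalign.invivo`)

The myelin index is T1w/T2\*w inside gray matter; zeros in T2\*w are
excluded with a logged count; values above an adaptive upper-percentile
threshold are discarded; survivors are min–max rescaled to [0, 100]
(rank-preserving).  The threshold scans p = 90…99.9 in 0.1 steps and cuts
at the first p where, after three consecutively decreasing increments, the
increment falls below twice the median increment; the increment sequence is
moving-average smoothed (window 5) first, because raw order-statistic gaps
are negatively autocorrelated and never show a sustained trend.  If the
rule never fires the last scanned percentile is used.

Tonotopy: sounds pass a 128-band log-spaced Butterworth band-pass filterbank
(180 Hz – 8 kHz, constant-Q, energies per Hz so white noise is flat) — a
deliberately simple stand-in for a full cochlear model that preserves the
encoding pipeline's structure.  Per fold, each vertex's hemodynamic
response is estimated by 9-stick FIR deconvolution on the training runs;
noise regressors are the top-5 principal components of the training
residuals of a sound-only model; per-sound betas are then estimated with
the vertex's response, separately for training and test runs.  Ridge
weights are computed in closed form via SVD over a log-spaced penalty grid
(1e-2…1e4, 13 points); the penalty is chosen per vertex by mean test-fold
prediction correlation (ties to the smaller penalty), and the final weights
are the across-fold mean of the training fits at that penalty — test data
can never touch the weights, only the penalty choice.  Best frequency is
the center frequency of the largest weight, ties to the lowest band.

## 8. Problem sizes

The test suite runs the cohort comparison at icosphere level 4 (2562
vertices, n = 10) and the acceptance script at level 5 (10242 vertices),
sizes chosen so the full stack executes comfortably on a single CPU while
preserving every ordering property; the standard mesh itself (level 7) is
constructed and checked at full density.  The encoding experiment uses 100
vertices.

## 9. Known limitations

* The alignment cost, regularizer, and schedule reproduce the published
  *procedure class*, not any proprietary implementation; agreement with
  real-data atlas figures is therefore qualitative (orderings, sharpness),
  never numeric.
* The warp gradient uses piecewise-linear interpolation of the smoothed
  maps; at map features narrower than ~2 mesh edges the transport error is
  second-order but visible (tested at the ridge crests).
* Decimation of perfectly uniform lattices degrades edge-length uniformity
  (see §3); inflation of deeply folded surfaces may need more smoothing
  steps than the default.
* The filterbank and noise-regressor stages are simplified stand-ins (see
  §7); they are not calibrated to any auditory model's output scale.
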