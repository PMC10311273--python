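# Methods

This note documents the models, parameter choices and numerical
conventions behind kvphasegen, and what its synthetic benchmarks do and
do not demonstrate.

## Coordinate and data conventions

The beam axis is +z; the scoring plane is orthogonal to it at
`z_plane` (default 500 mm), origin on the central axis, right-handed
axes. A phase space stores six float32 columns per photon — x, y (mm),
direction cosines dx, dy, dz, and energy E (keV) — in a single HDF5
container with a JSON header (format version, tube potential label,
plane position, count). Invariants enforced on read: unit direction to
1e-6, dz > 0, 0 < E ≤ kVp. All three cosines are stored (rather than
reconstructing dz) so generator outputs can be audited before
renormalization.

Normalization for training maps each parameter onto [0, 1] by the
training set's min/max; out-of-range values are clipped and counted,
never errored, because a trained generator may overshoot slightly.

## Analytic source

The source is an analytic stand-in for a full transport simulation of
an X-ray head. It reproduces the marginal structure the downstream
modules need, not the physics of electron transport.

* **Spectrum.** Kramers continuum `w(E) ∝ (kVp − E)/E` on a 1 keV grid
  from 10 keV, multiplied by the inherent-filtration transmission
  (default 2.5 mm Al — a typical tube value; the real head's filtration
  is proprietary). Tungsten K lines (Kα1 59.32, Kα2 57.98, Kβ 67.2 keV;
  intensity ratio 100:57:33, a configuration default) are injected when
  kVp exceeds the 69.5 keV K edge, with a summed pre-filtration weight
  ramping linearly to 8% of the continuum at 120 kV. Sampled continuum
  photons are jittered uniformly within their 1 keV bin; line photons
  stay at the exact line energy (they are physically discrete).
* **Focal spot.** Horizontal: four Gaussian components (weights
  0.22/0.28/0.28/0.22, means ±0.196/±0.069 mm, sigmas 0.088/0.118 mm);
  vertical: one Gaussian (σ = 0.154 mm). The component shapes were
  frozen once so that the mixture full widths at 15% of maximum equal
  the measured projected widths, 0.70 mm horizontal and 0.60 mm
  vertical.
* **Heel effect.** A photon effectively produced at depth d₀ = 0.05 mm
  below the anode surface leaves through a tungsten path
  `t_eff(θ) = d₀ · max(sin α / sin(α − θ) − 1, 0)` for emission angle θ
  (positive toward the anode) and anode angle α = 12° (a conventional
  value; the real geometry is proprietary). The acceptance weight
  `exp(−μ_W(E) t_eff)` is applied by rejection sampling so emitted
  phase spaces remain unweighted; rays with take-off ≤ 0 are cut off.
  The model is calibrated qualitatively (ratio of anode to cathode half
  integrals ≈ 0.6 at 120 kV over an 8° half-fan), not fitted to a
  measured profile.
* **Divergence.** Directions are uniform in tangent inside a
  rectangular ±8° fan, which makes the lateral photon density at any
  plane uniform for a point, heel-free source — the property the
  projector noise tests rely on.

## Beam quality and the HVL inverse problem

Attenuation data (μ/ρ for Al, Cu, W, water, air; μen/ρ for air;
10–150 keV; standard compilation values) are bundled and interpolated
log-log, exact at grid nodes. Tungsten's L-edge fine structure below
12.1 keV is smoothed — nothing in the package resolves it — while the
K edge is kept as a two-point jump at 69.5 keV.

Detector response is air kerma, `K = Σ w(E) E (μen/ρ)_air(E)`: the
dosimetric standard for HVL and linear in the weights. K(t) is strictly
decreasing in absorber thickness for any positive spectrum, so the HVL
is a unique root, found by bracketing + Brent iteration to 1e-5 mm.

The spectrum reconstruction uses monoenergetic photon bins at 2 keV
spacing on (10, kVp] — not electron-energy superposition, since the
observable constrains only the photon spectrum. Four HVL measurements
against ~25–55 unknowns is under-determined; reproducibility comes from
a flat initialisation, nonnegativity bounds, and a second-difference
roughness penalty (λ_s = 1e-3, scaled by the basis size). Solver
tolerances are 1e-8 with at most 400 function evaluations — the
residuals against the bundled measured table are below 1e-3 mm at every
setting, far inside the ±0.2 mm measurement uncertainty. Per-setting
residuals are always reported so circular fit targets are auditable.
Published simulated companions to such measured tables sometimes list
an entry where added filtration lowers the reported HVL; the package
asserts filtration monotonicity (a superset filter stack can never
soften the beam) and makes no attempt to reproduce such values.

## Adversarial phase-space models

The generator maps a 6-D standard-normal latent vector (conditional
models concatenate a learned 4-D embedding of the tube-potential label,
input width 10) through three hidden layers — ReLU, ReLU, sigmoid —
and a final affine head to the six normalized parameters. The
discriminator mirrors the hidden stack with a scalar output and, for
conditional models, its own label embedding. Spectral normalization
(one persistent power-iteration vector per matrix, σ = uᵀWv treated as
a graph node so gradients flow) is optional and audited to ‖W‖₂ = 1 ±
1e-3.

Because no tensor framework is assumed, training runs on an in-package
reverse-mode autodiff engine over numpy arrays whose backward passes
are built from the same primitives, so gradient-norm penalties can be
differentiated again (double backprop). Supported objectives:

* **non_saturated_r1** — softplus-form non-saturating losses with
  `R1 = (γ/2) E‖∇_x D(x)‖²` on real samples only (γ default 10);
* **wasserstein** — difference of critic means; a gradient penalty
  (coefficient 10) on latent-mixed samples when spectral normalization
  is off, penalty-free otherwise.

Optimisation: RMSProp (α = 0.99), learning rate default 2e-5, batch
1e4, 20 epochs — the production recipe. The D:G update ratio (default
1:1) is configurable. All randomness derives from one seed through
named substreams (init / shuffle / latent / validation); identical
configurations reproduce identical weights bit-exactly on a platform.

Two choices deviate from a naive transcription, both forced by desk
scale (10³–10⁴ optimisation steps instead of ~10⁵):

* **Bias-corrected EMA.** The shadow weights accumulate from zero and
  are divided by `1 − decay^t`. A plain decay-0.999 average still
  contains ~37% random-init weights after 1000 steps, which dominated
  every validation metric; the corrected form equals the plain one in
  the long-run limit and satisfies "decay 0 ⇒ raw weights" exactly.
* **Output-head initialisation at 0.3× He scale**, so freshly
  initialised generators emit particles inside the valid box (full
  scale put ~half of all samples outside it and sampling-by-rejection
  stalled).

`train_gan` logs the validation histogram loss each epoch and can
retain the weights of the best validation epoch (`keep_best`): at
desk-scale learning rates the validation loss bottoms after 15–40
epochs and then degrades, and selection on validation loss is the
standard remedy. An interim model whose rejection rate exceeds 50% is
scored at the disjoint-support worst case rather than aborting the run.

Sampling draws latents, denormalizes, renormalizes the direction to
unit length, and rejects rows with dz ≤ 0 or E outside (0, kVp],
resampling until n valid particles exist; a rejection rate above 50%
raises a model-quality error. Energy interpolation mixes first-hidden-
layer activations, `G2-3(λ G1(z, E(y1)) + (1 − λ) G1(z, E(y2)))`, with
an embedding-space companion mode for comparison; λ ∈ {0, 1} reproduce
direct generation bitwise.

## Evaluation

The histogram loss uses identical bin edges for both particle sets —
by default 100 equal-width bins per parameter spanning the reference
set's range, with out-of-range values accumulated in the clamped end
bins (this makes the loss on fully disjoint supports smaller than the
theoretical 2n unless the edges are chosen to cover both sets; tests of
that limit fix explicit edges). The percent error is
`E = L_total/(6 · n_particles) · 100`. The conditional figure of merit
averages L_total over trained energies.

FW-at-fraction widths scan outward from the profile peak to the first
sample below `fraction × max` on each side and interpolate linearly; a
strict mode errors when the profile crosses the threshold more than
once per side (sampled profiles jitter, so scan-from-peak is the
default). Gaussian-mixture profile fits use bounded least squares with
quantile-spread multi-start means and report components sorted by mean
plus the RMS residual.

## Projector

`trace_path` computes exact per-material chord lengths through the
voxel grid (plane-crossing reference implementation; an
Amanatides–Woo numba kernel handles photon batches and is tested
against the reference). Each photon deposits its expected transmitted
energy in the pixel its ray intersects on the detector plane;
boundary points belong to the lower-index pixel. There is no scatter,
no detector response, and no stochastic absorption: images are
expected primary energy fluence. Attenuation lookups clamp energies to
the 10–150 keV table range (generated sources can undershoot 10 keV by
a fraction of a keV). Material id 0 is vacuum.

The demo phantom is a 48³ × 2 mm grid: a water cylinder (extruded along
y) with an aluminium rod and an air cavity, placed between the source
plane (500 mm) and the demo detector (700 mm; 16 × 16 pixels of 16 mm).
The coarse pixels are deliberate: at 10⁶ photons the per-pixel counting
noise of two independent phase-space projections has a median relative
difference of ~2.5%, well below the model differences of interest.

## Bundled desk-scale benchmark

The production study is not desk-reproducible (10⁸ particles/energy,
400-wide networks, ~10⁵ optimisation steps). The frozen scaled-down
benchmark uses 10⁵ particles per energy split 50/50, 20 epochs, batch
10³, learning rate 2e-5, hidden width 48, EMA on, and a 2:1 D:G update
ratio (at the production learning rate with 100× fewer steps a 1:1
critic cannot hold the data support; the ratio is a free parameter of
the recipe). Under these conditions the qualitative production
findings reproduce: every (loss × normalization) setting improves from
epoch 1 to epoch 20, and the non-saturated + R1 objective reaches a
final validation histogram loss no worse than the Wasserstein one.

Quality-oriented experiments (interpolation, projector comparison) use
a desk-scale recipe instead: learning rate 1e-3, batch 500, validation-
selected weights. On the line-free 60 kV source this reaches a held-out
percent error of ≈9%, of which ≈5% is the resampling noise floor at
5·10⁴ comparison particles. At potentials above the K edge the energy
parameter dominates the residual — the discrete characteristic lines
are the hardest feature for the generator, consistent with the
production-scale experience — while projected images, which integrate
over the spectrum, agree with phase-space images to a median relative
difference of ~6% inside the phantom shadow at 10⁶ photons.

## What the synthetic benchmarks do not show

The synthetic source has exact Gaussian-mixture focal spots, a
first-order continuum model, no off-focal radiation, no scatter and no
detector response; its phase spaces are cleaner and lower-dimensional
in structure than transport-simulated ones. Passing benchmarks
demonstrates that the training, evaluation and projection machinery is
correct and that the qualitative orderings hold at desk scale — not
that a 48-wide model trained on 5·10⁴ particles would model a clinical
source, and not absolute image realism (the projector is primary-only
by design; its acceptance compares its own two source types, which is
also what the production study's image comparison did).

## Known limitations

* Electron transport, collimators, flattening filters and detector
  models are out of scope; the heel model is parametric, not fitted.
* The HVL inverse problem's solution spectrum is one member of a
  regularized family; only its HVL predictions are validated.
* Training determinism is per-platform (BLAS reduction order).
* Legacy tree-structured phase-space import is not implemented; the
  native HDF5 container is the only on-disk format.
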