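# Methods

`pclesr` simulates the image-formation physics of probe-based confocal
laser endomicroscopy (pCLE) well enough to manufacture perfectly aligned
low-resolution/high-resolution training pairs, and uses them to train and
evaluate single-image enhancement networks.  This note records the model,
its assumptions, the parameters that matter, and the design choices made
where more than one reasonable option existed.

## Forward model

A pCLE probe relays light through a coherent bundle of a few tens of
thousands of optical fibres.  Each fibre behaves as a single-pixel
detector on an irregular, roughly hexagonal grid confined to a circular
field of view (FoV); the clinical reconstruction software scatters the
per-fibre intensities back onto a Cartesian grid.  The simulator
reproduces that chain for one frame:

1. **Fibre lattice.**  Real bundle layouts are not published, so the
   generator synthesises a statistically similar one: hexagonal packing
   scaled so the requested number of fibres falls inside the FoV disc,
   each site displaced by an independent uniform jitter of magnitude at
   most `jitter_frac` × pitch (default 0.25).  Real bundles are
   near-hexagonally packed with manufacturing irregularity; the jitter
   fraction is the single knob controlling that irregularity and is
   exposed as configuration.  Desk-scale defaults are 600 fibres on a
   256×256 grid with FoV radius 120 px — two orders of magnitude below a
   clinical bundle, chosen so the whole test suite runs on one CPU, and
   fully configurable upward.
2. **Signal pooling.**  Each fibre's clean signal is the mean of the HR
   image over the fibre's Voronoi cell (equivalently: each in-FoV pixel
   is assigned to its nearest fibre).  A second variant pools the k=7
   nearest pixels, mimicking the acquisition step of the standard
   reconstruction algorithm.  At desk-scale densities a Voronoi cell can
   contain no pixel; such fibres take the image value at the pixel
   nearest their position (constant, artefact-free fallback that never
   triggers at clinical densities).
3. **Noise.**  `nfs = (1 + m)·fs + a` with `m ~ N(0, 0.05²)` and
   `a ~ N(0, (0.01·(max fs − min fs))²)` drawn independently per fibre.
   The defaults are the values tuned against real acquisitions; the
   range factor is computed per frame from that frame's clean signals
   (the only self-contained reading of the per-vector formula).  No
   clipping is applied — downstream standardisation makes the absolute
   range irrelevant, and clipping would distort the Gaussian model.
4. **Reconstruction.**  Delaunay triangulation of the fibre positions
   and barycentric (piecewise-linear) interpolation of the noisy signals
   onto the pixel grid.  In-FoV pixels outside the convex hull take the
   nearest fibre's value, so the image is defined over the whole FoV.
   Pixels on a simplex edge are attributed to the lowest-index simplex;
   barycentric weights sum to 1, so the value is unaffected up to float
   error.  Co-circular fibre configurations are pinned by a
   deterministic 1e-9×pitch perturbation before triangulating so the
   triangulation (and tests) are reproducible.

LR and HR share one pixel grid: pCLE's resolution loss comes from fibre
sampling, not pixel count, so the enhancement networks run at scale
factor 1.

Geometric conventions: pixel centres at integer coordinates, `(row,
col)` order, 0-based.  Nearest-fibre ties go to the lowest fibre index;
k-nearest-pixel ties at the k-th distance go to the lower row-major
pixel index.  Both rules exist purely for determinism.

## Phantoms and what they do not show

Real training targets would be video-registration-derived pseudo-HR
frames of epithelial tissue.  The phantom generator emulates their
statistics — anisotropic Gaussian blobs (bright and dark) over a smooth
low-frequency background, normalised to [0,1] inside the FoV, high SNR,
fine detail — with two texture presets (round crypt-like vs elongated
cell-like structures) standing in for the colon/oesophagus strata so
stratified splitting is exercised.  Phantoms do **not** reproduce
registration ghosting, motion deformation, fibre cross-talk, per-fibre
gain variation, or genuine tissue morphology.  Passing tests therefore
demonstrate that the pipeline and the learning machinery behave as
designed on data obeying the simulator's own physics; they say nothing
about clinical image quality, which in the original study required real
data and expert reading.

## Dataset protocol

Per pair: standardise both frames by the LR frame's in-FoV mean and
standard deviation (per-frame statistics; a training-set-global variant
is available behind a flag), then rescale each frame individually to
[0, 1], then cut non-overlapping 64×64 patches.  Tiles are laid from the
top-left of the FoV bounding box and kept when their in-FoV pixel
fraction reaches `coverage` (default 1.0 — fully inside the FoV; the
threshold is configurable because "inside the FoV" admits several
readings).  Splits are 70/15/15, stratified by texture label with
largest-remainder rounding, shuffled deterministically per seed.  Frame
seeds derive from `(master seed, frame index)` so a dataset is
reproducible regardless of generation order; rebuilding a dataset from
the same config yields a byte-identical manifest.

## Quality metrics

* **SSIM** — Gaussian window 11 px (σ = 1.5), k1 = 0.01, k2 = 0.03,
  population covariances, data range 1.0 after per-frame rescaling (the
  de-facto standard internals; the evaluation protocol does not pin
  them).  With no mask the mean runs over window centres fully inside
  the frame (matching reference implementations); with a FoV mask it
  runs over in-mask centres, and windows crossing the rim see the zeros
  outside — the same convention the reconstruction uses.
* **GCF** (global contrast factor) — gamma-linearised luminance
  `l = v^2.2`, perceptual lightness `L = 100·√l`; superpixel sizes 1, 2,
  4, 8, 16, 25, 50, 100, 200 formed by block-averaging *linear*
  luminance from the top-left; per-level contrast is the mean absolute
  lightness difference to 4-neighbours, combined with the published
  parabola weights `w_i = (−0.406385·i/7 + 0.334573)·(i/7) + 0.0877526`.
  Levels with a superpixel grid smaller than 2×2 are skipped.  Note the
  published weights are negative at the two coarsest levels, so GCF is
  only approximately non-negative on natural images; it is exactly zero
  on constants.  With a FoV mask, block averages use in-FoV pixels only
  and blocks without any are dropped.  GCF is defined on display
  intensities, so evaluation always runs on [0, 1]-rescaled frames.
* **Composite score** — per evaluation run, mean SSIM (to HR) and mean
  ΔGCF (to LR) are min-max normalised across the compared methods plus
  the LR identity baseline, then averaged.  A factor constant across
  methods is neutralised at 0.5.  The normalisation cohort is exactly
  the methods of one run — the only self-contained choice.
* **Paired t-test** — textbook formula on per-image score differences;
  cross-checked against `scipy.stats.ttest_rel` in the tests.

## Noise-parameter recovery (validation experiment)

Under the forward model `E[(nfs − fs)² | fs] = σ_m²·fs² + σ_a²`, so
regressing the squared perturbation on the squared clean signal
identifies both parameters.  The squared perturbations are strongly
heteroscedastic (variance `2(σ_m² fs² + σ_a²)²`), and over signals
uniform on [0.5, 1] the additive term carries only ~2% of the total
variance: the Cramér–Rao bound puts the relative sampling error of the
recovered additive coefficient at ≈28% for 10⁵ pairs, regardless of
estimator.  The recovery experiment therefore uses an iterated
variance-weighted regression (feasible GLS) on 4×10⁶ pairs, bringing the
sampling error to ~3–4% so both parameters are recovered well inside
±10%/±15%.  This is a precision requirement of the measurement, not a
change to the noise model, whose defaults are untouched.

## Enhancement networks and training

Two compact fully-convolutional architectures, both 1 channel → 1
channel at scale 1:

* `fsrcnn_like` — 5×5 feature extraction (d = 56), 1×1 shrink (s = 12),
  m = 4 mapping 3×3 layers, 1×1 expand, 9×9 reconstruction; the original
  deconvolution stage becomes a stride-1 convolution at scale 1.
  ≈12.6k parameters at defaults.
* `edsr_like` — 3×3 head, residual blocks (conv-ReLU-conv, no batch
  normalisation), 3×3 tail, plus a global input skip.  The tail is
  zero-initialised, so the untrained network is exactly the identity —
  training starts from "return the LR input" and can only move away
  from it by lowering the loss.

Losses: L1, and the mix `α·(1 − SSIM) + (1 − α)·L1` with α = 0.84 (the
value of the loss-design literature the mix follows; the evaluation
protocol states none).  The SSIM term uses the same Gaussian-window
statistics as the metric, with an analytic gradient (the zero-padded
Gaussian filter is self-adjoint, so the adjoint pass reuses the
filter); the gradient is validated against finite differences.  Its
data range defaults to the target minibatch's peak-to-peak.

Training is stochastic and patch-based: minibatches (default 54
patches, the memory-motivated protocol constant) drawn from a per-epoch
shuffled queue (with replacement when the pool is smaller than the
minibatch), Adam at learning rate 1e-4 by default, validation loss
every 25 steps, best-on-validation parameters returned.  Non-finite
loss raises immediately with the step index.  Inference is full-frame,
single-pass; interior pixels are independent of context beyond the
receptive field, which the tests check by crop-commutation.

The engine is a purpose-built numpy stack (im2col convolution, manual
reverse-mode gradients, float32) sized for single-CPU use; it is not a
general autodiff framework and supports exactly the layers above.

Classical baselines: unsharp-mask sharpening
(`x + amount·(x − blur(x, radius))`, clipped to [0, 1]) and
frequency-domain Wiener deconvolution with a Gaussian PSF, σ = 2 by
default (the experimentally estimated value of the comparison protocol)
and constant noise-to-signal ratio.

## Problem sizes in the test suite

The direction experiment (training must raise SSIM to HR, raise GCF over
the LR input, and win the composite score against the LR baseline in at
least 4 of 5 seeds) runs on 60 simulator pairs at 256×256 with 600
fibres and default noise; the network is `edsr_like` width 16 / depth 2
trained 300 steps with minibatch 8 at learning rate 1e-3 with the
SSIM+L1 loss.  These sizes were chosen so the full experiment (five
training runs plus evaluation) completes in a few minutes on one CPU;
the direction of the result, not its magnitude, is the claim under test.
Geometry oracles run exhaustive brute-force checks at ≤200 fibres on
64×64 grids, where exhaustive computation is exact and fast.

## Known limitations

* The lattice generator matches first-order spatial statistics
  (near-hexagonal packing, jitter) but not the long-range layout defects
  of real bundles.
* The noise model is Gaussian multiplicative+additive only — no
  shot noise, detector signatures, or fibre cross-talk.
* Masked SSIM/GCF near the FoV rim mix in the zeros outside the mask
  (SSIM) or shrink the neighbour set (GCF); both conventions are
  documented rather than hidden, and both are applied identically to all
  methods being compared, so rankings are unaffected.
* Training at desk scale demonstrates learnability and direction, not
  state-of-the-art restoration quality.
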