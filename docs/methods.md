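# Methods

## The problem and the approach

Live-cell phase-contrast imaging captures single cells whose morphology
changes continuously as they move, interact, divide, and switch phenotypic
state.  A single-frame ("snapshot") morphological description often cannot
separate cell states that differ mainly in their *dynamics*.  morphodyn
implements a trajectory-embedding analysis: every tracked cell contributes
all of its sliding-window feature trajectories of length `n_tau` frames, each
flattened into a supervector, and the pooled supervectors across all
experimental conditions are embedded into a shared low-dimensional cell-state
landscape.  In that landscape the package quantifies how distinguishable
conditions are (distribution overlap), how predictable trajectories are
(locality ratio, Markov-model likelihood), where cells flow (force-fields),
and which regions are metastable (density peaks, kinetic coarse-graining).

## Pipeline stages and their models

### Preprocessing

Each frame is z-normalized (mean subtracted, divided by the per-frame SD) and
background pixels are then set exactly to 0.  Whether the mean/SD statistics
include background pixels is configurable (`stats_on="frame"` by default,
`"foreground"` optional), since either convention is defensible and the
downstream features are robust to the choice.  Stacks are registered by pure
translation (no rotation or affine component) using phase cross-correlation
with 10x upsampling, either chained frame-to-frame with cumulative shifts
(default: matches a drift-correction reading) or against frame 0.

Foreground segmentation is pluggable: user-supplied masks pass through
unchanged; a per-frame Otsu/fixed-threshold fallback with hole filling and a
minimum object area exists for quick synthetic work.  Neural or
classifier-based backends can be wired in as callables producing label masks.

### Featurization (91 features per cell per frame)

Cells are cut out of the z-normalized frame (pixels outside the cell mask set
to 0), centered in a zero-padded square patch, and rotated so the mask's
principal axis — from the unweighted second central moments — lies along the
horizontal; the 180-degree ambiguity is resolved by requiring a nonnegative
third moment along the axis.  Patch size defaults to the cell's own extent
plus padding, with a global fixed size available so features are strictly
comparable across treatments.

* **Zernike block (49)** — magnitudes of Zernike moments up to polynomial
  degree 12 (exactly 49 moments with `0 <= m <= n <= 12`, `n - m` even),
  unit disk inscribed at half the patch width, patch normalized by total
  intensity.  Magnitudes make the block rotation-invariant.  Implemented from
  the radial-polynomial definition and validated against an independent
  binomial-form brute-force oracle.
* **Haralick block (12)** — the 13 classical co-occurrence statistics on a
  distance-1, 4-direction-averaged, symmetric GLCM of the patch quantized to
  8 gray levels over the cell mask, with the sum-average feature discarded
  (it scales with the arbitrary gray-level origin).  The GLCM is mask-aware:
  only pixel pairs fully inside the cell are counted.  Constant patches fall
  back to a zero vector with a warning.
* **Shape block (15)** — the centroid-to-boundary distance r(theta) is
  sampled along 64 equally spaced rays (farthest mask crossing per ray, a
  deterministic rule for non-convex masks); the block is |FFT(r)| at
  frequencies 0..14, rescaled to sum to 1.  A perfect disk concentrates all
  weight in the DC term; pixelation leaves small higher harmonics.
* **Environment block (15)** — a binary contact indicator c(theta) (1 where
  neighboring-cell foreground lies within ~2 px outside the boundary point)
  receives the same Fourier treatment.  An isolated cell yields the all-zero
  block rather than an invented uniform one.  Because sum-normalization
  distorts the interpretation of the DC component, the raw boundary contact
  fraction is reported as a separate auxiliary column.

Pooled raw features across all treatments and stacks are reduced by PCA on
the feature covariance (centering only; an optional standardized mode divides
by per-feature SDs first), retaining `n_pc = 3` components by default.

### Tracking

Contiguous foreground clusters (8-connected, configurable) are separated
first.  Cells in clusters under 10,000 px are linked by minimum centroid
distance with a 45 px cutoff: each cell at frame t+1 claims its nearest
predecessor, so several cells may share a parent (division or
over-segmentation), but no cell has two parents.  Clusters of at least
10,000 px are matched between frames by cluster-centroid distance (300 px
cutoff), each matched pair is rigidly registered (centroid translation plus
a coarse-to-fine rotation search within +/-20 degrees maximizing binary
overlap), and member cells are linked by maximum mask overlap requiring at
least 10 shared pixels.  Ties in distance go to the lower label.  Unlinked
cells simply start new histories; there is no gap closing or global
assignment.

Histories are the unique backward traces from leaf cells (cells without a
successor).  Daughters of a division are two separate histories sharing the
parental prefix; no mitosis classification is attempted.

### Trajectory embedding

A history of length T yields `T - n_tau + 1` snippets (a 12-frame track has 5
snippets of length 8: frames 1-8 through 5-12) and `T - n_tau` single-step
transitions between consecutive snippets.  Supervectors are the time-ordered
concatenation of per-frame PC vectors (length `n_pc * n_tau`).  The default
reducer is UMAP (`n_neighbors=15`, `min_dist=0.1`, fixed `random_state`) with
a pluggable contract — any object with `fit_transform`/`transform` works, and
a PCA reducer is built in for fast linear baselines.  Out-of-sample snippets
(validation sets) are transformed with the fitted model, never refit.
Determinism holds for a fixed seed and library version; coordinates are not
bit-stable across UMAP versions.

The **scrambled null** permutes per-cell-frame feature rows across all
(cell, frame) slots within each treatment and rebuilds snippets on the
original tracks, destroying temporal ordering while preserving the marginal
feature distribution exactly.  Null data are embedded with identical
hyperparameters, refit per condition, exactly as the real data.

### Dynamics layer

* **Overlap coefficient** — sum over shared-grid bins of min(p, q); the grid
  spans the 1st-99th percentile box of the pooled coordinates (100x100 bins
  by default, fewer for small samples since finite-sample overlap is biased
  downward on fine grids).
* **Locality ratio** — RMS single-step displacement divided by the RMS
  displacement between two random draws from the pooled population
  (sqrt(2) x the population SD, summed over dimensions inside the square
  root).  This normalization makes fully random (i.i.d.-position)
  trajectories score exactly 1 and frozen trajectories 0; a stationary AR(1)
  process with coefficient phi scores sqrt(1 - phi).
* **Force-field** — per-bin mean single-step displacement of all transitions
  starting in the bin (proportional to the effective drift in a Markovian
  diffusion picture); bins with fewer than `min_count` starts are undefined.
* **Microstate Markov model** — k-means with k = 100 microbins (scaled down
  for small samples), transition matrix `T_ij = C_ij / C_i` from observed
  counts with raw counts retained and empty rows flagged rather than
  normalized.  Birth/death is intentionally not modeled, so the matrix need
  not share a steady state with the population.  The validation score is the
  mean per-step log-likelihood `<L> = mean log T_ij` over held-out
  transitions, with a pseudocount `alpha = 1/k` added to all counts by
  default so unseen transitions remain finite (a strict mode errors
  instead); with uniform counts the pseudocount cancels exactly, so a
  uniform chain scores exactly -log k.
* **Metastable states** — per-treatment Gaussian-KDE density maxima on the
  shared grid, thresholded at a fraction of the per-treatment peak density
  and deduplicated across treatments within one bandwidth.  The KDE uses
  1.5x Scott's bandwidth by default: at exactly Scott scale the flat top of
  a sampled mode carries noise-induced spurious local maxima, and mild
  oversmoothing suppresses them without displacing well-separated peaks.
  Microstates are grouped into macrostates by spectral (PCCA-style)
  clustering of the symmetrized transition matrix — k-means on its leading
  eigenvectors — with a manual microstate-to-macrostate override supported,
  since refined state definitions are often curated by eye.  Fine-grained
  peaks inherit the macrostate of their nearest microstate center, and cells
  are mapped to states via their nearest peak.
* **Bayesian bootstrap** — replicate-level values are reweighted with
  Dirichlet(1, ..., 1) draws; the 95% interval is the 2.5/97.5 percentile
  range of the weighted means.

## What the simulators emulate — and what they do not

`simulate_feature_trajectories` produces per-cell feature time series driven
by a hidden Markov state chain with discrete-time Ornstein-Uhlenbeck
relaxation toward the current state mean
(`x_{t+1} = x_t + a (mu_s - x_t) + eps`).  It emits features directly on the
reduced (PC-like) scale, bypassing imaging, so the embedding and dynamics
layers can be tested against exactly known state dynamics.  `observed_dims`
withholds feature dimensions, emulating the partial-observation regime where
temporal context carries information a snapshot cannot.

`render_movie` draws textured ellipses (radial intensity gradient plus seeded
speckle, so texture features are non-degenerate) over an optionally noisy
background, with Gaussian random-walk motion, constant drift, border
reflection, and divisions that replace a parent by two half-area daughters
straddling its centroid.  Masks are exact and links are recorded, including
both daughters' links to the parent.

Neither simulator models optics (no PSF, no phase-contrast halo), realistic
cell shape deformation, intensity drift, segmentation errors, or cell death.
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the computational pipeline — not that the features or the
tracker are optimal on real microscopy data.

## Study conditions for the qualitative dynamics benchmarks

The treatment-distinguishability and predictability benchmarks use two
simulated "treatments" sharing one emission model — two hidden states with
means (-0.5, 0, -2) and (+0.5, 0, +2), relaxation rate 0.8, noise SD 0.4 —
but different symmetric switching probabilities: 0.45 (nearly memoryless)
versus 0.05 (persistent, metastable).  The third, strongly state-separated
feature dimension is withheld (`observed_dims = (0, 1)`), so the observed
marginal distributions of the two treatments are identical by construction
and only temporal structure can distinguish them.  Each treatment simulates
100 cells for 25 frames; embeddings are fitted per condition at
`n_tau in {1, 2, 4, 8}` with shared hyperparameters, and overlap is measured
on a 25x25 shared grid (appropriate to ~2-5 x 10^3 points per treatment).
Under these conditions the between-treatment overlap decreases monotonically
with `n_tau` and sits well below the scrambled null at `n_tau = 8`; the
locality ratio of the true dynamics decreases with `n_tau` while the null
stays near 1; and the validation log-likelihood of the true dynamics exceeds
the null's.  The Markov-recovery benchmark uses a separate 500-cell,
201-frame two-state simulation (1e5 transitions), recovering the hidden
transition matrix within 0.02 per entry.

## Numerical choices and degenerate inputs

* Boundary profiles use 64 rays and ray steps of 0.25 px; nearest-neighbor
  mask lookup.  Empty masks raise; all-zero contact indicators yield the
  all-zero environment block.
* Zernike moments use the inscribed disk of radius = half the patch width;
  an all-zero patch yields the zero vector.
* The k-means microstate count is clamped in the pipeline driver to at most
  a quarter of the available points.
* Histogram grids clip out-of-range points into border bins so every
  condition's histogram sums to exactly 1 on the shared support.
* Transition-matrix rows without observed transitions are left unnormalized
  (zeros) and flagged; the likelihood pseudocount policy is configurable.
* All stochastic components (simulators, k-means, UMAP, bootstrap) take
  explicit seeds; the pipeline driver derives per-stage seeds from one
  global seed by stable hashing.

## Known limitations

* The two-regime tracker is greedy and local; it does not close gaps across
  missing frames and will fragment tracks under heavy occlusion.
* UMAP coordinates (and hence landscape geometry) are stable only for a
  fixed library version and seed; all statistics are computed downstream of
  whatever embedding is supplied, and conclusions should be checked across
  seeds — the replicate-split and bootstrap utilities exist for exactly
  that.
* The locality ratio in an embedded space inherits the embedding's local
  metric distortion; on scrambled data it is exactly 1 in the supervector
  space but only approximately 1 (within ~5%) after a nonlinear embedding.
* Fourier shape features assume a star-shaped-enough mask for the
  farthest-crossing radial profile to be informative; highly filamentous
  shapes are summarized coarsely.
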