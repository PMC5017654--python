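# Methods

## Model

One grayscale image is modeled as a Dirichlet-process mixture over pixel
intensities whose label field is regularized by a pairwise Potts Markov
random field; several images are coupled by making each image-level DP's
base measure a draw from a top-level DP (a hierarchical Dirichlet process),
so all images draw their intensity classes from one shared, countable atom
set.

**Observation model.** The pixel feature is the scalar standardized
intensity. The likelihood is univariate Gaussian with unknown mean and
variance per atom under a conjugate normal–inverse-gamma (NIG) base
measure: `mean ~ N(μ₀, σ²/κ₀)`, `σ² ~ InvGamma(a₀, b₀)`. Atom parameters
are integrated out, so an atom is carried entirely by its sufficient
statistics `(n, Σx, Σx²)`; the one-point posterior predictive is a scaled,
shifted Student-t and the block marginal likelihood is available in closed
form. Defaults `μ₀ = 0, κ₀ = 0.1, a₀ = 2, b₀ = 1` are weakly informative on
standardized data (prior predictive scale ≈ 2.3). Richer per-pixel
features would slot in by replacing this observation model; only scalar
intensity is implemented.

**Spatial prior.** The label field interacts over a 4-connected pixel
lattice by default (8-connectivity optional), uniform edge weights
`w_il = 1`, no wraparound. Each candidate label's full conditional is
multiplied by `exp(+λ · Σ_{l∈∂(i)} w_il δ(S_i, S_l))` — agreement with
neighbors is *favored*. Note the sign: writing the pairwise energy as
`H_c = λ Σ w_il δ(S_i,S_l)` inside `exp(−H)` would penalize agreement and
roughen the segmentation; the implementation deliberately uses the
attractive convention, which is the one that makes a smoothing parameter
smooth. In joint mode the interaction acts on the *global* (atom) labels,
so the MRF and category sharing compose: a tumor pixel is pulled toward
the shared tumor atom by its neighbors.

**Concentrations.** `α₀` (default 0.01) controls how readily an image opens
a new local cluster, `γ` (default 1.0) how readily the hierarchy creates a
new global atom. Under the Chinese restaurant process a *larger* `α₀`
yields more clusters a priori (new-cluster probability `α₀/(α₀+n)`); the
implementation follows this standard predictive. `λ` (default 0.001) is
the smoothing weight; `λ = 0` turns the MRF off exactly, reducing every
conditional to the plain collapsed DP/HDP conditional (asserted to 1e-12
in the tests).

## Inference

Collapsed Gibbs in the Chinese-restaurant-franchise representation. One
sweep is:

1. **Pixel stage** (per image, fixed raster order): remove the pixel from
   its table; score every existing table of that image by
   `n_t · p(x | dish stats) · exp(λ·agreement)` and the new-table option by
   `α₀ · [Σ_k m_k p(x|k) e^{λ·agree(k)} + γ p(x|H)] / (γ + M)`, where `m_k`
   counts tables serving dish `k` and `M = Σ m_k`; sample, and if a new
   table was opened draw its dish from the bracketed mixture.
2. **Table stage** (all tables, ascending id): remove the table's block
   from its dish; score each dish by `m_k ·` (block marginal-likelihood
   ratio) `· exp(λ·boundary agreement)` and a fresh dish by `γ ·` (block
   marginal). The boundary factor — the Potts agreement between the
   table's member pixels and neighbors outside the table — is required for
   the chain to target the same joint the enumeration oracle scores; it
   vanishes at `λ = 0`.

Single-image mode is the same chain without the hierarchy (tables are
atoms, new-cluster weight `α₀ · p(x|H)`).

Empty tables and dishes are deleted immediately; all bookkeeping is O(1)
via active lists and free stacks in capacity-bounded arrays, and the sweeps
are numba-compiled (the scalar NIG densities are the same source functions
the pure-Python API uses). Correctness of the compiled chains is
established against `brute_force_posterior`, which enumerates all set
partitions (and all table-to-dish groupings in joint mode) on instances of
at most 6 pixels and scores them by CRP/CRF prior mass × collapsed marginal
likelihood × Potts factor: the empirical distribution of sampled
configurations matches the exact posterior within total-variation 0.02 at
10⁵ sweeps on the fixture instances, in both modes and with `λ > 0`.

**Initialization** is deterministic: pooled equal-*width* intensity bins
(8 by default) shared across images, one dish per occupied bin and one
table per (image, bin). Equal widths keep well-separated classes in
distinct bins even when a class covers few pixels — pooled *quantile* bins
would lump minority classes (tumor, vertebra) into one bin, and since the
collapsed sampler has no split moves, a table mixing two classes is hard
to undo. Starting with more clusters than classes and letting the chain
merge is the easy direction.

**Standardization.** Single mode standardizes each image to mean 0, sd 1
(population-sd convention). Joint mode standardizes with *pooled* mean and
sd across the image set: per-image standardization would shift class means
differently in images with different class subsets and break the
cross-image alignment the hierarchy depends on.

**Final estimate.** The "mode" is computed as a label-aligned per-pixel
majority vote: every retained sample (default: sweeps 200–599 thinned by
4, the last sweep always retained) is aligned to the last retained sample
by maximum-overlap injective matching of its global labels, then each
pixel takes its majority label, ties toward the smaller id. The retained
sample with the highest log joint is also stored (`map_labels`). The
per-sweep trace is the unnormalized log joint up to configuration-
independent constants.

**Determinism.** All draws come from one seeded kernel RNG stream;
identical inputs, hyperparameters and config reproduce results
byte-for-byte, including serialized label maps and CSV tables.

## Synthetic phantoms

The generator emulates exactly the structure the model assumes: global
Gaussian intensity classes shared across images, per-image class subsets,
spatially coherent regions. The geometric layout mimics an axial chest
slice — background, two lung ellipses, a vertebra rectangle, an optional
tumor disk — with a ±2-pixel seeded jitter of region positions per image
("similar but not identical positioning"); a Potts-sampled layout provides
irregular, patient-specific region shapes for stress tests. The canonical
validation fixture (`default_lung_spec`) is 4 images at 64×64 with class
means (−1, −3, 3, 1) and sd 0.5 — minimum separation 4 within-class sd —
and the tumor class absent from the second image.

What the phantom does *not* emulate: CT physics (beam hardening, partial
volume, streaks), intensity inhomogeneity within an organ, anatomical
shape variability beyond jitter, and 3-D context. Passing the recovery
suite therefore shows the inference machinery is correct and that category
sharing works under the model's own assumptions; it does not certify
clinical accuracy on scanner data, where within-class intensity overlap is
far larger (manual tracing remains the reference there).

## Validation surface and problem sizes

* Oracle equivalence: 2×2 single-image instance at `λ ∈ {0, 0.5}` and two
  1×2 images jointly at `λ = 0`, 10⁵ recorded sweeps, TV ≤ 0.02.
* Recovery: the canonical 4-image phantom, model defaults, 10 sampler
  seeds — recovered class count within ±1 of 4 and mean matched Jaccard
  ≥ 0.85 in ≥ 7 seeds; tumor regions of the three tumor-bearing images
  share one global atom id in ≥ 7 seeds.
* Smoothing direction: on a 32×32 two-class phantom at 1.5-sd separation,
  the mean distinct-label count over 10 seeds is non-increasing across
  `λ ∈ {0, 0.001, 0.01}` (a larger smoothing weight over-smooths toward
  fewer clusters).
* Exact surface: Jaccard toy cases, CRP new-cluster probabilities,
  lattice edge counts, sufficient-statistic add/remove inversion.

These sizes were chosen so the entire suite runs in a couple of minutes on
one CPU while keeping every check statistically meaningful.

## Evaluation

Predicted labels are arbitrary ids, so scoring first finds the
maximum-total-overlap injective mapping from predicted to truth labels
(Hungarian assignment on the contingency table; ties broken toward the
lowest id pair), then reports per-truth-object Jaccard. Truth objects left
unmatched score 0 — merging away an object (e.g. losing the vertebral
column into soft tissue) is counted against the method rather than
silently dropped.

## Known limitations

* No split–merge or other global moves: mixing relies on single-pixel and
  single-table moves plus the over-segmented initialization. Pathological
  merged states at very small `α₀` can persist.
* Scalar intensity only; no texture or gradient features.
* 2-D slices only; a volume must be segmented slice by slice.
* Hyperparameters are fixed, not resampled.
* The Potts weight interacts with cluster count: large `λ` deliberately
  over-smooths (fewer, larger segments), so `λ` should stay small when
  thin structures matter.
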