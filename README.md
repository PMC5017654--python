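# hdpseg

Joint Bayesian segmentation of grayscale medical images — typically axial
lung CT slices — with an MRF-regularized Dirichlet-process mixture per
image, tied together by a hierarchical Dirichlet process so that the images
share one global set of intensity classes ("organs"). The model is fully
nonparametric: the number of segments is inferred from the data, and a
class present in some images but absent from others (a tumor, say) is
handled naturally.

## The model

Each pixel intensity `x_ji` (pixel *j* of image *i*, standardized) is drawn
from a Gaussian `F(θ_ji)` whose parameter comes from an image-level random
measure `G_i`:

```
x_ji | θ_ji ~ N(θ_ji)            θ_ji | G_i ~ G_i
G_i | α₀, G₀ ~ DP(α₀, G₀)        G₀ | γ, H  ~ DP(γ, H)
```

Because `G₀` is itself a DP draw, it is discrete, so its atoms — the global
intensity classes — are shared across all images, each image using a
subset. The base measure `H` is a conjugate normal–inverse-gamma prior, so
atom parameters are collapsed analytically and every atom is summarized by
its sufficient statistics. Inside each image the label field `S` is
additionally regularized by a Potts Markov random field: every candidate
label's conditional probability is multiplied by
`exp(λ · Σ_{l∈∂(i)} w_il · δ(S_i, S_l))`, favoring agreement with lattice
neighbors (4- or 8-connectivity, unit edge weights).

Inference is collapsed Gibbs sampling in the Chinese-restaurant-franchise
representation (images = restaurants, local clusters = tables, global atoms
= dishes): a raster-order pixel pass per image resamples table assignments,
then every table resamples its dish given its member data. A plain
single-image DP-MRF sampler (`mode="single_dp"`) is included for
comparison. The final segmentation is the per-pixel majority label across
retained samples after aligning their labels by maximum-overlap matching.
Accuracy against ground truth is scored with the Jaccard index
`JI = |A∩B| / |A∪B|` after optimal injective label matching.

Defaults: `α₀ = 0.01`, `λ = 0.001`, `γ = 1`, with sweeps 600 / burn-in
200 / thinning 4. Both samplers' stationary distributions are validated in
the test suite against exact brute-force enumeration of the posterior on
tiny instances.

## Worked example

Segment the bundled 4-image synthetic chest phantom (64×64, four intensity
classes; the second image lacks the tumor class) jointly:

```python
import numpy as np
import hdpseg as H

pset = H.generate_phantoms(H.default_lung_spec(4, seed=0))
hp   = H.Hyperparameters()                       # alpha0=0.01, lam=0.001, gamma=1
res  = H.run_sampler(pset.images, hp, H.SamplerConfig(seed=1))

used = np.unique(np.concatenate([lf.flat() for lf in res.label_fields]))
print("global atoms in final estimate:", len(used))
print("atom posterior means:", {k: round(v, 2) for k, v in res.atom_means.items()})
df = H.score_run(res, pset.truth_labels,
                 object_names={0: "background", 1: "lung", 2: "vertebra", 3: "tumor"})
print(df.groupby("object").jaccard.mean().round(3))
```

prints

```
global atoms in final estimate: 4
atom posterior means: {1: -1.36, 3: 0.23, 5: 1.82, 6: 3.36}
object
background    0.971
lung          0.924
tumor         0.796
vertebra      0.966
```

The sampler recovers the true number of shared classes (4) without being
told it; the four atom means correspond to lung, background, tumor and
vertebra in pooled-standardized units; and the per-object Jaccard indices
quantify overlap with the ground-truth regions (mean 0.92 here). The
tumor atom is the *same* global id in every image that contains a tumor —
the category-sharing effect that motivates the hierarchical model.

The same pipeline is available from a shell:

```
hdpseg phantom --n-images 4 --seed 0 --out phantom/
hdpseg joint phantom/image_*.png --seed 1 --out run/
hdpseg score --pred run/labels_000.png --truth phantom/truth_000.png ...
hdpseg segment slice.png --seed 1 --out run_single/   # single-image DP-MRF
```

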