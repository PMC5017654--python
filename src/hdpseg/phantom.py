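"""Synthetic multi-image phantoms with shared intensity classes.

The generator reproduces exactly the statistical structure the hierarchical
segmentation model assumes: a common set of global intensity classes across
images, a per-image subset of those classes, spatially coherent regions,
and Gaussian intensity noise within each region.  The geometric layout
mimics an axial chest slice — a background, two lung ellipses, a vertebra
rectangle and an optional tumor disk — with a small seeded jitter of region
positions per image so images are similar but not identical.  The class
names are purely cosmetic; the model only ever sees intensities.

A Potts-sampled layout is also provided for stress tests with irregular,
patient-specific region shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mrf import LabelField, build_neighborhood

CLASS_NAMES = ("background", "lung", "vertebra", "tumor")


@dataclass
class PhantomSpec:
    n_images: int
    height: int
    width: int
    n_global_classes: int
    class_means: list
    class_sd: float
    per_image_class_subsets: list
    layout: str = "geometric"  # or "potts"
    potts_beta: float = 1.2
    potts_sweeps: int = 30
    jitter: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.height < 1 or self.width < 1:
            raise ValueError("n_images, height, width must be positive")
        if len(self.class_means) != self.n_global_classes:
            raise ValueError("class_means length must equal n_global_classes")
        if not self.class_sd > 0:
            raise ValueError("class_sd must be positive")
        if len(self.per_image_class_subsets) != self.n_images:
            raise ValueError("one class subset per image required")
        all_classes = set(range(self.n_global_classes))
        used = set()
        for sub in self.per_image_class_subsets:
            s = set(sub)
            if not s or not s <= all_classes:
                raise ValueError(f"invalid class subset {sub}")
            used |= s
        if used != all_classes:
            raise ValueError("every global class must appear in at least one image")
        if self.layout not in ("geometric", "potts"):
            raise ValueError(f"unknown layout {self.layout!r}")

    def min_separation_in_sd(self) -> float:
        """Smallest pairwise class-mean separation in units of class_sd."""
        m = np.sort(np.asarray(self.class_means, dtype=float))
        if m.size < 2:
            return np.inf
        return float(np.diff(m).min() / self.class_sd)


@dataclass
class PhantomSet:
    images: list            # list of 2-D float arrays
    truth_labels: list      # list of LabelField with global class ids
    spec: PhantomSpec = field(repr=False, default=None)


def _paint_geometric(height, width, classes_present, rng, jitter):
    """Label map for one image: background, two lungs, vertebra, tumor disk."""
    lab = np.zeros((height, width), dtype=np.int64)  # class 0 background
    rr, cc = np.ogrid[:height, :width]
    j = lambda: int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
    sy, sx = height / 64.0, width / 64.0

    if 1 in classes_present:  # two lung ellipses
        for cx0 in (20, 44):
            cy = 30 * sy + j()
            cx = cx0 * sx + j()
            ry, rx = 18 * sy, 9 * sx
            if ry <= 0 or rx <= 0:
                raise ValueError("degenerate lung ellipse (zero radius)")
            lab[((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0] = 1
    if 2 in classes_present:  # vertebra rectangle, posterior midline
        r0 = int(47 * sy) + j()
        c0 = int(27 * sx) + j()
        r1, c1 = r0 + max(int(12 * sy), 1), c0 + max(int(10 * sx), 1)
        lab[max(r0, 0):r1, max(c0, 0):c1] = 2
    if 3 in classes_present:  # tumor disk inside the right lung
        cy, cx = 24 * sy + j(), 44 * sx + j()
        rad = 6.0 * min(sy, sx)
        if rad <= 0:
            raise ValueError("degenerate tumor disk (zero radius)")
        lab[(rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2] = 3
    return lab


def _paint_potts(height, width, classes_present, rng, beta, sweeps):
    """Label map sampled from a Potts model restricted to the image's classes."""
    classes = sorted(classes_present)
    lab = rng.choice(classes, size=(height, width))
    graph = build_neighborhood(height, width, 4)
    flat = lab.ravel()
    for _ in range(sweeps):
        for i in rng.permutation(height * width):
            logw = np.empty(len(classes))
            for ci, c in enumerate(classes):
                agree = 0.0
                for l, w in zip(graph.nbr_idx[i], graph.nbr_w[i]):
                    if l >= 0 and flat[l] == c:
                        agree += w
                logw[ci] = beta * agree
            p = np.exp(logw - logw.max())
            p /= p.sum()
            flat[i] = classes[rng.choice(len(classes), p=p)]
    return flat.reshape(height, width)


def generate_phantoms(spec: PhantomSpec) -> PhantomSet:
    """Generate images and ground-truth label fields from a spec.

    Pixel (r, c) of image j is drawn Normal(class_means[label], class_sd^2)
    where the label map is built by the chosen layout.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    images, truths = [], []
    means = np.asarray(spec.class_means, dtype=np.float64)
    for idx in range(spec.n_images):
        present = set(spec.per_image_class_subsets[idx])
        if spec.layout == "geometric":
            lab = _paint_geometric(spec.height, spec.width, present, rng, spec.jitter)
        else:
            lab = _paint_potts(spec.height, spec.width, present, rng,
                               spec.potts_beta, spec.potts_sweeps)
        img = means[lab] + rng.normal(0.0, spec.class_sd, size=lab.shape)
        images.append(img)
        truths.append(LabelField(lab, image_index=idx))
    return PhantomSet(images=images, truth_labels=truths, spec=spec)


def default_lung_spec(n_images: int, seed: int = 0) -> PhantomSpec:
    """Canonical 64x64, 4-class phantom spec used by the validation suite.

    Class means (-1, -3, 3, 1) for (background, lung, vertebra, tumor) with
    sd 0.5 give a minimum pairwise separation of 4 within-class standard
    deviations.  With two or more images, the second image omits the tumor
    class, exercising partial category sharing.
    """
    all_classes = {0, 1, 2, 3}
    subsets = [set(all_classes) for _ in range(n_images)]
    if n_images >= 2:
        subsets[1] = {0, 1, 2}
    return PhantomSpec(
        n_images=n_images,
        height=64,
        width=64,
        n_global_classes=4,
        class_means=[-1.0, -3.0, 3.0, 1.0],
        class_sd=0.5,
        per_image_class_subsets=subsets,
        layout="geometric",
        seed=seed,
    )
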