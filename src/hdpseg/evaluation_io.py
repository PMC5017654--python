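"""Jaccard scoring with label matching, image/label-map IO and run config.

Scoring: a segmentation carries arbitrary cluster ids, so before computing
per-object Jaccard indices the predicted labels are put in optimal
correspondence with the ground-truth labels by a maximum-total-overlap
injective assignment (Hungarian algorithm on the label contingency table).
Truth objects left unmatched score 0 — a segmentation that merges away an
object is penalized, not silently dropped.

IO: grayscale PNG/TIFF (8/16-bit) and single-slice NIfTI images are read
into an :class:`ImageSlice`; label maps round-trip exactly as 16-bit PNG
with a JSON palette sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .inference import SamplerConfig, SegmentationResult
from .model_core import Hyperparameters
from .mrf import LabelField

logger = logging.getLogger("hdpseg")


@dataclass
class ImageSlice:
    """One 2-D grayscale intensity grid with acquisition metadata."""

    pixels: np.ndarray
    spacing: tuple = (1.0, 1.0)
    path: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice requires a 2-D grid")


@dataclass
class MatchResult:
    mapping: dict                # predicted label -> truth label (injective)
    jaccard: dict                # truth label -> Jaccard in [0, 1]
    unmatched_pred: set


@dataclass
class RunConfig:
    """Flat run configuration: hyperparameters + sampler settings + IO."""

    alpha0: float = 0.01
    gamma: float = 1.0
    lam: float = 0.001
    base_mu0: float = 0.0
    base_kappa0: float = 0.1
    base_a0: float = 2.0
    base_b0: float = 1.0
    n_sweeps: int = 600
    burn_in: int = 200
    thin: int = 4
    seed: int = 0
    mode: str = "joint_hdp"
    connectivity: int = 4
    inputs: list = field(default_factory=list)
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        # delegate validation to the typed containers
        self.hyperparameters()
        self.sampler_config()
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(self.alpha0, self.gamma, self.lam, self.base_mu0,
                               self.base_kappa0, self.base_a0, self.base_b0)

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(self.n_sweeps, self.burn_in, self.thin,
                             self.seed, self.mode)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Jaccard index and label matching
# ---------------------------------------------------------------------------

def jaccard_index(A, B) -> float:
    """|A n B| / |A u B| for two pixel sets; symmetric, in [0, 1]."""
    sa, sb = set(A), set(B)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(sa & sb) / len(union)


def match_labels(pred: LabelField, truth: LabelField) -> MatchResult:
    """Optimal injective correspondence of predicted to truth labels.

    Maximizes total pixel overlap over injective mappings (Hungarian
    assignment on the contingency table); ties between equally good
    assignments break toward the lowest (truth id, pred id) pair.  Truth
    objects without a match get Jaccard 0.
    """
    from scipy.optimize import linear_sum_assignment

    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.flat()
    t = truth.flat()
    pred_ids = np.unique(p)
    truth_ids = np.unique(t)
    pi = {v: j for j, v in enumerate(pred_ids)}
    ti = {v: j for j, v in enumerate(truth_ids)}
    cont = np.zeros((len(pred_ids), len(truth_ids)), dtype=np.int64)
    np.add.at(cont, (np.vectorize(pi.get)(p), np.vectorize(ti.get)(t)), 1)
    # tiny rank perturbation: total perturbation < 0.5 so it only breaks ties
    nP, nT = cont.shape
    rank = (np.arange(nT)[None, :] * nP + np.arange(nP)[:, None]).astype(float)
    eps = 0.4 / (nP * nT * (nP * nT + 1))
    rows, cols = linear_sum_assignment(-(cont - eps * rank))
    mapping = {}
    jac = {int(v): 0.0 for v in truth_ids}
    for r, c in zip(rows, cols):
        if cont[r, c] > 0:
            pv, tv = int(pred_ids[r]), int(truth_ids[c])
            mapping[pv] = tv
            inter = int(cont[r, c])
            union = int((p == pv).sum() + (t == tv).sum() - inter)
            jac[tv] = inter / union
    unmatched = set(int(v) for v in pred_ids) - set(mapping)
    return MatchResult(mapping=mapping, jaccard=jac, unmatched_pred=unmatched)


def score_run(result: SegmentationResult, truth: list,
              object_names: dict | None = None) -> pd.DataFrame:
    """Per-image, per-object Jaccard table for a segmentation result.

    ``truth`` is one ground-truth :class:`LabelField` per image.  Returns a
    tidy frame with columns (image, object, truth_label, jaccard).
    """
    if len(result.label_fields) != len(truth):
        raise ValueError("image count mismatch between result and truth")
    rows = []
    for img, (pred_lf, true_lf) in enumerate(zip(result.label_fields, truth)):
        m = match_labels(pred_lf, true_lf)
        for tv in sorted(m.jaccard):
            name = (object_names or {}).get(tv, f"object_{tv}")
            rows.append({"image": img, "object": name,
                         "truth_label": tv, "jaccard": m.jaccard[tv]})
    return pd.DataFrame(rows, columns=["image", "object", "truth_label", "jaccard"])


# ---------------------------------------------------------------------------
# Image and label-map IO
# ---------------------------------------------------------------------------

def read_image(path) -> ImageSlice:
    """Read a grayscale PNG/TIFF (8/16-bit) or single-slice NIfTI."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).squeeze()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        return ImageSlice(np.asarray(data, dtype=np.float64),
                          spacing=tuple(float(z) for z in zooms), path=str(path))
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "L", "F"):
            arr = np.asarray(im, dtype=np.float64)
        else:
            raise ValueError(
                f"{path}: multi-channel or unsupported mode {im.mode!r}; "
                "grayscale 8/16-bit input required")
    return ImageSlice(arr, path=str(path))


def write_labelmap(path, lf: LabelField, palette: dict | None = None) -> None:
    """Write a label field as 16-bit PNG with a JSON palette sidecar."""
    path = Path(path)
    labels = np.asarray(lf.labels)
    if labels.max() > 0xFFFF:
        raise ValueError("label value overflows 16 bits")
    Image.fromarray(labels.astype(np.uint16)).save(path)
    sidecar = {
        "image_index": int(lf.image_index),
        "palette": {str(k): v for k, v in (palette or {}).items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def read_labelmap(path) -> LabelField:
    """Round-trip counterpart of :func:`write_labelmap`."""
    path = Path(path)
    with Image.open(path) as im:
        labels = np.asarray(im, dtype=np.int64)
    image_index = 0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        image_index = json.loads(sidecar.read_text()).get("image_index", 0)
    return LabelField(labels, image_index=image_index)


def write_image_png(path, pixels: np.ndarray) -> None:
    """Write an intensity grid as 16-bit PNG (affinely rescaled to the range)."""
    arr = np.asarray(pixels, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 0xFFFF
    Image.fromarray(np.round(scaled).astype(np.uint16)).save(path)


def save_result(out_dir, result: SegmentationResult, config: RunConfig | None = None,
                object_names: dict | None = None) -> None:
    """Serialize a run: per-image label maps, JSON sidecar, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lf in result.label_fields:
        write_labelmap(out / f"labels_{lf.image_index:03d}.png", lf,
                       palette=object_names)
    manifest = {
        "seed": result.config.seed,
        "mode": result.config.mode,
        "n_sweeps": result.config.n_sweeps,
        "burn_in": result.config.burn_in,
        "thin": result.config.thin,
        "atom_means": {str(k): result.atom_means[k] for k in sorted(result.atom_means)},
        "log_joint": [float(v) for v in result.log_joint],
        "config": asdict(config) if config is not None else None,
    }
    (out / "run.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
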