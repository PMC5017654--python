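"""Pixel neighborhood graph and Potts-type label interaction.

The spatial prior is a pairwise Markov random field on the pixel lattice:
each edge (i, l) with weight w_il contributes a factor exp(lam * w_il) to
the joint whenever the two pixels carry the same label.  Agreement is
*favored* (the factor multiplies the conditional by exp(+lam * agreement)),
which is what "enforce label proximity for neighboring pixels" requires.
Only the per-pixel conditional is ever needed, so the MRF partition
function is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_OFFSETS_8 = _OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class NeighborhoodGraph:
    """Symmetric pixel adjacency on an ``height x width`` lattice.

    ``nbr_idx`` holds, for each flattened pixel, the flat indices of its
    neighbors padded with -1; ``nbr_w`` the matching edge weights
    (uniform 1.0).  Boundary pixels simply have fewer neighbors: there is
    no wraparound and no self-edges.
    """

    height: int
    width: int
    connectivity: int
    edge_weight_scheme: str = "uniform"
    nbr_idx: np.ndarray = field(default=None, repr=False)
    nbr_w: np.ndarray = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def neighbors(self, i: int):
        """Neighbors of flat pixel ``i`` as ``[(flat_index, weight), ...]``."""
        row = self.nbr_idx[i]
        return [(int(l), float(w)) for l, w in zip(row, self.nbr_w[i]) if l >= 0]

    def n_edges(self) -> int:
        return int((self.nbr_idx >= 0).sum()) // 2

    def total_weight(self, i: int) -> float:
        """Sum of edge weights incident to pixel ``i``."""
        return float(self.nbr_w[i][self.nbr_idx[i] >= 0].sum())


@dataclass
class LabelField:
    """Per-pixel integer segmentation labels for one image."""

    labels: np.ndarray
    image_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if (np.asarray(self.labels) < 0).any():
            raise ValueError("labels must be non-negative integers")

    @property
    def shape(self):
        return self.labels.shape

    def flat(self) -> np.ndarray:
        return self.labels.ravel()


def build_neighborhood(height: int, width: int, connectivity: int = 4) -> NeighborhoodGraph:
    """Build the lattice adjacency with uniform unit edge weights."""
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if connectivity == 4:
        offsets = _OFFSETS_4
    elif connectivity == 8:
        offsets = _OFFSETS_8
    else:
        raise ValueError(f"unsupported connectivity {connectivity!r}; use 4 or 8")

    n = height * width
    dmax = len(offsets)
    nbr_idx = np.full((n, dmax), -1, dtype=np.int64)
    nbr_w = np.zeros((n, dmax), dtype=np.float64)
    for r in range(height):
        for c in range(width):
            i = r * width + c
            k = 0
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < height and 0 <= cc < width:
                    nbr_idx[i, k] = rr * width + cc
                    nbr_w[i, k] = 1.0
                    k += 1
    return NeighborhoodGraph(height, width, connectivity, "uniform", nbr_idx, nbr_w)


def agreement_sum(i: int, candidate_label: int, labels: LabelField,
                  graph: NeighborhoodGraph) -> float:
    """Weighted count of neighbors of pixel ``i`` carrying ``candidate_label``.

    Returns sum over l in the neighborhood of i of w_il * [S_l == candidate].
    The conditional is on the other pixels only, so pixel i's own label is
    irrelevant (the lattice has no self-edges).
    """
    flat = labels.flat()
    total = 0.0
    for l, w in zip(graph.nbr_idx[i], graph.nbr_w[i]):
        if l >= 0 and flat[l] == candidate_label:
            total += w
    return total


def mrf_log_factor(agreement: float, lam: float) -> float:
    """Log multiplicative boost ``+lam * agreement`` for label agreement."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    return lam * agreement
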