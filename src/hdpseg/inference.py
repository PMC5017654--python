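"""Collapsed Gibbs samplers for DP-MRF and HDP-MRF image segmentation.

Two chains are implemented over the same collapsed Gaussian/NIG observation
model:

* ``single_dp`` — one image, a Dirichlet-process mixture whose label field
  is regularized by a Potts interaction: each pixel is resampled from
  (cluster size or alpha0) x posterior predictive x exp(lam * neighbor
  agreement).
* ``joint_hdp`` — many images coupled through a hierarchical DP, sampled in
  the Chinese-restaurant-franchise representation: each image is a
  restaurant, local clusters are tables, global atoms are dishes shared
  across images.  One sweep is (a) a pixel pass per image resampling table
  assignments (a new table draws its dish from the franchise mixture
  m_k/(M+gamma), gamma/(M+gamma)) and (b) a pass over all tables resampling
  each table's dish given its member data.  The Potts factor enters both
  passes on the *global* (dish) labels, so spatial smoothing and category
  sharing interact correctly.

Both chains target the unnormalized joint that ``brute_force_posterior``
enumerates exactly on tiny instances, which is how the kernels are
validated.  The sequential sweeps are numba-compiled; the per-pixel full
conditional is additionally exposed in pure Python (``conditional_for_pixel``)
for inspection and testing.

The final segmentation is the per-pixel majority label across retained
samples after aligning every sample's labels to the last retained sample by
maximum-overlap matching ("mode" estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from . import model_core
from .model_core import Hyperparameters, standardize_intensities
from .mrf import LabelField, NeighborhoodGraph, build_neighborhood

_log_pred = njit(cache=True)(model_core._nig_log_pred)
_log_marg = njit(cache=True)(model_core._nig_log_marginal)

_SEED_MOD = 2**31


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# Sampler configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    n_sweeps: int = 600
    burn_in: int = 200
    thin: int = 4
    seed: int = 0
    mode: str = "joint_hdp"  # or "single_dp"
    keep_samples: bool = False

    def __post_init__(self) -> None:
        if self.n_sweeps < 1 or self.burn_in < 0 or self.burn_in >= self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.mode not in ("single_dp", "joint_hdp"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SegmentationResult:
    label_fields: list                     # per-image LabelField, global atom ids
    atom_means: dict                       # live atom id -> posterior mean intensity
    log_joint: np.ndarray                  # unnormalized log joint, one per sweep
    config: SamplerConfig
    map_labels: list                       # retained sample with highest log joint
    retained: list | None = None           # optional retained label samples


# ---------------------------------------------------------------------------
# Numba sweep kernels
# ---------------------------------------------------------------------------
# State layout (shared by both modes):
#   xs       — all pixels of all images, concatenated, standardized
#   assign   — pixel -> table id (joint) or atom id (single)
#   nbr_idx  — per-pixel neighbor *global* flat indices, padded with -1
# Tables and dishes live in capacity-bounded parallel arrays with an active
# list, a position index and a free-slot stack, so creation and deletion of
# clusters is O(1) inside the kernels.

@njit(cache=True)
def _sweep_single(xs, assign, nbr_idx, nbr_w,
                  atom_n, atom_s, atom_s2,
                  active, pos, free_, meta,
                  alpha0, lam, mu0, k0, a0, b0, logw):
    n = xs.shape[0]
    dmax = nbr_idx.shape[1]
    for i in range(n):
        xi = xs[i]
        k_old = assign[i]
        atom_n[k_old] -= 1
        atom_s[k_old] -= xi
        atom_s2[k_old] -= xi * xi
        if atom_n[k_old] == 0:
            p = pos[k_old]
            last = active[meta[0] - 1]
            active[p] = last
            pos[last] = p
            meta[0] -= 1
            free_[meta[1]] = k_old
            meta[1] += 1
            atom_s[k_old] = 0.0
            atom_s2[k_old] = 0.0
        na = meta[0]
        best = -1.0e300
        for ci in range(na):
            k = active[ci]
            lw = math.log(atom_n[k]) + _log_pred(
                xi, atom_n[k], atom_s[k], atom_s2[k], mu0, k0, a0, b0)
            if lam > 0.0:
                agree = 0.0
                for d in range(dmax):
                    l = nbr_idx[i, d]
                    if l >= 0 and assign[l] == k:
                        agree += nbr_w[i, d]
                lw += lam * agree
            logw[ci] = lw
            if lw > best:
                best = lw
        lw = math.log(alpha0) + _log_pred(xi, 0, 0.0, 0.0, mu0, k0, a0, b0)
        logw[na] = lw
        if lw > best:
            best = lw
        tot = 0.0
        for ci in range(na + 1):
            logw[ci] = math.exp(logw[ci] - best)
            tot += logw[ci]
        u = np.random.random() * tot
        acc = 0.0
        choice = na
        for ci in range(na + 1):
            acc += logw[ci]
            if u <= acc:
                choice = ci
                break
        if choice == na:
            k = free_[meta[1] - 1]
            meta[1] -= 1
            active[meta[0]] = k
            pos[k] = meta[0]
            meta[0] += 1
            atom_n[k] = 0
            atom_s[k] = 0.0
            atom_s2[k] = 0.0
        else:
            k = active[choice]
        assign[i] = k
        atom_n[k] += 1
        atom_s[k] += xi
        atom_s2[k] += xi * xi


@njit(cache=True)
def _pixel_stage_joint(xs, assign, nbr_idx, nbr_w, lo, hi, img,
                       table_img, table_dish, table_n, table_s, table_s2,
                       t_active, t_pos, t_free, t_meta,
                       dish_m, dish_n, dish_s, dish_s2,
                       d_active, d_pos, d_free, d_meta, g_meta,
                       alpha0, gamma_, lam, mu0, k0, a0, b0,
                       cand, logw, dpred, dagree, comps):
    dmax = nbr_idx.shape[1]
    for i in range(lo, hi):
        xi = xs[i]
        t_old = assign[i]
        d_old = table_dish[t_old]
        table_n[t_old] -= 1
        table_s[t_old] -= xi
        table_s2[t_old] -= xi * xi
        dish_n[d_old] -= 1
        dish_s[d_old] -= xi
        dish_s2[d_old] -= xi * xi
        if table_n[t_old] == 0:
            p = t_pos[t_old]
            last = t_active[t_meta[0] - 1]
            t_active[p] = last
            t_pos[last] = p
            t_meta[0] -= 1
            t_free[t_meta[1]] = t_old
            t_meta[1] += 1
            table_s[t_old] = 0.0
            table_s2[t_old] = 0.0
            g_meta[0] -= 1
            dish_m[d_old] -= 1
            if dish_m[d_old] == 0:
                p = d_pos[d_old]
                last = d_active[d_meta[0] - 1]
                d_active[p] = last
                d_pos[last] = p
                d_meta[0] -= 1
                d_free[d_meta[1]] = d_old
                d_meta[1] += 1
                dish_s[d_old] = 0.0
                dish_s2[d_old] = 0.0
        nd = d_meta[0]
        # per-dish predictive and neighbor agreement for this pixel
        for kk in range(nd):
            k = d_active[kk]
            dpred[kk] = _log_pred(xi, dish_n[k], dish_s[k], dish_s2[k],
                                  mu0, k0, a0, b0)
            dagree[kk] = 0.0
        if lam > 0.0:
            for d in range(dmax):
                l = nbr_idx[i, d]
                if l >= 0:
                    dl = table_dish[assign[l]]
                    dagree[d_pos[dl]] += nbr_w[i, d]
        # existing tables of this image
        nt = 0
        best = -1.0e300
        for ci in range(t_meta[0]):
            t = t_active[ci]
            if table_img[t] == img:
                kk = d_pos[table_dish[t]]
                lw = math.log(table_n[t]) + dpred[kk] + lam * dagree[kk]
                cand[nt] = t
                logw[nt] = lw
                nt += 1
                if lw > best:
                    best = lw
        # new-table option: franchise mixture over dishes plus a fresh dish
        cbest = -1.0e300
        for kk in range(nd):
            k = d_active[kk]
            c = math.log(dish_m[k]) + dpred[kk] + lam * dagree[kk]
            comps[kk] = c
            if c > cbest:
                cbest = c
        c = math.log(gamma_) + _log_pred(xi, 0, 0.0, 0.0, mu0, k0, a0, b0)
        comps[nd] = c
        if c > cbest:
            cbest = c
        csum = 0.0
        for kk in range(nd + 1):
            csum += math.exp(comps[kk] - cbest)
        lw = math.log(alpha0) - math.log(gamma_ + g_meta[0]) + cbest + math.log(csum)
        logw[nt] = lw
        if lw > best:
            best = lw
        tot = 0.0
        for ci in range(nt + 1):
            logw[ci] = math.exp(logw[ci] - best)
            tot += logw[ci]
        u = np.random.random() * tot
        acc = 0.0
        choice = nt
        for ci in range(nt + 1):
            acc += logw[ci]
            if u <= acc:
                choice = ci
                break
        if choice < nt:
            t = cand[choice]
            k = table_dish[t]
        else:
            # pick the new table's dish from the mixture components
            tot = 0.0
            for kk in range(nd + 1):
                comps[kk] = math.exp(comps[kk] - cbest)
                tot += comps[kk]
            u = np.random.random() * tot
            acc = 0.0
            dchoice = nd
            for kk in range(nd + 1):
                acc += comps[kk]
                if u <= acc:
                    dchoice = kk
                    break
            if dchoice == nd:
                k = d_free[d_meta[1] - 1]
                d_meta[1] -= 1
                d_active[d_meta[0]] = k
                d_pos[k] = d_meta[0]
                d_meta[0] += 1
                dish_m[k] = 0
                dish_n[k] = 0
                dish_s[k] = 0.0
                dish_s2[k] = 0.0
            else:
                k = d_active[dchoice]
            t = t_free[t_meta[1] - 1]
            t_meta[1] -= 1
            t_active[t_meta[0]] = t
            t_pos[t] = t_meta[0]
            t_meta[0] += 1
            table_img[t] = img
            table_dish[t] = k
            table_n[t] = 0
            table_s[t] = 0.0
            table_s2[t] = 0.0
            g_meta[0] += 1
            dish_m[k] += 1
        assign[i] = t
        table_n[t] += 1
        table_s[t] += xi
        table_s2[t] += xi * xi
        dish_n[k] += 1
        dish_s[k] += xi
        dish_s2[k] += xi * xi


@njit(cache=True)
def _table_stage_joint(xs, assign, nbr_idx, nbr_w, img_off,
                       table_img, table_dish, table_n, table_s, table_s2,
                       dish_m, dish_n, dish_s, dish_s2,
                       d_active, d_pos, d_free, d_meta,
                       gamma_, lam, mu0, k0, a0, b0, comps, dagree):
    cap_t = table_n.shape[0]
    dmax = nbr_idx.shape[1]
    for t in range(cap_t):
        nt = table_n[t]
        if nt == 0:
            continue
        st = table_s[t]
        s2t = table_s2[t]
        d_old = table_dish[t]
        dish_m[d_old] -= 1
        dish_n[d_old] -= nt
        dish_s[d_old] -= st
        dish_s2[d_old] -= s2t
        if dish_m[d_old] == 0:
            p = d_pos[d_old]
            last = d_active[d_meta[0] - 1]
            d_active[p] = last
            d_pos[last] = p
            d_meta[0] -= 1
            d_free[d_meta[1]] = d_old
            d_meta[1] += 1
            dish_s[d_old] = 0.0
            dish_s2[d_old] = 0.0
        nd = d_meta[0]
        for kk in range(nd):
            dagree[kk] = 0.0
        if lam > 0.0:
            img = table_img[t]
            for p_ in range(img_off[img], img_off[img + 1]):
                if assign[p_] == t:
                    for d in range(dmax):
                        l = nbr_idx[p_, d]
                        if l >= 0 and assign[l] != t:
                            dl = table_dish[assign[l]]
                            dagree[d_pos[dl]] += nbr_w[p_, d]
        best = -1.0e300
        for kk in range(nd):
            k = d_active[kk]
            c = (math.log(dish_m[k])
                 + _log_marg(dish_n[k] + nt, dish_s[k] + st, dish_s2[k] + s2t,
                             mu0, k0, a0, b0)
                 - _log_marg(dish_n[k], dish_s[k], dish_s2[k], mu0, k0, a0, b0)
                 + lam * dagree[kk])
            comps[kk] = c
            if c > best:
                best = c
        c = math.log(gamma_) + _log_marg(nt, st, s2t, mu0, k0, a0, b0)
        comps[nd] = c
        if c > best:
            best = c
        tot = 0.0
        for kk in range(nd + 1):
            comps[kk] = math.exp(comps[kk] - best)
            tot += comps[kk]
        u = np.random.random() * tot
        acc = 0.0
        choice = nd
        for kk in range(nd + 1):
            acc += comps[kk]
            if u <= acc:
                choice = kk
                break
        if choice == nd:
            k = d_free[d_meta[1] - 1]
            d_meta[1] -= 1
            d_active[d_meta[0]] = k
            d_pos[k] = d_meta[0]
            d_meta[0] += 1
            dish_m[k] = 0
            dish_n[k] = 0
            dish_s[k] = 0.0
            dish_s2[k] = 0.0
        else:
            k = d_active[choice]
        table_dish[t] = k
        dish_m[k] += 1
        dish_n[k] += nt
        dish_s[k] += st
        dish_s2[k] += s2t


# ---------------------------------------------------------------------------
# Franchise state
# ---------------------------------------------------------------------------

class FranchiseState:
    """Full latent state of the collapsed sampler, array-backed.

    In ``single_dp`` mode tables *are* atoms (``table_dish[t] == t`` is never
    consulted; only the dish arrays would be redundant, so single mode uses
    the atom arrays directly and the table arrays are unused).
    """

    def __init__(self, images, hp: Hyperparameters, mode: str,
                 connectivity: int = 4, n_init_bins: int = 8):
        if mode not in ("single_dp", "joint_hdp"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "single_dp" and len(images) != 1:
            raise ValueError("single_dp state holds exactly one image")
        self.mode = mode
        self.hp = hp
        self.shapes = [np.asarray(im).shape for im in images]
        flats = [np.asarray(im, dtype=np.float64).ravel() for im in images]
        self.xs = np.concatenate(flats)
        self.img_off = np.zeros(len(images) + 1, dtype=np.int64)
        np.cumsum([f.size for f in flats], out=self.img_off[1:])
        self.n_images = len(images)
        self.n_pixels = int(self.xs.size)
        self.graphs = [build_neighborhood(h, w, connectivity) for h, w in self.shapes]
        # neighbor indices lifted to the concatenated (global) pixel space
        nbr_idx = []
        nbr_w = []
        for g, off in zip(self.graphs, self.img_off[:-1]):
            idx = g.nbr_idx.copy()
            idx[idx >= 0] += off
            nbr_idx.append(idx)
            nbr_w.append(g.nbr_w)
        self.nbr_idx = np.ascontiguousarray(np.concatenate(nbr_idx))
        self.nbr_w = np.ascontiguousarray(np.concatenate(nbr_w))
        self.sweep = 0
        self.seed_record = None
        self._alloc()
        self._init_assignments(n_init_bins)

    # -- allocation and initialization ------------------------------------

    def _alloc(self):
        cap = self.n_pixels + 1
        self.cap = cap
        self.assign = np.zeros(self.n_pixels, dtype=np.int64)
        if self.mode == "joint_hdp":
            self.table_img = np.zeros(cap, dtype=np.int64)
            self.table_dish = np.zeros(cap, dtype=np.int64)
            self.table_n = np.zeros(cap, dtype=np.int64)
            self.table_s = np.zeros(cap)
            self.table_s2 = np.zeros(cap)
            self.t_active = np.zeros(cap, dtype=np.int64)
            self.t_pos = np.zeros(cap, dtype=np.int64)
            self.t_free = np.zeros(cap, dtype=np.int64)
            self.t_meta = np.zeros(2, dtype=np.int64)
            self.g_meta = np.zeros(1, dtype=np.int64)
        self.dish_m = np.zeros(cap, dtype=np.int64)
        self.dish_n = np.zeros(cap, dtype=np.int64)
        self.dish_s = np.zeros(cap)
        self.dish_s2 = np.zeros(cap)
        self.d_active = np.zeros(cap, dtype=np.int64)
        self.d_pos = np.zeros(cap, dtype=np.int64)
        self.d_free = np.zeros(cap, dtype=np.int64)
        self.d_meta = np.zeros(2, dtype=np.int64)
        # scratch
        self._cand = np.zeros(cap, dtype=np.int64)
        self._logw = np.zeros(cap + 2)
        self._dpred = np.zeros(cap + 2)
        self._dagree = np.zeros(cap + 2)
        self._comps = np.zeros(cap + 2)

    def _init_assignments(self, n_init_bins):
        """Deterministic pooled equal-width intensity-bin initialization.

        Bins span the pooled intensity range so the initial dishes are
        shared across images, and equal widths keep well-separated classes
        in distinct bins even when a class covers few pixels (quantile bins
        would lump minority classes together).  The sampler then merges
        surplus clusters; merges are easy for the chain, splits are not.
        """
        nb = max(1, min(n_init_bins, self.n_pixels))
        lo, hi = float(self.xs.min()), float(self.xs.max())
        if hi == lo:
            edges = np.array([])
        else:
            edges = np.linspace(lo, hi, nb + 1)[1:-1]
        bins = np.searchsorted(edges, self.xs, side="right")
        present = np.unique(bins)
        bin_to_dish = {b: j for j, b in enumerate(present)}
        nd = len(present)
        # dishes: one per occupied pooled bin
        self.d_meta[:] = 0
        for j in range(nd):
            self.d_active[j] = j
            self.d_pos[j] = j
        self.d_meta[0] = nd
        nfree = 0
        for slot in range(self.cap - 1, nd - 1, -1):
            self.d_free[nfree] = slot
            nfree += 1
        self.d_meta[1] = nfree
        if self.mode == "single_dp":
            for i in range(self.n_pixels):
                k = bin_to_dish[bins[i]]
                self.assign[i] = k
                self.dish_m[k] = 1
                self.dish_n[k] += 1
                self.dish_s[k] += self.xs[i]
                self.dish_s2[k] += self.xs[i] ** 2
            return
        # joint: one table per (image, occupied bin)
        self.t_meta[:] = 0
        tid = 0
        table_of = {}
        for img in range(self.n_images):
            lo, hi = self.img_off[img], self.img_off[img + 1]
            for i in range(lo, hi):
                key = (img, bin_to_dish[bins[i]])
                if key not in table_of:
                    t = tid
                    tid += 1
                    table_of[key] = t
                    self.table_img[t] = img
                    self.table_dish[t] = key[1]
                    self.t_active[t] = t
                    self.t_pos[t] = t
                    self.dish_m[key[1]] += 1
                t = table_of[key]
                self.assign[i] = t
                self.table_n[t] += 1
                self.table_s[t] += self.xs[i]
                self.table_s2[t] += self.xs[i] ** 2
                self.dish_n[key[1]] += 1
                self.dish_s[key[1]] += self.xs[i]
                self.dish_s2[key[1]] += self.xs[i] ** 2
        self.t_meta[0] = tid
        self.g_meta[0] = tid
        nfree = 0
        for slot in range(self.cap - 1, tid - 1, -1):
            self.t_free[nfree] = slot
            nfree += 1
        self.t_meta[1] = nfree

    # -- views --------------------------------------------------------------

    def labels_flat(self, image_index: int) -> np.ndarray:
        """Global atom label per pixel of one image (flattened)."""
        lo, hi = self.img_off[image_index], self.img_off[image_index + 1]
        if self.mode == "single_dp":
            return self.assign[lo:hi].copy()
        return self.table_dish[self.assign[lo:hi]]

    def label_field(self, image_index: int) -> LabelField:
        return LabelField(
            self.labels_flat(image_index).reshape(self.shapes[image_index]),
            image_index=image_index,
        )

    @property
    def n_atoms(self) -> int:
        return int(self.d_meta[0])

    def live_atoms(self):
        return sorted(int(k) for k in self.d_active[: self.d_meta[0]])

    # -- consistency ---------------------------------------------------------

    def check_consistency(self):
        """Full recount of all sufficient statistics; raises on mismatch."""
        tol = 1e-6
        live_d = set(self.live_atoms())
        if self.mode == "single_dp":
            for k in live_d:
                sel = self.assign == k
                if self.dish_n[k] != sel.sum():
                    raise RuntimeError(f"atom {k} count mismatch")
                if abs(self.dish_s[k] - self.xs[sel].sum()) > tol:
                    raise RuntimeError(f"atom {k} sum mismatch")
                if abs(self.dish_s2[k] - (self.xs[sel] ** 2).sum()) > tol:
                    raise RuntimeError(f"atom {k} sumsq mismatch")
            if self.dish_n[self.d_active[: self.d_meta[0]]].sum() != self.n_pixels:
                raise RuntimeError("pixel count not conserved")
            return
        live_t = set(int(t) for t in self.t_active[: self.t_meta[0]])
        if set(np.unique(self.assign)) != live_t:
            raise RuntimeError("assigned tables != active tables")
        for t in live_t:
            sel = self.assign == t
            if self.table_n[t] != sel.sum():
                raise RuntimeError(f"table {t} count mismatch")
            if abs(self.table_s[t] - self.xs[sel].sum()) > tol:
                raise RuntimeError(f"table {t} sum mismatch")
            if int(self.table_dish[t]) not in live_d:
                raise RuntimeError(f"table {t} points to a dead dish")
        for k in live_d:
            ts = [t for t in live_t if self.table_dish[t] == k]
            if self.dish_m[k] != len(ts):
                raise RuntimeError(f"dish {k} m mismatch")
            if self.dish_n[k] != sum(int(self.table_n[t]) for t in ts):
                raise RuntimeError(f"dish {k} count mismatch")
            if abs(self.dish_s[k] - sum(float(self.table_s[t]) for t in ts)) > tol:
                raise RuntimeError(f"dish {k} sum mismatch")
        if self.dish_n[self.d_active[: self.d_meta[0]]].sum() != self.n_pixels:
            raise RuntimeError("pixel count not conserved")
        if self.g_meta[0] != len(live_t):
            raise RuntimeError("global table count mismatch")

    # -- python-side detach (for conditional_for_pixel tests) ---------------

    def detach_pixel(self, image_index: int, i: int):
        """Remove pixel i (flat, within image) from its cluster, in place."""
        p = int(self.img_off[image_index]) + i
        xi = self.xs[p]
        if self.mode == "single_dp":
            k = self.assign[p]
            self.dish_n[k] -= 1
            self.dish_s[k] -= xi
            self.dish_s2[k] -= xi * xi
            if self.dish_n[k] == 0:
                self._drop_dish(k)
                self.dish_m[k] = 0
            return
        t = self.assign[p]
        k = self.table_dish[t]
        self.table_n[t] -= 1
        self.table_s[t] -= xi
        self.table_s2[t] -= xi * xi
        self.dish_n[k] -= 1
        self.dish_s[k] -= xi
        self.dish_s2[k] -= xi * xi
        if self.table_n[t] == 0:
            pos = self.t_pos[t]
            last = self.t_active[self.t_meta[0] - 1]
            self.t_active[pos] = last
            self.t_pos[last] = pos
            self.t_meta[0] -= 1
            self.t_free[self.t_meta[1]] = t
            self.t_meta[1] += 1
            self.g_meta[0] -= 1
            self.dish_m[k] -= 1
            if self.dish_m[k] == 0:
                self._drop_dish(k)

    def _drop_dish(self, k):
        pos = self.d_pos[k]
        last = self.d_active[self.d_meta[0] - 1]
        self.d_active[pos] = last
        self.d_pos[last] = pos
        self.d_meta[0] -= 1
        self.d_free[self.d_meta[1]] = k
        self.d_meta[1] += 1
        self.dish_s[k] = 0.0
        self.dish_s2[k] = 0.0

    # -- canonical partition keys (for oracle comparison) --------------------

    def partition_key(self):
        """Single mode: restricted-growth label tuple over all pixels."""
        return _rgs(self.assign)

    def franchise_key(self):
        """Joint mode: per-image table partitions plus the dish grouping."""
        table_rgs = []
        table_order = []
        for img in range(self.n_images):
            lo, hi = self.img_off[img], self.img_off[img + 1]
            labels = self.assign[lo:hi]
            table_rgs.append(_rgs(labels))
            seen = set()
            for t in labels:
                if t not in seen:
                    seen.add(int(t))
                    table_order.append(int(t))
        dish_labels = [int(self.table_dish[t]) for t in table_order]
        return (tuple(table_rgs), _rgs(dish_labels))


def _rgs(seq):
    """Relabel a sequence by first occurrence (restricted growth string)."""
    mapping = {}
    out = []
    for v in seq:
        v = int(v)
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return tuple(out)


# ---------------------------------------------------------------------------
# Sweeps (python wrappers over the kernels)
# ---------------------------------------------------------------------------

def gibbs_sweep_single(state: FranchiseState, hp: Hyperparameters,
                       rng: int | None = None) -> FranchiseState:
    """One raster-order pass resampling every pixel of a single-image DP-MRF.

    ``rng`` is an optional integer used to (re)seed the kernel RNG stream;
    ``None`` continues the current stream.
    """
    if state.mode != "single_dp":
        raise ValueError("state is not in single_dp mode")
    if rng is not None:
        _seed_kernel(int(rng) % _SEED_MOD)
    _sweep_single(state.xs, state.assign, state.nbr_idx, state.nbr_w,
                  state.dish_n, state.dish_s, state.dish_s2,
                  state.d_active, state.d_pos, state.d_free, state.d_meta,
                  hp.alpha0, hp.lam,
                  hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0,
                  state._logw)
    state.dish_m[state.d_active[: state.d_meta[0]]] = 1
    state.sweep += 1
    return state


def gibbs_sweep_joint(state: FranchiseState, hp: Hyperparameters,
                      rng: int | None = None) -> FranchiseState:
    """One franchise sweep: pixel stage per image, then the table stage."""
    if state.mode != "joint_hdp":
        raise ValueError("state is not in joint_hdp mode")
    if rng is not None:
        _seed_kernel(int(rng) % _SEED_MOD)
    for img in range(state.n_images):
        _pixel_stage_joint(
            state.xs, state.assign, state.nbr_idx, state.nbr_w,
            state.img_off[img], state.img_off[img + 1], img,
            state.table_img, state.table_dish, state.table_n,
            state.table_s, state.table_s2,
            state.t_active, state.t_pos, state.t_free, state.t_meta,
            state.dish_m, state.dish_n, state.dish_s, state.dish_s2,
            state.d_active, state.d_pos, state.d_free, state.d_meta,
            state.g_meta,
            hp.alpha0, hp.gamma, hp.lam,
            hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0,
            state._cand, state._logw, state._dpred, state._dagree, state._comps)
    _table_stage_joint(
        state.xs, state.assign, state.nbr_idx, state.nbr_w, state.img_off,
        state.table_img, state.table_dish, state.table_n,
        state.table_s, state.table_s2,
        state.dish_m, state.dish_n, state.dish_s, state.dish_s2,
        state.d_active, state.d_pos, state.d_free, state.d_meta,
        hp.gamma, hp.lam,
        hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0,
        state._comps, state._dagree)
    state.sweep += 1
    return state


# ---------------------------------------------------------------------------
# Pure-python full conditional (inspection / tests)
# ---------------------------------------------------------------------------

def conditional_for_pixel(i: int, state: FranchiseState,
                          graph: NeighborhoodGraph, hp: Hyperparameters,
                          image_index: int = 0):
    """Normalized full conditional for pixel ``i`` of one image.

    The pixel's own contribution must already have been removed from the
    state (see :meth:`FranchiseState.detach_pixel`).  Returns
    ``(choices, probs)`` where ``choices`` lists existing atom ids (single
    mode) or table ids (joint mode) followed by ``-1`` for "new", and
    ``probs`` is the matching probability vector (sums to 1).
    """
    p = int(state.img_off[image_index]) + i
    xi = float(state.xs[p])
    mu0, k0, a0, b0 = hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0
    neighbor_dishes = []
    for d, l in enumerate(graph.nbr_idx[i]):
        if l >= 0:
            gl = int(state.img_off[image_index]) + int(l)
            lbl = (int(state.assign[gl]) if state.mode == "single_dp"
                   else int(state.table_dish[state.assign[gl]]))
            neighbor_dishes.append((lbl, float(graph.nbr_w[i][d])))

    def agree(label):
        return sum(w for lbl, w in neighbor_dishes if lbl == label)

    choices, logw = [], []
    if state.mode == "single_dp":
        for k in state.live_atoms():
            lw = (math.log(state.dish_n[k])
                  + model_core._nig_log_pred(xi, int(state.dish_n[k]),
                                             float(state.dish_s[k]),
                                             float(state.dish_s2[k]),
                                             mu0, k0, a0, b0)
                  + hp.lam * agree(k))
            choices.append(int(k))
            logw.append(lw)
        choices.append(-1)
        logw.append(math.log(hp.alpha0)
                    + model_core._nig_log_pred(xi, 0, 0.0, 0.0, mu0, k0, a0, b0))
    else:
        dishes = state.live_atoms()
        dpred = {k: model_core._nig_log_pred(xi, int(state.dish_n[k]),
                                             float(state.dish_s[k]),
                                             float(state.dish_s2[k]),
                                             mu0, k0, a0, b0)
                 for k in dishes}
        for t in sorted(int(t) for t in state.t_active[: state.t_meta[0]]):
            if state.table_img[t] != image_index:
                continue
            k = int(state.table_dish[t])
            lw = math.log(state.table_n[t]) + dpred[k] + hp.lam * agree(k)
            choices.append(t)
            logw.append(lw)
        comps = [math.log(state.dish_m[k]) + dpred[k] + hp.lam * agree(k)
                 for k in dishes]
        comps.append(math.log(hp.gamma)
                     + model_core._nig_log_pred(xi, 0, 0.0, 0.0, mu0, k0, a0, b0))
        m = max(comps)
        lse = m + math.log(sum(math.exp(c - m) for c in comps))
        choices.append(-1)
        logw.append(math.log(hp.alpha0)
                    - math.log(hp.gamma + int(state.g_meta[0])) + lse)
    logw = np.asarray(logw)
    w = np.exp(logw - logw.max())
    return choices, w / w.sum()


# ---------------------------------------------------------------------------
# Brute-force posterior oracle (tiny instances)
# ---------------------------------------------------------------------------

def _set_partitions(items):
    """All set partitions of a list, as lists of blocks (lists)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for j in range(len(part)):
            yield part[:j] + [[first] + part[j]] + part[j + 1:]
        yield [[first]] + part


def _block_stats(values):
    v = np.asarray(values, dtype=np.float64)
    return len(v), float(v.sum()), float((v**2).sum())


def brute_force_posterior(images, hp: Hyperparameters, mode: str,
                          connectivity: int = 4):
    """Exact posterior over label configurations by full enumeration.

    Intended as a test oracle: scores every configuration by CRP/CRF prior
    mass x collapsed marginal likelihood x Potts factor and normalizes.
    Instances are limited to 6 pixels in total (Bell-number blowup).

    Returns a dict mapping canonical configuration keys (matching
    :meth:`FranchiseState.partition_key` / :meth:`franchise_key`) to
    probabilities.
    """
    flats = [np.asarray(im, dtype=np.float64).ravel() for im in images]
    shapes = [np.asarray(im).shape for im in images]
    total = sum(f.size for f in flats)
    if total > 6:
        raise ValueError(f"instance too large for enumeration ({total} pixels > 6)")
    graphs = [build_neighborhood(h, w, connectivity) for h, w in shapes]
    edges = []  # (image, i, l, w) with i < l
    for gi, g in enumerate(graphs):
        for i in range(g.n_pixels):
            for l, w in g.neighbors(i):
                if i < l:
                    edges.append((gi, i, l, w))
    mu0, k0, a0, b0 = hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0

    def marg(vals):
        n, s, s2 = _block_stats(vals)
        return model_core._nig_log_marginal(n, s, s2, mu0, k0, a0, b0)

    scores = {}
    if mode == "single_dp":
        if len(images) != 1:
            raise ValueError("single_dp oracle takes exactly one image")
        x = flats[0]
        n = x.size
        for part in _set_partitions(list(range(n))):
            label = np.empty(n, dtype=np.int64)
            lp = len(part) * math.log(hp.alpha0)
            for bi, block in enumerate(part):
                label[block] = bi
                lp += math.lgamma(len(block)) + marg(x[block])
            if hp.lam > 0:
                lp += hp.lam * sum(w for _, i, l, w in edges
                                   if label[i] == label[l])
            scores[tuple(_rgs(label))] = lp
    elif mode == "joint_hdp":
        per_image_parts = [list(_set_partitions(list(range(f.size))))
                           for f in flats]
        for combo in product(*per_image_parts):
            tables = []  # (image, block) in canonical order
            for gi, part in enumerate(combo):
                order = sorted(part, key=min)
                for block in order:
                    tables.append((gi, tuple(sorted(block))))
            m_total = len(tables)
            lp_base = (sum(len(part) * math.log(hp.alpha0)
                           + sum(math.lgamma(len(b)) for b in part)
                           for part in combo)
                       - sum(math.log(hp.gamma + j) for j in range(m_total)))
            for dish_part in _set_partitions(list(range(m_total))):
                lp = lp_base + len(dish_part) * math.log(hp.gamma)
                dish_of_table = {}
                for di, dblock in enumerate(dish_part):
                    lp += math.lgamma(len(dblock))
                    vals = []
                    for ti in dblock:
                        gi, block = tables[ti]
                        dish_of_table[ti] = di
                        vals.extend(flats[gi][list(block)])
                    lp += marg(vals)
                if hp.lam > 0:
                    pix_dish = []
                    for gi, f in enumerate(flats):
                        lbl = np.empty(f.size, dtype=np.int64)
                        for ti, (gj, block) in enumerate(tables):
                            if gj == gi:
                                lbl[list(block)] = dish_of_table[ti]
                        pix_dish.append(lbl)
                    lp += hp.lam * sum(w for gi, i, l, w in edges
                                       if pix_dish[gi][i] == pix_dish[gi][l])
                table_rgs = tuple(_table_rgs_for(combo, flats))
                dish_rgs = _rgs([dish_of_table[ti] for ti in range(m_total)])
                key = (table_rgs, dish_rgs)
                prev = scores.get(key)
                scores[key] = lp if prev is None else _logaddexp(prev, lp)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logz = None
    for lp in scores.values():
        logz = lp if logz is None else _logaddexp(logz, lp)
    return {key: math.exp(lp - logz) for key, lp in scores.items()}


def _table_rgs_for(combo, flats):
    out = []
    for gi, part in enumerate(combo):
        label = np.empty(flats[gi].size, dtype=np.int64)
        for bi, block in enumerate(sorted(part, key=min)):
            label[block] = bi
        out.append(_rgs(label))
    return out


def _logaddexp(a, b):
    m = max(a, b)
    return m + math.log(math.exp(a - m) + math.exp(b - m))


# ---------------------------------------------------------------------------
# Log joint (trace)
# ---------------------------------------------------------------------------

def log_joint(state: FranchiseState, hp: Hyperparameters) -> float:
    """Unnormalized log joint of the current configuration.

    Constant terms that do not depend on the configuration (the per-image
    CRP denominators) are omitted; traces are comparable within one run.
    """
    mu0, k0, a0, b0 = hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0
    live = state.d_active[: state.d_meta[0]]
    lp = 0.0
    for k in live:
        lp += model_core._nig_log_marginal(
            int(state.dish_n[k]), float(state.dish_s[k]),
            float(state.dish_s2[k]), mu0, k0, a0, b0)
    if state.mode == "single_dp":
        lp += len(live) * math.log(hp.alpha0)
        lp += float(gammaln(state.dish_n[live]).sum())
    else:
        live_t = state.t_active[: state.t_meta[0]]
        lp += len(live_t) * math.log(hp.alpha0)
        lp += float(gammaln(state.table_n[live_t]).sum())
        lp += len(live) * math.log(hp.gamma)
        lp += float(gammaln(state.dish_m[live]).sum())
        m_total = int(state.g_meta[0])
        lp -= sum(math.log(hp.gamma + j) for j in range(m_total))
    if hp.lam > 0:
        labels = (state.assign if state.mode == "single_dp"
                  else state.table_dish[state.assign])
        mask = state.nbr_idx >= 0
        nb = np.where(mask, state.nbr_idx, 0)
        eq = (labels[:, None] == labels[nb]) & mask
        lp += hp.lam * float((state.nbr_w * eq).sum()) / 2.0
    return lp


# ---------------------------------------------------------------------------
# Mode estimate and the end-to-end runner
# ---------------------------------------------------------------------------

def mode_estimate(samples):
    """Label-aligned per-pixel majority vote over retained samples.

    ``samples`` is a list (over retained sweeps) of per-image
    :class:`LabelField` lists.  Every sample is aligned to the *last*
    sample by maximum-overlap injective matching of its labels (jointly
    across images, since labels are global atom ids), then each pixel takes
    its majority label.  Ties break toward the smaller label id.
    """
    if not samples:
        raise ValueError("need at least one retained sample")
    n_images = len(samples[-1])
    shapes = [lf.shape for lf in samples[-1]]
    ref = np.concatenate([lf.flat() for lf in samples[-1]])
    ref_ids = np.unique(ref)
    aligned = []
    next_fresh = int(ref_ids.max()) + 1 if ref_ids.size else 0
    for sample in samples:
        cur = np.concatenate([lf.flat() for lf in sample])
        cur_ids = np.unique(cur)
        # contingency of current labels vs reference labels
        ci = {v: j for j, v in enumerate(cur_ids)}
        ri = {v: j for j, v in enumerate(ref_ids)}
        cont = np.zeros((len(cur_ids), len(ref_ids)), dtype=np.int64)
        np.add.at(cont, (np.vectorize(ci.get)(cur), np.vectorize(ri.get)(ref)), 1)
        rows, cols = linear_sum_assignment(-cont)
        mapping = {}
        fresh = next_fresh
        for r, c in zip(rows, cols):
            if cont[r, c] > 0:
                mapping[int(cur_ids[r])] = int(ref_ids[c])
        for v in cur_ids:
            if int(v) not in mapping:
                mapping[int(v)] = fresh
                fresh += 1
        aligned.append(np.vectorize(mapping.get)(cur))
    stack = np.stack(aligned)
    max_label = int(stack.max()) + 1
    counts = np.zeros((max_label, stack.shape[1]), dtype=np.int32)
    for row in stack:
        counts[row, np.arange(stack.shape[1])] += 1
    voted = counts.argmax(axis=0)  # argmax takes the smallest id on ties
    out = []
    off = 0
    for idx, shape in enumerate(shapes):
        n = shape[0] * shape[1]
        out.append(LabelField(voted[off:off + n].reshape(shape), image_index=idx))
        off += n
    return out


def run_sampler(images, hp: Hyperparameters, cfg: SamplerConfig,
                connectivity: int = 4) -> SegmentationResult:
    """Run the collapsed Gibbs sampler end to end.

    Images are standardized first — per image in ``single_dp`` mode, with
    pooled mean/sd across the whole set in ``joint_hdp`` mode so that shared
    intensity classes stay aligned across images.  Deterministic given
    ``(images, hp, cfg)``.
    """
    if not images:
        raise ValueError("empty image list")
    arrays = [np.asarray(im, dtype=np.float64) for im in images]
    for im in arrays:
        if im.ndim != 2:
            raise ValueError("images must be 2-D grayscale grids")
    if cfg.mode == "single_dp":
        return _run_single(arrays, hp, cfg, connectivity)
    pooled = np.concatenate([im.ravel() for im in arrays])
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0:
        std_images = [np.zeros_like(im) for im in arrays]
    else:
        std_images = [(im - mu) / sd for im in arrays]
    state = FranchiseState(std_images, hp, "joint_hdp", connectivity)
    state.seed_record = cfg.seed
    _seed_kernel(cfg.seed % _SEED_MOD)
    return _drive(state, hp, cfg, gibbs_sweep_joint)


def _run_single(arrays, hp, cfg, connectivity):
    """single_dp over a list of images = independent chains, one per image."""
    results = []
    for idx, im in enumerate(arrays):
        state = FranchiseState([standardize_intensities(im)], hp,
                               "single_dp", connectivity)
        state.seed_record = cfg.seed
        _seed_kernel((cfg.seed + 1000003 * idx) % _SEED_MOD)
        results.append(_drive(state, hp, cfg, gibbs_sweep_single))
    if len(results) == 1:
        return results[0]
    fields = []
    atom_means = {}
    offset = 0
    map_labels = []
    for idx, res in enumerate(results):
        lf = res.label_fields[0]
        fields.append(LabelField(lf.labels + offset, image_index=idx))
        ml = res.map_labels[0]
        map_labels.append(LabelField(ml.labels + offset, image_index=idx))
        atom_means.update({k + offset: v for k, v in res.atom_means.items()})
        local_max = max(
            [max(res.atom_means, default=-1), int(lf.labels.max()),
             int(ml.labels.max())]
        )
        offset += local_max + 1
    trace = np.sum([r.log_joint for r in results], axis=0)
    return SegmentationResult(fields, atom_means, trace, cfg, map_labels)


def _drive(state, hp, cfg, sweep_fn):
    trace = np.empty(cfg.n_sweeps)
    retained = []
    retained_sweeps = []
    for s in range(cfg.n_sweeps):
        sweep_fn(state, hp)
        trace[s] = log_joint(state, hp)
        if not np.isfinite(trace[s]):
            raise RuntimeError(f"non-finite log joint at sweep {s}")
        live = state.d_active[: state.d_meta[0]]
        if int(state.dish_n[live].sum()) != state.n_pixels:
            raise RuntimeError(f"pixel count not conserved at sweep {s}")
        keep = s >= cfg.burn_in and (s - cfg.burn_in) % cfg.thin == 0
        if keep or s == cfg.n_sweeps - 1:
            retained.append([state.label_field(i) for i in range(state.n_images)])
            retained_sweeps.append(s)
    final = mode_estimate(retained)
    best = int(np.argmax(trace[retained_sweeps]))
    hp_ = hp
    atom_means = {}
    for k in state.live_atoms():
        kn = hp_.base_kappa0 + int(state.dish_n[k])
        atom_means[k] = float((hp_.base_kappa0 * hp_.base_mu0 + state.dish_s[k]) / kn)
    return SegmentationResult(
        label_fields=final,
        atom_means=atom_means,
        log_joint=trace,
        config=cfg,
        map_labels=retained[best],
        retained=retained if cfg.keep_samples else None,
    )
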