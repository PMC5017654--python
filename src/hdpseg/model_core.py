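"""Probabilistic primitives for DP/HDP mixture segmentation.

The observation model is a univariate Gaussian on standardized pixel
intensity with a conjugate normal-inverse-gamma (NIG) base measure, so the
cluster (atom) parameters can be integrated out analytically.  Every atom is
then fully described by its sufficient statistics (count, sum, sum of
squares), and the collapsed Gibbs sampler only ever needs two scalar
quantities derived from them:

* the posterior-predictive density of one new pixel given an atom's current
  members (a scaled, shifted Student-t), and
* the marginal likelihood of a whole block of pixels under the base measure
  (used when a local cluster is reassigned to a global atom, and by the
  brute-force enumeration oracle).

The Chinese-restaurant-process predictive weights for "join an existing
cluster of size n_k" vs "open a new cluster" (probability alpha0/(alpha0+n))
also live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Hyperparameters and sufficient statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparameters:
    """Model hyperparameters.

    Parameters
    ----------
    alpha0
        Per-image DP concentration. Larger values open new clusters more
        readily a priori (new-cluster probability alpha0/(alpha0+n)).
    gamma
        Top-level DP concentration controlling how readily the hierarchy
        creates new *global* atoms shared across images.
    lam
        Markov-random-field smoothing weight (lambda >= 0). Each candidate
        label is boosted by exp(lam * sum of neighbor edge weights agreeing
        with it); lam = 0 disables spatial smoothing.
    base_mu0, base_kappa0, base_a0, base_b0
        Normal-inverse-gamma base measure: mean ~ N(mu0, sigma^2/kappa0),
        sigma^2 ~ InvGamma(a0, b0). Defaults are weakly informative for
        intensities standardized to zero mean and unit variance.
    """

    alpha0: float = 0.01
    gamma: float = 1.0
    lam: float = 0.001
    base_mu0: float = 0.0
    base_kappa0: float = 0.1
    base_a0: float = 2.0
    base_b0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0):
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.lam >= 0):
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        for name in ("base_kappa0", "base_a0", "base_b0"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class AtomStats:
    """Sufficient statistics of the pixels currently assigned to one atom."""

    count: int = 0
    sum_x: float = 0.0
    sum_x2: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.count > 0:
            # Cauchy-Schwarz on the member data, with slack for float error
            if self.sum_x2 < self.sum_x**2 / self.count - 1e-9:
                raise ValueError("inconsistent stats: sum_x2 < sum_x^2/count")


@dataclass(frozen=True)
class PixelObservation:
    """One standardized intensity observation with its pixel coordinates."""

    value: float
    image_index: int
    row: int
    col: int


EMPTY_STATS = AtomStats()


def atom_add(stats: AtomStats, x: float) -> AtomStats:
    """Return ``stats`` with observation ``x`` added."""
    return replace(
        stats,
        count=stats.count + 1,
        sum_x=stats.sum_x + x,
        sum_x2=stats.sum_x2 + x * x,
    )


def atom_remove(stats: AtomStats, x: float) -> AtomStats:
    """Return ``stats`` with a previously added observation ``x`` removed.

    ``atom_remove(atom_add(s, x), x)`` restores ``s`` exactly in the count
    and to float round-off in the sums.
    """
    if stats.count < 1:
        raise ValueError("cannot remove an observation from an empty atom")
    return AtomStats(
        count=stats.count - 1,
        sum_x=stats.sum_x - x,
        sum_x2=max(stats.sum_x2 - x * x, 0.0) if stats.count == 1 else stats.sum_x2 - x * x,
    )


# ---------------------------------------------------------------------------
# Intensity standardization
# ---------------------------------------------------------------------------

def standardize_intensities(raw_image: np.ndarray) -> np.ndarray:
    """Standardize an intensity grid to sample mean 0 and sd 1.

    The population standard-deviation convention (``ddof=0``) is used.  A
    constant image maps to all zeros.  Non-finite pixels are an error; the
    message names the offending coordinates.
    """
    arr = np.asarray(raw_image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot standardize an empty image")
    bad = ~np.isfinite(arr)
    if bad.any():
        coords = np.argwhere(bad)[:5].tolist()
        raise ValueError(f"non-finite pixel values at coordinates {coords}")
    mu = arr.mean()
    sd = arr.std()  # ddof=0
    if sd == 0.0:
        return np.zeros_like(arr)
    return (arr - mu) / sd


# ---------------------------------------------------------------------------
# CRP predictive weights
# ---------------------------------------------------------------------------

def crp_weights(atom_counts, alpha0: float) -> np.ndarray:
    """Unnormalized Chinese-restaurant-process predictive weights.

    Returns ``(n_1, ..., n_K, alpha0)``: proportional to the probability of
    joining each existing cluster or opening a new one.  After
    normalization the last entry equals ``alpha0 / (alpha0 + n)``.
    """
    counts = np.asarray(atom_counts, dtype=np.float64)
    if counts.size and (counts <= 0).any():
        raise ValueError("all atom counts must be positive (remove empty atoms first)")
    if not alpha0 > 0:
        raise ValueError(f"alpha0 must be > 0, got {alpha0}")
    return np.concatenate([counts, [alpha0]])


# ---------------------------------------------------------------------------
# Collapsed NIG-Gaussian predictive and marginal likelihood
# ---------------------------------------------------------------------------
# Scalar helpers are written in plain math so the inference module can
# numba-compile the very same functions for its sweep kernels.

def _nig_posterior(n, s, s2, mu0, k0, a0, b0):
    """Posterior NIG parameters (kn, mun, an, bn) given n points with sums s, s2."""
    kn = k0 + n
    an = a0 + 0.5 * n
    if n > 0:
        mean = s / n
        ss = s2 - s * s / n
        if ss < 0.0:
            ss = 0.0
        mun = (k0 * mu0 + s) / kn
        bn = b0 + 0.5 * ss + 0.5 * k0 * n * (mean - mu0) * (mean - mu0) / kn
    else:
        mun = mu0
        bn = b0
    return kn, mun, an, bn


# NOTE: the two log-density helpers below are deliberately self-contained
# (no calls to other Python functions) so that the inference module can
# compile them unchanged with numba.

def _nig_log_pred(x, n, s, s2, mu0, k0, a0, b0):
    """Log posterior-predictive density of x: Student-t(2*an, mun, bn(kn+1)/(an*kn))."""
    kn = k0 + n
    an = a0 + 0.5 * n
    if n > 0:
        mean = s / n
        ss = s2 - s * s / n
        if ss < 0.0:
            ss = 0.0
        mun = (k0 * mu0 + s) / kn
        bn = b0 + 0.5 * ss + 0.5 * k0 * n * (mean - mu0) * (mean - mu0) / kn
    else:
        mun = mu0
        bn = b0
    df = 2.0 * an
    scale2 = bn * (kn + 1.0) / (an * kn)
    z2 = (x - mun) * (x - mun) / scale2
    return (
        math.lgamma(0.5 * (df + 1.0))
        - math.lgamma(0.5 * df)
        - 0.5 * math.log(df * math.pi * scale2)
        - 0.5 * (df + 1.0) * math.log(1.0 + z2 / df)
    )


def _nig_log_marginal(n, s, s2, mu0, k0, a0, b0):
    """Log marginal likelihood of n points with sums (s, s2) under the NIG base."""
    if n == 0:
        return 0.0
    kn = k0 + n
    an = a0 + 0.5 * n
    mean = s / n
    ss = s2 - s * s / n
    if ss < 0.0:
        ss = 0.0
    bn = b0 + 0.5 * ss + 0.5 * k0 * n * (mean - mu0) * (mean - mu0) / kn
    return (
        math.lgamma(an)
        - math.lgamma(a0)
        + a0 * math.log(b0)
        - an * math.log(bn)
        + 0.5 * (math.log(k0) - math.log(kn))
        - 0.5 * n * math.log(2.0 * math.pi)
    )


def log_predictive(x: float, stats: AtomStats, hp: Hyperparameters) -> float:
    """Log posterior-predictive density of ``x`` given an atom's members.

    With ``stats.count == 0`` this is the prior predictive under the base
    measure.  Equals ``log_marginal(stats + x) - log_marginal(stats)``.
    """
    return _nig_log_pred(
        x, stats.count, stats.sum_x, stats.sum_x2,
        hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0,
    )


def log_marginal(stats: AtomStats, hp: Hyperparameters) -> float:
    """Log marginal likelihood of all pixels in an atom under the base measure."""
    return _nig_log_marginal(
        stats.count, stats.sum_x, stats.sum_x2,
        hp.base_mu0, hp.base_kappa0, hp.base_a0, hp.base_b0,
    )
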