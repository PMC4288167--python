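"""From site occupancies to a ChIP-seq-like coverage profile.

ChIP fragments are modelled with lengths drawn from a normal distribution
(default mean 200 bp, sd 200 bp) truncated at 1 bp, placed uniformly at random
among the placements that cover the bound site.  The expected per-base
coverage contributed by one bound site is then a mixture over fragment
lengths of triangular kernels (for a fixed length l, the probability that a
uniformly placed covering fragment also covers a base at distance d is
max(0, l - |d|) / l).  The kernel integrates to E[fragment length] exactly,
so total profile mass equals sum_j P_j * E[length] away from region edges.
The profile is then smoothed with a centred moving average (default 250 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import (
    AccessibilityTrack,
    ModelParams,
    SiteOccupancy,
    predict_site_occupancy,
)
from .pwm import ScoredSites

__all__ = [
    "ChIPProfile",
    "fragment_length_distribution",
    "expected_coverage_kernel",
    "sample_fragment_kernel",
    "extend_occupancy_to_coverage",
    "smooth_profile",
    "simulate_chip_profile",
]


@dataclass
class ChIPProfile:
    """Per-base, non-negative coverage-like signal over one chromosome."""

    chrom: str
    values: np.ndarray
    bin_size: int = 1
    provenance: str = "simulated"  # "observed" or "simulated"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        if np.any(v < 0):
            raise ValueError("profile values must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


def fragment_length_distribution(mean: float = 200.0, sd: float = 200.0):
    """Discrete fragment-length pmf: normal(mean, sd) truncated at >= 1 bp.

    Returns (lengths, pmf).  With sd == 0 the distribution is a point mass at
    round(mean).
    """
    if mean <= 0:
        raise ValueError("fragment mean must be positive")
    if sd < 0:
        raise ValueError("fragment sd must be non-negative")
    if sd == 0:
        length = max(1, int(round(mean)))
        return np.array([length]), np.array([1.0])
    lmax = int(np.ceil(mean + 6 * sd))
    lengths = np.arange(1, lmax + 1)
    pmf = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
    pmf /= pmf.sum()
    return lengths, pmf


@lru_cache(maxsize=8)
def expected_coverage_kernel(mean: float = 200.0, sd: float = 200.0) -> np.ndarray:
    """Closed-form expected coverage around a bound site at offset d.

    kernel[d] = E_l[max(0, l - |d|) / l], a mixture of unit-peak triangles;
    sum(kernel) = E[l].  Returned as a symmetric array of length 2*lmax - 1
    with the site at the centre index lmax - 1.
    """
    lengths, pmf = fragment_length_distribution(mean, sd)
    lmax = int(lengths[-1])
    d = np.abs(np.arange(-(lmax - 1), lmax))
    # (n_lengths, n_offsets) triangle mixture
    tri = np.maximum(0.0, lengths[:, None] - d[None, :]) / lengths[:, None]
    return (pmf[:, None] * tri).sum(axis=0)


def sample_fragment_kernel(
    mean: float = 200.0,
    sd: float = 200.0,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
):
    """Monte-Carlo estimate of the coverage kernel, for cross-validation.

    Draws fragment lengths from the truncated discrete normal and placements
    uniformly among those covering the site; returns (kernel_estimate,
    standard_error) on the same offset axis as the closed form.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths, pmf = fragment_length_distribution(mean, sd)
    lmax = int(lengths[-1])
    ls = rng.choice(lengths, size=n_draws, p=pmf)
    # fragment start offset relative to the site, uniform on [-(l-1), 0]
    starts = -rng.integers(0, ls)  # integers in (-l, 0]
    width = 2 * lmax - 1
    hits = np.zeros(width + 1)
    a = starts + (lmax - 1)
    b = a + ls
    np.add.at(hits, a, 1.0)
    np.add.at(hits, np.minimum(b, width), -1.0)
    cov = np.cumsum(hits)[:width] / n_draws
    # binomial standard error, floored at the one-count level so that
    # offsets with zero observed coverage keep a meaningful scale
    se = np.sqrt(np.maximum(cov * (1 - cov), 1.0 / n_draws) / n_draws)
    return cov, se


def extend_occupancy_to_coverage(
    occ: SiteOccupancy,
    length: int,
    fragment_mean: float = 200.0,
    fragment_sd: float = 200.0,
) -> ChIPProfile:
    """Expected ChIP coverage: each site adds P_j times the coverage kernel
    centred on the site midpoint.  Coverage falling outside [0, length) is
    clipped, so mass conservation holds exactly only away from the edges."""
    values = np.zeros(length)
    if len(occ) == 0:
        warnings.warn("no sites to extend; returning a zero profile", stacklevel=2)
        return ChIPProfile(chrom=occ.sites.chrom, values=values)
    kernel = expected_coverage_kernel(fragment_mean, fragment_sd)
    half = (len(kernel) - 1) // 2
    centers = occ.sites.centers
    if len(centers) > 64:
        # impulse train convolved with the kernel (linearity of coverage)
        impulses = np.bincount(centers, weights=occ.probabilities, minlength=length)
        from scipy.signal import fftconvolve

        full = fftconvolve(impulses, kernel)
        values = np.clip(full[half : half + length], 0.0, None)
    else:
        for c, p in zip(centers, occ.probabilities):
            if p == 0.0:
                continue
            lo = c - half
            hi = c + half + 1
            klo = max(0, -lo)
            khi = len(kernel) - max(0, hi - length)
            values[max(0, lo) : min(length, hi)] += p * kernel[klo:khi]
    return ChIPProfile(chrom=occ.sites.chrom, values=values)


def smooth_profile(profile: ChIPProfile, window: int = 250) -> ChIPProfile:
    """Centred moving average over ``window`` bp; edge windows shrink to the
    available bases.  A window at least as long as the region returns the
    region mean everywhere."""
    if window < 1:
        raise ValueError("window must be >= 1")
    v = profile.values
    L = len(v)
    if window >= L:
        return ChIPProfile(chrom=profile.chrom, values=np.full(L, v.mean()),
                           provenance=profile.provenance)
    left = (window - 1) // 2
    right = window // 2
    cum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(L)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, L)
    out = (cum[hi] - cum[lo]) / (hi - lo)
    return ChIPProfile(chrom=profile.chrom, values=out, provenance=profile.provenance)


def simulate_chip_profile(
    params: ModelParams,
    filtered_sites: ScoredSites,
    all_sites: ScoredSites,
    acc: AccessibilityTrack,
    length: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fragment_mean: float = 200.0,
    fragment_sd: float = 200.0,
    smooth_window: int = 250,
    avg: float | None = None,
) -> ChIPProfile:
    """Forward generator: occupancy -> coverage -> smoothing -> optional
    additive Gaussian noise clipped at zero.  Deterministic given ``seed``."""
    occ = predict_site_occupancy(params, filtered_sites, all_sites, acc, avg=avg)
    prof = extend_occupancy_to_coverage(occ, length, fragment_mean, fragment_sd)
    prof = smooth_profile(prof, smooth_window)
    values = prof.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, size=len(values)), 0.0, None)
    return ChIPProfile(chrom=prof.chrom, values=values, provenance="simulated")
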