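"""Analytical statistical-thermodynamic model of genomic TF occupancy.

The probability that a TF occupies candidate site j is

    P_j = N a_j exp(w_j / lam) / (N a_j exp(w_j / lam) + L n <a_i exp(w_i / lam)>_i)

where N is the number of molecules bound to the DNA, a_j the accessibility of
the site (0..1), w_j its PWM score, lam (lambda) a factor scaling the
discrimination between strong and weak words, L the genome length in bp, n the
ploidy and <.>_i the mean statistical weight over all genomic site slots — the
competition (partition-function) term.  The model sums Boltzmann weights over
independent site slots; it contains no cooperativity or explicit competition
between factors.

Scores w and lambda share the same log base (bits here); changing the base
rescales lambda and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import ScoredSites

__all__ = [
    "AccessibilityTrack",
    "ModelParams",
    "SiteOccupancy",
    "site_accessibility",
    "boltzmann_weights",
    "genomic_boltzmann_average",
    "occupancy_probability",
    "predict_site_occupancy",
    "total_occupancy",
    "accessibility_from_read_density",
]

LN2 = float(np.log(2.0))


@dataclass
class AccessibilityTrack:
    """Per-base probability that the chromatin is open to TF binding."""

    chrom: str
    values: np.ndarray
    mode: str = "binary"  # "binary" or "continuous"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("accessibility values must lie in [0, 1]")
        if self.mode == "binary" and not np.all((v == 0) | (v == 1)):
            raise ValueError("binary accessibility track contains non 0/1 values")
        if self.mode not in ("binary", "continuous"):
            raise ValueError(f"unknown accessibility mode {self.mode!r}")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def all_open(cls, chrom: str, length: int) -> "AccessibilityTrack":
        """Naked-DNA assumption: a_j = 1 everywhere."""
        return cls(chrom=chrom, values=np.ones(length), mode="binary")

    @classmethod
    def from_intervals(cls, chrom: str, length: int, intervals) -> "AccessibilityTrack":
        """Binary track from 0-based half-open accessible intervals."""
        v = np.zeros(length)
        for start, end in intervals:
            if start < 0 or end > length:
                raise ValueError(f"interval ({start}, {end}) outside track of length {length}")
            v[start:end] = 1.0
        return cls(chrom=chrom, values=v, mode="binary")


@dataclass(frozen=True)
class ModelParams:
    """Free and structural parameters of the occupancy equation.

    N : number of DNA-bound TF molecules (positive real; an ensemble
        average over nuclei, so non-integer values are meaningful).
    lam : specificity scaling of the PWM score (> 0); lam > 1 flattens
        affinity differences, lam < 1 sharpens them.
    L : genome length in bp.
    n : ploidy (genome copies per nucleus; 2 for a diploid embryo).
    """

    N: float
    lam: float
    L: int
    n: int = 2

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n < 1:
            raise ValueError("ploidy n must be >= 1")


@dataclass
class SiteOccupancy:
    """Per-site binding probabilities for a set of scored sites."""

    sites: ScoredSites
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(self.sites):
            raise ValueError("probabilities must match site count")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = p

    def __len__(self) -> int:
        return len(self.sites)


def site_accessibility(sites: ScoredSites, acc: AccessibilityTrack) -> np.ndarray:
    """Accessibility a_j of each site: mean of the per-base track over the
    m-bp window (for a binary track this is the open fraction of the window)."""
    cum = np.concatenate(([0.0], np.cumsum(acc.values)))
    w = sites.width
    ends = np.minimum(sites.positions + w, len(acc.values))
    return (cum[ends] - cum[sites.positions]) / w


def boltzmann_weights(sites: ScoredSites, acc: AccessibilityTrack, lam: float) -> np.ndarray:
    """Statistical weight a_j * exp(w_j / lam) of every site."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    a = site_accessibility(sites, acc)
    return a * np.exp(sites.scores / lam)


def genomic_boltzmann_average(
    all_sites: ScoredSites,
    acc: AccessibilityTrack,
    lam: float,
    genome_length: int | None = None,
) -> float:
    """Mean statistical weight <a_i exp(w_i / lam)>_i over genomic site slots.

    ``all_sites`` must be the *unfiltered* scan (every scorable window, both
    strands); masked windows are absent and implicitly contribute zero weight.
    With ``genome_length`` given, the divisor is L, so that the occupancy
    denominator term ``L * n * avg`` equals the total weight summed over all
    L*n slots (the n identical genome copies cancel between numerator count
    and divisor).  Without it, the divisor is the number of sites supplied —
    convenient for toy calculations on explicit site lists.
    """
    w = boltzmann_weights(all_sites, acc, lam)
    divisor = len(all_sites) if genome_length is None else genome_length
    if divisor <= 0:
        raise ValueError("empty site set")
    avg = float(w.sum()) / divisor
    if avg == 0.0:
        raise ValueError(
            "genomic Boltzmann average is zero (no accessible site); the model is undefined"
        )
    return avg


def occupancy_probability(
    weight_j,
    params: ModelParams,
    avg: float,
):
    """Occupancy-equation binding probability for site weight(s)
    x_j = a_j exp(w_j / lam).

    ``avg`` must come from :func:`genomic_boltzmann_average` at the same
    lambda and accessibility.  Vectorised over ``weight_j``.
    """
    if avg <= 0:
        raise ValueError("genomic average must be positive")
    x = params.N * np.asarray(weight_j, dtype=float)
    return x / (x + params.L * params.n * avg)


def predict_site_occupancy(
    params: ModelParams,
    filtered_sites: ScoredSites,
    all_sites: ScoredSites,
    acc: AccessibilityTrack,
    avg: float | None = None,
) -> SiteOccupancy:
    """Binding probability for every reported (filtered) site.

    The competition term in the denominator is always computed over *all*
    scorable windows, not only the reported ones: the partition function of
    the genome does not depend on which sites we choose to report.
    """
    if avg is None:
        avg = genomic_boltzmann_average(all_sites, acc, params.lam, genome_length=params.L)
    x = boltzmann_weights(filtered_sites, acc, params.lam)
    p = occupancy_probability(x, params, avg)
    return SiteOccupancy(sites=filtered_sites, probabilities=np.asarray(p))


def total_occupancy(
    params: ModelParams,
    all_sites: ScoredSites,
    acc: AccessibilityTrack,
) -> float:
    """Expected number of bound molecules: sum of P_j over all L*n site slots.

    In the low-abundance regime (N * max weight << L * n * avg) this tends to
    N exactly — the model conserves molecules.
    """
    avg = genomic_boltzmann_average(all_sites, acc, params.lam, genome_length=params.L)
    x = boltzmann_weights(all_sites, acc, params.lam)
    p = occupancy_probability(x, params, avg)
    return float(params.n * p.sum())


def accessibility_from_read_density(
    read_density,
    scale: float = 2.0,
    midpoint: float | None = None,
    chrom: str = "chr",
) -> AccessibilityTrack:
    """Map a non-negative per-base read-density track to open-chromatin
    probabilities in [0, 1].

    The map is a Hill curve, i.e. a logistic in log-density:

        a(d) = d**scale / (d**scale + midpoint**scale)

    so a(0) = 0, a(midpoint) = 0.5, and a is monotone increasing.  The
    ``midpoint`` defaults to the median of the positive densities.  This is a
    documented stand-in for a calibrated read-density -> accessibility map;
    scale and midpoint are exposed in the configuration.
    """
    d = np.asarray(read_density, dtype=float)
    if np.any(d < 0):
        raise ValueError("read densities must be non-negative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if midpoint is None:
        pos = d[d > 0]
        if len(pos) == 0:
            return AccessibilityTrack(chrom=chrom, values=np.zeros_like(d), mode="continuous")
        midpoint = float(np.median(pos))
    if midpoint <= 0:
        raise ValueError("midpoint must be positive")
    with np.errstate(over="ignore"):
        a = d**scale / (d**scale + midpoint**scale)
    return AccessibilityTrack(chrom=chrom, values=a, mode="continuous")
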