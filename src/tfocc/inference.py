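"""Comparing predicted and observed profiles and inferring (N, lambda).

Two complementary metrics quantify the distance between a model profile and
an observed ChIP profile: the Pearson correlation coefficient rho, and the
normalized mean squared error over 1-kb bins (both profiles are binned to
1-kb means and divided by their own mean before squared differences, which
removes the arbitrary global scale of ChIP signal).  A grid search over
N in [1, 1e6] and lambda in [0.25, 5] evaluates both, and the optimum is the
minimum-MSE cell inside the intersection of the best-12% bands of the two
surfaces.  Correlation constrains lambda but is flat in N; the MSE constrains
N but is flatter in lambda — hence the intersection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chip import ChIPProfile
from .model import AccessibilityTrack

__all__ = [
    "DEFAULT_N_GRID",
    "DEFAULT_LAMBDA_GRID",
    "FitGrid",
    "FitResult",
    "RegionSummary",
    "pearson_correlation",
    "normalized_mse_1kb",
    "analysis_locus_mask",
    "select_optimum",
    "genome_wide_regions",
    "ks_two_sample",
]

# Log-spaced abundance grid covering every optimum reported for the five
# embryo TFs, and a 0.25-step lambda grid over the searched range.
DEFAULT_N_GRID = np.array(
    [1, 10, 100, 500, 1000, 2000, 5000, 10_000, 20_000, 50_000, 100_000, 1_000_000],
    dtype=float,
)
DEFAULT_LAMBDA_GRID = np.arange(0.25, 5.25, 0.25)


@dataclass
class FitGrid:
    """Correlation and MSE surfaces over the (N, lambda) grid."""

    N_values: np.ndarray
    lambda_values: np.ndarray
    rho: np.ndarray
    mse: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.N_values), len(self.lambda_values))
        if self.rho.shape != shape or self.mse.shape != shape:
            raise ValueError(f"surfaces must have shape {shape}")


@dataclass
class FitResult:
    """Selected optimum of a grid search.

    ``intersection_cells`` lists (N, lambda) pairs where the MSE is within
    the lowest ``band_fraction`` of its range and rho within the highest
    ``band_fraction`` of its range.  When the bands do not intersect the
    optimum falls back to the global MSE minimum and ``fallback`` is set.
    """

    N_opt: float
    lambda_opt: float
    mse_at_opt: float
    rho_at_opt: float
    mse_min: float
    rho_max: float
    intersection_cells: list = field(default_factory=list)
    fallback: bool = False
    degenerate: bool = False


@dataclass
class RegionSummary:
    """Fit quality of one fixed-width genomic region."""

    chrom: str
    start: int
    end: int
    mean_signal: float
    rho: float | None
    mse: float
    passes_background: bool


def pearson_correlation(pred: ChIPProfile, obs: ChIPProfile) -> float:
    """Pearson correlation coefficient between two same-region profiles."""
    x, y = pred.values, obs.values
    if len(x) != len(y):
        raise ValueError("profiles must cover the same region")
    if len(x) < 2:
        raise ValueError("need at least 2 bases to correlate")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroDivisionError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(x, y).statistic)


def _bin_means(v: np.ndarray, bin_size: int) -> np.ndarray:
    n_full = len(v) // bin_size
    out = v[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1)
    rest = v[n_full * bin_size :]
    if len(rest):
        out = np.append(out, rest.mean())
    return out


def normalized_mse_1kb(
    pred: ChIPProfile,
    obs: ChIPProfile,
    bin_size: int = 1000,
    normalization: str = "nmse",
) -> float:
    """Normalized mean squared error over ``bin_size`` bins (default 1 kb).

    Both profiles are reduced to per-bin means; then, with the default
    "nmse" normalization, the squared error is normalized by the observed
    signal power:

        mse = mean((pred_bin - obs_bin)^2) / mean(obs_bin^2)

    This metric is sensitive to the overall scale of the prediction, which
    is what lets it constrain the molecule number N (site occupancy — and
    with it the predicted signal level — saturates with N, while the
    correlation sees shape only).  The scale-free alternatives "mean" and
    "unit_max" divide each binned profile by its own mean or maximum before
    the squared difference, making the metric invariant to positive
    rescaling of either profile.
    """
    x, y = pred.values, obs.values
    if len(x) != len(y):
        raise ValueError("profiles must cover the same region")
    if len(x) < bin_size:
        warnings.warn("region shorter than one bin; comparing single-bin means", stacklevel=2)
    bx, by = _bin_means(x, bin_size), _bin_means(y, bin_size)
    if normalization == "nmse":
        power = float(np.mean(by**2))
        if power == 0:
            raise ZeroDivisionError("cannot normalize against an all-zero observed profile")
        return float(np.mean((bx - by) ** 2) / power)
    if normalization == "mean":
        sx, sy = bx.mean(), by.mean()
    elif normalization == "unit_max":
        sx, sy = bx.max(), by.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if sx == 0 or sy == 0:
        raise ZeroDivisionError("cannot normalize an all-zero profile")
    return float(np.mean((bx / sx - by / sy) ** 2))


def _dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation of a 1-D mask by ``radius`` bases on each side."""
    if radius <= 0:
        return mask.copy()
    cum = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    n = len(mask)
    idx = np.arange(n)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius + 1, n)
    return (cum[hi] - cum[lo]) > 0


def _mask_segments(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if len(mask) and mask[0]:
        starts.insert(0, 0)
    if len(mask) and mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def analysis_locus_mask(
    obs: dict[str, np.ndarray],
    acc: dict[str, np.ndarray],
    dilate: int = 500,
    background_mult: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-base mask of the analysed loci: accessible segments (dilated by
    ``dilate`` bp to capture fragment spill-over) whose mean observed signal
    exceeds ``background_mult`` times the background B, where B is the mean
    observed signal over all dilated accessible segments genome-wide.

    This mirrors restricting profile comparisons to strong-binding loci:
    regions where neither binding nor signal is possible carry no
    information about (N, lambda) and only dilute the metrics.  Falls back
    to all dilated accessible segments when none passes the filter.
    """
    dil = {c: _dilate_mask(np.asarray(acc[c]) > 0, dilate) for c in obs}
    covered = np.concatenate([np.asarray(obs[c])[dil[c]] for c in obs])
    if covered.size == 0:
        raise ValueError("no accessible base anywhere; cannot define analysis loci")
    background = float(covered.mean())
    out = {}
    any_kept = False
    for c in obs:
        keep = np.zeros(len(obs[c]), dtype=bool)
        for s, e in _mask_segments(dil[c]):
            if np.mean(obs[c][s:e]) > background_mult * background:
                keep[s:e] = True
        any_kept = any_kept or keep.any()
        out[c] = keep
    if not any_kept:
        out = dil
    return out


def select_optimum(grid: FitGrid, band_fraction: float = 0.12) -> FitResult:
    """Pick the optimal (N, lambda) via the 12%-band intersection rule.

    The MSE band keeps cells with mse <= mse_min + band_fraction * range;
    the rho band keeps cells with rho >= rho_max - band_fraction * range.
    The optimum is the minimum-MSE cell inside the intersection when it is
    non-empty, otherwise the global minimum-MSE cell (``fallback=True``).
    Ties break toward the smallest N, then the smallest lambda.
    """
    mse, rho = grid.mse, grid.rho
    if not (np.all(np.isfinite(mse)) and np.all(np.isfinite(rho))):
        raise ValueError("grid surfaces must be finite")
    mse_min, mse_max = float(mse.min()), float(mse.max())
    rho_min, rho_max = float(rho.min()), float(rho.max())

    degenerate = mse_min == mse_max and rho_min == rho_max
    mse_band = mse <= mse_min + band_fraction * (mse_max - mse_min)
    rho_band = rho >= rho_max - band_fraction * (rho_max - rho_min)
    inter = mse_band & rho_band

    def _argmin_cells(mask: np.ndarray) -> tuple[int, int]:
        # minimum MSE among masked cells; ties -> smallest N then lambda.
        masked = np.where(mask, mse, np.inf)
        best = masked.min()
        ii, jj = np.where(masked <= best)
        return int(ii[0]), int(jj[0])

    fallback = not inter.any()
    i, j = _argmin_cells(np.ones_like(inter) if fallback else inter)
    cells = [
        (float(grid.N_values[a]), float(grid.lambda_values[b]))
        for a, b in zip(*np.where(inter))
    ]
    return FitResult(
        N_opt=float(grid.N_values[i]),
        lambda_opt=float(grid.lambda_values[j]),
        mse_at_opt=float(mse[i, j]),
        rho_at_opt=float(rho[i, j]),
        mse_min=mse_min,
        rho_max=rho_max,
        intersection_cells=cells,
        fallback=fallback,
        degenerate=degenerate,
    )


def genome_wide_regions(
    obs: ChIPProfile,
    pred: ChIPProfile,
    acc: AccessibilityTrack,
    region_bp: int = 20_000,
    background_mult: float = 1.0,
    mse_bin: int = 1000,
) -> list[RegionSummary]:
    """Tile the genome into fixed-width regions and grade the fit per region.

    Regions with no accessible base are dropped.  The background B is the
    mean observed signal over all retained regions; a region passes when its
    mean observed signal strictly exceeds ``background_mult * B``.  rho is
    None for regions where either profile has zero variance.
    """
    L = len(obs)
    if len(pred) != L or len(acc.values) != L:
        raise ValueError("observed, predicted and accessibility tracks must align")
    edges = list(range(0, L, region_bp))
    regions = []
    for start in edges:
        end = min(start + region_bp, L)
        if not np.any(acc.values[start:end] > 0):
            continue
        regions.append((start, end))
    if not regions:
        return []
    retained = np.concatenate([obs.values[s:e] for s, e in regions])
    background = float(retained.mean())

    out = []
    for start, end in regions:
        o = ChIPProfile(obs.chrom, obs.values[start:end], provenance="observed")
        p = ChIPProfile(pred.chrom, pred.values[start:end])
        mean_signal = float(o.values.mean())
        try:
            rho = pearson_correlation(p, o)
        except ZeroDivisionError:
            rho = None
        try:
            mse = normalized_mse_1kb(p, o, bin_size=mse_bin)
        except ZeroDivisionError:
            mse = float("nan")
        out.append(
            RegionSummary(
                chrom=obs.chrom,
                start=start,
                end=end,
                mean_signal=mean_signal,
                rho=rho,
                mse=mse,
                passes_background=mean_signal > background_mult * background,
            )
        )
    return out


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (max ECDF difference, asymptotic p).

    Warns when either sample has fewer than 10 observations — the asymptotic
    p-value is unreliable there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if min(len(x), len(y)) < 10:
        warnings.warn("KS p-value unreliable for samples smaller than 10", stacklevel=2)
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
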