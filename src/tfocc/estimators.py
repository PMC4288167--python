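"""Estimator interfaces for the occupancy model and the (N, lambda) fit.

`OccupancyModel` is the forward model: configure it with a PWM and the
thermodynamic parameters, ``fit`` it to a genome (which scans and caches the
site landscape — the expensive, parameter-independent part), then ``predict``
ChIP-like profiles at any (N, lambda).  `ProfileGridSearch` wraps the forward
model in a scikit-learn style ``fit``: given a genome and an observed profile
it sweeps the (N, lambda) grid, stores the correlation and MSE surfaces, and
exposes the selected optimum as fitted attributes (``N_opt_``,
``lambda_opt_``, ``grid_``, ``result_``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .chip import ChIPProfile, extend_occupancy_to_coverage, smooth_profile
from .inference import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_N_GRID,
    FitGrid,
    FitResult,
    analysis_locus_mask,
    normalized_mse_1kb,
    pearson_correlation,
    select_optimum,
)
from .model import (
    AccessibilityTrack,
    ModelParams,
    SiteOccupancy,
    boltzmann_weights,
    occupancy_probability,
)
from .pwm import (
    PWM,
    ScoredSites,
    filter_by_relative_score,
    relative_score_threshold,
    score_sequence,
)

__all__ = ["OccupancyModel", "ProfileGridSearch"]


def _as_genome_dict(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return {"chr": genome}


class OccupancyModel(BaseEstimator):
    """Analytical occupancy model over a genome.

    Parameters
    ----------
    pwm : PWM
        Log2 likelihood-ratio scoring matrix.
    N : float, default 2000
        Number of DNA-bound molecules.
    lam : float, default 1.25
        Specificity scaling of the PWM score.
    ploidy : int, default 2
        Genome copies per nucleus.
    threshold_fraction : float, default 0.7
        Relative-score filter selecting which sites are reported; the
        partition function always runs over all scanned windows.
    threshold_mode : {"absolute_range", "offset_from_min"}
        Literal published rule (f * (max - min)) or the min-anchored variant.
    fragment_mean, fragment_sd : float, default 200, 200
        ChIP fragment length distribution (bp).
    smooth_window : int, default 250
        Moving-average smoothing of the simulated profile (bp).
    """

    def __init__(
        self,
        pwm: PWM = None,
        N: float = 2000.0,
        lam: float = 1.25,
        ploidy: int = 2,
        threshold_fraction: float = 0.7,
        threshold_mode: str = "absolute_range",
        fragment_mean: float = 200.0,
        fragment_sd: float = 200.0,
        smooth_window: int = 250,
    ):
        self.pwm = pwm
        self.N = N
        self.lam = lam
        self.ploidy = ploidy
        self.threshold_fraction = threshold_fraction
        self.threshold_mode = threshold_mode
        self.fragment_mean = fragment_mean
        self.fragment_sd = fragment_sd
        self.smooth_window = smooth_window

    # -- fitting = scanning the genome (parameter independent) ------------

    def fit(self, genome, accessibility=None):
        """Scan the genome, apply the site filter, attach accessibility.

        ``genome`` is a sequence string or a {chrom: sequence} dict;
        ``accessibility`` an AccessibilityTrack, a {chrom: track} dict, or
        None for naked DNA (a = 1 everywhere).
        """
        if self.pwm is None:
            raise ValueError("an OccupancyModel needs a PWM")
        genome = _as_genome_dict(genome)
        self.chroms_ = list(genome)
        self.genome_length_ = sum(len(s) for s in genome.values())
        self.sites_ = {c: score_sequence(self.pwm, seq, chrom=c) for c, seq in genome.items()}
        self.chrom_lengths_ = {c: len(seq) for c, seq in genome.items()}

        if accessibility is None:
            acc = {c: AccessibilityTrack.all_open(c, len(genome[c])) for c in genome}
        elif isinstance(accessibility, AccessibilityTrack):
            acc = {self.chroms_[0]: accessibility}
        else:
            acc = accessibility
        for c in self.chroms_:
            if len(acc[c]) != len(genome[c]):
                raise ValueError(f"accessibility track length mismatch on {c}")
        self.accessibility_ = acc

        # the relative-score threshold is anchored to the genome-wide range
        all_scores = np.concatenate([self.sites_[c].scores for c in self.chroms_])
        smin, smax = float(all_scores.min()), float(all_scores.max())
        for c in self.chroms_:
            self.sites_[c].score_min = smin
            self.sites_[c].score_max = smax
        self.score_threshold_ = relative_score_threshold(
            all_scores, self.threshold_fraction, self.threshold_mode
        )
        self.filtered_sites_ = {
            c: filter_by_relative_score(
                self.sites_[c], self.threshold_fraction, mode=self.threshold_mode
            )
            for c in self.chroms_
        }
        self._avg_cache: dict[float, float] = {}
        return self

    # -- model evaluation --------------------------------------------------

    def boltzmann_average(self, lam: float | None = None) -> float:
        """Genome-wide mean statistical weight at lambda, cached per lambda."""
        lam = self.lam if lam is None else lam
        if lam not in self._avg_cache:
            total = sum(
                float(boltzmann_weights(self.sites_[c], self.accessibility_[c], lam).sum())
                for c in self.chroms_
            )
            avg = total / self.genome_length_
            if avg == 0.0:
                raise ValueError("genome entirely inaccessible; the model is undefined")
            self._avg_cache[lam] = avg
        return self._avg_cache[lam]

    def params_(self, N=None, lam=None) -> ModelParams:
        return ModelParams(
            N=self.N if N is None else N,
            lam=self.lam if lam is None else lam,
            L=self.genome_length_,
            n=self.ploidy,
        )

    def predict_occupancy(self, N=None, lam=None) -> dict[str, SiteOccupancy]:
        """Binding probability of every reported site, per chromosome."""
        p = self.params_(N, lam)
        avg = self.boltzmann_average(p.lam)
        out = {}
        for c in self.chroms_:
            x = boltzmann_weights(self.filtered_sites_[c], self.accessibility_[c], p.lam)
            out[c] = SiteOccupancy(
                sites=self.filtered_sites_[c],
                probabilities=np.asarray(occupancy_probability(x, p, avg)),
            )
        return out

    def total_occupancy(self, N=None, lam=None) -> float:
        """Sum of P_j over all L*n site slots (expected bound molecules)."""
        p = self.params_(N, lam)
        avg = self.boltzmann_average(p.lam)
        total = 0.0
        for c in self.chroms_:
            x = boltzmann_weights(self.sites_[c], self.accessibility_[c], p.lam)
            total += float(np.sum(occupancy_probability(x, p, avg)))
        return self.ploidy * total

    def predict(self, N=None, lam=None) -> dict[str, ChIPProfile]:
        """Noise-free ChIP-like profile (coverage kernel + smoothing)."""
        occ = self.predict_occupancy(N, lam)
        out = {}
        for c in self.chroms_:
            prof = extend_occupancy_to_coverage(
                occ[c], self.chrom_lengths_[c], self.fragment_mean, self.fragment_sd
            )
            out[c] = smooth_profile(prof, self.smooth_window)
        return out

    def simulate(self, noise_sd: float = 0.0, seed=None, N=None, lam=None):
        """Noise-free prediction plus additive Gaussian noise clipped at 0."""
        profiles = self.predict(N, lam)
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            for c, prof in profiles.items():
                v = np.clip(prof.values + rng.normal(0, noise_sd, len(prof)), 0, None)
                profiles[c] = ChIPProfile(chrom=c, values=v, provenance="simulated")
        return profiles


class ProfileGridSearch(BaseEstimator):
    """Grid-search estimator of TF abundance N and specificity lambda.

    ``fit(genome, observed, accessibility=...)`` sweeps the grid, computing
    for every (N, lambda) the Pearson correlation and the normalized 1-kb MSE
    between the model profile and the observed profile, then selects the
    optimum with the 12%-band intersection rule.

    Metrics are computed over the analysed loci: with ``metric_loci="auto"``
    (the default) these are the dilated accessible segments whose mean
    observed signal exceeds the genome-wide background — profile comparisons
    are only informative where binding is possible and signal present.  Pass
    ``metric_loci=None`` for genome-wide metrics, or a
    ``{chrom: boolean mask or [(start, end), ...]}`` mapping for explicit
    loci (e.g. a curated locus list).

    Fitted attributes: ``grid_`` (FitGrid), ``result_`` (FitResult),
    ``N_opt_``, ``lambda_opt_``, ``model_`` (the fitted forward model),
    ``metric_mask_`` (the per-chromosome metric-domain mask).
    """

    def __init__(
        self,
        pwm: PWM = None,
        N_grid=None,
        lambda_grid=None,
        band_fraction: float = 0.12,
        ploidy: int = 2,
        threshold_fraction: float = 0.7,
        threshold_mode: str = "absolute_range",
        fragment_mean: float = 200.0,
        fragment_sd: float = 200.0,
        smooth_window: int = 250,
        normalization: str = "nmse",
        mse_bin: int = 1000,
        metric_loci="auto",
        loci_dilate: int = 500,
        loci_background_mult: float = 1.0,
    ):
        self.pwm = pwm
        self.N_grid = N_grid
        self.lambda_grid = lambda_grid
        self.band_fraction = band_fraction
        self.ploidy = ploidy
        self.threshold_fraction = threshold_fraction
        self.threshold_mode = threshold_mode
        self.fragment_mean = fragment_mean
        self.fragment_sd = fragment_sd
        self.smooth_window = smooth_window
        self.normalization = normalization
        self.mse_bin = mse_bin
        self.metric_loci = metric_loci
        self.loci_dilate = loci_dilate
        self.loci_background_mult = loci_background_mult

    def _metric_mask(self, genome, observed, accessibility) -> dict[str, np.ndarray]:
        if self.metric_loci is None or (self.metric_loci == "auto" and accessibility is None):
            return {c: np.ones(len(genome[c]), dtype=bool) for c in genome}
        if self.metric_loci == "auto":
            return analysis_locus_mask(
                {c: observed[c].values for c in genome},
                {c: accessibility[c].values for c in genome},
                dilate=self.loci_dilate,
                background_mult=self.loci_background_mult,
            )
        masks = {}
        for c in genome:
            loci = self.metric_loci.get(c)
            if loci is None:
                masks[c] = np.zeros(len(genome[c]), dtype=bool)
            elif isinstance(loci, np.ndarray) and loci.dtype == bool:
                masks[c] = loci
            else:
                masks[c] = np.zeros(len(genome[c]), dtype=bool)
                for s, e in loci:
                    masks[c][s:e] = True
        if not any(m.any() for m in masks.values()):
            raise ValueError("metric_loci selects no base")
        return masks

    def fit(self, genome, observed, accessibility=None):
        genome = _as_genome_dict(genome)
        observed = observed if isinstance(observed, dict) else {"chr": observed}
        if accessibility is not None and isinstance(accessibility, AccessibilityTrack):
            accessibility = {next(iter(genome)): accessibility}
        mask = self._metric_mask(genome, observed, accessibility)
        obs_concat = np.concatenate(
            [np.asarray(observed[c].values)[mask[c]] for c in genome]
        )
        if np.std(obs_concat) == 0:
            raise ValueError("observed profile is degenerate (zero variance)")
        obs_prof = ChIPProfile(chrom="all", values=obs_concat, provenance="observed")

        model = OccupancyModel(
            pwm=self.pwm,
            ploidy=self.ploidy,
            threshold_fraction=self.threshold_fraction,
            threshold_mode=self.threshold_mode,
            fragment_mean=self.fragment_mean,
            fragment_sd=self.fragment_sd,
            smooth_window=self.smooth_window,
        ).fit(genome, accessibility)
        if sum(len(model.filtered_sites_[c]) for c in model.chroms_) == 0:
            raise ValueError(
                "no site passes the relative-score filter; with "
                "threshold_mode='absolute_range' this is expected whenever the "
                "weakest window scores far below zero — see the methods note"
            )

        N_values = np.asarray(DEFAULT_N_GRID if self.N_grid is None else self.N_grid, dtype=float)
        lam_values = np.asarray(
            DEFAULT_LAMBDA_GRID if self.lambda_grid is None else self.lambda_grid, dtype=float
        )
        rho = np.empty((len(N_values), len(lam_values)))
        mse = np.empty_like(rho)
        for j, lam in enumerate(lam_values):
            # the Boltzmann average and the site weights depend on lambda only
            model.boltzmann_average(lam)
            for i, N in enumerate(N_values):
                pred = model.predict(N=N, lam=lam)
                pred_concat = np.concatenate([pred[c].values[mask[c]] for c in genome])
                pred_prof = ChIPProfile(chrom="all", values=pred_concat)
                rho[i, j] = pearson_correlation(pred_prof, obs_prof)
                mse[i, j] = normalized_mse_1kb(
                    pred_prof, obs_prof, bin_size=self.mse_bin,
                    normalization=self.normalization,
                )

        self.model_ = model
        self.metric_mask_ = mask
        self.grid_ = FitGrid(N_values=N_values, lambda_values=lam_values, rho=rho, mse=mse)
        self.result_ = select_optimum(self.grid_, self.band_fraction)
        self.N_opt_ = self.result_.N_opt
        self.lambda_opt_ = self.result_.lambda_opt
        return self

    def predict(self) -> dict[str, ChIPProfile]:
        """Model profile at the fitted optimum."""
        return self.model_.predict(N=self.N_opt_, lam=self.lambda_opt_)
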