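"""tfocc: statistical-thermodynamic TF occupancy modelling and inference.

The package predicts genome-wide transcription-factor binding probabilities
from a PWM, DNA accessibility, the number of DNA-bound molecules N and a
specificity factor lambda; converts them into ChIP-seq-like profiles; and
infers (N, lambda) from observed profiles by grid search over correlation
and normalized-MSE surfaces.
"""

from .pwm import (
    PWM,
    ScoredSites,
    build_pwm,
    information_content,
    score_sequence,
    filter_by_relative_score,
    relative_score_threshold,
)
from .model import (
    AccessibilityTrack,
    ModelParams,
    SiteOccupancy,
    boltzmann_weights,
    genomic_boltzmann_average,
    occupancy_probability,
    predict_site_occupancy,
    total_occupancy,
    accessibility_from_read_density,
)
from .chip import (
    ChIPProfile,
    expected_coverage_kernel,
    fragment_length_distribution,
    sample_fragment_kernel,
    extend_occupancy_to_coverage,
    smooth_profile,
    simulate_chip_profile,
)
from .inference import (
    DEFAULT_N_GRID,
    DEFAULT_LAMBDA_GRID,
    FitGrid,
    FitResult,
    RegionSummary,
    pearson_correlation,
    normalized_mse_1kb,
    select_optimum,
    genome_wide_regions,
    ks_two_sample,
)
from .estimators import OccupancyModel, ProfileGridSearch
from .synthetic import (
    SyntheticSpec,
    Fixture,
    default_pwm,
    default_pwm_counts,
    generate_genome,
    generate_accessibility,
    plant_sites,
    make_fixture,
)
from . import io

__version__ = "0.1.0"


def grid_search(observed, pwm, genome, accessibility=None, N_grid=None,
                lambda_grid=None, **kwargs):
    """Thin wrapper over :class:`ProfileGridSearch`: returns the FitGrid."""
    est = ProfileGridSearch(pwm=pwm, N_grid=N_grid, lambda_grid=lambda_grid, **kwargs)
    est.fit(genome, observed, accessibility=accessibility)
    return est.grid_

__all__ = [name for name in dir() if not name.startswith("_")]
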