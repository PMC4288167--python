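"""Synthetic genomes, accessibility tracks and forward-simulated ChIP profiles.

The generator emulates the statistical structure the occupancy model assumes:
an i.i.d. background genome, a set of planted high-affinity motif instances,
block-structured binary accessibility (as produced by FDR-thresholded DNase
peak calls), and an observed profile forward-simulated from the model at a
known (N, lambda) with additive noise.  Every latent variable is returned in
a truth table so recovery can be scored exactly.  All randomness flows from a
single integer seed.

The default motif is deliberately low-information (7 bp, ~1.3 bits): at the
default fixture scale the partition function must be dominated by genomic
background mass for the molecule-conservation limit (sum of P_j -> N at small
N) to hold, while planted sites still sit in the mid-saturation regime at the
default N* so that abundance remains identifiable from profile shape.  Real
motifs are sharper; what this fixture tests is the model arithmetic and the
inference machinery, not motif discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chip import ChIPProfile
from .estimators import OccupancyModel
from .io import write_bed, write_bedgraph, write_fasta, write_pwm
from .model import AccessibilityTrack
from .pwm import ALPHABET, PWM, build_pwm, encode_sequence

__all__ = [
    "SyntheticSpec",
    "Fixture",
    "default_pwm_counts",
    "default_pwm",
    "generate_genome",
    "plant_sites",
    "generate_accessibility",
    "make_fixture",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# 7-bp motif, consensus TGACTCA, consensus base 49/100 per column.
_DEFAULT_CONSENSUS = "TGACTCA"


def default_pwm_counts() -> np.ndarray:
    counts = np.full((4, len(_DEFAULT_CONSENSUS)), 17, dtype=float)
    for i, base in enumerate(_DEFAULT_CONSENSUS):
        counts[ALPHABET.index(base), i] = 49
    return counts


def default_pwm(pseudo_count: float = 1.0) -> PWM:
    return build_pwm(default_pwm_counts(), pseudo_count=pseudo_count, name="synthetic_tf")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic fixture.

    ``noise_sd`` is expressed as a fraction of the noise-free profile maximum
    (0.1 = noise sd at 10% of the peak).  ``site_strength_range`` gives the
    planted-site score band as fractions of the span between the weakest and
    the strongest possible word (1.0 = consensus).
    """

    genome_length: int = 200_000
    gc_content: float = 0.5
    n_planted_sites: int = 50
    site_strength_range: tuple = (0.85, 1.0)
    min_spacing: int = 20
    accessible_fraction: float = 0.15
    accessible_segment_mean: float = 1000.0
    force_accessible_sites: bool = False
    true_N: float = 5000.0
    true_lambda: float = 1.5
    noise_sd: float = 0.1
    ploidy: int = 2
    threshold_fraction: float = 0.7
    # the literal 'absolute_range' rule retains nothing on random sequence;
    # the min-anchored reading is the operable one for end-to-end fixtures
    threshold_mode: str = "offset_from_min"
    fragment_mean: float = 200.0
    fragment_sd: float = 200.0
    smooth_window: int = 250
    chrom: str = "chrS"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for name in ("gc_content", "accessible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.site_strength_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("site_strength_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class Fixture:
    """In-memory bundle of one synthetic data set plus its ground truth."""

    spec: SyntheticSpec
    genome: str
    pwm: PWM
    accessibility: AccessibilityTrack
    observed: ChIPProfile
    noiseless: ChIPProfile
    truth: dict
    model: OccupancyModel  # forward model already fitted to the genome


def generate_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> str:
    """i.i.d. random genome at the requested GC content."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.genome_length, p=p)
    return "".join(ALPHABET[c] for c in codes)


def _instance_for_target(pwm: PWM, target: float, rng: np.random.Generator) -> str:
    """Motif instance with score close to (and not below) ``target``.

    Starts from the consensus and accepts random single-base substitutions
    (drawn from the column frequencies) while the score stays >= target.
    """
    m = pwm.length
    codes = list(pwm.matrix.argmax(axis=0))
    score = pwm.max_score
    for _ in range(20 * m):
        i = int(rng.integers(m))
        b = int(rng.choice(4, p=pwm.frequencies[:, i] / pwm.frequencies[:, i].sum()))
        new = score - pwm.matrix[codes[i], i] + pwm.matrix[b, i]
        if new >= target:
            codes[i] = b
            score = new
    return "".join(ALPHABET[c] for c in codes)


def plant_sites(
    genome: str,
    pwm: PWM,
    n_sites: int,
    strength_range: tuple = (0.85, 1.0),
    min_spacing: int = 20,
    rng: np.random.Generator | None = None,
    accessibility: AccessibilityTrack | None = None,
) -> tuple[str, dict]:
    """Write non-overlapping motif instances into the genome.

    Returns the modified genome and a truth table with positions (0-based
    window starts), strands and the realised PWM scores.  When an
    accessibility track is given, sites are only placed in fully accessible
    windows (sites in closed chromatin are invisible to the model by
    construction).
    """
    rng = np.random.default_rng() if rng is None else rng
    m = pwm.length
    L = len(genome)
    if n_sites * (m + min_spacing) > L:
        raise ValueError("cannot pack the requested sites into the genome")
    if n_sites == 0:
        return genome, {"positions": [], "strands": [], "scores": []}

    allowed = None
    if accessibility is not None:
        open_base = accessibility.values > 0
        cum = np.concatenate(([0], np.cumsum(open_base)))
        allowed = np.flatnonzero((cum[m:] - cum[:-m]) == m)
        if len(allowed) < n_sites:
            raise ValueError("not enough accessible windows to place the sites")

    positions: list[int] = []
    taken = np.zeros(L, dtype=bool)
    for _ in range(n_sites):
        for _attempt in range(10_000):
            pos = int(rng.choice(allowed)) if allowed is not None else int(rng.integers(L - m + 1))
            lo = max(0, pos - min_spacing)
            hi = min(L, pos + m + min_spacing)
            if not taken[lo:hi].any():
                taken[pos : pos + m] = True
                positions.append(pos)
                break
        else:
            raise ValueError("could not place all sites without overlap")

    span = pwm.max_score - pwm.min_score
    lo_u, hi_u = strength_range
    seq = list(genome)
    strands, scores = [], []
    for pos in positions:
        u = float(rng.uniform(lo_u, hi_u))
        target = pwm.min_score + u * span
        instance = _instance_for_target(pwm, target, rng)
        codes = encode_sequence(instance)
        score = float(pwm.matrix[codes, np.arange(pwm.length)].sum())
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else instance.translate(_COMPLEMENT)[::-1]
        seq[pos : pos + m] = written
        strands.append(strand)
        scores.append(score)

    order = np.argsort(positions)
    truth = {
        "positions": [int(positions[i]) for i in order],
        "strands": [strands[i] for i in order],
        "scores": [scores[i] for i in order],
    }
    return "".join(seq), truth


def generate_accessibility(
    spec: SyntheticSpec, genome_length: int | None = None, rng: np.random.Generator | None = None
) -> AccessibilityTrack:
    """Binary block accessibility: alternating open/closed segments with
    geometric lengths, open segments averaging ``accessible_segment_mean`` bp
    and the closed-segment mean set so the open fraction matches the spec."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    L = spec.genome_length if genome_length is None else genome_length
    f = spec.accessible_fraction
    if f >= 1.0:
        return AccessibilityTrack(spec.chrom, np.ones(L), mode="binary")
    if f <= 0.0:
        return AccessibilityTrack(spec.chrom, np.zeros(L), mode="binary")
    mean_open = max(1.0, spec.accessible_segment_mean)
    mean_closed = mean_open * (1 - f) / f
    values = np.zeros(L)
    pos = 0
    open_state = rng.random() < f
    while pos < L:
        mean = mean_open if open_state else mean_closed
        seg = int(rng.geometric(1.0 / mean))
        if open_state:
            values[pos : pos + seg] = 1.0
        pos += seg
        open_state = not open_state
    return AccessibilityTrack(spec.chrom, values, mode="binary")


def make_fixture(spec: SyntheticSpec, out_dir=None, pwm: PWM | None = None) -> Fixture:
    """Compose all generators into a complete synthetic data set.

    Generates genome + accessibility, plants motif instances, forward
    simulates the observed profile at (true_N, true_lambda) with additive
    Gaussian noise of sd ``noise_sd * peak``, and optionally writes the
    bundle as FASTA / JASPAR PWM / BED / bedGraph / truth JSON.
    """
    rng = np.random.default_rng(spec.seed)
    pwm = default_pwm() if pwm is None else pwm

    genome = generate_genome(spec, rng)
    acc = generate_accessibility(spec, rng=rng)
    genome, truth = plant_sites(
        genome,
        pwm,
        spec.n_planted_sites,
        strength_range=spec.site_strength_range,
        min_spacing=spec.min_spacing,
        rng=rng,
        accessibility=acc if spec.force_accessible_sites else None,
    )

    model = OccupancyModel(
        pwm=pwm,
        N=spec.true_N,
        lam=spec.true_lambda,
        ploidy=spec.ploidy,
        threshold_fraction=spec.threshold_fraction,
        threshold_mode=spec.threshold_mode,
        fragment_mean=spec.fragment_mean,
        fragment_sd=spec.fragment_sd,
        smooth_window=spec.smooth_window,
    ).fit({spec.chrom: genome}, {spec.chrom: acc})

    noiseless = model.predict()[spec.chrom]
    peak = float(noiseless.values.max())
    noise_abs = spec.noise_sd * peak
    if noise_abs > 0:
        noise_rng = np.random.default_rng(rng.integers(2**31))
        values = np.clip(
            noiseless.values + noise_rng.normal(0, noise_abs, len(noiseless)), 0, None
        )
    else:
        values = noiseless.values.copy()
    observed = ChIPProfile(chrom=spec.chrom, values=values, provenance="observed")

    truth = {
        **truth,
        "n_planted_sites": spec.n_planted_sites,
        "true_N": spec.true_N,
        "true_lambda": spec.true_lambda,
        "noise_sd_absolute": noise_abs,
        "noiseless_peak": peak,
        "score_threshold": model.score_threshold_,
        "seed": spec.seed,
        "spec": asdict(spec),
    }

    fixture = Fixture(
        spec=spec,
        genome=genome,
        pwm=pwm,
        accessibility=acc,
        observed=observed,
        noiseless=noiseless,
        truth=truth,
        model=model,
    )
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _write_fixture(fx: Fixture, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = fx.spec.chrom
    write_fasta({chrom: fx.genome}, out_dir / "genome.fa")
    write_pwm(default_pwm_counts(), out_dir / "motif.pwm", name=fx.pwm.name)
    v = fx.accessibility.values
    change = np.flatnonzero(np.diff(v)) + 1
    edges = np.concatenate(([0], change, [len(v)]))
    intervals = [
        (int(edges[i]), int(edges[i + 1]))
        for i in range(len(edges) - 1)
        if v[edges[i]] == 1.0
    ]
    write_bed({chrom: intervals}, out_dir / "accessibility.bed")
    write_bedgraph({chrom: fx.observed.values}, out_dir / "observed.bedGraph")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(fx.truth, fh, indent=1)
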