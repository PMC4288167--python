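# Methods

## The occupancy model

`tfocc` computes, for every candidate binding site *j*, the probability that
a TF molecule occupies it:

    P_j = N a_j e^{w_j/λ} / ( N a_j e^{w_j/λ} + L n ⟨ a_i e^{w_i/λ} ⟩_i )

This is the analytical limit of a statistical-thermodynamics treatment in
which N molecules are distributed over the L·n site slots of an n-ploid
genome of length L, each slot weighted by its Boltzmann factor
a·e^{w/λ}.  The assumptions inherited from that derivation:

- **Independent site slots.** No steric hindrance between overlapping
  windows, no cooperativity, no competition with other factors.  Both
  strands are scanned and kept as distinct sites; the model simply sums
  weights.
- **Binding energy proportional to PWM score.** E_j = w_j/λ, with λ a free
  scaling of the discrimination between strong and weak words.  λ > 1:
  the factor is less specific than its motif suggests; λ < 1: more.
- **Accessibility gates binding multiplicatively.** a_j is the probability
  that the chromatin at site j is open; a_j = 0 removes the site, a_j = 1
  is naked DNA.  Setting every a_j = 1 recovers the accessibility-free
  model.
- **Population averaging.** P_j is the fraction of nuclei in which site j
  is bound, which is what a ChIP experiment over millions of nuclei
  measures.  N is correspondingly an ensemble average and is accepted as a
  positive real.

Two consequences that the test suite checks analytically: in the
low-abundance regime (N·max weight ≪ L·n·⟨x⟩), Σ_j P_j → N over all slots
(molecule conservation) and P_j/N converges to the single-molecule
Boltzmann distribution; for large N, sites saturate in order of their
weights.

### Conventions

- PWM scores are log2 likelihood ratios (bits): score[b,i] =
  log2(f[b,i]/bg[b]) with f the pseudo-count-regularised frequencies.  The
  Boltzmann exponent is w/λ with w in bits, so λ is quoted in the same bits
  convention; changing the log base only rescales λ.
- The pseudo-count (default 1, per column) is split across bases in
  proportion to the background — 0.25 each under the uniform default.
- Coordinates are 0-based half-open internally; BED shares this convention,
  wiggle is converted at the boundary.
- Windows containing non-ACGT bases are masked: they are excluded from the
  site list (and contribute zero weight) but still count in the L·n slots of
  the partition-function divisor, because L is the physical genome length.
- The genomic average ⟨·⟩ is always computed over **all** scanned windows,
  never only the reported (filtered) ones: the partition function of the
  genome cannot depend on a reporting threshold.
- Site accessibility a_j is the mean of the per-base track over the m-bp
  window (the open fraction under a binary track).

## Relative-score site filter

Only sites whose PWM score clears a relative threshold are *reported* (and
placed into profiles).  Two forms are implemented:

- `absolute_range` (API default, the published form):
  w_j ≥ f·(max − min).
- `offset_from_min`: w_j ≥ min + f·(max − min).

The literal form compares a score to a score *range*: whenever the weakest
genomic window scores below −(1−f)/f times the strongest (for f = 0.7, below
−3/7·max), the threshold exceeds the maximum and *no* site survives.  For
log-odds PWMs scanned over real or random genomes the weakest windows score
far below zero, so the literal rule is degenerate in practice; the
min-anchored form is the operable reading and is what the synthetic pipeline
uses explicitly.  Both the threshold anchor (genome-wide score range) and
the chosen fraction travel with the `ScoredSites` object, which makes
filtering idempotent and consistent across chromosomes.

## From occupancy to a ChIP-like profile

A bound site is observed through random sequencing fragments.  Fragment
lengths follow a discretised Normal(mean 200 bp, sd 200 bp) truncated at
1 bp; a fragment of length ℓ covering the site is placed uniformly among
its ℓ covering placements, so the probability that it also covers a base at
distance d is max(0, ℓ−|d|)/ℓ — a unit-peak triangle.  The expected
coverage kernel is the pmf mixture of these triangles, computed once in
closed form per (mean, sd); its integral is exactly E[ℓ], so total profile
mass equals Σ_j P_j·E[ℓ] (checked to 1e-6; a Monte-Carlo sampling mode
exists purely as an oracle for this closed form).  The profile is the
kernel convolved with the impulse train of P_j at site midpoints (FFT
convolution for large site sets, direct placement for small ones — the two
paths agree to 1e-9 and are tested against each other), then smoothed with
a centred 250-bp moving average whose edge windows shrink.  Optional
observation noise is additive Gaussian, clipped at zero.  Sequencing depth
enters only as a global scale and is not modelled.

## Comparing profiles and inferring (N, λ)

Two metrics, computed over the analysed loci (below):

- **Pearson correlation ρ** of the per-base profiles.  Affine-invariant:
  it sees shape only, which makes it nearly flat along N but selective in
  λ (λ reshapes the relative heights of strong versus weak sites).
- **Normalized MSE over 1-kb bins.**  Both profiles are reduced to 1-kb
  bin means; the default normalization is the standard NMSE,
  mean((pred−obs)²)/mean(obs²).  This metric *keeps* the scale of the
  prediction, and that is deliberate: the predicted signal level saturates
  with N, so the error pins the abundance while being comparatively flat
  in λ.  A fully scale-free variant (each profile divided by its own mean,
  or by its maximum) is available via `normalization="mean" | "unit_max"`;
  note that with shape-only metrics ρ and MSE become nearly redundant and
  N is identifiable only through residual saturation curvature — the
  anisotropy between the two surfaces disappears.  When fitting real data
  whose units are arbitrary, the observed profile should be brought to a
  defined scale first (the N estimate then absorbs that choice).

**Analysed loci.**  Profile comparisons are restricted to the loci where
binding is possible and signal is present: accessible segments dilated by
500 bp (fragment spill-over) whose mean observed signal exceeds the
genome-wide background B (the mean observed signal over all dilated
accessible segments).  Deserts with neither accessibility nor signal carry
no information about (N, λ) and only dilute both metrics; restricting to
strong loci mirrors comparing per-locus profiles at bound loci.  The locus
rule is exposed (`metric_loci="auto" | None | explicit intervals`), falls
back to all accessible segments if nothing passes, and to genome-wide
metrics when no accessibility is supplied.

**Grid search and selection.**  The default grids are N ∈ {1, 10, 100,
500, 1000, 2000, 5000, 10⁴, 2·10⁴, 5·10⁴, 10⁵, 10⁶} and λ = 0.25…5 in
steps of 0.25.  The genomic Boltzmann average is recomputed once per λ
(it is N-independent) and cached.  The optimum is the minimum-MSE cell
inside the intersection of the two best-12% bands (MSE ≤ min + 0.12·range;
ρ ≥ max − 0.12·range); if the bands do not intersect, the global
minimum-MSE cell is returned with a `fallback` flag.  Ties break toward
the smallest N, then the smallest λ (parsimony, determinism).  An all-equal
grid returns the first cell with a `degenerate` flag.

**Genome-wide scan.**  For whole-genome evaluation the genome is tiled
into 20-kb regions, regions without any accessible base are dropped, and
each region is scored by ρ and MSE and flagged by whether its mean observed
signal strictly exceeds background_mult·B (B = mean observed signal over
all retained regions; multipliers 1.0 and 0.5 correspond to strong- and
weak-binding region sets).  Region-set metric distributions can be compared
with the two-sample Kolmogorov–Smirnov test (asymptotic p; flagged
unreliable below 10 observations per sample).

## The synthetic data generator

The generator emulates exactly the statistical structure the model assumes,
so that every pipeline stage is testable without external data:

- i.i.d. background genome at a configurable GC content (default 0.5,
  200 kb);
- 50 planted motif instances at strengths drawn from the top score
  quantiles (default 0.85–1.0 of the score span), non-overlapping, random
  strand, optionally restricted to accessible chromatin (sites planted in
  closed chromatin are invisible to the model by construction, so recovery
  experiments use `force_accessible_sites=True`);
- binary block accessibility: alternating open/closed segments with
  geometric lengths (open mean 1 kb, closed mean set so the open fraction
  is 15%, the scale of FDR-thresholded DNase accessibility calls);
- an "observed" profile forward-simulated at true_N = 5000,
  true_λ = 1.5 with additive Gaussian noise of sd = 10% of the noise-free
  peak, clipped at zero.

A single integer seed fixes every artifact byte-for-byte; the truth table
records positions, strands, realised scores and all latent parameters.

**Why the default motif is weak.**  The bundled 7-bp motif
(consensus TGACTCA, 49/17/17/17 counts, ≈1.3 bits) is much less informative
than a real TF motif, and deliberately so.  Two regimes must coexist at the
fixture scale: (i) the partition function must be dominated by genomic
background mass — with ~60,000 accessible windows of mean weight ≈1 against
50 planted sites of weight ≤ e^{6.75/1.5} ≈ 90, Σx² /(Σx)² stays small
enough that the molecule-conservation limit Σ P_j ≈ N holds to ~0.1% at
N = 10; and (ii) planted sites must sit in the mid-saturation range at
N* = 5000 (P between ~0.3 and ~0.8), where profile shape and scale respond
to both N and λ, keeping the parameters identifiable.  A
high-information-content motif at this genome size would concentrate the
partition function on a handful of sites, breaking (i), and pin P ≈ 1 at
every strong site, weakening (ii).  Real genomes buy these regimes with
length (megabases of background); the fixture buys them with motif softness.

**What the generator does not emulate:** read-level sampling noise (the
noise model is per-base Gaussian, not Poisson counts), GC or mappability
bias, PCR duplication, correlated biological replicates, cooperative or
competitive binding, and continuous accessibility structure (the default
track is binary).  Passing tests therefore demonstrate the correctness of
the model arithmetic and the behaviour of the inference under the model's
own assumptions — not robustness to the systematic biases of real ChIP-seq
data.

## Numerical choices and degenerate inputs

- Boltzmann weights are evaluated in float64; with bit-scores bounded by
  the PWM score range, e^{w/λ} stays far from overflow for λ ≥ 0.25.
- The expected-coverage kernel is cached per (mean, sd); the Boltzmann
  average per λ.  Cached and fresh computations are tested for equality.
- An all-inaccessible genome makes the model undefined (zero partition
  function) and raises; an all-zero or zero-variance observed profile is
  rejected before the grid sweep; an empty filtered-site set raises with a
  pointer to the threshold-mode degeneracy.
- Zero-count PWM columns are only admissible with a positive pseudo-count;
  with pseudo-count 0 a zero *entry* yields a −inf score (never selected as
  a maximum) and a zero *column* is rejected.
- Read-density → accessibility uses a Hill curve (logistic in log-density)
  with exposed midpoint (default: median positive density) and exponent
  (default 2) — a documented stand-in for a calibrated map; zero density
  maps to zero.

## Known limitations

- N and λ trade off along a ridge: a smaller N at sharper λ mimics a
  larger, less specific factor.  Under the default noise conditions the
  grid resolves this, but with flat-shape metrics, very weak motifs or
  abundances below the saturation onset (N ≲ 100 here), abundance is not
  identifiable from profile shape alone.
- The N estimate from NMSE inherits the scale convention of the observed
  profile; for real data it is an order-of-magnitude estimate.
- The literal relative-threshold rule is preserved for fidelity but is
  degenerate on realistic score distributions (see above).
- Single-TF model: no cooperativity, no competition, no co-factor effects.
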