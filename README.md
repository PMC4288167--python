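# tfocc — TF occupancy from statistical thermodynamics

`tfocc` models genome-wide transcription-factor (TF) occupancy with an
analytical statistical-thermodynamics formula and, given an observed
ChIP-seq-like binding profile, infers the two parameters that are usually
unknown: the number of DNA-bound molecules *N* and the binding specificity
factor *λ*.  It is aimed at regulatory genomicists who want occupancy
predictions beyond naive PWM scanning — including chromatin accessibility,
molecule-number saturation and genome-wide competition between sites —
without paying the cost of an explicit configuration-enumerating
thermodynamic simulation.

## The model

Each m-bp window *j* of the genome (both strands) is a candidate site with a
PWM log-likelihood-ratio score *w<sub>j</sub>* (log2, bits) and an
accessibility *a<sub>j</sub>* ∈ [0, 1].  The probability that site *j* is
occupied in a nucleus with *N* DNA-bound molecules is

```
            N · a_j · exp(w_j / λ)
P_j  =  ─────────────────────────────────────────
        N · a_j · exp(w_j / λ)  +  L · n · ⟨ a_i · exp(w_i / λ) ⟩_i
```

where *L* is the genome length, *n* the ploidy and ⟨·⟩<sub>i</sub> the mean
statistical weight over all genomic site slots — the competition term of the
partition function.  λ scales the discrimination between strong and weak
words: λ > 1 means the factor distinguishes sequences less sharply than its
PWM suggests.  In the low-abundance limit Σ<sub>j</sub> P<sub>j</sub> → N
(molecules are conserved); as N grows, strong sites saturate first.

Site probabilities are turned into an artificial ChIP-seq profile by
convolving them with the expected-coverage kernel of random sequencing
fragments (length ~ Normal(200, 200) bp truncated at 1 bp, placed uniformly
among placements covering the site) and smoothing over 250 bp.  Fitting an
observed profile is a grid search over N ∈ [1, 10⁶] and λ ∈ [0.25, 5]
scoring every cell with two complementary metrics: the Pearson correlation ρ
(shape; flat along N, selective in λ) and the normalized mean squared error
over 1-kb bins (scale and saturation; selective in N).  The reported optimum
is the minimum-MSE cell inside the intersection of the best-12% bands of the
two surfaces.

## Worked example

Everything below is synthetic and self-contained — the package ships a
generator that builds a random genome with planted motif instances, a
block-structured accessibility track, and a forward-simulated noisy
"observed" profile at known parameters:

```python
from tfocc import SyntheticSpec, make_fixture, ProfileGridSearch, information_content

spec = SyntheticSpec(seed=1)          # 200 kb, 50 planted sites, N*=5000, lambda*=1.5
fx = make_fixture(spec)
print(f"motif information content: {information_content(fx.pwm):.2f} bits")

est = ProfileGridSearch(pwm=fx.pwm, threshold_mode=spec.threshold_mode,
                        ploidy=spec.ploidy)
est.fit({spec.chrom: fx.genome}, {spec.chrom: fx.observed},
        accessibility={spec.chrom: fx.accessibility})
r = est.result_
print(f"N_opt = {est.N_opt_:g}  lambda_opt = {est.lambda_opt_:g}")
print(f"rho at optimum = {r.rho_at_opt:.3f}  MSE at optimum = {r.mse_at_opt:.5f}")
```

prints

```
motif information content: 1.32 bits
N_opt = 5000  lambda_opt = 1.5
rho at optimum = 0.943  MSE at optimum = 0.00100
```

i.e. with noise at 10% of the profile peak, the grid search recovers the
molecule number and specificity the profile was generated with, exactly on
the grid; the correlation of 0.94 against the noisy observation is the noise
ceiling, and the near-zero normalized MSE says the fitted profile also
matches the observation in scale.

The same pipeline is scriptable from the shell:

```
tfocc synth --out demo --seed 5 --genome-length 30000
tfocc pwm-info --pwm demo/motif.pwm
tfocc predict  --fasta demo/genome.fa --pwm demo/motif.pwm --acc demo/accessibility.bed \
               --N 5000 --lambda 1.5 --threshold-mode offset_from_min --out demo/sites.bed
tfocc simulate --fasta demo/genome.fa --pwm demo/motif.pwm --acc demo/accessibility.bed \
               --N 5000 --lambda 1.5 --threshold-mode offset_from_min --noise-sd 0 \
               --out demo/sim.bedGraph
tfocc fit      --obs demo/observed.bedGraph --fasta demo/genome.fa --pwm demo/motif.pwm \
               --acc demo/accessibility.bed --out demo/fit.json
tfocc genome-scan --obs demo/observed.bedGraph --pred demo/sim.bedGraph \
               --fasta demo/genome.fa --acc demo/accessibility.bed \
               --region-size 10000 --out demo/regions.tsv
```

Formats: FASTA genomes, JASPAR-style count matrices, BED accessibility
(binary) or bedGraph/wig read density (continuous), bedGraph/wig profiles,
YAML configuration.  See `docs/methods.md` for the model assumptions,
parameter meanings and numerical choices.

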