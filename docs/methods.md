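# Methods

## Model

Gene-level ASE data for one sample are reference/total allelic read counts
(r_i, t_i) over genes i. The package models

    r_i ~ Binomial(t_i, λ_i),     logit(λ_i) ~ Normal(μ, σ),

the binomial logit-normal (BLN) compound distribution. μ (log allelic fold
change units) absorbs sample-wide reference bias; σ is the extra-binomial
standard deviation of allelic imbalance across genes and is the per-sample
quality score once fitted. The model is deliberately exchangeable across
genes: no per-gene λ is estimated, and gene identity only matters upstream,
when variant-level data are collapsed to one most-expressed heterozygous SNP
per gene.

Each observation's pmf is a two-component mixture

    P(r | t) = (1 − ε)·BLN(r; t, μ, σ) + ε·1/(t + 1),

where the second term is the *discrete* uniform on {0, …, t}. Its role is
purely numerical: a handful of extreme-imbalance, high-depth genes would
otherwise drive individual log pmf terms toward −∞ and destabilize the fit.
ε defaults to 10⁻³ and is not estimated. We read "uniform on (0, t)" as the
discrete uniform because it mixes with a discrete pmf; a continuous density
would not form a proper mixture on the same support.

### Assumptions

- Counts are gene-level, one record per gene, statistically independent
  across genes given (μ, σ). Correlated genes (co-regulation, imprinting
  clusters) mildly violate this but mainly affect standard errors, which the
  method does not use.
- λ is integrated out, so within-gene biological signal and technical noise
  are not distinguished; the score is a *sample-level* summary only.
- Samples are independent; the cohort enters only through the threshold.

## Likelihood evaluation

The BLN pmf has no closed form; it is the integral of a binomial likelihood
against a normal density on the logit scale. We evaluate it with fixed-order
Gauss–Hermite quadrature (61 nodes by default, configurable) **recentred on
the integrand**: the log-integrand is strictly concave, so its mode is found
by a damped Newton iteration (derivative is monotone; ~10 iterations to
machine precision) and the quadrature grid is placed at the mode with scale
set by the local curvature. This Laplace-adapted placement matters: a rule
standardized to the latent prior alone collapses when the binomial factor is
far narrower than the prior (t in the thousands) or vice versa (σ → 0).
All accumulation is in log space (log-sum-exp; binomial coefficients via
log-gamma). Against an independent adaptive-quadrature oracle the absolute
log-pmf error stays below 10⁻⁹ across a stress grid up to t = 5000, σ = 3
(the test suite asserts 10⁻⁶).

Repeated (r, t) pairs are collapsed with multiplicity weights before
evaluating the likelihood, which cuts the per-iteration cost several-fold at
typical sequencing depths.

## Fitting

Per sample, genes with total counts in [5, 5000] — both bounds inclusive —
enter the likelihood; (μ, σ) minimize the negative mixture log-likelihood by
L-BFGS-B within μ ∈ [−5, 5], σ ∈ [10⁻³, 5]. Initialization: μ₀ is the logit
of the continuity-corrected aggregate reference ratio (Σr + ½)/(Σt + 1);
σ₀ = 0.5. On optimizer failure up to 5 restarts perturb the start point,
with perturbations drawn from a generator seeded by a CRC-32 hash of the
sample id — fits are therefore bit-reproducible regardless of scheduling,
which the test suite checks by comparing single-threaded and multi-threaded
pipeline output bytes. Samples with fewer than `min_genes` (default 50)
usable genes are reported as `insufficient_data` rather than fitted: a
dispersion estimate from a handful of genes is noise, and silently emitting
one would poison the cohort threshold. Duplicate gene ids within a sample
are rejected at the model layer; deduplication belongs to aggregation.

## Cohort thresholding

The per-sample scores σ̂ are summarized with a skew-adjusted boxplot.
The medcouple MC — the median of the kernel
h(x_i, x_j) = ((x_j − m) − (m − x_i))/(x_j − x_i) over all pairs
x_i ≤ m ≤ x_j, with the standard sign kernel on pairs tied with the median —
is computed by the O(n²) all-pairs formula (cohorts are at most tens of
thousands of samples; the O(n log n) algorithm is not needed). Quartiles use
linear interpolation (type 7). Fences follow Hubert–Vandervieren:

    MC ≥ 0:  [q1 − 1.5·e^(−4·MC)·IQR,  q3 + 1.5·e^(+3·MC)·IQR]
    MC < 0:  [q1 − 1.5·e^(−3·MC)·IQR,  q3 + 1.5·e^(+4·MC)·IQR]

σ_t is the **upper fence** itself, not the largest observation inside it.
Under the strict rule "fail iff σ̂ > σ_t" the two conventions flag exactly
the same samples, and the fence has the advantage of not depending on which
data point happens to sit just inside it. Only the upper fence is used: low
dispersion is not a failure mode. Non-converged fits are excluded from fence
estimation and flagged fail with an annotation — including them would let a
broken fit inflate the threshold that judges everyone else. Cohorts with
fewer than three converged fits are an error. Per-tissue thresholds are
obtained by running the pipeline once per tissue; the tool does not
stratify internally.

## Synthetic cohorts

The generator draws per-gene depths (uniform [20, 200] by default, or
rounded log-normal clipped to [5, 5000]), latent ratios logit(λ) ~
N(μ, σ) with defaults μ = 0.1 (mild reference bias) and σ = 0.3, and
r ~ Binomial(t, p). Genotype-mismatch contamination at fraction c replaces
the expected ratio with p = (1 − c)·λ + c·λ_cont, where the contaminator at
each of the sample's het sites is hom-ref (λ_cont = 1), het (λ_cont = a
fresh logit-normal draw), or hom-alt (λ_cont = 0) with Hardy–Weinberg
probabilities (¼, ½, ¼) at allele frequency 0.5. The canonical dose design
is the quadratic 21-level ladder (k/20)², k = 0..20. Randomness uses one
master seed with per-sample substreams keyed by (level, replicate), so
enlarging a cohort never changes existing samples.

What this emulates: the count-level signature of RNA reads originating from
a different individual than the genotypes used for ASE extraction — shifted
and more dispersed allelic ratios at sites where the contaminator's genotype
differs. What it does not emulate: read-level effects (mapping, duplicates,
blacklisted regions), a specific contaminator individual with fixed
genotypes and its own expression levels, haplotype-level aggregation, or the
heavy-tailed imbalance of real transcriptomes (imprinting, nonsense-mediated
decay). Passing tests on these cohorts therefore demonstrate estimator
correctness and detection of expectation-shifting contamination, not
robustness to every real-data pathology.

### A known non-monotonicity at very low contamination

Under expectation mixing, the hom-contaminator shift of a gene's logit ratio
is approximately ±c/λ (resp. c/(1−λ)), which is anti-correlated with
logit(λ): low-ratio genes are pushed up hardest. To first order in c this
*compresses* the latent spread (dVar/dc ≈ −σ² at c = 0), while the
inflation from hom-ref/hom-alt group separation grows as c². Mean σ̂ along
the contamination ladder consequently dips by ~10⁻³ before rising steeply
(crossover near c ≈ 0.05 at σ = 0.3); the dose-response is strongly
monotone from a few percent contamination upward but not at the 0.25–2%
levels. This is a property of the generative abstraction, not of the
estimator: the test suite carries a rank-correlation check across the full
low-contamination ladder that documents exactly this behaviour. In
practice it means count-level simulation understates (and slightly
inverts) sensitivity below ~2% contamination; detection of the strong
contamination the method is deployed against (the end-to-end test flags
25%-contaminated samples with zero false positives in 50 clean samples) is
unaffected.

## Parameters that matter

| Parameter | Default | Units / meaning |
| --- | --- | --- |
| `min_total`, `max_total` | 5, 5000 | inclusive total-count gene filter |
| `epsilon` | 10⁻³ | uniform mixture weight (numerical guard) |
| `mu_bounds` | [−5, 5] | log allelic fold change |
| `sigma_bounds` | [10⁻³, 5] | score search range; lower bound > 0 |
| `n_quadrature_nodes` | 61 | Gauss–Hermite order |
| `min_genes` | 50 | minimum genes for a reportable fit |
| `max_restarts` | 5 | deterministic perturbed restarts |
| `tolerance` | 10⁻⁹ | L-BFGS-B relative objective tolerance |

Simulation defaults: 5000 genes/sample, μ = 0.1, σ = 0.3, depths uniform
[20, 200] (so the default filter drops nothing and the generative and
fitted gene sets coincide), contaminator genotype probabilities (¼, ½, ¼).

## Problem sizes used in checks

The calibration checks fit 50 replicate samples at 5000 genes (bias of σ̂
under 0.02; RMSE ≈ 0.004) and 50 at 500 genes (RMSE larger, confirming
n-scaling); the dose-response uses 5 replicates per level at 5000 genes;
the end-to-end detection cohort is 50 clean + 3 contaminated samples. The
acceptance script uses 20 calibration replicates, 3 replicates per level at
3000 genes, and a 53-sample detection cohort at 2000 genes.

## Limitations

- Cohort-based by construction: no meaningful threshold for n < 3, and
  thresholds are relative to the cohort's own score distribution.
- μ̂ summarizes reference bias; it is not corrected for, and gene-level
  outlier testing is out of scope.
- The O(n²) medcouple is quadratic in cohort size; fine up to ~10⁴ samples.
- ε = 0 is accepted but unsupported: with extreme genes the likelihood can
  become arbitrarily ill-conditioned even though log-space evaluation keeps
  it finite (the CLI stress test covers one such case).
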