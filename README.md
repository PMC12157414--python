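# aseqc

Sample-level quality control for allele-specific expression (ASE) data.

ASE measures allelic imbalance at heterozygous sites in RNA-seq and is a
sensitive readout of cis-regulatory variation — and, unfortunately, of
technical trouble: genotype/RNA mismatches, low-level contamination, library
and batch artifacts all inflate allelic noise across the whole transcriptome
without necessarily tripping conventional DNA- or RNA-seq QC. `aseqc` gives
cohort analysts (eQTL/sQTL mappers, rare-disease transcriptomics pipelines)
a single per-sample score for that inflation and a principled cohort
threshold for excluding aberrant samples.

## The model

For gene *i* in sample *j*, with reference count r_ij out of t_ij total
allelic reads, the counts follow a binomial logit-normal (BLN) distribution:

    r_ij ~ Binomial(t_ij, λ_ij),        logit(λ_ij) ~ Normal(μ_j, σ_j)

μ_j is the sample's mean log allelic fold change (mostly reference bias);
σ_j is the extra-binomial spread of allelic imbalance across genes — the
quantity that technical noise inflates. For numerical robustness against
extreme high-depth genes, each observation is modelled as a mixture with a
small discrete-uniform component (weight ε = 10⁻³ by default):

    P(r | t) = (1 − ε) · BLN(r; t, μ, σ) + ε / (t + 1)

Per sample, genes with 5 ≤ t ≤ 5000 enter the likelihood and (μ̂_j, σ̂_j)
are obtained by bounded L-BFGS-B maximum likelihood; σ̂_j is the sample's
quality score. Across the cohort, a medcouple-adjusted (skew-aware) boxplot
of the scores yields the threshold σ_t — its upper fence — and samples with
σ̂ > σ_t fail QC.

## Worked example

```python
from aseqc import SimulationConfig, simulate_sample, fit_cohort, qc_cohort
import pandas as pd

clean = SimulationConfig(n_genes=2000, mu=0.1, sigma=0.3, seed=7)
dirty = SimulationConfig(n_genes=2000, mu=0.1, sigma=0.3, seed=7, contamination=0.25)
frames = [simulate_sample(clean, f"clean{k}", stream=(0, k)) for k in range(6)]
frames.append(simulate_sample(dirty, "contam0", stream=(1, 0)))
records = pd.concat(frames, ignore_index=True)

statuses = fit_cohort(records)
result = qc_cohort([s.fit for s in statuses])
print(f"sigma_t = {result.sigma_t:.4f}  (medcouple = {result.medcouple:.3f})")
for fit in result.fits:
    print(f"{fit.sample_id}  mu={fit.mu_hat:+.3f}  sigma={fit.sigma_hat:.4f}  "
          f"{result.flags[fit.sample_id]}")
```

Output:

```
sigma_t = 0.3232  (medcouple = -0.028)
clean0  mu=+0.102  sigma=0.3026  pass
clean1  mu=+0.094  sigma=0.2918  pass
clean2  mu=+0.113  sigma=0.3112  pass
clean3  mu=+0.089  sigma=0.2969  pass
clean4  mu=+0.098  sigma=0.3029  pass
clean5  mu=+0.085  sigma=0.2931  pass
contam0  mu=+0.072  sigma=0.4326  fail
```

The six clean samples (generated at σ = 0.3) recover σ̂ ≈ 0.29–0.31 and
μ̂ ≈ 0.1 (the injected reference bias). The sample with 25% simulated
genotype-mismatch contamination shows σ̂ = 0.43, well above the cohort fence
σ_t = 0.32, and is flagged.

The same pipeline is available from the shell:

```bash
aseqc simulate --n-samples 5 --levels 0,0.25 --n-genes 2000 --seed 7 --out-prefix cohort
aseqc qc cohort.counts.tsv --out-prefix run        # run.samples.tsv, run.summary.json
aseqc fit cohort.counts.tsv -o fits.tsv            # scores only, no thresholding
aseqc aggregate counts.phaser.tsv --map genes.tsv -o gene_level.tsv
```

Estimator classes are also exposed sklearn-style: `BLNMixture().fit(X)` on an
`(n_genes, 2)` array of `[ref_count, total_count]` (fitted `mu_`, `sigma_`),
and `AdjustedBoxplotDetector().fit(scores)` for the fence rule
(`predict` → ±1).

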