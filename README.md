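# seqherit

Variance-component analysis of deregressed proofs (DRP) across minor-allele-
frequency (MAF) and linkage-disequilibrium (LD) classes of genome-wide
variants — the GREML-MS / GREML-LDMS family of analyses used to ask how much
of the genetic variance of dairy-cattle traits is carried by rare,
low-frequency and common variants, and how sequence variants compare with
SNP-array markers and plain pedigree relationships.

It is written for quantitative geneticists who want a self-contained,
scriptable implementation of this analysis: every stage — QC, stratification,
relationship-matrix construction, restricted maximum likelihood, reporting —
is a plain Python function, and a synthetic cattle-like data generator makes
the whole pipeline testable end to end without any external data.

## The model

DRP are modelled with an intercept and one random genetic effect per variant
class:

    y = 1μ + Σᵢ gᵢ + e,   gᵢ ~ N(0, Gᵢ σᵢ²),   e ~ N(0, I σₑ²)

where the classes are seven MAF bins (0.001–0.01, 0.01–0.05, 0.05–0.1,
0.1–0.2, 0.2–0.3, 0.3–0.4, 0.4–0.5), optionally crossed with 3 or 4 LD
groups formed from 20-Mb LD scores (21 or 28 components).  Variance
components are estimated by average-information REML with EM fallback, and
the proportion of DRP variance explained by class *i* is

    σ̂ᵢ² / (Σᵢ σ̂ᵢ² + σ̂ₑ²),

with delta-method standard errors from the full estimate covariance.

Relationship matrices:

* **VanRaden method 1** — `G = (X − 2p1′)(X − 2p1′)′ / 2Σ pⱼ(1−pⱼ)`,
  comparable to the pedigree numerator matrix **A** (tabular method).
* **α-scaled family** — columns weighted by `(2fⱼ(1−fⱼ))^(α/2)`; α = −1 is
  the variant-standardized GRM (VanRaden method 2, the GCTA convention,
  used for the per-class matrices), α = 0 recovers method 1 up to a global
  rescale.
* Pedigree-based variances are put on the genomic base with the
  `σ² × (mean diag K − mean K̄)` comparison rule before proportions are
  compared across models (REML-PED, REML-GRM, REML-PEDGRM), which are ranked
  by AIC.

Expected per-class shares under the two GRM scalings
(`Σ_class 2p(1−p) / Σ_all 2p(1−p)` vs `N_class/N`) are reported next to the
estimates, and single-variant shares (squared dosage–DRP correlation) cover
the major-gene case.

## Worked example

```python
import seqherit as sh

sim = sh.SimulationConfig(n_individuals=500, n_variants=3000, n_chromosomes=3,
                          founder_pool_size=80, seed=42)
g = sh.simulate_genotypes(sim)
g, qc = sh.qc_filter(g)

partition = sh.assign_maf_classes(sh.compute_maf(g))
arch = sh.ArchitectureConfig(n_causal=300, target_h2=0.6,
                             reliability_distribution=(0.85, 0.95), seed=43)
phenotypes, truth = sh.simulate_phenotypes(g, arch)
fit = sh.fit_model(phenotypes, "greml-ms", genotypes=g, partition=partition)
print(fit.to_frame().round(4).to_string(index=False))
```

prints

```
 component  sigma2     se  proportion  proportion_se  at_boundary
0.001-0.01  0.0433 0.0326      0.0667         0.0499        False
 0.01-0.05  0.0146 0.0355      0.0224         0.0546        False
  0.05-0.1  0.1474 0.0325      0.2268         0.0457        False
   0.1-0.2  0.1304 0.0315      0.2006         0.0456        False
   0.2-0.3  0.0987 0.0271      0.1518         0.0391        False
   0.3-0.4  0.1425 0.0316      0.2193         0.0426        False
   0.4-0.5  0.0516 0.0190      0.0794         0.0283        False
  residual  0.0214 0.0431         NaN            NaN        False
```

Each row is one MAF class: `sigma2` is its REML variance component,
`proportion` its share of the total DRP variance.  The total explained here
is 0.967 (SE 0.067) — with per-animal reliabilities drawn in (0.85, 0.95)
the deregression noise is small, so nearly all DRP variance is genetic, and
the common classes dominate because most heterozygosity sits there.
Aggregating (`sh.aggregate_contributions(fit, partition, mafs)`) gives
relative contributions rare 0.069, low-frequency 0.023, common 0.908.

The same analysis runs from the shell:

```
seqherit simulate --n-individuals 500 --n-variants 3000 --seed 42 --out-prefix demo
seqherit qc demo.vcf --out-vcf demo.qc.vcf --report-path demo.qc.tsv
seqherit reml --model greml-ms --genotypes demo.qc.vcf --phenotypes demo.pheno.tsv --out demo.fit.tsv
```

or end to end from a YAML config with `seqherit run config.yaml --out-dir out/`
(see `seqherit.report.run_pipeline` for the schema).

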