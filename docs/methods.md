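# Methods

## Model and estimation

All analyses fit the linear mixed model `y = 1μ + Σ_k g_k + e` on deregressed
proofs (DRP), with one record per individual, an intercept as the only fixed
effect, `g_k ~ N(0, K_k σ_k²)` for relationship matrices `K_k`, and
`e ~ N(0, I σ_e²)`.  The restricted log-likelihood (constants dropped) is
`−½[log|V| + log(1′V⁻¹1) + y′Py]` with `V = Σ_k σ_k² K_k + σ_e² I` and
`P = V⁻¹ − V⁻¹1(1′V⁻¹1)⁻¹1′V⁻¹`.

Optimization is stabilized average-information (AI) REML:

* gradient `½[y′PK_iPy − tr(PK_i)]`, AI matrix `½ y′PK_iPK_jPy`;
* EM updates (`σ² ← σ² + σ⁴(y′PKPy − tr(PK))/n`) for the first two
  iterations; afterwards AI steps with step halving, accepted only if the
  likelihood does not decrease, so the iteration sequence is monotone;
* a lower floor of `1e-8 × var(y)` per component.  Components pinned at the
  floor with a downhill gradient are dropped from the AI solve (active set)
  — without this, a single null component stalls the whole fit in slow EM
  creep;
* convergence when the likelihood changes by < 1e-8 (max 200 iterations);
  unconverged fits are returned flagged, never discarded;
* standard errors from the inverse AI matrix at the optimum; proportions of
  DRP variance `σ̂_i²/Σσ̂²` carry delta-method SEs using the full estimate
  covariance (the cross-covariances matter: per-class proportions are
  strongly negatively correlated under LD);
* if `V` is numerically singular a 1e-8 diagonal jitter is applied and
  logged.

AIC is `2k − 2 logL` with `k` the number of variance components not pinned
at the floor; the intercept is profiled out by REML and not counted.  In the
model-comparison table AIC is also expressed as the difference from the
pedigree-only model when present.

DRP reliabilities are read, validated and stored but never used as residual
weights; a weighted mode is deliberately absent so that results are
comparable with the common practice of fitting unweighted DRP.

## Variant stratification

MAF classes use lower-inclusive, upper-exclusive intervals with the last
class closed at 0.5; the defaults are the seven bins
0.001–0.01, …, 0.4–0.5.  A MAF below the first bound is treated as a QC
contract violation, not binned.

The LD score of a variant is the sum of r² with every *other* variant within
±10 Mb on the same chromosome ("20-Mb region centered on the SNP" read
literally; the self-term is excluded, although some of the literature
includes it).  r² is the squared Pearson correlation of mean-imputed
dosages; scores accumulate neighbours in ascending position order with plain
sequential summation so that an all-pairs double loop reproduces them
exactly — this makes the windowing logic testable against a brute-force
oracle at the bit level.

Chromosomes are cut into consecutive segments of
`s = round(2 m_chr / n_windows)` variants, where `n_windows` is the
chromosome span (max − min position) in 100-kb windows, minimum 1 — i.e.
twice the average number of variants per 100-kb window; the span definition
is ours, since only the windowing rule itself is standard.  Within each MAF
class, variants ranked by segment-mean LD score (ties broken by chromosome
and position, stable sort) are cut into 3 or 4 contiguous equal groups;
remainders go to the low-LD end; classes smaller than the group count keep a
single group with a logged warning.

## Relationship matrices

* VanRaden method 1: centered cross-product over `2Σf(1−f)`, frequencies
  recomputed from the analyzed sample by default (externally supplied
  frequencies are accepted).  Missing dosages are mean-imputed per variant
  inside matrix construction only, never persisted.
* α-family: `W_j = (X_j − 2f_j)(2f_j(1−f_j))^(α/2)`, `G = WW′/m`.  α = −1
  (every variant standardized — VanRaden method 2) is used for the
  per-class GRMs of the MAF/LD-stratified fits, matching the convention of
  the standard GREML software; α = 0 equals method 1 after rescaling by
  `m / 2Σf(1−f)`, which the tests verify elementwise.
* Pedigree A by the tabular method; pedigrees are topologically sorted on
  construction and cycles rejected.
* Base rescaling: a variance estimated under K is expressed in the base of
  the analyzed population as `σ² (mean diag K − mean K̄)`.  This is one
  published comparison rule among several; it is applied to pedigree
  components in the model-comparison table so pedigree-based and genomic
  variances are on one footing (a VanRaden-1 GRM with sample frequencies is
  already essentially in the sample base; the factor is ≈ 1).

## Synthetic data

The generator emulates the salient features of imputed cattle data at desk
scale, not a coalescent model:

* **MAF spectrum** — uniform, beta, or neutral (density ∝ 1/x on
  [0.001, 0.5]); target frequencies drive Bernoulli draws for a founder
  haplotype pool, with fixed columns redrawn so every variant is polymorphic
  in the pool.
* **LD** — individual haplotypes copy founder templates with Poisson switch
  points (`switch_rate` per bp).  A small pool with few switches produces
  the strong long-range LD and family structure typical of intensively
  selected dairy cattle; the defaults (pool 100, switch rate 1e-7, five
  100-Mb chromosomes) give per-variant LD scores far above human levels at
  the simulated marker density, though absolute cattle sequence-density
  scores (often > 1000) are only reached at far higher variant counts than
  are sensible here.
* **Pedigrees** — random pair matings per generation, fixed offspring per
  mating; gene dropping transmits one recombinant gamete per parent
  (Poisson crossovers, 1e-8 /bp default ≈ 1 cM/Mb), so descendants are
  Mendelian-consistent by construction.
* **Phenotypes** — causal effects drawn with variance ∝ `(2p(1−p))^α`
  (α = 0, the animal-genetics convention, by default) and rescaled against
  the realized genotypes; DRP = TBV + ε with
  `var(ε_i) = var(TBV)(1−r_i)/r_i` for reliability `r_i` — the standard
  deregression-error variance.  An optional pedigree-structured polygenic
  term (sampled through the Cholesky factor of A) and an optional planted
  major locus (a variant at a requested MAF carrying a fixed fraction of the
  genetic variance) cover the joint pedigree+genomic and major-gene cases.
  A dosage-noise knob emulating imputation error exists but is off by
  default — imputation error mainly attenuates rare-variant variance, and
  modelling it well would need a per-variant accuracy model we do not have.

Requested `per_class_variance_fractions` are target shares of the *DRP*
variance.  Under the deregression-noise model the total explained equals the
harmonic mean of the reliabilities, so the summed fractions are realized
exactly as the total explained only when the reliability is constant and
equal to that sum; the packaged seven-class recovery study therefore runs at
constant reliability 0.6 with fractions summing to 0.6.  Truth for recovery
tests is always computed from realized quantities (realized per-class
variances over the realized total), so heterogeneous-reliability settings
remain testable.

What passing tests on these data do *not* show: robustness to imputation
error, to selection-induced allele-frequency change, to non-random mating by
trait, or to the much larger LD scores of real sequence-density cattle data.
Sample sizes here (hundreds to 1000) give per-class SEs comparable in
relative terms to a real ~5000-bull study; both settings share the
qualitative conclusion that per-class estimates carry large SEs when LD
couples the classes.

## Study conditions packaged with the acceptance script

Problem sizes were chosen as the smallest that leave the statistical checks
well-posed: recovery study n = 1000 × 7000 variants (7 classes, ~100 causal
per class); model comparison 20 replicates of a 100-founder, 4-generation
pedigree (n = 500, 1200 variants, marker-tagged variance 0.35, pedigree-only
polygenic 0.25, reliability 0.90, SNP-array-like subset of ≤ 400 common
variants for the single-GRM models); oracle checks at n = 60–500.  The
planted-locus share is reported as the mean over five effect draws at fixed
genotypes to reduce draw-to-draw LD noise.

## Known limitations

* The AI-matrix SEs are asymptotic; near boundaries they understate
  uncertainty (the parametric-bootstrap test tolerates 25% disagreement).
* Only biallelic variants are handled; multi-allelic VCF records are
  rejected rather than split.
* The PLINK writer stores hard calls — fractional dosages survive only the
  VCF route (DS field, float32 precision).
* Pipeline config validation is by explicit checks, not a schema engine;
  unknown keys and invalid values are rejected with named errors.
* `run_pipeline` fits all requested models on one trait at a time;
  multi-trait REML, residual weighting and BLUP prediction are out of scope.
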