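"""Cattle-like synthetic genotypes, pedigrees and deregressed-proof phenotypes.

Every stage of the variance-partitioning pipeline is testable without any
download: this module generates

* founder haplotype pools with a controllable minor-allele-frequency
  spectrum (uniform, neutral 1/x, or beta),
* individual haplotypes by haplotype-copying from the founder pool with
  Poisson switch points — a small pool produces the strong, long-range
  linkage disequilibrium typical of intensively selected dairy cattle,
* multi-generation pedigrees and gene-dropped descendant genotypes that are
  Mendelian-consistent by construction,
* deregressed-proof (DRP) phenotypes: a true breeding value built from
  causal variants whose effect-size variance scales as ``(2p(1-p))^alpha``
  (alpha = 0 is the animal-genetics convention, alpha = -1 the human one),
  plus deregression noise with per-animal variance
  ``var(TBV) (1 - r) / r`` for reliability ``r``.

All randomness flows from explicit integer seeds through one
``numpy.random.Generator`` per operation call, so the same seed gives
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VARIANT_COLUMNS, compute_maf
from .relmat import Pedigree, UNKNOWN_PARENT, a_matrix
from .stratify import MafClassSpec, assign_maf_classes

logger = logging.getLogger("seqherit")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Genotype simulation parameters.

    ``maf_spectrum`` is ``("uniform", lo, hi)``, ``("neutral",)`` (density
    proportional to 1/x truncated to [0.001, 0.5]) or ``("beta", a, b)``
    (rescaled to [0.001, 0.5]).  ``founder_pool_size`` is the number of
    founder *individuals* in the copying pool (2x that many haplotypes); a
    small pool gives strong long-range LD.  ``switch_rate`` is the expected
    number of template switches per base pair when copying a haplotype.
    """

    n_individuals: int = 1000
    n_variants: int = 7000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    maf_spectrum: tuple = ("neutral",)
    founder_pool_size: int = 100
    switch_rate: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_chromosomes", "chromosome_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.founder_pool_size < 2:
            raise ValueError("founder_pool_size must be >= 2")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        kind = self.maf_spectrum[0]
        if kind == "uniform":
            _, lo, hi = self.maf_spectrum
            if not (0 < lo <= hi <= 0.5):
                raise ValueError(f"invalid uniform spectrum bounds ({lo}, {hi})")
        elif kind == "beta":
            _, a, b = self.maf_spectrum
            if a <= 0 or b <= 0:
                raise ValueError("beta spectrum parameters must be positive")
        elif kind != "neutral":
            raise ValueError(f"unknown MAF spectrum {kind!r}")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genetic architecture of the simulated trait.

    ``alpha`` scales causal effect variance as ``(2p(1-p))^alpha``.
    ``per_class_variance_fractions`` (one entry per MAF class, summing to
    <= 1) are target shares of the DRP variance and override ``target_h2``;
    effects are rescaled so the *realized* per-class genetic variances match.
    ``large_qtl`` plants one variant carrying a fixed fraction of the total
    genetic variance, emulating a major gene such as the milk-fat locus on
    bovine chromosome 14 (MAF ~0.29).
    """

    n_causal: int = 500
    alpha: float = 0.0
    target_h2: float = 0.6
    per_class_variance_fractions: tuple[float, ...] | None = None
    large_qtl: tuple[float, float] | None = None  # (maf, fraction_of_genetic_variance)
    reliability_distribution: tuple[float, float] = (0.85, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal < 0:
            raise ValueError("n_causal must be nonnegative")
        if not 0 <= self.target_h2 <= 1:
            raise ValueError("target_h2 must lie in [0, 1]")
        if self.per_class_variance_fractions is not None:
            fr = np.asarray(self.per_class_variance_fractions, dtype=float)
            if np.any(fr < 0):
                raise ValueError("per-class variance fractions must be nonnegative")
            if fr.sum() > 1 + 1e-12:
                raise ValueError(f"per-class variance fractions sum to {fr.sum():g} > 1")
        if self.large_qtl is not None:
            maf, frac = self.large_qtl
            if not (0 < maf <= 0.5) or not (0 <= frac <= 1):
                raise ValueError("invalid large_qtl (maf, fraction)")
        lo, hi = self.reliability_distribution
        if not (0 < lo <= hi <= 1):
            raise ValueError("reliability bounds must satisfy 0 < lo <= hi <= 1")


@dataclass
class TruthRecord:
    """Realized simulation truth for recovery tests.

    Per-class variances are variances of the realized per-class breeding
    values over the simulated individuals, not the requested targets.
    """

    causal_variant_ids: list[str]
    effects: np.ndarray
    true_variance_per_class: np.ndarray
    true_total_genetic_variance: float
    true_residual_variance: float
    class_labels: list[str] = field(default_factory=list)
    polygenic_variance: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_genetic_variance\t{self.true_total_genetic_variance:.10g}\n")
            fh.write(f"# residual_variance\t{self.true_residual_variance:.10g}\n")
            fh.write(f"# polygenic_variance\t{self.polygenic_variance:.10g}\n")
            for lab, v in zip(self.class_labels, self.true_variance_per_class):
                fh.write(f"# class_variance\t{lab}\t{v:.10g}\n")
            pd.DataFrame({"variant": self.causal_variant_ids, "effect": self.effects}).to_csv(
                fh, sep="\t", index=False
            )


@dataclass
class FounderHaplotypes:
    """Binary founder haplotype pool with variant coordinates."""

    haplotypes: np.ndarray  # (2 * founder_pool_size, n_variants) uint8
    variants: pd.DataFrame
    target_freqs: np.ndarray


# ---------------------------------------------------------------------------
# founders & haplotype copying
# ---------------------------------------------------------------------------

def _draw_frequencies(spectrum: tuple, m: int, rng: np.random.Generator) -> np.ndarray:
    kind = spectrum[0]
    if kind == "uniform":
        _, lo, hi = spectrum
        return rng.uniform(lo, hi, size=m)
    if kind == "neutral":
        lo, hi = 0.001, 0.5
        u = rng.uniform(size=m)
        return lo * np.exp(u * np.log(hi / lo))  # inverse CDF of 1/x on [lo, hi]
    _, a, b = spectrum
    return 0.001 + rng.beta(a, b, size=m) * (0.5 - 0.001)


def simulate_founder_haplotypes(config: SimulationConfig) -> FounderHaplotypes:
    """Draw the founder haplotype pool.

    Variant positions are sampled without replacement per chromosome (hence
    strictly increasing); target frequencies come from the configured
    spectrum and pool alleles are Bernoulli draws conditioned on the variant
    being polymorphic in the pool, so no pool column is fixed.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    rows = []
    j = 0
    for c, mc in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.chromosome_length_bp, size=mc, replace=False)) + 1
        for p in pos:
            rows.append((f"v{j}", f"chr{c}", int(p), "A", "C"))
            j += 1
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    freqs = _draw_frequencies(config.maf_spectrum, m, rng)
    nh = 2 * config.founder_pool_size
    hap = (rng.uniform(size=(nh, m)) < freqs).astype(np.uint8)
    # condition on polymorphic in the pool: redraw fixed columns
    for _ in range(200):
        counts = hap.sum(axis=0)
        fixed = np.flatnonzero((counts == 0) | (counts == nh))
        if fixed.size == 0:
            break
        hap[:, fixed] = (rng.uniform(size=(nh, fixed.size)) < freqs[fixed]).astype(np.uint8)
    counts = hap.sum(axis=0)
    still = np.flatnonzero((counts == 0) | (counts == nh))
    if still.size:  # extreme spectra: force a single carrier of the rarer allele
        for jj in still:
            i = int(rng.integers(nh))
            hap[i, jj] = 1 - hap[i, jj]
    return FounderHaplotypes(hap, variants, freqs)


def _copy_haplotypes(
    founders: FounderHaplotypes,
    n_haplotypes: int,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample haplotypes by copying founder templates with Poisson switches.

    With ``switch_rate`` 0 every sampled haplotype is an exact end-to-end
    copy of one founder haplotype per chromosome.
    """
    pool = founders.haplotypes
    nh_pool, m = pool.shape
    out = np.empty((n_haplotypes, m), dtype=np.uint8)
    chrom = founders.variants["chrom"].to_numpy()
    pos = founders.variants["pos"].to_numpy(dtype=float)
    # column blocks per chromosome (positions are sorted within)
    blocks = []
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        blocks.append((idx[0], idx[-1] + 1))
    for h in range(n_haplotypes):
        for lo, hi in blocks:
            span = pos[hi - 1] - pos[lo]
            n_switch = rng.poisson(switch_rate * span) if switch_rate > 0 else 0
            cuts = np.sort(rng.uniform(pos[lo], pos[hi - 1], size=n_switch)) if n_switch else np.empty(0)
            bounds = np.concatenate(([lo], np.searchsorted(pos[lo:hi], cuts) + lo, [hi])).astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                if a < b:
                    out[h, a:b] = pool[rng.integers(nh_pool), a:b]
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Unpedigreed sample: two copied haplotypes per individual."""
    founders = simulate_founder_haplotypes(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    haps = _copy_haplotypes(founders, 2 * config.n_individuals, config.switch_rate, rng)
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    ids = [f"ID{i + 1:05d}" for i in range(config.n_individuals)]
    return GenotypeMatrix(ids, founders.variants, dosages)


# ---------------------------------------------------------------------------
# pedigree & gene dropping
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int,
    seed: int = 0,
) -> Pedigree:
    """Random-mating multi-generation pedigree.

    Each generation pairs the previous generation's individuals at random
    (floor(n/2) matings) and every mating produces ``offspring_per_mating``
    offspring.  Founders have unknown sire and dam; records are emitted
    parents-first.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0 or offspring_per_mating < 1:
        raise ValueError("invalid pedigree parameters")
    rng = np.random.default_rng(seed)
    rows = [(f"G0_{i + 1}", UNKNOWN_PARENT, UNKNOWN_PARENT) for i in range(n_founders)]
    prev = [r[0] for r in rows]
    for gen in range(1, n_generations + 1):
        order = rng.permutation(len(prev))
        cur = []
        k = 0
        for a, b in zip(order[0::2], order[1::2]):
            for _ in range(offspring_per_mating):
                k += 1
                cid = f"G{gen}_{k}"
                rows.append((cid, prev[a], prev[b]))
                cur.append(cid)
        if not cur:
            break
        prev = cur
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def _meiosis(h1: np.ndarray, h2: np.ndarray, blocks, pos, rate: float, rng) -> np.ndarray:
    """One gamete: crossovers as a Poisson process along each chromosome."""
    gamete = np.empty_like(h1)
    for lo, hi in blocks:
        span = pos[hi - 1] - pos[lo]
        n_x = rng.poisson(rate * span) if rate > 0 else 0
        cuts = np.sort(rng.uniform(pos[lo], pos[hi - 1], size=n_x)) if n_x else np.empty(0)
        bounds = np.concatenate(([lo], np.searchsorted(pos[lo:hi], cuts) + lo, [hi])).astype(int)
        phase = int(rng.integers(2))
        for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            src = h1 if (phase + seg) % 2 == 0 else h2
            gamete[a:b] = src[a:b]
    return gamete


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: FounderHaplotypes,
    recombination_rate_per_bp: float = 1e-8,
    seed: int = 0,
) -> GenotypeMatrix:
    """Drop founder haplotypes through a pedigree.

    Each pedigree founder receives two distinct haplotypes from the pool (in
    pool order), so the pool must hold at least two haplotypes per founder;
    descendants receive one recombinant gamete from each parent.  Offspring
    genotypes are Mendelian-consistent with their parents at every locus by
    construction.
    """
    founders = pedigree.founders()
    pool = founder_haplotypes.haplotypes
    if pool.shape[0] < 2 * len(founders):
        raise ValueError(
            f"founder pool has {pool.shape[0]} haplotypes but the pedigree has "
            f"{len(founders)} founders (need 2 per founder)"
        )
    rng = np.random.default_rng(seed)
    chrom = founder_haplotypes.variants["chrom"].to_numpy()
    pos = founder_haplotypes.variants["pos"].to_numpy(dtype=float)
    blocks = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        blocks.append((int(idx[0]), int(idx[-1] + 1)))
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, fid in enumerate(founders):
        haps[fid] = (pool[2 * i], pool[2 * i + 1])
    rec = pedigree.records
    for _, row in rec.iterrows():
        iid, s, d = row["id"], row["sire"], row["dam"]
        if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
            continue
        g_s = _meiosis(*haps[s], blocks, pos, recombination_rate_per_bp, rng)
        g_d = _meiosis(*haps[d], blocks, pos, recombination_rate_per_bp, rng)
        haps[iid] = (g_s, g_d)
    dosages = np.stack([haps[i][0] + haps[i][1] for i in pedigree.ids]).astype(float)
    return GenotypeMatrix(pedigree.ids, founder_haplotypes.variants, dosages)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: ArchitectureConfig,
    trait: str = "SIM",
    maf_spec: MafClassSpec | None = None,
    polygenic: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """DRP-style phenotypes with known per-MAF-class genetic variances.

    Causal effects are drawn with variance proportional to
    ``(2 p (1 - p))^alpha`` and then rescaled: if per-class variance
    fractions are requested, each class's effects are scaled so the realized
    class variance (variance of the class breeding values over the simulated
    individuals) equals its fraction; otherwise all effects are scaled
    jointly so the realized total genetic variance equals ``target_h2``.
    ``polygenic`` adds a pre-simulated non-marker breeding value (e.g. from
    :func:`simulate_polygenic`) before the deregression noise is applied.

    DRP_i = TBV_i + eps_i with ``var(eps_i) = var(TBV) (1 - r_i) / r_i``;
    with reliability 1 the DRP equals the TBV exactly.
    """
    rng = np.random.default_rng(arch.seed)
    n, m = genotypes.dosages.shape
    if arch.n_causal > m:
        raise ValueError(f"n_causal={arch.n_causal} exceeds {m} variants")
    spec = maf_spec or MafClassSpec()
    maf = compute_maf(genotypes)
    # MAF below the first class bound can occur pre-QC; clip for class lookup
    partition = assign_maf_classes(np.clip(maf, spec.boundaries[0], 0.5), spec)

    tbv = np.zeros(n)
    effects = np.empty(0)
    causal: np.ndarray = np.empty(0, dtype=int)
    class_var = np.zeros(spec.n_classes)

    if arch.n_causal > 0:
        causal = np.sort(rng.choice(m, size=arch.n_causal, replace=False))
        qtl_j = -1
        qtl_frac = 0.0
        if arch.large_qtl is not None:
            qtl_maf, qtl_frac = arch.large_qtl
            qtl_j = int(np.argmin(np.abs(maf - qtl_maf)))
            if qtl_j not in causal:
                causal = np.sort(np.append(causal, qtl_j))
        x = genotypes.dosages[:, causal]
        if np.any(np.isnan(x)):
            raise ValueError("causal variants must have complete dosages")
        p = maf[causal]
        het = np.maximum(2.0 * p * (1.0 - p), 1e-12)
        beta = rng.normal(size=causal.size) * het ** (arch.alpha / 2.0)

        fractions = arch.per_class_variance_fractions
        if fractions is not None:
            fractions = np.asarray(fractions, dtype=float)
            if fractions.size != spec.n_classes:
                raise ValueError("need one variance fraction per MAF class")
            cls = partition.maf_class[causal]
            for c in range(spec.n_classes):
                sel = cls == c
                if fractions[c] == 0:
                    beta[sel] = 0.0
                    continue
                if not np.any(sel):
                    raise ValueError(f"no causal variant in MAF class {spec.labels[c]}")
                v = float(np.var(x[:, sel] @ beta[sel]))
                if v <= 0:
                    raise ValueError(f"degenerate causal genotypes in class {spec.labels[c]}")
                beta[sel] *= np.sqrt(fractions[c] / v)
        else:
            target = arch.target_h2
            if arch.large_qtl is not None and qtl_frac > 0:
                jq = int(np.searchsorted(causal, qtl_j))
                rest = np.ones(causal.size, dtype=bool)
                rest[jq] = False
                vq = float(np.var(x[:, jq] * 1.0))
                beta[jq] = np.sqrt(qtl_frac * target / vq) * np.sign(beta[jq] if beta[jq] != 0 else 1.0)
                vr = float(np.var(x[:, rest] @ beta[rest]))
                if vr > 0:
                    beta[rest] *= np.sqrt((1.0 - qtl_frac) * target / vr)
            else:
                v = float(np.var(x @ beta))
                if v > 0:
                    beta *= np.sqrt(target / v)
        tbv = x @ beta
        effects = beta
        cls = partition.maf_class[causal]
        for c in range(spec.n_classes):
            sel = cls == c
            if np.any(sel):
                class_var[c] = float(np.var(x[:, sel] @ beta[sel]))

    poly_var = 0.0
    if polygenic is not None:
        polygenic = np.asarray(polygenic, dtype=float)
        if polygenic.shape != (n,):
            raise ValueError("polygenic vector does not match the sample")
        poly_var = float(np.var(polygenic))
        tbv = tbv + polygenic

    v_g = float(np.var(tbv))
    lo, hi = arch.reliability_distribution
    reliability = rng.uniform(lo, hi, size=n)
    # with no genetic variance the reliability formula degenerates; use unit
    # scale so the DRP is pure noise rather than identically zero
    noise_scale = v_g if v_g > 0 else 1.0
    eps_var = noise_scale * (1.0 - reliability) / reliability
    drp = tbv + rng.normal(size=n) * np.sqrt(eps_var)

    phenotypes = pd.DataFrame(
        {"id": genotypes.individual_ids, "trait": trait, "drp": drp, "reliability": reliability}
    )
    truth = TruthRecord(
        causal_variant_ids=genotypes.variants["id"].iloc[causal].tolist(),
        effects=effects,
        true_variance_per_class=class_var,
        true_total_genetic_variance=v_g,
        true_residual_variance=float(np.mean(eps_var)),
        class_labels=spec.labels,
        polygenic_variance=poly_var,
    )
    return phenotypes, truth


def simulate_polygenic(pedigree: Pedigree, sigma2: float, seed: int = 0) -> pd.Series:
    """Pedigree-structured breeding values u ~ N(0, A sigma2).

    Sampled through the Cholesky factor of the numerator relationship
    matrix; indexed by pedigree id.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    a = a_matrix(pedigree).values
    chol = np.linalg.cholesky(a + 1e-10 * np.eye(a.shape[0]))
    u = chol @ rng.normal(size=a.shape[0]) * np.sqrt(sigma2)
    return pd.Series(u, index=pedigree.ids)


@dataclass
class PedigreeDataset:
    """Joint pedigree + genotype + phenotype simulation output."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: TruthRecord


def simulate_pedigree_dataset(
    seed: int,
    n_founders: int = 100,
    n_generations: int = 4,
    offspring_per_mating: int = 2,
    n_variants: int = 1200,
    n_chromosomes: int = 3,
    chromosome_length_bp: int = 100_000_000,
    n_causal: int = 150,
    marker_variance: float = 0.35,
    polygenic_variance: float = 0.25,
    reliability: float = 0.9,
) -> PedigreeDataset:
    """Gene-dropped genotypes plus a DRP trait with marker and pedigree parts.

    The trait carries a marker-tagged breeding value (causal variants among
    the genotyped loci, realized variance ``marker_variance``) and an
    additional pedigree-structured polygenic value with variance
    ``polygenic_variance`` that is *not* tagged by the markers — the
    structure under which fitting genomic and pedigree relationships jointly
    describes the data best.
    """
    sim = SimulationConfig(
        n_individuals=n_founders,  # founders drawn from the pool; descendants gene-dropped
        n_variants=n_variants,
        n_chromosomes=n_chromosomes,
        chromosome_length_bp=chromosome_length_bp,
        founder_pool_size=n_founders,
        seed=seed,
    )
    founders = simulate_founder_haplotypes(sim)
    pedigree = simulate_pedigree(n_founders, n_generations, offspring_per_mating, seed=seed + 1)
    genotypes = gene_drop(pedigree, founders, seed=seed + 2)
    u = simulate_polygenic(pedigree, polygenic_variance, seed=seed + 3)
    arch = ArchitectureConfig(
        n_causal=n_causal,
        target_h2=marker_variance,
        reliability_distribution=(reliability, reliability),
        seed=seed + 4,
    )
    phenotypes, truth = simulate_phenotypes(
        genotypes, arch, polygenic=u.loc[genotypes.individual_ids].to_numpy()
    )
    return PedigreeDataset(genotypes, pedigree, phenotypes, truth)


def add_dosage_noise(g: GenotypeMatrix, sd: float, seed: int = 0) -> GenotypeMatrix:
    """Optional imputation-error emulation: Gaussian dosage noise, clipped to [0, 2].

    Off by default everywhere; provided as a knob because imputed rare
    variants in real data carry non-trivial dosage error.
    """
    rng = np.random.default_rng(seed)
    noisy = np.clip(g.dosages + rng.normal(scale=sd, size=g.dosages.shape), 0.0, 2.0)
    noisy[np.isnan(g.dosages)] = np.nan
    return GenotypeMatrix(list(g.individual_ids), g.variants.copy(), noisy)
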