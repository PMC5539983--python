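"""Synthetic genotype, pedigree and DRP phenotype generation."""

import numpy as np
import pandas as pd
import pytest

import seqherit as sh
from seqherit.synthetic import FounderHaplotypes, _copy_haplotypes


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def test_degenerate_uniform_spectrum_half_frequency():
    cfg = sh.SimulationConfig(
        n_individuals=10, n_variants=200, n_chromosomes=1,
        maf_spectrum=("uniform", 0.5, 0.5), founder_pool_size=100, seed=1,
    )
    f = sh.simulate_founder_haplotypes(cfg)
    np.testing.assert_allclose(f.target_freqs, 0.5)
    freq = f.haplotypes.mean(axis=0)
    nh = f.haplotypes.shape[0]
    # realized pool frequencies within 4 binomial SDs of 0.5
    assert np.all(np.abs(freq - 0.5) < 4 * np.sqrt(0.25 / nh))


def test_positions_strictly_increasing_within_chromosome():
    cfg = sh.SimulationConfig(n_individuals=5, n_variants=300, n_chromosomes=3,
                              founder_pool_size=10, seed=2)
    f = sh.simulate_founder_haplotypes(cfg)
    for _, sub in f.variants.groupby("chrom", sort=False):
        assert np.all(np.diff(sub["pos"].to_numpy()) > 0)


def test_neutral_spectrum_enriches_rare_variants():
    cfg = sh.SimulationConfig(n_individuals=5, n_variants=10_000, n_chromosomes=1,
                              maf_spectrum=("neutral",), founder_pool_size=300, seed=3)
    f = sh.simulate_founder_haplotypes(cfg)
    rare = np.mean(f.target_freqs < 0.01)
    common_tail = np.mean((f.target_freqs >= 0.4) & (f.target_freqs <= 0.5))
    assert rare > common_tail
    # integral of 1/x on [0.001, 0.01] vs [0.4, 0.5] over log(500)
    assert rare == pytest.approx(np.log(10) / np.log(500), abs=0.02)
    assert common_tail == pytest.approx(np.log(0.5 / 0.4) / np.log(500), abs=0.02)


def test_invalid_spectrum_rejected():
    with pytest.raises(ValueError):
        sh.SimulationConfig(maf_spectrum=("uniform", 0.6, 0.7))
    with pytest.raises(ValueError):
        sh.SimulationConfig(maf_spectrum=("gamma", 1.0))
    with pytest.raises(ValueError):
        sh.SimulationConfig(founder_pool_size=1)


def test_zero_switch_rate_copies_founders_end_to_end():
    cfg = sh.SimulationConfig(n_individuals=5, n_variants=150, n_chromosomes=1,
                              founder_pool_size=4, switch_rate=0.0, seed=4)
    f = sh.simulate_founder_haplotypes(cfg)
    haps = _copy_haplotypes(f, 12, 0.0, np.random.default_rng(9))
    pool = f.haplotypes
    for h in haps:
        assert any(np.array_equal(h, pool[k]) for k in range(pool.shape[0]))


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def test_zero_generations_founders_only():
    ped = sh.simulate_pedigree(7, 0, 2, seed=0)
    assert ped.n == 7
    assert len(ped.founders()) == 7


def test_two_founders_one_mating():
    ped = sh.simulate_pedigree(2, 1, 2, seed=0)
    assert ped.n == 4
    kids = ped.records[ped.records["sire"] != "0"]
    assert len(kids) == 2
    assert kids["sire"].nunique() == 1 and kids["dam"].nunique() == 1


def test_parents_always_precede_offspring():
    ped = sh.simulate_pedigree(10, 3, 2, seed=5)
    seen = set()
    for _, r in ped.records.iterrows():
        for parent in (r["sire"], r["dam"]):
            assert parent == "0" or parent in seen
        seen.add(r["id"])


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _manual_founders(hap_rows, pos=None):
    hap = np.asarray(hap_rows, dtype=np.uint8)
    m = hap.shape[1]
    pos = pos or list(range(1, m + 1))
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "chr1", "pos": pos,
         "ref": "A", "alt": "C"}
    )
    return FounderHaplotypes(hap, variants, hap.mean(axis=0))


def test_homozygous_parents_force_offspring_dosage():
    ped = sh.Pedigree(pd.DataFrame(
        [("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")],
        columns=["id", "sire", "dam"],
    ))
    # locus 0: everyone 0/0 -> offspring 0; locus 1: everyone 1/1 -> offspring 2
    f = _manual_founders([[0, 1], [0, 1], [0, 1], [0, 1]])
    g = sh.gene_drop(ped, f, seed=1)
    o = g.dosages[g.individual_ids.index("o")]
    np.testing.assert_array_equal(o, [0.0, 2.0])


def test_gene_drop_requires_enough_founder_haplotypes():
    ped = sh.simulate_pedigree(5, 1, 1, seed=0)
    f = _manual_founders(np.zeros((4, 3)))
    with pytest.raises(ValueError, match="founder pool"):
        sh.gene_drop(ped, f, seed=0)


def test_gene_drop_is_mendelian_consistent_everywhere():
    ped = sh.simulate_pedigree(12, 3, 2, seed=6)
    cfg = sh.SimulationConfig(n_individuals=12, n_variants=300, n_chromosomes=2,
                              founder_pool_size=12, seed=7)
    f = sh.simulate_founder_haplotypes(cfg)
    g = sh.gene_drop(ped, f, recombination_rate_per_bp=1e-8, seed=8)
    idx = {s: i for i, s in enumerate(g.individual_ids)}
    bounds = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    bad = 0
    for _, r in ped.records.iterrows():
        if r["sire"] == "0":
            continue
        o = g.dosages[idx[r["id"]]]
        s = g.dosages[idx[r["sire"]]]
        d = g.dosages[idx[r["dam"]]]
        for oj, sj, dj in zip(o, s, d):
            lo = bounds[sj][0] + bounds[dj][0]
            hi = bounds[sj][1] + bounds[dj][1]
            bad += not (lo <= oj <= hi)
    assert bad == 0


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _tbv_from_truth(g, truth):
    pos = {v: i for i, v in enumerate(g.variants["id"])}
    x = g.dosages[:, [pos[v] for v in truth.causal_variant_ids]]
    return x @ truth.effects


def test_full_reliability_makes_drp_equal_tbv(ld_genotypes):
    arch = sh.ArchitectureConfig(n_causal=40, reliability_distribution=(1.0, 1.0), seed=1)
    phe, truth = sh.simulate_phenotypes(ld_genotypes, arch)
    np.testing.assert_allclose(phe["drp"].to_numpy(), _tbv_from_truth(ld_genotypes, truth), atol=1e-10)


def test_no_causal_variants_pure_noise(ld_genotypes):
    arch = sh.ArchitectureConfig(n_causal=0, seed=2)
    phe, truth = sh.simulate_phenotypes(ld_genotypes, arch)
    assert truth.true_total_genetic_variance == 0.0
    assert np.var(phe["drp"]) > 0.0


def test_constant_reliability_scales_drp_variance():
    g = sh.simulate_genotypes(sh.SimulationConfig(
        n_individuals=2500, n_variants=800, n_chromosomes=2, founder_pool_size=80, seed=12))
    g, _ = sh.qc_filter(g)
    arch = sh.ArchitectureConfig(n_causal=100, target_h2=0.5,
                                 reliability_distribution=(0.5, 0.5), seed=13)
    phe, truth = sh.simulate_phenotypes(g, arch)
    ratio = float(np.var(phe["drp"])) / truth.true_total_genetic_variance
    # var(DRP) ~ var(TBV) / r for constant reliability r
    assert ratio == pytest.approx(1.0 / 0.5, rel=0.1)


def test_per_class_fractions_realized_exactly(ld_genotypes):
    fracs = (0.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
    arch = sh.ArchitectureConfig(n_causal=150, per_class_variance_fractions=fracs,
                                 reliability_distribution=(0.6, 0.6), seed=3)
    phe, truth = sh.simulate_phenotypes(ld_genotypes, arch)
    np.testing.assert_allclose(truth.true_variance_per_class, fracs, atol=1e-10)


def test_fraction_sum_above_one_rejected():
    with pytest.raises(ValueError, match="> 1"):
        sh.ArchitectureConfig(per_class_variance_fractions=(0.5,) * 7)


def test_large_qtl_tags_requested_share_of_tbv():
    g = sh.simulate_genotypes(sh.SimulationConfig(
        n_individuals=2000, n_variants=1500, n_chromosomes=3,
        founder_pool_size=200, switch_rate=5e-7, seed=21))
    g, _ = sh.qc_filter(g)
    arch = sh.ArchitectureConfig(n_causal=200, target_h2=0.6, large_qtl=(0.29, 0.15),
                                 reliability_distribution=(0.99, 0.99), seed=22)
    phe, truth = sh.simulate_phenotypes(g, arch)
    tbv = _tbv_from_truth(g, truth)
    maf = sh.compute_maf(g)
    j = int(np.argmin(np.abs(maf - 0.29)))
    r2 = float(np.corrcoef(g.dosages[:, j], tbv)[0, 1] ** 2)
    assert r2 == pytest.approx(0.15, abs=0.03)


def test_effect_size_scaling_with_alpha(ld_genotypes):
    """Average per-variant variance contribution tracks heterozygosity when
    alpha = 0 and is flat when alpha = -1."""
    g = ld_genotypes
    maf = sh.compute_maf(g)
    keep = maf >= 0.05  # avoid the noisy rare tail for the regression check
    g = g.subset(variants=keep)
    het = 2 * sh.compute_maf(g) * (1 - sh.compute_maf(g))
    m = g.n_variants
    corr = {}
    for alpha in (0.0, -1.0):
        contrib = np.zeros(m)
        for seed in range(60):
            arch = sh.ArchitectureConfig(n_causal=m, alpha=alpha, target_h2=0.5, seed=seed)
            _, truth = sh.simulate_phenotypes(g, arch)
            pos = {v: i for i, v in enumerate(g.variants["id"])}
            beta = np.zeros(m)
            for v, b in zip(truth.causal_variant_ids, truth.effects):
                beta[pos[v]] = b
            contrib += beta ** 2 * np.var(g.dosages, axis=0)
        corr[alpha] = float(np.corrcoef(contrib, het)[0, 1])
    assert corr[0.0] > 0.5
    assert abs(corr[-1.0]) < 0.3


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_same_seed_bit_identical_outputs():
    cfg = sh.SimulationConfig(n_individuals=50, n_variants=200, n_chromosomes=2,
                              founder_pool_size=20, seed=99)
    g1 = sh.simulate_genotypes(cfg)
    g2 = sh.simulate_genotypes(cfg)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    arch = sh.ArchitectureConfig(n_causal=30, seed=100)
    p1, t1 = sh.simulate_phenotypes(g1, arch)
    p2, t2 = sh.simulate_phenotypes(g2, arch)
    pd.testing.assert_frame_equal(p1, p2)
    np.testing.assert_array_equal(t1.effects, t2.effects)
    d1 = sh.simulate_pedigree_dataset(7, n_founders=20, n_generations=2, n_variants=150)
    d2 = sh.simulate_pedigree_dataset(7, n_founders=20, n_generations=2, n_variants=150)
    np.testing.assert_array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
    pd.testing.assert_frame_equal(d1.phenotypes, d2.phenotypes)


def test_dosage_noise_preserves_range_and_missing(ld_genotypes):
    g = ld_genotypes
    noisy = sh.add_dosage_noise(g, 0.3, seed=1)
    assert np.nanmin(noisy.dosages) >= 0.0 and np.nanmax(noisy.dosages) <= 2.0
    np.testing.assert_array_equal(np.isnan(noisy.dosages), np.isnan(g.dosages))
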