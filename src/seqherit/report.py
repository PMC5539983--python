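"""Expected-vs-estimated variance partitions, aggregation and orchestration.

Under VanRaden method 1 scaling, the expected share of genetic variance for
a class of variants is ``sum_class 2p(1-p) / sum_all 2p(1-p)``; under method
2 (every standardized variant contributes equally) it is ``N_class / N``.
Method 2 therefore assigns at least the method-1 share to any class whose
mean heterozygosity is below the overall mean — it puts more emphasis on
rare variants.

Estimated per-class proportions from a MAF-stratified REML fit are
aggregated into rare (MAF < 0.01), low-frequency (0.01 <= MAF < 0.05) and
common (MAF >= 0.05) relative contributions, each divided by the total
proportion explained.  ``run_pipeline`` chains the whole analysis
(simulate/read -> QC -> stratify -> relationship matrices -> REML -> report
tables) from a YAML configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotypes as gt
from . import relmat, reml, stratify, synthetic

logger = logging.getLogger("seqherit")

RARE_UPPER = 0.01
LOW_UPPER = 0.05


def expected_partition_vr1(mafs: np.ndarray, partition: stratify.VariantPartition) -> np.ndarray:
    """Expected per-class variance shares under VanRaden method 1 scaling."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size != partition.n_variants:
        raise ValueError("MAF vector and partition differ in length")
    het = 2.0 * mafs * (1.0 - mafs)
    total = float(het.sum())
    if total <= 0:
        raise ValueError("zero total heterozygosity")
    out = np.zeros(partition.spec.n_classes)
    for c in range(partition.spec.n_classes):
        out[c] = float(het[partition.maf_class == c].sum()) / total
    return out


def expected_partition_vr2(partition: stratify.VariantPartition) -> np.ndarray:
    """Expected per-class variance shares under VanRaden method 2 (N_class / N)."""
    sizes = partition.class_sizes().astype(float)
    if partition.n_variants == 0:
        raise ValueError("empty partition")
    return sizes / partition.n_variants


def single_variant_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Share of DRP variance tagged by one variant: squared dosage-DRP correlation.

    This is how a single major locus (e.g. the chromosome-14 milk-fat gene)
    is credited with a percentage of the DRP variance.
    """
    return stratify.ld_r2(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


@dataclass
class PartitionReport:
    """Per-MAF-class table plus rare/low/common aggregate contributions."""

    table: pd.DataFrame  # class, n_variants, proportion, se, expected_vr1, expected_vr2, flag
    total_explained: float
    relative_rare: float
    relative_low: float
    relative_common: float

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_proportion_explained\t{self.total_explained:.6g}\n")
            fh.write(f"# relative_rare\t{self.relative_rare:.6g}\n")
            fh.write(f"# relative_low_frequency\t{self.relative_low:.6g}\n")
            fh.write(f"# relative_common\t{self.relative_common:.6g}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def aggregate_contributions(
    fit: reml.VarianceComponentFit,
    partition: stratify.VariantPartition,
    mafs: np.ndarray,
) -> PartitionReport:
    """Aggregate a MAF-stratified fit into a per-class and rare/low/common report.

    Relative contributions divide each aggregate's summed class proportions
    by the total proportion explained (undefined, reported as NaN, when the
    total is zero).  Estimates larger than one standard error are flagged,
    mirroring the usual bold-face convention in supplementary tables.
    LD-stratified fits are aggregated over LD groups within each MAF class.
    """
    spec = partition.spec
    # map fitted component labels back to MAF classes ("<class>" or "<class>|LDk")
    class_prop = np.zeros(spec.n_classes)
    class_var_se2 = np.zeros(spec.n_classes)
    label_to_class = {lab: c for c, lab in enumerate(spec.labels)}
    for lab, prop, se in zip(fit.component_labels[:-1], fit.proportions, fit.proportion_se):
        base = lab.split("|")[0]
        if base not in label_to_class:
            raise ValueError(f"component {lab!r} does not match a MAF class")
        c = label_to_class[base]
        class_prop[c] += prop
        class_var_se2[c] += se ** 2  # covariance between groups ignored in the per-class SE
    class_se = np.sqrt(class_var_se2)

    counts = partition.class_sizes()
    evr1 = expected_partition_vr1(mafs, partition)
    evr2 = expected_partition_vr2(partition)
    table = pd.DataFrame(
        {
            "maf_class": spec.labels,
            "n_variants": counts,
            "proportion": class_prop,
            "se": class_se,
            "expected_vr1": evr1,
            "expected_vr2": evr2,
            "exceeds_se": class_prop > class_se,
        }
    )
    total = float(class_prop.sum())
    bounds = np.asarray(spec.boundaries)
    uppers = bounds[1:]
    rare = float(class_prop[uppers <= RARE_UPPER].sum())
    low = float(class_prop[(uppers > RARE_UPPER) & (uppers <= LOW_UPPER)].sum())
    common = float(class_prop[uppers > LOW_UPPER].sum())
    if total > 0:
        rel = (rare / total, low / total, common / total)
    else:
        rel = (np.nan, np.nan, np.nan)
    return PartitionReport(table, total, *rel)


# ---------------------------------------------------------------------------
# model comparison helpers
# ---------------------------------------------------------------------------

def total_proportion_explained(fit: reml.VarianceComponentFit, rescale: dict[str, float] | None = None) -> float:
    """Total genetic share of DRP variance, optionally base-rescaling components.

    ``rescale`` maps component labels to multiplicative base factors (the
    ``mean diag - mean`` rule); unlisted components keep factor 1.
    """
    theta = fit.estimates
    factors = np.ones(theta.size - 1)
    if rescale:
        for i, lab in enumerate(fit.component_labels[:-1]):
            factors[i] = rescale.get(lab, 1.0)
    genetic = float(np.sum(theta[:-1] * factors))
    return genetic / (genetic + fit.sigma2_e)


def model_comparison_table(fits: dict[str, reml.VarianceComponentFit],
                           rescales: dict[str, dict[str, float]] | None = None) -> pd.DataFrame:
    """Per-model total proportion explained, log-likelihood and AIC.

    AIC differences are reported against the pedigree-only model when it is
    present (its AIC is scaled to zero), matching the usual presentation.
    """
    rescales = rescales or {}
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "model": name,
                "converged": fit.converged,
                "total_proportion_explained": total_proportion_explained(fit, rescales.get(name)),
                "loglik": fit.loglik,
                "aic": reml.aic(fit) if fit.converged else np.nan,
                "n_components": len(fit.component_labels) - 1,
            }
        )
    df = pd.DataFrame(rows)
    if "reml-ped" in fits and fits["reml-ped"].converged:
        ref = df.loc[df["model"] == "reml-ped", "aic"].iloc[0]
        df["aic_vs_reml_ped"] = df["aic"] - ref
    return df


def grm_class_correlations(genotypes: gt.GenotypeMatrix, partition: stratify.VariantPartition) -> pd.DataFrame:
    """Pairwise off-diagonal correlations between per-MAF-class GRMs."""
    labels, grms = [], []
    for c in range(partition.spec.n_classes):
        idx = np.flatnonzero(partition.maf_class == c)
        if idx.size == 0:
            continue
        labels.append(partition.spec.labels[c])
        grms.append(relmat.grm_alpha(genotypes.subset(variants=idx)))
    k = len(grms)
    mat = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            mat[a, b] = mat[b, a] = relmat.grm_offdiag_correlation(grms[a], grms[b])
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_QC_DEFAULTS = {
    "min_individual_call_rate": 0.85,
    "min_locus_call_rate": 0.95,
    "hwe_p_min": 0.00001,
    "maf_min": 0.001,
}


def _validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    known = {"seed", "simulation", "architecture", "inputs", "qc", "stratify", "models", "ld_plot"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if ("simulation" in cfg) == ("inputs" in cfg):
        raise ValueError("config needs exactly one of 'simulation' or 'inputs'")
    models = cfg.get("models", ["greml-ms"])
    for mdl in models:
        if mdl.lower() not in reml.MODEL_LABELS:
            raise ValueError(f"unknown model {mdl!r}")
    n_ld = cfg.get("stratify", {}).get("n_ld_groups", 0)
    if n_ld not in (0, 3, 4):
        raise ValueError("stratify.n_ld_groups must be 0, 3 or 4")
    for k in cfg.get("qc", {}):
        if k not in _QC_DEFAULTS:
            raise ValueError(f"unknown qc threshold {k!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run QC -> stratify -> relationship matrices -> REML -> report.

    ``config`` is a YAML path or an equivalent mapping; outputs are
    tab-separated tables in ``out_dir`` with a config-hash header comment,
    so re-running the same configuration reproduces byte-identical files.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    seed = int(cfg.get("seed", 0))
    models = [m.lower() for m in cfg.get("models", ["greml-ms"])]

    def _write(df: pd.DataFrame, name: str, index: bool = False, **meta) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash\t{chash}\n# seed\t{seed}\n")
            for k, v in meta.items():
                fh.write(f"# {k}\t{v}\n")
            df.to_csv(fh, sep="\t", index=index)

    pedigree = None
    truth = None
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"])
        ped_kwargs = sim_kwargs.pop("pedigree", None)
        sim_kwargs["maf_spectrum"] = tuple(sim_kwargs.get("maf_spectrum", ("neutral",)))
        sim = synthetic.SimulationConfig(seed=seed, **sim_kwargs)
        arch_kwargs = dict(cfg.get("architecture", {}))
        for key in ("per_class_variance_fractions", "large_qtl", "reliability_distribution"):
            if key in arch_kwargs and arch_kwargs[key] is not None:
                arch_kwargs[key] = tuple(arch_kwargs[key])
        arch = synthetic.ArchitectureConfig(seed=seed + 1, **arch_kwargs)
        if ped_kwargs:
            pedigree = synthetic.simulate_pedigree(seed=seed + 2, **ped_kwargs)
            founders = synthetic.simulate_founder_haplotypes(sim)
            g = synthetic.gene_drop(pedigree, founders, seed=seed + 3)
        else:
            g = synthetic.simulate_genotypes(sim)
        phenotypes, truth = synthetic.simulate_phenotypes(g, arch)
    else:
        inp = cfg["inputs"]
        g = gt.read_genotypes(inp["genotypes"], inp.get("format", "vcf"))
        phenotypes = pd.read_csv(inp["phenotypes"], sep="\t")
        if "pedigree" in inp:
            pedigree = relmat.read_pedigree(inp["pedigree"])

    qc_kwargs = {**_QC_DEFAULTS, **cfg.get("qc", {})}
    g, qc_report = gt.qc_filter(g, **qc_kwargs)
    qc_report.write(out / "qc_report.tsv")

    mafs = gt.compute_maf(g)
    partition = stratify.assign_maf_classes(mafs)
    n_ld_groups = cfg.get("stratify", {}).get("n_ld_groups", 0)
    ld_table = None
    if n_ld_groups:
        ld_table = stratify.ld_scores(g)
        ld_table = stratify.segment_mean_ld(ld_table)
        partition = stratify.stratify_ld_groups(partition, ld_table, n_ld_groups)
        if cfg.get("ld_plot", False):
            _ld_plot(ld_table, out / "ld_scores.png")
    _write(stratify.partition_table(partition, g.variants, mafs, ld_table), "partition.tsv")

    keep = phenotypes["id"].astype(str).isin(set(g.individual_ids))
    phenotypes = phenotypes.loc[keep]
    fits: dict[str, reml.VarianceComponentFit] = {}
    rescales: dict[str, dict[str, float]] = {}
    for mdl in models:
        fit = reml.fit_model(
            phenotypes, mdl, genotypes=g, partition=partition, pedigree=pedigree
        )
        fits[mdl] = fit
        if mdl in ("reml-ped", "reml-pedgrm") and pedigree is not None:
            a = relmat.a_matrix(pedigree).align(phenotypes["id"].astype(str).tolist())
            rescales[mdl] = {
                "pedigree": float(np.mean(np.diag(a.values)) - np.mean(a.values))
            }
        fit.write(out / f"fit_{mdl}.tsv")
        logger.info("model %s: %d components, logL=%.4f, converged=%s",
                    mdl, len(fit.component_labels) - 1, fit.loglik, fit.converged)

    comparison = model_comparison_table(fits, rescales)
    _write(comparison, "model_comparison.tsv")

    strat_model = "greml-ldms" if n_ld_groups else "greml-ms"
    if strat_model in fits:
        rep = aggregate_contributions(fits[strat_model], partition, mafs)
        rep.write(out / "partition_report.tsv")

    corr = grm_class_correlations(g, partition)
    _write(corr, "grm_correlations.tsv", index=True)

    if truth is not None:
        truth.write(out / "truth.tsv")
    with open(out / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(
            {"config": cfg, "config_hash": chash, "seed": seed,
             "n_individuals": g.n_individuals, "n_variants": g.n_variants,
             "n_components": {m: len(f.component_labels) - 1 for m, f in fits.items()}},
            fh, sort_keys=True,
        )
    return out


def _ld_plot(ld_table: pd.DataFrame, path: Path) -> None:
    """One diagnostic figure: LD score against position, per chromosome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for chrom, sub in ld_table.groupby("chrom", sort=False):
        ax.plot(sub["pos"] / 1e6, sub["ld_score"], ".", ms=2, label=str(chrom))
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("LD score")
    ax.legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
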