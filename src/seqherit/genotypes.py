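"""Genotype container, VCF / PLINK IO, allele frequencies and QC filters.

Dosages are counts of the alternate allele on the closed interval [0, 2];
fractional values (imputed dosages) are allowed and missing entries are
``NaN``.  Allele frequencies are always recomputed from the sample at hand,
and the minor allele is defined per realized sample: the minor allele
frequency (MAF) is ``min(f, 1 - f)`` where ``f`` is the alternate-allele
frequency.

Quality control mirrors standard SNP-array editing: a minimum call rate of
0.85 for individuals and 0.95 for loci, exclusion of monomorphic loci and of
loci deviating from Hardy-Weinberg proportions at P < 1e-5, and a minimum
MAF of 0.001 (at the scale of ~5000 genotyped bulls that threshold keeps
variants with roughly ten or more copies of the minor allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("seqherit")

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant coordinates.

    Parameters
    ----------
    individual_ids
        Unique sample identifiers, one per row of ``dosages``.
    variants
        Table with columns ``id, chrom, pos, ref, alt``; positions are
        1-based and must be nondecreasing within a chromosome.
    dosages
        ``(n_individuals, n_variants)`` float array of alternate-allele
        counts in [0, 2]; missing entries are NaN.
    """

    individual_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.variants)} variants"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual ids")
        v = self.variants
        missing = [c for c in VARIANT_COLUMNS if c not in v.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        if v["id"].duplicated().any():
            dup = v.loc[v["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicated variant id {dup!r}")
        for chrom, sub in v.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
                raise ValueError(f"positions not nondecreasing on chromosome {chrom}")
        self.variants = v.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        variants: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset (boolean masks or index arrays)."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        var = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if var.dtype == bool:
            var = np.flatnonzero(var)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in ind],
            self.variants.iloc[var].reset_index(drop=True),
            self.dosages[np.ix_(ind, var)],
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def alt_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant alternate-allele frequency over non-missing entries."""
    n_obs = np.sum(~np.isnan(g.dosages), axis=0)
    if np.any(n_obs == 0):
        vid = g.variants["id"].iloc[int(np.argmax(n_obs == 0))]
        raise ValueError(f"variant {vid!r} has no non-missing dosages")
    with np.errstate(invalid="ignore"):
        return np.nanmean(g.dosages, axis=0) / 2.0


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per variant, folded to [0, 0.5]."""
    f = alt_allele_frequency(g)
    return np.minimum(f, 1.0 - f)


def expected_minor_allele_copies(n_individuals: int, maf: float) -> float:
    """Number of minor-allele copies implied by a MAF in a diploid sample.

    A MAF threshold of 0.001 in ~5000 individuals corresponds to keeping
    variants with roughly ten or more copies of the minor allele.
    """
    return 2.0 * n_individuals * maf


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test for Hardy-Weinberg proportions.

    Expected genotype counts are (p^2, 2pq, q^2) x N at the sample allele
    frequency. Monomorphic input returns (0.0, 1.0) by convention; the
    monomorphic state is flagged separately during QC.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter removal counts; ``removed + retained = input`` per axis."""

    n_individuals_in: int
    n_variants_in: int
    individuals_removed_call_rate: int = 0
    variants_removed_call_rate: int = 0
    variants_removed_monomorphic: int = 0
    variants_removed_hwe: int = 0
    variants_removed_maf: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.individuals_removed_call_rate

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - (
            self.variants_removed_call_rate
            + self.variants_removed_monomorphic
            + self.variants_removed_hwe
            + self.variants_removed_maf
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individuals_in", self.n_individuals_in),
            ("individuals_removed_call_rate", self.individuals_removed_call_rate),
            ("individuals_out", self.n_individuals_out),
            ("variants_in", self.n_variants_in),
            ("variants_removed_call_rate", self.variants_removed_call_rate),
            ("variants_removed_monomorphic", self.variants_removed_monomorphic),
            ("variants_removed_hwe", self.variants_removed_hwe),
            ("variants_removed_maf", self.variants_removed_maf),
            ("variants_out", self.n_variants_out),
        ] + [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["step", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_filter(
    g: GenotypeMatrix,
    min_individual_call_rate: float = 0.85,
    min_locus_call_rate: float = 0.95,
    hwe_p_min: float = 0.00001,
    maf_min: float = 0.001,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard QC filters in a fixed order.

    Order: individual call rate -> locus call rate -> monomorphic -> HWE ->
    MAF.  Individual filters precede locus filters so that locus statistics
    are computed on retained individuals only.  HWE is tested on dosages
    rounded to the nearest hard genotype; dosages themselves stay fractional.
    """
    report = QCReport(
        g.n_individuals,
        g.n_variants,
        thresholds={
            "min_individual_call_rate": min_individual_call_rate,
            "min_locus_call_rate": min_locus_call_rate,
            "hwe_p_min": hwe_p_min,
            "maf_min": maf_min,
        },
    )
    obs = ~np.isnan(g.dosages)

    ind_rate = obs.mean(axis=1) if g.n_variants else np.ones(g.n_individuals)
    keep_ind = ind_rate >= min_individual_call_rate
    report.individuals_removed_call_rate = int(np.sum(~keep_ind))
    if not np.any(keep_ind):
        raise ValueError("all individuals removed by the individual call-rate filter")
    g = g.subset(individuals=keep_ind)

    obs = ~np.isnan(g.dosages)
    locus_rate = obs.mean(axis=0)
    keep = locus_rate >= min_locus_call_rate
    report.variants_removed_call_rate = int(np.sum(~keep))
    g = g.subset(variants=keep)

    f = alt_allele_frequency(g) if g.n_variants else np.empty(0)
    poly = (f > 0.0) & (f < 1.0)
    report.variants_removed_monomorphic = int(np.sum(~poly))
    g = g.subset(variants=poly)

    if g.n_variants:
        hard = np.rint(g.dosages)
        keep = np.empty(g.n_variants, dtype=bool)
        for j in range(g.n_variants):
            col = hard[:, j]
            col = col[~np.isnan(col)]
            n_aa = int(np.sum(col == 0))
            n_het = int(np.sum(col == 1))
            n_AA = int(np.sum(col == 2))
            _, p = hwe_test(n_aa, n_het, n_AA)
            keep[j] = p >= hwe_p_min
        report.variants_removed_hwe = int(np.sum(~keep))
        g = g.subset(variants=keep)

    if g.n_variants:
        maf = compute_maf(g)
        keep = maf >= maf_min
        report.variants_removed_maf = int(np.sum(~keep))
        g = g.subset(variants=keep)

    logger.info(
        "QC: %d/%d individuals, %d/%d variants retained",
        report.n_individuals_out,
        report.n_individuals_in,
        report.n_variants_out,
        report.n_variants_in,
    )
    return g, report


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    The DS (dosage) FORMAT field is preferred over GT when present.  Only
    biallelic records are accepted.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    seen: set[str] = set()
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in seen:
            raise GenotypeParseError(f"{path}: duplicated variant id {vid!r} at record {i + 1}")
        seen.add(vid)
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(samples))
            col[(col < -0.5) | (col > 2.5)] = np.nan
        else:
            gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append((vid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        dosage_cols.append(col)
    if not rows:
        raise GenotypeParseError(f"{path}: no variant records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(samples, variants, np.column_stack(dosage_cols))


def write_vcf(g: GenotypeMatrix, path: str | Path, write_dosage: bool | None = None) -> None:
    """Write a VCF v4.2 with GT and (optionally) DS per sample.

    ``write_dosage=None`` writes DS whenever any dosage is fractional, which
    makes write -> read a dosage-exact round trip.
    """
    if write_dosage is None:
        finite = g.dosages[~np.isnan(g.dosages)]
        write_dosage = bool(np.any(finite != np.rint(finite)))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seqherit\n")
        for chrom, sub in g.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if write_dosage:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        fmt = "GT:DS" if write_dosage else "GT"
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.variants.iterrows():
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", fmt,
            ]
            for i in range(g.n_individuals):
                d = g.dosages[i, j]
                if np.isnan(d):
                    cell = "./."
                    if write_dosage:
                        cell += ":."
                else:
                    cell = gt_codes[int(np.rint(d))]
                    if write_dosage:
                        cell += f":{d:.9g}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK1 .bed/.bim/.fam IO (hand-rolled 2-bit codec)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit codes with A1 = alt: 00 hom A1 (dosage 2), 10 het, 11 hom A2, 01 missing
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK1 .bed/.bim/.fam trio (hard calls; dosages are rounded).

    A1 in the .bim is the alternate allele, so the stored genotype counts the
    same allele as the in-memory dosage.
    """
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"].astype(int),
            "a1": g.variants["alt"],
            "a2": g.variants["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.individual_ids, "iid": g.individual_ids, "sire": 0, "dam": 0, "sex": 0, "phe": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = g.n_individuals
    hard = np.rint(g.dosages)
    dose_to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_variants):
            col = hard[:, j]
            byte_arr = bytearray((n + 3) // 4)
            for i in range(n):
                code = 0b01 if np.isnan(col[i]) else dose_to_code[float(col[i])]
                byte_arr[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(byte_arr))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK1 .bed/.bim/.fam trio written in SNP-major order."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    ids = fam[1].tolist()
    n, m = len(ids), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeParseError(f"{prefix}.bed: bad magic bytes {raw[:3]!r} (want SNP-major PLINK1)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise GenotypeParseError(f"{prefix}.bed: size mismatch for {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, sample 0 in the low-order bits
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dosages = _CODE_TO_DOSE[codes].T
    variants = pd.DataFrame(
        {"id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"].astype(int),
         "ref": bim["a2"], "alt": bim["a1"]}
    )[VARIANT_COLUMNS]
    return GenotypeMatrix(ids, variants, dosages)


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Dispatch to the VCF or PLINK reader.

    ``format='plink'`` expects ``path`` to be the trio prefix.
    """
    if format == "vcf":
        return read_vcf(path)
    if format in ("plink", "plink-dialect"):
        return read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (never persisted)."""
    if not np.any(np.isnan(dosages)):
        return np.array(dosages, dtype=float)
    out = np.array(dosages, dtype=float)
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out
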