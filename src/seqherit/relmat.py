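"""Genomic and pedigree relationship matrices.

Three genomic relationship matrix (GRM) flavours are provided:

* VanRaden method 1: ``G = (X - 2p1')(X - 2p1')' / (2 sum_j p_j (1 - p_j))``,
  scaled to be comparable to the pedigree numerator relationship matrix.
* The alpha-scaled family ``W_j = (X_j - 2 f_j) (2 f_j (1 - f_j))^(alpha/2)``,
  ``G = W W' / m``: alpha = -1 standardizes every variant (VanRaden method 2,
  more weight on rare variants, the GCTA default), alpha = 0 reproduces
  method 1 up to the global scale ``m`` vs ``2 sum f(1-f)``.
* The pedigree numerator relationship matrix A via the tabular method.

``rescale_to_base`` expresses a variance component estimated under a
relationship matrix K in the base of the analyzed population via
``sigma2 * (mean(diag K) - mean(K))``, which puts pedigree-based and genomic
variances on one footing before proportions are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, alt_allele_frequency, mean_impute

logger = logging.getLogger("seqherit")


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship matrix with scaling metadata."""

    values: np.ndarray
    ids: list[str]
    kind: str  # grm_vr1 | grm_vr2 | grm_alpha | pedigree_A
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: list[str]) -> "RelationshipMatrix":
        """Subset/reorder to the given individual ids."""
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"{len(missing)} ids absent from the matrix, e.g. {missing[0]!r}")
        idx = np.array([index[s] for s in ids])
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind, dict(self.meta))


# ---------------------------------------------------------------------------
# GRMs
# ---------------------------------------------------------------------------

def grm_vanraden1(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method 1 GRM.

    ``freqs`` are alternate-allele frequencies (not folded MAF) matching the
    columns of the dosage matrix; by default they are recomputed from the
    sample. Missing dosages are mean-imputed before centering.
    """
    f = alt_allele_frequency(g) if freqs is None else np.asarray(freqs, dtype=float)
    if f.shape != (g.n_variants,):
        raise ValueError("frequency vector does not match variant count")
    denom = float(2.0 * np.sum(f * (1.0 - f)))
    if denom <= 0.0:
        raise ValueError("all variants monomorphic: zero heterozygosity denominator")
    w = mean_impute(g.dosages) - 2.0 * f
    values = (w @ w.T) / denom
    return RelationshipMatrix(
        values, list(g.individual_ids), "grm_vr1",
        {"denominator": denom, "n_variants": g.n_variants, "freqs_source": "sample" if freqs is None else "external"},
    )


def grm_alpha(g: GenotypeMatrix, freqs: np.ndarray | None = None, alpha: float = -1.0) -> RelationshipMatrix:
    """Alpha-scaled GRM: columns weighted by ``(2 f (1-f))^(alpha/2)``, G = WW'/m.

    alpha = -1 gives the variant-standardized GRM (VanRaden method 2 / GCTA
    default); alpha = 0 equals VanRaden method 1 after rescaling by
    ``m / (2 sum f(1-f))``. Negative alpha requires every variant to be
    polymorphic.
    """
    f = alt_allele_frequency(g) if freqs is None else np.asarray(freqs, dtype=float)
    if f.shape != (g.n_variants,):
        raise ValueError("frequency vector does not match variant count")
    het = 2.0 * f * (1.0 - f)
    if alpha < 0 and np.any(het <= 0.0):
        j = int(np.argmax(het <= 0.0))
        raise ValueError(
            f"monomorphic variant {g.variants['id'].iloc[j]!r} with alpha < 0"
        )
    with np.errstate(divide="ignore"):
        scale = np.where(het > 0.0, het ** (alpha / 2.0), 0.0)
    w = (mean_impute(g.dosages) - 2.0 * f) * scale
    m = g.n_variants
    values = (w @ w.T) / m
    kind = "grm_vr2" if alpha == -1.0 else "grm_alpha"
    return RelationshipMatrix(
        values, list(g.individual_ids), kind,
        {"alpha": alpha, "n_variants": m, "freqs_source": "sample" if freqs is None else "external"},
    )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

UNKNOWN_PARENT = "0"


@dataclass
class Pedigree:
    """Topologically ordered pedigree records (id, sire, dam; '0' = unknown).

    The constructor reorders records so parents precede offspring and raises
    on cycles or parents that never appear as individuals.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise ValueError(f"pedigree lacks column {col!r}")
            df[col] = df[col].astype(str)
        df[["sire", "dam"]] = df[["sire", "dam"]].replace({"": UNKNOWN_PARENT, "nan": UNKNOWN_PARENT})
        if df["id"].duplicated().any():
            raise ValueError("duplicated pedigree id")
        known = set(df["id"])
        for col in ("sire", "dam"):
            bad = set(df[col]) - known - {UNKNOWN_PARENT}
            if bad:
                raise ValueError(f"{col} {next(iter(bad))!r} not in pedigree")
        # Kahn topological sort, stable in input order
        order: list[int] = []
        placed: set[str] = set()
        pending = list(df.index)
        while pending:
            progressed = False
            remaining = []
            for i in pending:
                s, d = df.at[i, "sire"], df.at[i, "dam"]
                if (s == UNKNOWN_PARENT or s in placed) and (d == UNKNOWN_PARENT or d in placed):
                    order.append(i)
                    placed.add(df.at[i, "id"])
                    progressed = True
                else:
                    remaining.append(i)
            if not progressed:
                raise ValueError("pedigree contains a cycle")
            pending = remaining
        self.records = df.loc[order].reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()

    @property
    def n(self) -> int:
        return len(self.records)

    def founders(self) -> list[str]:
        r = self.records
        mask = (r["sire"] == UNKNOWN_PARENT) & (r["dam"] == UNKNOWN_PARENT)
        return r.loc[mask, "id"].tolist()

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    return Pedigree(df)


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    a_ii = 1 + a(sire, dam)/2; a_ij = (a(j, sire_i) + a(j, dam_i))/2 for j
    preceding i; an unknown parent contributes 0.
    """
    n = ped.n
    idx = {s: i for i, s in enumerate(ped.ids)}
    sire = [idx.get(s, -1) for s in ped.records["sire"]]
    dam = [idx.get(d, -1) for d in ped.records["dam"]]
    a = np.zeros((n, n))
    for i in range(n):
        si, di = sire[i], dam[i]
        for j in range(i):
            v = 0.0
            if si >= 0:
                v += a[j, si]
            if di >= 0:
                v += a[j, di]
            a[i, j] = a[j, i] = 0.5 * v
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(a, ped.ids, "pedigree_A")


# ---------------------------------------------------------------------------
# comparisons & rescaling
# ---------------------------------------------------------------------------

def grm_offdiag_correlation(k1: RelationshipMatrix, k2: RelationshipMatrix) -> float:
    """Pearson correlation of the strict lower triangles of two matrices."""
    if k1.ids != k2.ids:
        raise ValueError("matrices are over different (or differently ordered) individuals")
    if k1.n < 3:
        raise ValueError("need at least 3 individuals for an off-diagonal correlation")
    tri = np.tril_indices(k1.n, k=-1)
    return float(np.corrcoef(k1.values[tri], k2.values[tri])[0, 1])


def rescale_to_base(sigma2: float, k: RelationshipMatrix) -> float:
    """Variance expressed in the base of the analyzed population.

    Returns ``sigma2 * (mean(diag K) - mean(K))`` — the comparison rule that
    expresses a variance estimated under relationship matrix K relative to
    the average relatedness of the sample, so pedigree-based and genomic
    variances become comparable.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    factor = float(np.mean(np.diag(k.values)) - np.mean(k.values))
    if factor <= 0:
        raise ValueError(f"degenerate relationship structure: mean diag - mean = {factor:g} <= 0")
    return sigma2 * factor


# ---------------------------------------------------------------------------
# IO: full text matrix and lower-triangle binary
# ---------------------------------------------------------------------------

def write_relmat_text(k: RelationshipMatrix, path: str | Path) -> None:
    """Full-matrix tab-separated text with an id header row."""
    df = pd.DataFrame(k.values, index=k.ids, columns=k.ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_relmat_text(path: str | Path, kind: str = "grm_vr1") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    return RelationshipMatrix(values, [str(c) for c in df.columns], kind)


def write_relmat_bin(k: RelationshipMatrix, path: str | Path) -> None:
    """Row-major lower triangle (diagonal included), little-endian float32,
    with a plain-text id sidecar at ``<path>.ids``."""
    path = Path(path)
    tri = k.values[np.tril_indices(k.n)]
    tri.astype("<f4").tofile(path)
    Path(str(path) + ".ids").write_text("\n".join(k.ids) + "\n")


def read_relmat_bin(path: str | Path, kind: str = "grm_vr1") -> RelationshipMatrix:
    path = Path(path)
    ids = Path(str(path) + ".ids").read_text().split()
    n = len(ids)
    tri = np.fromfile(path, dtype="<f4").astype(float)
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{path}: expected {n * (n + 1) // 2} lower-triangle entries, found {tri.size}")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, k=-1).T
    return RelationshipMatrix(values, ids, kind)
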