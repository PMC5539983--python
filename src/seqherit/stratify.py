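"""MAF classes, LD scores, LD-score segments and MAF x LD variant groups.

Variants are first binned into seven MAF classes
(0.001-0.01, 0.01-0.05, 0.05-0.1, 0.1-0.2, 0.2-0.3, 0.3-0.4, 0.4-0.5);
intervals are lower-inclusive / upper-exclusive with the last class closed
at 0.5.  For LD-and-MAF stratified analyses each variant additionally gets
an LD score — the sum of r^2 with every other variant within a 20-Mb window
centred on it (±10 Mb; the variant itself is excluded) — chromosomes are cut
into consecutive segments holding twice the average number of variants per
100-kb window, and variants are ranked by their segment-mean LD score within
each MAF class and split into 3 or 4 equally sized LD groups (21 or 28
groups in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, mean_impute

logger = logging.getLogger("seqherit")

DEFAULT_MAF_BOUNDARIES = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class MafClassSpec:
    """Ordered MAF class boundaries; class k is [b_k, b_{k+1}) and the last
    class is closed at 0.5."""

    boundaries: tuple[float, ...] = DEFAULT_MAF_BOUNDARIES

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2:
            raise ValueError("need at least two boundaries")
        if not all(x < y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if b[0] < 0:
            raise ValueError("first boundary must be >= 0")
        if b[-1] != 0.5:
            raise ValueError("last boundary must be 0.5")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) - 1

    @property
    def labels(self) -> list[str]:
        b = self.boundaries
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(b, b[1:])]


@dataclass
class VariantPartition:
    """Assignment of each variant to one MAF class and optionally one LD group."""

    maf_class: np.ndarray  # int index per variant
    spec: MafClassSpec
    ld_group: np.ndarray | None = None  # int index per variant, within MAF class
    n_ld_groups: int = 0

    def __post_init__(self) -> None:
        self.maf_class = np.asarray(self.maf_class, dtype=int)
        if np.any(self.maf_class < 0) or np.any(self.maf_class >= self.spec.n_classes):
            raise ValueError("MAF class index out of range")

    @property
    def n_variants(self) -> int:
        return self.maf_class.size

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.maf_class, minlength=self.spec.n_classes)

    def class_labels(self) -> list[str]:
        return self.spec.labels

    def groups(self) -> list[tuple[str, np.ndarray]]:
        """(label, variant-index array) per nonempty component, MAF-major order."""
        out = []
        for c in range(self.spec.n_classes):
            in_class = np.flatnonzero(self.maf_class == c)
            if in_class.size == 0:
                continue
            if self.ld_group is None:
                out.append((self.spec.labels[c], in_class))
            else:
                for k in sorted(set(self.ld_group[in_class].tolist())):
                    idx = in_class[self.ld_group[in_class] == k]
                    out.append((f"{self.spec.labels[c]}|LD{k + 1}", idx))
        return out


def assign_maf_classes(mafs: np.ndarray, spec: MafClassSpec | None = None) -> VariantPartition:
    """Bin folded MAFs into classes; errors below the first boundary.

    A MAF below the first class boundary should already have been removed by
    QC, so it is treated as a contract violation rather than silently binned.
    """
    spec = spec or MafClassSpec()
    mafs = np.asarray(mafs, dtype=float)
    b = np.asarray(spec.boundaries)
    if np.any(mafs < b[0]):
        bad = float(mafs[mafs < b[0]][0])
        raise ValueError(f"MAF {bad} below first class boundary {b[0]} (QC should remove it)")
    if np.any(mafs > 0.5):
        raise ValueError("MAF above 0.5; frequencies must be folded")
    cls = np.searchsorted(b, mafs, side="right") - 1
    cls[mafs == 0.5] = spec.n_classes - 1  # closed upper end of the last class
    return VariantPartition(cls, spec)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over individuals non-missing in both columns; either column
    being monomorphic on that overlap is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("fewer than two jointly observed individuals")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("monomorphic column in r2 computation")
    r = float(xd @ yd) / np.sqrt(sx * sy)
    return r * r


def _standardize(g: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, column-standardized dosages; monomorphic columns -> 0."""
    x = mean_impute(g.dosages)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z


def ld_scores(g: GenotypeMatrix, window_bp: int = 20_000_000) -> pd.DataFrame:
    """Windowed LD score per variant.

    The score of variant j is the sum of r^2(j, k) over every other variant k
    on the same chromosome with |pos_k - pos_j| <= window_bp / 2.  r^2 is the
    squared correlation of mean-imputed dosages; neighbours are accumulated
    in ascending position order with plain sequential summation, so an
    all-pairs double loop using the same per-pair formula reproduces the
    scores exactly.  Monomorphic variants contribute and receive 0.
    """
    half = window_bp / 2.0
    n = g.n_individuals
    z = _standardize(g)
    scores = np.zeros(g.n_variants)
    pos_all = g.variants["pos"].to_numpy(dtype=float)
    for chrom, sub in g.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = pos_all[idx]
        for a, j in enumerate(idx):
            lo = int(np.searchsorted(pos, pos[a] - half, side="left"))
            hi = int(np.searchsorted(pos, pos[a] + half, side="right"))
            s = 0.0
            zj = z[:, j]
            for b in range(lo, hi):
                if b == a:
                    continue
                r = float(zj @ z[:, idx[b]]) / n
                s += r * r
            scores[j] = s
    out = g.variants[["id", "chrom", "pos"]].copy()
    out["ld_score"] = scores
    return out


def segment_mean_ld(table: pd.DataFrame, window_bp: int = 100_000) -> pd.DataFrame:
    """Annotate an LD-score table with segments and segment-mean LD scores.

    Per chromosome the segment size is ``s = round(2 * m_chr / n_windows)``
    where ``n_windows`` is the chromosome span (max - min position) in 100-kb
    windows (minimum 1); variants are cut into consecutive position-ordered
    runs of ``s`` (the last run may be shorter).
    """
    table = table.copy()
    table["segment"] = ""
    table["segment_mean_ld"] = np.nan
    for chrom, sub in table.groupby("chrom", sort=False):
        m_chr = len(sub)
        span = float(sub["pos"].max() - sub["pos"].min())
        n_windows = max(1, int(np.ceil(span / window_bp)))
        s = int(round(2.0 * m_chr / n_windows))
        if s < 1:
            raise ValueError(
                f"chromosome {chrom}: segment size {s} < 1 "
                f"({m_chr} variants over {n_windows} windows)"
            )
        order = sub.sort_values("pos", kind="stable").index
        seg_of = np.arange(len(order)) // s
        seg_ids = [f"{chrom}:{k}" for k in seg_of]
        table.loc[order, "segment"] = seg_ids
        seg_series = pd.Series(seg_of, index=order)
        means = table.loc[order, "ld_score"].groupby(seg_series).transform("mean")
        table.loc[order, "segment_mean_ld"] = means
    return table


def stratify_ld_groups(
    partition: VariantPartition,
    table: pd.DataFrame,
    n_groups: int,
) -> VariantPartition:
    """Split each MAF class into ``n_groups`` equally sized LD groups.

    Within a class, variants are stably sorted by (segment-mean LD score,
    chromosome, position) and cut into contiguous groups whose sizes differ
    by at most one; remainders go to the low-LD end.  A class with fewer
    variants than ``n_groups`` keeps a single group (warning logged).
    """
    if n_groups not in (3, 4):
        raise ValueError("n_groups must be 3 or 4")
    if "segment_mean_ld" not in table.columns or table["segment_mean_ld"].isna().any():
        raise ValueError("segment means missing; run segment_mean_ld first")
    if len(table) != partition.n_variants:
        raise ValueError("LD table and partition cover different variant sets")
    mean_ld = table["segment_mean_ld"].to_numpy()
    pos = table["pos"].to_numpy()
    chrom = table["chrom"].astype(str).to_numpy()
    ld_group = np.zeros(partition.n_variants, dtype=int)
    for c in range(partition.spec.n_classes):
        in_class = np.flatnonzero(partition.maf_class == c)
        if in_class.size == 0:
            continue
        if in_class.size < n_groups:
            logger.warning(
                "MAF class %s has %d (<%d) variants; kept as a single LD group",
                partition.spec.labels[c], in_class.size, n_groups,
            )
            ld_group[in_class] = 0
            continue
        order = in_class[np.lexsort((pos[in_class], chrom[in_class], mean_ld[in_class]))]
        for k, chunk in enumerate(np.array_split(order, n_groups)):
            ld_group[chunk] = k
    return VariantPartition(partition.maf_class, partition.spec, ld_group, n_groups)


def partition_table(
    partition: VariantPartition,
    variants: pd.DataFrame,
    mafs: np.ndarray,
    ld_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabular export: id, chrom, pos, MAF, MAF class, LD annotations."""
    out = variants[["id", "chrom", "pos"]].copy()
    out["maf"] = np.asarray(mafs, dtype=float)
    out["maf_class"] = [partition.spec.labels[c] for c in partition.maf_class]
    if ld_table is not None:
        for col in ("ld_score", "segment", "segment_mean_ld"):
            if col in ld_table.columns:
                out[col] = ld_table[col].to_numpy()
    if partition.ld_group is not None:
        out["ld_group"] = partition.ld_group + 1
    return out
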