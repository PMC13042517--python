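"""Cell-level quality control, normalization, and Wilcoxon differential expression.

QC keeps cells whose detected-gene count lies strictly between the bounds
and whose mitochondrial fraction is strictly below the cap. Normalization
is library-size correction to a fixed scale factor followed by log1p.
Differential expression is a two-sided Wilcoxon rank-sum on normalized
values with Seurat-style detection-fraction and log-fold-change
pre-filters; small groups use exact enumeration of the rank-sum null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from escctme.core_io import ExpressionBundle, ValidationError


class EmptyResultWarning(UserWarning):
    """All cells (or all genes) were removed by a filtering step."""


@dataclass(frozen=True)
class QCParams:
    """Cell-quality thresholds: detected-gene window and mitochondrial cap."""

    min_genes: int = 300
    max_genes: int = 8000
    max_mito: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ValidationError("need 0 < min_genes < max_genes")
        if not 0 < self.max_mito <= 1:
            raise ValidationError("max_mito must lie in (0, 1]")


@dataclass(frozen=True)
class NormParams:
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")


@dataclass(frozen=True)
class DEParams:
    """Detection and fold-change pre-filters for marker testing.

    ``min_pct=0.25, logfc_threshold=0.25`` is the cluster-marker default;
    ``0.001/0.001`` is the near-exhaustive two-condition setting.
    """

    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValidationError("min_pct must lie in [0, 1]")
        if self.logfc_threshold < 0:
            raise ValidationError("logfc_threshold must be >= 0")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    pct_in: float
    pct_out: float
    p_value: float
    p_adjusted: float


def _detected_and_mito(bundle: ExpressionBundle, mito_prefix: str):
    counts = sp.csc_matrix(bundle.counts)
    n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    names = bundle.gene_symbols if bundle.gene_symbols is not None else bundle.gene_ids
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in names])
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_counts = np.asarray(counts[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    return n_detected, mito_frac


def filter_cells(bundle: ExpressionBundle, params: QCParams = QCParams()) -> ExpressionBundle:
    """Drop low-quality cells; genes and cell order are preserved.

    A cell is kept iff min_genes < n_genes_detected < max_genes (strict)
    and mito_fraction < max_mito (strict). Missing per-cell QC metrics are
    computed from counts (mitochondrial genes by symbol prefix).
    """
    meta = bundle.cell_meta
    n_detected, mito_frac = _detected_and_mito(bundle, params.mito_prefix)
    if meta["n_genes_detected"].notna().all():
        n_detected = meta["n_genes_detected"].to_numpy(dtype=float)
    if meta["mito_fraction"].notna().all():
        mito_frac = meta["mito_fraction"].to_numpy(dtype=float)
    keep = (
        (n_detected > params.min_genes)
        & (n_detected < params.max_genes)
        & (mito_frac < params.max_mito)
    )
    out = bundle.subset_cells(keep)
    out.cell_meta = out.cell_meta.assign(
        n_genes_detected=n_detected[keep].astype(int), mito_fraction=mito_frac[keep]
    )
    if bundle.n_cells and not out.n_cells:
        warnings.warn(
            "quality control removed every cell", EmptyResultWarning, stacklevel=2
        )
    return out


def normalize(bundle: ExpressionBundle, params: NormParams = NormParams()) -> ExpressionBundle:
    """Fill ``bundle.normalized`` with ln(1 + count / cell_total * scale).

    Counts are untouched. Cells with zero total are an error (QC should
    have removed them).
    """
    counts = sp.csc_matrix(bundle.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cells with zero total counts: {bundle.cell_ids[zero][:3].tolist()}"
        )
    norm = counts.multiply(params.scale_factor / totals).tocsr()
    norm.data = np.log1p(norm.data)
    bundle.normalized = sp.csr_matrix(norm)
    return bundle


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Handles ties through midranks; feasible for combined sizes where
    C(n+m, n) is small (both groups <= 8 by the caller's dispatch rule).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    observed = ranks[:n].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n)])
    mean = sums.mean()
    extreme = np.sum(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-12)
    return float(extreme / len(sums))


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) <= 8 and len(y) <= 8:
        return _exact_ranksum_p(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.pvalue)


def wilcoxon_de(
    bundle: ExpressionBundle,
    group_in: np.ndarray,
    group_out: np.ndarray,
    params: DEParams = DEParams(),
) -> list[DERecord]:
    """Two-sided Wilcoxon rank-sum DE between two disjoint cell masks.

    A gene is tested only if max(pct_in, pct_out) >= min_pct and
    |log2fc| >= logfc_threshold, where log2fc compares expm1-means of
    normalized expression with a pseudocount. Bonferroni correction is
    applied over the genes actually tested.
    """
    if bundle.normalized is None:
        raise ValidationError("normalize the bundle before differential expression")
    group_in = np.asarray(group_in, dtype=bool)
    group_out = np.asarray(group_out, dtype=bool)
    if not group_in.any() or not group_out.any():
        raise ValidationError("both cell masks must be nonempty")
    if (group_in & group_out).any():
        raise ValidationError("cell masks must be disjoint")

    norm = sp.csr_matrix(bundle.normalized)
    X_in = norm[:, group_in].toarray()
    X_out = norm[:, group_out].toarray()
    n_in, n_out = X_in.shape[1], X_out.shape[1]

    pct_in = (X_in > 0).mean(axis=1)
    pct_out = (X_out > 0).mean(axis=1)
    mean_in = np.expm1(X_in).mean(axis=1)
    mean_out = np.expm1(X_out).mean(axis=1)
    log2fc = np.log2((mean_in + params.pseudocount) / (mean_out + params.pseudocount))

    testable = (np.maximum(pct_in, pct_out) >= params.min_pct) & (
        np.abs(log2fc) >= params.logfc_threshold
    )
    tested = np.flatnonzero(testable)
    n_tested = tested.size
    records: list[DERecord] = []
    for g in tested:
        p = _ranksum_p(X_in[g], X_out[g])
        records.append(
            DERecord(
                gene_id=str(bundle.gene_ids[g]),
                log2fc=float(log2fc[g]),
                pct_in=float(pct_in[g]),
                pct_out=float(pct_out[g]),
                p_value=p,
                p_adjusted=min(1.0, p * n_tested),
            )
        )
    records.sort(key=lambda r: (r.p_value, -r.log2fc, r.gene_id))
    return records


@dataclass
class GeneSet:
    """A named gene list, optionally flagged short of the requested size."""

    name: str
    genes: list[str]
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def signature_from_de(
    de_records: list[DERecord], n: int = 40, name: str = "signature"
) -> GeneSet:
    """Top-``n`` up-regulated genes by log2 fold change.

    Ties on log2fc break by smaller p-value, then lexicographic gene id.
    When fewer than ``n`` genes are up-regulated, all are returned and the
    set is flagged ``truncated``.
    """
    if not de_records:
        raise ValidationError("no DE records to build a signature from")
    up = [r for r in de_records if r.log2fc > 0]
    up.sort(key=lambda r: (-r.log2fc, r.p_value, r.gene_id))
    chosen = up[:n]
    return GeneSet(
        name=name, genes=[r.gene_id for r in chosen], truncated=len(chosen) < n
    )


def de_records_frame(records: list[DERecord]) -> pd.DataFrame:
    """DE results as a DataFrame (the TSV export layout)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "log2fc": r.log2fc,
                "pct_in": r.pct_in,
                "pct_out": r.pct_out,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in records
        ]
    )
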