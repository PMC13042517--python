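"""Gene-signature scoring: per-cell module scores, single-sample rank scores
for bulk matrices, and preranked gene-set enrichment with a resampling null.

The per-cell module score follows the expression-bin control-gene scheme
(signature mean minus pooled-control mean). The bulk score is a weighted
Kolmogorov-Smirnov running-sum statistic computed per sample on expression
ranks. Preranked GSEA reports the signed maximum deviation of the weighted
hit/miss CDF difference, with a null built from random gene sets of equal
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from escctme.core_io import ExpressionBundle, ValidationError


@dataclass(frozen=True)
class ScoreParams:
    """Module-score settings: expression bins and controls per signature gene."""

    n_bins: int = 24
    n_ctrl: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValidationError("n_ctrl must be >= 1")


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene, binned on average expression.

    Ranks (with stable tie-breaking on gene order) are cut into n_bins
    near-equal chunks, so every bin is populated whenever n_genes >= n_bins.
    """
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(avg.size)
    return (ranks * n_bins) // avg.size


def module_score(
    bundle: ExpressionBundle,
    gene_set,
    params: ScoreParams = ScoreParams(),
) -> pd.Series:
    """Per-cell signature score: signature mean minus pooled-control mean.

    Genes are binned by average normalized expression across cells; for
    each signature gene, ``n_ctrl`` control genes are drawn (with
    replacement, seeded) from its bin. Returns a Series indexed by cell id.
    """
    if bundle.normalized is None:
        raise ValidationError("normalize the bundle before scoring")
    genes = list(gene_set)
    idx = []
    missing = []
    for g in genes:
        try:
            idx.append(bundle.gene_index(g))
        except KeyError:
            missing.append(g)
    if not idx:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    X = sp.csr_matrix(bundle.normalized)
    avg = np.asarray(X.mean(axis=1)).ravel()
    bins = _expression_bins(avg, params.n_bins)
    rng = np.random.default_rng(params.rng_seed)

    ctrl_idx: list[np.ndarray] = []
    for g in idx:
        pool = np.flatnonzero(bins == bins[g])
        ctrl_idx.append(rng.choice(pool, size=params.n_ctrl, replace=True))
    controls = np.concatenate(ctrl_idx)

    sig_mean = np.asarray(X[idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[controls].mean(axis=0)).ravel()
    return pd.Series(sig_mean - ctrl_mean, index=bundle.cell_ids, name="module_score")


def _single_sample_stat(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Weighted KS running-sum score for one sample.

    Genes are ordered by expression descending; the hit CDF is weighted by
    rank^alpha (rank counted from the bottom, so top genes weigh most), the
    miss CDF is uniform; the score is the mean running difference, a
    normalized integral comparable across samples sharing a gene universe.
    """
    n = values.size
    order = np.argsort(-values, kind="stable")
    hits = in_set[order]
    rank_from_bottom = np.arange(n, 0, -1, dtype=float)
    w = np.where(hits, rank_from_bottom**alpha, 0.0)
    w_total = w.sum()
    n_miss = n - hits.sum()
    if w_total == 0 or n_miss == 0:
        return 0.0
    hit_cdf = np.cumsum(w) / w_total
    miss_cdf = np.cumsum(~hits) / n_miss
    return float(np.mean(hit_cdf - miss_cdf))


def rank_signature_score(
    bulk_matrix: pd.DataFrame, gene_set, alpha: float = 0.25
) -> pd.Series:
    """Single-sample rank-based signature score for a samples x genes matrix.

    Constant samples (all genes equal) score exactly 0 and raise a tie
    warning attribute on the returned Series (``.attrs['tied_samples']``).
    """
    genes = list(gene_set)
    in_set = bulk_matrix.columns.isin(genes)
    if in_set.sum() < 2:
        raise ValidationError("need >= 2 signature genes present in the bulk matrix")
    values = bulk_matrix.to_numpy(dtype=float)
    scores = np.zeros(values.shape[0])
    tied = []
    for i in range(values.shape[0]):
        if np.ptp(values[i]) == 0:
            tied.append(bulk_matrix.index[i])
            continue
        scores[i] = _single_sample_stat(values[i], np.asarray(in_set), alpha)
    out = pd.Series(scores, index=bulk_matrix.index, name="signature_score")
    out.attrs["tied_samples"] = tied
    return out


@dataclass
class GseaResult:
    """Preranked enrichment outcome: ES, normalized ES, p and leading edge."""

    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_perm: int

    def __post_init__(self) -> None:
        if not -1 <= self.es <= 1:
            raise ValidationError("ES must lie in [-1, 1]")


def _running_es(weights: np.ndarray, hits: np.ndarray, weight_exp: float):
    """Running hit-minus-miss sum; returns (ES, index of extremum)."""
    w = np.where(hits, np.abs(weights) ** weight_exp, 0.0)
    w_total = w.sum()
    n_miss = (~hits).sum()
    if w_total == 0:
        raise ValidationError("gene set does not intersect the ranking")
    if w_total > 0 and n_miss == 0:
        return 1.0, len(hits) - 1
    running = np.cumsum(np.where(hits, w / w_total, -1.0 / n_miss))
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def preranked_gsea(
    ranked_genes: pd.Series,
    gene_set,
    weight_exp: float = 1.0,
    n_perm: int = 999,
    rng_seed: int = 0,
) -> GseaResult:
    """Preranked GSEA on a gene -> weight Series sorted by decreasing weight.

    ES is the signed maximum deviation of the weighted hit CDF minus miss
    CDF. The null resamples random gene sets of the same size from the
    ranking; NES divides ES by the mean |null ES| of matching sign; the
    one-sided p is (1 + #{null as or more extreme})/(1 + n_perm).
    """
    ranked_genes = ranked_genes.sort_values(ascending=False, kind="stable")
    if ranked_genes.index.has_duplicates:
        raise ValidationError("ranked gene list has duplicate ids")
    genes = np.asarray(ranked_genes.index)
    weights = ranked_genes.to_numpy(dtype=float)
    hits = np.isin(genes, list(gene_set))
    k = int(hits.sum())
    if k < 2:
        raise ValidationError("gene set shares < 2 genes with the ranking")

    es, peak = _running_es(weights, hits, weight_exp)
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hits[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hits[peak:]) if h]

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    n = genes.size
    for i in range(n_perm):
        null_hits = np.zeros(n, dtype=bool)
        null_hits[rng.choice(n, size=k, replace=False)] = True
        null[i], _ = _running_es(weights, null_hits, weight_exp)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.nan
    nes = es / denom if denom and not np.isnan(denom) else np.nan
    # one-sided p against the same-sign tail of the null (the convention
    # that keeps null p-values uniform for a signed statistic)
    extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
    p = (1 + extreme) / (1 + same_sign.size)
    return GseaResult(es=es, nes=float(nes), p_value=p, leading_edge=leading, n_perm=n_perm)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (used when scoring more than one gene set)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)
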