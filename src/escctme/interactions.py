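"""Ligand-receptor interaction scoring between annotated cell clusters.

The score for a pair is the product of the mean normalized ligand
expression in the sender cluster and the mean normalized receptor
expression in the receiver. Significance comes from a one-sided
permutation test that shuffles cluster labels across all cells (sizes
preserved). A cohort-level variant for bulk data multiplies ligand and
receptor expression by min-max rescaled signature scores standing in for
the sender/receiver cell fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from escctme.core_io import ExpressionBundle, ValidationError
from escctme.scoring import rank_signature_score


class SelfPairWarning(UserWarning):
    """Ligand and receptor are the same gene; the pair is scored anyway."""


@dataclass(frozen=True)
class LRPair:
    name: str
    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValidationError("both ligand and receptor must be named")
        if self.ligand == self.receptor:
            warnings.warn(
                f"pair {self.name!r} has ligand == receptor", SelfPairWarning, stacklevel=3
            )


@dataclass(frozen=True)
class InteractionResult:
    pair: LRPair
    sender: str
    receiver: str
    score: float
    p_value: float
    significant: bool
    alpha: float
    n_perm: int


def _gene_vector(bundle: ExpressionBundle, gene: str) -> np.ndarray:
    try:
        g = bundle.gene_index(gene)
    except KeyError:
        raise ValidationError(f"gene {gene!r} absent from the expression matrix")
    if bundle.normalized is None:
        raise ValidationError("normalize the bundle before interaction scoring")
    return np.asarray(sp.csr_matrix(bundle.normalized)[g].todense()).ravel()


def lr_score(
    bundle: ExpressionBundle,
    clusters: pd.Series,
    pair: LRPair,
    sender: str,
    receiver: str,
) -> float:
    """Mean ligand expression in sender x mean receptor expression in receiver."""
    clusters = pd.Series(np.asarray(clusters), index=bundle.cell_ids)
    s_mask = (clusters == sender).to_numpy()
    r_mask = (clusters == receiver).to_numpy()
    if not s_mask.any() or not r_mask.any():
        raise ValidationError("sender and receiver clusters must be nonempty")
    lig = _gene_vector(bundle, pair.ligand)
    rec = _gene_vector(bundle, pair.receptor)
    return float(lig[s_mask].mean() * rec[r_mask].mean())


def lr_permutation_test(
    bundle: ExpressionBundle,
    clusters: pd.Series,
    pair: LRPair,
    sender: str,
    receiver: str,
    n_perm: int = 999,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> InteractionResult:
    """One-sided permutation test of the ligand-receptor score.

    Cluster labels are shuffled across all cells (cluster sizes kept);
    p = (1 + #{null >= observed}) / (1 + n_perm), never exactly zero.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    clusters = pd.Series(np.asarray(clusters), index=bundle.cell_ids)
    s_mask = (clusters == sender).to_numpy()
    r_mask = (clusters == receiver).to_numpy()
    if not s_mask.any() or not r_mask.any():
        raise ValidationError("sender and receiver clusters must be nonempty")
    lig = _gene_vector(bundle, pair.ligand)
    rec = _gene_vector(bundle, pair.receptor)
    observed = lig[s_mask].mean() * rec[r_mask].mean()

    rng = np.random.default_rng(rng_seed)
    n = len(clusters)
    n_s, n_r = int(s_mask.sum()), int(r_mask.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = lig[perm[:n_s]].mean() * rec[perm[n_s : n_s + n_r]].mean()
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return InteractionResult(
        pair=pair,
        sender=sender,
        receiver=receiver,
        score=float(observed),
        p_value=float(p),
        significant=p < alpha,
        alpha=alpha,
        n_perm=n_perm,
    )


def count_significant_pairs(
    results: list[InteractionResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Count significant pairs per (sender, receiver) cluster pair."""
    alphas = {r.alpha for r in results}
    if len(alphas) > 1:
        raise ValidationError("results were tested at different alpha levels")
    rows = [
        {"sender": r.sender, "receiver": r.receiver, "significant": r.p_value < alpha}
        for r in results
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["sender", "receiver", "n_significant"])
    out = (
        df.groupby(["sender", "receiver"], sort=True)["significant"]
        .sum()
        .astype(int)
        .rename("n_significant")
        .reset_index()
    )
    return out


def adjusted_interaction_score(
    bulk_matrix: pd.DataFrame,
    pair: LRPair,
    sender_signature,
    receiver_signature,
    alpha: float = 0.25,
) -> pd.Series:
    """Cell-fraction-adjusted interaction score for bulk cohorts.

    Per sample: ligand expression x receptor expression x f_sender x
    f_receiver, where each f is the sender/receiver signature score
    min-max rescaled to [0, 1] across the cohort — a surrogate for the
    unmeasured cell fractions. The fractions are computed on the matrix
    with the pair's own genes removed, so the score is monotone in ligand
    and receptor expression.
    """
    if len(bulk_matrix) < 2:
        raise ValidationError("cohort rescaling needs >= 2 samples")
    for gene in (pair.ligand, pair.receptor):
        if gene not in bulk_matrix.columns:
            raise ValidationError(f"gene {gene!r} absent from the bulk matrix")
    background = bulk_matrix.drop(columns=[pair.ligand, pair.receptor], errors="ignore")

    def _fraction(sig) -> np.ndarray:
        s = rank_signature_score(background, sig, alpha=alpha).to_numpy()
        lo, hi = s.min(), s.max()
        return np.zeros_like(s) if hi == lo else (s - lo) / (hi - lo)

    f_s = _fraction(sender_signature)
    f_r = _fraction(receiver_signature)
    score = (
        bulk_matrix[pair.ligand].to_numpy()
        * bulk_matrix[pair.receptor].to_numpy()
        * f_s
        * f_r
    )
    return pd.Series(score, index=bulk_matrix.index, name=f"{pair.name}_score")


def read_lr_pairs(path) -> list[LRPair]:
    """Read a 3-column TSV of (name, ligand, receptor)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "ligand", "receptor"])
    return [LRPair(r.name, r.ligand, r.receptor) for r in df.itertuples(index=False)]
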