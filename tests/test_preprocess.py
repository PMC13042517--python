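import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from escctme.core_io import ValidationError
from escctme.preprocess import (
    DEParams,
    DERecord,
    EmptyResultWarning,
    NormParams,
    QCParams,
    filter_cells,
    normalize,
    signature_from_de,
    wilcoxon_de,
)
from tests.conftest import make_bundle, normalized_bundle


def exact_ranksum_oracle(x, y):
    """Independent exact two-sided rank-sum p: enumerate every assignment."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    observed = ranks[: n].sum()
    mean = ranks.sum() * n / len(pooled)
    count = total = 0
    for combo in combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestFilterCells:
    def _qc_bundle(self, n_genes, mito):
        counts = np.ones((3, len(n_genes)), dtype=int)
        return make_bundle(
            counts, meta={"n_genes_detected": n_genes, "mito_fraction": mito}
        )

    def test_strict_boundaries(self):
        # (n_genes, mito): only strictly inside the window survives
        bundle = self._qc_bundle(
            [500, 300, 500, 9000, 4000], [0.10, 0.10, 0.25, 0.05, 0.19]
        )
        out = filter_cells(bundle)
        assert list(out.cell_ids) == ["c0", "c4"]

    def test_cell_below_min_genes_removed(self):
        bundle = self._qc_bundle([250, 500], [0.0, 0.0])
        out = filter_cells(bundle)
        assert list(out.cell_ids) == ["c1"]

    def test_empty_bundle_passes_through(self):
        bundle = make_bundle(np.zeros((3, 0), dtype=int))
        assert filter_cells(bundle).n_cells == 0

    def test_all_removed_warns(self):
        bundle = self._qc_bundle([100, 100], [0.0, 0.0])
        with pytest.warns(EmptyResultWarning):
            out = filter_cells(bundle)
        assert out.n_cells == 0

    def test_idempotent_and_metrics_computed_from_counts(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(40, 30))
        symbols = [f"MT-{i}" if i < 4 else f"S{i}" for i in range(40)]
        bundle = make_bundle(counts, gene_symbols=symbols)
        params = QCParams(min_genes=5, max_genes=35, max_mito=0.2)
        once = filter_cells(bundle, params)
        twice = filter_cells(once, params)
        assert list(once.cell_ids) == list(twice.cell_ids)
        meta = once.cell_meta
        assert ((meta["n_genes_detected"] > 5) & (meta["n_genes_detected"] < 35)).all()
        assert (meta["mito_fraction"] < 0.2).all()

    def test_genes_never_removed(self):
        bundle = self._qc_bundle([500, 100], [0.0, 0.0])
        assert filter_cells(bundle).n_genes == bundle.n_genes


class TestNormalize:
    def test_closed_form(self):
        bundle = make_bundle(np.array([[1], [1], [2]]))
        normalize(bundle, NormParams(scale_factor=10_000))
        got = bundle.normalized.toarray().ravel()
        expected = [math.log(2501), math.log(2501), math.log(5001)]
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        np.testing.assert_allclose(got, [7.8244, 7.8244, 8.5174], atol=5e-5)

    def test_all_zero_gene_stays_zero(self):
        bundle = make_bundle(np.array([[0, 0], [1, 2]]))
        normalize(bundle)
        assert bundle.normalized.toarray()[0].tolist() == [0.0, 0.0]

    def test_per_cell_scale_invariance(self):
        a = make_bundle(np.array([[1], [2], [3]]))
        b = make_bundle(np.array([[2], [4], [6]]))
        normalize(a)
        normalize(b)
        np.testing.assert_allclose(a.normalized.toarray(), b.normalized.toarray())

    def test_column_sums_equal_scale_factor(self):
        rng = np.random.default_rng(7)
        bundle = make_bundle(rng.integers(0, 10, size=(50, 20)) + 1)
        normalize(bundle, NormParams(scale_factor=5000))
        sums = np.expm1(bundle.normalized.toarray()).sum(axis=0)
        np.testing.assert_allclose(sums, 5000, rtol=1e-8)

    def test_zero_total_cell_named(self):
        bundle = make_bundle(np.array([[0, 1], [0, 2]]))
        with pytest.raises(ValidationError, match="c0"):
            normalize(bundle)

    def test_counts_untouched(self):
        bundle = make_bundle(np.array([[1, 2], [3, 4]]))
        before = bundle.counts.toarray().copy()
        normalize(bundle)
        np.testing.assert_array_equal(bundle.counts.toarray(), before)


class TestWilcoxonDE:
    def test_exact_p_for_separated_triples(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        bundle = normalized_bundle(values)
        mask_in = np.array([True] * 3 + [False] * 3)
        recs = wilcoxon_de(
            bundle, mask_in, ~mask_in, DEParams(min_pct=0, logfc_threshold=0)
        )
        assert len(recs) == 1
        assert recs[0].p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_excluded_at_positive_threshold(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        bundle = normalized_bundle(values)
        mask_in = np.array([True] * 3 + [False] * 3)
        recs = wilcoxon_de(
            bundle, mask_in, ~mask_in, DEParams(min_pct=0, logfc_threshold=0.01)
        )
        assert recs == []

    def test_min_pct_filter(self):
        # detected in 10% of each group of 10 cells: below min_pct 0.25
        values = np.zeros((1, 20))
        values[0, 0] = 5.0
        values[0, 10] = 1.0
        bundle = normalized_bundle(values)
        mask_in = np.array([True] * 10 + [False] * 10)
        recs = wilcoxon_de(
            bundle, mask_in, ~mask_in, DEParams(min_pct=0.25, logfc_threshold=0)
        )
        assert recs == []

    def test_disjointness_and_empty_mask_errors(self):
        bundle = normalized_bundle(np.ones((2, 4)))
        with pytest.raises(ValidationError):
            wilcoxon_de(bundle, np.array([True] * 4), np.array([True] * 4))
        with pytest.raises(ValidationError):
            wilcoxon_de(bundle, np.zeros(4, bool), np.ones(4, bool))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_small_group_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_in, n_out = rng.integers(3, 9, size=2)
        values = rng.poisson(2.0, size=(5, n_in + n_out)).astype(float)
        bundle = normalized_bundle(values)
        mask_in = np.zeros(n_in + n_out, bool)
        mask_in[:n_in] = True
        recs = wilcoxon_de(
            bundle, mask_in, ~mask_in, DEParams(min_pct=0, logfc_threshold=0)
        )
        for rec in recs:
            g = int(rec.gene_id[1:])
            expected = exact_ranksum_oracle(values[g, :n_in], values[g, n_in:])
            assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_null_type_one_error_in_binomial_band(self):
        # both groups drawn from one NB distribution; large groups exercise
        # the tie-corrected normal approximation
        rng = np.random.default_rng(123)
        n_genes = 1000
        values = np.log1p(rng.negative_binomial(2, 0.3, size=(n_genes, 40))).astype(float)
        bundle = normalized_bundle(values)
        mask_in = np.zeros(40, bool)
        mask_in[:20] = True
        recs = wilcoxon_de(
            bundle, mask_in, ~mask_in, DEParams(min_pct=0, logfc_threshold=0)
        )
        assert len(recs) == n_genes
        hits = sum(r.p_value < 0.05 for r in recs)
        lo = stats.binom.ppf(0.005, n_genes, 0.05)
        hi = stats.binom.ppf(0.995, n_genes, 0.05)
        assert lo <= hits <= hi

    def test_bonferroni_over_tested_genes(self):
        rng = np.random.default_rng(9)
        values = rng.poisson(3.0, size=(10, 30)).astype(float)
        bundle = normalized_bundle(values)
        mask_in = np.zeros(30, bool)
        mask_in[:15] = True
        recs = wilcoxon_de(bundle, mask_in, ~mask_in, DEParams(min_pct=0, logfc_threshold=0))
        n_tested = len(recs)
        for r in recs:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * n_tested))
            assert r.p_adjusted >= r.p_value


class TestSignatureFromDE:
    def _rec(self, gene, fc, p=0.01):
        return DERecord(gene, fc, 0.5, 0.1, p, p)

    def test_top_40_of_50(self):
        recs = [self._rec(f"g{i:02d}", fc=i * 0.1 + 0.1) for i in range(50)]
        sig = signature_from_de(recs, n=40)
        assert len(sig) == 40
        assert not sig.truncated
        # the 40 largest fold changes are g10..g49
        assert set(sig.genes) == {f"g{i:02d}" for i in range(10, 50)}

    def test_short_set_flagged(self):
        recs = [self._rec(f"g{i}", fc=1.0 + i) for i in range(10)]
        sig = signature_from_de(recs, n=40)
        assert len(sig) == 10 and sig.truncated

    def test_tie_breaks_by_smaller_p(self):
        recs = [self._rec("gA", 1.0, p=0.5), self._rec("gB", 1.0, p=0.001)]
        sig = signature_from_de(recs, n=1)
        assert sig.genes == ["gB"]

    def test_downregulated_genes_never_included(self):
        recs = [self._rec("up", 2.0), self._rec("down", -3.0)]
        sig = signature_from_de(recs, n=40)
        assert sig.genes == ["up"]
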