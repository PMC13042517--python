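import math

import numpy as np
import pandas as pd
import pytest

from escctme.core_io import ContigRecord, ValidationError
from escctme.repertoire import (
    ClonotypeTable,
    FateParams,
    call_clonotypes,
    classify_clone_fate,
    clonotype_overlap,
    expansion_classes,
    expansion_index,
    fate_response_association,
    fate_sensitivity,
)


def contig(barcode, chain, nt, umis=1, productive=True, full_length=True):
    return ContigRecord(
        barcode=barcode,
        chain=chain,
        cdr3_nt=nt,
        cdr3_aa=nt[:3],
        productive=productive,
        full_length=full_length,
        umis=umis,
    )


def clono_table(rows):
    """rows: (cell, clone, patient, timepoint, response, cluster)."""
    df = pd.DataFrame(
        rows, columns=["cell_id", "clonotype_id", "patient_id", "timepoint", "response", "cluster"]
    )
    df["cdr3a"] = df["clonotype_id"]
    df["cdr3b"] = df["clonotype_id"]
    return ClonotypeTable(df)


class TestCallClonotypes:
    def test_paired_cell_assigned(self):
        t = call_clonotypes([contig("b1", "TRA", "AAA"), contig("b1", "TRB", "CCC")])
        assert len(t) == 1
        assert t.data.loc[0, "cdr3a"] == "AAA" and t.data.loc[0, "cdr3b"] == "CCC"

    def test_unpaired_cell_dropped(self):
        t = call_clonotypes([contig("b1", "TRB", "CCC")])
        assert len(t) == 0

    def test_nonproductive_chain_ignored(self):
        t = call_clonotypes(
            [contig("b1", "TRA", "AAA", productive=False), contig("b1", "TRB", "CCC")]
        )
        assert len(t) == 0

    def test_highest_umi_chain_wins(self):
        t = call_clonotypes(
            [
                contig("b1", "TRA", "AAA", umis=5),
                contig("b1", "TRA", "GGG", umis=9),
                contig("b1", "TRB", "CCC", umis=2),
            ]
        )
        assert t.data.loc[0, "cdr3a"] == "GGG"

    def test_same_pair_same_clonotype_id(self):
        t = call_clonotypes(
            [
                contig("b1", "TRA", "AAA"),
                contig("b1", "TRB", "CCC"),
                contig("b2", "TRA", "AAA"),
                contig("b2", "TRB", "CCC"),
                contig("b3", "TRA", "TTT"),
                contig("b3", "TRB", "CCC"),
            ]
        )
        ids = t.data.set_index("cell_id")["clonotype_id"]
        assert ids["b1"] == ids["b2"] != ids["b3"]

    def test_aa_level_merges_synonymous(self):
        # same first-3-nt prefix (our toy aa) but different full nt
        recs = [
            contig("b1", "TRA", "AAATTT"),
            contig("b1", "TRB", "CCCGGG"),
            contig("b2", "TRA", "AAACCC"),
            contig("b2", "TRB", "CCCTTT"),
        ]
        nt = call_clonotypes(recs, level="nt")
        aa = call_clonotypes(recs, level="aa")
        assert nt.data["clonotype_id"].nunique() == 2
        assert aa.data["clonotype_id"].nunique() == 1


class TestExpansion:
    def test_cells_in_expanded_clones_fraction(self):
        rows = [(f"c{i}", "A", "p1", "PreT", "MPR", "T") for i in range(5)]
        rows += [("c5", "B", "p1", "PreT", "MPR", "T"), ("c6", "C", "p1", "PreT", "MPR", "T")]
        out = expansion_classes(clono_table(rows), by=["cluster"])
        assert out.loc[0, "frac_expanded"] == pytest.approx(5 / 7)
        assert out.loc[0, "frac_small"] == pytest.approx(2 / 7)

    def test_all_singletons_zero(self):
        rows = [(f"c{i}", f"K{i}", "p1", "PreT", "MPR", "T") for i in range(4)]
        out = expansion_classes(clono_table(rows), by=["cluster"])
        assert out.loc[0, "frac_expanded"] == 0.0

    def test_single_clone_of_three_is_one(self):
        rows = [(f"c{i}", "A", "p1", "PreT", "MPR", "T") for i in range(3)]
        out = expansion_classes(clono_table(rows), by=["cluster"])
        assert out.loc[0, "frac_expanded"] == 1.0

    def test_clones_not_merged_across_patients(self):
        # clone A has 2 cells in each patient: size 2 within patient -> small
        rows = [("c1", "A", "p1", "PreT", "MPR", "T"), ("c2", "A", "p1", "PreT", "MPR", "T")]
        rows += [("c3", "A", "p2", "PreT", "MPR", "T"), ("c4", "A", "p2", "PreT", "MPR", "T")]
        out = expansion_classes(clono_table(rows), by=["cluster"])
        assert out.loc[0, "frac_expanded"] == 0.0

    def test_expansion_index_hand_computed(self):
        rows = [("c0", "A", "p1", "PreT", "MPR", "T"), ("c1", "A", "p1", "PreT", "MPR", "T")]
        rows += [("c2", "B", "p1", "PreT", "MPR", "T"), ("c3", "C", "p1", "PreT", "MPR", "T")]
        idx = expansion_index(clono_table(rows))
        H = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert idx == pytest.approx(1 - H / math.log(3), abs=1e-10)
        assert idx == pytest.approx(0.0536, abs=5e-4)

    def test_expansion_index_extremes(self):
        singletons = [(f"c{i}", f"K{i}", "p1", "PreT", "MPR", "T") for i in range(5)]
        assert expansion_index(clono_table(singletons)) == pytest.approx(0.0)
        mono = [(f"c{i}", "A", "p1", "PreT", "MPR", "T") for i in range(10)]
        assert expansion_index(clono_table(mono)) == 1.0
        tiny = [("c0", "A", "p1", "PreT", "MPR", "T")]
        assert math.isnan(expansion_index(clono_table(tiny)))

    def test_expansion_index_range_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sizes = rng.integers(1, 6, size=rng.integers(2, 8))
            rows, c = [], 0
            for k, s in enumerate(sizes):
                for _ in range(s):
                    rows.append((f"c{c}", f"K{k}", "p1", "PreT", "MPR", "T"))
                    c += 1
            idx = expansion_index(clono_table(rows))
            assert 0.0 <= idx <= 1.0


class TestOverlap:
    def _table(self):
        rows = [("c0", "x", "p1", "PreT", "MPR", "A"), ("c1", "y", "p1", "PreT", "MPR", "A")]
        rows += [("c2", "z", "p1", "PreT", "MPR", "A"), ("c3", "y", "p1", "PreT", "MPR", "B")]
        rows += [("c4", "z", "p1", "PreT", "MPR", "B"), ("c5", "w", "p1", "PreT", "MPR", "B")]
        return clono_table(rows)

    def test_shared_and_jaccard(self):
        shared, jaccard = clonotype_overlap(self._table(), "cluster")
        assert shared.loc["A", "B"] == 2
        assert jaccard.loc["A", "B"] == pytest.approx(0.5)
        assert shared.loc["A", "A"] == 3 and jaccard.loc["B", "B"] == 1.0

    def test_symmetry(self):
        shared, jaccard = clonotype_overlap(self._table(), "cluster")
        assert (shared == shared.T).all().all()
        assert (jaccard == jaccard.T).all().all()

    def test_disjoint_and_identical(self):
        rows = [("c0", "x", "p1", "PreT", "MPR", "A"), ("c1", "y", "p1", "PreT", "MPR", "B")]
        shared, jaccard = clonotype_overlap(clono_table(rows), "cluster")
        assert shared.loc["A", "B"] == 0 and jaccard.loc["A", "B"] == 0.0
        rows = [("c0", "x", "p1", "PreT", "MPR", "A"), ("c1", "x", "p1", "PreT", "MPR", "B")]
        _, jaccard = clonotype_overlap(clono_table(rows), "cluster")
        assert jaccard.loc["A", "B"] == 1.0


class TestCloneFate:
    def _rows(self, clone, n_pre, n_post, patient="p1", response="MPR", start=0):
        rows = []
        for i in range(n_pre):
            rows.append((f"{patient}{clone}pre{start + i}", clone, patient, "PreT", response, "T"))
        for i in range(n_post):
            rows.append((f"{patient}{clone}post{start + i}", clone, patient, "PostT", response, "T"))
        return rows

    def test_threshold_rule(self):
        t = clono_table(self._rows("A", 2, 2) + self._rows("B", 3, 1))
        res = classify_clone_fate(t)
        fates = {r.clonotype_id: r.fate for r in res.records}
        assert fates["A"] == "TCR_Alive"  # ratio 0.5 > 0.3
        assert fates["B"] == "TCR_Dead"  # ratio 0.25
        ratios = {r.clonotype_id: r.ratio for r in res.records}
        assert ratios["A"] == 0.5 and ratios["B"] == 0.25

    def test_no_baseline_excluded(self):
        t = clono_table(self._rows("A", 0, 4) + self._rows("B", 1, 1))
        res = classify_clone_fate(t)
        fates = {r.clonotype_id: r.fate for r in res.records}
        assert fates["A"] == "excluded"
        res2 = classify_clone_fate(
            t, FateParams(require_baseline=False)
        )
        assert {r.clonotype_id: r.fate for r in res2.records}["A"] == "TCR_Alive"

    def test_no_post_treatment_errors(self):
        t = clono_table(self._rows("A", 3, 0))
        with pytest.raises(ValidationError):
            classify_clone_fate(t)

    def test_cell_fates_follow_clone(self):
        t = clono_table(self._rows("A", 1, 3))
        res = classify_clone_fate(t)
        assert (res.cell_fates == "TCR_Alive").all()

    def test_order_invariance(self):
        rows = self._rows("A", 2, 2) + self._rows("B", 3, 1, patient="p2")
        fwd = classify_clone_fate(clono_table(rows))
        rev = classify_clone_fate(clono_table(rows[::-1]))
        assert {(r.patient_id, r.clonotype_id): r.fate for r in fwd.records} == {
            (r.patient_id, r.clonotype_id): r.fate for r in rev.records
        }

    def test_sensitivity_grid_and_nesting(self):
        t = clono_table(
            self._rows("A", 11, 9)  # ratio 0.45
            + self._rows("B", 1, 9)  # ratio 0.9
            + self._rows("C", 9, 1)  # ratio 0.1
        )
        grids = fate_sensitivity(t, FateParams(sensitivity_grid=(0.4, 0.5, 0.6)))
        fates = {
            thr: {r.clonotype_id: r.fate for r in res.records} for thr, res in grids.items()
        }
        assert fates[0.4]["A"] == "TCR_Alive"
        assert fates[0.5]["A"] == "TCR_Dead" and fates[0.6]["A"] == "TCR_Dead"
        alive = {
            thr: {c for c, f in fs.items() if f == "TCR_Alive"} for thr, fs in fates.items()
        }
        assert alive[0.6] <= alive[0.5] <= alive[0.4]

    def test_frequency_mode_normalizes_compartments(self):
        # 2 pre of 10 pre-cells vs 2 post of 4 post-cells: raw ratio 0.5,
        # frequency ratio 0.2/(0.2+0.5) ~ 0.714
        rows = self._rows("A", 2, 2)
        rows += self._rows("B", 8, 2)
        t = clono_table(rows)
        raw = classify_clone_fate(t)
        freq = classify_clone_fate(t, FateParams(use_frequencies=True))
        r_raw = {r.clonotype_id: r.ratio for r in raw.records}["A"]
        r_freq = {r.clonotype_id: r.ratio for r in freq.records}["A"]
        assert r_raw == 0.5
        assert r_freq == pytest.approx((2 / 4) / (2 / 10 + 2 / 4))


class TestFateResponse:
    def _fates_and_resp(self, a_mpr, d_mpr, a_nmpr, d_nmpr):
        fates, resp = [], []
        for fate, r, n in [
            ("TCR_Alive", "MPR", a_mpr),
            ("TCR_Dead", "MPR", d_mpr),
            ("TCR_Alive", "NMPR", a_nmpr),
            ("TCR_Dead", "NMPR", d_nmpr),
        ]:
            fates += [fate] * n
            resp += [r] * n
        idx = pd.Index([f"c{i}" for i in range(len(fates))])
        return pd.Series(fates, index=idx), pd.Series(resp, index=idx)

    def test_independent_fixture_statistic_zero(self):
        fates, resp = self._fates_and_resp(20, 20, 20, 20)
        res, _ = fate_response_association(fates, resp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_90_10(self):
        fates, resp = self._fates_and_resp(90, 10, 10, 90)
        res, tab = fate_response_association(fates, resp)
        assert res.statistic == pytest.approx(128.0)
        assert res.df == 1

    def test_degenerate_errors(self):
        fates, resp = self._fates_and_resp(10, 0, 10, 0)
        with pytest.raises(ValidationError):
            fate_response_association(fates, resp)

    def test_planted_persistence_detected_across_replicates(self):
        # response-dependent clone persistence at the generator's stated
        # effect: association should reach p < 0.05 in >= 95 of 100 runs
        from escctme.core_io import contig_records_from_frame
        from escctme.synthetic import CohortConfig, _generate_repertoire

        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = CohortConfig(rng_seed=seed)
            contigs, meta = _generate_repertoire(cfg, np.random.default_rng(seed))
            table = call_clonotypes(contig_records_from_frame(contigs), cell_meta=meta)
            fate = classify_clone_fate(table)
            responses = table.data.set_index("cell_id")["response"]
            res, _ = fate_response_association(fate.cell_fates, responses)
            hits += res.p_value < 0.05
        assert hits >= 95
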