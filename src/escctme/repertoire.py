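"""scTCR clonotype calling, expansion statistics, overlap, and clone fate.

A clonotype is a paired (CDR3a, CDR3b) sequence; cells sharing one are a
clone. Fate tracking splits baseline-persisting clones into TCR_Alive and
TCR_Dead by the post-treatment share of the clone's cells, with a
sensitivity grid of stricter thresholds, and tests the association of
cell-level fate with therapy response by chi-square.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from escctme.core_io import ContigRecord, ValidationError
from escctme.enrichment import ChiSquareResult, ContingencyTable, chi_square_test


@dataclass
class ClonotypeTable:
    """One row per cell: clonotype assignment plus phenotype labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        required = ["cell_id", "clonotype_id", "cdr3a", "cdr3b"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"clonotype table missing columns: {missing}")
        if df["cell_id"].duplicated().any():
            raise ValidationError("one record per cell required")
        for col in ("cluster", "patient_id", "timepoint", "response"):
            if col not in df.columns:
                df[col] = pd.NA
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def _clonotype_id(cdr3a: str, cdr3b: str) -> str:
    digest = hashlib.sha1(f"{cdr3a}|{cdr3b}".encode()).hexdigest()
    return f"ct_{digest[:12]}"


def call_clonotypes(
    contigs: list[ContigRecord],
    level: str = "nt",
    cell_meta: pd.DataFrame | None = None,
) -> ClonotypeTable:
    """Assign paired-chain clonotypes to cells from contig records.

    Only cells with at least one productive full-length TRA *and* TRB are
    retained; with multiple chains of one type the highest-UMI contig wins
    (ties break on lexicographically smaller CDR3 for determinism).
    ``level`` selects nucleotide ("nt", default) or amino-acid ("aa") CDR3
    identity. ``cell_meta`` (indexed by barcode) contributes cluster,
    patient, timepoint and response labels.
    """
    if level not in ("nt", "aa"):
        raise ValidationError("level must be 'nt' or 'aa'")
    by_cell: dict[str, dict[str, ContigRecord]] = defaultdict(dict)
    for rec in contigs:
        if not (rec.productive and rec.full_length):
            continue
        if rec.chain not in ("TRA", "TRB"):
            continue
        seq = rec.cdr3_nt if level == "nt" else rec.cdr3_aa
        best = by_cell[rec.barcode].get(rec.chain)
        if best is None:
            by_cell[rec.barcode][rec.chain] = rec
        else:
            best_seq = best.cdr3_nt if level == "nt" else best.cdr3_aa
            # higher UMI wins; on a UMI tie keep the smaller CDR3
            if rec.umis > best.umis or (rec.umis == best.umis and seq < best_seq):
                by_cell[rec.barcode][rec.chain] = rec

    rows = []
    for barcode in sorted(by_cell):
        chains = by_cell[barcode]
        if "TRA" not in chains or "TRB" not in chains:
            continue
        a = chains["TRA"].cdr3_nt if level == "nt" else chains["TRA"].cdr3_aa
        b = chains["TRB"].cdr3_nt if level == "nt" else chains["TRB"].cdr3_aa
        rows.append(
            {
                "cell_id": barcode,
                "clonotype_id": _clonotype_id(a, b),
                "cdr3a": a,
                "cdr3b": b,
            }
        )
    df = pd.DataFrame(rows, columns=["cell_id", "clonotype_id", "cdr3a", "cdr3b"])
    if cell_meta is not None and len(df):
        for col in ("cluster", "patient_id", "timepoint", "response"):
            if col in cell_meta.columns:
                df[col] = cell_meta.reindex(df["cell_id"])[col].to_numpy()
    return ClonotypeTable(df)


def _clone_sizes(df: pd.DataFrame, within_patient: bool) -> pd.Series:
    keys = ["clonotype_id"] + (["patient_id"] if within_patient else [])
    return df.groupby(keys, dropna=False)["cell_id"].transform("size")


def expansion_classes(
    table: ClonotypeTable,
    by: list[str],
    size_cutoff: int = 2,
    within_patient: bool = True,
) -> pd.DataFrame:
    """Per-group fraction of cells in expanded (size > cutoff) clones.

    Clone sizes are counted within the grouping scope (and within patient
    by default; clones are not merged across individuals). Fractions of
    the two classes sum to 1 per group.
    """
    if not len(table):
        raise ValidationError("empty clonotype table")
    df = table.data.copy()
    keys = list(by) + (["patient_id"] if within_patient and "patient_id" not in by else [])
    df["clone_size"] = df.groupby(keys + ["clonotype_id"], dropna=False)[
        "cell_id"
    ].transform("size")
    df["expanded"] = df["clone_size"] > size_cutoff
    out = (
        df.groupby(list(by), dropna=False)["expanded"]
        .agg(frac_expanded="mean", n_cells="size")
        .reset_index()
    )
    out["frac_small"] = 1.0 - out["frac_expanded"]
    return out


def expansion_index(table: ClonotypeTable, mask: np.ndarray | None = None) -> float:
    """Clonal expansion index: 1 - H/ln(C) on clonotype frequencies.

    H is the Shannon entropy (nats) of clone-size frequencies within the
    selected cells and C the number of distinct clonotypes; a single
    clonotype scores 1 (monoclonal), an all-singleton group scores 0, and
    groups of fewer than 2 cells return NaN.
    """
    df = table.data if mask is None else table.data.loc[np.asarray(mask, dtype=bool)]
    n = len(df)
    if n < 2:
        return float("nan")
    sizes = df.groupby("clonotype_id")["cell_id"].size().to_numpy(dtype=float)
    C = sizes.size
    if C == 1:
        return 1.0
    freq = sizes / n
    H = -np.sum(freq * np.log(freq))
    return float(1.0 - H / np.log(C))


def clonotype_overlap(
    table: ClonotypeTable, phenotype_key: str = "cluster"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise clonotype sharing between phenotypes.

    Returns (shared counts, Jaccard indices), both symmetric with the
    diagonal holding each phenotype's own clonotype count and 1.
    """
    df = table.data
    phenos = sorted(df[phenotype_key].dropna().unique())
    if len(phenos) < 2:
        raise ValidationError("need >= 2 phenotypes for overlap")
    sets = {p: set(df.loc[df[phenotype_key] == p, "clonotype_id"]) for p in phenos}
    shared = pd.DataFrame(0, index=phenos, columns=phenos, dtype=int)
    jaccard = pd.DataFrame(0.0, index=phenos, columns=phenos)
    for p in phenos:
        for q in phenos:
            inter = len(sets[p] & sets[q])
            union = len(sets[p] | sets[q])
            shared.loc[p, q] = inter
            jaccard.loc[p, q] = inter / union if union else 0.0
        jaccard.loc[p, p] = 1.0
    return shared, jaccard


@dataclass(frozen=True)
class FateParams:
    """Clone-fate thresholds on the post-treatment cell share."""

    threshold: float = 0.3
    sensitivity_grid: tuple[float, ...] = (0.4, 0.5, 0.6)
    require_baseline: bool = True
    use_frequencies: bool = False

    def __post_init__(self) -> None:
        for t in (self.threshold, *self.sensitivity_grid):
            if not 0 < t < 1:
                raise ValidationError("fate thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class CloneFateRecord:
    clonotype_id: str
    patient_id: str
    n_pre: int
    n_post: int
    ratio: float
    fate: str  # TCR_Alive | TCR_Dead | excluded


@dataclass
class CloneFateResult:
    """Clone-level fate calls plus the induced per-cell fate labels."""

    records: list[CloneFateRecord]
    cell_fates: pd.Series = field(repr=False)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def classify_clone_fate(
    table: ClonotypeTable, params: FateParams = FateParams(), threshold: float | None = None
) -> CloneFateResult:
    """Split clones into TCR_Alive / TCR_Dead by post-treatment share.

    Within each patient, ratio = n_post / (n_pre + n_post) per clonotype;
    a clone is TCR_Alive when the ratio exceeds the threshold, TCR_Dead
    otherwise. Clones absent at baseline (n_pre = 0) are marked excluded
    when ``require_baseline`` — the analysis tracks clones persisting from
    baseline. ``use_frequencies`` computes the ratio on compartment-size
    normalized frequencies instead of raw counts.
    """
    thr = params.threshold if threshold is None else threshold
    df = table.data
    if not (df["timepoint"] == "PostT").any():
        raise ValidationError("no post-treatment cells in the clonotype table")
    pre = df["timepoint"] == "PreT"
    post = df["timepoint"] == "PostT"
    compartment = df.groupby(["patient_id", "timepoint"], dropna=False)["cell_id"].transform(
        "size"
    )

    records: list[CloneFateRecord] = []
    fate_by_clone: dict[tuple, str] = {}
    grouped = df.assign(_pre=pre, _post=post, _comp=compartment).groupby(
        ["patient_id", "clonotype_id"], dropna=False
    )
    for (patient, clone), sub in sorted(grouped, key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        n_pre = int(sub["_pre"].sum())
        n_post = int(sub["_post"].sum())
        if n_pre + n_post == 0:
            continue
        if params.use_frequencies:
            f_pre = (sub["_pre"] / sub["_comp"]).sum()
            f_post = (sub["_post"] / sub["_comp"]).sum()
            ratio = f_post / (f_pre + f_post) if (f_pre + f_post) > 0 else 0.0
        else:
            ratio = n_post / (n_pre + n_post)
        if n_pre == 0 and params.require_baseline:
            fate = "excluded"
        else:
            fate = "TCR_Alive" if ratio > thr else "TCR_Dead"
        records.append(
            CloneFateRecord(
                clonotype_id=str(clone),
                patient_id=str(patient),
                n_pre=n_pre,
                n_post=n_post,
                ratio=float(ratio),
                fate=fate,
            )
        )
        fate_by_clone[(patient, clone)] = fate

    keys = list(zip(df["patient_id"], df["clonotype_id"]))
    cell_fates = pd.Series(
        [fate_by_clone.get(k, "excluded") for k in keys],
        index=pd.Index(df["cell_id"], name="cell_id"),
        name="fate",
    )
    return CloneFateResult(records=records, cell_fates=cell_fates)


def fate_sensitivity(
    table: ClonotypeTable, params: FateParams = FateParams()
) -> dict[float, CloneFateResult]:
    """Clone fate at each threshold in the sensitivity grid."""
    return {
        thr: classify_clone_fate(table, params, threshold=thr)
        for thr in params.sensitivity_grid
    }


def fate_response_association(
    cell_fates: pd.Series, responses: pd.Series
) -> tuple[ChiSquareResult, ContingencyTable]:
    """Chi-square association of per-cell clone fate with therapy response.

    Excluded cells (no baseline) are dropped; the 2x2 table of cell counts
    (fate x response) is tested with the raw Pearson statistic.
    """
    responses = responses.reindex(cell_fates.index)
    keep = cell_fates.isin(["TCR_Alive", "TCR_Dead"]) & responses.notna()
    fates = cell_fates[keep]
    resp = responses[keep]
    if fates.nunique() < 2 or resp.nunique() < 2:
        raise ValidationError("need both fates and both responses present")
    tab = ContingencyTable.from_labels(fates, resp)
    return chi_square_test(tab), tab
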