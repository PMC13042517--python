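"""Readers, writers and validated containers for the pipeline's file formats.

Formats handled: Matrix Market count matrices with features/barcodes TSVs
(10x convention), per-cell annotation CSV, 10x-style filtered contig
annotation CSV for TCR, GMT gene sets, and clinical survival CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

TISSUES = ("Normal", "Adjacent", "PreT", "PostT")
RESPONSES = ("MPR", "NMPR", "NA")
CHAINS = ("TRA", "TRB", "other")


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


# ---------------------------------------------------------------------------
# ExpressionBundle
# ---------------------------------------------------------------------------

META_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "response",
    "cluster",
    "mito_fraction",
    "n_genes_detected",
)


@dataclass
class ExpressionBundle:
    """Counts plus (lazily filled) normalized matrix and per-cell annotations.

    Matrices are genes x cells. ``counts`` holds non-negative integers;
    ``normalized`` is filled by :func:`escctme.preprocess.normalize`.
    ``cell_meta`` is indexed by cell id and carries sample, patient, tissue,
    response, cluster label, mitochondrial fraction and detected-gene count.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    gene_symbols: pd.Index | None = None
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.gene_symbols is not None:
            self.gene_symbols = pd.Index(self.gene_symbols)
            if len(self.gene_symbols) != len(self.gene_ids):
                raise ValidationError("gene_symbols length must match gene_ids")
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n_cells} columns"
            )
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if self.cell_ids.has_duplicates:
            dup = self.cell_ids[self.cell_ids.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate cell barcodes: {dup}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.floor(self.counts.data)):
            raise ValidationError("counts must be integer-valued")
        if not self.cell_meta.index.equals(self.cell_ids):
            # allow same labels in matrix order
            if set(self.cell_meta.index) != set(self.cell_ids):
                raise ValidationError("cell_meta index does not match cell ids")
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")
        mito = self.cell_meta["mito_fraction"].dropna()
        if len(mito) and ((mito < 0).any() or (mito > 1).any()):
            raise ValidationError("mito_fraction must lie in [0, 1]")
        bad_tissue = set(self.cell_meta["tissue"].dropna()) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        bad_resp = set(self.cell_meta["response"].dropna()) - set(RESPONSES)
        if bad_resp:
            raise ValidationError(f"unknown response labels: {sorted(bad_resp)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionBundle":
        """Return a bundle restricted to the cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return ExpressionBundle(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            cell_ids=self.cell_ids[mask],
            cell_meta=self.cell_meta.loc[mask],
            normalized=None if self.normalized is None else self.normalized[:, mask],
        )

    def gene_index(self, gene: str) -> int:
        """Index of ``gene``, matching ids first, then display symbols."""
        pos = self.gene_ids.get_indexer([gene])
        if pos[0] >= 0:
            return int(pos[0])
        if self.gene_symbols is not None:
            hits = np.flatnonzero(self.gene_symbols == gene)
            if hits.size:
                return int(hits[0])
        raise KeyError(gene)


def _default_meta(cell_ids: pd.Index) -> pd.DataFrame:
    meta = pd.DataFrame(index=cell_ids)
    for col in ("sample_id", "patient_id", "tissue", "cluster"):
        meta[col] = pd.NA
    meta["response"] = "NA"
    meta["mito_fraction"] = np.nan
    meta["n_genes_detected"] = pd.NA
    return meta


def read_mtx_bundle(
    matrix_path: str | os.PathLike,
    features_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
    *,
    permissive: bool = False,
    strip_suffix: str | None = "-1",
) -> ExpressionBundle:
    """Read a 10x-style MTX triple (plus optional metadata CSV) into a bundle.

    The features TSV is id<TAB>symbol (ids must be unique; symbols may
    repeat); barcodes is one barcode per line. Metadata rows are joined on
    barcode after stripping ``strip_suffix`` (10x's ``-1``) from both sides.
    Cells absent from the metadata get ``response="NA"`` defaults only when
    ``permissive`` is set, otherwise a validation error is raised.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:  # noqa: BLE001 - re-raise with filename
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and np.any(mat.data != np.floor(mat.data)):
        raise FormatError(f"{matrix_path}: matrix is not integer-valued")

    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 1:
        raise FormatError(f"{features_path}: empty features file")
    gene_ids = pd.Index(feats.iloc[:, 0])
    gene_symbols = pd.Index(feats.iloc[:, 1]) if feats.shape[1] > 1 else None

    bars = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    cell_ids = pd.Index(bars.iloc[:, 0])
    if strip_suffix:
        cell_ids = pd.Index(
            [c[: -len(strip_suffix)] if c.endswith(strip_suffix) else c for c in cell_ids]
        )
    if cell_ids.has_duplicates:
        raise ValidationError(f"{barcodes_path}: duplicate barcodes")

    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"{features_path}: {len(gene_ids)} features but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(cell_ids):
        raise FormatError(
            f"{barcodes_path}: {len(cell_ids)} barcodes but matrix has {mat.shape[1]} columns"
        )

    meta = _default_meta(cell_ids)
    if meta_path is not None:
        user = pd.read_csv(meta_path)
        key = "barcode" if "barcode" in user.columns else user.columns[0]
        idx = user[key].astype(str)
        if strip_suffix:
            idx = idx.str.replace(f"{strip_suffix}$", "", regex=True)
        user = user.set_index(pd.Index(idx))
        if user.index.has_duplicates:
            raise ValidationError(f"{meta_path}: duplicate barcodes in metadata")
        known = cell_ids.isin(user.index)
        if not known.all() and not permissive:
            missing = cell_ids[~known][:3].tolist()
            raise ValidationError(
                f"{meta_path}: cells absent from metadata (e.g. {missing}); "
                "pass permissive=True to keep them with NA defaults"
            )
        for col in user.columns:
            if col == key:
                continue
            meta.loc[cell_ids[known], col] = user.loc[cell_ids[known], col].to_numpy()
    return ExpressionBundle(
        counts=mat,
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        cell_ids=cell_ids,
        cell_meta=meta,
    )


def write_mtx_bundle(bundle: ExpressionBundle, out_dir: str | os.PathLike) -> None:
    """Write a bundle as matrix.mtx + features.tsv + barcodes.tsv + meta.csv."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out, "matrix.mtx"), sp.coo_matrix(bundle.counts))
    symbols = bundle.gene_symbols if bundle.gene_symbols is not None else bundle.gene_ids
    pd.DataFrame({"id": bundle.gene_ids, "symbol": symbols}).to_csv(
        os.path.join(out, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(bundle.cell_ids).to_csv(
        os.path.join(out, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    meta = bundle.cell_meta.copy()
    meta.insert(0, "barcode", bundle.cell_ids)
    meta.to_csv(os.path.join(out, "meta.csv"), index=False)


# ---------------------------------------------------------------------------
# TCR contigs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    """One assembled TCR contig from a 10x filtered_contig_annotations row."""

    barcode: str
    chain: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    full_length: bool
    umis: int

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValidationError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.umis < 0:
            raise ValidationError("umis must be >= 0")


_CONTIG_COLUMNS = {
    "barcode": "barcode",
    "chain": "chain",
    "cdr3": "cdr3_aa",
    "cdr3_nt": "cdr3_nt",
    "productive": "productive",
    "full_length": "full_length",
    "umis": "umis",
}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "t", "1", "yes"}


def read_contig_csv(
    path: str | os.PathLike, *, column_map: Mapping[str, str] | None = None
) -> list[ContigRecord]:
    """Parse a 10x-dialect filtered contig annotation CSV into records.

    Chains outside {TRA, TRB} (e.g. IGH from ambient B cells) are retained
    but flagged ``other`` so downstream pairing can ignore them.
    ``column_map`` renames non-standard headers to the 10x names.
    """
    return contig_records_from_frame(pd.read_csv(path), column_map=column_map, source=path)


def contig_records_from_frame(
    df: pd.DataFrame,
    *,
    column_map: Mapping[str, str] | None = None,
    source: str | os.PathLike = "<frame>",
) -> list[ContigRecord]:
    """Convert an in-memory contig annotation table to records."""
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["barcode", "chain", "cdr3", "productive", "umis"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing mandatory columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        chain = getattr(row, "chain")
        chain = chain if chain in ("TRA", "TRB") else "other"
        records.append(
            ContigRecord(
                barcode=str(getattr(row, "barcode")),
                chain=chain,
                cdr3_aa=str(getattr(row, "cdr3")),
                cdr3_nt=str(getattr(row, "cdr3_nt", getattr(row, "cdr3"))),
                productive=_parse_bool(getattr(row, "productive")),
                full_length=_parse_bool(getattr(row, "full_length", True)),
                umis=int(getattr(row, "umis")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT semantics): no empty sets, unique ids per set."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate gene ids")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------


@dataclass
class SurvivalTable:
    """Per-subject time-to-event records (times in months, events binary)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in ("subject_id", "time", "event") if c not in df.columns]
        if missing:
            raise ValidationError(f"survival table missing columns: {missing}")
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "subject_id"].tolist()[:3]
            raise ValidationError(f"non-positive survival times for subjects {bad}")
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event indicators must be 0 or 1")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject ids in survival table")
        if "group" not in df.columns:
            df["group"] = pd.NA
        if "score" not in df.columns:
            df["score"] = np.nan
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    @classmethod
    def from_records(
        cls,
        subject_ids: Sequence,
        times: Sequence[float],
        events: Sequence[int],
        groups: Sequence | None = None,
        scores: Sequence[float] | None = None,
    ) -> "SurvivalTable":
        df = pd.DataFrame(
            {"subject_id": list(subject_ids), "time": list(times), "event": list(events)}
        )
        if groups is not None:
            df["group"] = list(groups)
        if scores is not None:
            df["score"] = list(scores)
        return cls(df)


def read_survival_csv(path: str | os.PathLike) -> SurvivalTable:
    """Read a clinical survival CSV (subject_id, time, event[, group, score])."""
    df = pd.read_csv(path)
    missing = [c for c in ("time", "event") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"S{i}" for i in range(len(df))])
    return SurvivalTable(df)


def write_survival_csv(table: SurvivalTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, index=False)


def validate_directory(directory: str | os.PathLike) -> dict[str, str]:
    """Validate the recognized input files in ``directory``.

    Returns a {filename: status} report; status is "ok" or the error text.
    Used by the ``escctme validate`` CLI command.
    """
    directory = os.fspath(directory)
    report: dict[str, str] = {}
    mtx = os.path.join(directory, "matrix.mtx")
    if os.path.exists(mtx):
        try:
            read_mtx_bundle(
                mtx,
                os.path.join(directory, "features.tsv"),
                os.path.join(directory, "barcodes.tsv"),
                meta_path=os.path.join(directory, "meta.csv")
                if os.path.exists(os.path.join(directory, "meta.csv"))
                else None,
                permissive=True,
            )
            report["matrix.mtx"] = "ok"
        except (FormatError, ValidationError, OSError) as exc:
            report["matrix.mtx"] = str(exc)
    for name, reader in [
        ("contigs.csv", read_contig_csv),
        ("gene_sets.gmt", read_gmt),
        ("survival.csv", read_survival_csv),
    ]:
        path = os.path.join(directory, name)
        if os.path.exists(path):
            try:
                reader(path)
                report[name] = "ok"
            except (FormatError, ValidationError) as exc:
                report[name] = str(exc)
    return report
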