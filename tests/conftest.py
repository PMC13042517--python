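import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from escctme.core_io import ExpressionBundle


def make_bundle(
    counts: np.ndarray,
    gene_ids=None,
    gene_symbols=None,
    cell_ids=None,
    meta: dict | None = None,
) -> ExpressionBundle:
    """Build a small validated bundle from a dense genes x cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = pd.Index(gene_ids or [f"g{i}" for i in range(n_genes)])
    cell_ids = pd.Index(cell_ids or [f"c{i}" for i in range(n_cells)])
    cell_meta = pd.DataFrame(index=cell_ids)
    cell_meta["sample_id"] = "s0"
    cell_meta["patient_id"] = "p0"
    cell_meta["tissue"] = "PreT"
    cell_meta["response"] = "NA"
    cell_meta["cluster"] = pd.NA
    cell_meta["mito_fraction"] = np.nan
    cell_meta["n_genes_detected"] = pd.NA
    if meta:
        for key, values in meta.items():
            cell_meta[key] = values
    return ExpressionBundle(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        gene_symbols=pd.Index(gene_symbols) if gene_symbols is not None else None,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
    )


def normalized_bundle(values: np.ndarray, **kwargs) -> ExpressionBundle:
    """Bundle whose *normalized* matrix is set directly to ``values``
    (counts filled with a compatible placeholder)."""
    values = np.asarray(values, dtype=float)
    bundle = make_bundle(np.ceil(values).astype(int), **kwargs)
    bundle.normalized = sp.csr_matrix(values)
    return bundle


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests (seed fixed)."""
    from escctme.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(cells_per_sample=60, n_genes=200, rng_seed=11)
    return generate_cohort(cfg)
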