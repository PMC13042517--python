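"""Seeded synthetic-cohort generators with planted, recoverable effects.

The default cohort mirrors the study design the pipeline targets: 9
patients (5 MPR, 4 NMPR) contributing 26 samples across four tissue
categories (Normal, Adjacent, pre-treatment and post-treatment tumor; one
NMPR patient lacks a post-treatment sample). Counts are negative binomial
with log-normal gene baselines and per-cell library-size factors;
clusters carry marker-gene fold changes; cluster proportions per
tissue x response condition are configurable so Ro/e ground truth is
analytic; designated sender/receiver clusters carry planted
ligand-receptor coexpression; TCR repertoires follow per-patient
power-law clone sizes with response-dependent post-treatment persistence;
survival times are exponential per group with administrative censoring.
Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from escctme.core_io import ExpressionBundle, SurvivalTable, ValidationError


@dataclass(frozen=True)
class LRPlant:
    """A planted ligand-receptor coexpression effect."""

    pair_name: str
    ligand: str
    receptor: str
    sender: str
    receiver: str
    fold: float = 8.0


@dataclass(frozen=True)
class CloneSpec:
    """Power-law baseline repertoire with response-dependent persistence."""

    n_clones_per_patient: int = 60
    power_exponent: float = 2.0
    max_clone_size: int = 30
    persistence: tuple[tuple[str, float], ...] = (("MPR", 0.6), ("NMPR", 0.2))
    post_growth: float = 1.0


@dataclass(frozen=True)
class SurvivalSpec:
    hazards: tuple[tuple[str, float], ...] = (("high", 0.030), ("low", 0.015))
    censor_time: float = 60.0


@dataclass
class CohortConfig:
    """Full description of the simulated cohort; defaults mirror the study
    design (9 patients, 26 samples, MPR 5 / NMPR 4) at reduced scale."""

    n_patients: int = 9
    n_mpr: int = 5
    cells_per_sample: int = 250
    n_genes: int = 600
    clusters: tuple[str, ...] = (
        "Epi_PRDM1",
        "Epi_other",
        "Treg",
        "Mac_TREM2",
        "CD8_Teff",
        "Fibroblast",
    )
    n_markers_per_cluster: int = 10
    marker_log2_fold: float = 3.0
    nb_dispersion: float = 0.5
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    # proportion overrides: {(cluster, tissue, response): proportion};
    # remaining mass is spread evenly over the other clusters
    enrichments: dict = field(default_factory=dict)
    treg_nmpr_post_fold: float = 3.0
    lr_plants: tuple[LRPlant, ...] = (
        LRPlant("IL1A_IL1R2", "IL1A", "IL1R2", "Epi_PRDM1", "Treg"),
        LRPlant("CD47_SIRPA", "CD47", "SIRPA", "Epi_PRDM1", "Mac_TREM2"),
    )
    clone_spec: CloneSpec = field(default_factory=CloneSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_mpr < self.n_patients:
            raise ValidationError("need 0 < n_mpr < n_patients")
        if self.treg_nmpr_post_fold <= 0:
            raise ValidationError("enrichment folds must be positive")
        for p in self.lr_plants:
            if p.fold <= 0:
                raise ValidationError("LR plant folds must be positive")

    def patients(self) -> pd.DataFrame:
        ids = [f"P{i + 1}" for i in range(self.n_patients)]
        resp = ["MPR"] * self.n_mpr + ["NMPR"] * (self.n_patients - self.n_mpr)
        return pd.DataFrame({"patient_id": ids, "response": resp})

    def samples(self) -> pd.DataFrame:
        """26-sample layout at the default 9 patients: Normal x4, Adjacent x5,
        PreT for all, PostT for all but the last NMPR patient."""
        pats = self.patients()
        rows = []
        for i, (pid, resp) in enumerate(zip(pats["patient_id"], pats["response"])):
            tissues = ["PreT"]
            if i < 4:
                tissues.append("Normal")
            if i < 5:
                tissues.append("Adjacent")
            if i != self.n_patients - 1:  # one post-treatment sample missing
                tissues.append("PostT")
            for t in tissues:
                rows.append(
                    {
                        "sample_id": f"{pid}_{t}",
                        "patient_id": pid,
                        "tissue": t,
                        "response": resp,
                    }
                )
        return pd.DataFrame(rows)

    def cluster_proportions(self, tissue: str, response: str) -> np.ndarray:
        """Cluster mixing proportions for one tissue x response condition."""
        k = len(self.clusters)
        props = np.full(k, 1.0 / k)
        overrides = dict(self.enrichments)
        if self.treg_nmpr_post_fold != 1.0 and tissue == "PostT" and response == "NMPR":
            overrides.setdefault(("Treg", "PostT", "NMPR"), self.treg_nmpr_post_fold / k)
        for (cluster, t, r), prop in overrides.items():
            if t == tissue and r == response:
                j = self.clusters.index(cluster)
                props[j] = prop
        props = props / props.sum()
        if (props <= 0).any():
            raise ValidationError("infeasible cluster proportions")
        return props


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by (mean, dispersion).

    Var = mu + dispersion * mu^2; implemented as Gamma-Poisson mixture.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(config: CohortConfig | None = None):
    """Generate (ExpressionBundle, contigs, tcr_meta, SurvivalTable, sidecar).

    The contigs DataFrame is in the 10x filtered_contig_annotations dialect
    and round-trips through :func:`escctme.core_io.read_contig_csv`; the
    sidecar dict records every planted effect for recovery tests.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    symbols = list(gene_ids)
    # reserve named genes: ligands/receptors first, then mito markers
    special = []
    for plant in cfg.lr_plants:
        special.extend([plant.ligand, plant.receptor])
    special = list(dict.fromkeys(special))
    for j, name in enumerate(special):
        symbols[j] = name
    n_mito = 5
    for j in range(n_mito):
        symbols[len(special) + j] = f"MT-SIM{j}"

    # cluster marker blocks after the reserved genes
    marker_start = len(special) + n_mito
    markers: dict[str, list[int]] = {}
    for c, cluster in enumerate(cfg.clusters):
        lo = marker_start + c * cfg.n_markers_per_cluster
        markers[cluster] = list(range(lo, lo + cfg.n_markers_per_cluster))
    if marker_start + len(cfg.clusters) * cfg.n_markers_per_cluster > cfg.n_genes:
        raise ValidationError("n_genes too small for the marker layout")

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)

    samples = cfg.samples()
    cells_meta = []
    count_blocks = []
    cell_counter = 0
    for srow in samples.itertuples(index=False):
        props = cfg.cluster_proportions(srow.tissue, srow.response)
        labels = rng.choice(len(cfg.clusters), size=cfg.cells_per_sample, p=props)
        lib = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, cfg.cells_per_sample)
        mean = baseline[:, None] * lib[None, :]
        fold = np.ones((cfg.n_genes, cfg.cells_per_sample))
        for c, cluster in enumerate(cfg.clusters):
            in_c = labels == c
            if not in_c.any():
                continue
            fold[np.ix_(markers[cluster], in_c)] = 2.0**cfg.marker_log2_fold
        for plant in cfg.lr_plants:
            lig_j = symbols.index(plant.ligand)
            rec_j = symbols.index(plant.receptor)
            s_cells = labels == cfg.clusters.index(plant.sender)
            r_cells = labels == cfg.clusters.index(plant.receiver)
            if s_cells.any():
                fold[lig_j, s_cells] = plant.fold
            if r_cells.any():
                fold[rec_j, r_cells] = plant.fold
        counts = _nb_counts(rng, mean * fold, cfg.nb_dispersion)
        count_blocks.append(sp.csr_matrix(counts))
        for i, c in enumerate(labels):
            cells_meta.append(
                {
                    "barcode": f"C{cell_counter + i:06d}",
                    "sample_id": srow.sample_id,
                    "patient_id": srow.patient_id,
                    "tissue": srow.tissue,
                    "response": srow.response,
                    "cluster": cfg.clusters[c],
                }
            )
        cell_counter += cfg.cells_per_sample

    counts = sp.hstack(count_blocks, format="csr")
    meta = pd.DataFrame(cells_meta).set_index("barcode")
    meta.index.name = None
    meta["mito_fraction"] = np.nan
    meta["n_genes_detected"] = pd.NA
    bundle = ExpressionBundle(
        counts=counts,
        gene_ids=pd.Index(gene_ids),
        gene_symbols=pd.Index(symbols),
        cell_ids=pd.Index(meta.index),
        cell_meta=meta,
    )

    contigs, tcr_meta = _generate_repertoire(cfg, rng)
    surv = generate_survival_from_spec(cfg.survival_spec, cfg.n_patients * 4, rng)

    sidecar = {
        "seed": cfg.rng_seed,
        "clusters": list(cfg.clusters),
        "markers": {k: [gene_ids[j] for j in v] for k, v in markers.items()},
        "treg_nmpr_post_fold": cfg.treg_nmpr_post_fold,
        "lr_plants": [asdict(p) for p in cfg.lr_plants],
        "clone_persistence": dict(cfg.clone_spec.persistence),
        "survival_hazards": dict(cfg.survival_spec.hazards),
        "samples": samples.to_dict(orient="records"),
    }
    return bundle, contigs, tcr_meta, surv, sidecar


_NT = "ACGT"


def _random_cdr3(rng: np.random.Generator, length: int = 39) -> tuple[str, str]:
    nt = "".join(_NT[i] for i in rng.integers(0, 4, size=length))
    codons = [nt[i : i + 3] for i in range(0, length, 3)]
    # deterministic toy translation (codon -> letter), not the genetic code
    aa = "".join("ACDEFGHIKLMNPQRSTVWY"[sum(map(ord, c)) % 20] for c in codons)
    return nt, aa


def _generate_repertoire(cfg: CohortConfig, rng: np.random.Generator):
    """Per-patient power-law repertoires with response-dependent persistence.

    Returns (contigs DataFrame, per-cell metadata DataFrame indexed by
    barcode). Each clone has a baseline (PreT) size drawn from a truncated
    power law; it persists after treatment with the response-dependent
    probability, and persisting clones get a zero-truncated Poisson
    post-treatment size proportional to their baseline size.
    """
    spec = cfg.clone_spec
    persistence = dict(spec.persistence)
    sizes_support = np.arange(1, spec.max_clone_size + 1)
    size_probs = sizes_support ** (-spec.power_exponent)
    size_probs = size_probs / size_probs.sum()

    contig_rows = []
    meta_rows = []
    cell_i = 0
    for prow in cfg.patients().itertuples(index=False):
        p_persist = persistence[prow.response]
        for k in range(spec.n_clones_per_patient):
            nt_a, aa_a = _random_cdr3(rng)
            nt_b, aa_b = _random_cdr3(rng)
            n_pre = int(rng.choice(sizes_support, p=size_probs))
            if rng.random() < p_persist:
                lam = max(spec.post_growth * n_pre, 0.1)
                n_post = int(rng.poisson(lam)) + 1  # zero-truncated
            else:
                n_post = 0
            for timepoint, n_cells in (("PreT", n_pre), ("PostT", n_post)):
                for _ in range(n_cells):
                    barcode = f"T{cell_i:06d}"
                    cell_i += 1
                    for chain, nt, aa in (("TRA", nt_a, aa_a), ("TRB", nt_b, aa_b)):
                        contig_rows.append(
                            {
                                "barcode": barcode,
                                "chain": chain,
                                "cdr3": aa,
                                "cdr3_nt": nt,
                                "productive": "True",
                                "full_length": "True",
                                "umis": int(rng.integers(1, 20)),
                            }
                        )
                    meta_rows.append(
                        {
                            "barcode": barcode,
                            "patient_id": prow.patient_id,
                            "response": prow.response,
                            "timepoint": timepoint,
                            "cluster": "CD8_Teff",
                        }
                    )
    contigs = pd.DataFrame(contig_rows)
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    meta.index.name = None
    return contigs, meta


def generate_survival(
    n: int,
    hazard_by_group: dict[str, float],
    censor_time: float,
    rng_seed: int = 0,
) -> SurvivalTable:
    """Exponential event times per group with administrative censoring."""
    rng = np.random.default_rng(rng_seed)
    return generate_survival_from_spec(
        SurvivalSpec(hazards=tuple(hazard_by_group.items()), censor_time=censor_time),
        n,
        rng,
    )


def generate_survival_from_spec(
    spec: SurvivalSpec, n: int, rng: np.random.Generator
) -> SurvivalTable:
    hazards = dict(spec.hazards)
    if any(h <= 0 for h in hazards.values()):
        raise ValidationError("hazards must be positive")
    groups = sorted(hazards)
    per_group = [n // len(groups)] * len(groups)
    per_group[0] += n - sum(per_group)
    rows = []
    sid = 0
    for g, m in zip(groups, per_group):
        t = rng.exponential(1.0 / hazards[g], size=m)
        for ti in t:
            event = 1 if ti <= spec.censor_time else 0
            rows.append(
                {
                    "subject_id": f"S{sid}",
                    "time": min(ti, spec.censor_time),
                    "event": event,
                    "group": g,
                }
            )
            sid += 1
    return SurvivalTable(pd.DataFrame(rows))


def generate_bulk(
    n_samples: int,
    n_genes: int,
    signature_genes: list[str] | None = None,
    planted_samples: list[int] | None = None,
    shift: float = 2.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Log-normal bulk expression (samples x genes) with optional plants.

    ``planted_samples`` get an additive ``shift`` on the signature genes,
    emulating samples rich in the signature's cell state.
    """
    rng = np.random.default_rng(rng_seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    X = rng.lognormal(1.0, 0.5, size=(n_samples, n_genes))
    df = pd.DataFrame(X, index=[f"S{i}" for i in range(n_samples)], columns=genes)
    if signature_genes and planted_samples:
        present = [g for g in signature_genes if g in df.columns]
        df.iloc[planted_samples, [df.columns.get_loc(g) for g in present]] += shift
    return df


def write_cohort(out_dir, config: CohortConfig | None = None) -> dict:
    """Write a simulated cohort to ``out_dir`` (MTX + TSV + CSV + JSON).

    Files: matrix.mtx/features.tsv/barcodes.tsv/meta.csv, contigs.csv,
    tcr_meta.csv, survival.csv, ground_truth.json. Returns the sidecar.
    """
    import json
    import os

    from escctme.core_io import write_mtx_bundle, write_survival_csv

    bundle, contigs, tcr_meta, surv, sidecar = generate_cohort(config)
    os.makedirs(out_dir, exist_ok=True)
    write_mtx_bundle(bundle, out_dir)
    contigs.to_csv(os.path.join(out_dir, "contigs.csv"), index=False)
    tcr_meta.rename_axis("barcode").to_csv(os.path.join(out_dir, "tcr_meta.csv"))
    write_survival_csv(surv, os.path.join(out_dir, "survival.csv"))
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
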