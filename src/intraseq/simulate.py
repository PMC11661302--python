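"""Synthetic multimodal single-cell data with the structure the pipeline assumes.

The generator emulates a droplet experiment that measures RNA and
antibody-derived tags (ADTs) in the same cells: several cell types with
distinct RNA/protein mean profiles, negative-binomial UMI counts, PTM
antibodies whose protein signal is decoupled from their encoding gene's
transcription, a cell-cycle phase mixture in which phospho-Histone-H3
(Ser10) is strongly elevated only in the small mitotic fraction, and a
per-molecule read-count table that supports read-level downsampling.

Counts are negative binomial parameterized by (mean mu, dispersion k) with
variance mu + mu^2/k; the (r, p) form used for sampling is r = k,
p = k / (k + mu). Parameter sets with variance <= mean fall back to Poisson.
All randomness flows through a single ``numpy.random.default_rng`` (PCG64)
stream seeded from the config, so identical configs reproduce datasets
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    ADT,
    PTM,
    RNA,
    CountMatrix,
    MoleculeTable,
    PanelManifest,
    ValidationError,
)
from . import io as _io

PHASES = ("G1", "S", "G2M", "M")

GENERATOR_FAMILY = "numpy.random.default_rng (PCG64)"


def nb_rp(mu: np.ndarray, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert (mean, dispersion) to the (r, p) sampling parameterization."""
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    return k, k / (k + mu)


def draw_counts(rng: np.random.Generator, mu: np.ndarray, k: np.ndarray) -> np.ndarray:
    """NB(mu, k) draws, elementwise over broadcast mu/k; mu = 0 yields 0."""
    r, p = nb_rp(np.broadcast_to(mu, np.broadcast_shapes(np.shape(mu), np.shape(k))), k)
    # negative_binomial requires p in (0, 1]; mu = 0 gives p = 1 -> always 0
    return rng.negative_binomial(r, p, size=p.shape)


def draw_counts_mean_var(
    rng: np.random.Generator, mean: float, variance: float, size: int
) -> np.ndarray:
    """Draws from NB given (mean, variance); Poisson when variance <= mean."""
    if mean < 0:
        raise ValidationError("mean must be >= 0")
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    if variance <= mean:
        return rng.poisson(mean, size=size)
    r = mean**2 / (variance - mean)
    p = mean / variance
    return rng.negative_binomial(r, p, size=size)


@dataclass
class SimulationConfig:
    """Everything the generator needs, with validation of the NB setup.

    ``rna_mean_matrix`` and ``adt_mean_matrix`` are (cell type x feature)
    NB means; ``rna_dispersion`` / ``adt_dispersion`` are per-feature k.
    ``ptm_decoupling`` flags PTM antibodies whose ADT means were drawn
    independently of their encoding gene's RNA (ground truth for the
    concordance analysis). ``phase_proportions`` orders G1/S/G2M/M; the
    ``ph3_antibody`` ADT column is overridden with draws from the M or null
    (mean, variance) pair according to each cell's true phase. Per-molecule
    read counts are 1 + Poisson(reads_per_umi_mean - 1), so every observed
    UMI has at least one read.
    """

    n_cells: int
    cell_types: list[str]
    cell_type_proportions: np.ndarray
    gene_names: list[str]
    rna_mean_matrix: np.ndarray
    rna_dispersion: np.ndarray
    manifest: PanelManifest
    adt_mean_matrix: np.ndarray
    adt_dispersion: np.ndarray
    ptm_decoupling: dict[str, bool]
    phase_proportions: np.ndarray
    ph3_antibody: str
    ph3_null_mean: float
    ph3_null_variance: float
    ph3_m_mean: float
    ph3_m_variance: float
    reads_per_umi_mean: float
    seed: int
    s_signature_genes: list[str] = field(default_factory=list)
    g2m_signature_genes: list[str] = field(default_factory=list)
    phase_boost: float = 1.0
    generator_family: str = GENERATOR_FAMILY

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_antibodies(self) -> int:
        return len(self.manifest.antibodies)

    def __post_init__(self) -> None:
        self.cell_type_proportions = np.asarray(self.cell_type_proportions, float)
        self.phase_proportions = np.asarray(self.phase_proportions, float)
        self.rna_mean_matrix = np.asarray(self.rna_mean_matrix, float)
        self.adt_mean_matrix = np.asarray(self.adt_mean_matrix, float)
        self.rna_dispersion = np.asarray(self.rna_dispersion, float)
        self.adt_dispersion = np.asarray(self.adt_dispersion, float)
        self.validate()

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        for name, p, n in (
            ("cell_type_proportions", self.cell_type_proportions, len(self.cell_types)),
            ("phase_proportions", self.phase_proportions, len(PHASES)),
        ):
            if len(p) != n:
                raise ValidationError(f"{name} has length {len(p)}, expected {n}")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1 within 1e-9")
        n_types = len(self.cell_types)
        if self.rna_mean_matrix.shape != (n_types, self.n_genes):
            raise ValidationError(
                f"rna_mean_matrix shape {self.rna_mean_matrix.shape} != ({n_types}, {self.n_genes})"
            )
        if self.adt_mean_matrix.shape != (n_types, self.n_antibodies):
            raise ValidationError(
                f"adt_mean_matrix shape {self.adt_mean_matrix.shape} != ({n_types}, {self.n_antibodies})"
            )
        if self.rna_dispersion.shape != (self.n_genes,) or np.any(self.rna_dispersion <= 0):
            raise ValidationError("rna_dispersion must be positive, one k per gene")
        if self.adt_dispersion.shape != (self.n_antibodies,) or np.any(self.adt_dispersion <= 0):
            raise ValidationError("adt_dispersion must be positive, one k per antibody")
        if np.any(self.rna_mean_matrix < 0) or np.any(self.adt_mean_matrix < 0):
            raise ValidationError("all NB means must be >= 0")
        if self.ph3_m_mean <= self.ph3_null_mean:
            raise ValidationError("ph3_m_mean must exceed ph3_null_mean")
        if self.reads_per_umi_mean < 1:
            raise ValidationError("reads_per_umi_mean must be >= 1")
        if self.ph3_antibody not in self.manifest.antibodies:
            raise ValidationError(f"ph3_antibody {self.ph3_antibody!r} not in panel")
        missing = [g for g in self.s_signature_genes + self.g2m_signature_genes
                   if g not in self.gene_names]
        if missing:
            raise ValidationError(f"signature genes not in gene_names: {missing[:5]}")


@dataclass
class SyntheticDataset:
    """Generated dataset: both modalities, the molecule table, and the truth."""

    rna: CountMatrix
    adt: CountMatrix
    molecules: MoleculeTable
    truth: pd.DataFrame  # cell, cell_type, phase, is_M
    manifest: PanelManifest

    def equals(self, other: "SyntheticDataset") -> bool:
        truth_a = self.truth.reset_index(drop=True)
        truth_b = other.truth.reset_index(drop=True)
        return (
            self.rna.equals(other.rna)
            and self.adt.equals(other.adt)
            and self.molecules.equals(other.molecules)
            and truth_a.equals(truth_b)
            and self.manifest.equals(other.manifest)
        )


def _empty_dataset(config: SimulationConfig) -> SyntheticDataset:
    empty_rna = CountMatrix(
        cells=[], features=list(config.gene_names),
        counts=sp.csr_matrix((0, config.n_genes), dtype=np.int64), modality=RNA,
    )
    empty_adt = CountMatrix(
        cells=[], features=config.manifest.antibodies,
        counts=sp.csr_matrix((0, config.n_antibodies), dtype=np.int64), modality=ADT,
    )
    molecules = MoleculeTable(records=pd.DataFrame(columns=list(MoleculeTable.COLUMNS)))
    truth = pd.DataFrame(columns=["cell", "cell_type", "phase", "is_M"])
    return SyntheticDataset(empty_rna, empty_adt, molecules, truth, config.manifest)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full dataset from the configured mixture.

    Cell types and phases are categorical draws from the configured
    proportions; RNA and ADT UMI counts are NB draws at the (type, feature)
    means, with S/G2M signature genes multiplied by ``phase_boost`` in
    S-phase and G2M/M-phase cells respectively (mitosis keeps the G2M
    transcriptional program, so the RNA signature alone cannot isolate M).
    The phospho-H3 ADT column is redrawn from the M or null distribution per
    the true phase. Molecules are emitted for the RNA modality.
    """
    config.validate()
    if config.n_cells == 0:
        return _empty_dataset(config)

    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    cells = [f"cell_{i:06d}" for i in range(n)]

    type_idx = rng.choice(len(config.cell_types), size=n, p=config.cell_type_proportions)
    phase_idx = rng.choice(len(PHASES), size=n, p=config.phase_proportions)
    phases = np.array(PHASES)[phase_idx]
    is_m = phases == "M"

    # RNA: per-cell mean = type profile, with phase boosts on signature genes
    mu_rna = config.rna_mean_matrix[type_idx].copy()  # (n, n_genes)
    gene_pos = {g: j for j, g in enumerate(config.gene_names)}
    if config.phase_boost != 1.0:
        s_cols = [gene_pos[g] for g in config.s_signature_genes]
        g2m_cols = [gene_pos[g] for g in config.g2m_signature_genes]
        if s_cols:
            mu_rna[np.ix_(phases == "S", s_cols)] *= config.phase_boost
        if g2m_cols:
            mu_rna[np.ix_((phases == "G2M") | is_m, g2m_cols)] *= config.phase_boost
    rna_counts = draw_counts(rng, mu_rna, config.rna_dispersion[None, :])

    # ADT: type profiles, then override the phospho-H3 channel by true phase
    mu_adt = config.adt_mean_matrix[type_idx]
    adt_counts = draw_counts(rng, mu_adt, config.adt_dispersion[None, :])
    ph3_col = config.manifest.antibodies.index(config.ph3_antibody)
    ph3 = np.empty(n, dtype=np.int64)
    ph3[~is_m] = draw_counts_mean_var(
        rng, config.ph3_null_mean, config.ph3_null_variance, int((~is_m).sum())
    )
    ph3[is_m] = draw_counts_mean_var(
        rng, config.ph3_m_mean, config.ph3_m_variance, int(is_m.sum())
    )
    adt_counts[:, ph3_col] = ph3

    rna = CountMatrix(cells=cells, features=list(config.gene_names),
                      counts=sp.csr_matrix(rna_counts), modality=RNA)
    adt = CountMatrix(cells=cells, features=config.manifest.antibodies,
                      counts=sp.csr_matrix(adt_counts), modality=ADT)

    molecules = _molecules_from_counts(rng, rna, config.reads_per_umi_mean)

    truth = pd.DataFrame(
        {"cell": cells,
         "cell_type": [config.cell_types[t] for t in type_idx],
         "phase": phases,
         "is_M": is_m}
    )
    return SyntheticDataset(rna=rna, adt=adt, molecules=molecules, truth=truth,
                            manifest=config.manifest)


def _molecules_from_counts(
    rng: np.random.Generator, matrix: CountMatrix, reads_per_umi_mean: float
) -> MoleculeTable:
    """One molecule record per UMI; reads ~ 1 + Poisson(mean - 1)."""
    coo = matrix.counts.tocoo()
    if coo.nnz == 0:
        return MoleculeTable(records=pd.DataFrame(columns=list(MoleculeTable.COLUMNS)))
    reps = coo.data.astype(np.int64)
    total = int(reps.sum())
    cell_idx = np.repeat(coo.row, reps)
    feat_idx = np.repeat(coo.col, reps)
    # umi index within each (cell, feature) group: 0..count-1
    starts = np.concatenate(([0], np.cumsum(reps)[:-1]))
    within = np.arange(total) - np.repeat(starts, reps)
    reads = 1 + rng.poisson(reads_per_umi_mean - 1.0, size=total)
    cells_arr = np.array(matrix.cells)
    feats_arr = np.array(matrix.features)
    df = pd.DataFrame(
        {"cell": cells_arr[cell_idx],
         "feature": feats_arr[feat_idx],
         "umi": np.char.add("u", within.astype(str)),
         "reads": reads}
    )
    return MoleculeTable(records=df)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> list[Path]:
    """Write a dataset as MTX + TSV names per modality plus CSV tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    paths += _io.write_count_matrix(dataset.rna, d, prefix="rna_")
    paths += _io.write_count_matrix(dataset.adt, d, prefix="adt_")
    paths.append(_io.write_molecule_table(dataset.molecules, d / "molecules.csv"))
    truth_path = d / "truth.csv"
    dataset.truth.to_csv(truth_path, index=False)
    paths.append(truth_path)
    paths.append(_io.write_manifest(dataset.manifest, d / "manifest.csv"))
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_fixture`."""
    d = Path(directory)
    rna = _io.read_count_matrix(d, prefix="rna_")
    adt = _io.read_count_matrix(d, prefix="adt_")
    molecules = _io.read_molecule_table(d / "molecules.csv")
    truth = pd.read_csv(d / "truth.csv", dtype={"cell": str, "cell_type": str, "phase": str})
    if truth.empty:
        truth = pd.DataFrame(columns=["cell", "cell_type", "phase", "is_M"])
    else:
        truth["is_M"] = truth["is_M"].astype(bool)
    manifest = _io.read_manifest(d / "manifest.csv")
    return SyntheticDataset(rna=rna, adt=adt, molecules=molecules, truth=truth,
                            manifest=manifest)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_panel() -> PanelManifest:
    """A small CD4 T-cell-flavoured panel with surface, intracellular and PTM
    antibodies; two of the three PTM channels are biologically decoupled from
    their encoding gene's transcription."""
    rows = [
        ("CD4", "Cd4", "surface", None),
        ("CD8a", "Cd8a", "surface", None),
        ("CD19", "Cd19", "surface", None),
        ("CD44", "Cd44", "surface", None),
        ("STAT3", "Stat3", "intracellular", None),
        ("TCF-7", "Tcf7", "intracellular", None),
        ("NFAT1", "Nfatc2", "intracellular", None),
        ("Histone-H3", "Hist1h3a", "intracellular", None),
        ("S6", "Rps6", "intracellular", None),
        ("p-STAT3-Tyr705", "Stat3", "PTM", "STAT3"),
        ("p-H3-Ser10", "Hist1h3a", "PTM", "Histone-H3"),
        ("p-S6-Ser235/236", "Rps6", "PTM", "S6"),
    ]
    return PanelManifest(entries=pd.DataFrame(rows, columns=list(PanelManifest.COLUMNS)))


DEFAULT_PTM_DECOUPLING = {
    "p-STAT3-Tyr705": False,
    "p-H3-Ser10": True,       # driven by cell cycle, not Hist1h3a transcription
    "p-S6-Ser235/236": True,  # signalling-driven
}


def default_config(
    n_cells: int = 2000,
    n_genes: int = 300,
    seed: int = 0,
    n_s_signature: int = 10,
    n_g2m_signature: int = 10,
) -> SimulationConfig:
    """Study conditions for the synthetic experiment.

    Three cell types with distinct marker programs; ~24-hour activated
    T-cell cell-cycle mix (62% G1, 12% S, 22% G2M, 4% M); phospho-H3 null
    NB(mean 2, variance 8) versus mitotic NB(mean 50, variance 100); a mean
    of 4 reads per UMI. Mean profiles are drawn once from a config-seeded
    stream that is independent of the dataset-generation stream.
    """
    panel = default_panel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915_261]))
    cell_types = ["Th_activated", "Th_resting", "Th_memory", "Treg_like", "B_like", "NK_like"]
    proportions = np.array([0.30, 0.20, 0.15, 0.15, 0.10, 0.10])

    panel_genes = sorted(set(panel.entries["encoding_gene"]))
    s_sig = [f"Ssig{i+1}" for i in range(n_s_signature)]
    g2m_sig = [f"G2msig{i+1}" for i in range(n_g2m_signature)]
    mito = [f"mt-Gene{i+1}" for i in range(5)]
    n_named = len(panel_genes) + len(s_sig) + len(g2m_sig) + len(mito)
    if n_genes < n_named + 10:
        raise ValidationError(f"n_genes must be at least {n_named + 10}")
    filler = [f"Gene{i+1:04d}" for i in range(n_genes - n_named)]
    gene_names = panel_genes + s_sig + g2m_sig + mito + filler

    # per-gene baseline means, log-uniform over a realistic droplet range
    base = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=n_genes))
    n_types = len(cell_types)
    rna_mean = np.tile(base, (n_types, 1))
    # disjoint marker blocks among filler genes, elevated 8x per type
    filler_start = n_named
    block = max(1, len(filler) // (2 * n_types))
    for t in range(n_types):
        lo = filler_start + t * block
        rna_mean[t, lo:lo + block] *= 8.0
    # panel-encoding genes vary across types so coupled pairs carry signal
    for g in panel_genes:
        j = gene_names.index(g)
        rna_mean[:, j] = np.exp(rng.uniform(np.log(0.2), np.log(8.0), size=n_types))
    rna_dispersion = rng.uniform(1.0, 5.0, size=n_genes)

    # ADT: coupled antibodies track their gene's RNA mean (x25 capture scale);
    # decoupled PTMs draw per-type means log-uniformly, independent of RNA
    antibodies = panel.antibodies
    adt_mean = np.zeros((n_types, len(antibodies)))
    for a, ab in enumerate(antibodies):
        gene = panel.encoding_gene(ab)
        decoupled = DEFAULT_PTM_DECOUPLING.get(ab, False)
        if decoupled:
            adt_mean[:, a] = np.exp(rng.uniform(np.log(5.0), np.log(500.0), size=n_types))
        else:
            j = gene_names.index(gene)
            adt_mean[:, a] = 25.0 * rna_mean[:, j]
    adt_dispersion = rng.uniform(5.0, 15.0, size=len(antibodies))

    return SimulationConfig(
        n_cells=n_cells,
        cell_types=cell_types,
        cell_type_proportions=proportions,
        gene_names=gene_names,
        rna_mean_matrix=rna_mean,
        rna_dispersion=rna_dispersion,
        manifest=panel,
        adt_mean_matrix=adt_mean,
        adt_dispersion=adt_dispersion,
        ptm_decoupling=dict(DEFAULT_PTM_DECOUPLING),
        phase_proportions=np.array([0.62, 0.12, 0.22, 0.04]),
        ph3_antibody="p-H3-Ser10",
        ph3_null_mean=2.0,
        ph3_null_variance=8.0,
        ph3_m_mean=50.0,
        ph3_m_variance=100.0,
        reads_per_umi_mean=4.0,
        seed=seed,
        s_signature_genes=s_sig,
        g2m_signature_genes=g2m_sig,
        phase_boost=4.0,
    )
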