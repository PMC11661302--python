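# intraseq

Analysis pipeline for multimodal single-cell experiments that measure RNA
and antibody-derived tags (ADTs) — including antibodies against
intracellular proteins and post-translational modifications (PTMs) — in the
same cells. It is written for computational biologists who want the
analysis layer of such an experiment as tested, reusable functions:
depth-matched benchmarking preprocessing, the three normalizations the
modality mix requires, cell-type-level RNA–protein concordance, a
phospho-Histone-H3-based mitotic-cell caller, and ChIP-bound
transcription-factor target sets intersected with differential expression.

## What it computes

**Preprocessing** (`intraseq.preprocess`) makes libraries comparable before
quality comparisons: keep the top-N cells by total UMIs, thin sequencing
reads at the molecule level so reads per cell match a reference sample
(each read kept with probability `p = target/current`; a UMI survives iff
≥ 1 read survives, so a molecule with `r` reads survives w.p.
`1 − (1−p)^r`), and drop cells violating percentile QC rules on genes
detected, total UMIs, or mitochondrial fraction.

**Normalization** (`intraseq.normalize`):

- RNA: `ln(1 + count/total × 10,000)` per cell;
- ADT: centered log-ratio across cells,
  `clr(c,f) = ln(x_cf + 1) − (1/n)Σ_c ln(x_cf + 1)`;
- PTM ratio: `(ptm + 1)/(total + 1)` per cell against the matching
  total-protein antibody, then the across-cells CLR of the ratios.

**Concordance** (`intraseq.correlate`): Pearson r between per-cell-type
mean RNA of each antibody's encoding gene and its per-type mean ADT signal,
with two-sided p from `t = r√((n−2)/(1−r²))`, Benjamini–Hochberg FDR across
the panel, and classes *significant_positive* / *negative* / *minimal*.

**Mitotic calling** (`intraseq.cellcycle`): RNA signature scores give
provisional G1/S/G2M labels; phospho-H3-Ser10 ADT counts in non-mitotic
cells are modelled as `X ~ NB(μ, σ²)` with the null fitted by method of
moments on the S-phase cells (`μ̂ = (1/n)Σxᵢ`, `σ̂² = (1/n)Σ(xᵢ−μ̂)²`,
Poisson fallback when `σ̂² ≤ μ̂`); each other cell is tested upper-tail,
`p = P(X ≥ x)`, and cells with BH-adjusted p < α = 0.05 are relabelled M.

**TF targets** (`intraseq.tf_targets`): bound sets as
`(⋃ include lists) \ (⋃ exclude lists)`; per-gene Wilcoxon rank-sum DE
(exact enumeration for groups ≤ 8, tie-corrected normal approximation
otherwise) with `log2FC` on back-transformed means; a bound gene is a
target when some time point has FDR < 0.05 and |log2FC| > log2(1.5).

**Synthetic data** (`intraseq.simulate`) generates datasets with the
structure all of the above assumes — NB counts per cell type, coupled and
decoupled PTM channels, a G1/S/G2M/M phase mixture with phospho-H3 elevated
only in M, and a per-molecule read table — so the whole pipeline runs and
is tested without any external download.

## Worked example

```python
import pandas as pd
import intraseq as iq

cfg = iq.default_config(n_cells=2000, n_genes=300, seed=7)
ds = iq.generate_dataset(cfg)

rna_norm = iq.lognormalize_rna(ds.rna)
adt_norm = iq.clr_across_cells(ds.adt)

labels = ds.truth.set_index("cell")["cell_type"]
records = iq.rna_protein_correlation(
    iq.celltype_means(rna_norm, labels),
    iq.celltype_means(adt_norm, labels),
    ds.manifest,
)
print(records[["antibody", "target_class", "r", "fdr", "concordance_class"]]
      .round(4).to_string(index=False))

sig = iq.signature_phase_score(rna_norm, cfg.s_signature_genes,
                               cfg.g2m_signature_genes, seed=7)
ph3 = pd.Series(ds.adt.dense()[:, ds.adt.feature_index("p-H3-Ser10")],
                index=ds.adt.cells)
annotated, null = iq.annotate_phases(sig, ph3)
print(f"null: {null.family}(mu={null.mu_hat:.2f}, var={null.sigma2_hat:.2f})")
print(f"M-phase cells: {int((annotated['phase']=='M').sum())} "
      f"({(annotated['phase']=='M').mean()*100:.1f}%)")
```

prints

```
       antibody  target_class      r    fdr    concordance_class
            CD4       surface 0.9929 0.0001 significant_positive
           CD8a       surface 0.9932 0.0001 significant_positive
           CD19       surface 0.9947 0.0001 significant_positive
           CD44       surface 0.9979 0.0000 significant_positive
          STAT3 intracellular 0.9971 0.0000 significant_positive
          TCF-7 intracellular 0.9957 0.0000 significant_positive
          NFAT1 intracellular 0.9975 0.0000 significant_positive
     Histone-H3 intracellular 0.9962 0.0000 significant_positive
             S6 intracellular 0.9966 0.0000 significant_positive
 p-STAT3-Tyr705           PTM 0.9970 0.0000 significant_positive
     p-H3-Ser10           PTM 0.2146 0.6830              minimal
p-S6-Ser235/236           PTM 0.3195 0.5858              minimal

null: NB(mu=1.95, var=10.02)
M-phase cells: 80 (4.0%)
```

Every coupled antibody (surface and intracellular proteins, and the
transcription-coupled phospho-STAT3) shows a significantly positive
type-level RNA–protein correlation, while the two PTM channels whose
biology decouples them from transcription (phospho-H3 tracks mitosis,
phospho-S6 tracks signalling) are correctly classified *minimal* — protein
modification states that cannot be inferred from RNA. The mitotic caller
recovers 4.0% M-phase cells, matching the simulated mitotic fraction.

A command-line surface wraps the same functions:

```bash
intraseq simulate --out data/ --seed 7
intraseq normalize --rna data/ --adt data/ --manifest data/manifest.csv --out norm/
intraseq cellcycle --rna-norm norm/rna_lognorm.csv --adt data/ \
    --s-genes s.txt --g2m-genes g2m.txt --seed 7 --out phases.csv
```

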