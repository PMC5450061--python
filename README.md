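# cellverdict

Whole-tumor single-cell RNA-seq profiles every cell in a biopsy — neoplastic
cells and the infiltrating stromal/immune cells alike — and telling the two
apart by expression clustering alone is unreliable: clusters mix
stochastically, and tumor cells can express immune-associated genes.
`cellverdict` implements an integrative classification that anchors the
scRNA-seq data on a matched tumor/blood exome-seq experiment and combines
**four sources of per-cell evidence**:

1. **Large-scale CNVs.** Gains and losses are first called from exome
   tumor/blood depth ratios (run-length thresholding at 1 ± δ, default
   δ = 0.2, spans ≥ 10 Mb). In expression, each cell's profile is summarized
   in sliding windows of 100 genomically adjacent genes as
   log2((mean CPM + c)/(control mean + c)) against a non-malignant control,
   and per segment the cell's **sum-total CPM** is ranked within the
   empirical control distribution: a gain is *present* when the cell's
   quantile exceeds 1 − α, a loss when it falls below α (α = 0.05, the 5%
   significance level of the control distribution; one-sided because the
   direction is known from exome-seq).
2. **Germline heterozygous SNVs.** Sites with blood VAF ≈ 0.5 whose tumor
   VAF shifts away from 0.5 inside a CNV segment are informative: a cell
   carrying the loss can express only one allele (LOH), so observing *both*
   alleles (each with ≥ 2 reads, ≥ 3 reads total) is evidence against the
   deletion.
3. **Somatic SNVs.** Exome-validated somatic variants are tallied per cell;
   one expressed somatic SNV (alt reads ≥ 1) suffices to mark a cell
   neoplastic.
4. **Marker-space clustering.** Hierarchical clustering (complete linkage,
   Euclidean distance) over log2(CPM+1) vectors of tumor-stemness and
   macrophage/microglia markers. Clustering is corroborative only: it can
   confirm a non-neoplastic call, never make a neoplastic one on its own.

A deterministic decision table merges the votes into
`neoplastic / non_neoplastic / ambiguous`, with explicit conflict flags.
The package also scores **cell-cycle activity** (centered mean of
log2(CPM/10+1) over G1/S and G2/M programs; cycling when the averaged score
exceeds 1.2) and infers **ligand–receptor crosstalk** between populations
(ligand expressed by ≥ 20% of senders with mean > 2 CPM, receptor passing
the same rule among receivers by default).

Because the analysis is only testable end-to-end with ground truth, the
package ships a first-class **synthetic-data generator**: negative-binomial
counts with log-normal gene means, cell library factors and logistic
mean-dependent dropout, a clonal chr7-gain / chr10-loss tumor population,
CNV-free immune cells, LOH-driven monoallelic germline sites, sparsely
expressed somatic SNVs, cycling subpopulations and planted ligand–receptor
pairs — with full truth labels and byte-reproducible output.

## Worked example

```bash
cellverdict simulate --out sim --seed 4      # synthetic biopsy + config.yaml
cellverdict all --config sim/config.yaml --out run --seed 4
```

`run/verdicts.tsv` then starts:

```
cell_id  verdict     cnv_vote        germline_vote           somatic_vote  cluster_vote  conflict  rationale
T0000    neoplastic  supports_tumor  monoallelic_consistent  1             2             False     exome-defined CNV detected in expression; 1 expressed somatic SNV(s)
T0001    neoplastic  supports_tumor  monoallelic_consistent  0             2             False     exome-defined CNV detected in expression
```

Each row is one cell: the CNV vote says whether the exome-defined chr7
gain / chr10 loss was detected in that cell's expression, the germline vote
summarizes allele patterns at informative heterozygous sites (tumor cells
in the loss region are `monoallelic_consistent`), the somatic vote counts
expressed exome-validated SNVs, and the cluster vote is the marker-space
cluster id. `run/interactions.tsv` lists the recovered ligand–receptor
pairs (e.g. `IL1B → IL1R1`, `TGFB1 → TGFBR1`) with prevalence and mean CPM
in both populations, and `run/cell_cycle.tsv` carries the per-cell G1/S,
G2/M and averaged scores with the cycling/phase call.

The same stages are available programmatically:

```python
from cellverdict.simulate import SimulationConfig, simulate, write_bundle
from cellverdict import pipeline as pl

bundle = simulate(SimulationConfig(seed=4))
paths = write_bundle(bundle, "sim")
result = pl.run_pipeline(pl.load_config(paths["config"]), seed=4)
print(result.verdicts["verdict"].value_counts())
```

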