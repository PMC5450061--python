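"""Synthetic whole-tumor scRNA-seq datasets with matched exome-style tables.

The default scenario emulates the structure of a primary glioblastoma
biopsy: a clonal neoplastic population carrying a chromosome-7 gain and a
chromosome-10 loss, a minority (10%) immune population free of CNVs,
heterozygous germline SNVs that become monoallelic in the loss region of
neoplastic cells (LOH), sparsely expressed somatic SNVs, cycling tumor
subpopulations, and macrophage-expressed ligands whose cognate receptors
are expressed by the tumor cells.  Counts follow a negative-binomial model
(gamma-Poisson) with log-normal gene base means, log-normal cell library
factors, and a logistic mean-dependent dropout; a matched non-malignant
control matrix is drawn from the same baseline without CNVs or boosts.

Every output is reproducible bit-for-bit from the seed, and the emitted
files are exactly the formats the analysis modules consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cellverdict import markers
from cellverdict.io import (
    ExpressionMatrix,
    site_id,
    write_bed,
    write_expression,
    write_table,
    write_vcf,
)

PLANTED_LR_PAIRS = (
    ("IL1B", "IL1R1"),
    ("TNF", "TNFRSF1A"),
    ("TGFB1", "TGFBR1"),
    ("PDGFB", "PDGFRB"),
    ("HBEGF", "EGFR"),
)


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Counts and fractions describe the emulated biopsy: ~2000 genes over five
    chromosomes, 90 neoplastic and 10 immune cells plus a 200-cell
    non-malignant control, a clonal chr7 gain (fold 1.5) and chr10 loss
    (fold 0.5) at 90% tumor purity, six heterozygous germline SNVs inside
    the loss, twenty exome-validated somatic SNVs each expressed per
    expressing cell with probability 0.055 (so roughly two thirds of tumor
    cells express at least one), 20% allelic dropout at germline sites, and
    a 20% cycling fraction among tumor cells.
    """

    n_genes: int = 2000
    chromosomes: tuple[str, ...] = ("chr1", "chr5", "chr7", "chr10", "chr17")
    n_tumor_cells: int = 90
    n_immune_cells: int = 10
    n_control_cells: int = 200
    cnv_specs: tuple[tuple[str, str, float], ...] = (
        ("chr7", "gain", 1.5),
        ("chr10", "loss", 0.5),
    )
    purity: float = 0.9
    n_somatic_snvs: int = 20
    somatic_expression_rate: float = 0.055
    n_germline_het_snvs: int = 6
    allelic_dropout: float = 0.2
    allele_site_depth: float = 8.0
    nb_dispersion: float = 0.3  # var = mu + dispersion * mu^2
    base_mean_log: float = math.log(4.0)
    base_mean_sigma: float = 1.2
    library_sigma: float = 0.25
    dropout_midpoint: float = -2.0  # log2(mu+1) at 50% detection failure
    dropout_steepness: float = 1.0
    cycling_fraction: float = 0.2
    marker_base_mean: float = 0.5
    cycle_base_mean: float = 2.0
    marker_boost: float = 12.0
    cycle_boost: float = 8.0
    cycle_secondary_boost: float = 4.0  # the non-dominant program is elevated too
    lr_boost: float = 15.0
    germline_host_mean: float = 25.0
    decoy_mean: float = 0.02
    n_lr_decoys: int = 50
    gene_spacing: int = 100_000
    bin_size: int = 2_000_000
    depth_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        gpc = self.n_genes // len(self.chromosomes)
        if gpc < 1:
            raise ValueError("fewer genes than chromosomes")
        for count in (self.n_tumor_cells, self.n_immune_cells, self.n_control_cells):
            if count < 0:
                raise ValueError("cell counts must be non-negative")
        for _, direction, fold in self.cnv_specs:
            if direction not in ("gain", "loss"):
                raise ValueError(f"unknown CNV direction {direction!r}")
            if fold <= 0:
                raise ValueError("CNV folds must be positive")
        for p in (self.purity, self.somatic_expression_rate, self.allelic_dropout,
                  self.cycling_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_germline_het_snvs > gpc:
            raise ValueError("more germline SNVs than genes on the loss chromosome")
        if self.n_somatic_snvs > 3 * gpc:
            raise ValueError("more somatic SNVs than available host genes")


@dataclass
class SimulatedBundle:
    """All generated tables plus the hidden truth."""

    config: SimulationConfig
    annotation: pd.DataFrame
    biopsy: ExpressionMatrix  # tumor + immune cells, counts
    control: ExpressionMatrix  # non-malignant control, counts
    depth_bins: pd.DataFrame
    germline_sites: pd.DataFrame
    somatic_sites: pd.DataFrame
    allele_counts: pd.DataFrame
    lr_pairs: pd.DataFrame
    truth_cells: pd.DataFrame
    germline_truth: pd.DataFrame  # retained allele per site under LOH
    base_means: pd.Series | None = None  # generative per-gene base means


def _layout_genome(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene coordinates plus named special-gene placement per chromosome.

    Marker, cell-cycle and ligand-receptor genes are laid out on CNV-neutral
    chromosomes at evenly spaced slots so that window logic is exercised with
    realistic adjacency while segment statistics stay clean.
    """
    gpc = cfg.n_genes // len(cfg.chromosomes)
    neutral = [c for c in cfg.chromosomes if c not in {s[0] for s in cfg.cnv_specs}]
    ligands = [p[0] for p in PLANTED_LR_PAIRS]
    receptors = [p[1] for p in PLANTED_LR_PAIRS]
    decoys = [f"DECOYL{i:02d}" for i in range(cfg.n_lr_decoys)] + [
        f"DECOYR{i:02d}" for i in range(cfg.n_lr_decoys)
    ]
    special_by_chrom: dict[str, list[str]] = {c: [] for c in cfg.chromosomes}
    panels = [
        list(markers.GBM_TUMOR_MARKERS) + list(markers.G1S_GENES),
        list(markers.TAM_MARKERS) + list(markers.G2M_GENES),
        [g for g in ligands + [r for r in receptors if r not in markers.GBM_TUMOR_MARKERS]]
        + decoys,
    ]
    for chrom, panel in zip(neutral, panels):
        if len(panel) > gpc:
            raise ValueError(f"too many named genes for {chrom}")
        special_by_chrom[chrom] = panel

    rows = []
    counter = 0
    for chrom in cfg.chromosomes:
        names = special_by_chrom[chrom]
        slots = (
            np.linspace(2, gpc - 3, num=len(names)).round().astype(int)
            if names else np.array([], dtype=int)
        )
        slot_name = dict(zip(slots.tolist(), names))
        for j in range(gpc):
            gene = slot_name.get(j, f"SIMG{counter:05d}")
            counter += 1
            start = (j + 1) * cfg.gene_spacing
            rows.append((gene, chrom, start, start + 10_000, "+"))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if ann["gene_id"].duplicated().any():
        raise ValueError("named gene placed twice; adjust chromosome panels")
    return ann, special_by_chrom


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _detection_prob(mu: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    x = (np.log2(mu + 1.0) - midpoint) / steepness
    return 1.0 / (1.0 + np.exp(-x))


def simulate(cfg: SimulationConfig | None = None) -> SimulatedBundle:
    """Draw a complete dataset bundle from the generative model."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ann, _special = _layout_genome(cfg)
    genes = ann["gene_id"].tolist()
    gene_pos = {g: i for i, g in enumerate(genes)}
    chrom_of = dict(zip(ann["gene_id"], ann["chrom"]))

    # --- base means with overrides for named gene classes
    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sigma, size=len(genes))
    named = (
        set(markers.GBM_TUMOR_MARKERS) | set(markers.TAM_MARKERS)
        | {p[0] for p in PLANTED_LR_PAIRS} | {p[1] for p in PLANTED_LR_PAIRS}
    )
    cycle_named = set(markers.G1S_GENES) | set(markers.G2M_GENES)
    for gene in genes:
        if gene in named:
            base[gene_pos[gene]] = cfg.marker_base_mean
        elif gene in cycle_named:
            base[gene_pos[gene]] = cfg.cycle_base_mean
        elif gene.startswith("DECOY"):
            base[gene_pos[gene]] = cfg.decoy_mean

    # germline host genes: well-expressed genes inside the loss chromosome(s)
    loss_chroms = [c for c, d, _ in cfg.cnv_specs if d == "loss"]
    host_chrom = loss_chroms[0] if loss_chroms else cfg.chromosomes[-1]
    host_candidates = [g for g in genes if chrom_of[g] == host_chrom and not g[0].isdigit()]
    host_idx = np.linspace(5, len(host_candidates) - 6, cfg.n_germline_het_snvs).round().astype(int)
    germline_hosts = [host_candidates[i] for i in host_idx]
    for gene in germline_hosts:
        base[gene_pos[gene]] = cfg.germline_host_mean

    # somatic host genes: expression-biased choice on non-loss chromosomes
    som_pool = [
        g for g in genes
        if chrom_of[g] not in loss_chroms and g.startswith("SIMG")
        and base[gene_pos[g]] >= np.median(base)
    ]
    somatic_hosts = list(rng.choice(som_pool, size=cfg.n_somatic_snvs, replace=False))

    # --- cells and truth
    tumor_cells = [f"T{i:04d}" for i in range(cfg.n_tumor_cells)]
    immune_cells = [f"I{i:04d}" for i in range(cfg.n_immune_cells)]
    control_cells = [f"N{i:04d}" for i in range(cfg.n_control_cells)]
    biopsy_cells = tumor_cells + immune_cells

    n_cycling = int(round(cfg.cycling_fraction * cfg.n_tumor_cells))
    cycling_cells = list(rng.choice(tumor_cells, size=n_cycling, replace=False))
    phases = ["G1/S" if i % 2 == 0 else "G2/M" for i in range(n_cycling)]
    phase_of = dict(zip(cycling_cells, phases))

    fold_by_chrom = {c: f for c, _, f in cfg.cnv_specs}
    chrom_fold = np.ones(len(genes))
    for gene in genes:
        chrom_fold[gene_pos[gene]] = fold_by_chrom.get(chrom_of[gene], 1.0)

    g1s_idx = [gene_pos[g] for g in markers.G1S_GENES if g in gene_pos]
    g2m_idx = [gene_pos[g] for g in markers.G2M_GENES if g in gene_pos]
    tum_idx = [gene_pos[g] for g in markers.GBM_TUMOR_MARKERS if g in gene_pos]
    tam_idx = [gene_pos[g] for g in markers.TAM_MARKERS if g in gene_pos]
    lig_idx = [gene_pos[p[0]] for p in PLANTED_LR_PAIRS]
    rec_idx = [gene_pos[p[1]] for p in PLANTED_LR_PAIRS]

    def draw_matrix(cells: list[str], kind: str) -> pd.DataFrame:
        mu = np.tile(base[:, None], (1, len(cells)))
        if kind == "tumor":
            mu *= chrom_fold[:, None]
            mu[tum_idx, :] *= cfg.marker_boost
            mu[rec_idx, :] *= cfg.lr_boost
            # a cycling cell runs both programs, the dominant one peaking
            for j, cell in enumerate(cells):
                phase = phase_of.get(cell)
                if phase == "G1/S":
                    mu[g1s_idx, j] *= cfg.cycle_boost
                    mu[g2m_idx, j] *= cfg.cycle_secondary_boost
                elif phase == "G2/M":
                    mu[g2m_idx, j] *= cfg.cycle_boost
                    mu[g1s_idx, j] *= cfg.cycle_secondary_boost
        elif kind == "immune":
            mu[tam_idx, :] *= cfg.marker_boost
            mu[lig_idx, :] *= cfg.lr_boost
        lib = rng.lognormal(0.0, cfg.library_sigma, size=len(cells))
        mu = mu * lib[None, :]
        counts = _nb_counts(rng, mu, cfg.nb_dispersion)
        detect = rng.random(mu.shape) < _detection_prob(
            mu, cfg.dropout_midpoint, cfg.dropout_steepness
        )
        return pd.DataFrame(counts * detect, index=genes, columns=cells)

    tumor_mat = draw_matrix(tumor_cells, "tumor")
    immune_mat = draw_matrix(immune_cells, "immune")
    control_mat = draw_matrix(control_cells, "control")
    biopsy = ExpressionMatrix(pd.concat([tumor_mat, immune_mat], axis=1))
    control = ExpressionMatrix(
        control_mat,
        group=pd.Series("control", index=control_mat.columns),
    )

    # --- exome depth-ratio bins (bulk biopsy vs blood at the given purity)
    bin_rows = []
    gpc = cfg.n_genes // len(cfg.chromosomes)
    chrom_len = (gpc + 1) * cfg.gene_spacing
    for chrom in cfg.chromosomes:
        fold = fold_by_chrom.get(chrom, 1.0)
        bulk = 1.0 + cfg.purity * (fold - 1.0)
        for start in range(0, chrom_len, cfg.bin_size):
            end = min(start + cfg.bin_size, chrom_len)
            ratio = bulk + rng.normal(0.0, cfg.depth_noise_sd)
            bin_rows.append((chrom, start, end, max(ratio, 0.01)))
    depth_bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "depth_ratio"])

    # --- germline heterozygous sites inside the loss, with LOH truth
    bases = ["A", "C", "G", "T"]
    germ_rows, truth_rows = [], []
    for gene in germline_hosts:
        pos = int(ann.loc[ann["gene_id"] == gene, "start"].iloc[0]) + 100
        ref, alt = rng.choice(bases, size=2, replace=False)
        retained = str(rng.choice(["ref", "alt"]))
        vaf_blood = float(np.clip(0.5 + rng.normal(0.0, 0.01), 0.45, 0.55))
        # one tumor copy retained at purity p against the diploid normal background
        p = cfg.purity
        alt_copies = (1 - p) * 1 + (p * 1 if retained == "alt" else 0)
        total_copies = (1 - p) * 2 + p * 1
        vaf_tumor = float(alt_copies / total_copies)
        sid = site_id(host_chrom, pos, ref, alt)
        germ_rows.append((sid, host_chrom, pos, ref, alt, "germline", vaf_blood, vaf_tumor))
        truth_rows.append((sid, gene, retained))
    germline_sites = pd.DataFrame(
        germ_rows,
        columns=["site_id", "chrom", "pos", "ref", "alt", "kind", "vaf_blood", "vaf_tumor"],
    )
    germline_truth = pd.DataFrame(truth_rows, columns=["site_id", "gene_id", "retained_allele"])

    # --- somatic sites (clonal, VAF ~ purity/2)
    som_rows = []
    for gene in somatic_hosts:
        row = ann.loc[ann["gene_id"] == gene].iloc[0]
        pos = int(row["start"]) + 200
        ref, alt = rng.choice(bases, size=2, replace=False)
        vaf = float(np.clip(cfg.purity * 0.5 + rng.normal(0.0, 0.03), 0.05, 0.95))
        som_rows.append(
            (site_id(row["chrom"], pos, ref, alt), row["chrom"], pos, ref, alt,
             "somatic", None, vaf)
        )
    somatic_sites = pd.DataFrame(
        som_rows,
        columns=["site_id", "chrom", "pos", "ref", "alt", "kind", "vaf_blood", "vaf_tumor"],
    )

    # --- per-cell allele counts at SNV sites (biopsy cells, expressed sites only)
    retained_of = dict(zip(germline_truth["site_id"], germline_truth["retained_allele"]))
    gene_of_site = dict(zip(germline_truth["site_id"], germline_truth["gene_id"]))
    ac_rows = []
    for _, site in germline_sites.iterrows():
        gene = gene_of_site[site["site_id"]]
        for cell in biopsy_cells:
            if biopsy.values.at[gene, cell] == 0:
                continue
            n = int(rng.poisson(cfg.allele_site_depth))
            if n == 0:
                continue
            is_tumor = cell.startswith("T")
            if is_tumor:
                # clonal LOH: only the retained haplotype is present
                refc, altc = (n, 0) if retained_of[site["site_id"]] == "ref" else (0, n)
            elif rng.random() < cfg.allelic_dropout:
                refc, altc = (n, 0) if rng.random() < 0.5 else (0, n)
            else:
                altc = int(rng.binomial(n, 0.5))
                refc = n - altc
            ac_rows.append(
                (cell, site["chrom"], site["pos"], site["ref"], site["alt"], refc, altc)
            )
    som_host_of = dict(zip(somatic_sites["site_id"], somatic_hosts))
    for _, site in somatic_sites.iterrows():
        gene = som_host_of[site["site_id"]]
        for cell in biopsy_cells:
            if biopsy.values.at[gene, cell] == 0:
                continue
            is_tumor = cell.startswith("T")
            expressed_variant = is_tumor and rng.random() < cfg.somatic_expression_rate
            if expressed_variant:
                altc = 1 + int(rng.poisson(3.0))
                refc = int(rng.poisson(3.0))
            else:
                altc = 0
                refc = 1 + int(rng.poisson(3.0))
            ac_rows.append(
                (cell, site["chrom"], site["pos"], site["ref"], site["alt"], refc, altc)
            )
    allele_counts = pd.DataFrame(
        ac_rows,
        columns=["cell_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"],
    )

    # --- ligand-receptor database: planted pairs among decoys
    lr_rows = list(PLANTED_LR_PAIRS) + [
        (f"DECOYL{i:02d}", f"DECOYR{i:02d}") for i in range(cfg.n_lr_decoys)
    ]
    lr_pairs = pd.DataFrame(lr_rows, columns=["ligand", "receptor"])

    # --- truth table
    truth = pd.DataFrame(
        {
            "cell_id": biopsy_cells,
            "true_class": ["neoplastic"] * len(tumor_cells) + ["immune"] * len(immune_cells),
            "cycling": [c in phase_of for c in biopsy_cells],
            "phase": [phase_of.get(c, "none") for c in biopsy_cells],
        }
    )
    for chrom, direction, _fold in cfg.cnv_specs:
        truth[f"{chrom}_{direction}"] = [c.startswith("T") for c in biopsy_cells]

    return SimulatedBundle(
        config=cfg,
        annotation=ann,
        biopsy=biopsy,
        control=control,
        depth_bins=depth_bins,
        germline_sites=germline_sites,
        somatic_sites=somatic_sites,
        allele_counts=allele_counts,
        lr_pairs=lr_pairs,
        truth_cells=truth,
        germline_truth=germline_truth,
        base_means=pd.Series(base, index=genes, name="base_mean"),
    )


def write_bundle(bundle: SimulatedBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact formats the analysis modules read.

    Also emits a ready-to-run pipeline configuration (``config.yaml``) with
    paths relative to the output directory, and the simulation parameters as
    JSON.  Returns the path of every written file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    gpc = cfg.n_genes // len(cfg.chromosomes)
    contig_lengths = {c: (gpc + 1) * cfg.gene_spacing for c in cfg.chromosomes}

    paths = {
        "biopsy_counts": out / "biopsy_counts.tsv",
        "control_counts": out / "control_counts.tsv",
        "annotation": out / "genes.bed",
        "depth_ratio": out / "depth_ratio.tsv",
        "germline_vcf": out / "germline.vcf",
        "somatic_vcf": out / "somatic.vcf",
        "allele_counts": out / "allele_counts.tsv",
        "lr_pairs": out / "lr_pairs.tsv",
        "truth_labels": out / "truth_labels.tsv",
        "germline_truth": out / "truth_germline_sites.tsv",
        "config": out / "config.yaml",
        "sim_params": out / "sim_params.json",
    }
    write_expression(bundle.biopsy, paths["biopsy_counts"])
    write_expression(bundle.control, paths["control_counts"])
    write_bed(bundle.annotation, paths["annotation"])
    write_table(bundle.depth_bins, paths["depth_ratio"])
    write_vcf(bundle.germline_sites, paths["germline_vcf"], contig_lengths)
    write_vcf(bundle.somatic_sites, paths["somatic_vcf"], contig_lengths)
    write_table(bundle.allele_counts, paths["allele_counts"])
    with open(paths["lr_pairs"], "w") as fh:
        fh.write("ligand\treceptor\n")
        for row in bundle.lr_pairs.itertuples(index=False):
            fh.write(f"{row.ligand}\t{row.receptor}\n")
    write_table(bundle.truth_cells, paths["truth_labels"])
    write_table(bundle.germline_truth, paths["germline_truth"])

    pipeline_cfg = {
        "inputs": {
            "tumor_expression": "biopsy_counts.tsv",
            "control_expression": "control_counts.tsv",
            "annotation": "genes.bed",
            "depth_ratio": "depth_ratio.tsv",
            "germline_vcf": "germline.vcf",
            "somatic_vcf": "somatic.vcf",
            "allele_counts": "allele_counts.tsv",
            "lr_pairs": "lr_pairs.tsv",
        },
        "params": {},
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    with open(paths["sim_params"], "w") as fh:
        cfg_dict = asdict(cfg)
        cfg_dict["chromosomes"] = list(cfg.chromosomes)
        cfg_dict["cnv_specs"] = [list(s) for s in cfg.cnv_specs]
        json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def summarize_truth(bundle: SimulatedBundle) -> dict:
    """Deterministic tabulation of the hidden truth for test assertions."""
    truth = bundle.truth_cells
    class_counts = truth["true_class"].value_counts().to_dict()
    carriage = {
        col: int(truth[col].sum())
        for col in truth.columns
        if col.endswith(("_gain", "_loss"))
    }
    return {
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "cycling_counts": int(truth["cycling"].sum()),
        "segment_carriage": carriage,
        "n_germline_sites": int(len(bundle.germline_sites)),
        "n_somatic_sites": int(len(bundle.somatic_sites)),
        "n_allele_count_rows": int(len(bundle.allele_counts)),
        "mean_library_size": float(bundle.biopsy.values.sum(axis=0).mean()),
    }
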