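"""Editable default gene lists for marker-space clustering and cell-cycle scoring.

These ship as configuration defaults, not as fixed biology: every pipeline
entry point accepts replacement lists.  The glioma stem-cell markers are the
canonical GBM panel (CD44, PROM1/CD133, NES, KLF4, MYC, NANOG, STAT3, SOX2,
MET); the macrophage/microglia panel and the G1/S and G2/M programs follow
the gene sets in common use for glioma single-cell studies.
"""

GBM_TUMOR_MARKERS = (
    "CD44", "PROM1", "NES", "KLF4", "MYC", "NANOG", "STAT3", "SOX2", "MET",
    "EGFR", "OLIG2", "GFAP",
)

TAM_MARKERS = (
    "AIF1", "CD14", "CD68", "CSF1R", "CX3CR1", "P2RY12", "TMEM119",
    "ITGAM", "PTPRC", "TYROBP", "C1QA", "C1QB", "FCGR1A",
)

G1S_GENES = (
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "HELLS", "RFC2", "RPA2",
    "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7", "POLD3",
    "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1", "USP1",
    "CLSPN", "POLA1", "CHAF1B", "BRIP1", "E2F8",
)

G2M_GENES = (
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "SMC4",
    "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
)
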