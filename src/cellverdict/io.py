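"""Shared data model and I/O for expression matrices, annotation, variants and tables.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open; GTF is 1-based closed.  Everything is converted to 1-based closed
internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

COUNTS = "counts"
CPM = "CPM"
CPM_TOTAL = 1e6


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x cells abundance matrix with a unit tag and optional cell groups.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and cell ids as columns.  Entries
        must be non-negative; gene and cell ids must be unique.
    unit
        Either ``"counts"`` (raw) or ``"CPM"`` (each non-zero cell column sums
        to 1e6).
    group
        Optional per-cell label (e.g. ``tumor`` / ``control``), indexed by
        cell id.
    zero_cells
        Cell ids whose columns were all zero when the matrix was normalized;
        these columns stay all-zero under CPM and are carried as a flag.
    """

    values: pd.DataFrame
    unit: str = COUNTS
    group: pd.Series | None = None
    zero_cells: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.unit not in (COUNTS, CPM):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        if not self.values.columns.is_unique:
            raise ValueError("cell ids are not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")
        if self.group is not None:
            self.group = self.group.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        """Re-check all invariants, including CPM column sums."""
        self.__post_init__()
        if self.unit == CPM:
            sums = self.values.sum(axis=0).to_numpy()
            nonzero = sums > 0
            if nonzero.any():
                rel = np.abs(sums[nonzero] - CPM_TOTAL) / CPM_TOTAL
                if rel.max() > 1e-6:
                    raise ValueError("CPM column sums deviate from 1e6")
            zero_ids = set(self.values.columns[~nonzero])
            if not zero_ids.issubset(self.zero_cells):
                raise ValueError("all-zero CPM columns are not flagged in zero_cells")

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        group = self.group.loc[list(cells)] if self.group is not None else None
        return ExpressionMatrix(
            self.values[list(cells)], unit=self.unit, group=group,
            zero_cells=tuple(c for c in self.zero_cells if c in set(cells)),
        )


def to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every non-zero cell column to sum to one million.

    All-zero columns are left untouched and recorded in ``zero_cells``.
    Calling on a matrix already in CPM is a warning no-op.
    """
    if m.unit == CPM:
        log.warning("to_cpm called on a matrix already in CPM; returning unchanged")
        return m
    sums = m.values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        log.warning("%d all-zero cell columns left unscaled by CPM", int(zero.sum()))
    denom = np.where(zero, 1.0, sums.to_numpy(dtype=float))
    scale = np.where(zero, 1.0, CPM_TOTAL / denom)
    values = m.values.astype(float).mul(scale, axis=1)
    return ExpressionMatrix(
        values, unit=CPM, group=m.group,
        zero_cells=tuple(m.values.columns[zero]),
    )


_UNIT_RE = re.compile(r"unit\s*[:=]\s*(\S+)", re.IGNORECASE)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from TSV or MatrixMarket MTX.

    TSV layout: genes as rows, first column gene id, header row of cell ids.
    Leading ``#`` comment lines are allowed; a comment declaring ``unit=CPM``
    marks the matrix as CPM, otherwise counts is assumed.  Duplicate gene rows
    are collapsed by summation (logged).  MTX input requires the two name
    files (one id per line) and checks their lengths against the matrix shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        unit = COUNTS
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                match = _UNIT_RE.search(line)
                if match and match.group(1).upper() == "CPM":
                    unit = CPM
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            try:
                values = pd.read_csv(fh, sep="\t", index_col=0)
            except Exception as exc:  # pandas raises several parse error types
                raise ParseError(f"malformed expression TSV {path}: {exc}") from exc
    elif format == "mtx":
        from scipy import io as spio

        if genes_file is None or cells_file is None:
            raise ValueError("MTX input requires genes_file and cells_file")
        try:
            mat = spio.mmread(str(path))
        except Exception as exc:
            raise ParseError(f"malformed MTX {path}: {exc}") from exc
        genes = [ln.strip() for ln in open(genes_file) if ln.strip()]
        cells = [ln.strip() for ln in open(cells_file) if ln.strip()]
        mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if mat.shape != (len(genes), len(cells)):
            raise ParseError(
                f"MTX shape {mat.shape} does not match name files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        values = pd.DataFrame(mat, index=genes, columns=cells)
        unit = COUNTS
    else:
        raise ValueError(f"unknown expression format {format!r}")

    try:
        values = values.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric expression entries in {path}: {exc}") from exc
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][:5].tolist()
        raise ParseError(f"missing/ragged expression entries in {path}, e.g. rows {bad}")
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by summation", n_dup)
        values = values.groupby(level=0, sort=False).sum()
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, unit=unit)


def write_expression(
    m: ExpressionMatrix, path: str | Path, float_format: str = "%.10g"
) -> None:
    """Write a matrix as TSV with a leading ``# unit=`` comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit={m.unit}\n")
        m.values.to_csv(fh, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Gene annotation and genomic ordering
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read gene coordinates from BED (>=4 columns) or GTF.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand in
    1-based closed coordinates.  One record per gene_id is retained: for BED,
    the first occurrence; for GTF, ``gene`` features when present, otherwise
    the per-gene min/max over all features.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gtf" if suffix in (".gtf", ".gff") else "bed"
    if format == "bed":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: BED line has <4 columns")
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                rows.append(
                    (parts[3], parts[0], int(parts[1]) + 1, int(parts[2]), strand)
                )
        ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    elif format == "gtf":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ParseError(f"{path}:{lineno}: GTF line has <9 columns")
                match = _GTF_GENE_ID.search(parts[8])
                if not match:
                    raise ParseError(f"{path}:{lineno}: GTF attributes lack gene_id")
                strand = parts[6] if parts[6] in "+-" else "."
                rows.append(
                    (match.group(1), parts[0], parts[2], int(parts[3]), int(parts[4]), strand)
                )
        raw = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "feature", "start", "end", "strand"]
        )
        gene_rows = raw[raw["feature"] == "gene"]
        if not gene_rows.empty:
            ann = gene_rows.drop(columns="feature")
        else:
            ann = (
                raw.groupby("gene_id", sort=False)
                .agg(chrom=("chrom", "first"), start=("start", "min"),
                     end=("end", "max"), strand=("strand", "first"))
                .reset_index()
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    if (ann["start"] >= ann["end"]).any():
        bad = ann.loc[ann["start"] >= ann["end"], "gene_id"].tolist()[:5]
        raise ParseError(f"annotation records with start >= end, e.g. {bad}")
    n_dup = int(ann["gene_id"].duplicated().sum())
    if n_dup:
        log.info("dropping %d duplicate annotation records (first kept)", n_dup)
        ann = ann.drop_duplicates("gene_id", keep="first")
    return ann.reset_index(drop=True)[["gene_id", "chrom", "start", "end", "strand"]]


def write_bed(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann[["chrom", "start", "end", "gene_id", "strand"]].copy()
    out["start"] = out["start"] - 1  # back to BED 0-based half-open
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def _chrom_sort_key(chrom: str):
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def natural_chrom_sort(chroms: Iterable[str]) -> list[str]:
    """chr1..chr22, chrX, chrY, chrM, then anything else lexicographically."""
    return sorted(set(chroms), key=_chrom_sort_key)


def order_genes(
    ann: pd.DataFrame,
    genes: Sequence[str],
    chrom_order: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Order measured genes genomically within each chromosome.

    Genes are sorted by start coordinate (strand ignored), ties broken by
    gene_id lexicographically.  Genes in ``genes`` but absent from the
    annotation are excluded and counted in the log.  Raises if no measured
    gene is annotated.
    """
    measured = set(map(str, genes))
    sub = ann[ann["gene_id"].isin(measured)]
    n_missing = len(measured) - sub["gene_id"].nunique()
    if n_missing:
        log.info("%d measured genes absent from annotation; excluded", n_missing)
    if sub.empty:
        raise ValueError("no measured gene is present in the annotation")
    chroms = (
        list(chrom_order)
        if chrom_order is not None
        else natural_chrom_sort(sub["chrom"])
    )
    out: dict[str, list[str]] = {}
    for chrom in chroms:
        block = sub[sub["chrom"] == chrom]
        if block.empty:
            continue
        block = block.sort_values(["start", "gene_id"], kind="mergesort")
        out[chrom] = block["gene_id"].tolist()
    return out


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

GERMLINE = "germline"
SOMATIC = "somatic"


def site_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def _info_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0]
    return float(value)


def read_vcf(
    path: str | Path,
    kind: str,
    vaf_blood_key: str = "VAF_BLOOD",
    vaf_tumor_key: str = "VAF_TUMOR",
) -> pd.DataFrame:
    """Read SNV sites from a VCF 4.x file.

    ``kind`` is ``germline`` or ``somatic``; germline records must carry the
    blood VAF INFO field.  Returns columns site_id, chrom, pos, ref, alt,
    kind, vaf_blood, vaf_tumor.
    """
    if kind not in (GERMLINE, SOMATIC):
        raise ValueError(f"kind must be germline or somatic, got {kind!r}")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if rec.ref == alt:
                    raise ParseError(f"{path}: site with ref == alt at {rec.pos}")
                vaf_blood = _info_float(rec.info.get(vaf_blood_key))
                vaf_tumor = _info_float(rec.info.get(vaf_tumor_key))
                if kind == GERMLINE and vaf_blood is None:
                    raise ParseError(
                        f"{path}: germline site {rec.chrom}:{rec.pos} lacks "
                        f"{vaf_blood_key}"
                    )
                rows.append(
                    (
                        site_id(rec.chrom, rec.pos, rec.ref, alt),
                        rec.chrom,
                        rec.pos,
                        rec.ref,
                        alt,
                        kind,
                        vaf_blood,
                        vaf_tumor,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "chrom", "pos", "ref", "alt", "kind", "vaf_blood", "vaf_tumor",
        ],
    )


def write_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNV sites as an uncompressed VCF 4.2 file with VAF INFO fields."""
    sites = sites.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
    )
    chroms = natural_chrom_sort(sites["chrom"]) if len(sites) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=VAF_BLOOD,Number=1,Type=Float,'
            'Description="Variant allele frequency in blood exome-seq">\n'
        )
        fh.write(
            '##INFO=<ID=VAF_TUMOR,Number=1,Type=Float,'
            'Description="Variant allele frequency in tumor exome-seq">\n'
        )
        for chrom in chroms:
            length = (
                contig_lengths[chrom]
                if contig_lengths and chrom in contig_lengths
                else int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1_000_000
            )
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples(index=False):
            info = []
            if getattr(row, "vaf_blood", None) is not None and not pd.isna(row.vaf_blood):
                info.append(f"VAF_BLOOD={row.vaf_blood:.4f}")
            if getattr(row, "vaf_tumor", None) is not None and not pd.isna(row.vaf_tumor):
                info.append(f"VAF_TUMOR={row.vaf_tumor:.4f}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + (";".join(info) or ".")
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

_ALLELE_COLS = ["cell_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Per-cell ref/alt read counts at SNV sites.

    TSV columns: cell_id, chrom, pos, ref, alt, ref_count, alt_count.
    Adds a site_id column matching the VCF readers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ALLELE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: allele-count table lacks columns {missing}")
    if (df[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative allele counts")
    df = df.copy()
    df["site_id"] = [
        site_id(c, int(p), r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return df


def read_depth_bins(path: str | Path) -> pd.DataFrame:
    """Tumor/blood exome depth ratios per genomic bin (chrom, start, end, depth_ratio)."""
    df = pd.read_csv(path, sep="\t")
    needed = ["chrom", "start", "end", "depth_ratio"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: depth-ratio table lacks columns {missing}")
    if (df["depth_ratio"] < 0).any():
        raise ParseError(f"{path}: negative depth ratios")
    return df[needed].copy()


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Two-column ligand/receptor pair database; malformed rows are rejected
    with their line numbers."""
    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                bad.append(lineno)
                continue
            rows.append((parts[0].strip(), parts[1].strip()))
    if bad:
        raise ParseError(f"{path}: malformed ligand-receptor rows at lines {bad}")
    if rows and rows[0] == ("ligand", "receptor"):
        rows = rows[1:]
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Deterministic TSV writer used for all pipeline outputs."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
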