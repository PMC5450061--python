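"""Per-cell evidence from expressed germline and somatic SNVs.

Germline heterozygous sites (blood VAF near 0.5) whose tumor VAF shifts away
from 0.5 and that lie inside an exome CNV segment are "informative": in a
cell carrying a copy-number loss they should show only one allele (LOH),
whereas a CNV-free cell can express both.  Somatic SNVs validated in
exome-seq give direct positive evidence: a cell expressing at least one is
classified as neoplastic downstream.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from cellverdict.cnv import CnvSegment, LOSS

log = logging.getLogger(__name__)

# per-site calls
NO_COVERAGE = "no_coverage"
REF_ONLY = "ref_only"
ALT_ONLY = "alt_only"
BIALLELIC = "biallelic"

# per-cell summaries
MONOALLELIC_CONSISTENT = "monoallelic_consistent"
BIALLELIC_OBSERVED = "biallelic_observed"
UNINFORMATIVE = "uninformative"


def select_informative_germline(
    sites: pd.DataFrame,
    segments: Sequence[CnvSegment],
    het_tol: float = 0.1,
    shift_min: float = 0.15,
) -> pd.DataFrame:
    """Select heterozygous germline sites with a tumor VAF shift inside a CNV segment.

    Keeps sites with |vaf_blood - 0.5| <= het_tol, |vaf_tumor - 0.5| >=
    shift_min and position inside one of the exome segments.  The containing
    segment id and direction are recorded per site; sites on gain segments
    carry allelic imbalance rather than strict LOH, so the direction flag lets
    downstream logic restrict the mono/biallelic argument to losses.
    """
    if not segments:
        log.warning("no CNV segments supplied; no informative germline sites")
        return sites.iloc[0:0].assign(segment_id=pd.Series(dtype=str),
                                      segment_direction=pd.Series(dtype=str))
    germ = sites[sites["kind"] == "germline"]
    rows = []
    for row in germ.itertuples(index=False):
        if row.vaf_blood is None or pd.isna(row.vaf_blood):
            raise ValueError(f"germline site {row.site_id} lacks a blood VAF")
        if abs(row.vaf_blood - 0.5) > het_tol:
            continue
        if abs(row.vaf_tumor - 0.5) < shift_min:
            continue
        hit = None
        for seg in segments:
            if row.chrom != seg.chrom:
                continue
            if seg.whole_chromosome or seg.start <= row.pos <= seg.end:
                hit = seg
                break
        if hit is None:
            continue
        rows.append({**row._asdict(), "segment_id": hit.id, "segment_direction": hit.direction})
    out = pd.DataFrame(rows, columns=list(germ.columns) + ["segment_id", "segment_direction"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def call_allele_pattern(
    counts: pd.DataFrame,
    informative_sites: pd.DataFrame,
    min_reads: int = 3,
    min_minor: int = 2,
    cells: Sequence[str] | None = None,
    known_sites: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call per-site allele status and a per-cell mono/biallelic summary.

    Per covered site: ``no_coverage`` if ref+alt < min_reads; ``biallelic``
    if both alleles have >= min_minor reads; otherwise ``ref_only`` /
    ``alt_only``.  Per cell: ``biallelic_observed`` if any site is biallelic,
    ``monoallelic_consistent`` if at least one covered site and none
    biallelic, else ``uninformative``.

    ``counts`` rows at sites absent from ``informative_sites`` are ignored
    when those sites appear in ``known_sites`` (they belong to other site
    classes, e.g. somatic); rows referencing sites unknown to both lists are
    rejected with an error naming the offenders.

    Returns ``(site_calls, cell_summary)``.
    """
    if informative_sites.empty:
        raise ValueError("informative site list is empty")
    site_index = informative_sites.set_index("site_id")
    if known_sites is not None:
        universe = set(known_sites) | set(site_index.index)
        unknown = sorted(set(counts["site_id"]) - universe)
        if unknown:
            raise ValueError(f"allele counts reference unknown sites: {unknown[:10]}")
    sub = counts[counts["site_id"].isin(site_index.index)]
    if cells is None:
        cells = sorted(sub["cell_id"].unique())
    site_rows = []
    for row in sub.itertuples(index=False):
        total = row.ref_count + row.alt_count
        if total < min_reads:
            call = NO_COVERAGE
        elif row.ref_count >= min_minor and row.alt_count >= min_minor:
            call = BIALLELIC
        elif row.alt_count > row.ref_count:
            call = ALT_ONLY
        else:
            call = REF_ONLY
        site_rows.append(
            (
                row.cell_id,
                row.site_id,
                site_index.loc[row.site_id, "segment_id"],
                site_index.loc[row.site_id, "segment_direction"],
                int(row.ref_count),
                int(row.alt_count),
                call,
            )
        )
    site_calls = pd.DataFrame(
        site_rows,
        columns=[
            "cell_id", "site_id", "segment_id", "segment_direction",
            "ref_count", "alt_count", "call",
        ],
    )
    summaries = []
    grouped = dict(list(site_calls.groupby("cell_id"))) if len(site_calls) else {}
    for cell in cells:
        block = grouped.get(cell)
        if block is None:
            summaries.append((cell, 0, 0, 0, UNINFORMATIVE))
            continue
        covered = block[block["call"] != NO_COVERAGE]
        n_biallelic = int((covered["call"] == BIALLELIC).sum())
        n_biallelic_loss = int(
            ((covered["call"] == BIALLELIC) & (covered["segment_direction"] == LOSS)).sum()
        )
        if n_biallelic > 0:
            summary = BIALLELIC_OBSERVED
        elif len(covered) > 0:
            summary = MONOALLELIC_CONSISTENT
        else:
            summary = UNINFORMATIVE
        summaries.append((cell, len(covered), n_biallelic, n_biallelic_loss, summary))
    cell_summary = pd.DataFrame(
        summaries,
        columns=["cell_id", "n_covered", "n_biallelic", "n_biallelic_loss", "summary"],
    )
    return site_calls, cell_summary


def tally_somatic(
    counts: pd.DataFrame,
    somatic_sites: pd.DataFrame,
    min_alt: int = 1,
    cells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count expressed somatic SNVs per cell.

    A site is detected in a cell iff its alt read count is >= ``min_alt``
    (default 1: "at least one somatic SNV" classifies the cell as tumor
    downstream).  Returns cell_id, n_somatic_expressed, sites_detected
    (semicolon-joined site ids).
    """
    if min_alt < 1:
        raise ValueError("min_alt must be >= 1")
    known = set(somatic_sites["site_id"])
    sub = counts[counts["site_id"].isin(known)]
    if cells is None:
        cells = sorted(sub["cell_id"].unique())
    detected = sub[sub["alt_count"] >= min_alt]
    per_cell = {
        cell: sorted(block["site_id"].unique())
        for cell, block in detected.groupby("cell_id")
    }
    rows = [
        (cell, len(per_cell.get(cell, [])), ";".join(per_cell.get(cell, [])))
        for cell in cells
    ]
    return pd.DataFrame(rows, columns=["cell_id", "n_somatic_expressed", "sites_detected"])
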