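"""Per-cell presence/absence calls for exome-defined large-scale CNVs.

The approach: (1) call gain/loss segments from tumor/blood exome depth
ratios with a simple run-length threshold; (2) summarize single-cell
expression in sliding windows of adjacent genes, normalized by a
non-malignant control; (3) for each exome segment, compare a cell's
sum-total CPM over the segment's genes against the empirical distribution
of the same statistic in control cells, one-sided in the exome-defined
direction at a 5% significance level by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cellverdict.io import CPM, ExpressionMatrix, natural_chrom_sort

log = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
PRESENT = "present"
ABSENT = "absent"


@dataclass(frozen=True)
class CnvSegment:
    """A large-scale gain or loss supported by exome depth ratios."""

    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    depth_ratio: float
    whole_chromosome: bool = False

    @property
    def id(self) -> str:
        if self.whole_chromosome:
            return f"{self.chrom}:{self.direction}"
        return f"{self.chrom}:{self.start}-{self.end}:{self.direction}"


def call_exome_segments(
    bins: pd.DataFrame,
    delta: float = 0.2,
    min_span: int = 10_000_000,
    whole_chrom_frac: float = 0.9,
) -> list[CnvSegment]:
    """Call maximal runs of gain/loss bins from tumor/blood depth ratios.

    A bin is a gain if depth_ratio > 1 + delta and a loss if < 1 - delta.
    Maximal runs of consecutive same-direction bins spanning at least
    ``min_span`` bp are reported with their mean depth ratio; a run covering
    at least ``whole_chrom_frac`` of the chromosome's binned span is flagged
    whole-chromosome.
    """
    if bins.empty:
        log.warning("empty depth-ratio bin set: no CNV segments called")
        return []
    segments: list[CnvSegment] = []
    for chrom in natural_chrom_sort(bins["chrom"]):
        block = bins[bins["chrom"] == chrom].sort_values("start")
        chrom_span = int(block["end"].max() - block["start"].min())
        ratios = block["depth_ratio"].to_numpy(dtype=float)
        states = np.where(ratios > 1 + delta, 1, np.where(ratios < 1 - delta, -1, 0))
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        i = 0
        while i < len(states):
            if states[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(states) and states[j + 1] == states[i]:
                j += 1
            span = int(ends[j] - starts[i])
            if span >= min_span:
                segments.append(
                    CnvSegment(
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[j]),
                        direction=GAIN if states[i] == 1 else LOSS,
                        depth_ratio=float(ratios[i : j + 1].mean()),
                        whole_chromosome=span >= whole_chrom_frac * chrom_span,
                    )
                )
            i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Sliding-window expression profiles
# ---------------------------------------------------------------------------


@dataclass
class WindowProfile:
    """Long-format per-cell window log2 fold-changes vs. the control.

    ``data`` columns: cell_id, chrom, window_index, mid_gene, log2fc.
    """

    data: pd.DataFrame
    window_size: int
    pseudocount: float
    skipped_chroms: tuple[str, ...] = ()

    def matrix(self, chrom: str) -> pd.DataFrame:
        """Cells x windows log2fc matrix for one chromosome."""
        block = self.data[self.data["chrom"] == chrom]
        return block.pivot(index="cell_id", columns="window_index", values="log2fc")


def _window_means(arr: np.ndarray, w: int) -> np.ndarray:
    """Mean over sliding windows of width w along the last axis, step 1."""
    view = np.lib.stride_tricks.sliding_window_view(arr, w, axis=-1)
    return view.mean(axis=-1)


def window_log2fc(
    tumor: ExpressionMatrix,
    control: ExpressionMatrix,
    order: Mapping[str, Sequence[str]],
    w: int = 100,
    pseudocount: float = 1.0,
) -> WindowProfile:
    """Windowed log2 fold-change of tumor-cell expression over the control mean.

    For each cell and each window of ``w`` genomically adjacent genes
    (sliding step 1, never spanning chromosome boundaries):

        log2((mean cell CPM over window genes + pseudocount) /
             (mean over control cells of the same window statistic + pseudocount))

    Only genes measured in both matrices participate; chromosomes with fewer
    than ``w`` such genes yield zero windows and are logged.
    """
    if tumor.unit != CPM or control.unit != CPM:
        raise ValueError("window_log2fc requires both matrices in CPM")
    if w < 2:
        raise ValueError("window size must be >= 2")
    tumor_genes = set(tumor.gene_ids)
    control_genes = set(control.gene_ids)
    frames = []
    skipped = []
    any_common = False
    for chrom, genes in order.items():
        common = [g for g in genes if g in tumor_genes and g in control_genes]
        if common:
            any_common = True
        if len(common) < w:
            skipped.append(chrom)
            log.info("chromosome %s has %d < %d usable genes; no windows", chrom, len(common), w)
            continue
        t = tumor.values.loc[common].to_numpy(dtype=float).T  # cells x genes
        c_mean = control.values.loc[common].to_numpy(dtype=float).mean(axis=1)
        t_win = _window_means(t, w)  # cells x windows
        # mean over control cells of per-cell window means == window mean of
        # per-gene control means (both are linear); computed in the cheap order
        c_win = _window_means(c_mean[None, :], w)[0]
        log2fc = np.log2((t_win + pseudocount) / (c_win + pseudocount)[None, :])
        n_win = log2fc.shape[1]
        mid = [common[i + (w - 1) // 2] for i in range(n_win)]
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.repeat(list(tumor.cell_ids), n_win),
                    "chrom": chrom,
                    "window_index": np.tile(np.arange(n_win), tumor.n_cells),
                    "mid_gene": np.tile(mid, tumor.n_cells),
                    "log2fc": log2fc.ravel(),
                }
            )
        )
    if not any_common:
        raise ValueError("tumor and control matrices share no ordered genes")
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "chrom", "window_index", "mid_gene", "log2fc"])
    )
    return WindowProfile(data, window_size=w, pseudocount=pseudocount,
                         skipped_chroms=tuple(skipped))


# ---------------------------------------------------------------------------
# Per-cell segment test
# ---------------------------------------------------------------------------


def segment_genes(segment: CnvSegment, ann: pd.DataFrame) -> list[str]:
    """Genes assigned to a segment: all genes on the chromosome for
    whole-chromosome segments, otherwise genes whose start lies inside it."""
    block = ann[ann["chrom"] == segment.chrom]
    if not segment.whole_chromosome:
        block = block[(block["start"] >= segment.start) & (block["start"] <= segment.end)]
    block = block.sort_values(["start", "gene_id"], kind="mergesort")
    return block["gene_id"].tolist()


def segment_statistic(m: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Sum-total CPM over segment genes, per cell."""
    if m.unit != CPM:
        raise ValueError("segment_statistic expects a CPM matrix")
    present = [g for g in genes if g in m.gene_ids]
    if not present:
        return pd.Series(0.0, index=m.cell_ids)
    return m.values.loc[present].sum(axis=0)


def empirical_quantile(value: float, control_stats: np.ndarray) -> float:
    """Mid-rank empirical quantile of ``value`` within the control statistics."""
    control_stats = np.asarray(control_stats, dtype=float)
    less = int((control_stats < value).sum())
    ties = int((control_stats == value).sum())
    return (less + 0.5 * ties) / len(control_stats)


def test_cnv_presence(
    statistic: float,
    control_stats: np.ndarray,
    direction: str,
    alpha: float = 0.05,
    min_controls: int = 20,
    two_sided: bool = False,
) -> tuple[str, float, str | None]:
    """Empirical one-sided test of a cell's segment statistic against controls.

    The cell's sum-total CPM is ranked within the control distribution
    (mid-rank for ties).  For a gain the segment is called present when the
    quantile exceeds 1 - alpha; for a loss, when it falls below alpha.  With
    ``two_sided=True`` the directional threshold uses alpha/2, mirroring a
    symmetric significance band.  A degenerate control distribution (all
    values equal) yields an ``absent`` call with a warning flag.

    Returns ``(call, quantile, warning)``.
    """
    control_stats = np.asarray(control_stats, dtype=float)
    if len(control_stats) < min_controls:
        raise ValueError(
            f"only {len(control_stats)} control cells; need >= {min_controls}"
        )
    q = empirical_quantile(statistic, control_stats)
    if np.ptp(control_stats) == 0:
        return ABSENT, q, "degenerate_control"
    a = alpha / 2 if two_sided else alpha
    if direction == GAIN:
        call = PRESENT if q > 1 - a else ABSENT
    elif direction == LOSS:
        call = PRESENT if q < a else ABSENT
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return call, q, None


def call_cnv(
    tumor: ExpressionMatrix,
    control: ExpressionMatrix,
    segments: Sequence[CnvSegment],
    ann: pd.DataFrame,
    alpha: float = 0.05,
    min_controls: int = 20,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-cell presence calls for every exome segment.

    Returns a long DataFrame: cell_id, segment_id, direction, statistic,
    quantile, call, warning.
    """
    rows = []
    for seg in segments:
        genes = [g for g in segment_genes(seg, ann) if g in tumor.gene_ids]
        stats = segment_statistic(tumor, genes)
        control_stats = segment_statistic(control, genes).to_numpy()
        for cell, value in stats.items():
            call, q, warning = test_cnv_presence(
                float(value), control_stats, seg.direction,
                alpha=alpha, min_controls=min_controls, two_sided=two_sided,
            )
            rows.append((cell, seg.id, seg.direction, float(value), q, call, warning))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "segment_id", "direction", "statistic", "quantile", "call", "warning",
        ],
    )
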