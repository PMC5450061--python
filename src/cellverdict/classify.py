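"""Integrate the four evidence sources into a per-cell verdict.

Evidence per cell: (1) presence calls for exome-defined CNV segments,
(2) the germline allele-pattern summary, (3) the expressed somatic-SNV
tally, and (4) membership in the immune-majority marker-space cluster.
Mutational evidence is decisive; clustering is corroborative only — it can
confirm a cell as non-neoplastic but never alone make it neoplastic,
because clustering by expression mixes stochastically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from cellverdict.io import CPM, ExpressionMatrix
from cellverdict import snv as _snv

log = logging.getLogger(__name__)

# aggregated CNV votes
CNV_TUMOR = "supports_tumor"
CNV_NORMAL = "supports_normal"
CNV_UNINFORMATIVE = "uninformative"

NEOPLASTIC = "neoplastic"
NON_NEOPLASTIC = "non_neoplastic"
AMBIGUOUS = "ambiguous"


def log_expression(m: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Cells x genes matrix of log2(CPM + 1) over the listed genes."""
    if m.unit != CPM:
        raise ValueError("expected a CPM matrix")
    present = [g for g in genes if g in m.gene_ids]
    if not present:
        raise ValueError("none of the requested genes is measured")
    dropped = len(genes) - len(present)
    if dropped:
        log.info("%d marker genes absent from matrix; dropped", dropped)
    return np.log2(m.values.loc[present].T.astype(float) + 1.0)


def marker_linkage(m: ExpressionMatrix, marker_genes: Sequence[str]) -> np.ndarray:
    """Complete-linkage Euclidean hierarchy over log2(CPM+1) marker vectors."""
    X = log_expression(m, marker_genes).to_numpy()
    return linkage(X, method="complete", metric="euclidean")


def cluster_cells(
    m: ExpressionMatrix, marker_genes: Sequence[str], k: int = 2
) -> pd.Series:
    """Agglomerative clustering in marker space, cut to ``k`` clusters.

    Complete linkage on Euclidean distance over log2(CPM+1) vectors; merge
    order on exactly tied heights follows the lowest pair index, which is the
    behaviour of the underlying nearest-neighbour chain and is deterministic
    across runs.
    """
    if k > m.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({m.n_cells})")
    Z = marker_linkage(m, marker_genes)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=m.cell_ids, name="cluster")


def marker_scores(
    m: ExpressionMatrix,
    tumor_markers: Sequence[str],
    immune_markers: Sequence[str],
) -> pd.DataFrame:
    """Per-cell mean log2(CPM+1) over each marker panel and their difference."""
    tumor = log_expression(m, tumor_markers).mean(axis=1)
    immune = log_expression(m, immune_markers).mean(axis=1)
    return pd.DataFrame(
        {"tumor_score": tumor, "immune_score": immune, "marker_score": tumor - immune}
    )


def immune_majority_cluster(labels: pd.Series, immune_score: pd.Series) -> int:
    """The cluster whose cells have the highest mean immune-marker score."""
    means = immune_score.groupby(labels).mean()
    return int(means.idxmax())


@dataclass(frozen=True)
class CellEvidence:
    """The four per-cell votes feeding the decision table."""

    cell_id: str
    cnv_vote: str  # supports_tumor | supports_normal | uninformative
    germline_vote: str  # monoallelic_consistent | biallelic_observed | uninformative
    somatic_count: int
    in_immune_cluster: bool
    biallelic_in_called_loss: bool = False  # biallelic site inside a loss called present


@dataclass(frozen=True)
class Verdict:
    cell_id: str
    verdict: str  # neoplastic | non_neoplastic | ambiguous
    rationale: str
    conflict: bool = False


def integrate_evidence(e: CellEvidence) -> Verdict:
    """Deterministic decision table over the four evidence votes.

    - conflict (ambiguous, flagged): an expressed somatic SNV together with a
      biallelic germline site inside a loss segment called present in this
      cell — two strong signals that contradict each other.
    - neoplastic: CNV supports tumor OR >= 1 expressed somatic SNV, provided
      the germline pattern does not contradict (no biallelic site inside a
      called-present loss).
    - non_neoplastic: all segments called absent (adequate controls), zero
      somatic SNVs, germline biallelic or uninformative, and membership in
      the immune-majority cluster.
    - otherwise ambiguous.
    """
    somatic_positive = e.somatic_count >= 1
    if somatic_positive and e.biallelic_in_called_loss:
        return Verdict(
            e.cell_id, AMBIGUOUS,
            "conflict: expressed somatic SNV but biallelic germline site in a "
            "called copy-number loss",
            conflict=True,
        )
    if e.biallelic_in_called_loss and e.cnv_vote == CNV_TUMOR:
        return Verdict(
            e.cell_id, AMBIGUOUS,
            "CNV called present but a germline site in the loss region shows "
            "both alleles",
            conflict=True,
        )
    if e.cnv_vote == CNV_TUMOR or somatic_positive:
        parts = []
        if e.cnv_vote == CNV_TUMOR:
            parts.append("exome-defined CNV detected in expression")
        if somatic_positive:
            parts.append(f"{e.somatic_count} expressed somatic SNV(s)")
        return Verdict(e.cell_id, NEOPLASTIC, "; ".join(parts))
    if (
        e.cnv_vote == CNV_NORMAL
        and e.somatic_count == 0
        and e.germline_vote in (_snv.BIALLELIC_OBSERVED, _snv.UNINFORMATIVE)
        and e.in_immune_cluster
    ):
        detail = (
            "both germline alleles expressed"
            if e.germline_vote == _snv.BIALLELIC_OBSERVED
            else "no informative germline coverage"
        )
        return Verdict(
            e.cell_id, NON_NEOPLASTIC,
            f"no CNV, no somatic SNV, {detail}, immune-majority cluster",
        )
    return Verdict(e.cell_id, AMBIGUOUS, "evidence insufficient or discordant")


def aggregate_cnv_vote(calls: pd.DataFrame) -> str:
    """Collapse a cell's per-segment calls into one vote.

    supports_tumor iff any segment is called present; supports_normal iff
    every segment is called absent with a usable (non-degenerate) control;
    uninformative otherwise (no segments, or only degenerate tests).
    """
    if calls.empty:
        return CNV_UNINFORMATIVE
    if (calls["call"] == "present").any():
        return CNV_TUMOR
    if calls["warning"].isna().all():
        return CNV_NORMAL
    return CNV_UNINFORMATIVE


def classify_cells(
    cnv_calls: pd.DataFrame,
    allele_summary: pd.DataFrame,
    site_calls: pd.DataFrame,
    somatic_tally: pd.DataFrame,
    cluster_labels: pd.Series,
    immune_cluster: int,
    cells: Sequence[str],
) -> pd.DataFrame:
    """Assemble CellEvidence for every cell and apply the decision table.

    Returns a verdict table: cell_id, verdict, cnv_vote, germline_vote,
    somatic_vote, cluster_vote, conflict, rationale.
    """
    cnv_by_cell = dict(list(cnv_calls.groupby("cell_id"))) if len(cnv_calls) else {}
    germline = allele_summary.set_index("cell_id")["summary"] if len(allele_summary) else pd.Series(dtype=str)
    somatic = somatic_tally.set_index("cell_id")["n_somatic_expressed"] if len(somatic_tally) else pd.Series(dtype=int)

    # biallelic germline site in a loss segment that this cell's CNV test called present
    biallelic_loss = set()
    if len(site_calls) and len(cnv_calls):
        bi = site_calls[
            (site_calls["call"] == _snv.BIALLELIC)
            & (site_calls["segment_direction"] == "loss")
        ][["cell_id", "segment_id"]]
        present = cnv_calls[cnv_calls["call"] == "present"][["cell_id", "segment_id"]]
        merged = bi.merge(present, on=["cell_id", "segment_id"])
        biallelic_loss = set(merged["cell_id"])

    rows = []
    for cell in cells:
        ev = CellEvidence(
            cell_id=cell,
            cnv_vote=aggregate_cnv_vote(cnv_by_cell.get(cell, pd.DataFrame(columns=cnv_calls.columns))),
            germline_vote=germline.get(cell, _snv.UNINFORMATIVE),
            somatic_count=int(somatic.get(cell, 0)),
            in_immune_cluster=bool(cluster_labels.get(cell) == immune_cluster),
            biallelic_in_called_loss=cell in biallelic_loss,
        )
        verdict = integrate_evidence(ev)
        rows.append(
            (
                cell, verdict.verdict, ev.cnv_vote, ev.germline_vote,
                ev.somatic_count, int(cluster_labels.get(cell, -1)),
                verdict.conflict, verdict.rationale,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "verdict", "cnv_vote", "germline_vote", "somatic_vote",
            "cluster_vote", "conflict", "rationale",
        ],
    )
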