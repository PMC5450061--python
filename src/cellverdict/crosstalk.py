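"""Ligand-receptor crosstalk inference between a sender and a receiver population.

A database pair (ligand, receptor) is reported when the ligand is robustly
expressed by the senders — at least 20% of cells expressing it and a mean
above 2 CPM — and the receptor passes the receiver rule (by default the same
thresholds, relaxable to "any expression").  Boundary semantics follow the
stated rule exactly: prevalence is inclusive (>= 20%), mean is strict
(> 2 CPM).
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from cellverdict.io import CPM, ExpressionMatrix

log = logging.getLogger(__name__)


def population_stats(
    m: ExpressionMatrix,
    cells: Sequence[str],
    gene: str,
    expressed_floor: float = 0.0,
    mean_over_expressing: bool = False,
) -> tuple[float, float]:
    """(percentage of cells expressing the gene, mean CPM) in a population.

    A cell "expresses" the gene when its CPM exceeds ``expressed_floor``
    (default 0).  The mean is over all listed cells, zeros included, unless
    ``mean_over_expressing`` restricts it to expressing cells.  A gene absent
    from the matrix yields (0, 0) with a log entry.
    """
    if m.unit != CPM:
        raise ValueError("population_stats expects a CPM matrix")
    if len(cells) == 0:
        raise ValueError("empty cell population")
    if gene not in m.gene_ids:
        log.info("gene %s absent from matrix; stats (0, 0)", gene)
        return 0.0, 0.0
    values = m.values.loc[gene, list(cells)]
    expressing = values > expressed_floor
    pct = 100.0 * float(expressing.sum()) / len(cells)
    if mean_over_expressing:
        mean = float(values[expressing].mean()) if expressing.any() else 0.0
    else:
        mean = float(values.mean())
    return pct, mean


def infer_interactions(
    m: ExpressionMatrix,
    sender_cells: Sequence[str],
    receiver_cells: Sequence[str],
    lr_db: pd.DataFrame,
    sender_pct_min: float = 20.0,
    sender_mean_min: float = 2.0,
    receiver_pct_min: float = 20.0,
    receiver_mean_min: float = 2.0,
    receiver_any_expression: bool = False,
    expressed_floor: float = 0.0,
    mean_over_expressing: bool = False,
) -> pd.DataFrame:
    """Filter the ligand-receptor database by population expression thresholds.

    A pair is kept iff the ligand reaches ``sender_pct_min`` prevalence
    (inclusive) AND strictly exceeds ``sender_mean_min`` mean CPM among the
    senders, and the receptor passes the receiver rule among the receivers
    (``receiver_any_expression=True`` relaxes it to prevalence > 0).  Output
    is sorted by ligand then receptor for determinism.
    """
    stats: dict[tuple[str, str], tuple[float, float]] = {}

    def get_stats(gene: str, cells: Sequence[str], side: str) -> tuple[float, float]:
        key = (side, gene)
        if key not in stats:
            stats[key] = population_stats(
                m, cells, gene,
                expressed_floor=expressed_floor,
                mean_over_expressing=mean_over_expressing,
            )
        return stats[key]

    rows = []
    for row in lr_db.itertuples(index=False):
        pct_s, mean_s = get_stats(row.ligand, sender_cells, "sender")
        if not (pct_s >= sender_pct_min and mean_s > sender_mean_min):
            continue
        pct_r, mean_r = get_stats(row.receptor, receiver_cells, "receiver")
        if receiver_any_expression:
            ok = pct_r > 0
        else:
            ok = pct_r >= receiver_pct_min and mean_r > receiver_mean_min
        if not ok:
            continue
        rows.append((row.ligand, row.receptor, pct_s, mean_s, pct_r, mean_r))
    out = pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "pct_sender", "mean_sender",
            "pct_receiver", "mean_receiver",
        ],
    )
    return out.sort_values(["ligand", "receptor"], kind="mergesort").reset_index(drop=True)
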