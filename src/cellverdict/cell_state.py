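"""Cell-cycle program scoring and cycling/non-cycling classification.

A cell's score for a gene program is the mean of E = log2(CPM/10 + 1) over
the program's genes, centred by the mean E over all measured genes.  Cells
whose averaged G1/S and G2/M score exceeds 1.2 are classified as cycling;
the dominant program assigns a phase.  The 1.2 cutoff is meaningful only on
this documented scale, so both the score formula and the threshold are
configuration-exposed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from cellverdict.io import CPM, ExpressionMatrix
from cellverdict import markers

log = logging.getLogger(__name__)

G1S = "G1/S"
G2M = "G2/M"
INTERMEDIATE = "intermediate"
NONE = "none"


def expression_index(m: ExpressionMatrix) -> pd.DataFrame:
    """E = log2(CPM/10 + 1), genes x cells."""
    if m.unit != CPM:
        raise ValueError("cell-cycle scoring expects a CPM matrix")
    return np.log2(m.values.astype(float) / 10.0 + 1.0)


def phase_score(
    m: ExpressionMatrix, gene_set: Sequence[str], set_name: str = "gene set"
) -> pd.Series:
    """Centred mean program expression per cell.

    score(cell) = mean over gene_set of E_g  -  mean over all measured genes
    of E_g.  Genes missing from the matrix are dropped and logged; an empty
    intersection is an error naming the set.
    """
    E = expression_index(m)
    present = [g for g in gene_set if g in E.index]
    if not present:
        raise ValueError(f"no gene of {set_name!r} is measured in the matrix")
    dropped = len(gene_set) - len(present)
    if dropped:
        log.info("%d genes of %s missing from matrix; dropped", dropped, set_name)
    return E.loc[present].mean(axis=0) - E.mean(axis=0)


def classify_cycling(
    g1s: pd.Series,
    g2m: pd.Series,
    threshold: float = 1.2,
    margin: float = 0.3,
) -> pd.DataFrame:
    """Cycling iff (g1s + g2m)/2 strictly exceeds ``threshold``.

    Phase for cycling cells: G1/S if g1s - g2m > margin, G2/M if
    g2m - g1s > margin, otherwise intermediate; non-cycling cells have
    phase ``none``.
    """
    if not (np.isfinite(g1s).all() and np.isfinite(g2m).all()):
        raise ValueError("non-finite cycle scores")
    avg = (g1s + g2m) / 2.0
    cycling = avg > threshold
    diff = g1s - g2m
    phase = np.where(
        ~cycling, NONE,
        np.where(diff > margin, G1S, np.where(-diff > margin, G2M, INTERMEDIATE)),
    )
    return pd.DataFrame(
        {"cell_id": g1s.index, "g1s": g1s.to_numpy(), "g2m": g2m.to_numpy(),
         "avg": avg.to_numpy(), "cycling": cycling.to_numpy(), "phase": phase}
    ).reset_index(drop=True)


def score_cell_cycle(
    m: ExpressionMatrix,
    g1s_genes: Sequence[str] | None = None,
    g2m_genes: Sequence[str] | None = None,
    threshold: float = 1.2,
    margin: float = 0.3,
) -> pd.DataFrame:
    """Score both programs with the default (editable) gene sets and classify."""
    g1s = phase_score(m, g1s_genes or markers.G1S_GENES, "G1/S")
    g2m = phase_score(m, g2m_genes or markers.G2M_GENES, "G2/M")
    return classify_cycling(g1s, g2m, threshold=threshold, margin=margin)
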