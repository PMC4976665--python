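"""Per-gene, per-stage log fold change of mutant vs wildtype expression.

The counts are pooled-library expression values over six grain
developmental stages (7, 14, 21, 28, 35 days after flowering and mature
seed). With no biological replicates a dispersion model is off the
table; differential expression is summarised descriptively as
log2((mutant + c) / (wildtype + c)) with pseudocount c and flagged by a
plain |logFC| threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import STAGES

logger = logging.getLogger(__name__)


def log_fold_change(
    counts: pd.DataFrame,
    wt_strain: str,
    mut_strain: str,
    pseudocount: float = 1.0,
    gene_subset: list[str] | None = None,
    cpm: bool = False,
) -> pd.DataFrame:
    """logFC matrix (genes x stages) of mutant over wildtype.

    ``counts`` uses the (strain, stage) column MultiIndex produced by
    :func:`emsnv.io_formats.read_counts`. With ``cpm`` both strains are
    first scaled to counts-per-million per stage. Genes in ``gene_subset``
    missing from the table get NaN rows (logged).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    stages = [s for s in STAGES if (wt_strain, s) in counts.columns]
    wt = counts[wt_strain][stages].astype(float)
    mut = counts[mut_strain][stages].astype(float)
    if cpm:
        wt = wt * 1e6 / wt.sum(axis=0)
        mut = mut * 1e6 / mut.sum(axis=0)
    lfc = np.log2((mut + pseudocount) / (wt + pseudocount))
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in lfc.index]
        if missing:
            logger.warning("%d subset gene(s) absent from counts table",
                           len(missing))
        lfc = lfc.reindex(gene_subset)
    lfc.columns.name = "stage"
    lfc.index.name = "gene_id"
    return lfc


def flag_differential(
    matrix: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Per-gene and per-stage differential flags from a logFC matrix.

    A gene is flagged when any stage's |logFC| reaches ``threshold``.
    Returns the per-stage boolean matrix plus an ``any_stage`` column.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flags = matrix.abs() >= threshold
    flags = flags.fillna(False)
    out = flags.copy()
    out["any_stage"] = flags.any(axis=1)
    return out
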