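"""Replicate-free fold-change differential expression between DD and LL.

With one sample per time point there is no within-condition variance to
model, so differential expression is called on the ratio of per-condition
medians over the 12 time points (robust to isolated aberrant time points).
Genes are stratified as DDu (fold > cutoff, higher in DD), DDh (higher in DD
but within the cutoff), LLh and LLu symmetrically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError

__all__ = ["fold_change_de", "STRATA"]

STRATA = ("DDu", "DDh", "LLh", "LLu")


def fold_change_de(matrix_dd: ExpressionMatrix, matrix_ll: ExpressionMatrix,
                   cutoff: float = 1.5, gene_level: bool | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Median-fold-change DE table and per-stratum counts.

    fold = median over DD time points / median over LL time points.
    gene_level=None sums member transcripts per gene when gene ids are
    available (set False to force transcript level). Features with a zero
    median in either condition are flagged and excluded from the strata.
    """
    if cutoff <= 1:
        raise ValidationError("cutoff must exceed 1")
    if gene_level is None:
        gene_level = matrix_dd.gene_ids is not None and matrix_ll.gene_ids is not None
    if gene_level:
        matrix_dd = matrix_dd.by_gene()
        matrix_ll = matrix_ll.by_gene()

    ids_dd = matrix_dd.transcript_ids.astype(str)
    ids_ll = matrix_ll.transcript_ids.astype(str)
    common, ia, ib = np.intersect1d(ids_dd, ids_ll, return_indices=True)
    if len(common) == 0:
        raise ValidationError("matrices share no feature ids")

    med_dd = np.median(matrix_dd.values[ia], axis=1)
    med_ll = np.median(matrix_ll.values[ib], axis=1)
    ok = (med_dd > 0) & (med_ll > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(ok, med_dd / np.where(med_ll > 0, med_ll, np.nan), np.nan)

    stratum = np.full(len(common), "", dtype=object)
    stratum[ok & (fold > cutoff)] = "DDu"
    stratum[ok & (fold < 1.0 / cutoff)] = "LLu"
    stratum[ok & (fold >= 1.0) & (fold <= cutoff)] = "DDh"
    stratum[ok & (fold < 1.0) & (fold >= 1.0 / cutoff)] = "LLh"

    table = pd.DataFrame({
        "id": common,
        "median_dd": med_dd,
        "median_ll": med_ll,
        "fold": fold,
        "stratum": stratum,
        "excluded_zero_median": ~ok,
    })
    counts = {s: int((stratum == s).sum()) for s in STRATA}
    counts["excluded"] = int((~ok).sum())
    counts["analyzed"] = int(ok.sum())
    return table, counts
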