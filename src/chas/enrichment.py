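"""Hypergeometric enrichment of cell-type-specific peaks among DARs.

Given a list of differentially acetylated regions (DARs) drawn from an
annotated bulk peak universe, tests per cell type whether the cell type's
specific peaks are over-represented among the DARs relative to the whole
universe (upper-tail hypergeometric test), with Benjamini-Hochberg
correction across the cell types tested in one call. The universe is all
annotated bulk peaks (DARs plus non-DARs); "multiple"-category peaks do
not count toward any single cell type's successes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chas.annotation import AnnotationResult

__all__ = ["EnrichmentResult", "hypergeometric_enrichment", "bh_fdr"]


@dataclass
class EnrichmentResult:
    """Per-cell-type 2×2 margins, fold enrichment, p and FDR."""

    table: pd.DataFrame
    direction: str

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["fdr"] < alpha])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    dar_ids: Iterable[str],
    annotation: AnnotationResult,
    direction: str = "both",
    depletion: bool = False,
) -> EnrichmentResult:
    """Test each cell type's specific peaks for over-representation in DARs.

    Parameters
    ----------
    dar_ids : iterable of str
        Peak ids of the differentially acetylated regions; must be a
        subset of the annotated universe.
    annotation : AnnotationResult
        Annotation of the bulk universe the DARs were tested in.
    direction : {"hyper", "hypo", "both"}
        Label describing which DAR list is being tested; recorded in the
        result (the caller supplies per-direction id lists).
    depletion : bool
        When True, test the lower tail (under-representation) instead of
        the default upper-tail enrichment.

    For cell type x with K specific peaks in a universe of N annotated
    peaks, and k of the n DARs specific to x, the enrichment p value is
    P(X >= k) for X ~ Hypergeom(N, K, n); fold enrichment is
    (k/n)/(K/N). FDR is BH-adjusted across the cell types in this call.
    """
    if direction not in {"hyper", "hypo", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    dars = list(dict.fromkeys(dar_ids))
    if not dars:
        raise ValueError("empty DAR set")
    universe = set(annotation.table.index)
    unknown = [d for d in dars if d not in universe]
    if unknown:
        raise ValueError(
            f"{len(unknown)} DAR ids absent from the annotated universe: "
            f"{unknown[:5]}"
        )
    N, n = len(universe), len(dars)
    dar_set = set(dars)
    rows = []
    for ct in annotation.cell_types:
        specific = set(annotation.specific_peaks(ct))
        K = len(specific)
        k = len(specific & dar_set)
        if depletion:
            p = stats.hypergeom.cdf(k, N, K, n)
        else:
            p = stats.hypergeom.sf(k - 1, N, K, n)
        fold = (k / n) / (K / N) if K > 0 else np.nan
        rows.append(
            {"cell_type": ct, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p_value": float(p)}
        )
    table = pd.DataFrame(rows).set_index("cell_type")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    return EnrichmentResult(table, direction)
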