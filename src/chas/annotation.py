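"""Cell-type annotation of bulk peaks against a cell-sorted reference panel.

A bulk peak is annotated to every reference cell type whose peaks it
overlaps by at least 1 bp. Peaks overlapping exactly one cell type carry
that cell type as their category; peaks overlapping several are
"multiple"; peaks overlapping none are "other". A peak is *cell-type
specific* (high confidence, used for scoring) when it is annotated to a
single cell type and covers at least a threshold fraction (default 50%)
of one of that cell type's reference peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
import pyranges as pr

from chas.genomic_io import Peak, PeakSet

__all__ = [
    "ReferencePanel",
    "AnnotationResult",
    "MULTIPLE",
    "OTHER",
    "find_overlaps",
    "annotate_peaks",
    "annotation_summary",
]

MULTIPLE = "multiple"
OTHER = "other"


@dataclass
class ReferencePanel:
    """Named cell types with one reference peak set each."""

    peak_sets: dict[str, PeakSet]

    def __post_init__(self) -> None:
        if not self.peak_sets:
            raise ValueError("reference panel needs at least one cell type")
        for name, ps in self.peak_sets.items():
            if len(ps) == 0:
                raise ValueError(f"empty reference peak set for {name!r}")
        if MULTIPLE in self.peak_sets or OTHER in self.peak_sets:
            raise ValueError(
                f"cell type names {MULTIPLE!r}/{OTHER!r} are reserved"
            )

    @property
    def cell_types(self) -> list[str]:
        return list(self.peak_sets)

    def drop(self, cell_type: str) -> "ReferencePanel":
        if cell_type not in self.peak_sets:
            raise KeyError(cell_type)
        remaining = {k: v for k, v in self.peak_sets.items() if k != cell_type}
        if not remaining:
            raise ValueError("cannot drop the last cell type")
        return ReferencePanel(remaining)


def _to_pyranges(peaks: PeakSet, id_col: str) -> pr.PyRanges:
    df = peaks.to_dataframe().rename(columns={"peak_id": id_col})
    return pr.PyRanges(df)


def find_overlaps(
    query: PeakSet, subject: PeakSet
) -> list[tuple[str, str, int]]:
    """All (query_id, subject_id, overlap_bp) pairs with >=1 bp overlap.

    Overlap is half-open: ``overlap_bp = min(ends) - max(starts)`` and
    bookended intervals ([a,b) vs [b,c)) do not overlap.
    """
    if len(query) == 0 or len(subject) == 0:
        return []
    j = _to_pyranges(query, "query_id").join(
        _to_pyranges(subject, "subject_id")
    )
    df = j.df
    if df.empty:
        return []
    overlap = (
        df[["End", "End_b"]].min(axis=1) - df[["Start", "Start_b"]].max(axis=1)
    ).astype(int)
    out = list(zip(df["query_id"], df["subject_id"], overlap))
    return sorted(out)


@dataclass
class AnnotationResult:
    """Per-bulk-peak cell-type annotation.

    ``table`` has one row per bulk peak (index = peak id) with columns
    ``category`` (a cell-type name, "multiple", or "other") and
    ``specific`` (bool), plus one ``frac_<cell type>`` column per panel
    entry giving the maximum fraction of a single reference peak of that
    cell type covered by the bulk peak (0 when no overlap).
    """

    table: pd.DataFrame
    cell_types: list[str]
    specificity_threshold: float

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def specific_peaks(self, cell_type: str) -> list[str]:
        """Ids of the high-confidence peaks specific to ``cell_type`` (P_x)."""
        if cell_type not in self.cell_types:
            raise KeyError(cell_type)
        t = self.table
        mask = (t["category"] == cell_type) & t["specific"]
        return list(t.index[mask])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def annotate_peaks(
    bulk: PeakSet,
    panel: ReferencePanel,
    specificity_threshold: float = 0.5,
) -> AnnotationResult:
    """Annotate bulk peaks to reference cell types.

    Any >=1 bp overlap annotates a bulk peak to a cell type. The covered
    fraction per cell type is the maximum, over that cell type's
    overlapping reference peaks, of overlap_bp / reference peak length.
    A peak is specific when exactly one cell type is overlapped and its
    fraction reaches ``specificity_threshold``.
    """
    if not (0 < specificity_threshold <= 1):
        raise ValueError("specificity_threshold must be in (0, 1]")
    cell_types = panel.cell_types
    index = pd.Index(bulk.peak_ids, name="peak_id")
    frac = pd.DataFrame(0.0, index=index, columns=cell_types)
    for ct in cell_types:
        ref = panel.peak_sets[ct]
        ref_len = {p.peak_id: p.length for p in ref}
        for qid, sid, bp in find_overlaps(bulk, ref):
            f = bp / ref_len[sid]
            if f > frac.at[qid, ct]:
                frac.at[qid, ct] = f
    n_hit = (frac > 0).sum(axis=1)
    category = pd.Series(OTHER, index=index, dtype=object)
    category[n_hit > 1] = MULTIPLE
    single = n_hit == 1
    if single.any():
        category[single] = frac.loc[single].idxmax(axis=1)
    specific = single & (frac.max(axis=1) >= specificity_threshold)
    table = pd.concat(
        [category.rename("category"), specific.rename("specific")], axis=1
    )
    for ct in cell_types:
        table[f"frac_{ct}"] = frac[ct]
    return AnnotationResult(table, cell_types, specificity_threshold)


def annotation_summary(result: AnnotationResult) -> pd.DataFrame:
    """Per-category peak counts and fractions (cell types, multiple, other)."""
    order = result.cell_types + [MULTIPLE, OTHER]
    counts = result.categories.value_counts().reindex(order, fill_value=0)
    total = int(counts.sum())
    frac = counts / total if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "fraction": frac})
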