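"""Cell-type scores from bulk counts over cell-type-specific peaks.

The score for cell type x in sample y is the average, over the peaks
specific to x (P_x), of the max-standardized CPM signal: counts are
converted to CPM, each peak's CPM row is divided by its maximum across
samples (so every informative peak peaks at 1 in some sample), and the
standardized values are averaged over P_x. Scores lie in [0, 1] and are a
rank proxy for the cell type's abundance, not an absolute proportion; in
particular they are not constrained to sum to 1 across cell types.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chas.annotation import AnnotationResult
from chas.genomic_io import CountsMatrix

__all__ = [
    "cpm_normalize",
    "standardize_peaks",
    "chas_scores",
    "compute_scores",
    "compare_groups",
    "score_truth_correlation",
]


def cpm_normalize(counts: CountsMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6, per sample."""
    if (counts.library_sizes <= 0).any():
        bad = list(counts.library_sizes.index[counts.library_sizes <= 0])
        raise ValueError(f"non-positive library size for samples {bad}")
    return counts.counts.div(counts.library_sizes, axis=1) * 1e6


def standardize_peaks(cpm: pd.DataFrame) -> pd.DataFrame:
    """Scale each peak's CPM row by its maximum across samples.

    Rows with any signal have maximum 1 after scaling; all-zero rows map
    to 0 everywhere (0/0 is defined as 0 here: a peak with no reads
    anywhere carries no signal).
    """
    if (cpm.to_numpy() < 0).any():
        raise ValueError("negative CPM values")
    row_max = cpm.max(axis=1)
    safe = row_max.replace(0, 1.0)
    return cpm.div(safe, axis=0)


def chas_scores(
    signal: pd.DataFrame,
    annotation: AnnotationResult,
    cell_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Average standardized signal over each cell type's specific peaks.

    Returns a samples × cell-types DataFrame with values in [0, 1]. A cell
    type with no specific peaks in the annotation is *omitted* from the
    output (with a warning) rather than reported as 0 — absence of
    evidence is not a zero score.
    """
    cts = list(cell_types) if cell_types is not None else annotation.cell_types
    cols = {}
    for ct in cts:
        px = [p for p in annotation.specific_peaks(ct) if p in signal.index]
        if not px:
            warnings.warn(
                f"no cell-type-specific peaks for {ct!r}; score omitted",
                stacklevel=2,
            )
            continue
        cols[ct] = signal.loc[px].mean(axis=0)
    return pd.DataFrame(cols)


def compute_scores(
    counts: CountsMatrix,
    annotation: AnnotationResult,
    cell_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """CPM -> per-peak max standardization -> per-cell-type averaging."""
    return chas_scores(
        standardize_peaks(cpm_normalize(counts)), annotation, cell_types
    )


def compare_groups(
    values: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_order: Optional[tuple[str, str]] = None,
) -> pd.DataFrame:
    """Welch's unequal-variance t-test per cell type between two groups.

    ``values`` is samples × cell types (scores or proportions); ``labels``
    maps sample id to one of exactly two group names. The mean difference
    is group1 − group2 with the group order taken from ``group_order`` or,
    by default, sorted group names; the order is recorded in the output.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(values.index)
    if labels.isna().any():
        missing = list(values.index[labels.isna()])
        raise ValueError(f"samples without group label: {missing[:5]}")
    groups = sorted(labels.unique()) if group_order is None else list(group_order)
    if len(set(labels)) != 2 or len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = groups
    idx1, idx2 = labels.index[labels == g1], labels.index[labels == g2]
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for ct in values.columns:
        a, b = values.loc[idx1, ct], values.loc[idx2, ct]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        note = "zero variance" if a.var() == 0 and b.var() == 0 else ""
        rows.append(
            {
                "cell_type": ct,
                "group1": g1,
                "group2": g2,
                "mean_diff": a.mean() - b.mean(),
                "t": t,
                "p": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def score_truth_correlation(
    scores: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation of scores against known proportions.

    Computed per cell type across the samples shared by both frames
    (matched by sample id); requires at least 3 samples.
    """
    common = scores.index.intersection(truth.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched samples")
    rows = []
    for ct in scores.columns:
        if ct not in truth.columns:
            continue
        rho, p = stats.spearmanr(
            scores.loc[common, ct], truth.loc[common, ct]
        )
        rows.append({"cell_type": ct, "rho": rho, "p": p})
    if not rows:
        raise ValueError("no cell types shared between scores and truth")
    return pd.DataFrame(rows).set_index("cell_type")
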