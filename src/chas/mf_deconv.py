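"""Absolute cell-type proportions by weighted constrained least squares.

The bulk signal at each consensus peak is modelled as a non-negative
mixture of reference cell-type signals:

    b_p,y ≈ Σ_x R_p,x · p_x,y      with  p_x,y ≥ 0,  Σ_x p_x,y ≤ 1,

where b and R are length- and library-normalized CPM values on consensus
peaks (the merged union of bulk and reference peaks). Three adaptations
for histone-acetylation data: (1) counts are divided by peak length
before CPM scaling, (2) with several reference samples per cell type the
per-peak median normalized CPM is used, and (3) peaks are weighted by
inverse signal variability (half the CPM range across reference samples).
The fit runs on *signature peaks* only — consensus peaks whose strongest
cell type carries at least ``ratio`` (default 5) times the signal of any
other cell type. The slack 1 − Σ_x p_x,y is reported as "other":
cell types absent from the reference leave an unexplained remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.optimize import nnls

from chas.annotation import ReferencePanel, find_overlaps
from chas.genomic_io import CountsMatrix, Peak, PeakSet

__all__ = [
    "ConsensusPeakSet",
    "ReferenceProfile",
    "SignaturePeakSet",
    "ProportionEstimate",
    "OTHER_CELLS",
    "build_consensus",
    "map_counts_to_consensus",
    "normalize_counts",
    "build_reference_profile",
    "select_signature_peaks",
    "estimate_proportions",
    "deconvolve",
]

OTHER_CELLS = "other"

#: KKT residual tolerance for the constrained solver.
KKT_TOL = 1e-8


@dataclass
class ConsensusPeakSet:
    """Merged union of bulk and reference peaks.

    ``peaks`` are pairwise-disjoint sorted intervals; ``cell_types`` maps
    each consensus peak id to the set of panel cell types whose reference
    peaks it overlaps.
    """

    peaks: PeakSet
    cell_types: dict[str, frozenset[str]]

    def lengths(self) -> pd.Series:
        return self.peaks.lengths()


def build_consensus(bulk: PeakSet, panel: ReferencePanel) -> ConsensusPeakSet:
    """Merge bulk and all reference peaks into disjoint consensus intervals.

    Every input peak is contained in exactly one consensus interval. Each
    consensus peak is annotated with the cell types whose reference peaks
    overlap it (empty set for bulk-only intervals).
    """
    frames = [bulk.to_dataframe()]
    for ps in panel.peak_sets.values():
        frames.append(ps.to_dataframe())
    allpeaks = pd.concat(frames, ignore_index=True)
    merged = pr.PyRanges(allpeaks[["Chromosome", "Start", "End"]]).merge()
    mdf = merged.df
    consensus = PeakSet(
        [
            Peak(r.Chromosome, r.Start, r.End, f"{r.Chromosome}:{r.Start}-{r.End}")
            for r in mdf.itertuples()
        ],
        label="consensus",
    )
    ct_map: dict[str, set[str]] = {p.peak_id: set() for p in consensus}
    for ct, ps in panel.peak_sets.items():
        for cid, _, _ in find_overlaps(consensus, ps):
            ct_map[cid].add(ct)
    return ConsensusPeakSet(
        consensus, {k: frozenset(v) for k, v in ct_map.items()}
    )


def map_counts_to_consensus(
    counts: CountsMatrix, peaks: PeakSet, consensus: ConsensusPeakSet
) -> CountsMatrix:
    """Re-index a counts matrix from its native peaks onto consensus peaks.

    Each source peak's counts are assigned to the consensus interval that
    contains it (original counts serve as a proxy for consensus-peak
    counts); several source peaks falling in one consensus interval have
    their counts summed. Consensus intervals with no source peak get 0.
    """
    known = set(peaks.peak_ids)
    missing = [pid for pid in counts.peak_ids if pid not in known]
    if missing:
        raise ValueError(
            f"count rows without coordinates in the peak set: {missing[:5]}"
        )
    parent: dict[str, str] = {}
    for src_id, cons_id, _ in find_overlaps(peaks, consensus.peaks):
        parent[src_id] = cons_id  # containment: unique consensus parent
    rows = counts.counts.copy()
    rows.index = [parent[pid] for pid in rows.index]
    summed = rows.groupby(level=0).sum()
    full = summed.reindex(consensus.peaks.peak_ids, fill_value=0)
    return CountsMatrix(full)


def normalize_counts(
    counts: CountsMatrix, peak_lengths: pd.Series
) -> pd.DataFrame:
    """Length-normalized CPM: divide by bp length, rescale columns to 1e6."""
    lengths = peak_lengths.reindex(counts.counts.index)
    if lengths.isna().any():
        raise ValueError("peak lengths missing for some count rows")
    if (lengths <= 0).any():
        raise ValueError("zero or negative peak length")
    per_bp = counts.counts.div(lengths, axis=0)
    totals = per_bp.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total signal")
    return per_bp.div(totals, axis=1) * 1e6


@dataclass
class ReferenceProfile:
    """Per-cell-type median normalized CPM with variability weights.

    ``profile`` is consensus peaks × cell types; ``variability`` is half
    the normalized-CPM range across all reference samples; ``weights``
    down-weight variable peaks (default 1 / (1 + v)). With a single
    reference sample per cell type the variability is 0 and all weights
    are 1.
    """

    profile: pd.DataFrame
    variability: pd.Series
    weights: pd.Series

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.columns)


def build_reference_profile(
    ref_norm: Mapping[str, pd.DataFrame],
    weight_exponent: float = 1.0,
) -> ReferenceProfile:
    """Median reference profile and variability weights.

    Parameters
    ----------
    ref_norm : mapping of cell type -> normalized CPM DataFrame
        Each frame is consensus peaks × that cell type's reference
        samples (output of :func:`normalize_counts`), sharing one index.
    weight_exponent : float
        Weights are ``1 / (1 + v) ** weight_exponent``.
    """
    if not ref_norm:
        raise ValueError("empty reference")
    cts = list(ref_norm)
    index = ref_norm[cts[0]].index
    medians = {}
    for ct in cts:
        df = ref_norm[ct]
        if not df.index.equals(index):
            raise ValueError("reference matrices must share one peak index")
        medians[ct] = df.median(axis=1)
    profile = pd.DataFrame(medians)
    stacked = pd.concat(ref_norm.values(), axis=1)
    v = (stacked.max(axis=1) - stacked.min(axis=1)) / 2.0
    w = 1.0 / (1.0 + v) ** weight_exponent
    return ReferenceProfile(profile, v.rename("variability"), w.rename("weight"))


@dataclass
class SignaturePeakSet:
    """Signature peaks and the dominant cell type of each."""

    dominant: pd.Series  # index: peak id, value: cell type
    ratio: float

    @property
    def peak_ids(self) -> list[str]:
        return list(self.dominant.index)

    def counts_per_cell_type(self) -> pd.Series:
        return self.dominant.value_counts()


def select_signature_peaks(
    profile: ReferenceProfile, ratio: float = 5.0
) -> SignaturePeakSet:
    """Peaks whose top cell type is >= ``ratio`` times the second highest.

    A peak with positive signal in exactly one cell type (second-highest
    0) always qualifies. Cell types that end up with no signature peak
    trigger a warning; deconvolution may still proceed but estimates for
    such cell types are unidentified.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    vals = profile.profile.to_numpy(dtype=float)
    if vals.shape[1] == 1:
        top, second = vals[:, 0], np.zeros(len(vals))
    else:
        order = np.sort(vals, axis=1)
        top, second = order[:, -1], order[:, -2]
    keep = (top > 0) & (top >= ratio * second)
    dominant = profile.profile.idxmax(axis=1)[keep]
    missing = set(profile.cell_types) - set(dominant.unique())
    if missing:
        warnings.warn(
            f"no signature peaks for cell types {sorted(missing)}",
            stacklevel=2,
        )
    return SignaturePeakSet(dominant, ratio)


@dataclass
class ProportionEstimate:
    """Samples × (cell types + "other") proportion matrix with diagnostics."""

    proportions: pd.DataFrame
    residuals: pd.Series
    diagnostics: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return [c for c in self.proportions.columns if c != OTHER_CELLS]


def _solve_sample(
    A: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """min ||Ap - y||² s.t. p >= 0, Σp <= 1, exactly and deterministically.

    NNLS solves the problem when the simplex constraint is slack. When the
    NNLS solution exceeds Σp = 1, the optimum lies on that face and is
    found by enumerating supports of the equality-constrained KKT system
    (the number of cell types is small). Degenerate ties resolve to the
    lstsq minimum-norm solution.
    """
    k = A.shape[1]
    p, _ = nnls(A, y)
    if p.sum() <= 1.0 + KKT_TOL:
        return np.clip(p, 0.0, None)
    best: tuple[float, float, np.ndarray] | None = None
    G, c = A.T @ A, A.T @ y
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            s = list(support)
            # KKT for min ||A_S p - y||^2 s.t. 1'p = 1 on the support
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = G[np.ix_(s, s)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([c[s], [1.0]])
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            ps = sol[:size]
            if (ps < -KKT_TOL).any():
                continue
            full = np.zeros(k)
            full[s] = np.clip(ps, 0.0, None)
            r = A @ full - y
            obj = float(r @ r)
            norm = float(full @ full)
            if (
                best is None
                or obj < best[0] - KKT_TOL
                or (abs(obj - best[0]) <= KKT_TOL and norm < best[1])
            ):
                best = (obj, norm, full)
    assert best is not None  # the full support is always attempted
    return best[2]


def estimate_proportions(
    bulk_norm: pd.DataFrame,
    profile: ReferenceProfile,
    weights: Optional[pd.Series] = None,
) -> ProportionEstimate:
    """Weighted constrained least squares per sample on signature peaks.

    ``bulk_norm`` is signature peaks × samples normalized CPM; the model
    matrix is the reference profile restricted to the same peaks. The
    unexplained remainder 1 − Σ p is reported as "other".
    """
    R = profile.profile.reindex(bulk_norm.index)
    if R.isna().any().any():
        raise ValueError("bulk peaks missing from the reference profile")
    w = (
        profile.weights.reindex(bulk_norm.index)
        if weights is None
        else weights.reindex(bulk_norm.index)
    )
    if w.isna().any():
        raise ValueError("weights missing for some peaks")
    if (w < 0).any():
        raise ValueError("negative weights")
    cts = profile.cell_types
    if len(bulk_norm) < len(cts):
        raise ValueError(
            f"need at least {len(cts)} signature peaks, got {len(bulk_norm)}"
        )
    sw = np.sqrt(w.to_numpy(dtype=float))
    A = R.to_numpy(dtype=float) * sw[:, None]
    cond = float(np.linalg.cond(A))
    if cond > 1e8:
        warnings.warn(
            f"reference profile nearly collinear (condition number {cond:.3g})",
            stacklevel=2,
        )
    props, resids = {}, {}
    for sample in bulk_norm.columns:
        y = bulk_norm[sample].to_numpy(dtype=float) * sw
        p = _solve_sample(A, y)
        props[sample] = p
        resids[sample] = float(np.linalg.norm(A @ p - y))
    out = pd.DataFrame(props, index=cts).T
    out[OTHER_CELLS] = np.clip(1.0 - out.sum(axis=1), 0.0, None)
    return ProportionEstimate(
        out,
        pd.Series(resids, name="weighted_residual_norm"),
        {"condition_number": cond, "n_signature_peaks": len(bulk_norm)},
    )


def deconvolve(
    bulk_peaks: PeakSet,
    bulk_counts: CountsMatrix,
    panel: ReferencePanel,
    ref_counts: Mapping[str, CountsMatrix],
    ref_count_peaks: Optional[Mapping[str, PeakSet] | PeakSet] = None,
    ratio: float = 5.0,
    weight_exponent: float = 1.0,
) -> ProportionEstimate:
    """Full pipeline from peaks and counts to proportion estimates.

    Stages: consensus peaks -> counts mapped onto consensus -> length +
    library normalization -> median reference profile with variability
    weights -> signature peak selection -> weighted constrained least
    squares. Normalization uses all consensus peaks as the CPM
    denominator; the fit is then restricted to signature peaks.

    ``ref_count_peaks`` gives the peak set each reference counts matrix is
    defined on (a single PeakSet for all, or one per cell type); by
    default the panel's own reference peak sets are used.
    """
    consensus = build_consensus(bulk_peaks, panel)
    lengths = consensus.lengths()

    bulk_cons = map_counts_to_consensus(bulk_counts, bulk_peaks, consensus)
    bulk_norm = normalize_counts(bulk_cons, lengths)

    ref_norm = {}
    for ct in panel.cell_types:
        if ct not in ref_counts:
            raise ValueError(f"missing reference counts for {ct!r}")
        if ref_count_peaks is None:
            peaks = panel.peak_sets[ct]
        elif isinstance(ref_count_peaks, PeakSet):
            peaks = ref_count_peaks
        else:
            peaks = ref_count_peaks[ct]
        cons_counts = map_counts_to_consensus(ref_counts[ct], peaks, consensus)
        ref_norm[ct] = normalize_counts(cons_counts, lengths)

    profile = build_reference_profile(ref_norm, weight_exponent)
    signature = select_signature_peaks(profile, ratio)
    est = estimate_proportions(
        bulk_norm.loc[signature.peak_ids], profile
    )
    est.diagnostics["signature_peaks_per_cell_type"] = (
        signature.counts_per_cell_type().to_dict()
    )
    est.diagnostics["n_consensus_peaks"] = len(consensus.peaks)
    return est
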