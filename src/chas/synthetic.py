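"""Synthetic reference panels and pseudobulk mixtures of known composition.

Emulates the validation design for reference-based deconvolution of bulk
brain H3K27ac: a panel of cell types (by default astrocytes, microglia,
neurons, oligodendrocytes) each owning a set of high-signal specific
peaks, plus shared peaks with comparable signal in every cell type.
Pseudobulk samples are multinomial draws over peaks whose expected rates
are mixtures of the per-cell-type rates at known proportions — the
counts-level analogue of pooling randomly sampled reads from sorted
cell populations. The "paper-like" composition mode draws neuron-dominant
brain compositions with microglia between 5% and 21% of the sample.

Everything is reproducible from (spec, seed). Variants support the
standard robustness designs: reference peak downsampling, and a cell
type missing from either the reference panel or the mixture itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from chas.annotation import ReferencePanel
from chas.genomic_io import CountsMatrix, Peak, PeakSet

__all__ = [
    "SyntheticPanelSpec",
    "MixtureTruth",
    "Benchmark",
    "DEFAULT_CELL_TYPES",
    "generate_panel",
    "bulk_peak_set",
    "mix_pseudobulk",
    "benchmark_composition",
    "downsample_reference",
    "drop_cell_type",
    "standard_benchmark",
]

DEFAULT_CELL_TYPES = ("astrocytes", "microglia", "neurons", "oligodendrocytes")

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]

#: Minimum gap between placed peaks, so no two peaks touch or merge.
_MIN_GAP = 10


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of the synthetic reference panel.

    The defaults define the standard benchmark: 4 cell types × 500
    specific peaks plus 200 shared peaks on a 2 × 30 Mb toy genome.
    Owner-cell-type signal at a specific peak is
    ``background_rate * separation * LogNormal(0, sdlog)``, floored at
    ``min_separation`` times the background, so the expected
    owner/background ratio is at least ``min_separation`` (default 5) for
    every specific peak; shared peaks carry one log-normal rate common to
    all cell types. Reference read counts are multinomial draws of
    ``reference_depth`` reads per reference sample.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    peaks_per_type: int = 500
    n_shared_peaks: int = 200
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
    )
    peak_length_range: tuple[int, int] = (500, 1500)
    background_rate: float = 1.0
    separation: float = 10.0
    sdlog: float = 0.75
    min_separation: float = 5.0
    n_reference_samples_per_type: int = 3
    reference_depth: int = 1_000_000
    seed: Optional[int] = None

    @property
    def n_peaks(self) -> int:
        return len(self.cell_types) * self.peaks_per_type + self.n_shared_peaks


@dataclass
class MixtureTruth:
    """Known mixing proportions (samples × cell types) and read depth."""

    proportions: pd.DataFrame
    depth: int = 1_000_000

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative proportion")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("truth rows must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _place_peaks(
    spec: SyntheticPanelSpec, rng: np.random.Generator
) -> list[Peak]:
    """Place ``spec.n_peaks`` mutually disjoint intervals on the genome."""
    lo, hi = spec.peak_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_peaks)
    chrom_names = [c for c, _ in spec.genome]
    chrom_sizes = np.array([s for _, s in spec.genome], dtype=float)
    assign = rng.choice(
        len(chrom_names), size=spec.n_peaks, p=chrom_sizes / chrom_sizes.sum()
    )
    peaks: list[Peak] = []
    for ci, (chrom, size) in enumerate(spec.genome):
        ls = lengths[assign == ci]
        k = len(ls)
        occupied = int(ls.sum()) + (k + 1) * _MIN_GAP
        if occupied > size:
            raise ValueError(
                f"genome too small: need {occupied} bp on {chrom} "
                f"({size} available); enlarge the genome or reduce peaks"
            )
        free = size - occupied
        gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for i in range(k):
            pos += int(gaps[i]) + _MIN_GAP
            start, end = pos, pos + int(ls[i])
            peaks.append(Peak(chrom, start, end, f"{chrom}:{start}-{end}"))
            pos = end
    rng.shuffle(peaks)
    return peaks


def generate_panel(
    spec: SyntheticPanelSpec = SyntheticPanelSpec(), seed: SeedLike = None
) -> tuple[ReferencePanel, dict[str, CountsMatrix], pd.DataFrame]:
    """Generate a reference panel, reference counts and expected rates.

    Returns ``(panel, ref_counts, rates)``: the panel's peak set for each
    cell type holds its specific peaks plus all shared peaks; each
    reference counts matrix has one row per panel peak (union across cell
    types) and one column per reference sample of that cell type; and
    ``rates`` (peaks × cell types) gives the expected relative read rate
    of each peak in each pure cell type.
    """
    rng = _rng(seed if seed is not None else spec.seed)
    placed = _place_peaks(spec, rng)
    cts = list(spec.cell_types)
    owners: dict[str, list[Peak]] = {}
    cursor = 0
    for ct in cts:
        owners[ct] = placed[cursor : cursor + spec.peaks_per_type]
        cursor += spec.peaks_per_type
    shared = placed[cursor:]

    all_ids = [p.peak_id for p in placed]
    rates = pd.DataFrame(
        spec.background_rate, index=pd.Index(all_ids, name="peak_id"),
        columns=cts, dtype=float,
    )
    floor = spec.min_separation * spec.background_rate
    for ct in cts:
        ids = [p.peak_id for p in owners[ct]]
        draw = spec.background_rate * spec.separation * rng.lognormal(
            0.0, spec.sdlog, size=len(ids)
        )
        rates.loc[ids, ct] = np.maximum(draw, floor)
    if shared:
        sids = [p.peak_id for p in shared]
        sdraw = spec.background_rate * spec.separation * rng.lognormal(
            0.0, spec.sdlog, size=len(sids)
        )
        for ct in cts:
            rates.loc[sids, ct] = sdraw

    panel = ReferencePanel(
        {ct: PeakSet(owners[ct] + shared, label=ct) for ct in cts}
    )
    # union peak set defines the row order of counts and rates
    union = PeakSet(placed, label="panel_union")
    rates = rates.reindex(union.peak_ids)

    ref_counts: dict[str, CountsMatrix] = {}
    for ct in cts:
        prob = rates[ct].to_numpy()
        prob = prob / prob.sum()
        cols = {}
        for r in range(spec.n_reference_samples_per_type):
            cols[f"{ct}_ref{r + 1}"] = rng.multinomial(
                spec.reference_depth, prob
            )
        ref_counts[ct] = CountsMatrix(
            pd.DataFrame(cols, index=rates.index)
        )
    return panel, ref_counts, rates


def bulk_peak_set(panel: ReferencePanel) -> PeakSet:
    """Union of all panel peak sets, de-duplicated by peak id."""
    seen: dict[str, Peak] = {}
    for ps in panel.peak_sets.values():
        for p in ps:
            seen.setdefault(p.peak_id, p)
    return PeakSet(seen.values(), label="bulk")


def mix_pseudobulk(
    rates: pd.DataFrame,
    truth: MixtureTruth,
    depth: Optional[int] = None,
    seed: SeedLike = None,
) -> CountsMatrix:
    """Multinomial pseudobulk counts at known mixing proportions.

    Each cell type's rate column is first normalized to a probability
    vector, so a truth proportion is a proportion of *reads* from that
    cell type (read pooling); the mixture probabilities are
    ``Σ_x proportion_x · q_x`` and each sample draws ``depth`` reads
    multinomially.
    """
    depth = int(depth if depth is not None else truth.depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    missing = [c for c in truth.cell_types if c not in rates.columns]
    if missing:
        raise ValueError(f"truth cell types absent from rates: {missing}")
    rng = _rng(seed)
    q = rates[truth.cell_types].to_numpy(dtype=float)
    q = q / q.sum(axis=0, keepdims=True)
    cols = {}
    for sample, row in truth.proportions.iterrows():
        prob = q @ row.to_numpy(dtype=float)
        cols[sample] = rng.multinomial(depth, prob)
    return CountsMatrix(pd.DataFrame(cols, index=rates.index))


def benchmark_composition(
    n_samples: int = 49,
    depth: int = 1_000_000,
    proportions_source: str = "paper_like",
    alpha: Optional[Sequence[float]] = None,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    seed: SeedLike = None,
) -> MixtureTruth:
    """Draw known mixing compositions.

    ``paper_like`` (requires the four standard brain cell types) draws
    microglia uniformly in [0.05, 0.21] and neuron-dominant remainders:
    raw weights neurons U(0.40, 0.55), oligodendrocytes U(0.15, 0.32),
    astrocytes U(0.08, 0.22), rescaled to fill 1 − microglia, which keeps
    neurons the most abundant type in every sample. ``dirichlet`` draws
    rows from Dirichlet(alpha) (default all-ones).
    """
    rng = _rng(seed)
    cts = list(cell_types)
    ids = [f"sample{i + 1}" for i in range(n_samples)]
    if proportions_source == "paper_like":
        if set(cts) != set(DEFAULT_CELL_TYPES):
            raise ValueError(
                "paper_like compositions are defined for the four standard "
                f"brain cell types {DEFAULT_CELL_TYPES}"
            )
        mg = rng.uniform(0.05, 0.21, size=n_samples)
        neu = rng.uniform(0.40, 0.55, size=n_samples)
        oli = rng.uniform(0.15, 0.32, size=n_samples)
        ast = rng.uniform(0.08, 0.22, size=n_samples)
        rest = neu + oli + ast
        scale = (1.0 - mg) / rest
        df = pd.DataFrame(
            {
                "astrocytes": ast * scale,
                "microglia": mg,
                "neurons": neu * scale,
                "oligodendrocytes": oli * scale,
            },
            index=ids,
        )[cts]
    elif proportions_source == "dirichlet":
        a = np.ones(len(cts)) if alpha is None else np.asarray(alpha, float)
        if len(a) != len(cts):
            raise ValueError("alpha length must match cell types")
        df = pd.DataFrame(
            rng.dirichlet(a, size=n_samples), index=ids, columns=cts
        )
    else:
        raise ValueError(f"unknown proportions_source {proportions_source!r}")
    return MixtureTruth(df, depth=depth)


def downsample_reference(
    panel: ReferencePanel, fraction: float, seed: SeedLike = None
) -> ReferencePanel:
    """Remove ``fraction`` of each cell type's peaks uniformly at random.

    Sampling is without replacement and seed-deterministic. Note that
    removing 25% twice is not the same as removing 50% once — each call
    samples independently from its input.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = _rng(seed)
    new_sets = {}
    for ct, ps in panel.peak_sets.items():
        n = len(ps)
        n_keep = n - int(round(fraction * n))
        if n_keep == 0:
            warnings.warn(
                f"downsampling leaves no peaks for {ct!r}; "
                "cell type dropped from the panel",
                stacklevel=2,
            )
            continue
        keep_idx = rng.choice(n, size=n_keep, replace=False)
        new_sets[ct] = PeakSet(
            [ps[i] for i in sorted(keep_idx)], label=ps.label
        )
    return ReferencePanel(new_sets)


def drop_cell_type(
    obj: Union[ReferencePanel, MixtureTruth], cell_type: str
) -> Union[ReferencePanel, MixtureTruth]:
    """Remove a cell type from a panel, or zero it out of a truth matrix.

    Dropping from a :class:`ReferencePanel` removes the reference entry
    (the cell type becomes invisible to annotation and deconvolution).
    Dropping from a :class:`MixtureTruth` removes the column and
    renormalizes the remaining proportions to sum to 1 — the cell type is
    then genuinely absent from the mixtures. Dropping then re-adding is
    not an identity.
    """
    if isinstance(obj, ReferencePanel):
        return obj.drop(cell_type)
    if isinstance(obj, MixtureTruth):
        if cell_type not in obj.proportions.columns:
            raise KeyError(cell_type)
        rest = obj.proportions.drop(columns=cell_type)
        if rest.shape[1] == 0:
            raise ValueError("cannot drop the last cell type")
        return MixtureTruth(
            rest.div(rest.sum(axis=1), axis=0), depth=obj.depth
        )
    raise TypeError(f"cannot drop a cell type from {type(obj).__name__}")


@dataclass
class Benchmark:
    """Everything needed to run the full pipeline against known truth."""

    spec: SyntheticPanelSpec
    panel: ReferencePanel
    ref_counts: dict[str, CountsMatrix]
    rates: pd.DataFrame
    truth: MixtureTruth
    bulk_peaks: PeakSet
    bulk_counts: CountsMatrix


def standard_benchmark(
    seed: int = 0,
    n_samples: int = 49,
    depth: int = 1_000_000,
    spec: Optional[SyntheticPanelSpec] = None,
) -> Benchmark:
    """The standard pseudobulk benchmark at desk scale.

    49 samples with paper-like compositions mixed at depth 1e6 from the
    default 4 × 500-specific-peak panel. The bulk peak set is the union
    of the panel peaks (every mixture read falls in a panel peak). All
    randomness derives from ``seed``.
    """
    spec = spec if spec is not None else SyntheticPanelSpec()
    s_panel, s_truth, s_mix = np.random.SeedSequence(seed).spawn(3)
    panel, ref_counts, rates = generate_panel(spec, seed=s_panel)
    truth = benchmark_composition(
        n_samples=n_samples,
        depth=depth,
        cell_types=spec.cell_types,
        seed=s_truth,
    )
    bulk_counts = mix_pseudobulk(rates, truth, seed=s_mix)
    return Benchmark(
        spec, panel, ref_counts, rates, truth, bulk_peak_set(panel), bulk_counts
    )
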