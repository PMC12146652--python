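"""Peak and count-matrix I/O.

All genomic intervals in this package use 0-based half-open (BED)
coordinates. Peaks are held in :class:`PeakSet` objects that stay sorted by
``(chrom, start, end)``; read counts live in :class:`CountsMatrix`, a thin
wrapper around a peaks × samples :class:`pandas.DataFrame` that carries
per-sample library sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakSet",
    "CountsMatrix",
    "PeakFileError",
    "CANONICAL_CHROMS",
    "read_peaks",
    "write_peaks",
    "filter_peaks",
    "read_counts",
    "write_counts",
    "filter_low_counts",
]

#: Default canonical chromosome names (human autosomes + sex chromosomes).
CANONICAL_CHROMS: frozenset[str] = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"}
)


class PeakFileError(ValueError):
    """Raised when a peak or counts file cannot be parsed or validated."""


@dataclass(frozen=True)
class Peak:
    """A genomic interval in 0-based half-open coordinates.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must satisfy ``end > start``.
    peak_id : str
        Identifier, unique within a :class:`PeakSet`.
    signal : float, optional
        Signal value (e.g. narrowPeak column 7).
    neg_log10_p : float, optional
        -log10 peak-calling p value (narrowPeak column 8).
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    signal: Optional[float] = None
    neg_log10_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PeakFileError(
                f"peak {self.peak_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.start < 0:
            raise PeakFileError(f"peak {self.peak_id!r}: negative start")
        if self.signal is not None and self.signal < 0:
            raise PeakFileError(f"peak {self.peak_id!r}: negative signal")
        if self.neg_log10_p is not None and self.neg_log10_p < 0:
            raise PeakFileError(f"peak {self.peak_id!r}: negative -log10(p)")

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered, duplicate-free collection of peaks.

    Peaks are sorted by ``(chrom, start, end)`` on construction and the
    order is maintained by every filtering operation.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = "") -> None:
        sorted_peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        ids = [p.peak_id for p in sorted_peaks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PeakFileError(f"duplicate peak ids: {dupes[:5]}")
        self._peaks: tuple[Peak, ...] = tuple(sorted_peaks)
        self.label = label

    def __len__(self) -> int:
        return len(self._peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks)

    def __getitem__(self, i: int) -> Peak:
        return self._peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._peaks == other._peaks

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self._peaks]

    def by_id(self, peak_id: str) -> Peak:
        try:
            return self._index[peak_id]
        except AttributeError:
            self._index = {p.peak_id: p for p in self._peaks}
            return self._index[peak_id]

    def lengths(self) -> pd.Series:
        """Per-peak interval length in bp, indexed by peak id."""
        return pd.Series(
            {p.peak_id: p.length for p in self._peaks}, name="length"
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Chromosome": [p.chrom for p in self._peaks],
                "Start": [p.start for p in self._peaks],
                "End": [p.end for p in self._peaks],
                "peak_id": [p.peak_id for p in self._peaks],
            }
        )


def _auto_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def read_peaks(path: str | Path, format: str = "bed") -> PeakSet:
    """Read a BED3+ or narrowPeak file into a sorted :class:`PeakSet`.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. When the
    name column is missing or ``"."``, ids are auto-generated as
    ``chrom:start-end``. For narrowPeak input, column 7 (signalValue) and
    column 8 (-log10 p) are parsed into ``signal`` and ``neg_log10_p``.
    """
    path = Path(path)
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakFileError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if format == "narrowPeak" and len(fields) < 10:
                raise PeakFileError(
                    f"{path.name}:{lineno}: narrowPeak requires 10 fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakFileError(f"{path.name}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            peak_id = name if name not in {".", ""} else _auto_id(chrom, start, end)
            signal = neg_log10_p = None
            if format == "narrowPeak":
                try:
                    signal = float(fields[6])
                    neg_log10_p = float(fields[7])
                except ValueError as exc:
                    raise PeakFileError(f"{path.name}:{lineno}: {exc}") from exc
            try:
                peaks.append(
                    Peak(chrom, start, end, peak_id, signal, neg_log10_p)
                )
            except PeakFileError as exc:
                raise PeakFileError(f"{path.name}:{lineno}: {exc}") from exc
    return PeakSet(peaks, label=path.stem)


def _header_comment(params: dict) -> str:
    from chas import __version__

    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# chas v{__version__} {kv}".rstrip()


def write_peaks(peaks: PeakSet, path: str | Path, **params) -> None:
    """Write a PeakSet as BED, with a header comment carrying version/params."""
    with open(path, "w") as fh:
        fh.write(_header_comment(params) + "\n")
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def filter_peaks(
    peaks: PeakSet,
    blacklist: Optional[PeakSet] = None,
    canonical_only: bool = False,
    min_neg_log10_p: Optional[float] = None,
    canonical_chroms: frozenset[str] = CANONICAL_CHROMS,
) -> PeakSet:
    """Remove blacklisted, non-canonical, and low-significance peaks.

    A peak is removed when it overlaps any blacklist interval by at least
    1 bp, when ``canonical_only`` is set and its chromosome is not in
    ``canonical_chroms`` (default chr1-22, chrX, chrY), or when its
    ``neg_log10_p`` is below ``min_neg_log10_p``. A peak with
    ``neg_log10_p`` exactly at the threshold is kept.
    """
    kept = list(peaks)
    if min_neg_log10_p is not None:
        if any(p.neg_log10_p is None for p in kept):
            raise PeakFileError(
                "min_neg_log10_p filter requires neg_log10_p on every peak "
                "(narrowPeak input)"
            )
        kept = [p for p in kept if p.neg_log10_p >= min_neg_log10_p]
    if canonical_only:
        kept = [p for p in kept if p.chrom in canonical_chroms]
    if blacklist is not None and len(blacklist) > 0 and kept:
        from chas.annotation import find_overlaps

        hit = {q for q, _, _ in find_overlaps(PeakSet(kept), blacklist)}
        kept = [p for p in kept if p.peak_id not in hit]
    return PeakSet(kept, label=peaks.label)


@dataclass
class CountsMatrix:
    """Peaks × samples read counts with per-sample library sizes.

    ``library_sizes`` defaults to the column sums of ``counts`` and is
    recomputed after row filtering unless it was provided externally
    (``external_library_sizes=True``), in which case it is preserved.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]
    external_library_sizes: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise PeakFileError(f"duplicate peak ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            raise PeakFileError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise PeakFileError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
            self.external_library_sizes = False
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float)
            if not self.library_sizes.index.equals(self.counts.columns):
                self.library_sizes = self.library_sizes.reindex(
                    self.counts.columns
                )
            if self.library_sizes.isna().any():
                raise PeakFileError("library_sizes missing for some samples")
            self.external_library_sizes = True

    @property
    def peak_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_peaks(self, peak_ids: Sequence[str]) -> "CountsMatrix":
        """Row subset; library sizes follow the external/recompute rule."""
        sub = self.counts.loc[list(peak_ids)]
        if self.external_library_sizes:
            return CountsMatrix(sub, self.library_sizes.copy())
        return CountsMatrix(sub)


def read_counts(path: str | Path) -> CountsMatrix:
    """Read a tab-delimited counts matrix (first column peak ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise PeakFileError(f"{path.name}: non-numeric counts")
    return CountsMatrix(df)


def write_counts(counts: CountsMatrix, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(params) + "\n")
        counts.counts.to_csv(fh, sep="\t", index_label="peak_id")


def filter_low_counts(
    counts: CountsMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountsMatrix:
    """Keep peaks with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    CPM is computed against the current library sizes; library sizes of the
    result are recomputed from the retained rows (unless external).
    """
    if min_samples > counts.n_samples:
        raise ValueError(
            f"min_samples ({min_samples}) exceeds sample count "
            f"({counts.n_samples})"
        )
    if (counts.library_sizes <= 0).any():
        raise ValueError("non-positive library size")
    cpm = counts.counts.div(counts.library_sizes, axis=1) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.subset_peaks(list(counts.counts.index[keep]))
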