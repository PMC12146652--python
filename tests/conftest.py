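import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chas import (
    CountsMatrix,
    Peak,
    PeakSet,
    ReferencePanel,
    annotate_peaks,
    standard_benchmark,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def brute_force_overlaps(query, subject):
    """All-pairs quadratic scan: the oracle for interval overlap."""
    out = []
    for q in query:
        for s in subject:
            if q.chrom != s.chrom:
                continue
            bp = min(q.end, s.end) - max(q.start, s.start)
            if bp > 0:
                out.append((q.peak_id, s.peak_id, bp))
    return sorted(out)


def random_peakset(rng, n, label, chroms=("chr1", "chr2"), span=10_000):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 300))
        peaks.append(Peak(chrom, start, end, f"{label}_{i}"))
    return PeakSet(peaks, label=label)


@pytest.fixture
def toy_panel():
    """Two cell types with one shared region of ambiguity."""
    neuron = PeakSet(
        [
            Peak("chr1", 100, 200, "neu_1"),
            Peak("chr1", 1000, 1400, "neu_2"),
            Peak("chr2", 50, 150, "neu_3"),
        ],
        label="neuron",
    )
    microglia = PeakSet(
        [
            Peak("chr1", 150, 260, "mg_1"),
            Peak("chr2", 500, 700, "mg_2"),
        ],
        label="microglia",
    )
    return ReferencePanel({"neuron": neuron, "microglia": microglia})


@pytest.fixture(scope="session")
def benchmark():
    """The standard pseudobulk benchmark, generated once per session."""
    return standard_benchmark(seed=0)


@pytest.fixture(scope="session")
def benchmark_annotation(benchmark):
    return annotate_peaks(benchmark.bulk_peaks, benchmark.panel)
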