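import itertools

import numpy as np
import pandas as pd
import pytest

from chas.annotation import ReferencePanel
from chas.genomic_io import CountsMatrix, Peak, PeakSet
from chas.mf_deconv import (
    OTHER_CELLS,
    ReferenceProfile,
    build_consensus,
    build_reference_profile,
    deconvolve,
    estimate_proportions,
    map_counts_to_consensus,
    normalize_counts,
    select_signature_peaks,
)
from chas.synthetic import (
    SyntheticPanelSpec,
    benchmark_composition,
    bulk_peak_set,
    generate_panel,
    mix_pseudobulk,
)

from conftest import random_peakset


def simplex_grid_oracle(A, y, step=0.01):
    """Exhaustive search over the probability sub-simplex (p >= 0, sum <= 1)."""
    k = A.shape[1]
    ticks = np.arange(0.0, 1.0 + 1e-12, step)
    best = None
    for combo in itertools.product(ticks, repeat=k):
        if sum(combo) > 1 + 1e-9:
            continue
        p = np.array(combo)
        obj = float(np.sum((A @ p - y) ** 2))
        if best is None or obj < best[0]:
            best = (obj, p)
    return best[1]


class TestBuildConsensus:
    def _panel(self, *peaks):
        return ReferencePanel({"ct": PeakSet(list(peaks))})

    def test_overlapping_bulk_and_reference_merge(self):
        bulk = PeakSet([Peak("chr1", 100, 200, "b")])
        panel = self._panel(Peak("chr1", 150, 250, "r"))
        cons = build_consensus(bulk, panel)
        assert [(p.start, p.end) for p in cons.peaks] == [(100, 250)]
        assert cons.cell_types["chr1:100-250"] == frozenset({"ct"})

    def test_disjoint_peaks_remain_separate(self):
        bulk = PeakSet([Peak("chr1", 0, 50, "b")])
        panel = self._panel(Peak("chr1", 100, 150, "r"))
        cons = build_consensus(bulk, panel)
        assert len(cons.peaks) == 2

    def test_union_matches_boolean_mask_oracle(self):
        rng = np.random.default_rng(8)
        bulk = random_peakset(rng, 150, "b", chroms=("chr1",), span=5000)
        ref = random_peakset(rng, 150, "r", chroms=("chr1",), span=5000)
        cons = build_consensus(bulk, ReferencePanel({"ct": ref}))
        mask = np.zeros(6000, dtype=bool)
        for p in list(bulk) + list(ref):
            mask[p.start:p.end] = True
        got = np.zeros(6000, dtype=bool)
        prev_end = -1
        for p in cons.peaks:
            got[p.start:p.end] = True
            assert p.start > prev_end  # pairwise disjoint, sorted
            prev_end = p.end
        assert (mask == got).all()

    def test_every_input_contained_in_exactly_one_consensus(self):
        rng = np.random.default_rng(12)
        bulk = random_peakset(rng, 80, "b", span=4000)
        ref = random_peakset(rng, 80, "r", span=4000)
        cons = build_consensus(bulk, ReferencePanel({"ct": ref}))
        intervals = [(p.chrom, p.start, p.end) for p in cons.peaks]
        for p in list(bulk) + list(ref):
            parents = [
                iv for iv in intervals
                if iv[0] == p.chrom and iv[1] <= p.start and p.end <= iv[2]
            ]
            assert len(parents) == 1


class TestMapCountsToConsensus:
    def test_constituent_counts_summed(self):
        bulk = PeakSet(
            [Peak("chr1", 0, 100, "a"), Peak("chr1", 50, 150, "b"),
             Peak("chr1", 500, 600, "c")]
        )
        panel = ReferencePanel({"ct": PeakSet([Peak("chr1", 90, 120, "r")])})
        cons = build_consensus(bulk, panel)
        cm = CountsMatrix(
            pd.DataFrame({"s": [10, 20, 7]}, index=["a", "b", "c"])
        )
        out = map_counts_to_consensus(cm, bulk, cons)
        assert out.counts.loc["chr1:0-150", "s"] == 30
        assert out.counts.loc["chr1:500-600", "s"] == 7

    def test_unknown_row_id_errors(self):
        bulk = PeakSet([Peak("chr1", 0, 10, "a")])
        cons = build_consensus(
            bulk, ReferencePanel({"ct": PeakSet([Peak("chr1", 0, 10, "r")])})
        )
        cm = CountsMatrix(pd.DataFrame({"s": [1]}, index=["mystery"]))
        with pytest.raises(ValueError):
            map_counts_to_consensus(cm, bulk, cons)


class TestNormalizeCounts:
    def test_single_peak_forces_one_million(self):
        cm = CountsMatrix(pd.DataFrame({"s": [37]}, index=["p"]))
        out = normalize_counts(cm, pd.Series({"p": 250}))
        assert out.loc["p", "s"] == pytest.approx(1e6)

    def test_length_weighting_hand_computed(self):
        cm = CountsMatrix(pd.DataFrame({"s": [10, 10]}, index=["a", "b"]))
        out = normalize_counts(cm, pd.Series({"a": 100, "b": 200}))
        assert out.loc["a", "s"] == pytest.approx(666666.6667, rel=1e-6)
        assert out.loc["b", "s"] == pytest.approx(333333.3333, rel=1e-6)

    def test_count_scale_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"s": rng.integers(1, 100, 10).astype(float)},
            index=[f"p{i}" for i in range(10)],
        )
        lengths = pd.Series(
            rng.integers(100, 1000, 10), index=df.index
        )
        base = normalize_counts(CountsMatrix(df), lengths)
        doubled = normalize_counts(CountsMatrix(df * 2), lengths)
        pd.testing.assert_frame_equal(base, doubled)

    def test_zero_length_errors(self):
        cm = CountsMatrix(pd.DataFrame({"s": [1]}, index=["p"]))
        with pytest.raises(ValueError):
            normalize_counts(cm, pd.Series({"p": 0}))


class TestBuildReferenceProfile:
    def test_median_and_half_range(self):
        ref = {
            "ct": pd.DataFrame(
                {"r1": [2.0], "r2": [4.0], "r3": [9.0]}, index=["p"]
            )
        }
        prof = build_reference_profile(ref)
        assert prof.profile.loc["p", "ct"] == 4.0
        assert prof.variability.loc["p"] == pytest.approx(3.5)

    def test_single_sample_degrades_gracefully(self):
        ref = {"ct": pd.DataFrame({"r1": [5.0, 2.0]}, index=["p", "q"])}
        prof = build_reference_profile(ref)
        assert prof.profile["ct"].tolist() == [5.0, 2.0]
        assert (prof.variability == 0).all()
        assert (prof.weights == 1.0).all()

    def test_constant_peak_gets_maximal_weight(self):
        ref = {
            "a": pd.DataFrame({"r1": [3.0, 1.0], "r2": [3.0, 9.0]},
                              index=["p", "q"]),
        }
        prof = build_reference_profile(ref)
        assert prof.weights.loc["p"] == 1.0
        assert prof.weights.loc["q"] < 1.0

    def test_variability_spans_all_reference_samples(self):
        # range computed across cell types' samples jointly
        ref = {
            "a": pd.DataFrame({"a1": [1.0]}, index=["p"]),
            "b": pd.DataFrame({"b1": [7.0]}, index=["p"]),
        }
        prof = build_reference_profile(ref)
        assert prof.variability.loc["p"] == pytest.approx(3.0)


class TestSelectSignaturePeaks:
    def _profile(self, rows, cts=("a", "b", "c", "d")):
        df = pd.DataFrame(
            rows, columns=list(cts),
            index=[f"p{i}" for i in range(len(rows))],
        )
        v = pd.Series(0.0, index=df.index)
        return ReferenceProfile(df, v, 1.0 / (1.0 + v))

    def test_fivefold_dominance_kept(self):
        sig = select_signature_peaks(self._profile([[10, 1, 1, 1]]), 5)
        assert sig.dominant.to_dict() == {"p0": "a"}

    def test_below_ratio_rejected(self):
        sig = select_signature_peaks(self._profile([[10, 3, 0, 0]]), 5)
        assert len(sig.dominant) == 0

    def test_zero_competitors_always_pass(self):
        sig = select_signature_peaks(self._profile([[10, 0, 0, 0]]), 5)
        assert sig.dominant.to_dict() == {"p0": "a"}

    def test_missing_cell_type_warns(self):
        with pytest.warns(UserWarning, match="no signature peaks"):
            select_signature_peaks(
                self._profile([[10, 1, 1, 1], [1, 10, 1, 1], [1, 1, 10, 1]]),
                5,
            )

    def test_ratio_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            select_signature_peaks(self._profile([[1, 1, 1, 1]]), 1.0)


class TestEstimateProportions:
    def _profile(self, R, weights=None):
        idx = [f"p{i}" for i in range(R.shape[0])]
        df = pd.DataFrame(R, index=idx, columns=list("AB")[: R.shape[1]])
        v = pd.Series(0.0, index=idx)
        w = pd.Series(1.0, index=idx) if weights is None else weights
        return ReferenceProfile(df, v, w)

    def test_vertex_recovery(self):
        rng = np.random.default_rng(3)
        R = rng.random((12, 2)) * 10
        prof = self._profile(R)
        bulk = pd.DataFrame({"s": R[:, 0]}, index=prof.profile.index)
        est = estimate_proportions(bulk, prof)
        assert est.proportions.loc["s", "A"] >= 0.99
        assert est.proportions.loc["s", OTHER_CELLS] <= 0.01

    def test_noiseless_mixture_recovered_exactly(self):
        rng = np.random.default_rng(4)
        R = rng.random((20, 2)) * 5
        prof = self._profile(R)
        bulk = pd.DataFrame(
            {"s": R @ np.array([0.6, 0.4])}, index=prof.profile.index
        )
        est = estimate_proportions(bulk, prof)
        assert est.proportions.loc["s", "A"] == pytest.approx(0.6, abs=1e-6)
        assert est.proportions.loc["s", "B"] == pytest.approx(0.4, abs=1e-6)

    def test_null_signal_gives_all_other(self):
        rng = np.random.default_rng(5)
        R = rng.random((10, 2)) + 0.5
        prof = self._profile(R)
        bulk = pd.DataFrame({"s": np.zeros(10)}, index=prof.profile.index)
        est = estimate_proportions(bulk, prof)
        assert est.proportions.loc["s", ["A", "B"]].sum() == pytest.approx(0.0)
        assert est.proportions.loc["s", OTHER_CELLS] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3])
    def test_agrees_with_simplex_grid_search(self, k):
        rng = np.random.default_rng(6 + k)
        for _ in range(5):
            R = rng.random((8, k)) * 10
            idx = [f"p{i}" for i in range(8)]
            prof = ReferenceProfile(
                pd.DataFrame(R, index=idx, columns=list("ABC")[:k]),
                pd.Series(0.0, index=idx),
                pd.Series(1.0, index=idx),
            )
            ptrue = rng.dirichlet(np.ones(k)) * rng.choice([0.7, 1.0, 1.3])
            y = R @ ptrue + rng.normal(0, 0.3, 8)
            bulk = pd.DataFrame({"s": y}, index=idx)
            est = estimate_proportions(bulk, prof)
            oracle = simplex_grid_oracle(R, y)
            got = est.proportions.loc["s", list("ABC")[:k]].to_numpy()
            assert np.abs(got - oracle).max() <= 0.02

    def test_simplex_constraints_hold(self):
        rng = np.random.default_rng(7)
        R = rng.random((15, 2)) * 3
        prof = self._profile(R)
        bulk = pd.DataFrame(
            {f"s{i}": R @ rng.random(2) * 2 for i in range(6)},
            index=prof.profile.index,
        )
        est = estimate_proportions(bulk, prof)
        vals = est.proportions.to_numpy()
        assert (vals >= 0).all()
        assert (est.proportions[["A", "B"]].sum(axis=1) <= 1 + 1e-9).all()

    def test_negative_weights_rejected(self):
        R = np.ones((4, 2))
        idx = [f"p{i}" for i in range(4)]
        prof = ReferenceProfile(
            pd.DataFrame(R, index=idx, columns=["A", "B"]),
            pd.Series(0.0, index=idx),
            pd.Series(1.0, index=idx),
        )
        bulk = pd.DataFrame({"s": np.ones(4)}, index=idx)
        with pytest.raises(ValueError):
            estimate_proportions(
                bulk, prof, weights=pd.Series(-1.0, index=idx)
            )

    def test_too_few_signature_peaks_rejected(self):
        prof = self._profile(np.ones((1, 2)))
        bulk = pd.DataFrame({"s": [1.0]}, index=prof.profile.index)
        with pytest.raises(ValueError):
            estimate_proportions(bulk, prof)


@pytest.fixture(scope="module")
def small_benchmark():
    spec = SyntheticPanelSpec(
        peaks_per_type=120,
        n_shared_peaks=40,
        genome=(("chr1", 5_000_000),),
    )
    s_panel, s_truth, s_mix = np.random.SeedSequence(21).spawn(3)
    panel, ref_counts, rates = generate_panel(spec, seed=s_panel)
    truth = benchmark_composition(n_samples=20, depth=500_000, seed=s_truth)
    bulk_counts = mix_pseudobulk(rates, truth, seed=s_mix)
    return panel, ref_counts, rates, truth, bulk_counts


class TestDeconvolvePipeline:
    def test_recovers_generating_proportions(self, small_benchmark):
        panel, ref_counts, rates, truth, bulk_counts = small_benchmark
        bulk = bulk_peak_set(panel)
        est = deconvolve(bulk, bulk_counts, panel, ref_counts,
                         ref_count_peaks=bulk)
        from scipy.stats import spearmanr

        for ct in truth.cell_types:
            rho, _ = spearmanr(
                est.proportions[ct], truth.proportions[ct]
            )
            assert rho >= 0.9, ct

    def test_sample_permutation_equivariance(self, small_benchmark):
        panel, ref_counts, _, _, bulk_counts = small_benchmark
        bulk = bulk_peak_set(panel)
        base = deconvolve(bulk, bulk_counts, panel, ref_counts,
                          ref_count_peaks=bulk)
        perm = list(reversed(bulk_counts.sample_ids))
        shuffled = CountsMatrix(bulk_counts.counts[perm])
        out = deconvolve(bulk, shuffled, panel, ref_counts,
                         ref_count_peaks=bulk)
        pd.testing.assert_frame_equal(
            out.proportions.loc[base.proportions.index], base.proportions
        )

    def test_bit_identical_across_runs(self, small_benchmark):
        panel, ref_counts, _, _, bulk_counts = small_benchmark
        bulk = bulk_peak_set(panel)
        a = deconvolve(bulk, bulk_counts, panel, ref_counts,
                       ref_count_peaks=bulk)
        b = deconvolve(bulk, bulk_counts, panel, ref_counts,
                       ref_count_peaks=bulk)
        assert a.proportions.equals(b.proportions)

    def test_bulk_sample_scale_invariance(self, small_benchmark):
        panel, ref_counts, _, _, bulk_counts = small_benchmark
        bulk = bulk_peak_set(panel)
        base = deconvolve(bulk, bulk_counts, panel, ref_counts,
                          ref_count_peaks=bulk)
        scaled_df = bulk_counts.counts.copy().astype(float)
        first = scaled_df.columns[0]
        scaled_df[first] *= 3.0
        out = deconvolve(bulk, CountsMatrix(scaled_df), panel, ref_counts,
                         ref_count_peaks=bulk)
        pd.testing.assert_series_equal(
            out.proportions.loc[first], base.proportions.loc[first]
        )
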