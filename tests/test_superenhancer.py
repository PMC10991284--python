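"""ROSE calling, constituent summation, differential super-enhancers."""

import numpy as np
import pandas as pd
import pytest

from gcbreg.intervals import GeneAnnotation, GenomicInterval
from gcbreg.superenhancer import (
    link_se_to_genes,
    rose_call,
    rose_cutoff_index,
    se_differential,
    se_sum_constituents,
)


def cutoff_oracle(signals):
    """Exhaustive scan of scaled_rank - scaled_signal on the ascending sort."""
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 2 or s[0] == s[-1]:
        return None
    best_i, best_v = None, -np.inf
    for i in range(n):
        v = i / (n - 1) - (s[i] - s[0]) / (s[-1] - s[0])
        if v > best_v:
            best_i, best_v = i, v
    return best_i


class TestRoseCutoff:
    def test_one_outlier(self):
        # four flat regions and one dominant: cutoff at the 4th ascending
        idx = rose_cutoff_index([1, 1, 1, 1, 100])
        assert idx == 3

    def test_all_equal_no_cutoff(self):
        assert rose_cutoff_index([5, 5, 5]) is None

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_exhaustive_scan(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 51))
        signals = rng.gamma(2.0, 50.0, size=n)
        if trial % 7 == 0:  # inject ties
            signals = np.round(signals, -1)
        assert rose_cutoff_index(signals) == cutoff_oracle(signals)

    def test_scaling_invariance(self, rng):
        signals = rng.gamma(2.0, 50.0, size=30)
        assert rose_cutoff_index(signals) == rose_cutoff_index(signals * 7.3)


def _mk_peaks(starts, chrom="chr1", width=500):
    return [GenomicInterval(chrom, s, s + width) for s in starts]


class TestRoseCall:
    GENES = [GeneAnnotation("g1", "chr1", 500_000, "+")]

    def test_outlier_region_is_super(self):
        # five well-separated peaks, one with dominant signal
        peaks = _mk_peaks([0, 100_000, 200_000, 300_000, 400_000])
        signal = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        se = rose_call(peaks, signal, genes=[], stitch_gap=12_500)
        assert len(se) == 5
        assert se["is_super"].sum() == 1
        assert se.loc[se["is_super"], "signal"].iloc[0] == 100.0

    def test_equal_signals_warns_no_super(self):
        peaks = _mk_peaks([0, 100_000, 200_000])
        with pytest.warns(UserWarning, match="no super-enhancer cutoff"):
            se = rose_call(peaks, np.ones(3), genes=[])
        assert not se["is_super"].any()

    def test_tss_exclusion_boundary(self):
        # centers 2,400 vs 2,600 bp from the TSS at 100,000
        near = GenomicInterval("chr1", 97_350, 97_850)  # center 97,600
        far = GenomicInterval("chr1", 97_150, 97_650)  # center 97,400
        genes = [GeneAnnotation("g", "chr1", 100_000, "+")]
        se = rose_call(
            [near, far], np.array([5.0, 50.0]), genes, stitch_gap=0
        )
        kept = {m for ms in se["members"] for m in ms}
        assert 0 not in kept  # 2,400 bp away: excluded
        assert 1 in kept  # 2,600 bp away: retained

    def test_stitching_groups_adjacent_peaks(self):
        peaks = _mk_peaks([0, 5_000, 300_000])
        se = rose_call(peaks, np.array([1.0, 2.0, 10.0]), genes=[])
        assert len(se) == 2
        sizes = sorted(len(m) for m in se["members"])
        assert sizes == [1, 2]

    def test_max_signal_region_always_super(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            starts = np.arange(10) * 100_000
            signal = rng.gamma(2.0, 50.0, size=10)
            if signal.max() == signal.min():
                continue
            se = rose_call(_mk_peaks(starts), signal, genes=[])
            top = se.loc[se["signal"].idxmax()]
            assert top["is_super"]

    def test_super_count_invariant_under_scaling(self, rng):
        starts = np.arange(12) * 50_000
        signal = rng.gamma(2.0, 50.0, size=12)
        a = rose_call(_mk_peaks(starts), signal, genes=[])
        b = rose_call(_mk_peaks(starts), signal * 100, genes=[])
        assert a["is_super"].sum() == b["is_super"].sum()

    def test_ranks_are_permutation(self, rng):
        starts = np.arange(8) * 60_000
        se = rose_call(_mk_peaks(starts), rng.gamma(2, 10, 8), genes=[])
        assert sorted(se["rank"]) == list(range(1, len(se) + 1))


class TestSumConstituents:
    def _se_table(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10_000]},
            index=pd.Index(["SE_0"], name="se_id"),
        )

    def test_addition(self):
        peaks = [GenomicInterval("chr1", 100, 600), GenomicInterval("chr1", 700, 1_200)]
        counts = pd.DataFrame([[5, 7], [3, 3]], columns=["s1", "s2"])
        out = se_sum_constituents(self._se_table(), peaks, counts)
        assert out.loc["SE_0"].tolist() == [8, 10]

    def test_zero_overlap_contributes_nothing(self):
        peaks = [GenomicInterval("chr1", 20_000, 21_000)]
        counts = pd.DataFrame([[9, 9]], columns=["s1", "s2"])
        out = se_sum_constituents(self._se_table(), peaks, counts)
        assert (out.values == 0).all()

    def test_multi_overlap_goes_to_max_and_partitions(self):
        se = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 900], "end": [1_000, 2_000]},
            index=pd.Index(["SE_0", "SE_1"], name="se_id"),
        )
        # 60% of the peak in SE_1, 40% in SE_0
        peaks = [GenomicInterval("chr1", 800, 1_300)]
        counts = pd.DataFrame([[10, 20]], columns=["s1", "s2"])
        out = se_sum_constituents(se, peaks, counts)
        assert out.loc["SE_1"].tolist() == [10, 20]
        assert (out.loc["SE_0"] == 0).all()

    def test_column_sums_bounded(self, rng):
        se = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50_000], "end": [10_000, 60_000]},
            index=pd.Index(["SE_0", "SE_1"], name="se_id"),
        )
        starts = rng.integers(0, 100_000, size=30)
        peaks = [GenomicInterval("chr1", int(s), int(s) + 400) for s in starts]
        counts = pd.DataFrame(
            rng.poisson(30, size=(30, 3)), columns=["s1", "s2", "s3"]
        )
        out = se_sum_constituents(se, peaks, counts)
        assert (out.sum(axis=0) <= counts.sum(axis=0)).all()


class TestSeDifferential:
    def test_doubled_counts_log2fc_one(self):
        counts = pd.DataFrame(
            {"w1": [100.0], "w2": [100.0], "m1": [200.0], "m2": [200.0]},
            index=["SE_0"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = {"w1": "WT", "w2": "WT", "m1": "CK", "m2": "CK"}
        out = se_differential(counts, sf, groups, "WT")
        assert out.loc["SE_0", "log2FC"] == pytest.approx(1.0, abs=0.01)

    def test_size_factors_drive_fold_change(self):
        # equal raw counts, factors (2,2,1,1) on the mutant pair: log2FC ~ -1
        counts = pd.DataFrame(
            {"m1": [400.0], "m2": [400.0], "w1": [400.0], "w2": [400.0]},
            index=["SE_0"],
        )
        sf = pd.Series([2.0, 2.0, 1.0, 1.0], index=counts.columns)
        groups = {"m1": "CK", "m2": "CK", "w1": "WT", "w2": "WT"}
        out = se_differential(counts, sf, groups, "WT")
        assert out.loc["SE_0", "log2FC"] == pytest.approx(-1.0, abs=0.01)

    def test_rank_permutation_and_mismatch_error(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(6, 4)).astype(float),
            index=[f"SE_{i}" for i in range(6)],
            columns=["w1", "w2", "m1", "m2"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = {"w1": "WT", "w2": "WT", "m1": "CK", "m2": "CK"}
        out = se_differential(counts, sf, groups, "WT")
        assert sorted(out["rank"]) == [1, 2, 3, 4, 5, 6]
        bad_sf = pd.Series(1.0, index=["x", "y", "z", "w"])
        with pytest.raises(ValueError, match="size-factor"):
            se_differential(counts, bad_sf, groups, "WT")


class TestLinkSeToGenes:
    TADS = {
        "tad_a": GenomicInterval("chr1", 0, 100_000),
        "tad_b": GenomicInterval("chr1", 100_000, 200_000),
    }

    def _se(self, start, end):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end]},
            index=pd.Index(["SE_0"], name="se_id"),
        )

    def test_links_all_tad_genes(self):
        genes = [
            GeneAnnotation("g1", "chr1", 10_000, "+"),
            GeneAnnotation("g2", "chr1", 50_000, "-"),
            GeneAnnotation("g3", "chr1", 90_000, "+"),
            GeneAnnotation("g4", "chr1", 150_000, "+"),
        ]
        links = link_se_to_genes(self._se(20_000, 30_000), self.TADS, genes)
        assert [g for g, _ in links["SE_0"]] == ["g1", "g2", "g3"]

    def test_gene_free_tad_links_nothing(self):
        genes = [GeneAnnotation("g4", "chr1", 150_000, "+")]
        links = link_se_to_genes(self._se(20_000, 30_000), self.TADS, genes)
        assert links["SE_0"] == []

    def test_se_outside_tads_links_nothing(self):
        links = link_se_to_genes(
            self._se(500_000, 510_000),
            self.TADS,
            [GeneAnnotation("g1", "chr1", 10_000, "+")],
        )
        assert links["SE_0"] == []

    def test_diff_calls_attached(self):
        genes = [GeneAnnotation("g1", "chr1", 10_000, "+")]
        diff = pd.DataFrame({"call": ["down"]}, index=["g1"])
        links = link_se_to_genes(self._se(20_000, 30_000), self.TADS, genes, diff)
        assert links["SE_0"] == [("g1", "down")]


def test_planted_se_clusters_recovered(small_dataset):
    """Generator-coupled check: planted SE clusters surface as super calls."""
    from gcbreg.differential import size_factors

    d = small_dataset
    sf = size_factors(d["counts"])
    se = rose_call(d["peaks"], (d["counts"] / sf).values, d["genome"].genes)
    pid = list(d["counts"].index)
    super_members = set()
    for r in se[se["is_super"]].itertuples():
        super_members |= {pid[m] for m in r.members}
    recovered = sum(
        bool(set(region) & super_members) for region in d["truth"].se_regions
    )
    assert recovered == len(d["truth"].se_regions)
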