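import itertools

import numpy as np
import pandas as pd
import pytest

from g4age.coverage import (
    compute_normalization, depth_track, filter_peaks, fragments_to_cutsites,
    intersection_counts, logspace_sd, presence_matrix, replicate_summary,
    sample_background_regions, summarize_peak_coverage, trimmed_mean,
)
from g4age.io_model import GenomicInterval, Peak, PeakSet, SampleMeta
from oracles import trimmed_mean_oracle


def _iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def _peaks(*spans, assay="ATAC"):
    return PeakSet([
        Peak(_iv(s, e), f"p{i + 1}", assay) for i, (s, e) in enumerate(spans)
    ])


class TestCutsites:
    def test_two_windows_per_fragment(self):
        out = fragments_to_cutsites([_iv(100, 300)], width=50)
        assert [(o.start, o.end) for o in out] == [(75, 125), (275, 325)]

    def test_clipping_near_chrom_start(self):
        out = fragments_to_cutsites([_iv(10, 5000)], width=50,
                                    chrom_sizes={"chr1": 10_000})
        assert (out[0].start, out[0].end) == (0, 35)

    def test_width_two(self):
        out = fragments_to_cutsites([_iv(100, 300)], width=2)
        assert [(o.start, o.end) for o in out] == [(99, 101), (299, 301)]

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            fragments_to_cutsites([_iv(0, 10)], width=51)


class TestTrimmedMean:
    def test_worked_example(self):
        assert trimmed_mean([1, 2, 3, 4, 100], 0.2) == 3.0

    def test_constant_invariance_and_zero_trim(self):
        assert trimmed_mean([7.0] * 9, 0.3) == 7.0
        vals = [1.0, 5.0, 2.0]
        assert trimmed_mean(vals, 0.0) == pytest.approx(np.mean(vals))

    def test_matches_sort_slice_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            vals = rng.exponential(5.0, size=n)
            trim = float(rng.uniform(0, 0.49))
            assert trimmed_mean(vals, trim) == pytest.approx(
                trimmed_mean_oracle(vals, trim), rel=1e-12
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([])


class TestNormalization:
    def test_uniform_background(self):
        nf = compute_normalization({("s1", "ATAC"): [4.0] * 10})
        assert nf.get("s1", "ATAC") == pytest.approx(0.25)

    def test_doubling_halves_factor(self):
        vals = np.abs(np.random.default_rng(0).normal(5, 1, 100))
        f1 = compute_normalization({("s", "ATAC"): vals}).get("s", "ATAC")
        f2 = compute_normalization({("s", "ATAC"): 2 * vals}).get("s", "ATAC")
        assert f2 == pytest.approx(f1 / 2)

    def test_trimmed_outlier_example(self):
        nf = compute_normalization({("s", "G4Q"): [1, 2, 3, 4, 100]})
        assert nf.get("s", "G4Q") == pytest.approx(1 / 3)

    def test_all_zero_background_rejected(self):
        with pytest.raises(ValueError):
            compute_normalization({("s", "ATAC"): [0.0] * 50})

    def test_norm_depth_scale_invariance(self):
        # scaling every depth (peak and background) by k leaves norm_depth
        rng = np.random.default_rng(3)
        bg = rng.poisson(5, 500).astype(float) + 1
        peaks = _peaks((0, 4))
        depth = {"chr1": rng.poisson(20, 100).astype(float)}
        for k in (0.5, 3.0, 10.0):
            f1 = compute_normalization({("s", "ATAC"): bg}).get("s", "ATAC")
            fk = compute_normalization({("s", "ATAC"): k * bg}).get("s", "ATAC")
            d1 = summarize_peak_coverage(peaks, depth, f1)
            dk = summarize_peak_coverage(
                peaks, {"chr1": k * depth["chr1"]}, fk
            )
            assert dk["norm_depth"].iloc[0] == pytest.approx(
                d1["norm_depth"].iloc[0], rel=1e-12
            )


class TestSummaries:
    def test_arithmetic_example(self):
        peaks = _peaks((0, 4))
        depth = {"chr1": np.array([0, 0, 5, 5])}
        df = summarize_peak_coverage(peaks, depth, factor=0.5)
        row = df.iloc[0]
        assert (row.max_depth, row.avg_depth, row.norm_depth) == (5, 2.5, 2.5)

    def test_all_zero_and_missing_chrom(self):
        peaks = PeakSet([Peak(_iv(0, 4), "p1"),
                         Peak(_iv(0, 4, "chrZZ"), "p2")])
        df = summarize_peak_coverage(peaks, {"chr1": np.zeros(10)}, 1.0)
        assert (df[["max_depth", "avg_depth", "norm_depth"]].to_numpy()
                == 0).all()

    def test_logspace_sd_formula(self):
        v = np.array([2.0, 8.0])
        expected = np.exp(np.std(np.log([2.0001, 8.0001]), ddof=1))
        assert logspace_sd(v) == pytest.approx(expected, rel=1e-9)

    def test_replicate_summary_per_culture(self):
        samples = [SampleMeta("s1", "c1", 30), SampleMeta("s2", "c1", 30),
                   SampleMeta("s3", "c2", 50)]
        summary = pd.DataFrame({
            "peak_id": ["p1"] * 3, "sample_id": ["s1", "s2", "s3"],
            "assay": ["ATAC"] * 3, "max_depth": [4, 8, 6.0],
            "avg_depth": [2, 4, 3.0], "norm_depth": [2.0, 8.0, 6.0],
        })
        rep = replicate_summary(summary, samples)
        assert rep["mean_norm"].iloc[0] == pytest.approx(16 / 3)
        c1 = rep[rep["culture_id"] == "c1"]
        assert c1["mean_norm_culture"].iloc[0] == pytest.approx(5.0)
        # single-replicate culture: the replicate's value is the mean
        c2 = rep[rep["culture_id"] == "c2"]
        assert c2["mean_norm_culture"].iloc[0] == pytest.approx(6.0)

    def test_depth_track_piles_intervals(self):
        track = depth_track([_iv(0, 4), _iv(2, 6)], {"chr1": 8})
        assert track["chr1"].tolist() == [1, 1, 2, 2, 1, 1, 0, 0]


class TestFiltering:
    def test_one_bp_blacklist_overlap_removes(self):
        ps = _peaks((100, 200), (300, 400))
        kept = filter_peaks(ps, [_iv(199, 300)])
        assert kept.ids == ["p2"]

    def test_chry_removed_by_default(self):
        ps = PeakSet([Peak(_iv(0, 10, "chrY"), "y"),
                      Peak(_iv(0, 10, "chrX"), "x"),
                      Peak(_iv(0, 10, "chr5"), "a")])
        assert filter_peaks(ps).ids == ["a", "x"]

    def test_empty_blacklist_only_chrom_filter(self):
        ps = _peaks((0, 10))
        assert len(filter_peaks(ps, [])) == 1


class TestBackgroundRegions:
    def test_regions_avoid_peaks_and_are_deterministic(self):
        peaks = _peaks((1000, 2000), (5000, 7000))
        sizes = {"chr1": 50_000}
        r1 = sample_background_regions(sizes, peaks, n=50, length=200, seed=9)
        r2 = sample_background_regions(sizes, peaks, n=50, length=200, seed=9)
        assert [(r.start, r.end) for r in r1] == [(r.start, r.end)
                                                 for r in r2]
        for r in r1:
            assert all(not r.overlaps(p.interval) for p in peaks)
            assert len(r) == 200

    def test_saturated_genome_errors(self):
        peaks = _peaks((0, 10_000))
        with pytest.raises(RuntimeError, match="background regions"):
            sample_background_regions({"chr1": 10_050}, peaks, n=5,
                                      length=200, seed=0,
                                      max_attempts_per_region=10)


def _rep_summary(norm_by_culture, max_by_culture, assay):
    rows = []
    for culture, nv in norm_by_culture.items():
        rows.append({
            "peak_id": "p1", "assay": assay, "culture_id": culture,
            "mean_norm_culture": nv, "mean_max_culture":
                max_by_culture[culture],
        })
    return pd.DataFrame(rows)


class TestPresence:
    def test_atac_threshold_inclusive(self):
        rep = _rep_summary({"c1": 5.0, "c2": 4.999}, {"c1": 9, "c2": 9},
                           "ATAC")
        mat = presence_matrix(rep)["ATAC"]
        assert mat.loc["p1", "c1"] == 1 and mat.loc["p1", "c2"] == 0

    def test_g4_uses_raw_depth(self):
        rep = _rep_summary({"c1": 100.0, "c2": 100.0},
                           {"c1": 1.9, "c2": 2.0}, "G4Q")
        mat = presence_matrix(rep)["G4Q"]
        assert mat.loc["p1", "c1"] == 0 and mat.loc["p1", "c2"] == 1


class TestIntersections:
    def test_two_culture_worked_example(self):
        mat = pd.DataFrame([[1, 1], [1, 0], [0, 1], [1, 1]],
                           columns=["a", "b"],
                           index=[f"p{i}" for i in range(4)])
        out = intersection_counts(mat)
        lookup = dict(zip(out["cultures"], out["count"]))
        assert lookup == {"a&b": 2, "a": 1, "b": 1}

    def test_all_zero_rows_excluded_and_partition_sums(self):
        rng = np.random.default_rng(2)
        for n_cult in (2, 4, 8):
            mat = pd.DataFrame(
                rng.integers(0, 2, size=(60, n_cult)),
                columns=[f"c{i}" for i in range(n_cult)],
                index=[f"p{i}" for i in range(60)],
            )
            out = intersection_counts(mat)
            present = (mat.sum(axis=1) > 0).sum()
            assert out["count"].sum() == present
            # brute force over all non-empty subsets
            for subset in itertools.chain.from_iterable(
                itertools.combinations(mat.columns, k)
                for k in range(1, n_cult + 1)
            ):
                exact = int((
                    (mat[list(subset)] == 1).all(axis=1)
                    & (mat.drop(columns=list(subset)) == 0).all(axis=1)
                ).sum())
                key = "&".join(subset)
                got = out.loc[out["cultures"] == key, "count"]
                assert (int(got.iloc[0]) if len(got) else 0) == exact
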