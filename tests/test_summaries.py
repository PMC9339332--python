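"""Peak calling, transcriptome maps, hotspots, correlations, profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mppqtl.data_model import CovariateMatrix, LODScan, TraitMatrix
from mppqtl.summaries import (
    correlate,
    find_peaks,
    hotspot_counts,
    profile,
    transcriptome_map,
)

from conftest import make_map


def _scan_from_curve(curve: np.ndarray, chrom="1") -> LODScan:
    mm = make_map({chrom: len(curve)}).frame
    return LODScan(
        lod=pd.DataFrame({"tr": curve}, index=mm["marker_id"].tolist()),
        marker_map=mm,
        kind="additive",
    )


def _triangle(n, peak_at, height):
    x = np.arange(n, dtype=float)
    return np.maximum(height - np.abs(x - peak_at) * (height / 10.0), 0.0)


class TestFindPeaks:
    def test_flat_curve_empty(self):
        assert find_peaks(_scan_from_curve(np.zeros(20)), threshold=3.0).empty

    def test_single_triangular_peak(self):
        scan = _scan_from_curve(_triangle(101, 50, 8.0))
        peaks = find_peaks(scan, threshold=7.0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["marker_id"] == scan.marker_map["marker_id"].iloc[50]
        assert peaks.iloc[0]["lod"] == pytest.approx(8.0)

    def test_support_interval_contains_peak(self):
        scan = _scan_from_curve(_triangle(101, 50, 8.0))
        row = find_peaks(scan, threshold=7.0).iloc[0]
        assert row["ci_lo_Mbp"] <= row["pos_Mbp"] <= row["ci_hi_Mbp"]

    def test_peakdrop_separates_two_peaks(self):
        curve = np.concatenate([_triangle(41, 20, 8.0), _triangle(40, 20, 7.5)])
        # valley between the two triangles reaches 0 < 7.5 - 1.8
        scan = _scan_from_curve(curve)
        both = find_peaks(scan, threshold=7.0, peakdrop=1.8)
        assert len(both) == 2
        assert sorted(both["lod"]) == pytest.approx([7.5, 8.0])
        only_higher = find_peaks(scan, threshold=7.0, peakdrop=None)
        assert len(only_higher) == 1
        assert only_higher.iloc[0]["lod"] == pytest.approx(8.0)

    def test_shallow_valley_merges(self):
        # valley at 7.2 drops only 0.3 below the lower peak: merged
        curve = np.concatenate(
            [
                np.linspace(0.0, 8.0, 21),
                np.linspace(8.0, 7.2, 6)[1:],
                np.linspace(7.2, 7.5, 4)[1:],
                np.linspace(7.5, 0.0, 20)[1:],
            ]
        )
        scan = _scan_from_curve(curve)
        peaks = find_peaks(scan, threshold=7.0, peakdrop=1.8)
        assert len(peaks) == 1
        assert peaks.iloc[0]["lod"] == pytest.approx(8.0)

    def test_threshold_monotone(self):
        rng = np.random.default_rng(141)
        curve = np.abs(rng.normal(scale=4.0, size=200))
        scan = _scan_from_curve(curve)
        prev = None
        for threshold in (1.0, 2.0, 4.0, 6.0, 8.0):
            n = len(find_peaks(scan, threshold=threshold, peakdrop=1.5))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            find_peaks(_scan_from_curve(np.zeros(5)), threshold=0.0)


def _peaks_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["trait_id", "chromosome", "marker_id", "pos_Mbp", "lod", "ci_lo_Mbp", "ci_hi_Mbp"],
    )


def _ann(rows):
    return pd.DataFrame(rows, columns=["trait_id", "symbol", "chromosome", "midpoint_Mbp"])


class TestTranscriptomeMap:
    def test_other_chromosome_is_distal(self):
        peaks = _peaks_frame([("g1", "13", "mk", 65.0, 8.0, 60.0, 70.0)])
        ann = _ann([("g1", "Gene1", "11", 70.0)])
        table, skipped = transcriptome_map(peaks, ann)
        assert table.iloc[0]["kind"] == "distal"
        assert skipped == 0

    def test_nearby_same_chromosome_is_local(self):
        peaks = _peaks_frame([("g1", "13", "mk", 65.0, 8.0, 60.0, 70.0)])
        ann = _ann([("g1", "Gene1", "13", 63.0)])
        table, _ = transcriptome_map(peaks, ann)
        assert table.iloc[0]["kind"] == "local"

    def test_far_same_chromosome_is_distal(self):
        peaks = _peaks_frame([("g1", "13", "mk", 65.0, 8.0, 60.0, 70.0)])
        ann = _ann([("g1", "Gene1", "13", 105.0)])
        table, _ = transcriptome_map(peaks, ann)
        assert table.iloc[0]["kind"] == "distal"

    def test_unannotated_skipped_with_count(self):
        peaks = _peaks_frame(
            [("g1", "1", "mk", 5.0, 8.0, 1.0, 9.0), ("g2", "1", "mk2", 6.0, 8.0, 1.0, 9.0)]
        )
        ann = _ann([("g1", "Gene1", "1", 5.0)])
        table, skipped = transcriptome_map(peaks, ann)
        assert len(table) == 1 and skipped == 1

    def test_window_shrink_never_converts_distal_to_local(self):
        rng = np.random.default_rng(143)
        peaks = _peaks_frame(
            [
                (f"g{i}", "1", f"mk{i}", float(rng.uniform(0, 100)), 8.0, 0.0, 100.0)
                for i in range(30)
            ]
        )
        ann = _ann([(f"g{i}", f"G{i}", "1", float(rng.uniform(0, 100))) for i in range(30)])
        wide, _ = transcriptome_map(peaks, ann, window_Mbp=20.0)
        narrow, _ = transcriptome_map(peaks, ann, window_Mbp=5.0)
        for w_kind, n_kind in zip(wide["kind"], narrow["kind"]):
            if w_kind == "distal":
                assert n_kind == "distal"


class TestHotspots:
    def test_stacked_peaks_one_bin(self):
        tmap = _peaks_frame(
            [(f"g{i}", "2", "mk", 13.0, 8.0, 10.0, 16.0) for i in range(10)]
        ).assign(kind="distal")
        counts = hotspot_counts(tmap, window_Mbp=4.0)
        assert counts["n_distal"].max() == 10
        assert (counts["n_distal"] > 0).sum() == 1
        hot = counts.loc[counts["n_distal"].idxmax()]
        assert hot["bin_lo_Mbp"] == 12.0 and hot["bin_hi_Mbp"] == 16.0

    def test_empty_table_all_zero(self):
        counts = hotspot_counts(_peaks_frame([]).assign(kind="distal"), window_Mbp=4.0)
        assert counts.empty or (counts["n_distal"] == 0).all()

    def test_uniform_peaks_within_poisson_band(self):
        rng = np.random.default_rng(145)
        n, length, window = 200, 100.0, 5.0
        tmap = _peaks_frame(
            [
                (f"g{i}", "1", "mk", float(rng.uniform(0, length)), 8.0, 0.0, 100.0)
                for i in range(n)
            ]
        ).assign(kind="distal")
        counts = hotspot_counts(tmap, window_Mbp=window)
        expect = n * window / length  # 10 per bin
        assert counts["n_distal"].sum() == n
        assert counts["n_distal"].max() < expect + 6 * np.sqrt(expect)


class TestCorrelate:
    def _dataset(self, rng, n=50):
        ids = [f"i{k}" for k in range(n)]
        base = rng.standard_normal(n)
        frame = pd.DataFrame(
            {
                "self": base,
                "neg": -base,
                "other": rng.standard_normal(n),
            },
            index=ids,
        )
        return TraitMatrix(frame, name="d"), pd.Series(base, index=ids)

    def test_self_correlation_one(self, rng):
        ds, focus = self._dataset(rng)
        table = correlate(focus, ds).set_index("trait_id")
        assert table.loc["self", "r"] == pytest.approx(1.0)

    def test_negation_minus_one(self, rng):
        ds, focus = self._dataset(rng)
        table = correlate(focus, ds).set_index("trait_id")
        assert table.loc["neg", "r"] == pytest.approx(-1.0)

    def test_intercept_only_equals_plain_pearson(self, rng):
        ds, focus = self._dataset(rng)
        adj = CovariateMatrix.intercept_only(ds.individual_ids)
        table = correlate(focus, ds, adjust=adj).set_index("trait_id")
        plain = float(np.corrcoef(focus, ds.values["other"])[0, 1])
        assert table.loc["other", "r"] == pytest.approx(plain, abs=1e-10)

    def test_sorted_by_absolute_r(self, rng):
        ds, focus = self._dataset(rng)
        table = correlate(focus, ds)
        r = table["r"].abs().to_numpy()
        assert np.all(np.diff(r) <= 1e-12)

    def test_negative_regulator_pair(self):
        # mediator inhibits target: residual correlation stays negative
        rng = np.random.default_rng(147)
        n = 200
        ids = [f"i{k}" for k in range(n)]
        mediator = rng.standard_normal(n)
        target = -0.8 * mediator + 0.4 * rng.standard_normal(n)
        ds = TraitMatrix(pd.DataFrame({"mediator": mediator}, index=ids), name="d")
        table = correlate(pd.Series(target, index=ids), ds).set_index("trait_id")
        assert table.loc["mediator", "r"] < 0

    def test_min_n_respected(self, rng):
        ids = [f"i{k}" for k in range(5)]
        vals = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan, np.nan]}, index=ids)
        ds = TraitMatrix(vals, name="d")
        focus = pd.Series(rng.standard_normal(5), index=ids)
        assert correlate(focus, ds).empty


class TestProfile:
    def test_two_level_medians(self):
        ids = [f"i{k}" for k in range(6)]
        trait = pd.Series([1.0, 2, 3, 4, 5, 6], index=ids)
        factors = pd.DataFrame({"sex": [0, 0, 0, 1, 1, 1]}, index=ids)
        table = profile(trait, factors).set_index("sex")
        assert table.loc[0, "median"] == 2.0
        assert table.loc[1, "median"] == 5.0

    def test_single_level_whole_sample(self):
        ids = ["a", "b", "c"]
        table = profile(pd.Series([1.0, 2, 3], index=ids), None)
        assert len(table) == 1
        assert table.iloc[0]["n"] == 3

    def test_missing_excluded_from_counts(self):
        ids = [f"i{k}" for k in range(4)]
        trait = pd.Series([1.0, np.nan, 3.0, 4.0], index=ids)
        factors = pd.DataFrame({"grp": [0, 0, 1, 1]}, index=ids)
        table = profile(trait, factors).set_index("grp")
        assert table.loc[0, "n"] == 1
        assert table.loc[1, "n"] == 2
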