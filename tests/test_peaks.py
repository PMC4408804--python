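"""Peak model: normalization, dynamic Poisson background, combination, enrichment."""

import numpy as np
import pandas as pd
import pytest

from clippeak.annotation import WindowUniverse
from clippeak.errors import DataError
from clippeak.peaks import (
    call_peaks,
    enrichment_score,
    estimate_background,
    normalize_rnaseq,
)


def exon_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def count_table(universe, clip, rnaseq, unique=None):
    df = universe.to_frame()[["window_id"]].copy()
    df["clip_count"] = clip
    df["rnaseq_count"] = rnaseq
    df["unique_positions"] = unique if unique is not None else clip
    return df


class TestNormalization:
    def test_ratio_arithmetic(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 300, "+", "g")]))
        t = count_table(uni, [400, 600], [10, 1990])
        out, s = normalize_rnaseq(t)
        assert s == pytest.approx(0.5)
        assert out.rnaseq_norm.tolist() == [5.0, 995.0]

    def test_equal_totals_identity(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 300, "+", "g")]))
        t = count_table(uni, [500, 500], [300, 700])
        out, s = normalize_rnaseq(t)
        assert s == 1.0
        assert out.rnaseq_norm.tolist() == [300.0, 700.0]

    def test_zero_rnaseq_total_rejected(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 150, "+", "g")]))
        with pytest.raises(DataError):
            normalize_rnaseq(count_table(uni, [5], [0]))


class TestDynamicBackground:
    def test_uniform_rates_rescaled_by_window_length(self):
        # one gene == one exon == one island; uniform normalized RNA-seq 15
        # per 150-bp window -> per-base rate 0.1 -> lambda 15 per window
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 450, "+", "g")]))
        t = count_table(uni, [15, 15, 15], [15, 15, 15])
        t, _ = normalize_rnaseq(t)
        lam = estimate_background(uni, t, exon_df([("chr1", 0, 450, "+", "g")]))
        assert np.allclose(lam, [15.0, 15.0, 15.0])

    def test_max_rule_uses_hottest_parent(self):
        # two genes share an island; gene A is hot (rate 0.2), gene B silent.
        # B's windows still get the island-wide rate, A's get A's gene rate.
        exons = exon_df([("chr1", 0, 300, "+", "A"), ("chr1", 300, 600, "+", "B")])
        uni = WindowUniverse.from_exons(exons)
        t = count_table(uni, [0, 0, 0, 0], [30, 30, 0, 0])
        t, _ = normalize_rnaseq(t)
        t["rnaseq_norm"] = t["rnaseq_count"] * 1.0  # force s=1 scale for clarity
        lam = estimate_background(uni, t, exons)
        # island rate = 60/600 = 0.1 -> 15/window; gene A rate = 60/300 = 0.2 -> 30
        assert np.allclose(lam, [30.0, 30.0, 15.0, 15.0])

    def test_monotone_in_component_rates(self):
        exons = exon_df([("chr1", 0, 300, "+", "A"), ("chr1", 300, 600, "+", "B")])
        uni = WindowUniverse.from_exons(exons)
        base = count_table(uni, [0] * 4, [10, 10, 10, 10])
        base, _ = normalize_rnaseq(base)
        lam0 = estimate_background(uni, base, exons)
        hot = base.copy()
        hot["rnaseq_norm"] = [40, 10, 10, 10]  # raise gene A only
        lam1 = estimate_background(uni, hot, exons)
        assert np.all(lam1 >= lam0 - 1e-12)

    def test_floor_one_read_per_island(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 300, "+", "g")]))
        t = count_table(uni, [5, 5], [0, 0])
        t["rnaseq_norm"] = 0.0
        lam = estimate_background(uni, t, exon_df([("chr1", 0, 300, "+", "g")]))
        assert np.allclose(lam, [150 / 300, 150 / 300])

    def test_window_without_parent_exon_rejected(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 300, "+", "g")]))
        t = count_table(uni, [5, 5], [1, 1])
        t, _ = normalize_rnaseq(t)
        with pytest.raises(DataError):
            estimate_background(uni, t, exon_df([("chr2", 0, 300, "+", "g")]))


class TestCallPeaks:
    def _fixture(self, n_windows=240, seed=0):
        rng = np.random.default_rng(seed)
        width = 150
        exons = exon_df([("chr1", 0, n_windows * width, "+", "g")])
        uni = WindowUniverse.from_exons(exons)
        r = rng.poisson(20, n_windows)
        x = rng.poisson(10, n_windows)
        uniq = rng.integers(5, 40, n_windows)
        return uni, count_table(uni, x, r, uniq), exons

    def test_combined_p_is_product_and_bounded(self):
        uni, t, exons = self._fixture()
        peaks, fit, info = call_peaks(uni, t, exons, min_fit_windows=100)
        assert np.allclose(peaks.p_combined, peaks.p_poisson * peaks.p_nb)
        assert np.all(peaks.p_combined <= np.minimum(peaks.p_poisson, peaks.p_nb) + 1e-15)

    def test_strict_third_quartile_filter(self):
        uni, t, exons = self._fixture()
        peaks, fit, info = call_peaks(uni, t, exons, min_fit_windows=100)
        q3 = info["unique_positions_q3"]
        assert np.all(peaks.unique_positions > q3)
        held = t[t.unique_positions == int(q3)]
        if len(held):
            assert not set(held.window_id) & set(peaks.window_id)

    def test_extension_and_ranking_deterministic(self):
        uni, t, exons = self._fixture()
        p1, _, _ = call_peaks(uni, t, exons, min_fit_windows=100)
        p2, _, _ = call_peaks(uni, t, exons, min_fit_windows=100)
        pd.testing.assert_frame_equal(p1, p2)
        assert np.all(p1["ext_start"] == np.maximum(p1["start"] - 100, 0))
        assert np.all(p1["ext_end"] == p1["end"] + 100)
        assert list(p1["rank"]) == sorted(p1["rank"])

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(4)
        exons = exon_df([("chr1", 0, 300 * 150, "+", "g")])
        uni = WindowUniverse.from_exons(exons)
        r = rng.poisson(20, 300)
        x = rng.poisson(8, 300)
        x[137] = 8 * 8  # one 8x enriched window
        t = count_table(uni, x, r, np.full(300, 30))
        t.loc[:, "unique_positions"] = rng.integers(10, 30, 300)
        t.loc[137, "unique_positions"] = 35
        peaks, _, _ = call_peaks(uni, t, exons, min_fit_windows=100)
        assert peaks.iloc[0]["window_id"] == uni.window_ids[137]

    def test_nonconvergence_requires_explicit_poisson_only(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 150 * 10, "+", "g")]))
        t = count_table(uni, [1] * 10, [2] * 10, [3] * 10)
        with pytest.raises(DataError):
            call_peaks(uni, t, exon_df([("chr1", 0, 1500, "+", "g")]), min_fit_windows=200)
        peaks, fit, _ = call_peaks(
            uni, t, exon_df([("chr1", 0, 1500, "+", "g")]),
            min_fit_windows=200, allow_poisson_only=True,
        )
        assert fit is None
        assert np.allclose(peaks.p_nb, 1.0)


class TestEnrichmentScore:
    PARTITION = pd.DataFrame(
        [
            ("3UTR", "chr1", 0, 1500, "+", "g1"),
            ("3UTR", "chr1", 5000, 6500, "+", "g2"),
            ("3UTR", "chr1", 9000, 10500, "+", "g3"),
            ("CDS", "chr1", 20000, 30000, "+", "g1"),
        ],
        columns=["region_type", "chrom", "start", "end", "strand", "gene_id"],
    )

    def peaks_at(self, midpoints):
        return pd.DataFrame(
            [("chr1", m - 75, m + 75, "+") for m in midpoints],
            columns=["chrom", "start", "end", "strand"],
        )

    def test_hand_computed_score(self):
        # 10 peaks in 3'UTRs totalling 4500 bp over 3 genes -> 10/1500
        mids = [100, 200, 300, 400, 5100, 5200, 5300, 9100, 9200, 9300]
        out = enrichment_score(self.peaks_at(mids), self.PARTITION)
        utr3 = out[out.region_type == "3UTR"].iloc[0]
        assert utr3.n_peaks == 10
        assert utr3.enrich_score == pytest.approx(10 / (4500 / 3))

    def test_zero_peaks_zero_score(self):
        out = enrichment_score(self.peaks_at([25000]), self.PARTITION)
        assert out[out.region_type == "3UTR"].enrich_score.iloc[0] == 0.0

    def test_doubling_lengths_halves_score(self):
        mids = [100, 5100, 9100]
        out1 = enrichment_score(self.peaks_at(mids), self.PARTITION)
        doubled = self.PARTITION.copy()
        doubled["end"] = doubled["start"] + 2 * (doubled["end"] - doubled["start"])
        out2 = enrichment_score(self.peaks_at(mids), doubled)
        s1 = out1[out1.region_type == "3UTR"].enrich_score.iloc[0]
        s2 = out2[out2.region_type == "3UTR"].enrich_score.iloc[0]
        assert s2 == pytest.approx(s1 / 2)
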