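"""Pooled scan: classification, window tracks, region calling, annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sdscan.poolscan import (
    FEMALE_SPECIFIC,
    LOW_DEPTH,
    MALE_SPECIFIC,
    NONE,
    ScanParams,
    SexRegionCall,
    annotate_region,
    call_sdr,
    classify_site,
    classify_sites,
    coverage_regions,
    manhattan_bins,
    pool_frequencies,
    window_scan,
)
from sdscan.simdata import COUNT_COLUMNS, SimParams, simulate_pools
from sdscan.pipeline import default_demo_config

from conftest import make_sites

P = ScanParams()


def vec(A=0, C=0, G=0, T=0, N=0, dele=0):
    return np.array([A, C, G, T, N, dele])


# ---------------------------------------------------------------------------
# frequencies & classification


class TestPoolFrequencies:
    def test_even_split_and_fixed(self):
        maj, freq, second, depth = pool_frequencies(vec(A=15, T=15), P)
        assert freq == 0.5 and second == 0.5 and depth == 30
        maj, freq, second, depth = pool_frequencies(vec(A=30), P)
        assert freq == 1.0 and second == 0.0

    def test_one_stray_read_breaks_homozygosity(self):
        _, freq, _, _ = pool_frequencies(vec(A=19, T=1), P)
        assert freq == pytest.approx(0.95)
        assert freq < P.hom_min_major

    def test_n_and_del_excluded_from_denominator(self):
        _, freq, _, depth = pool_frequencies(vec(A=20, N=10, dele=10), P)
        assert freq == 1.0 and depth == 20

    def test_low_depth_flagged(self):
        assert pool_frequencies(vec(A=6), ScanParams(min_depth=10)) is None


class TestClassifySite:
    def test_ideal_xy_site_is_male_specific(self):
        assert classify_site(vec(A=20, G=20), vec(A=40), P) == MALE_SPECIFIC

    def test_monomorphic_site_is_none(self):
        assert classify_site(vec(A=40), vec(A=40), P) == NONE

    def test_symmetric_site_is_female_specific(self):
        assert classify_site(vec(A=40), vec(A=20, G=20), P) == FEMALE_SPECIFIC

    def test_low_depth_excluded(self):
        assert classify_site(vec(A=20, G=20), vec(A=6), P) == LOW_DEPTH

    def test_exhaustive_grid_matches_brute_force(self):
        """All count compositions at depth 12 per pool (A/G biallelic, every
        A/C/G/T split for the female) classify identically to a direct
        re-evaluation of the frequency rules."""
        params = ScanParams(min_depth=10)

        def oracle(cm, cf):
            def stats(c):
                acgt = sorted(c[:4], reverse=True)
                tot = sum(acgt)
                if tot < params.min_depth:
                    return None
                return acgt[0] / tot, acgt[1] / tot

            sm, sf = stats(cm), stats(cf)
            if sm is None or sf is None:
                return LOW_DEPTH
            het_m = 0.5 - params.het_delta <= sm[1] <= 0.5 + params.het_delta
            het_f = 0.5 - params.het_delta <= sf[1] <= 0.5 + params.het_delta
            if het_m and sf[0] >= params.hom_min_major:
                return MALE_SPECIFIC
            if het_f and sm[0] >= params.hom_min_major:
                return FEMALE_SPECIFIC
            return NONE

        comps = [
            (a, c, g, 12 - a - c - g, 0, 0)
            for a in range(13)
            for c in range(13 - a)
            for g in range(13 - a - c)
        ]
        male_comps = female_comps = comps  # 455 x 455 count compositions
        records = []
        expected = []
        pos = 0
        for cm, cf in itertools.product(male_comps, female_comps):
            records.append(("chr1", pos, cm, cf))
            expected.append(oracle(cm, cf))
            pos += 1
        sites = make_sites(records)
        got = classify_sites(sites, params)
        assert got.tolist() == expected

    def test_label_swap_symmetry(self, demo_sites):
        """Exchanging the pool columns exchanges male/female calls exactly."""
        swapped = demo_sites.copy()
        ren = {f"m_{b}": f"f_{b}" for b in ("A", "C", "G", "T", "N", "del")}
        ren.update({v: k for k, v in ren.items()})
        swapped = swapped.rename(columns=ren)[demo_sites.columns]
        a = classify_sites(demo_sites, P)
        b = classify_sites(swapped, P)
        flip = {MALE_SPECIFIC: FEMALE_SPECIFIC, FEMALE_SPECIFIC: MALE_SPECIFIC}
        assert b.tolist() == [flip.get(x, x) for x in a]

    def test_threshold_monotonicity(self, demo_sites):
        """Raising min_depth or hom_min_major never increases the number of
        sex-specific calls."""
        def n_specific(params):
            c = classify_sites(demo_sites, params)
            return int(((c == MALE_SPECIFIC) | (c == FEMALE_SPECIFIC)).sum())

        for lo, hi in [(10, 20), (20, 30)]:
            assert n_specific(ScanParams(min_depth=hi)) <= n_specific(ScanParams(min_depth=lo))
        for lo, hi in [(0.9, 0.95), (0.95, 0.99)]:
            assert n_specific(ScanParams(hom_min_major=hi)) <= n_specific(
                ScanParams(hom_min_major=lo)
            )


# ---------------------------------------------------------------------------
# windows & bins


def sites_with_one_snv(pos, chrom_len=20_000):
    return make_sites([(c, p, m, f) for c, p, m, f in [
        ("chr1", pos, (20, 0, 20, 0, 0, 0), (40, 0, 0, 0, 0, 0))
    ]]), {"chr1": chrom_len}


class TestWindowScan:
    def test_single_snv_hits_expected_sliding_windows(self):
        sites, sizes = sites_with_one_snv(4500)
        track = window_scan(sites, P, chrom_sizes=sizes)
        hot = track[track.male_specific_snvs > 0]["start"].tolist()
        assert hot == [0, 1000, 2000, 3000, 4000]

    def test_empty_chromosome_gives_zero_track(self):
        sites, _ = sites_with_one_snv(100)
        track = window_scan(sites, P, chrom_sizes={"chr1": 5000, "chr2": 5000})
        chr2 = track[track.chrom == "chr2"]
        assert len(chr2) == 5 and (chr2.male_specific_snvs == 0).all()
        assert chr2.depth_m.isna().all()

    def test_unsorted_input_rejected_with_position(self):
        sites = make_sites([
            ("chr1", 500, (40, 0, 0, 0, 0, 0), (40, 0, 0, 0, 0, 0)),
            ("chr1", 100, (40, 0, 0, 0, 0, 0), (40, 0, 0, 0, 0, 0)),
        ])
        with pytest.raises(ValueError, match="chr1:100"):
            window_scan(sites, P)

    def test_matches_interval_arithmetic_oracle(self, rng):
        """Sliding-window counts equal a brute-force per-window recount on a
        random classified site set."""
        n = 300
        pos = np.sort(rng.choice(30_000, size=n, replace=False))
        is_snv = rng.random(n) < 0.3
        records = []
        for p, s in zip(pos, is_snv):
            m = (20, 0, 20, 0, 0, 0) if s else (40, 0, 0, 0, 0, 0)
            records.append(("chr1", int(p), m, (40, 0, 0, 0, 0, 0)))
        sites = make_sites(records)
        params = ScanParams(window_size=5000, output_resolution=1000)
        track = window_scan(sites, params, chrom_sizes={"chr1": 30_000})
        snv_pos = pos[is_snv]
        for _, row in track.iterrows():
            s = row["start"]
            expect = int(((snv_pos >= s) & (snv_pos < s + 5000)).sum())
            assert row["male_specific_snvs"] == expect

    def test_sliding_conservation(self, demo_sites):
        """Each interior SNV is counted window_size/output_resolution times."""
        classes = classify_sites(demo_sites, P)
        track = window_scan(demo_sites, P, classes=classes)
        total_windowed = track.male_specific_snvs.sum()
        n_snv = int((classes == MALE_SPECIFIC).sum())
        ratio = P.window_size // P.output_resolution
        # edge SNVs (< window_size from a chromosome start) appear fewer times
        assert n_snv * ratio * 0.99 <= total_windowed <= n_snv * ratio


class TestManhattanBins:
    def test_bin_edges(self):
        records = [("chr1", p, (20, 0, 20, 0, 0, 0), (40, 0, 0, 0, 0, 0))
                   for p in (10, 49_999, 50_000)]
        bins = manhattan_bins(make_sites(records), P, chrom_sizes={"chr1": 100_000})
        assert bins.male_specific_snvs.tolist() == [2, 1]

    def test_no_snvs_zero_bins(self):
        sites = make_sites([("chr1", 5, (40, 0, 0, 0, 0, 0), (40, 0, 0, 0, 0, 0))])
        bins = manhattan_bins(sites, P, chrom_sizes={"chr1": 60_000})
        assert (bins.male_specific_snvs == 0).all()

    def test_bin_sums_equal_classified_totals(self, demo_sites):
        classes = classify_sites(demo_sites, P)
        bins = manhattan_bins(demo_sites, P, classes=classes)
        assert bins.male_specific_snvs.sum() == (classes == MALE_SPECIFIC).sum()
        assert bins.female_specific_snvs.sum() == (classes == FEMALE_SPECIFIC).sum()


# ---------------------------------------------------------------------------
# region calling


def brute_force_runs(counts, min_count, min_windows, max_gap):
    """Independent run scanner: all maximal index sets of qualifying windows
    whose consecutive gaps stay within max_gap."""
    qual = [i for i, c in enumerate(counts) if c >= min_count]
    runs, cur = [], []
    for i in qual:
        if cur and i - cur[-1] - 1 > max_gap:
            runs.append(cur)
            cur = []
        cur.append(i)
    if cur:
        runs.append(cur)
    return [r for r in runs if len(r) >= min_windows]


def track_from_counts(counts, res=1000, win=5000):
    t = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(counts)) * res,
            "male_specific_snvs": counts,
            "female_specific_snvs": 0,
            "n_sites": 1,
            "depth_m": 40.0,
            "depth_f": 40.0,
        }
    )
    t.attrs["window_size"] = win
    return t


class TestCallSdr:
    def test_contiguous_run_yields_100kb_region(self):
        """A 96-step qualifying run at 1-kb steps with 5-kb windows spans
        exactly 100 kb."""
        counts = np.zeros(300, dtype=int)
        counts[100:196] = 6
        calls = call_sdr(track_from_counts(counts), min_count=5, min_windows=10, max_gap=2)
        assert len(calls) == 1
        assert calls[0].length == 100_000
        assert calls[0].n_windows == 96

    def test_all_zero_track_empty(self):
        assert call_sdr(track_from_counts(np.zeros(50, dtype=int))) == []

    def test_min_count_validated(self):
        with pytest.raises(ValueError):
            call_sdr(track_from_counts(np.ones(5, dtype=int)), min_count=0)

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(200):
            counts = rng.poisson(1.5, size=rng.integers(10, 80))
            mc = int(rng.integers(1, 4))
            mw = int(rng.integers(1, 6))
            gap = int(rng.integers(0, 4))
            calls = call_sdr(track_from_counts(counts), min_count=mc,
                             min_windows=mw, max_gap=gap)
            expected = brute_force_runs(counts, mc, mw, gap)
            got = sorted((c.start // 1000, (c.end - 5000) // 1000) for c in calls)
            want = sorted((r[0], r[-1]) for r in expected)
            assert got == want

    def test_recovers_true_sdr_in_simulation(self, demo_sites):
        track = window_scan(demo_sites, P)
        calls = call_sdr(track)
        assert calls and calls[0].overlaps("chr2", 900_000, 1_000_000)
        # brute-force max: the hottest window lies inside the true SDR
        hottest = track.loc[track.male_specific_snvs.idxmax()]
        assert hottest.chrom == "chr2" and 895_000 <= hottest.start < 1_000_000


class TestCoverageRegions:
    def test_recovers_y_insertion(self, demo_sites):
        track = window_scan(demo_sites, P)
        calls = coverage_regions(track)
        assert len(calls) == 1
        c = calls[0]
        assert c.overlaps("chr3", 1_200_000, 1_253_000)
        assert c.mean_depth_m == pytest.approx(20, abs=2)
        assert c.mean_depth_f <= 1.0

    def test_equal_depth_genome_no_calls(self):
        track = track_from_counts(np.zeros(100, dtype=int))
        assert coverage_regions(track) == []

    def test_zero_median_rejected(self):
        track = track_from_counts(np.zeros(10, dtype=int))
        track["depth_m"] = 0.0
        with pytest.raises(ValueError):
            coverage_regions(track)

    def test_matches_brute_force_flagging(self, rng):
        """Calls equal an independent window-flag + run-merge re-evaluation
        across a grid of thresholds."""
        for f_max in (0.05, 0.1, 0.3):
            for lo, hi in ((0.35, 0.65), (0.2, 0.8)):
                dm = rng.uniform(0, 60, size=120)
                df = rng.uniform(0, 60, size=120)
                track = track_from_counts(np.zeros(120, dtype=int))
                track["depth_m"] = dm
                track["depth_f"] = df
                med_m, med_f = np.median(dm), np.median(df)
                flags = (df <= f_max * med_f) & (dm >= lo * med_m) & (dm <= hi * med_m)
                expected = brute_force_runs(flags.astype(int), 1, 3, 2)
                calls = coverage_regions(track, f_max_frac=f_max, m_band=(lo, hi),
                                         min_windows=3, max_gap=2)
                got = sorted((c.start // 1000, (c.end - 5000) // 1000) for c in calls)
                want = sorted((r[0], r[-1]) for r in expected)
                assert got == want


class TestAnnotateRegion:
    def region(self, chrom="chr2", start=900_000, end=1_000_000):
        return SexRegionCall(chrom, start, end, 10, 5.0, "allelic_sdr")

    def test_six_sdr_genes_recovered(self, demo_layout):
        names = annotate_region(self.region(), demo_layout.genes)
        assert names == ["c18h1orf198", "cx32.2", "gja13.2", "cx32.7", "hsdl1", "tbc1d32"]

    def test_region_outside_genes_empty(self, demo_layout):
        assert annotate_region(self.region("chr1"), demo_layout.genes) == []

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            genes = [("chr1", int(s), int(s + rng.integers(1, 5000)), "+", f"g{i}")
                     for i, s in enumerate(rng.integers(0, 100_000, size=30))]
            start = int(rng.integers(0, 90_000))
            end = start + int(rng.integers(1, 20_000))
            region = SexRegionCall("chr1", start, end, 1, 1.0, "allelic_sdr")
            got = annotate_region(region, genes)
            want = [g[4] for g in sorted(genes, key=lambda g: g[1])
                    if g[1] < end and start < g[2]]
            assert got == want
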