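import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fascimap import bsa_scan, segsim
from fascimap.bsa_scan import (
    CandidateRegion,
    ScanPoint,
    Window,
    call_regions,
    compute_scan,
    delta_snp_index,
    euclidean_distance,
    filter_variants,
    null_threshold_delta,
    null_threshold_ed,
    sliding_window,
    snp_index,
)


class TestFilterVariants:
    def test_hand_counted_fixture(self, toy_records):
        kept, drops = filter_variants(toy_records, min_depth_per_pool=10)
        assert len(kept) == 4
        assert drops == {"parent_het": 1, "parent_missing": 0, "low_depth": 1}

    def test_no_filters_is_identity(self, toy_records):
        hom = [r for r in toy_records if r.parent_gt == "hom_alt"]
        kept, _ = filter_variants(hom, min_depth_per_pool=0)
        assert kept == hom

    def test_all_parent_missing_gives_empty(self, toy_records):
        for r in toy_records:
            r.parent_gt = "missing"
        kept, drops = filter_variants(toy_records)
        assert kept == []
        assert drops["parent_missing"] == len(toy_records)


class TestPerSiteStatistics:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(10, 30, 0.75), (20, 0, 0.0), (0, 44, 1.0)]
    )
    def test_snp_index(self, ref, alt, expected):
        assert snp_index(ref, alt) == pytest.approx(expected)

    def test_snp_index_zero_depth_fatal(self):
        with pytest.raises(ValueError):
            snp_index(0, 0)

    @pytest.mark.parametrize(
        "mut,wt,expected", [(1.0, 1 / 3, 2 / 3), (0.4, 0.4, 0.0), (0.0, 1.0, -1.0)]
    )
    def test_delta_sign_convention(self, mut, wt, expected):
        assert delta_snp_index(mut, wt) == pytest.approx(expected)

    def test_ed_recessive_design_value(self):
        # mutant pool fixed for alt, normal pool at the 1/3 recessive expectation
        ed, ed_k = euclidean_distance([0, 1], [2 / 3, 1 / 3], power=5)
        assert ed == pytest.approx(np.sqrt(8 / 9), abs=1e-12)
        assert ed_k == pytest.approx(np.sqrt(8 / 9) ** 5)

    def test_ed_identical_vectors_zero(self):
        assert euclidean_distance([0.3, 0.7], [0.3, 0.7])[0] == 0.0

    def test_ed_biallelic_maximum(self):
        assert euclidean_distance([0, 1], [1, 0])[0] == pytest.approx(np.sqrt(2))

    def test_ed_requires_normalized_frequencies(self):
        with pytest.raises(ValueError):
            euclidean_distance([0.5, 0.4], [0.5, 0.5])

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_ed_equals_sqrt2_abs_delta_on_biallelic_sites(self, im, iw):
        """Oracle equivalence: ED = sqrt(2)|Δ| over {ref, alt} frequencies."""
        ed, _ = euclidean_distance([1 - im, im], [1 - iw, iw])
        assert ed == pytest.approx(np.sqrt(2) * abs(im - iw), abs=1e-9)


def _point(pos, delta, chrom="chr4", ed_k=0.0):
    return ScanPoint(
        chrom=chrom, pos=pos, snp_index_mut=0.5, snp_index_wt=0.5 - delta,
        delta=delta, ed=np.sqrt(2) * abs(delta), ed_k=ed_k,
    )


class TestSlidingWindow:
    def test_single_window_mean(self):
        pts = [_point(100, 0.1), _point(200, 0.2), _point(300, 0.6)]
        (w,) = sliding_window(pts, window_bp=1000, step_bp=1000, min_sites=3)
        assert w.n_sites == 3
        assert w.mean_delta == pytest.approx(0.3)

    def test_constant_delta_everywhere(self):
        pts = [_point(p, 0.25) for p in range(1000, 50_000, 1000)]
        for w in sliding_window(pts, 10_000, 5_000, min_sites=1):
            assert w.mean_delta == pytest.approx(0.25)

    def test_windows_match_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        pts = [
            _point(int(p), float(d), ed_k=float(e))
            for p, d, e in zip(
                sorted(rng.integers(1, 10_000_000, 200)),
                rng.uniform(-1, 1, 200),
                rng.uniform(0, 1, 200),
            )
        ]
        window_bp, step_bp, min_sites = 1_000_000, 500_000, 2
        windows = sliding_window(pts, window_bp, step_bp, min_sites)
        # brute force: enumerate every window start and filter per point
        expected = []
        start = 1
        last = max(p.pos for p in pts)
        while start <= last:
            inside = [p for p in pts if start <= p.pos <= start + window_bp - 1]
            if len(inside) >= min_sites:
                expected.append(
                    (start, np.mean([p.delta for p in inside]),
                     np.mean([p.ed_k for p in inside]), len(inside))
                )
            start += step_bp
        assert len(windows) == len(expected)
        for w, (s, md, me, n) in zip(windows, expected):
            assert w.start == s and w.n_sites == n
            assert w.mean_delta == pytest.approx(md)
            assert w.mean_ed_k == pytest.approx(me)

    def test_nonpositive_window_fatal(self):
        with pytest.raises(ValueError):
            sliding_window([], window_bp=0, step_bp=1)


class TestNullThresholds:
    def test_alpha_one_gives_zero_threshold(self):
        thr = null_threshold_delta([50], bulk_size=50, n_sim=1000, alpha=1.0, seed=0)
        assert thr[50] == pytest.approx(0.0)

    def test_threshold_decreases_with_depth_and_bulk(self):
        thr = null_threshold_delta([10, 50, 200], bulk_size=50, n_sim=20_000, seed=0)
        assert thr[10] > thr[50] > thr[200]
        thr_big_bulk = null_threshold_delta([50], bulk_size=500, n_sim=20_000, seed=0)
        assert thr_big_bulk[50] < thr[50]

    def test_threshold_stable_across_seeds(self):
        a = null_threshold_delta([50], 50, n_sim=10_000, alpha=0.05, seed=1)[50]
        b = null_threshold_delta([50], 50, n_sim=10_000, alpha=0.05, seed=2)[50]
        assert 0 < a < 1
        assert abs(a - b) < 0.01

    def test_ed_cutoff_constant_input(self):
        assert null_threshold_ed([0.5] * 200) == pytest.approx(0.5)

    def test_ed_cutoff_needs_enough_points(self):
        with pytest.raises(ValueError):
            null_threshold_ed([0.5] * 10)

    def test_window_calibration_reduces_to_per_site_at_one(self):
        a = null_threshold_delta([50], 50, n_sim=10_000, seed=4)[50]
        b = null_threshold_delta([50], 50, n_sim=10_000, seed=4, n_sites_per_window=1)[50]
        assert a == b

    def test_null_only_windows_rarely_exceed_ed_cutoff(self):
        """On bulks drawn blind to phenotype, <1% of windows pass the ED rule."""
        n_exceed = n_tot = 0
        for seed in range(30):
            design = segsim.CrossDesign(
                chrom_lengths_bp={"chr1": 20_000_000}, causal_chrom="chr1",
                causal_pos=10_000_000, n_f2=200, seed=seed,
            )
            rng = np.random.default_rng(seed + 70)
            g = segsim.simulate_f2(design)
            perm = rng.permutation(design.n_f2)
            records = segsim.pool_reads(g, perm[:50], perm[50:100], design)
            points = compute_scan(records)
            cutoff = null_threshold_ed([p.ed_k for p in points])
            windows = sliding_window(points)
            n_exceed += sum(w.mean_ed_k > cutoff for w in windows)
            n_tot += len(windows)
        assert n_exceed / n_tot < 0.01


def _window(start, end, sig=True, chrom="chr4"):
    w = Window(chrom=chrom, start=start, end=end, n_sites=10,
               mean_delta=0.5, mean_ed_k=0.5)
    w.significant_delta = w.significant_ed = sig
    return w


class TestCallRegions:
    def test_region_width_matches_mapping_interval(self):
        region = CandidateRegion(chrom="chr4", start=4_680_000, end=11_260_000)
        assert region.width_mb == 6.58

    def test_single_significant_window(self):
        regs = call_regions([_window(1, 100)], "delta")
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (1, 100)

    def test_gap_of_three_windows_splits(self):
        ws = (
            [_window(1 + i * 100, 100 + i * 100) for i in range(2)]
            + [_window(201 + i * 100, 300 + i * 100, sig=False) for i in range(3)]
            + [_window(501 + i * 100, 600 + i * 100) for i in range(2)]
        )
        regs = call_regions(ws, "delta")
        assert len(regs) == 2

    def test_gap_of_one_window_bridged(self):
        ws = [_window(1, 100), _window(101, 200, sig=False), _window(201, 300)]
        regs = call_regions(ws, "delta")
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (1, 300)

    def test_no_significant_windows_empty(self):
        assert call_regions([_window(1, 100, sig=False)], "delta") == []

    def test_regions_sorted_non_overlapping(self):
        rng = np.random.default_rng(1)
        ws = [
            _window(1 + i * 500, 1000 + i * 500, sig=bool(rng.random() < 0.4))
            for i in range(100)
        ]
        regs = call_regions(ws, "delta")
        for a, b in zip(regs, regs[1:]):
            assert a.end < b.start


class TestEndToEnd:
    def test_called_region_contains_causal_locus(self):
        """A study-scale replicate localizes the planted recessive locus."""
        design = segsim.CrossDesign(seed=11)
        records, _ = segsim.simulate_bsa_experiment(design)
        _, windows, regions = bsa_scan.scan_pipeline(
            records, bulk_size=design.bulk_size, seed=11
        )
        assert any(r.contains(design.causal_chrom, design.causal_pos) for r in regions)

    def test_causal_windows_exceed_ed_cutoff(self):
        design = segsim.CrossDesign(seed=13)
        records, _ = segsim.simulate_bsa_experiment(design)
        kept, _ = filter_variants(records)
        points = compute_scan(kept)
        cutoff = null_threshold_ed([p.ed_k for p in points])
        windows = sliding_window(points)
        causal = [
            w for w in windows
            if w.chrom == design.causal_chrom
            and w.start <= design.causal_pos <= w.end
        ]
        assert causal
        assert max(w.mean_ed_k for w in causal) > cutoff

    def test_null_calibration_false_positive_rate(self):
        """Per-window FPR for Δ at alpha=0.05 stays near nominal on null bulks."""
        n_sig = n_tot = 0
        lengths = {"chr1": 20_000_000}
        for seed in range(100):
            design = segsim.CrossDesign(
                chrom_lengths_bp=lengths, causal_chrom="chr1",
                causal_pos=10_000_000, n_f2=200, seed=seed,
            )
            rng = np.random.default_rng(seed + 7)
            g = segsim.simulate_f2(design)
            # null bulks: random individuals, ignoring phenotype
            perm = rng.permutation(design.n_f2)
            records = segsim.pool_reads(g, perm[:50], perm[50:100], design)
            kept, _ = filter_variants(records)
            points = compute_scan(kept)
            windows = sliding_window(points)
            depths = [
                (r.depth_mut_ref + r.depth_mut_alt + r.depth_wt_ref + r.depth_wt_alt) // 2
                for r in kept
            ]
            md = int(np.median(depths))
            med_sites = int(np.median([w.n_sites for w in windows]))
            thr = null_threshold_delta(
                [md], design.bulk_size, seed=seed, n_sites_per_window=med_sites
            )[md]
            sig = [abs(w.mean_delta) >= thr for w in windows]
            n_sig += sum(sig)
            n_tot += len(sig)
        assert 0.02 <= n_sig / n_tot <= 0.08
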