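"""K-S periodicity scan: geometric null, window tests, region calling."""

import numpy as np
import pytest

from aroscan import (
    BernoulliStickers,
    FixedStickers,
    Interval,
    ProteinRecord,
    SyntheticConfig,
    annotate_regions,
    call_regions,
    gen_cohort,
    geometric_cdf,
    ks_window_test,
    overlaps,
    scan_protein,
)
from aroscan.ksscan import KSWindow

from oracles import oracle_ks, oracle_regions


class TestGeometricCdf:
    def test_closed_form_values(self):
        assert geometric_cdf(0.5, 0) == pytest.approx(0.5)
        assert geometric_cdf(0.5, 1) == pytest.approx(0.75)

    def test_mean_is_one_minus_p_over_p(self, rng):
        """Expected spacer from the CDF matches (1-p)/p, e.g. 9.0 at p=0.1."""
        p = 0.1
        s = np.arange(0, 5000)
        pmf = np.diff(np.concatenate([[0.0], geometric_cdf(p, s)]))
        assert float((s * pmf).sum()) == pytest.approx((1 - p) / p, abs=1e-3)

    def test_tends_to_one(self):
        assert geometric_cdf(0.01, 10_000) > 1 - 1e-6

    def test_invalid_p_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                geometric_cdf(bad, 3)


class TestKsWindowTest:
    def test_identical_spacers_match_direct_recount(self):
        D, p = ks_window_test([9] * 10, 0.10)
        D_ref, p_ref = oracle_ks([9] * 10, 0.10)
        assert D == pytest.approx(D_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_oracle_on_random_windows(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 15))
            spacers = rng.geometric(0.1, size=n) - 1
            p_aro = float(rng.uniform(0.02, 0.3))
            D, p = ks_window_test(spacers.tolist(), p_aro)
            D_ref, p_ref = oracle_ks(spacers.tolist(), p_aro)
            assert D == pytest.approx(D_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_conservative_under_geometric_null(self):
        """On truly geometric spacers the discrete K-S with the continuous
        tail is conservative: < 0.05 P values arise in at most 7% of windows."""
        rng = np.random.default_rng(77)
        p_aro = 0.1
        hits = 0
        n_windows = 1000
        for _ in range(n_windows):
            spacers = (rng.geometric(p_aro, size=8) - 1).tolist()
            _, p = ks_window_test(spacers, p_aro)
            if p < 0.05:
                hits += 1
        assert hits / n_windows <= 0.07

    def test_single_spacer_skipped(self):
        D, p = ks_window_test([5], 0.1)
        assert p is None and np.isnan(D)

    def test_degenerate_p_aro_skipped(self):
        assert ks_window_test([5, 5, 5], 1.0)[1] is None


class TestScanProtein:
    def test_window_counts(self):
        assert len(scan_protein(ProteinRecord("p", "G" * 100))) == 1
        assert len(scan_protein(ProteinRecord("p", "G" * 102))) == 3

    def test_short_protein_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_protein(ProteinRecord("p", "G" * 50)) == []
        assert "no windows tested" in caplog.text

    def test_spacers_require_both_flanking_stickers_inside(self):
        # stickers at 50 and 150: the window [1,100] sees one sticker, no spacer
        seq = ["G"] * 200
        seq[49] = "F"
        seq[149] = "Y"
        windows = scan_protein(ProteinRecord("p", "".join(seq)))
        w1 = windows[0]
        assert (w1.n_aro, w1.n_spacers) == (1, 0)
        # window [51,150] contains only the second sticker
        w51 = windows[50]
        assert (w51.n_aro, w51.n_spacers) == (1, 0)

    def test_min_p_window_localises_periodic_segment(self):
        """Stickers every 10 residues within [101,300] of a 400-aa protein:
        the argmin-P window starts inside [81,301]."""
        rng = np.random.default_rng(3)
        seq = np.array(list("".join(rng.choice(list("GSPQNA"), 400))))
        for pos in range(100, 300, 10):
            seq[pos] = "F"
        windows = scan_protein(ProteinRecord("p", "".join(seq)))
        tested = [w for w in windows if w.p_value is not None]
        best = min(tested, key=lambda w: w.p_value)
        assert 81 <= best.start <= 301


def mkwin(start, p, n_aro=6, pid="p"):
    return KSWindow(protein_id=pid, start=start, window_len=100, n_aro=n_aro,
                    n_spacers=max(0, n_aro - 1), p_aro_window=n_aro / 100,
                    ks_D=0.5, p_value=p)


class TestCallRegions:
    def test_identical_ps_yield_no_region(self):
        windows = [mkwin(s, 0.2) for s in range(1, 20)]
        assert call_regions(windows) == []

    def test_single_subthreshold_window_span_rule(self):
        windows = [mkwin(s, 0.5) for s in range(1, 101)]
        windows[50] = mkwin(51, 1e-4)
        regions = call_regions(windows)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.length) == (51, 150, 100)
        assert r.min_p == 1e-4 and r.best_window_start == 51
        assert r.significant  # n_aro_best 6 >= 5 and min_p <= 0.01

    def test_aromatic_count_filter_blocks_significance(self):
        windows = [mkwin(s, 0.5) for s in range(1, 101)]
        windows[50] = mkwin(51, 1e-4, n_aro=4)
        (r,) = call_regions(windows)
        assert not r.significant and r.min_p == 1e-4

    def test_untested_windows_break_runs(self):
        # unit-length windows so the two broken runs cannot span-merge
        def w(start, p):
            return KSWindow("p", start, 1, 6, 5, 0.06, 0.5, p)

        untested = KSWindow("p", 2, 1, 1, 0, 0.01, float("nan"), None)
        windows = [w(1, 1e-4), untested, w(3, 1e-4)] + [w(s, 0.9) for s in range(4, 40)]
        regions = call_regions(windows)
        assert len(regions) == 2
        assert [(r.start, r.end) for r in regions] == [(1, 1), (3, 3)]

    def test_overlapping_spans_merge_into_one_region(self):
        windows = [mkwin(s, 0.5) for s in range(1, 201)]
        windows[0] = mkwin(1, 1e-4)    # run A: span [1,100]
        windows[50] = mkwin(51, 1e-3)  # run B: span [51,150], overlaps A
        (r,) = call_regions(windows)
        assert (r.start, r.end) == (1, 150)
        assert r.min_p == 1e-4 and r.best_window_start == 1

    def test_regions_disjoint_ordered_and_filters_recount(self, small_cohort):
        for rec in small_cohort.records[:30]:
            regions = call_regions(scan_protein(rec))
            for a, b in zip(regions, regions[1:]):
                assert a.end < b.start
            for r in regions:
                if r.significant:
                    assert r.min_p <= 0.01 and r.n_aro_best >= 5

    def test_matches_independent_reimplementation(self, small_cohort):
        """Region tables equal the literal reimplementation on a labelled
        synthetic proteome, and every fixed-spacing protein the oracle
        detects is also called by the implementation."""
        for rec in small_cohort.records:
            windows = scan_protein(rec)
            got = call_regions(windows)
            ref = oracle_regions(
                [(w.start, w.p_value, w.n_aro) for w in windows], window_len=100
            )
            assert len(got) == len(ref)
            for g, r in zip(got, ref):
                assert (g.start, g.end, g.best_window_start, g.n_aro_best,
                        g.significant) == (
                    r["start"], r["end"], r["best_window_start"], r["n_aro_best"],
                    r["significant"],
                )
                assert g.min_p == pytest.approx(r["min_p"], abs=1e-15)

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            call_regions([mkwin(1, 0.5, pid="a"), mkwin(2, 0.5, pid="b")])


class TestAnnotateRegions:
    def _region(self):
        windows = [mkwin(s, 0.5) for s in range(1, 101)]
        windows[50] = mkwin(51, 1e-4)
        return call_regions(windows)

    def test_one_residue_idr_overlap(self):
        (r,) = annotate_regions(self._region(), [Interval("p", 150, 300)])
        assert r.overlaps_idr and not r.overlaps_domain

    def test_no_annotation_both_false(self):
        (r,) = annotate_regions(self._region())
        assert not r.overlaps_idr and not r.overlaps_domain

    def test_flags_equal_pairwise_overlap_calls(self, small_cohort):
        regions = []
        for rec in small_cohort.records[:20]:
            regions.extend(call_regions(scan_protein(rec)))
        annotated = annotate_regions(regions, small_cohort.idr_intervals)
        by_id = {}
        for iv in small_cohort.idr_intervals:
            by_id.setdefault(iv.protein_id, []).append(iv)
        for r in annotated:
            expected = any(
                overlaps(r.interval, iv) for iv in by_id.get(r.protein_id, [])
            )
            assert r.overlaps_idr == expected


class TestCalibrationAndPower:
    def test_null_false_positive_rate_at_most_five_percent(self):
        """Per-protein significant-region rate on geometric-null proteomes."""
        cohort = gen_cohort(
            [SyntheticConfig(n_proteins=300, length=400,
                             model=BernoulliStickers(p=0.08), id_prefix="n")],
            seed=7,
        )
        n_sig = sum(
            1 for rec in cohort.records
            if any(r.significant for r in call_regions(scan_protein(rec)))
        )
        assert n_sig / 300 <= 0.05

    def test_power_on_fixed_spacing_at_least_ninety_percent(self):
        cohort = gen_cohort(
            [SyntheticConfig(n_proteins=50, length=400,
                             model=FixedStickers(k=10, n_stickers=25),
                             id_prefix="p")],
            seed=7,
        )
        hits = sum(
            1 for rec in cohort.records
            if any(r.significant for r in call_regions(scan_protein(rec)))
        )
        assert hits / 50 >= 0.90
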