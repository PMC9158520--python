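"""Gap-aware diversity estimator, window scan and hotspot merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastome.diversity import (WindowStat, classify_site, merge_hotspots,
                                name_region, sliding_windows, window_pi)
from plastome.io_formats import AlignmentMatrix, AnnotatedGenome, Feature
from plastome.synthetic import HotspotSpec, simulate_alignment

from conftest import brute_window, random_gapped_alignment


def aln_of(*rows: str) -> AlignmentMatrix:
    return AlignmentMatrix([f"s{i}" for i in range(len(rows))], list(rows))


class TestClassifySite:
    @pytest.mark.parametrize("column,status,diff,pairs", [
        ("AAAA", "invariant", 0, 6),
        ("AAT-", "singleton", 2, 3),
        ("AATT", "parsimony_informative", 4, 6),
        ("A---", "invalid", 0, 0),
        ("ANN-", "invalid", 0, 0),
        ("ACGT", "singleton", 6, 6),
        ("AACG", "singleton", 5, 6),
        ("AACCGG", "parsimony_informative", 12, 15),
    ])
    def test_examples(self, column, status, diff, pairs):
        sc = classify_site(column)
        assert (sc.status, sc.n_diff_pairs, sc.n_pairs) == (status, diff, pairs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN-", min_size=1, max_size=20))
    def test_any_column_matches_enumeration_oracle(self, column):
        from conftest import brute_site

        sc = classify_site(column)
        n_valid, diff, pairs, status = brute_site(column)
        assert (sc.n_valid, sc.n_diff_pairs, sc.n_pairs, sc.status) == \
            (n_valid, diff, pairs, status)
        assert sc.n_diff_pairs <= sc.n_pairs
        assert (sc.status == "invalid") == (sc.n_valid < 2)

    def test_gaps_never_count_as_fifth_state(self):
        # two As and two gaps: the gaps must not make this informative
        assert classify_site("AA--").status == "invariant"
        assert classify_site("AT--").status == "singleton"


class TestWindowPi:
    def test_worked_three_sequence_example(self):
        # ACGT / AC-T / ATGA: sum of differing pairs 4, comparable pairs 10
        aln = aln_of("ACGT", "AC-T", "ATGA")
        pi, n_pis, n_single = window_pi(aln, 0, 4)
        assert pi == pytest.approx(0.4)
        assert brute_window(["ACGT", "AC-T", "ATGA"], 0, 4)[0] == pytest.approx(0.4)

    def test_identical_rows_zero(self):
        aln = aln_of("ACGTACGT", "ACGTACGT", "ACGTACGT")
        assert window_pi(aln, 0, 8)[0] == 0.0

    def test_no_comparable_pairs_is_na(self):
        aln = aln_of("AAAA", "----")
        assert window_pi(aln, 0, 4)[0] is None

    def test_empty_interval_rejected(self):
        aln = aln_of("ACGT", "ACGT")
        with pytest.raises(ValueError):
            window_pi(aln, 2, 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_gapped_alignment(rng, int(rng.integers(3, 10)), 60)
        rows = [aln.row(i) for i in aln.ids]
        got = window_pi(aln, 5, 55)
        expect = brute_window(rows, 5, 55)
        assert got[0] == pytest.approx(expect[0])
        assert got[1:] == expect[1:]

    def test_all_gap_row_does_not_change_pi(self):
        aln = aln_of("ACGTAC", "ACTTAC", "AGGTAC")
        plus = aln_of("ACGTAC", "ACTTAC", "AGGTAC", "------")
        assert window_pi(aln, 0, 6) == window_pi(plus, 0, 6)

    def test_row_permutation_invariance(self):
        rows = ["ACGTAC", "ACTTAC", "AGGTA-", "AC-TNC"]
        assert window_pi(aln_of(*rows), 0, 6) == \
            window_pi(aln_of(*rows[::-1]), 0, 6)

    def test_concatenation_is_ratio_of_sums(self):
        rng = np.random.default_rng(77)
        aln = random_gapped_alignment(rng, 6, 90)
        rows = [aln.row(i) for i in aln.ids]
        d_ab, c_ab = _sums(rows, 0, 40)
        d_bc, c_bc = _sums(rows, 40, 90)
        whole = window_pi(aln, 0, 90)[0]
        assert whole == pytest.approx((d_ab + d_bc) / (c_ab + c_bc))


def _sums(rows, start, end):
    import itertools

    d = c = 0
    for col in range(start, end):
        chars = [r[col] for r in rows if r[col] in "ACGT"]
        for a, b in itertools.combinations(chars, 2):
            c += 1
            d += a != b
    return d, c


class TestSlidingWindows:
    def test_window_start_arithmetic(self):
        aln = aln_of("A" * 1000, "A" * 1000)
        ws = sliding_windows(aln, 600, 200)
        assert [w.start for w in ws] == [0, 200, 400, 600, 800]
        assert ws[0].end == 600 and ws[-1].end == 1000

    def test_identical_rows_all_zero(self):
        aln = aln_of("ACGT" * 300, "ACGT" * 300)
        for w in sliding_windows(aln):
            assert w.pi == 0.0 and w.n_pis == 0

    def test_max_pi_window_overlaps_planted_hotspot(self):
        aln, truth = simulate_alignment(
            HotspotSpec(n_samples=22, n_columns=8000, hotspots=[(3000, 3700)],
                        seed=4))
        ws = sliding_windows(aln)
        best = max(ws, key=lambda w: w.pi if w.pi is not None else -1)
        (hs, he), = truth
        assert best.start < he and best.end > hs


class TestMergeHotspots:
    def test_no_qualifying_window_empty(self):
        aln = aln_of("ACGT" * 300, "ACGT" * 300)
        assert merge_hotspots(sliding_windows(aln), aln) == []

    def test_interval_arithmetic_of_merged_run(self):
        # windows 10..12 qualify in a 600/200 series -> [2000, 3000)
        aln = aln_of("A" * 4000, "A" * 4000)
        windows = []
        for start in range(0, 4000, 200):
            end = min(start + 600, 4000)
            q = start in (2000, 2200, 2400)
            windows.append(WindowStat(start, end, 0.02 if q else 0.001,
                                      30 if q else 0, 0))
        (region,) = merge_hotspots(windows, aln)
        assert (region.start, region.end, region.length) == (2000, 3000, 1000)

    def test_strict_threshold_boundaries_do_not_qualify(self):
        aln = aln_of("A" * 1000, "A" * 1000)
        at_pi = [WindowStat(0, 600, 0.01, 30, 0)]
        at_pis = [WindowStat(0, 600, 0.02, 25, 0)]
        above = [WindowStat(0, 600, 0.0100001, 26, 0)]
        assert merge_hotspots(at_pi, aln) == []
        assert merge_hotspots(at_pis, aln) == []
        assert len(merge_hotspots(above, aln)) == 1

    def test_region_stats_recomputed_on_span(self):
        aln, _ = simulate_alignment(
            HotspotSpec(n_samples=22, n_columns=6000, hotspots=[(2400, 3300)],
                        seed=8))
        regions = merge_hotspots(sliding_windows(aln), aln)
        assert regions
        for r in regions:
            rows = [aln.row(i) for i in aln.ids]
            pi, n_pis, n_single = brute_window(rows, r.start, r.end)
            assert r.pi == pytest.approx(pi)
            assert (r.n_pip, r.n_svs) == (n_pis, n_single)
        # disjoint and sorted
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start

    def test_monotone_hotspot_recovery(self):
        counts = []
        for rate in (0.01, 0.02, 0.04, 0.08):
            spec = HotspotSpec(n_samples=22, n_columns=6000,
                               hotspots=[(2000, 2900)], hotspot_rate=rate,
                               seed=12)
            aln, _ = simulate_alignment(spec)
            ws = sliding_windows(aln)
            qualifying = sum(1 for w in ws
                             if w.pi is not None and w.pi > 0.01
                             and w.n_pis > 25)
            counts.append(qualifying)
        assert counts == sorted(counts)


class TestNameRegion:
    def _ref(self):
        feats = [Feature("gA", "gene", "+", [(100, 200)]),
                 Feature("gB", "gene", "+", [(400, 500)]),
                 Feature("gC", "gene", "+", [(700, 800)])]
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 900))
        return AnnotatedGenome("ref", seq, features=feats)

    def _region(self, start, end):
        from plastome.diversity import HypervariableRegion

        return HypervariableRegion(start, end, end - start, 0, 0, 0.02)

    def test_intergenic_spacer_label(self):
        ref = self._ref()
        # gap-free reference row: columns equal reference coordinates
        aln = AlignmentMatrix(["ref", "other"], [ref.seq, ref.seq])
        assert name_region(self._region(250, 350), ref, aln, "ref") == "gA-gB"

    def test_gap_skipping_projection(self):
        ref = self._ref()
        row = "-" * 5 + ref.seq[:400]
        aln = AlignmentMatrix(["ref", "other"], [row, "A" * len(row)])
        # alignment column 5 is reference coordinate 0, so columns
        # [105, 200) sit wholly inside gA = [100, 200)
        label = name_region(self._region(105, 200), ref, aln, "ref")
        assert label == "gA"

    def test_region_in_reference_gap_unplaced(self):
        ref = self._ref()
        row = "-" * 50 + ref.seq[: 400]
        aln = AlignmentMatrix(["ref", "other"], [row, "A" * len(row)])
        assert name_region(self._region(0, 40), ref, aln, "ref") == "unplaced"
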