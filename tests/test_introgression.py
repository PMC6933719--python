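"""Phase rules, shared-allele scans, match ratios and the paired test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtseek.introgression import (
    ArchaicGenotypes,
    MatchRatioResult,
    PhasedPanel,
    SharedAlleleSite,
    annotate_frequencies,
    carrier_vs_noncarrier_test,
    estimate_haplotype_boundary,
    infer_phase,
    match_ratio,
    null_distribution,
    shared_allele_scan,
)


class TestInferPhase:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ([0, 0, 0, 0, 1], "hap1"),  # 4 of 5: 4 > 10/3 and >= 3
            ([0, 0, 1], "unphased"),  # 2 of 3: 2 is not > 2
            ([1, 1, 1], "hap2"),  # 3 of 3
            ([0, 0], "unphased"),  # only 2 reads
            ([], "unphased"),
        ],
    )
    def test_rule_arithmetic(self, votes, expected):
        call = infer_phase("n", "s", votes)
        assert call.haplotype == expected

    @settings(deadline=None, max_examples=200)
    @given(votes=st.lists(st.integers(0, 1), max_size=30))
    def test_thresholds_never_jointly_violated(self, votes):
        call = infer_phase("n", "s", votes)
        if call.haplotype != "unphased":
            assert call.n_concordant > (2 / 3) * call.n_informative_reads
            assert call.n_concordant >= 3


def _panel(positions, gts, alt=None):
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    return PhasedPanel(
        positions=positions,
        ref=["A"] * n,
        alt=alt or ["T"] * n,
        gt=np.asarray(gts, dtype=np.int8),
        samples=["S0"],
    )


def _archaic(positions, carries, alt=None):
    n = len(positions)
    return ArchaicGenotypes(
        positions=np.asarray(positions, dtype=np.int64),
        ref=["A"] * n,
        alt=alt or ["T"] * n,
        carries_alt=np.asarray(carries, dtype=bool),
    )


class TestSharedAlleleScan:
    def test_reference_haplotype_shares_nothing(self):
        panel = _panel([100, 200], [[0, 1], [0, 1]])
        arch = _archaic([100, 200], [True, True])
        assert shared_allele_scan(panel, "S0", 0, arch, 150) == []

    def test_window_boundary_is_inclusive_at_20kb(self):
        x = 100_000
        panel = _panel([x - 20_001, x - 19_999], [[1, 0], [1, 0]])
        arch = _archaic([x - 20_001, x - 19_999], [True, True])
        sites = shared_allele_scan(panel, "S0", 0, arch, x, window=20_000)
        assert [s.position for s in sites] == [x - 19_999]

    def test_unphased_sites_excluded(self):
        panel = _panel([100, 200], [[1, 0], [1, 0]])
        panel.phased[0] = False
        arch = _archaic([100, 200], [True, True])
        sites = shared_allele_scan(panel, "S0", 0, arch, 150)
        assert [s.position for s in sites] == [200]

    def test_different_alternate_allele_is_not_shared(self):
        panel = _panel([100], [[1, 0]], alt=["G"])
        arch = _archaic([100], [True], alt=["C"])
        assert shared_allele_scan(panel, "S0", 0, arch, 100) == []


class TestAnnotateFrequencies:
    def _site(self, pos=100):
        return SharedAlleleSite(position=pos, allele="T")

    def _ref_panel(self, freq, n_hap=100):
        gt = np.zeros((1, n_hap), dtype=np.int8)
        gt[0, : int(round(freq * n_hap))] = 1
        return PhasedPanel(
            positions=np.array([100]), ref=["A"], alt=["T"], gt=gt,
            samples=[f"x{i}" for i in range(n_hap // 2)],
        )

    def test_rare_in_one_panel_is_flagged(self):
        (site,) = annotate_frequencies(
            [self._site()], {"A": self._ref_panel(0.04), "B": self._ref_panel(0.5)}
        )
        assert site.introgression_candidate

    def test_exactly_005_in_both_is_not_flagged(self):
        (site,) = annotate_frequencies(
            [self._site()], {"A": self._ref_panel(0.05), "B": self._ref_panel(0.05)}
        )
        assert not site.introgression_candidate

    def test_common_everywhere_not_flagged(self):
        (site,) = annotate_frequencies(
            [self._site()], {"A": self._ref_panel(0.9), "B": self._ref_panel(0.9)}
        )
        assert not site.introgression_candidate

    def test_absent_allele_has_frequency_zero_and_flags(self):
        panel = self._ref_panel(0.5)
        panel.positions = np.array([999])  # site not present in panel
        (site,) = annotate_frequencies([self._site()], {"A": panel})
        assert site.panel_frequencies["A"] == 0.0
        assert site.introgression_candidate


class TestMatchRatio:
    def test_five_shared_union_ten(self):
        pos = list(range(100, 1100, 100))
        hap = [1] * 5 + [1] * 5  # carries alt at all ten
        arch = [True] * 5 + [False] * 5
        panel = _panel(pos, [[g, 0] for g in hap])
        result = match_ratio(panel, "S0", 0, _archaic(pos, arch), 500)
        assert (result.n_shared, result.n_union, result.ratio) == (5, 10, 0.5)

    def test_perfect_sharing_is_one(self):
        pos = [100, 200, 300]
        panel = _panel(pos, [[1, 0]] * 3)
        result = match_ratio(panel, "S0", 0, _archaic(pos, [True] * 3), 200)
        assert result.ratio == 1.0

    def test_no_sharing_is_zero(self):
        pos = list(range(100, 800, 100))
        panel = _panel(pos, [[1, 0]] * 7)
        result = match_ratio(panel, "S0", 0, _archaic(pos, [False] * 7), 400)
        assert result.ratio == 0.0 and result.n_union == 7

    def test_empty_union_is_undefined(self):
        panel = _panel([100], [[0, 0]])
        result = match_ratio(panel, "S0", 0, _archaic([100], [False]), 100)
        assert not result.defined and result.ratio is None


class TestNullDistribution:
    def _results(self, null_ratios, focal_ratio):
        out = [
            MatchRatioResult(f"N{i}", 0, 1, 2, r) for i, r in enumerate(null_ratios)
        ]
        out.append(MatchRatioResult("focal", 0, 1, 2, focal_ratio))
        return out, {f"N{i}" for i in range(len(null_ratios))}

    def test_exceeding_every_null_gives_percentile_one(self):
        results, null = self._results(list(np.linspace(0, 0.5, 40)), 0.9)
        annotated = null_distribution(results, null)
        assert annotated[-1].null_percentile == 1.0

    def test_null_median_gives_half(self):
        ratios = list(np.linspace(0, 1, 41))
        results, null = self._results(ratios, float(np.median(ratios)))
        annotated = null_distribution(results, null)
        assert annotated[-1].null_percentile == pytest.approx(0.5, abs=0.02)

    def test_too_few_null_haplotypes_rejected(self):
        results, null = self._results([0.1] * 10, 0.5)
        with pytest.raises(ValueError, match="null"):
            null_distribution(results, null)


class TestPairedTest:
    def test_all_zero_differences(self):
        t, p = carrier_vs_noncarrier_test([(0.3, 0.3)] * 5)
        assert t == 0.0 and p == 0.5

    def test_constant_positive_difference_with_jitter(self):
        rng = np.random.default_rng(0)
        pairs = [(0.75 + e, 0.25) for e in rng.normal(0, 1e-3, size=4)]
        _, p = carrier_vs_noncarrier_test(pairs)
        assert p < 0.01

    def test_matches_textbook_formula(self):
        """Oracle equivalence to the hand-computed paired-t on 20 pairs."""
        rng = np.random.default_rng(1)
        pairs = [(float(a), float(b)) for a, b in rng.random((20, 2))]
        t, p = carrier_vs_noncarrier_test(pairs)
        d = np.array([a - b for a, b in pairs])
        n = len(d)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        from scipy.stats import t as tdist

        p_hand = tdist.sf(t_hand, n - 1)
        assert abs(t - t_hand) < 1e-10
        assert abs(p - p_hand) < 1e-10

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            carrier_vs_noncarrier_test([(0.5, 0.1)])


class TestBoundary:
    def _sites(self, positions):
        return [
            SharedAlleleSite(position=p, allele="T", introgression_candidate=True)
            for p in positions
        ]

    def test_insertion_anchors_the_chain(self):
        x = 100_000
        sites = self._sites([x - 10_000, x - 5_000, x + 2_000])
        assert estimate_haplotype_boundary(sites, x, gap_threshold=5_000) == (
            x - 10_000,
            x + 2_000,
        )

    def test_far_site_dropped(self):
        x = 100_000
        sites = self._sites([x - 20_000, x - 5_000, x + 2_000])
        assert estimate_haplotype_boundary(sites, x, gap_threshold=5_000) == (
            x - 5_000,
            x + 2_000,
        )

    def test_single_site_gives_no_interval(self):
        assert estimate_haplotype_boundary(self._sites([123]), 100) is None

    def test_simulated_interval_recovered_within_2kb(self):
        """End-to-end: scan + frequency filter + boundary on a simulated
        introgressed panel recovers the truth interval edge within 2 kbp."""
        from numtseek.sim import SimConfig, simulate_introgressed_panel

        cfg = SimConfig(nuclear_length=400_000, seed=17,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        interval = (180_000, 200_000)
        sim = simulate_introgressed_panel(
            cfg, [f"P{i:03d}" for i in range(10)], interval, n_samples=60
        )
        carrier, hap = next(iter(sim.carrier_haps.items()))
        sites = shared_allele_scan(
            sim.panel, carrier, hap, sim.archaic, sim.insertion_position, window=20_000
        )
        sites = annotate_frequencies(sites, sim.reference_panels)
        lo, hi = estimate_haplotype_boundary(sites, sim.insertion_position)
        assert abs(lo - interval[0]) <= 2_000
        assert abs(hi - interval[1]) <= 2_000
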