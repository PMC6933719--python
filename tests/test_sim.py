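"""The synthetic cohort: panel calibration, read simulation and truth tables."""

import numpy as np
import pytest
from scipy import stats

from numtseek.detect import find_supports
from numtseek.introgression import match_ratio
from numtseek.sim import (
    SimConfig,
    TruthRecord,
    diagnostic_sites,
    random_truths,
    simulate_introgressed_panel,
    simulate_mt_panel,
    simulate_sample,
)


class TestSimConfig:
    def test_defaults_encode_study_conditions(self):
        cfg = SimConfig()
        assert cfg.read_length == 150 and cfg.mt_length == 16569
        assert cfg.archaic_divergence * 150 == pytest.approx(3.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"error_rate": 0.1},
            {"coverage": 0},
            {"nuclear_length": 0},
            {"n_denisovan_mt": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestMtPanel:
    def test_archaic_divergence_calibration(self, panel_sim, small_config):
        """Mean Denisovan-vs-modern mismatches over 1000 random 150 bp
        windows must land at 3.5 +/- 0.5."""
        rng = np.random.default_rng(11)
        moderns = panel_sim.panel.rows_by_label("modern_human")
        dens = panel_sim.panel.rows_by_label("denisovan")
        L = small_config.mt_length
        total = 0
        for _ in range(1000):
            s = rng.integers(0, L - 150)
            m = moderns[rng.integers(len(moderns))][s : s + 150]
            d = dens[rng.integers(len(dens))][s : s + 150]
            total += sum(a != b for a, b in zip(m, d))
        assert abs(total / 1000 - 3.5) < 0.5

    def test_within_modern_diversity_much_smaller_than_divergence(self, panel_sim):
        moderns = panel_sim.panel.rows_by_label("modern_human")
        dens = panel_sim.panel.rows_by_label("denisovan")
        within = np.mean(
            [sum(a != b for a, b in zip(moderns[0], m)) for m in moderns[1:6]]
        )
        between = np.mean(
            [sum(a != b for a, b in zip(moderns[0], d)) for d in dens]
        )
        assert within < between / 5

    def test_diagnostic_sites_exist(self, panel_sim):
        diag = diagnostic_sites(panel_sim.panel)
        assert len(diag["archaic"]) > 0
        assert len(diag["denisovan"]) > 0

    def test_zero_divergence_panel_is_uniform(self):
        cfg = SimConfig(
            archaic_divergence=0.0,
            within_diversity=0.0,
            outgroup_divergence=0.0,
            error_rate=0.0,
            n_modern_mt=3,
            n_neanderthal_mt=2,
            n_denisovan_mt=2,
            mt_length=2000,
        )
        ps = simulate_mt_panel(cfg)
        assert len(set(ps.panel.sequences)) == 1
        diag = diagnostic_sites(ps.panel)
        assert all(len(v) == 0 for v in diag.values())

    def test_seeded_panel_is_byte_identical(self, small_config):
        a = simulate_mt_panel(small_config)
        b = simulate_mt_panel(small_config)
        assert a.panel.sequences == b.panel.sequences
        assert a.root_sequence == b.root_sequence


class TestSampleSimulation:
    def test_negative_control_has_no_discordant_pairs(self, panel_sim):
        cfg = SimConfig(nuclear_length=60_000, coverage=10, seed=5,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        sim = simulate_sample(cfg, [], panel_sim)
        for rec in sim.alignments():
            assert not rec.is_mt
            assert rec.mate_contig == rec.contig

    def test_mean_depth_within_5pct_of_coverage(self, cohort_sample, small_config):
        aligned = sum(r.aligned_length for r in cohort_sample.alignments())
        hap_len = sum(len(h.sequence) for h in cohort_sample.haplotypes) / 2
        assert abs(aligned / hap_len / small_config.coverage - 1) < 0.05

    def test_depth_distribution_is_poisson(self, cohort_sample, small_config):
        """Chi-square goodness of fit of positional depth to
        Poisson(coverage) at alpha=0.01 over >= 10^4 positions."""
        L = small_config.nuclear_length
        depth = np.zeros(L + 2, dtype=np.int32)
        for rec in cohort_sample.alignments():
            if not rec.is_mt:
                depth[rec.position] += 1
                depth[min(rec.end + 1, L + 1)] -= 1
        depth = np.cumsum(depth)[1 : L + 1]
        exclude = np.zeros(L, dtype=bool)
        for t in cohort_sample.truths:
            p = t.insertion_position
            exclude[max(p - 1500, 0) : p + 1500] = True
        exclude[:10_000] = exclude[-10_000:] = True
        pos = np.arange(0, L, 36)
        sample = depth[pos][~exclude[pos]]
        assert len(sample) >= 10_000
        lam = small_config.coverage
        kmax = int(lam + 6 * np.sqrt(lam))
        observed = np.bincount(np.minimum(sample, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax + 1), lam)
        probs[kmax] = stats.poisson.sf(kmax - 1, lam)
        expected = probs / probs.sum() * len(sample)
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_junction_clip_coordinates_match_truth_exactly(self, cohort_sample):
        sups = find_supports(
            cohort_sample.alignments(), mt_reference=cohort_sample.mt_reference
        )
        split_anchors = {}
        for s in sups:
            if s.evidence == "split":
                split_anchors.setdefault(s.anchor, 0)
                split_anchors[s.anchor] += 1
        for t in cohort_sample.truths:
            assert split_anchors.get(t.insertion_position, 0) >= 1

    def test_het_numt_reads_come_from_one_haplotype(self, panel_sim):
        cfg = SimConfig(nuclear_length=120_000, coverage=30, seed=9,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        truth = TruthRecord("1_6000", "1", 60_000, "modern_human", 100, 400, "hap2")
        sim = simulate_sample(cfg, [truth], panel_sim)
        for rec in sim.alignments():
            if rec.is_mt or max(rec.cigar_clips) >= 20:
                assert rec.read_name.split(":")[1] == "1"  # haplotype index 1

    def test_homozygous_numt_has_enough_clipped_reads(self, panel_sim):
        """At 30x a 300 bp homozygous insertion must reach the >=5 clipped
        read threshold (clipped-read count is Poisson with mean ~40, so
        failure probability is < 1e-2)."""
        cfg = SimConfig(nuclear_length=120_000, coverage=30, seed=13,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        truth = TruthRecord("1_6000", "1", 60_000, "modern_human", 1001, 1300, "both")
        sim = simulate_sample(cfg, [truth], panel_sim)
        sups = find_supports(sim.alignments(), mt_reference=sim.mt_reference)
        n_clip = sum(1 for s in sups if s.evidence == "split")
        assert n_clip >= 5

    def test_truth_spacing_enforced(self, panel_sim):
        cfg = SimConfig(nuclear_length=200_000, seed=1,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        truths = [
            TruthRecord("1_5000", "1", 50_000, "modern_human", 1, 200, "hap1"),
            TruthRecord("1_8000", "1", 80_000, "modern_human", 1, 200, "hap1"),
        ]
        with pytest.raises(ValueError, match="closer"):
            simulate_sample(cfg, truths, panel_sim)

    def test_stream_is_deterministic(self, panel_sim):
        cfg = SimConfig(nuclear_length=60_000, coverage=5, seed=21,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        sim = simulate_sample(cfg, [], panel_sim)
        first = [(r.read_name, r.position, r.sequence) for r in sim.alignments()]
        second = [(r.read_name, r.position, r.sequence) for r in sim.alignments()]
        assert first == second

    def test_random_truths_respect_spacing(self, small_config):
        rng = np.random.default_rng(3)
        truths = random_truths(small_config, rng, n_modern=4, n_denisovan=2)
        pos = sorted(t.insertion_position for t in truths)
        assert all(b - a >= 50_000 for a, b in zip(pos, pos[1:]))


class TestIntrogressedPanel:
    def _sim(self, seed=0, carriers=15):
        cfg = SimConfig(nuclear_length=400_000, seed=seed,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        names = [f"P{i:03d}" for i in range(carriers)]
        return simulate_introgressed_panel(
            cfg, names, (180_000, 200_000), n_samples=100
        )

    def test_introgressed_alleles_are_rare_in_reference_panels(self):
        sim = self._sim()
        lo, hi = sim.interval
        in_interval = (sim.panel.positions >= lo) & (sim.panel.positions <= hi)
        carrier_cols = [
            2 * sim.panel.samples.index(s) + h for s, h in sim.carrier_haps.items()
        ]
        for i in np.flatnonzero(in_interval & sim.archaic.carries_alt):
            if sim.panel.gt[i, carrier_cols].all():  # an introgressed site
                for ref in sim.reference_panels.values():
                    assert ref.allele_frequency(int(i)) < 0.05

    def test_outside_interval_shared_alleles_are_common(self):
        sim = self._sim()
        lo, hi = sim.interval
        outside = (sim.panel.positions < lo) | (sim.panel.positions > hi)
        shared_out = np.flatnonzero(outside & sim.archaic.carries_alt)
        assert len(shared_out) > 0
        freqs = [sim.panel.gt[i].mean() for i in shared_out]
        assert np.median(freqs) > 0.1

    def test_empty_carrier_list_leaves_no_rare_shared_alleles(self):
        cfg = SimConfig(nuclear_length=400_000, seed=2,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        sim = simulate_introgressed_panel(cfg, [], (180_000, 200_000), n_samples=50)
        shared = np.flatnonzero(sim.archaic.carries_alt)
        for i in shared:
            freq = sim.panel.gt[i].mean()
            assert freq >= 0.05  # all archaic-shared alleles are common

    def test_unknown_carrier_rejected(self):
        cfg = SimConfig(nuclear_length=400_000, seed=3,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        with pytest.raises(ValueError, match="carriers"):
            simulate_introgressed_panel(cfg, ["NOPE"], (180_000, 200_000))

    def test_noncarrier_ratio_below_carrier_in_most_simulations(self):
        """The designed contrast: in (at least) 19/20 replicate panels a
        non-carrier haplotype scores below a carrier haplotype."""
        wins = 0
        for seed in range(20):
            sim = self._sim(seed=seed, carriers=5)
            carrier, hap = next(iter(sim.carrier_haps.items()))
            rc = match_ratio(sim.panel, carrier, hap, sim.archaic, sim.insertion_position)
            nc_sample = sorted(sim.null_samples)[0]
            rn = match_ratio(sim.panel, nc_sample, 0, sim.archaic, sim.insertion_position)
            if rn.defined and rc.defined and rn.ratio < rc.ratio:
                wins += 1
        assert wins >= 19
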