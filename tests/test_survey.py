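"""Rarefaction, Poisson detectability, downsampling, diagnostics, refswap."""

import numpy as np
import pytest
from math import comb

from numtseek.detect import find_supports
from numtseek.sim import SimConfig, TruthRecord, simulate_sample
from numtseek.survey import (
    diagnostic_scan,
    downsampling_experiment,
    poisson_detectable_fraction,
    rarefaction,
    reference_swap_experiment,
)


class TestRarefaction:
    def test_shared_single_numt_gives_flat_curve(self):
        sets = {f"s{i}": {"numt_a"} for i in range(6)}
        curve = rarefaction(sets, n_reps=10)
        assert np.allclose(curve.mean_distinct, 1.0)

    def test_disjoint_singletons_give_diagonal(self):
        sets = {f"s{i}": {f"numt_{i}"} for i in range(6)}
        curve = rarefaction(sets, n_reps=10)
        assert np.allclose(curve.mean_distinct, np.arange(1, 7))

    def test_curve_is_nondecreasing_and_ends_at_total(self):
        rng = np.random.default_rng(0)
        sets = {
            f"s{i}": {f"n{j}" for j in rng.choice(12, size=rng.integers(1, 6), replace=False)}
            for i in range(8)
        }
        curve = rarefaction(sets, n_reps=50, rng=np.random.default_rng(1))
        assert np.all(np.diff(curve.mean_distinct) >= -1e-12)
        assert curve.mean_distinct[-1] == len(set().union(*sets.values()))

    def test_matches_hypergeometric_expectation(self):
        """Closed-form oracle: E[distinct at k] = sum_j 1 - C(n-m_j,k)/C(n,k),
        with the exact variance computed from pairwise carrier unions; each
        mean must fall within 3 standard errors on 20 random matrices."""
        rng = np.random.default_rng(42)
        n_reps = 100
        for trial in range(20):
            n = int(rng.integers(4, 9))
            n_numts = int(rng.integers(2, 10))
            carriers = []
            for _ in range(n_numts):
                m = int(rng.integers(1, n + 1))
                carriers.append(frozenset(rng.choice(n, size=m, replace=False).tolist()))
            sets = {
                f"s{i}": {f"n{j}" for j, c in enumerate(carriers) if i in c}
                for i in range(n)
            }
            if not set().union(*sets.values()):
                continue
            curve = rarefaction(
                sets, n_reps=n_reps, rng=np.random.default_rng(trial)
            )
            for k in range(1, n + 1):
                absent = [comb(n - len(c), k) / comb(n, k) for c in carriers]
                expect = sum(1 - a for a in absent)
                # exact variance of the distinct count for one permutation
                var = sum(a * (1 - a) for a in absent)
                for i in range(n_numts):
                    for j in range(i + 1, n_numts):
                        u = len(carriers[i] | carriers[j])
                        both_absent = comb(n - u, k) / comb(n, k) if n - u >= k else 0.0
                        cov = both_absent - absent[i] * absent[j]
                        var += 2 * cov
                se = np.sqrt(max(var, 0.0) / n_reps)
                got = curve.mean_distinct[k - 1]
                assert abs(got - expect) <= 3 * se + 1e-9, (trial, k, got, expect, se)


class TestPoissonDetectability:
    def test_matches_direct_summation(self):
        """Oracle: 1 - sum_{i<min_reads} e^-lam lam^i / i! to 1e-12."""
        import math

        for lam in (0.5, 4.0, 10.0, 30.0):
            for m in (1, 5, 8):
                direct = 1.0 - sum(
                    math.exp(-lam) * lam**i / math.factorial(i) for i in range(m)
                )
                assert abs(poisson_detectable_fraction(lam, m) - direct) < 1e-12

    def test_high_coverage_exceeds_95pct(self):
        assert poisson_detectable_fraction(30, 5) > 0.95

    def test_min_reads_zero_is_certain(self):
        assert poisson_detectable_fraction(7.3, 0) == 1.0

    def test_low_coverage_below_half(self):
        assert poisson_detectable_fraction(4, 5) < 0.5


class TestDownsampling:
    def test_full_fraction_equals_full_detection(self, cohort_sample):
        df, _ = downsampling_experiment(cohort_sample, [1.0], seed=0)
        from numtseek.survey import detect_calls

        full = detect_calls(
            cohort_sample.alignments(),
            mt_contig=cohort_sample.mt_contig,
            mt_reference=cohort_sample.mt_reference,
        )
        assert df.loc[0, "n_detected"] == len(full)

    def test_low_coverage_detects_fewer(self, cohort_sample):
        df, r2 = downsampling_experiment(
            cohort_sample, [0.15, 1.0], seed=1
        )
        low, high = df["n_detected"].tolist()
        assert low < high

    def test_invalid_fraction_rejected(self, cohort_sample):
        with pytest.raises(ValueError):
            downsampling_experiment(cohort_sample, [0.0], seed=0)


class TestDiagnosticScan:
    def _setup(self):
        rng = np.random.default_rng(8)
        mt = "".join(rng.choice(list("ACGT"), size=3000))
        pos = 1500
        allele = "T" if mt[pos - 1] != "T" else "A"
        def read(q_at_site=30, start=1400):
            seq = list(mt[start : start + 150])
            seq[pos - start - 1] = allele
            quals = [30] * 150
            quals[pos - start - 1] = q_at_site
            return "".join(seq), quals
        return mt, pos, allele, read

    def test_four_supporting_reads_discarded(self):
        mt, pos, allele, read = self._setup()
        reads = [read() for _ in range(4)]
        assert diagnostic_scan(reads, [(pos, allele, "denisovan")], mt) == []

    def test_five_reads_one_below_baseq15_discarded(self):
        mt, pos, allele, read = self._setup()
        reads = [read() for _ in range(4)] + [read(q_at_site=14)]
        assert diagnostic_scan(reads, [(pos, allele, "denisovan")], mt) == []

    def test_five_good_reads_retained(self):
        mt, pos, allele, read = self._setup()
        reads = [read(q_at_site=15, start=1380 + 10 * i) for i in range(5)]
        hits = diagnostic_scan(reads, [(pos, allele, "denisovan")], mt)
        assert len(hits) == 1 and hits[0].n_support == 5
        assert len(hits[0].consensus_context) >= 30

    def test_position_outside_reference_rejected(self):
        mt, pos, allele, read = self._setup()
        with pytest.raises(ValueError, match="outside"):
            diagnostic_scan([read()], [(99_999, allele, "denisovan")], mt)

    def test_long_denisovan_numt_found_and_classified(self, panel_sim):
        """Interior reads of a NUMT longer than the split-read bound carry
        diagnostic alleles; the scan must recover and classify them."""
        from numtseek.sim import diagnostic_sites

        rng = np.random.default_rng(9)
        den = panel_sim.source_sequence("denisovan")
        diag = diagnostic_sites(panel_sim.panel)
        table = [(p, a, "denisovan_sima") for p, a in diag["denisovan_sima"]]
        region = next(p for p, _ in diag["denisovan_sima"] if 2000 < p < 14000)
        reads = []
        for _ in range(40):
            start = int(rng.integers(region - 140, region))
            reads.append((den[start : start + 150], [30] * 150))
        hits = diagnostic_scan(
            reads, table, panel_sim.rsrs_sequence, panel=panel_sim.panel,
            rng=np.random.default_rng(3),
        )
        assert any(
            h.lineage_call is not None and h.lineage_call.category == "denisovan"
            for h in hits
        )


class TestReferenceSwap:
    def _sample(self, panel_sim, lineage, seed):
        cfg = SimConfig(nuclear_length=150_000, coverage=30, seed=seed,
                        n_modern_mt=20, n_neanderthal_mt=5, n_denisovan_mt=4)
        truth = TruthRecord("1_7500", "1", 75_000, lineage, 3001, 3400, "both")
        return simulate_sample(cfg, [truth], panel_sim)

    def test_identical_references_identical_counts(self, panel_sim):
        sim = self._sample(panel_sim, "modern_human", 31)
        res = reference_swap_experiment(
            [sim], {"a": sim.mt_reference, "b": sim.mt_reference}
        )
        counts = res.counts.groupby("reference")["n_detected"].sum()
        assert counts["a"] == counts["b"]

    def test_modern_reads_lose_supports_against_archaic_reference(self, panel_sim):
        sim = self._sample(panel_sim, "modern_human", 32)
        arch_ref = panel_sim.source_sequence("denisovan")
        n_modern = len(find_supports(
            sim.alignments(), mt_reference=sim.mt_reference,
            max_clip_divergence=0.025, validate_discordant=True,
        ))
        n_arch = len(find_supports(
            sim.alignments(), mt_reference=arch_ref,
            max_clip_divergence=0.025, validate_discordant=True,
        ))
        assert n_arch < n_modern

    def test_archaic_reads_prefer_archaic_reference(self, panel_sim):
        sim = self._sample(panel_sim, "denisovan", 33)
        arch_ref = panel_sim.source_sequence("denisovan")
        res = reference_swap_experiment(
            [sim], {"modern": sim.mt_reference, "archaic": arch_ref}
        )
        counts = res.counts.set_index("reference")["n_detected"]
        assert counts["archaic"] >= counts["modern"]
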