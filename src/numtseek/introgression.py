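"""Phase assignment of NUMT insertions and archaic-ancestry tests on their
flanking haplotypes.

A NUMT is assigned to a haplotype when its supporting reads agree with the
phased alleles at flanking heterozygous sites (>2/3 of informative reads and
at least three reads).  The 20 kbp flanks are then scanned for non-reference
alleles shared with an archaic genome; alleles rare (<0.05) in at least one
worldwide reference panel are flagged as introgression candidates.  A match
ratio (shared / union of non-reference sites) summarises each haplotype's
similarity to the archaic genome, is ranked against an empirical null from
populations without archaic ancestry, and carrier vs non-carrier haplotypes
of heterozygous samples are compared with a one-tailed paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Genotype containers


@dataclass
class PhasedPanel:
    """Phased biallelic genotypes for a set of diploid samples.

    `gt` has shape (n_sites, 2 * n_samples); haplotype ``2*i`` and ``2*i+1``
    belong to sample ``i``.  `phased` marks sites whose genotypes carry phase
    information (unphased sites are excluded from haplotype-level scans).
    """

    positions: np.ndarray  # 1-based, strictly increasing
    ref: list[str]
    alt: list[str]
    gt: np.ndarray  # int8: 0 ref, 1 alt
    samples: list[str]
    chrom: str = "1"
    phased: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phased is None:
            self.phased = np.ones(len(self.positions), dtype=bool)

    @property
    def n_haplotypes(self) -> int:
        return self.gt.shape[1]

    def haplotype(self, sample: str, hap: int) -> np.ndarray:
        i = self.samples.index(sample)
        return self.gt[:, 2 * i + hap]

    def haplotype_ids(self):
        for s in self.samples:
            yield (s, 0)
            yield (s, 1)

    def allele_frequency(self, site_index: int) -> float:
        return float(self.gt[site_index].mean())


@dataclass
class ArchaicGenotypes:
    """Genotypes of one (possibly unphased) archaic diploid.

    A site "carries" the alternate allele when either archaic allele is
    non-reference; archaic phasing is never required.
    """

    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    carries_alt: np.ndarray  # bool per site
    chrom: str = "1"


# ---------------------------------------------------------------------------
# Phase of the NUMT insertion


@dataclass
class PhaseCall:
    numt_id: str
    sample: str
    haplotype: str  # hap1 | hap2 | unphased
    n_informative_reads: int
    n_concordant: int
    reason: str | None = None


def infer_phase(
    numt_id: str,
    sample: str,
    read_votes: list[int],
    majority: float = 2.0 / 3.0,
    min_reads: int = 3,
) -> PhaseCall:
    """Assign the NUMT to a haplotype from its reads' alleles at flanking
    heterozygous sites.

    `read_votes` holds one entry per informative supporting read: 0 if the
    read carries haplotype-1 alleles, 1 for haplotype 2.  The winning
    haplotype must be supported by strictly more than `majority` of the
    informative reads and by at least `min_reads` reads; otherwise the NUMT
    stays unphased.
    """
    n = len(read_votes)
    if n == 0:
        return PhaseCall(numt_id, sample, "unphased", 0, 0, reason="no informative het sites")
    n1 = sum(1 for v in read_votes if v == 1)
    n0 = n - n1
    winner, n_conc = ("hap2", n1) if n1 >= n0 else ("hap1", n0)
    if n_conc > majority * n and n_conc >= min_reads:
        return PhaseCall(numt_id, sample, winner, n, n_conc)
    return PhaseCall(numt_id, sample, "unphased", n, n_conc, reason="support below phase thresholds")


def phase_votes_from_reads(records, het_sites, hap_of_alt) -> list[int]:
    """Turn NUMT-supporting nuclear reads into haplotype votes.

    `het_sites` maps a 1-based reference position to (ref_allele,
    alt_allele); `hap_of_alt[pos]` says which haplotype (0/1) carries the
    alternate allele.  A read voting for several sites must be consistent;
    inconsistent reads are dropped.
    """
    votes = []
    for rec in records:
        site_votes = set()
        left = rec.cigar_clips[0]
        for pos, (ref_a, alt_a) in het_sites.items():
            if not (rec.position <= pos <= rec.end):
                continue
            base = rec.sequence[left + (pos - rec.position)]
            if base == alt_a:
                site_votes.add(hap_of_alt[pos])
            elif base == ref_a:
                site_votes.add(1 - hap_of_alt[pos])
        if len(site_votes) == 1:
            votes.append(site_votes.pop())
    return votes


# ---------------------------------------------------------------------------
# Shared alleles, frequencies, match ratio


@dataclass
class SharedAlleleSite:
    position: int
    allele: str
    panel_frequencies: dict[str, float] = field(default_factory=dict)
    introgression_candidate: bool = False


def shared_allele_scan(
    panel: PhasedPanel,
    sample: str,
    hap: int,
    archaic: ArchaicGenotypes,
    insertion_position: int,
    window: int = 20000,
) -> list[SharedAlleleSite]:
    """Sites within +/- window of the insertion where the focal haplotype and
    the archaic genome share the same non-reference allele.

    Unphased sites are excluded.
    """
    hap_alt = panel.haplotype(sample, hap) == 1
    lo, hi = insertion_position - window, insertion_position + window
    arch_by_pos = {
        int(p): (a, c)
        for p, a, c in zip(archaic.positions, archaic.alt, archaic.carries_alt)
    }
    out = []
    for i, pos in enumerate(panel.positions):
        if not lo <= pos <= hi or not panel.phased[i] or not hap_alt[i]:
            continue
        arch = arch_by_pos.get(int(pos))
        if arch is None or not arch[1]:
            continue
        if arch[0] != panel.alt[i]:
            continue  # multi-allelic: sharing requires the identical alternate
        out.append(SharedAlleleSite(position=int(pos), allele=panel.alt[i]))
    return out


def annotate_frequencies(
    sites: list[SharedAlleleSite],
    reference_panels: dict[str, PhasedPanel],
    freq_threshold: float = 0.05,
) -> list[SharedAlleleSite]:
    """Flag shared alleles that are rare in at least one reference panel.

    The frequency is the allele count over all haplotypes with non-missing
    genotypes; an allele absent from a panel has frequency 0 and is flagged.
    """
    for site in sites:
        for name, panel in reference_panels.items():
            idx = np.searchsorted(panel.positions, site.position)
            if (
                idx < len(panel.positions)
                and panel.positions[idx] == site.position
                and panel.alt[idx] == site.allele
            ):
                site.panel_frequencies[name] = panel.allele_frequency(int(idx))
            else:
                site.panel_frequencies[name] = 0.0
        site.introgression_candidate = any(
            f < freq_threshold for f in site.panel_frequencies.values()
        )
    return sites


@dataclass
class MatchRatioResult:
    sample: str
    haplotype: int
    n_shared: int
    n_union: int
    ratio: float | None  # None when n_union == 0
    null_percentile: float | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def match_ratio(
    panel: PhasedPanel,
    sample: str,
    hap: int,
    archaic: ArchaicGenotypes,
    insertion_position: int,
    window: int = 20000,
) -> MatchRatioResult:
    """Proportion of non-reference sites shared with the archaic genome.

    shared = sites where both the focal haplotype and the archaic genome
    carry the same non-reference allele; union = sites where either does.
    """
    hap_alt = panel.haplotype(sample, hap) == 1
    lo, hi = insertion_position - window, insertion_position + window

    panel_by_pos = {}
    for i, pos in enumerate(panel.positions):
        if lo <= int(pos) <= hi and panel.phased[i]:
            panel_by_pos[int(pos)] = (panel.alt[i], bool(hap_alt[i]))

    arch_by_pos = {
        int(p): (a, bool(c))
        for p, a, c in zip(archaic.positions, archaic.alt, archaic.carries_alt)
        if lo <= int(p) <= hi
    }

    n_shared = 0
    union_positions = set()
    for pos, (alt, carries) in panel_by_pos.items():
        if carries:
            union_positions.add(pos)
            arch = arch_by_pos.get(pos)
            if arch is not None and arch[1] and arch[0] == alt:
                n_shared += 1
    for pos, (alt, carries) in arch_by_pos.items():
        if carries:
            union_positions.add(pos)
    n_union = len(union_positions)
    ratio = n_shared / n_union if n_union > 0 else None
    return MatchRatioResult(sample=sample, haplotype=hap, n_shared=n_shared, n_union=n_union, ratio=ratio)


def null_distribution(
    results: list[MatchRatioResult], null_samples: set[str]
) -> list[MatchRatioResult]:
    """Annotate each result with its percentile in the empirical null.

    The null is the set of defined ratios from haplotypes of samples in
    `null_samples` (populations without archaic ancestry).  The percentile
    is the mid-rank fraction of null ratios below the focal ratio, so a
    ratio equal to the null median lands at 0.5 and one above every null
    value at 1.0.
    """
    null = np.array(
        [r.ratio for r in results if r.sample in null_samples and r.defined]
    )
    if len(null) < 30:
        raise ValueError(
            f"only {len(null)} null haplotypes; at least 30 are needed for a stable null"
        )
    for r in results:
        if not r.defined:
            continue
        less = float((null < r.ratio).sum())
        equal = float((null == r.ratio).sum())
        r.null_percentile = (less + 0.5 * equal) / len(null)
    return results


def carrier_vs_noncarrier_test(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """One-tailed paired t-test: carrier-haplotype vs other-haplotype ratios.

    `pairs` holds (carrier_ratio, noncarrier_ratio) per heterozygous
    carrier.  Returns (t statistic, upper-tailed p) on the differences with
    n-1 degrees of freedom.  With zero variance the p-value degenerates to
    0, 0.5 or 1 by the sign of the common difference.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two heterozygous carriers")
    diffs = np.array([c - nc for c, nc in pairs])
    if np.allclose(diffs.std(ddof=1), 0.0):
        mean = diffs.mean()
        warnings.warn("zero variance of paired differences; degenerate p-value")
        if np.isclose(mean, 0.0):
            return 0.0, 0.5
        return (np.inf, 0.0) if mean > 0 else (-np.inf, 1.0)
    t, p = stats.ttest_rel(diffs, np.zeros_like(diffs), alternative="greater")
    return float(t), float(p)


@dataclass
class IntrogressionSummary:
    """All-haplotype match ratios plus the carrier-vs-noncarrier paired test."""

    results: list[MatchRatioResult]
    pairs: list[tuple[float, float]]
    t_statistic: float
    p_value: float

    def carrier_mean(self) -> float:
        return float(np.mean([c for c, _ in self.pairs])) if self.pairs else float("nan")

    def noncarrier_mean(self) -> float:
        return float(np.mean([n for _, n in self.pairs])) if self.pairs else float("nan")


def estimate_haplotype_boundary(
    sites: list[SharedAlleleSite],
    insertion_position: int,
    gap_threshold: int = 5000,
) -> tuple[int, int] | None:
    """Extent of the putatively introgressed haplotype around the insertion.

    Chains introgression-candidate sites (plus the insertion point itself,
    which anchors the chain) so that consecutive anchors are at most
    `gap_threshold` apart, and returns the first..last flagged site of the
    chain containing the insertion.  Needs at least two flagged sites.
    """
    flagged = sorted(s.position for s in sites if s.introgression_candidate)
    if len(flagged) < 2:
        return None
    anchors = sorted(set(flagged) | {insertion_position})
    runs: list[list[int]] = [[anchors[0]]]
    for a, b in zip(anchors, anchors[1:]):
        if b - a <= gap_threshold:
            runs[-1].append(b)
        else:
            runs.append([b])
    for run in runs:
        if insertion_position in run:
            members = [p for p in run if p != insertion_position or p in flagged]
            members = [p for p in members if p in set(flagged)]
            if len(members) < 2:
                return None
            return (members[0], members[-1])
    return None
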