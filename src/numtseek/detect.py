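"""Detection of non-reference NUMT insertions from paired-end alignments.

Two evidence classes are used: discordant pairs (one mate on the mtDNA
contig, the other on a nuclear contig) and split reads (nuclear reads whose
soft-clipped segment matches mtDNA).  Supports on one chromosome whose
anchors lie within 2 kbp of each other are chained into one cluster; a
cluster becomes a call only when at least five clipped reads agree, and the
breakpoint is the modal clip coordinate.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class AlignmentRecord:
    """One read's mapping, SAM-like but format-agnostic.

    `sequence` is stored in reference-forward orientation (SAM convention);
    `cigar_clips` gives the soft-clipped base counts on each side of the
    aligned segment.
    """

    read_name: str
    contig: str
    position: int  # 1-based leftmost mapped base
    cigar_clips: tuple[int, int]
    mate_contig: str | None
    mate_position: int | None
    sequence: str
    base_qualities: list[int] | None = None
    is_mt: bool = False
    is_reverse: bool = False
    is_proper: bool = False
    template_length: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based")
        if min(self.cigar_clips) < 0:
            raise ValueError("clip lengths must be non-negative")
        if self.base_qualities is not None and len(self.base_qualities) != len(self.sequence):
            raise ValueError("sequence and base_qualities must have equal length")

    @property
    def aligned_length(self) -> int:
        return len(self.sequence) - self.cigar_clips[0] - self.cigar_clips[1]

    @property
    def end(self) -> int:
        """1-based rightmost aligned reference base."""
        return self.position + self.aligned_length - 1

    def clipped_segment(self, side: str) -> str:
        left, right = self.cigar_clips
        if side == "left":
            return self.sequence[:left]
        if side == "right":
            return self.sequence[len(self.sequence) - right :] if right else ""
        raise ValueError(side)


@dataclass
class Support:
    """One read supporting a candidate insertion on a nuclear chromosome."""

    chromosome: str
    anchor: int  # 1-based breakpoint estimate
    evidence: str  # "discordant" or "split"
    record: AlignmentRecord
    mt_sequence: str | None = None  # mt-derived bases carried by this support


@dataclass
class SupportCluster:
    chromosome: str
    anchor_positions: list[int]
    n_clipped: int
    member_reads: list[Support]

    def __post_init__(self) -> None:
        if self.n_clipped > len(self.member_reads):
            raise ValueError("n_clipped cannot exceed member count")


@dataclass
class NumtCall:
    numt_id: str
    chromosome: str
    insertion_position: int
    n_support: int
    n_clipped: int
    sample: str = "sample"
    genotype: str = "unknown"  # het | hom | unknown
    phase: str = "unphased"  # hap1 | hap2 | unphased
    cluster: SupportCluster | None = None


@dataclass
class InsertSizeMetrics:
    mean: float
    sd: float
    median: float
    n_pairs: int


def insert_size_metrics(alignments) -> InsertSizeMetrics:
    """Mean/sd/median of absolute template lengths over proper nuclear pairs.

    Discordant mtDNA/nuclear pairs are excluded; each pair is counted once
    (positive template length).
    """
    tlens = [
        abs(a.template_length)
        for a in alignments
        if a.is_proper and not a.is_mt and a.template_length > 0
    ]
    if not tlens:
        raise ValueError("no properly paired nuclear reads: cannot estimate insert size")
    arr = np.asarray(tlens, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return InsertSizeMetrics(
        mean=float(arr.mean()), sd=sd, median=float(np.median(arr)), n_pairs=len(arr)
    )


def clip_matches_mt(
    segment: str,
    mt_reference_doubled: str,
    max_divergence: float = 0.10,
) -> bool:
    """Does a soft-clipped segment align to the (doubled, circular) mtDNA?"""
    if not segment:
        return False
    max_ed = math.floor(max_divergence * len(segment))
    from .reconstruct import revcomp

    for q in (segment, revcomp(segment)):
        res = edlib.align(q, mt_reference_doubled, mode="HW", task="distance", k=max_ed)
        if res["editDistance"] != -1:
            return True
    return False


def find_supports(
    alignments,
    mt_contig: str = "MT",
    mt_reference: str | None = None,
    min_clip: int = 20,
    max_clip_divergence: float = 0.10,
    validate_discordant: bool = False,
) -> list[Support]:
    """Extract NUMT-supporting reads from an alignment stream.

    Two classes are returned:

    * ``discordant`` — an mtDNA-mapped read whose mate sits on a nuclear
      contig; the support is anchored at the nuclear mate's position.
    * ``split`` — a nuclear read with a soft-clipped segment of at least
      `min_clip` bases that matches the mtDNA reference (checked by
      semi-global alignment when `mt_reference` is given; any sufficiently
      long clip qualifies when it is not).  Anchored at the clip boundary:
      the last aligned base for a right clip, one base left of the first
      aligned base for a left clip, i.e. the reference base after which the
      novel sequence begins.
    """
    doubled = (mt_reference + mt_reference) if mt_reference else None
    supports: list[Support] = []
    for rec in alignments:
        if rec.is_mt:
            if rec.mate_contig is not None and rec.mate_contig != mt_contig:
                # only the aligned portion is mitochondrial; clipped tails of a
                # junction-spanning mt read are nuclear sequence
                l, r = rec.cigar_clips
                mt_seq = rec.sequence[l : len(rec.sequence) - r if r else None]
                if (
                    validate_discordant
                    and doubled is not None
                    and not clip_matches_mt(mt_seq, doubled, max_clip_divergence)
                ):
                    continue
                supports.append(
                    Support(
                        chromosome=rec.mate_contig,
                        anchor=rec.mate_position,
                        evidence="discordant",
                        record=rec,
                        mt_sequence=mt_seq,
                    )
                )
            continue
        left, right = rec.cigar_clips
        for side, cliplen in (("left", left), ("right", right)):
            if cliplen < min_clip:
                continue
            segment = rec.clipped_segment(side)
            if doubled is not None and not clip_matches_mt(
                segment, doubled, max_clip_divergence
            ):
                continue
            anchor = rec.position - 1 if side == "left" else rec.end
            supports.append(
                Support(
                    chromosome=rec.contig,
                    anchor=anchor,
                    evidence="split",
                    record=rec,
                    mt_sequence=segment,
                )
            )
    return supports


def cluster_supports(supports: list[Support], max_span: int = 2000) -> list[SupportCluster]:
    """Single-linkage chaining of supports along each chromosome.

    Consecutive anchors at most `max_span` apart join the same cluster;
    supports on different chromosomes never merge.  The result is invariant
    to the input order.
    """
    clusters: list[SupportCluster] = []
    by_key = sorted(supports, key=lambda s: (s.chromosome, s.anchor))
    current: list[Support] = []
    for sup in by_key:
        if (
            current
            and sup.chromosome == current[-1].chromosome
            and sup.anchor - current[-1].anchor <= max_span
        ):
            current.append(sup)
        else:
            if current:
                clusters.append(_make_cluster(current))
            current = [sup]
    if current:
        clusters.append(_make_cluster(current))
    return clusters


def _make_cluster(members: list[Support]) -> SupportCluster:
    return SupportCluster(
        chromosome=members[0].chromosome,
        anchor_positions=sorted(s.anchor for s in members),
        n_clipped=sum(1 for s in members if s.evidence == "split"),
        member_reads=list(members),
    )


def numt_name(chromosome: str, position: int) -> str:
    """First four digits of the insertion position, e.g. chr3:13848625 -> 3_1384."""
    return f"{chromosome}_{str(position)[:4]}"


def call_numt(
    cluster: SupportCluster,
    min_clipped: int = 5,
    sample: str = "sample",
    spanning_reads: int | None = None,
) -> NumtCall | None:
    """Emit a call when at least `min_clipped` clipped reads support the cluster.

    The insertion position is the modal clip coordinate (ties broken to the
    smallest).  Genotype: when the caller supplies the number of unclipped
    reference-spanning reads across the breakpoint (>=10 bp on each side),
    their presence marks the site heterozygous and their absence homozygous;
    without that information the genotype is unknown.
    """
    split = [s for s in cluster.member_reads if s.evidence == "split"]
    if len(split) < min_clipped:
        logger.info(
            "cluster on %s at %s discarded: %d clipped reads (< %d)",
            cluster.chromosome,
            cluster.anchor_positions[:1],
            len(split),
            min_clipped,
        )
        return None
    counts = Counter(s.anchor for s in split)
    top = max(counts.values())
    position = min(p for p, c in counts.items() if c == top)
    genotype = "unknown"
    if spanning_reads is not None:
        genotype = "het" if spanning_reads > 0 else "hom"
    return NumtCall(
        numt_id=numt_name(cluster.chromosome, position),
        chromosome=cluster.chromosome,
        insertion_position=position,
        n_support=len(cluster.member_reads),
        n_clipped=len(split),
        sample=sample,
        genotype=genotype,
        cluster=cluster,
    )


def count_spanning_reads(
    alignments, chromosome: str, position: int, min_span: int = 10
) -> int:
    """Unclipped reads covering >= min_span bases on both sides of a breakpoint."""
    n = 0
    for rec in alignments:
        if rec.is_mt or rec.contig != chromosome or rec.cigar_clips != (0, 0):
            continue
        if rec.position <= position - min_span + 1 and rec.end >= position + min_span:
            n += 1
    return n


# ---------------------------------------------------------------------------
# VCF output / input for calls


_VCF_HEADER = """##fileformat=VCFv4.2
##source=numtseek
##ALT=<ID=INS:MT,Description="Non-reference insertion of mitochondrial origin">
##INFO=<ID=NSUP,Number=1,Type=Integer,Description="Total supporting reads">
##INFO=<ID=NCLIP,Number=1,Type=Integer,Description="Clipped supporting reads">
##INFO=<ID=NUMTID,Number=1,Type=String,Description="NUMT name (chrom_first4digits)">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">
##INFO=<ID=GT2,Number=1,Type=String,Description="Genotype class (het/hom/unknown)">
##INFO=<ID=PHASE,Number=1,Type=String,Description="Haplotype of insertion (hap1/hap2/unphased)">
"""


def write_calls(calls: list[NumtCall], path: str | Path) -> None:
    """Write calls as symbolic <INS:MT> VCF records, positions ascending."""
    path = Path(path)
    recs = sorted(calls, key=lambda c: (c.chromosome, c.insertion_position))
    lines = [_VCF_HEADER]
    for chrom in sorted({c.chromosome for c in recs}):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for c in recs:
        info = (
            f"NSUP={c.n_support};NCLIP={c.n_clipped};NUMTID={c.numt_id};"
            f"SAMPLE={c.sample};GT2={c.genotype};PHASE={c.phase}"
        )
        lines.append(
            f"{c.chromosome}\t{c.insertion_position}\t{c.numt_id}\tN\t<INS:MT>\t.\tPASS\t{info}\n"
        )
    path.write_text("".join(lines))


def read_calls(path: str | Path) -> list[NumtCall]:
    """Read back a VCF produced by :func:`write_calls` (lossless round-trip)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            calls.append(
                NumtCall(
                    numt_id=str(info["NUMTID"]),
                    chromosome=rec.chrom,
                    insertion_position=rec.pos,
                    n_support=int(info["NSUP"]),
                    n_clipped=int(info["NCLIP"]),
                    sample=str(info["SAMPLE"]),
                    genotype=str(info["GT2"]),
                    phase=str(info["PHASE"]),
                )
            )
    return calls
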