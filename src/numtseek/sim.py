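"""Synthetic cohorts for exercising the NUMT pipeline at desk scale.

Three generators are provided:

* a hominin mtDNA panel on a star-like phylogeny (modern humans,
  Neanderthals, Denisovans, Sima de los Huesos, chimpanzee outgroup and an
  RSRS-style reference row), with the archaic-vs-modern divergence
  calibrated so that a 150 bp read differs by ~3.5 substitutions between
  the two groups;
* a diploid sample whose haplotypes carry NUMT insertions of known mtDNA
  source lineage and phase, sequenced into 150 bp read pairs with
  junction soft-clips recorded in an oracle alignment;
* a phased genotype panel in which chosen carrier samples bear an
  introgressed archaic haplotype, together with worldwide-style reference
  panels for the allele-frequency filter.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import AlignmentRecord, numt_name
from .introgression import ArchaicGenotypes, PhasedPanel
from .lineage import HomininPanel
from .reconstruct import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_QUAL = 37


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the sequencing regime the pipeline targets: 150 bp
    paired reads, ~350 bp templates (median insert below 400 bp), 30x
    coverage, and an archaic mtDNA divergence of 3.5/150 per base so an
    archaic read differs from a modern one by ~3.5 substitutions.
    """

    nuclear_length: int = 1_000_000
    mt_length: int = 16_569
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 30.0
    error_rate: float = 0.001
    archaic_divergence: float = 3.5 / 150.0
    within_diversity: float = 5e-4
    outgroup_divergence: float = 0.09
    snp_rate: float = 0.001
    n_modern_mt: int = 87
    n_neanderthal_mt: int = 17
    n_denisovan_mt: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nuclear_length, self.mt_length, self.read_length) <= 0:
            raise ValueError("all lengths must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if min(self.n_modern_mt, self.n_neanderthal_mt, self.n_denisovan_mt) < 2:
            raise ValueError("each required mtDNA lineage needs at least 2 panel members")


@dataclass
class TruthRecord:
    """Ground truth for one simulated NUMT insertion."""

    numt_id: str
    chromosome: str
    insertion_position: int  # 1-based: base after which the insert sits
    mt_source_lineage: str  # modern_human | neanderthal | denisovan | ancestral
    mt_start: int  # 1-based circular interval on the mt genome
    mt_end: int
    haplotype: str  # hap1 | hap2 | both
    introgressed_interval: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start + 1 if self.mt_end >= self.mt_start else 0

    def circular_length(self, mt_length: int) -> int:
        if self.mt_end >= self.mt_start:
            return self.mt_end - self.mt_start + 1
        return mt_length - self.mt_start + 1 + self.mt_end


# ---------------------------------------------------------------------------
# mtDNA panel


def _random_seq_arr(rng: np.random.Generator, length: int, gc: float = 0.45) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4, dtype=np.uint8), size=length, p=p)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson number of substitutions at distinct positions (no indels)."""
    out = seq.copy()
    n = min(rng.poisson(rate * len(seq)), len(seq))
    if n:
        pos = rng.choice(len(seq), size=n, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


@dataclass
class MtPanelSim:
    """A simulated hominin mtDNA panel plus its internal ancestral states."""

    panel: HomininPanel
    root_sequence: str  # hominin ancestor (source for "ancestral" NUMTs)
    rsrs_sequence: str  # the reference row; also the mt mapping reference
    config: SimConfig

    def source_sequence(self, lineage: str, index: int = 0) -> str:
        if lineage == "ancestral":
            return self.root_sequence
        rows = [
            s for s, l in zip(self.panel.sequences, self.panel.labels) if l == lineage
        ]
        if not rows:
            raise ValueError(f"no panel rows with lineage {lineage}")
        return rows[index % len(rows)]


def simulate_mt_panel(config: SimConfig) -> MtPanelSim:
    """Gap-free labelled mtDNA alignment on a star-like hominin phylogeny.

    Branch budget: the total modern-to-archaic path length equals
    `archaic_divergence`, split equally over the modern stem, the shared
    archaic stem and the lineage-specific archaic branch; tips add
    `within_diversity` private substitutions.  Sima de los Huesos branches
    midway along the Denisovan stem, so Denisovan+Sima form a clade.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.mt_length
    stem = config.archaic_divergence / 3.0
    w = config.within_diversity

    root = _random_seq_arr(rng, L)
    chimp = _mutate(root, config.outgroup_divergence, rng)
    modern_anc = _mutate(root, stem, rng)
    archaic_anc = _mutate(root, stem, rng)
    nea_anc = _mutate(archaic_anc, stem, rng)
    den_mid = _mutate(archaic_anc, stem / 2.0, rng)
    den_anc = _mutate(den_mid, stem / 2.0, rng)
    sima = _mutate(den_mid, stem / 2.0 + w, rng)

    names, labels, seqs = [], [], []
    names.append("RSRS")
    labels.append("reference")
    seqs.append(_to_str(modern_anc))
    for i in range(config.n_modern_mt):
        names.append(f"MH{i:03d}")
        labels.append("modern_human")
        seqs.append(_to_str(_mutate(modern_anc, w, rng)))
    for i in range(config.n_neanderthal_mt):
        names.append(f"NEA{i:02d}")
        labels.append("neanderthal")
        seqs.append(_to_str(_mutate(nea_anc, w, rng)))
    for i in range(config.n_denisovan_mt):
        names.append(f"DEN{i:02d}")
        labels.append("denisovan")
        seqs.append(_to_str(_mutate(den_anc, w, rng)))
    names.append("SIMA")
    labels.append("sima")
    seqs.append(_to_str(sima))
    names.append("CHIMP")
    labels.append("outgroup")
    seqs.append(_to_str(chimp))

    panel = HomininPanel(
        names=names, labels=labels, sequences=seqs, rsrs_column_map=np.arange(L)
    )
    return MtPanelSim(
        panel=panel,
        root_sequence=_to_str(root),
        rsrs_sequence=_to_str(modern_anc),
        config=config,
    )


def diagnostic_sites(panel: HomininPanel) -> dict[str, list[tuple[int, str]]]:
    """Branch-diagnostic mtDNA positions computed from the panel itself.

    For each archaic branch, a position is diagnostic when every member of
    the branch shares an allele carried by no modern human (and no member
    of the other archaic branch, for the lineage-specific sets).  Positions
    are 1-based.
    """
    def rows(label):
        return panel.rows_by_label(label)

    moderns = rows("modern_human") + rows("ancient_modern") + rows("reference")
    neas = rows("neanderthal")
    dens = rows("denisovan")
    simas = rows("sima")
    out: dict[str, list[tuple[int, str]]] = {
        "neanderthal": [], "denisovan": [], "sima": [], "denisovan_sima": [],
        "archaic": [],
    }
    L = panel.mt_length
    for p in range(L):
        col = lambda group: {s[p] for s in group}
        m = col(moderns)
        nset, dset, sset = col(neas), col(dens), col(simas)
        if len(nset) == 1 and not nset & (m | dset | sset):
            out["neanderthal"].append((p + 1, next(iter(nset))))
        if len(dset) == 1 and not dset & (m | nset | sset):
            out["denisovan"].append((p + 1, next(iter(dset))))
        if sset and len(sset) == 1 and not sset & (m | nset | dset):
            out["sima"].append((p + 1, next(iter(sset))))
        ds = dset | sset
        if len(ds) == 1 and not ds & (m | nset):
            out["denisovan_sima"].append((p + 1, next(iter(ds))))
        arch = nset | dset | sset
        if len(arch) == 1 and not arch & m:
            out["archaic"].append((p + 1, next(iter(arch))))
    return out


def circular_slice(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice of a circular sequence; start > end wraps."""
    if start <= end:
        return seq[start - 1 : end]
    return seq[start - 1 :] + seq[:end]


# ---------------------------------------------------------------------------
# Diploid sample with NUMT insertions


@dataclass
class _Piece:
    hap_start: int  # 0-based offset in the haplotype sequence
    length: int
    is_mt: bool
    ref_start: int  # 0-based: nuclear coordinate, or virtual mt offset
    numt_id: str | None = None


@dataclass
class Haplotype:
    sequence: str
    pieces: list[_Piece]

    def piece_starts(self) -> np.ndarray:
        return np.array([p.hap_start for p in self.pieces])


def _build_haplotype(
    nuclear: np.ndarray,
    snp_positions: np.ndarray,
    snp_alt_codes: np.ndarray,
    snp_on_hap: np.ndarray,
    hap_index: int,
    truths: list[TruthRecord],
    inserts: dict[str, str],
) -> Haplotype:
    seq = nuclear.copy()
    mine = snp_on_hap == hap_index
    seq[snp_positions[mine] - 1] = snp_alt_codes[mine]
    nuc = _to_str(seq)

    parts: list[str] = []
    pieces: list[_Piece] = []
    cursor_ref = 0  # 0-based nuclear coordinate consumed so far
    cursor_hap = 0
    label = f"hap{hap_index + 1}"
    for t in sorted(truths, key=lambda t: t.insertion_position):
        if t.haplotype not in ("both", label):
            continue
        ins = inserts[t.numt_id]
        left = nuc[cursor_ref : t.insertion_position]
        if left:
            pieces.append(_Piece(cursor_hap, len(left), False, cursor_ref))
            parts.append(left)
            cursor_hap += len(left)
        pieces.append(
            _Piece(cursor_hap, len(ins), True, t.mt_start - 1, numt_id=t.numt_id)
        )
        parts.append(ins)
        cursor_hap += len(ins)
        cursor_ref = t.insertion_position
    tail = nuc[cursor_ref:]
    if tail:
        pieces.append(_Piece(cursor_hap, len(tail), False, cursor_ref))
        parts.append(tail)
    return Haplotype(sequence="".join(parts), pieces=pieces)


def _place_read(hap: Haplotype, starts: np.ndarray, s: int, rl: int, mt_length: int):
    """Oracle placement of the read at haplotype offset `s` (0-based).

    Returns (contig_is_mt, position, (left_clip, right_clip)).  The aligned
    segment is the longest run of the read inside one piece; the rest is
    soft-clipped, which is exactly what an aligner does at an insertion
    junction.
    """
    i0 = int(np.searchsorted(starts, s, side="right")) - 1
    i1 = int(np.searchsorted(starts, s + rl - 1, side="right")) - 1
    best = None
    for i in range(i0, i1 + 1):
        p = hap.pieces[i]
        ov_s = max(s, p.hap_start)
        ov_e = min(s + rl, p.hap_start + p.length)
        if ov_e - ov_s <= 0:
            continue
        if best is None or (ov_e - ov_s) > best[1]:
            best = (i, ov_e - ov_s, ov_s)
    i, ov_len, ov_s = best
    p = hap.pieces[i]
    lclip = ov_s - s
    rclip = rl - lclip - ov_len
    if not p.is_mt:
        pos = p.ref_start + (ov_s - p.hap_start) + 1
        return False, pos, (lclip, rclip)
    v = p.ref_start + (ov_s - p.hap_start)
    p0 = v % mt_length
    if p0 + ov_len <= mt_length:
        return True, p0 + 1, (lclip, rclip)
    left_len = mt_length - p0
    right_len = ov_len - left_len
    if left_len >= right_len:
        return True, p0 + 1, (lclip, rclip + right_len)
    return True, 1, (lclip + left_len, rclip)


@dataclass
class SampleSim:
    """One simulated diploid sample: haplotypes, truth and read streams."""

    config: SimConfig
    sample: str
    chrom: str
    mt_contig: str
    truths: list[TruthRecord]
    haplotypes: list[Haplotype]
    het_positions: np.ndarray  # 1-based nuclear SNP positions
    het_ref: list[str]
    het_alt: list[str]
    het_hap_with_alt: np.ndarray  # 0 or 1
    mt_reference: str

    _n_pairs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        rl = self.config.read_length
        self._n_pairs = [
            int(round(self.config.coverage / 2.0 * len(h.sequence) / (2 * rl)))
            for h in self.haplotypes
        ]

    @property
    def n_pairs(self) -> int:
        return sum(self._n_pairs)

    def read_pairs(self):
        """Deterministic stream of (name, hap_index, start, template_length)."""
        cfg = self.config
        rl = cfg.read_length
        for h, hap in enumerate(self.haplotypes):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 3, h])
            )
            hap_len = len(hap.sequence)
            n = self._n_pairs[h]
            chunk = 200_000
            made = 0
            while made < n:
                m = min(chunk, n - made)
                tlens = rng.normal(cfg.insert_mean, cfg.insert_sd, size=m)
                tlens = np.clip(np.rint(tlens), rl, max(rl, hap_len)).astype(np.int64)
                starts = np.floor(
                    rng.random(m) * (hap_len - tlens + 1)
                ).astype(np.int64)
                nerr = rng.binomial(2 * rl, cfg.error_rate, size=m)
                for j in range(m):
                    name = f"{self.sample}:{h}:{made + j}"
                    yield name, h, int(starts[j]), int(tlens[j]), int(nerr[j]), rng
                made += m

    def alignments(self):
        """Oracle alignment records for all read pairs (SAM-equivalent)."""
        cfg = self.config
        rl = cfg.read_length
        mtL = cfg.mt_length
        starts_by_hap = [h.piece_starts() for h in self.haplotypes]
        for name, h, s, tlen, nerr, rng in self.read_pairs():
            hap = self.haplotypes[h]
            s2 = s + tlen - rl
            seq1 = hap.sequence[s : s + rl]
            seq2 = hap.sequence[s2 : s2 + rl]
            if nerr:
                seq1, seq2 = _apply_pair_errors(seq1, seq2, nerr, rng)
            m1 = _place_read(hap, starts_by_hap[h], s, rl, mtL)
            m2 = _place_read(hap, starts_by_hap[h], s2, rl, mtL)
            c1 = self.mt_contig if m1[0] else self.chrom
            c2 = self.mt_contig if m2[0] else self.chrom
            proper = c1 == c2 and m1[2] == (0, 0) and m2[2] == (0, 0)
            if proper:
                left = min(m1[1], m2[1])
                right = max(m1[1] + rl - 1, m2[1] + rl - 1)
                span = right - left + 1
            else:
                span = 0
            rec1 = AlignmentRecord(
                read_name=name, contig=c1, position=m1[1], cigar_clips=m1[2],
                mate_contig=c2, mate_position=m2[1], sequence=seq1,
                is_mt=m1[0], is_reverse=False, is_proper=proper,
                template_length=span if proper else 0,
            )
            rec2 = AlignmentRecord(
                read_name=name, contig=c2, position=m2[1], cigar_clips=m2[2],
                mate_contig=c1, mate_position=m1[1], sequence=seq2,
                is_mt=m2[0], is_reverse=True, is_proper=proper,
                template_length=-span if proper else 0,
            )
            yield rec1
            yield rec2

    # -- file output -------------------------------------------------------

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        q = chr(_DEFAULT_QUAL + 33) * self.config.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for rec in self.alignments():
                if rec.is_reverse:
                    f2.write(f"@{rec.read_name}/2\n{revcomp(rec.sequence)}\n+\n{q}\n")
                else:
                    f1.write(f"@{rec.read_name}/1\n{rec.sequence}\n+\n{q}\n")

    def write_sam(self, path: str | Path) -> None:
        from .io import write_sam_records

        write_sam_records(
            sorted(self.alignments(), key=lambda r: (r.contig, r.position)),
            path,
            contigs={self.chrom: self.config.nuclear_length, self.mt_contig: self.config.mt_length},
            mt_contig=self.mt_contig,
            default_qual=_DEFAULT_QUAL,
        )

    def write_vcf(self, path: str | Path) -> None:
        lines = [
            "##fileformat=VCFv4.2\n",
            "##source=numtseek-sim\n",
            f"##contig=<ID={self.chrom},length={self.config.nuclear_length}>\n",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{self.sample}\n",
        ]
        for pos, r, a, h in zip(
            self.het_positions, self.het_ref, self.het_alt, self.het_hap_with_alt
        ):
            gt = "1|0" if h == 0 else "0|1"
            lines.append(f"{self.chrom}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t.\tGT\t{gt}\n")
        Path(path).write_text("".join(lines))

    def write_truth(self, path: str | Path) -> None:
        header = (
            "numt_id\tchromosome\tinsertion_position\tmt_source_lineage\t"
            "mt_start\tmt_end\thaplotype\tintrogressed_start\tintrogressed_end\n"
        )
        rows = [header]
        for t in self.truths:
            iv = t.introgressed_interval or ("", "")
            rows.append(
                f"{t.numt_id}\t{t.chromosome}\t{t.insertion_position}\t"
                f"{t.mt_source_lineage}\t{t.mt_start}\t{t.mt_end}\t{t.haplotype}\t"
                f"{iv[0]}\t{iv[1]}\n"
            )
        Path(path).write_text("".join(rows))

    def het_sites(self) -> dict[int, tuple[str, str]]:
        return {
            int(p): (r, a)
            for p, r, a in zip(self.het_positions, self.het_ref, self.het_alt)
        }

    def hap_of_alt(self) -> dict[int, int]:
        return {
            int(p): int(h)
            for p, h in zip(self.het_positions, self.het_hap_with_alt)
        }


def _apply_pair_errors(seq1: str, seq2: str, nerr: int, rng: np.random.Generator):
    rl = len(seq1)
    joined = bytearray((seq1 + seq2).encode())
    pos = rng.integers(0, 2 * rl, size=nerr)
    for p in pos:
        old = joined[p]
        idx = int(np.where(_BASES == old)[0][0]) if old in _BASES else 0
        joined[p] = int(_BASES[(idx + int(rng.integers(1, 4))) % 4])
    s = joined.decode()
    return s[:rl], s[rl:]


def simulate_sample(
    config: SimConfig,
    truths: list[TruthRecord],
    panel: MtPanelSim,
    sample: str = "S0",
    chrom: str = "1",
    mt_contig: str = "MT",
    min_spacing: int = 50_000,
) -> SampleSim:
    """Simulate one diploid sample carrying the given NUMT insertions.

    Insertion sites must be pairwise at least `min_spacing` apart (matching
    the observed spacing of real polymorphic NUMTs) and inside the nuclear
    contig; violations raise ValueError.
    """
    pos = sorted(t.insertion_position for t in truths)
    for a, b in zip(pos, pos[1:]):
        if b - a < min_spacing:
            raise ValueError(f"truth insertions {a} and {b} closer than {min_spacing} bp")
    for t in truths:
        if not 1 <= t.insertion_position <= config.nuclear_length:
            raise ValueError("insertion_position outside the nuclear contig")
        if t.circular_length(config.mt_length) < 1:
            raise ValueError("empty mt interval")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    nuclear = _random_seq_arr(rng, config.nuclear_length, gc=0.41)

    n_snp = rng.poisson(config.snp_rate * config.nuclear_length)
    snp_pos = np.sort(
        rng.choice(config.nuclear_length, size=min(n_snp, config.nuclear_length), replace=False)
    ) + 1
    ref_codes = nuclear[snp_pos - 1]
    alt_codes = (ref_codes + rng.integers(1, 4, size=len(snp_pos))) % 4
    on_hap = rng.integers(0, 2, size=len(snp_pos))

    inserts = {
        t.numt_id: circular_slice(
            panel.source_sequence(t.mt_source_lineage), t.mt_start, t.mt_end
        )
        for t in truths
    }
    haplotypes = [
        _build_haplotype(nuclear, snp_pos, alt_codes, on_hap, h, truths, inserts)
        for h in (0, 1)
    ]
    return SampleSim(
        config=config,
        sample=sample,
        chrom=chrom,
        mt_contig=mt_contig,
        truths=list(truths),
        haplotypes=haplotypes,
        het_positions=snp_pos,
        het_ref=[chr(c) for c in _BASES[ref_codes]],
        het_alt=[chr(c) for c in _BASES[alt_codes]],
        het_hap_with_alt=on_hap,
        mt_reference=panel.rsrs_sequence,
    )


def random_truths(
    config: SimConfig,
    rng: np.random.Generator,
    n_modern: int = 0,
    n_neanderthal: int = 0,
    n_denisovan: int = 0,
    n_ancestral: int = 0,
    length_range: tuple[int, int] = (100, 700),
    min_spacing: int = 50_000,
    chrom: str = "1",
    min_length_by_lineage: dict[str, int] | None = None,
) -> list[TruthRecord]:
    """Draw a valid truth table: spaced insertion sites, random circular mt
    intervals, random haplotype labels."""
    lineages = (
        ["modern_human"] * n_modern
        + ["neanderthal"] * n_neanderthal
        + ["denisovan"] * n_denisovan
        + ["ancestral"] * n_ancestral
    )
    n = len(lineages)
    margin = 2 * config.read_length + int(config.insert_mean + 4 * config.insert_sd)
    lo, hi = margin, config.nuclear_length - margin
    if n == 0:
        return []
    g = (hi - lo) / n
    if g < min_spacing:
        raise ValueError("nuclear contig too short for the requested spacing")
    # jittered grid: consecutive sites differ by at least g - (g - spacing) = spacing
    slots = lo + np.arange(n) * g
    jitter = rng.integers(0, max(int(g - min_spacing), 1), size=n)
    positions = (slots + jitter).astype(int)
    rng.shuffle(lineages)
    truths = []
    for p, lin in zip(positions, lineages):
        floor_len = (min_length_by_lineage or {}).get(lin, length_range[0])
        length = int(rng.integers(floor_len, length_range[1] + 1))
        start = int(rng.integers(1, config.mt_length + 1))
        end = start + length - 1
        if end > config.mt_length:
            end -= config.mt_length
        hap = ["hap1", "hap2", "both"][int(rng.integers(0, 3))]
        truths.append(
            TruthRecord(
                numt_id=numt_name(chrom, int(p)),
                chromosome=chrom,
                insertion_position=int(p),
                mt_source_lineage=lin,
                mt_start=start,
                mt_end=end,
                haplotype=hap,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Introgressed phased panel


@dataclass
class IntrogressionSim:
    panel: PhasedPanel
    archaic: ArchaicGenotypes
    reference_panels: dict[str, PhasedPanel]
    carrier_haps: dict[str, int]  # sample -> haplotype index carrying the NUMT
    insertion_position: int
    interval: tuple[int, int]
    null_samples: set[str] = field(default_factory=set)


def simulate_introgressed_panel(
    config: SimConfig,
    carriers: list[str],
    interval: tuple[int, int],
    n_samples: int = 100,
    insertion_position: int | None = None,
    n_reference_samples: int = 250,
    intro_density: float = 1.5e-3,
    homoplasy_density: float = 1.0e-3,
    modern_density: float = 1.0e-3,
    flank: int = 25_000,
    freq_threshold: float = 0.05,
) -> IntrogressionSim:
    """Phased panel with an introgressed archaic haplotype in the carriers.

    Inside `interval`, carrier haplotypes share archaic non-reference
    alleles whose frequency in both worldwide-style reference panels is
    kept strictly below `freq_threshold`.  Outside the interval,
    archaic-shared alleles stand in for homoplasy / incomplete lineage
    sorting and are placed at high frequency everywhere.  Carrier samples
    are heterozygous: one haplotype carries the archaic segment.
    """
    if not 1 <= interval[0] < interval[1] <= config.nuclear_length:
        raise ValueError("interval must lie within the nuclear contig")
    samples = [f"P{i:03d}" for i in range(n_samples)]
    missing = [c for c in carriers if c not in samples]
    if missing:
        raise ValueError(f"carriers not in panel: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    insertion = (
        insertion_position
        if insertion_position is not None
        else (interval[0] + interval[1]) // 2
    )

    span_lo = max(1, interval[0] - flank)
    span_hi = min(config.nuclear_length, interval[1] + flank)

    def draw_positions(lo, hi, density):
        n = rng.poisson(density * max(hi - lo, 0))
        return rng.integers(lo, hi + 1, size=n)

    intro_pos = (
        draw_positions(interval[0], interval[1], intro_density) if carriers else np.array([], dtype=int)
    )
    homo_pos = np.concatenate([
        draw_positions(span_lo, interval[0] - 1, homoplasy_density),
        draw_positions(interval[1] + 1, span_hi, homoplasy_density),
    ])
    modern_pos = draw_positions(span_lo, span_hi, modern_density)

    sites = []  # (position, category)
    used = set()
    for cat, arr in (("intro", intro_pos), ("homo", homo_pos), ("modern", modern_pos)):
        for p in np.sort(arr):
            p = int(p)
            if p in used:
                continue
            used.add(p)
            sites.append((p, cat))
    sites.sort()
    n_sites = len(sites)
    positions = np.array([p for p, _ in sites], dtype=np.int64)
    cats = [c for _, c in sites]

    ref_alleles, alt_alleles = [], []
    for _ in range(n_sites):
        r, a = rng.choice(4, size=2, replace=False)
        ref_alleles.append(chr(_BASES[r]))
        alt_alleles.append(chr(_BASES[a]))

    n_hap = 2 * n_samples
    gt = np.zeros((n_sites, n_hap), dtype=np.int8)
    carrier_haps = {c: int(rng.integers(0, 2)) for c in carriers}
    carrier_cols = [2 * samples.index(c) + h for c, h in carrier_haps.items()]
    carries_alt = np.zeros(n_sites, dtype=bool)

    homo_freq = rng.uniform(0.2, 0.6, size=n_sites)
    modern_freq = rng.uniform(0.05, 0.4, size=n_sites)

    for i, cat in enumerate(cats):
        if cat == "intro":
            gt[i, carrier_cols] = 1
            carries_alt[i] = True
        elif cat == "homo":
            gt[i] = (rng.random(n_hap) < homo_freq[i]).astype(np.int8)
            carries_alt[i] = True
        else:
            gt[i] = (rng.random(n_hap) < modern_freq[i]).astype(np.int8)

    panel = PhasedPanel(
        positions=positions, ref=ref_alleles, alt=alt_alleles, gt=gt, samples=samples
    )
    archaic = ArchaicGenotypes(
        positions=positions.copy(), ref=list(ref_alleles), alt=list(alt_alleles),
        carries_alt=carries_alt,
    )

    reference_panels = {}
    for study in ("study1", "study2"):
        rn = 2 * n_reference_samples
        rgt = np.zeros((n_sites, rn), dtype=np.int8)
        cap = int(np.ceil(freq_threshold * rn)) - 1
        for i, cat in enumerate(cats):
            if cat == "intro":
                k = min(rng.binomial(rn, rng.uniform(0.0, 0.04)), cap)
            elif cat == "homo":
                k = rng.binomial(rn, homo_freq[i])
            else:
                k = rng.binomial(rn, modern_freq[i])
            if k:
                rgt[i, rng.choice(rn, size=k, replace=False)] = 1
        reference_panels[study] = PhasedPanel(
            positions=positions.copy(), ref=list(ref_alleles), alt=list(alt_alleles),
            gt=rgt, samples=[f"{study}_{j:03d}" for j in range(n_reference_samples)],
        )

    null_samples = {s for s in samples if s not in carrier_haps}
    return IntrogressionSim(
        panel=panel,
        archaic=archaic,
        reference_panels=reference_panels,
        carrier_haps=carrier_haps,
        insertion_position=insertion,
        interval=interval,
        null_samples=null_samples,
    )
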