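"""Readers and writers for the pipeline's file formats.

Text SAM / VCF / FASTA / TSV only; parsing of SAM and VCF goes through
pysam, FASTA through scikit-bio.  Every writer is the inverse of the
corresponding reader on the domain types.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import skbio

from .detect import AlignmentRecord
from .introgression import ArchaicGenotypes, PhasedPanel
from .lineage import HomininPanel

# ---------------------------------------------------------------------------
# SAM


def write_sam_records(
    records,
    path: str | Path,
    contigs: dict[str, int],
    mt_contig: str = "MT",
    default_qual: int = 37,
) -> None:
    """Write AlignmentRecords as a coordinate-sorted text SAM."""
    recs = sorted(records, key=lambda r: (r.contig, r.position))
    lines = ["@HD\tVN:1.6\tSO:coordinate\n"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}\n")
    for r in recs:
        flag = 0x1
        if r.is_proper:
            flag |= 0x2
        if r.is_reverse:
            flag |= 0x10
        else:
            flag |= 0x20
        flag |= 0x80 if r.is_reverse else 0x40
        left, right = r.cigar_clips
        cigar = ""
        if left:
            cigar += f"{left}S"
        cigar += f"{len(r.sequence) - left - right}M"
        if right:
            cigar += f"{right}S"
        rnext = "=" if r.mate_contig == r.contig else (r.mate_contig or "*")
        qual = (
            "".join(chr(q + 33) for q in r.base_qualities)
            if r.base_qualities is not None
            else chr(default_qual + 33) * len(r.sequence)
        )
        lines.append(
            f"{r.read_name}\t{flag}\t{r.contig}\t{r.position}\t60\t{cigar}\t"
            f"{rnext}\t{r.mate_position or 0}\t{r.template_length}\t{r.sequence}\t{qual}\n"
        )
    Path(path).write_text("".join(lines))


def read_sam_records(path: str | Path, mt_contig: str = "MT") -> list[AlignmentRecord]:
    """Load a SAM file into AlignmentRecords (soft clips from the CIGAR).

    Malformed alignment lines raise ValueError naming the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 11:
                raise ValueError(f"malformed SAM record at line {lineno} of {path}")
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            ct = aln.cigartuples or []
            left = ct[0][1] if ct and ct[0][0] == 4 else 0
            right = ct[-1][1] if ct and ct[-1][0] == 4 else 0
            quals = list(aln.query_qualities) if aln.query_qualities is not None else None
            out.append(
                AlignmentRecord(
                    read_name=aln.query_name,
                    contig=aln.reference_name,
                    position=aln.reference_start + 1,
                    cigar_clips=(left, right),
                    mate_contig=(
                        aln.next_reference_name if aln.next_reference_id >= 0 else None
                    ),
                    mate_position=(
                        aln.next_reference_start + 1 if aln.next_reference_id >= 0 else None
                    ),
                    sequence=aln.query_sequence,
                    base_qualities=quals,
                    is_mt=aln.reference_name == mt_contig,
                    is_reverse=aln.is_reverse,
                    is_proper=aln.is_proper_pair,
                    template_length=aln.template_length,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(entries: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out = {}
    for seq in skbio.io.read(str(path), format="fasta", verify=False):
        out[seq.metadata["id"]] = str(seq)
    return out


def write_panel_fasta(panel: HomininPanel, path: str | Path) -> None:
    """Aligned panel FASTA with `>name|lineage` headers."""
    entries = {
        f"{n}|{l}": s for n, l, s in zip(panel.names, panel.labels, panel.sequences)
    }
    write_fasta(entries, path)


def read_panel_fasta(path: str | Path) -> HomininPanel:
    names, labels, seqs = [], [], []
    for header, seq in read_fasta(path).items():
        name, _, label = header.partition("|")
        names.append(name)
        labels.append(label)
        seqs.append(seq)
    return HomininPanel.from_alignment(names, labels, seqs)


# ---------------------------------------------------------------------------
# Phased VCF


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2\n",
        "##source=numtseek\n",
        f"##contig=<ID={panel.chrom}>\n",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.samples)
        + "\n",
    ]
    for i, pos in enumerate(panel.positions):
        sep = "|" if panel.phased[i] else "/"
        gts = "\t".join(
            f"{panel.gt[i, 2 * j]}{sep}{panel.gt[i, 2 * j + 1]}"
            for j in range(len(panel.samples))
        )
        lines.append(
            f"{panel.chrom}\t{pos}\t.\t{panel.ref[i]}\t{panel.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


def load_phased_vcf(path: str | Path) -> PhasedPanel:
    positions, ref, alt, rows, phased = [], [], [], [], []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            chrom = rec.chrom
            positions.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0] if rec.alts else ".")
            row = []
            site_phased = True
            for s in samples:
                call = rec.samples[s]
                alleles = call["GT"]
                site_phased = site_phased and bool(call.phased)
                row.extend(a if a is not None else 0 for a in alleles)
            rows.append(row)
            phased.append(site_phased)
    return PhasedPanel(
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        gt=np.asarray(rows, dtype=np.int8),
        samples=samples,
        chrom=chrom,
        phased=np.asarray(phased, dtype=bool),
    )


def write_archaic_vcf(arch: ArchaicGenotypes, path: str | Path, sample: str = "ARCHAIC") -> None:
    lines = [
        "##fileformat=VCFv4.2\n",
        "##source=numtseek\n",
        f"##contig=<ID={arch.chrom}>\n",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n",
    ]
    for i, pos in enumerate(arch.positions):
        gt = "1/1" if arch.carries_alt[i] else "0/0"
        lines.append(
            f"{arch.chrom}\t{pos}\t.\t{arch.ref[i]}\t{arch.alt[i]}\t.\tPASS\t.\tGT\t{gt}\n"
        )
    Path(path).write_text("".join(lines))


def load_archaic_vcf(path: str | Path) -> ArchaicGenotypes:
    positions, ref, alt, carries = [], [], [], []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            chrom = rec.chrom
            positions.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0] if rec.alts else ".")
            gt = rec.samples[sample]["GT"]
            carries.append(any(a not in (0, None) for a in gt))
    return ArchaicGenotypes(
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        carries_alt=np.asarray(carries, dtype=bool),
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# Newick


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def read_newick(path: str | Path):
    from skbio.tree import TreeNode

    return TreeNode.read(str(path))


# ---------------------------------------------------------------------------
# Truth tables


def read_truth_tsv(path: str | Path):
    from .sim import TruthRecord

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        iv = None
        if not (pd.isna(row.get("introgressed_start")) or row.get("introgressed_start") == ""):
            iv = (int(row["introgressed_start"]), int(row["introgressed_end"]))
        out.append(
            TruthRecord(
                numt_id=str(row["numt_id"]),
                chromosome=str(row["chromosome"]),
                insertion_position=int(row["insertion_position"]),
                mt_source_lineage=str(row["mt_source_lineage"]),
                mt_start=int(row["mt_start"]),
                mt_end=int(row["mt_end"]),
                haplotype=str(row["haplotype"]),
                introgressed_interval=iv,
            )
        )
    return out
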