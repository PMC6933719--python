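"""End-to-end orchestration: detect -> reconstruct -> classify -> phase ->
introgression, with a machine-readable run manifest.

Each stage is a thin wrapper over the corresponding module so that scripts
and tests can also run stages individually.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .detect import NumtCall, call_numt, cluster_supports, find_supports
from .introgression import (
    IntrogressionSummary,
    PhaseCall,
    carrier_vs_noncarrier_test,
    infer_phase,
    match_ratio,
    null_distribution,
    phase_votes_from_reads,
)
from .lineage import (
    LineageCall,
    add_numt_row,
    build_tree,
    classify,
    dedupe_alignment,
    extract_region_circular,
)
from .reconstruct import (
    NumtSequence,
    SeedIndex,
    call_consensus,
    concatenate_fragments,
    map_supports_to_mt,
    pad_circular_reference,
    qc_filter,
)


def detect_sample(
    sample_sim, config: PipelineConfig, genotype: bool = True
) -> list[NumtCall]:
    """Run support finding, clustering and calling on one simulated sample.

    With `genotype=True` a second pass over the alignments counts unclipped
    reference-spanning reads at each called breakpoint to separate het from
    hom insertions.
    """
    supports = find_supports(
        sample_sim.alignments(),
        mt_contig=sample_sim.mt_contig,
        mt_reference=sample_sim.mt_reference,
    )
    clusters = cluster_supports(supports, max_span=config.cluster_span)
    calls = []
    for cl in clusters:
        c = call_numt(cl, min_clipped=config.min_clipped_reads, sample=sample_sim.sample)
        if c is not None:
            calls.append(c)
    if genotype and calls:
        spanning = {(c.chromosome, c.insertion_position): 0 for c in calls}
        for rec in sample_sim.alignments():
            if rec.is_mt or rec.cigar_clips != (0, 0):
                continue
            for (chrom, pos), _ in spanning.items():
                if (
                    rec.contig == chrom
                    and rec.position <= pos - 9
                    and rec.end >= pos + 10
                ):
                    spanning[(chrom, pos)] += 1
        for c in calls:
            n = spanning[(c.chromosome, c.insertion_position)]
            c.genotype = "het" if n > 0 else "hom"
    return calls


def reconstruct_call(
    call: NumtCall,
    mt_reference: str,
    config: PipelineConfig,
    seed_index: SeedIndex | None = None,
) -> tuple[NumtSequence, object]:
    """Rebuild the NUMT consensus from the call's supporting reads."""
    ref = pad_circular_reference(mt_reference, pad=config.circular_pad)
    mt_seqs = [s.mt_sequence for s in call.cluster.member_reads if s.mt_sequence]
    pile = map_supports_to_mt(mt_seqs, ref, seed_index=seed_index)
    frags = call_consensus(pile, min_depth=config.min_fragment_coverage)
    seq = concatenate_fragments(call.numt_id, frags, mt_length=len(mt_reference))
    decision = qc_filter(
        seq, min_len=config.min_sequence_length, min_mean_depth=config.min_mean_depth
    )
    return seq, decision


def numt_region_row(seq: NumtSequence, mt_length: int) -> tuple[int, int, str]:
    """The consensus laid out over its covered mt region, gaps at holes.

    Returns (region_start, region_end, row); the region runs circularly
    from the first fragment's start to the last fragment's end in the
    concatenation order.
    """
    if not seq.fragments:
        raise ValueError("no fragments")
    frags = seq.fragments
    start = frags[0].start
    end = frags[-1].end
    length = end - start + 1 if end >= start else mt_length - start + 1 + end
    covered: dict[int, str] = {}
    for f in frags:
        for i in range(len(f)):
            pos = f.start + i
            if pos > mt_length:
                pos -= mt_length
            covered[pos] = f.sequence[i]
    row = []
    pos = start
    for _ in range(length):
        row.append(covered.get(pos, "-"))
        pos = pos + 1 if pos < mt_length else 1
    return start, end, "".join(row)


def classify_numt(
    seq: NumtSequence,
    panel,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> LineageCall:
    """Place one reconstructed NUMT on the hominin mtDNA tree."""
    start, end, row = numt_region_row(seq, panel.mt_length)
    rows = extract_region_circular(panel, start, end)
    numt_row_name = f"NUMT_{seq.numt_id}"
    rows = add_numt_row(rows, numt_row_name, row)
    clean = dedupe_alignment(rows)
    numt_name = next(
        n for n, labs in zip(clean.names, clean.labels) if "numt" in labs
    )
    tree = build_tree(
        clean,
        panel.outgroup_name,
        n_bootstrap=config.bootstrap_reps,
        rng=rng if rng is not None else np.random.default_rng(config.seed),
    )
    return classify(
        tree, clean, numt_name, bootstrap_gate=config.bootstrap_gate, numt_id=seq.numt_id
    )


def phase_call(call: NumtCall, sample_sim, config: PipelineConfig) -> PhaseCall:
    """Assign the insertion to a haplotype from its split reads' alleles."""
    split_records = [
        s.record for s in call.cluster.member_reads if s.evidence == "split"
    ]
    votes = phase_votes_from_reads(
        split_records, sample_sim.het_sites(), sample_sim.hap_of_alt()
    )
    pc = infer_phase(
        call.numt_id,
        call.sample,
        votes,
        majority=config.phase_majority,
        min_reads=config.phase_min_reads,
    )
    call.phase = pc.haplotype
    return pc


@dataclass
class PipelineResult:
    calls: list[NumtCall] = field(default_factory=list)
    sequences: dict[str, NumtSequence] = field(default_factory=dict)
    qc: dict[str, object] = field(default_factory=dict)
    lineages: dict[str, LineageCall] = field(default_factory=dict)
    phases: dict[str, PhaseCall] = field(default_factory=dict)
    introgression: object | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    samples: list,
    panel,
    mt_reference: str,
    outdir: str | Path | None = None,
    introgression_sim=None,
    genotype: bool = True,
) -> PipelineResult:
    """Run all stages over a cohort of simulated samples.

    `panel` is the labelled hominin alignment; `mt_reference` the RSRS-style
    mtDNA used for the circular remap.  When `introgression_sim` is absent
    the introgression stage is reported as skipped rather than failing.
    """
    result = PipelineResult()
    stages = []
    rng = np.random.default_rng(config.seed)
    ref = pad_circular_reference(mt_reference, pad=config.circular_pad)
    seed_index = SeedIndex(ref)

    try:
        for sim in samples:
            result.calls.extend(detect_sample(sim, config, genotype=genotype))
        stages.append("detect")

        for call in result.calls:
            key = f"{call.sample}:{call.numt_id}"
            seq, decision = reconstruct_call(
                call, mt_reference, config, seed_index=seed_index
            )
            result.sequences[key] = seq
            result.qc[key] = decision
        stages.append("reconstruct")

        for key, seq in result.sequences.items():
            if result.qc[key].keep and seq.fragments:
                result.lineages[key] = classify_numt(seq, panel, config, rng=rng)
        stages.append("classify")

        sims_by_name = {s.sample: s for s in samples}
        for call in result.calls:
            sim = sims_by_name[call.sample]
            result.phases[f"{call.sample}:{call.numt_id}"] = phase_call(
                call, sim, config
            )
        stages.append("phase")

        if introgression_sim is not None:
            result.introgression = introgression_analysis(
                introgression_sim, config
            )
            stages.append("introgression")
        else:
            stages.append("introgression:skipped")
    except Exception as exc:  # annotate which stage broke
        done = stages[-1] if stages else "start"
        raise RuntimeError(f"pipeline failed after stage '{done}': {exc}") from exc

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    result.manifest = {
        "stages": stages,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"numtseek": __version__, "numpy": np.__version__},
        "n_samples": len(samples),
        "n_calls": len(result.calls),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
        _write_tables(result, outdir)
    return result


def introgression_analysis(intro_sim, config: PipelineConfig) -> "IntrogressionSummary":
    """Match ratios for every haplotype, empirical null and the paired test."""
    panel = intro_sim.panel
    results = []
    for sample, hap in panel.haplotype_ids():
        results.append(
            match_ratio(
                panel,
                sample,
                hap,
                intro_sim.archaic,
                intro_sim.insertion_position,
                window=config.flank_window,
            )
        )
    results = null_distribution(results, intro_sim.null_samples)
    by_key = {(r.sample, r.haplotype): r for r in results}
    pairs = []
    for sample, hap in intro_sim.carrier_haps.items():
        carrier = by_key[(sample, hap)]
        other = by_key[(sample, 1 - hap)]
        if carrier.defined and other.defined:
            pairs.append((carrier.ratio, other.ratio))
    t, p = carrier_vs_noncarrier_test(pairs) if len(pairs) >= 2 else (float("nan"), float("nan"))
    return IntrogressionSummary(results=results, pairs=pairs, t_statistic=t, p_value=p)


def _write_tables(result: PipelineResult, outdir: Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": c.sample,
                "numt_id": c.numt_id,
                "chromosome": c.chromosome,
                "insertion_position": c.insertion_position,
                "n_support": c.n_support,
                "n_clipped": c.n_clipped,
                "genotype": c.genotype,
                "phase": c.phase,
            }
            for c in result.calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "key": k,
                "total_length": s.total_length,
                "mean_depth": round(s.mean_depth, 2),
                "gc_content": round(s.gc_content, 3),
                "kept": result.qc[k].keep,
                "reason": result.qc[k].reason or "",
            }
            for k, s in result.sequences.items()
        ]
    ).to_csv(outdir / "sequences_qc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "key": k,
                "category": lc.category,
                "bootstrap_support": lc.bootstrap_support,
                "n_diagnostic": lc.n_diagnostic,
            }
            for k, lc in result.lineages.items()
        ]
    ).to_csv(outdir / "lineages.tsv", sep="\t", index=False)
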