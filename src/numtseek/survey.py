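"""Survey analyses: discovery saturation, coverage effects and reference bias.

Rarefaction estimates how the number of distinct NUMTs grows as samples are
added; downsampling re-runs detection at reduced coverage; the Poisson tail
quantifies what fraction of the genome carries enough reads for a call; the
diagnostic-allele screen looks for archaic NUMTs too long for split reads;
and the reference-swap experiment measures how a diverged mtDNA reference
suppresses detection.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import detect as _detect
from . import lineage as _lineage
from .reconstruct import (
    MtPileup,
    SeedIndex,
    pad_circular_reference,
    revcomp,
)


@dataclass
class RarefactionCurve:
    group: str
    sample_sizes: np.ndarray
    mean_distinct: np.ndarray
    n_reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "sample_size": self.sample_sizes,
                "mean_distinct": self.mean_distinct,
            }
        )


def rarefaction(
    numt_sets: dict[str, set[str]],
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    group: str = "all",
) -> RarefactionCurve:
    """Mean distinct-NUMT count after k samples, over random sample orders.

    For each repetition the samples are shuffled and added one by one; the
    curve is the mean over `n_reps` repetitions of the running count of
    distinct NUMT ids.
    """
    if not numt_sets:
        raise ValueError("need at least one sample")
    rng = rng if rng is not None else np.random.default_rng(0)
    samples = sorted(numt_sets)
    all_ids = sorted(set().union(*numt_sets.values()))
    idx = {x: i for i, x in enumerate(all_ids)}
    presence = np.zeros((len(all_ids), len(samples)), dtype=bool)
    for j, s in enumerate(samples):
        for x in numt_sets[s]:
            presence[idx[x], j] = True
    n = len(samples)
    totals = np.zeros(n)
    for _ in range(n_reps):
        order = rng.permutation(n)
        seen = np.cumsum(presence[:, order], axis=1) > 0
        totals += seen.sum(axis=0)
    return RarefactionCurve(
        group=group,
        sample_sizes=np.arange(1, n + 1),
        mean_distinct=totals / n_reps,
        n_reps=n_reps,
    )


def poisson_detectable_fraction(mean_coverage: float, min_reads: int = 5) -> float:
    """P(depth >= min_reads) for Poisson(mean_coverage) positional depth.

    With a >=5-read calling rule, this is the fraction of the genome covered
    well enough for a NUMT to be detectable at all.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if min_reads <= 0:
        return 1.0
    return float(stats.poisson.sf(min_reads - 1, mean_coverage))


# ---------------------------------------------------------------------------
# Downsampling


def _keep_pair(name: str, fraction: float, seed: int) -> bool:
    h = zlib.crc32(f"{seed}:{name}".encode()) / 2**32
    return h < fraction


def detect_calls(
    alignments,
    mt_contig: str = "MT",
    mt_reference: str | None = None,
    min_clipped: int = 5,
    cluster_span: int = 2000,
    sample: str = "sample",
    **support_kwargs,
):
    """Convenience: supports -> clusters -> calls in one go."""
    sup = _detect.find_supports(
        alignments, mt_contig=mt_contig, mt_reference=mt_reference, **support_kwargs
    )
    clusters = _detect.cluster_supports(sup, max_span=cluster_span)
    calls = []
    for cl in clusters:
        c = _detect.call_numt(cl, min_clipped=min_clipped, sample=sample)
        if c is not None:
            calls.append(c)
    return calls


def downsampling_experiment(
    sample_sim,
    fractions,
    seed: int = 0,
    min_clipped: int = 5,
    cluster_span: int = 2000,
) -> tuple[pd.DataFrame, float]:
    """Re-run detection on read subsets; report counts and the coverage/count r^2.

    Each read pair is kept with probability `fraction` (deterministic in the
    pair name and seed, so fractions are nested-like but independent draws).
    """
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        kept = (
            r
            for r in sample_sim.alignments()
            if _keep_pair(r.read_name, frac, seed)
        )
        calls = detect_calls(
            kept,
            mt_contig=sample_sim.mt_contig,
            mt_reference=sample_sim.mt_reference,
            min_clipped=min_clipped,
            cluster_span=cluster_span,
            sample=sample_sim.sample,
        )
        rows.append(
            {
                "fraction": frac,
                "effective_coverage": frac * sample_sim.config.coverage,
                "n_detected": len(calls),
            }
        )
    df = pd.DataFrame(rows)
    if df["n_detected"].nunique() > 1 and len(df) > 1:
        r, _ = stats.pearsonr(df["effective_coverage"], df["n_detected"])
        r2 = float(r**2)
    else:
        r2 = float("nan")
    return df, r2


# ---------------------------------------------------------------------------
# Diagnostic alleles


@dataclass
class DiagnosticHit:
    rsrs_position: int
    allele: str
    branch: str
    n_support: int
    consensus_context: str
    context_start: int  # 1-based mt coordinate of the context's first base
    lineage_call: object | None = None


def diagnostic_scan(
    mt_reads,
    diagnostics: list[tuple[int, str, str]],
    mt_reference: str,
    panel=None,
    min_baseq: int = 15,
    min_reads: int = 5,
    min_context: int = 30,
    k: int = 25,
    max_mismatch_frac: float = 0.10,
    bootstrap_reps: int = 100,
    rng: np.random.Generator | None = None,
    pad: int = 1000,
) -> list[DiagnosticHit]:
    """Screen mt-mapped reads for branch-diagnostic alleles.

    `mt_reads` is a list of (sequence, base_qualities) tuples;
    `diagnostics` rows are (1-based position, allele, branch).  A position
    is retained when at least `min_reads` reads carry the diagnostic allele
    at base quality >= `min_baseq`.  For every retained position a majority
    consensus over the supporting reads' union span is built and, when a
    panel is supplied and the context is long enough, classified on the
    hominin tree.
    """
    ref = pad_circular_reference(mt_reference, pad=min(pad, len(mt_reference) - 1))
    index = SeedIndex(ref, k=k)
    L = ref.original_length
    placements = []  # (sequence, qualities, 0-based padded start)
    for seq, quals in mt_reads:
        if len(seq) < k:
            continue
        best, oriented, q = None, seq, quals
        for cand_seq, cand_q in ((seq, quals), (revcomp(seq), (quals or [])[::-1] or None)):
            b = _best_placement_for(cand_seq, index, max_mismatch_frac)
            if b is not None:
                best, oriented, q = b, cand_seq, cand_q
                break
        if best is None:
            continue
        placements.append((oriented, q, best))

    hits: list[DiagnosticHit] = []
    rng = rng if rng is not None else np.random.default_rng(0)
    for pos, allele, branch in diagnostics:
        if not 1 <= pos <= L:
            raise ValueError(f"diagnostic position {pos} outside the mt reference")
        supporting = []
        for seq, quals, start in placements:
            for rep in _padded_copies(pos, L, ref.pad):
                off = rep - 1 - start
                if 0 <= off < len(seq):
                    if quals is not None and quals[off] < min_baseq:
                        continue
                    if seq[off] == allele:
                        supporting.append((seq, start))
                    break
        if len(supporting) < min_reads:
            continue
        lo = min(s for _, s in supporting)
        hi = max(s + len(seq) for seq, s in supporting)
        context = _context_consensus(supporting, lo, hi)
        hit = DiagnosticHit(
            rsrs_position=pos,
            allele=allele,
            branch=branch,
            n_support=len(supporting),
            consensus_context=context,
            context_start=(lo % L) + 1,
        )
        if panel is not None and len(context) >= min_context:
            hit.lineage_call = _classify_context(
                panel, context, (lo % L) + 1, L, bootstrap_reps, rng
            )
        hits.append(hit)
    return hits


def _best_placement_for(seq: str, index: SeedIndex, max_mismatch_frac: float):
    best = None
    for start in index.candidate_offsets(seq):
        mm = index.mismatches(seq, start)
        if best is None or mm < best[1]:
            best = (start, mm)
    if best is None or best[1] > max_mismatch_frac * len(seq):
        return None
    return best[0]


def _padded_copies(pos: int, L: int, pad: int):
    yield pos
    if pos <= pad:
        yield pos + L


def _context_consensus(supporting, lo: int, hi: int) -> str:
    counts: dict[int, dict[str, int]] = {}
    for seq, start in supporting:
        for i, base in enumerate(seq):
            counts.setdefault(start + i, {}).setdefault(base, 0)
            counts[start + i][base] += 1
    out = []
    for p in range(lo, hi):
        if p not in counts:
            out.append("N")
            continue
        best = max(sorted(counts[p]), key=lambda b: counts[p][b])
        out.append(best)
    return "".join(out)


def _classify_context(panel, context, start, L, bootstrap_reps, rng):
    end = start + len(context) - 1
    if end > L:
        end -= L
    rows = _lineage.extract_region_circular(panel, start, end)
    rows = _lineage.add_numt_row(rows, "diag_numt", context)
    clean = _lineage.dedupe_alignment(rows)
    tree = _lineage.build_tree(
        clean, panel.outgroup_name, n_bootstrap=bootstrap_reps, rng=rng
    )
    return _lineage.classify(tree, clean, _find_numt_row(clean), numt_id="diag_numt")


def _find_numt_row(rows) -> str:
    for name, labs in zip(rows.names, rows.labels):
        if "numt" in labs:
            return name
    raise ValueError("numt row lost during dedupe")


# ---------------------------------------------------------------------------
# Reference swap


@dataclass
class ReferenceSwapResult:
    counts: pd.DataFrame  # sample, reference, n_detected
    coverage_profiles: dict[str, np.ndarray]  # reference name -> mt depth


def reference_swap_experiment(
    sample_sims,
    references: dict[str, str],
    min_clipped: int = 5,
    cluster_span: int = 2000,
    max_divergence: float = 0.025,
    k: int = 25,
) -> ReferenceSwapResult:
    """Detection counts when supports must match each candidate mt reference.

    Emulates remapping against a diverged (e.g. archaic) mtDNA: both the
    clipped segments and the mt-side mates must align to the reference
    within `max_divergence` (a strict aligner-like tolerance), so reads from
    a diverged mtDNA lineage drop out.  Also reports the per-position mt
    coverage profile of the validated supports under each reference.
    """
    from .reconstruct import map_supports_to_mt

    rows = []
    profiles: dict[str, np.ndarray] = {}
    for ref_name, ref_seq in references.items():
        depth_total = None
        for sim in sample_sims:
            calls = detect_calls(
                sim.alignments(),
                mt_contig=sim.mt_contig,
                mt_reference=ref_seq,
                min_clipped=min_clipped,
                cluster_span=cluster_span,
                sample=sim.sample,
                max_clip_divergence=max_divergence,
                validate_discordant=True,
            )
            rows.append(
                {"sample": sim.sample, "reference": ref_name, "n_detected": len(calls)}
            )
            sup = _detect.find_supports(
                sim.alignments(),
                mt_contig=sim.mt_contig,
                mt_reference=ref_seq,
                max_clip_divergence=max_divergence,
                validate_discordant=True,
            )
            mt_seqs = [s.mt_sequence for s in sup if s.mt_sequence]
            pile = map_supports_to_mt(
                mt_seqs,
                pad_circular_reference(ref_seq, pad=min(1000, len(ref_seq) - 1)),
                k=k,
                max_mismatch_frac=max_divergence,
            )
            depth_total = pile.depth if depth_total is None else depth_total + pile.depth
        profiles[ref_name] = (
            depth_total if depth_total is not None else np.zeros(len(ref_seq))
        )
    return ReferenceSwapResult(counts=pd.DataFrame(rows), coverage_profiles=profiles)
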