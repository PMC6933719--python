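"""Survey analyses: rarefaction, coverage effects and reference bias.

Rarefaction of distinct-NUMT discovery over the cohort; detection counts
after downsampling one sample; the Poisson detectable fraction across
coverages; the reference-swap experiment (modern vs archaic mtDNA
reference); and the diagnostic-allele screen for a NUMT too long to be
covered by split reads.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import PIPE_CONFIG, SEED, SIM_CONFIG, build_cohort, build_panel

from numtseek.pipeline import detect_sample
from numtseek.sim import SimConfig, TruthRecord, diagnostic_sites, simulate_sample
from numtseek.survey import (
    diagnostic_scan,
    downsampling_experiment,
    poisson_detectable_fraction,
    rarefaction,
    reference_swap_experiment,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    panel = build_panel()
    sims = build_cohort(panel)

    # rarefaction over detected (not truth) NUMT sets
    sets = {}
    for sim in sims:
        calls = detect_sample(sim, PIPE_CONFIG, genotype=False)
        sets[sim.sample] = {c.numt_id for c in calls}
    curve = rarefaction(
        sets, n_reps=PIPE_CONFIG.rarefaction_reps, rng=np.random.default_rng(SEED)
    )
    curve.as_frame().to_csv(RESULTS / "rarefaction.tsv", sep="\t", index=False)
    print("rarefaction mean distinct NUMTs:",
          [round(float(x), 1) for x in curve.mean_distinct])

    # downsampling one sample
    df, r2 = downsampling_experiment(
        sims[0], [0.1, 0.2, 0.35, 0.5, 0.75, 1.0], seed=SEED
    )
    df.to_csv(RESULTS / "downsampling.tsv", sep="\t", index=False)
    print(f"downsampling: counts {df.n_detected.tolist()} at "
          f"{[round(c,1) for c in df.effective_coverage]}x; r^2 = {r2:.2f}")

    # Poisson detectability across coverages
    pdf = pd.DataFrame(
        [
            {"coverage": c, "detectable_fraction": round(poisson_detectable_fraction(c, 5), 4)}
            for c in (2, 5, 10, 20, 30, 40)
        ]
    )
    pdf.to_csv(RESULTS / "poisson_detectability.tsv", sep="\t", index=False)
    print("Poisson detectable fraction:", dict(zip(pdf.coverage, pdf.detectable_fraction)))

    # reference swap on the two samples without Denisovan-source NUMTs:
    # their (modern) mtDNA reads align poorly to a diverged archaic reference
    arch_ref = panel.source_sequence("denisovan")
    swap = reference_swap_experiment(
        [sims[3], sims[5]], {"modern": panel.rsrs_sequence, "archaic": arch_ref}
    )
    swap.counts.to_csv(RESULTS / "reference_swap.tsv", sep="\t", index=False)
    per_ref = swap.counts.groupby("reference")["n_detected"].mean()
    print(f"reference swap: mean NUMTs/sample modern={per_ref['modern']:.1f} "
          f"vs archaic={per_ref['archaic']:.1f}")

    # diagnostic-allele screen: a 3 kb Denisovan NUMT exceeds the split-read
    # bound, so its interior is only visible through diagnostic alleles
    cfg = SimConfig(**{**SIM_CONFIG.__dict__, "nuclear_length": 200_000, "seed": SEED + 99})
    long_truth = TruthRecord("1_1000", "1", 100_000, "denisovan", 5_000, 8_000, "both")
    long_sim = simulate_sample(cfg, [long_truth], panel)
    mt_reads = [
        (r.sequence, r.base_qualities or [30] * len(r.sequence))
        for r in long_sim.alignments()
        if r.is_mt
    ]
    diag = diagnostic_sites(panel.panel)
    table = [(p, a, "denisovan_sima") for p, a in diag["denisovan_sima"]]
    hits = diagnostic_scan(
        mt_reads, table, panel.rsrs_sequence, panel=panel.panel,
        min_baseq=PIPE_CONFIG.diag_min_baseq, min_reads=PIPE_CONFIG.diag_min_reads,
        rng=np.random.default_rng(SEED),
    )
    hdf = pd.DataFrame(
        [
            {
                "position": h.rsrs_position, "allele": h.allele, "branch": h.branch,
                "n_support": h.n_support,
                "context_bp": len(h.consensus_context),
                "classified": h.lineage_call.category if h.lineage_call else "",
            }
            for h in hits
        ]
    )
    hdf.to_csv(RESULTS / "diagnostic_hits.tsv", sep="\t", index=False)
    n_den = (hdf.classified == "denisovan").sum() if len(hdf) else 0
    print(f"diagnostic screen: {len(hdf)} retained positions, "
          f"{n_den} classified denisovan from consensus context")


if __name__ == "__main__":
    main()
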