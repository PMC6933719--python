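"""Shared study conditions for the analysis scripts.

A small synthetic cohort standing in for a high-coverage population sample:
six diploid genomes (600 kb each, 30x, 150 bp reads, 350 +/- 50 bp
templates), a hominin mtDNA panel at the published composition (87 modern
humans, 17 Neanderthals, 4 Denisovans, Sima, chimpanzee, RSRS), and a
catalogue of polymorphic NUMTs of mixed source lineage.  One
Denisovan-source NUMT is shared by four carriers, mirroring an introgressed
insertion segregating in a population.

Every script re-derives the same cohort from these constants, so each stage
can be run on its own and results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from numtseek.config import PipelineConfig
from numtseek.detect import numt_name
from numtseek.sim import (
    SimConfig,
    TruthRecord,
    simulate_mt_panel,
    simulate_sample,
)

SEED = 20240901
N_SAMPLES = 6
CHROM = "1"

SIM_CONFIG = SimConfig(nuclear_length=600_000, coverage=30, seed=SEED)
PIPE_CONFIG = PipelineConfig(seed=SEED % 2**16)

# Catalogue of polymorphic NUMTs: (position, mt_start, mt_end, lineage).
# The Denisovan NUMT at 310 kb is the shared, putatively introgressed one.
CATALOGUE = [
    (60_000, 4_200, 4_520, "modern_human"),
    (130_000, 11_050, 11_420, "modern_human"),
    (200_000, 16_450, 150, "modern_human"),  # wraps the mtDNA origin
    (310_000, 7_000, 7_450, "denisovan"),
    (420_000, 2_300, 2_520, "ancestral"),
    (520_000, 9_700, 9_980, "modern_human"),
]

# sample index -> (catalogue indices carried, haplotype of the Denisovan NUMT)
CARRIAGE = {
    0: ([0, 1, 3], "hap1"),
    1: ([0, 3, 4], "hap2"),
    2: ([1, 2, 3], "hap1"),
    3: ([2, 4, 5], None),
    4: ([0, 3, 5], "hap2"),
    5: ([1, 4], None),
}

DENISOVAN_IDX = 3
INTROGRESSED_INTERVAL = (300_000, 320_000)


def build_panel():
    return simulate_mt_panel(SIM_CONFIG)


def sample_truths(sample_index: int) -> list[TruthRecord]:
    carried, den_hap = CARRIAGE[sample_index]
    rng = np.random.default_rng([SEED, 7, sample_index])
    truths = []
    for ci in carried:
        pos, mt_start, mt_end, lineage = CATALOGUE[ci]
        if ci == DENISOVAN_IDX:
            hap = den_hap
            interval = INTROGRESSED_INTERVAL
        else:
            hap = ["hap1", "hap2", "both"][int(rng.integers(0, 3))]
            interval = None
        truths.append(
            TruthRecord(
                numt_id=numt_name(CHROM, pos),
                chromosome=CHROM,
                insertion_position=pos,
                mt_source_lineage=lineage,
                mt_start=mt_start,
                mt_end=mt_end,
                haplotype=hap,
                introgressed_interval=interval,
            )
        )
    return truths


def build_cohort(panel):
    sims = []
    for i in range(N_SAMPLES):
        cfg = SimConfig(**{**SIM_CONFIG.__dict__, "seed": SEED + 11 * i})
        sims.append(
            simulate_sample(
                cfg, sample_truths(i), panel, sample=f"S{i}", chrom=CHROM
            )
        )
    return sims
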