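# numtseek

Discovery and archaic-lineage analysis of polymorphic NUMTs (NUclear
MiTochondrial DNA segments) in paired-end sequencing data.

Fragments of mitochondrial DNA occasionally insert into nuclear chromosomes.
Most NUMTs descend from the mtDNA of the carrier's own lineage, but a NUMT
can also arrive *horizontally*: if an archaic hominin (Neanderthal,
Denisovan) carried an insertion of its own mtDNA and later interbred with
modern humans, the insertion — and the nuclear haplotype around it — can
survive in present-day genomes long after the archaic mtDNA itself
disappeared. Finding such a NUMT therefore gives a window on interbreeding
that ordinary mtDNA phylogenetics cannot. This package implements the full
chain of analyses needed to find and interpret them, plus a synthetic-cohort
simulator so every stage is testable at desk scale, for population
geneticists working with high-coverage short-read genomes.

## What the pipeline computes

1. **Detection** (`numtseek.detect`). Non-reference insertions are found
   from two read classes: *discordant pairs* (one mate on the mtDNA contig,
   the other on a nuclear chromosome) and *split reads* (nuclear reads whose
   soft-clipped tail matches mtDNA). Supports within 2 kbp chain into one
   cluster; a call requires ≥ 5 clipped reads; the breakpoint is the modal
   clip coordinate; a NUMT at position 13848625 of chromosome 3 is named
   `3_1384` (chromosome + first four digits).
2. **Reconstruction** (`numtseek.reconstruct`). Supporting reads are
   remapped to a circularly padded mtDNA reference (positions 1–1000 copied
   after 16569, so origin-spanning reads map without bias), piled up, and
   collapsed into consensus fragments wherever depth ≥ 5. Fragments are
   concatenated in circular order; sequences < 20 bp or below 5× mean depth
   are discarded. Because only junction-spanning pairs are recoverable, a
   single fragment is bounded by
   `2 × (read_length + insert_size + read_length/2)` — 1250 bp for 150 bp
   reads and a 400 bp insert.
3. **Lineage classification** (`numtseek.lineage`). Each consensus is
   placed into the matching region of an aligned hominin mtDNA panel
   (modern humans, Neanderthals, Denisovans, Sima de los Huesos, chimpanzee
   outgroup, RSRS), identical rows are collapsed, and a bootstrapped
   neighbor-joining tree (Jukes–Cantor distances, outgroup-rooted) is read
   with monophyly rules: a NUMT inside a supported all-Denisovan clade is
   Denisovan, inside the modern clade it is modern, basal to all humans it
   is ancestral, and so on. Diagnostic positions — alleles the NUMT shares
   with its assigned lineage to the exclusion of all modern humans — are
   counted as corroborating evidence.
4. **Phase and introgression** (`numtseek.introgression`). The insertion is
   assigned to a haplotype when > 2/3 of informative junction reads (and at
   least 3) agree with phased flanking heterozygotes. Within ±20 kbp of the
   breakpoint, non-reference alleles shared with an archaic genome are
   collected; alleles with frequency < 0.05 in at least one worldwide
   reference panel are flagged as introgression candidates and chained into
   a haplotype boundary. Each haplotype gets a *match ratio*
   `|shared non-reference alleles| / |union of non-reference sites|`,
   ranked against an empirical null from populations without archaic
   ancestry; carrier vs non-carrier haplotypes of heterozygous samples are
   compared with a one-tailed paired t-test.
5. **Survey** (`numtseek.survey`). Rarefaction of distinct-NUMT discovery
   (mean of 100 resampled sample orders), coverage downsampling, the
   Poisson detectable fraction `P(depth ≥ 5)`, a diagnostic-allele screen
   for NUMTs too long for split reads (base quality ≥ 15, ≥ 5 reads), and a
   reference-swap experiment quantifying how a diverged mtDNA reference
   suppresses detection.
6. **Simulator** (`numtseek.sim`). Star-like hominin mtDNA panels with
   archaic-vs-modern divergence calibrated to ~3.5 mismatches per 150 bp
   read, diploid genomes carrying NUMTs of known source lineage and phase,
   paired reads with exact junction soft-clips in an oracle SAM, and phased
   panels with introgressed carrier haplotypes — all deterministic given a
   seed.

## Worked example

The `analysis/` scripts run the whole study on a six-sample synthetic
cohort (600 kb genomes, 30×, six catalogued NUMTs, one Denisovan-source
insertion shared by four carriers):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_detect_numts.py
...
python analysis/06_survey.py
```

Output of the detection and introgression stages (tables land in
`results/`):

```
detected 16 calls over 6 samples (mean 2.7/sample); recall 16/17 at +/-10 bp
...
Denisovan-source NUMT 1_3100: 4/4 carriers classified denisovan,
diagnostic sites per carrier: [7, 7, 9, 10]
...
carrier mean match ratio 0.626 vs non-carrier 0.094;
one-tailed paired t-test p = 5.95e-16
estimated introgressed haplotype (300279, 317723) (truth (300000, 320000))
```

Read: 16 of 17 simulated insertions were recovered at their exact
breakpoints (one heterozygous NUMT fell below the five-clipped-read rule —
the expected failure mode at 15× per-haplotype depth); every carrier of the
Denisovan-source NUMT was classified `denisovan` from its reconstructed
sequence; and the carrier haplotypes look archaic over the flanking 20 kbp
(match ratio 0.63 vs 0.09) with the paired test rejecting decisively, so the
insertion travelled on an introgressed nuclear haplotype rather than
arising in a modern human.

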