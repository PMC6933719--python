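# Methods

## Detection model

A non-reference NUMT leaves two footprints in a coordinate-sorted paired-end
alignment: read pairs with one mate on the mtDNA contig and the other on a
nuclear chromosome (discordant pairs), and nuclear reads soft-clipped at the
insertion junction whose clipped tail realigns to mtDNA (split reads).
`find_supports` collects both; clipped tails shorter than 20 bp are ignored
(too little sequence to verify), longer ones are verified against the mtDNA
by semi-global alignment (edlib) allowing 10% edits by default. Supports on
one chromosome chain into a cluster by single-linkage with a 2 kbp gap —
the gap, not the total span, is bounded, since real support scatter follows
the insert-size distribution around the junction. A cluster becomes a call
only with ≥ 5 clipped reads; the breakpoint is the modal clip coordinate
with ties broken to the smaller coordinate, making calls deterministic. The
published detector that inspired this stage does not document its internal
scoring, so this package substitutes the transparent rule above; the ≥ 5
clipped-read minimum is the documented behaviour being matched.

Genotype is assigned from unclipped reference-spanning reads across the
breakpoint (≥ 10 bp on each side): their presence marks the site
heterozygous, their absence homozygous. This is a deliberately simple rule —
a homozygous call can be wrong when spanning coverage happens to be zero —
and is reported, not filtered on.

Breakpoint convention: `insertion_position` is the 1-based nuclear base
*after which* the insert sits. A right-clipped read anchors at its last
aligned base, a left-clipped read at one base left of its first aligned
base, so both sides of the junction vote for the same coordinate.

## Circular remap and consensus

Supporting reads are remapped to the mtDNA reference padded by copying its
first 1000 bases after the end, so reads spanning the replication origin map
contiguously; coordinates are folded back modulo the mtDNA length. Only the
aligned portion of a discordant mt read is remapped — its clipped tail is
nuclear sequence by construction. The mapper is seed-and-extend: exact
25-mers (probed on a stride of 8, falling back to every offset for diverged
reads) anchor candidate placements, ungapped extension counts mismatches,
and the best placement is accepted below 10% mismatches, forward or reverse
complement. These tolerances accommodate archaic-source reads (~2.3%
divergent from the reference) plus sequencing error, while rejecting
non-mitochondrial sequence. Gapped alignment is out of scope: the panels
are SNP-only and indels inside NUMTs are not modelled.

Consensus: maximal runs of positions with depth ≥ 5 become fragments; the
consensus base is the per-position majority, and a position where the
majority holds < 80% of reads is written as `N` rather than guessed — real
data were clean enough that this never triggered, but the pipeline must be
deterministic when that luck fails. Fragments concatenate in mtDNA order;
when the set wraps the origin the fragment touching the end of the molecule
is placed first. Overlapping fragments are treated as an internal error
(the pileup cannot produce them). QC discards sequences < 20 bp (too little
phylogenetic information) or below 5× mean depth (likely artefact); GC
content is computed and reported but never filtered on.

## Lineage classification

The hominin panel is a gap-free alignment by construction (the simulator's
mutation model is substitution-only); the coordinate map from mtDNA
positions to alignment columns nevertheless supports gapped reference rows,
and region extraction walks that map. The NUMT consensus is laid onto its
covered interval with gaps at uncovered positions, identical rows are
collapsed (labels pooled, the NUMT row always survives), and with ≥ 4
distinct sequences a neighbor-joining tree on Jukes–Cantor distances is
built and rooted on the outgroup. Support comes from a nonparametric
bootstrap (column resampling, 100 replicates); only clades at support ≥ 50
are trusted, mirroring the convention of annotating support above 50.
Neighbor joining replaces maximum likelihood deliberately: classification
consumes topology and monophyly only, NJ is deterministic and fast at this
scale, and an externally computed newick tree can be supplied instead.

Classification rules, applied in order:

* If the NUMT row collapsed onto identical panel rows, those rows' lineages
  decide directly (identity outranks any clade) — all-modern rows give
  `modern_human`, all-Denisovan give `denisovan`, conflicting lineages give
  `unclassifiable`.
* Otherwise the smallest supported clade containing the NUMT decides by its
  other members: all Denisovan/Sima → `denisovan`; all Neanderthal →
  `neanderthal`; all modern → `modern_human`; all archaic →
  `neanderthal_denisovan_ancestral` (the shared archaic state). An archaic
  call additionally requires the clade to contain *every* pure tip of that
  lineage — the group must be monophyletic with the NUMT inside it, not a
  few stray tips; without this, bootstrap noise can hand a NUMT to a
  partial clade of the wrong lineage.
* A NUMT outside a supported clade of all humans is `ancestral_all`.
* Anything else — mixed companions, no supported clade, < 4 distinct rows —
  is `unclassifiable`.

`n_diagnostic` counts alignment columns where the NUMT shares an allele
with every tip of its assigned lineage while every modern human differs; it
is evidence strength, not a filter. Short or conserved regions legitimately
produce `unclassifiable` or drift towards the ancestral categories — an
ancestral-state NUMT is genuinely indistinguishable from the
Neanderthal-Denisovan ancestor wherever the region carries no
archaic-stem variation, and the category naming preserves that honesty.

## Phase and introgression

Phase: junction reads overlapping phased heterozygous flanking sites vote
for the haplotype whose alleles they carry (reads voting inconsistently
across sites are dropped). The insertion is phased iff the winning
haplotype has strictly more than 2/3 of informative reads *and* at least 3
reads; 2-of-3 is deliberately insufficient.

Shared-allele scan: within ±20 kbp of the breakpoint, sites where the focal
haplotype carries a non-reference allele equal to an archaic allele.
Archaic genotypes are treated as an allele set (either allele of an
unphased archaic diploid can be shared); at multi-allelic sites sharing
requires the identical alternate allele, not merely both-non-reference.
Unphased panel sites are excluded. Allele frequency is computed per
reference panel as allele count over non-missing haplotypes; a shared
allele rare (< 0.05, strictly) in at least one panel is an introgression
candidate. The haplotype boundary chains candidate sites with gaps ≤ 5 kbp,
with the insertion point itself as an extra chain anchor — the NUMT is part
of the haplotype, so a gap is measured to it, not across it. The 5 kbp gap
is a package choice; the original boundary was read off a figure by eye.

Match ratio = shared / union of non-reference sites in the window; undefined
(and excluded) when the union is empty. The empirical null is the set of
ratios from haplotypes of populations without archaic ancestry (≥ 30
required); percentiles use mid-ranks so a ratio equal to the null median
lands at 0.5. Heterozygous carriers contribute (carrier-haplotype,
other-haplotype) pairs to a one-tailed paired t-test (scipy, cross-checked
in tests against the textbook formula); zero-variance differences degenerate
to p ∈ {0, 0.5, 1} by sign, with a warning.

## Survey analyses

Rarefaction: for each repetition the samples are shuffled and added one by
one, counting distinct NUMT ids; the curve is the mean of 100 repetitions
(tested against the closed-form hypergeometric expectation with exact
variance). Downsampling keeps each read pair with probability *f*
(deterministic in pair name and seed) and reruns detection. The Poisson
detectable fraction is `P(X ≥ 5)` for `X ~ Poisson(coverage)` — the plain
tail, with no correction for clipped-read mappability, which would lower
the effective rate. The diagnostic-allele screen pileups branch-diagnostic
positions over mt-mapped reads (base quality ≥ 15, ≥ 5 supporting reads),
builds a majority consensus over the supporting reads' union span (≥ 30 bp
to attempt classification) and classifies it on the panel. The
reference-swap experiment reruns support finding with both clipped segments
and discordant mt reads validated against each candidate reference at a
strict 2.5% divergence, emulating an aligner's reluctance to place diverged
reads; with a modern cohort, an archaic mtDNA reference loses most
supports, and vice versa.

## Simulator

The mtDNA panel evolves on a star-like tree: a hominin root, equal-length
stem branches to the modern ancestor (= the reference row) and the archaic
ancestor, archaic lineage branches (Sima de los Huesos branching midway
along the Denisovan stem), and private tip substitutions. Per-branch
substitution counts are Poisson; there are no indels, so panel coordinates
equal mtDNA coordinates exactly. The archaic divergence default, 3.5/150
per base, makes an archaic read differ from a modern one by ~3.5
substitutions on average; within-lineage diversity (5 × 10⁻⁴ per base) is a
free parameter since no canonical value exists for it, set so that modern
diversity is far below archaic divergence; the chimpanzee outgroup sits at
9% — all verified by the calibration tests.

Samples are diploid: a random nuclear contig (GC 0.41), heterozygous SNPs
at 10⁻³ per bp phased at random, and NUMT insertions applied per haplotype
(`hap1`/`hap2`/`both`), with insertion sites ≥ 50 kbp apart as observed for
real polymorphic NUMTs. Read pairs have truncated-normal template lengths
(min = read length, default 350 ± 50), uniform fragment starts,
substitution errors at 10⁻³ per base, and constant base quality 37. The
oracle alignment places each read by its longest run within one haplotype
piece and soft-clips the rest — exactly what an aligner does at a junction
— so detection is testable without bundling an aligner. Reads wholly inside
an insert map to the mtDNA contig (clipped at the origin when the interval
wraps). The simulator does **not** model: true mitochondrial reads (~1000×
mt coverage in real data; they map mt–mt and are invisible to detection),
indels, quality-score profiles, repetitive nuclear sequence, or alignment
ambiguity. Passing tests therefore demonstrate the pipeline's logic and
thresholds, not robustness to mapping artefacts in repeats — the published
caveat that detection fails in highly repetitive regions carries over.

The introgressed-panel generator places three site classes around a chosen
interval: introgressed sites (archaic-shared, on all carrier haplotypes,
frequency clamped strictly below 0.05 in two simulated worldwide reference
panels), homoplasy/incomplete-lineage-sorting stand-ins outside the
interval (archaic-shared at frequency 0.2–0.6 everywhere), and
modern-only variants (archaic-reference, frequency 0.05–0.4). Carriers are
heterozygous, with the carrier haplotype recorded as truth. Site densities
(1.5, 1.0, 1.0 per kbp) were chosen once to reproduce the qualitative
carrier/non-carrier match-ratio contrast reported for real data (≈ 0.7 vs
≈ 0.1–0.25 here); the acceptance checks depend on the separation's sign and
significance, not its exact magnitude.

## Problem sizes and determinism

The test suite runs the full pipeline on a 5 Mb diploid genome at 30× with
twenty insertions (~1 million read pairs, ≈ 1 minute) and the
introgression analysis on a 200-haplotype panel; the analysis scripts use a
six-sample 600 kb cohort so the whole study replays in a couple of minutes.
Every random draw flows from explicit `numpy` generators seeded from the
config, so identical configs give byte-identical outputs; per-haplotype
read streams are regenerated lazily from child seeds rather than stored.

## Known limitations

* Reconstruction reaches only as far as junction-anchored pairs: interior
  positions of long NUMTs stay uncovered, so their classification rests on
  the ends (or on the diagnostic-allele screen).
* Heterozygous insertions see half coverage; at 30× a het NUMT occasionally
  drops below the five-clipped-read rule — visible as the simulated
  cohort's single missed call.
* The genotype rule cannot distinguish a homozygous insertion from a
  coverage gap.
* NJ topology near the bootstrap gate is noisy for regions with very few
  informative sites; the completeness requirement and the gate trade a few
  extra `unclassifiable` calls for archaic-call specificity.
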