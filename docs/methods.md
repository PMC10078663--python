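# Methods

## The problem and the model

Surveys of marine phytoplankton communities traditionally count rRNA-gene
reads (16S/18S amplicons or miTags). Two biases make those counts poor
proxies for *cell* abundance: PCR primer bias, and rRNA gene copy number,
which spans five orders of magnitude across protists (from one copy in
small chlorophytes to tens of thousands in dinoflagellates, plus plastid
multiplicity for plastid-encoded 16S). `phytomark` implements the
alternative: recruit raw shotgun metagenomic reads (PCR-free) to a curated
database of *psbO* — the nuclear-encoded, single/low-copy gene for the
manganese-stabilising protein of photosystem II, present in every oxygenic
phototroph and lacking non-photosynthetic homologues — and read relative
cell abundance directly off normalised read counts.

The abundance model is: expected read share of taxon *t* for gene *g* is

    share(t, g)  ∝  cell_fraction(t) × copies(t, g) × length(g)

For a single-copy gene, rpkm-normalised counts are therefore proportional
to cell fractions; for rRNA genes the copy-number factor dominates and the
profile is distorted. The simulator encodes exactly this model, which is
what makes every downstream claim testable.

## Quantification

**Recruitment.** A read is recruited when (1) it is at least
`min_read_size` = 70 bp long, (2) it passes a 3-mer complexity screen
(fails when fewer than `complexity_number` = 30 distinct 3-mers, or when
the dominant 3-mer occupies ≥ `complexity_percent` = 75% of windows — the
published parameter values; the screen's internal semantics are this
package's own deterministic definition), and (3) its best local alignment
reaches `identity` ≥ 80% over alignment columns and covers ≥ 80% of the
read (`alignment`). The aligner is an exact affine-gap Smith-Waterman
(match +1, mismatch −1, gap of length *k* costs 2 + *k*; scheme is a
config default — only the four filter thresholds are fixed by the method).
Ties across (reference, strand) candidates break deterministically:
score, then identity, then reference span, then reference id, then forward
strand. A q-gram lower-bound prescreen skips references that provably
cannot reach the current best score; tests verify it never changes a best
hit. Identity is computed over alignment columns (not read length); N
never matches.

**rpkm.** `rpkm = n_reads / (covered_kb × mapped_reads/10⁶)` where
`covered_kb` is the union of reference bases touched by at least one
alignment — "per kilobase covered" is taken literally; a `gene`-length
normalisation is available for sensitivity analysis. `total_mapped_reads`
is the number of reads recruited to *any* marker database supplied in the
run. rpkm is computed per reference sequence and then summed per taxon.
Zero-coverage references are kept at rpkm 0 so tables align across samples.

**Relative abundance** is expressed over a declared denominator set:
all profiled taxa (total phytoplankton), all non-cyanobacterial taxa
(eukaryotic phytoplankton), or the picophytoplankton groups
(*Prochlorococcus*, *Synechococcus* and the typically pico-sized eukaryote
groups); arbitrary custom denominators are supported (e.g. Syn/(Syn+Pro)).

**Phototroph fractions.** psbO rpkm over bacterial *recA* rpkm estimates
the cyanobacterial share of bacterioplankton; psbO over the arithmetic
mean of 25 ribosomal-protein genes estimates the phytoplankton share of
eukaryotes; chloroplast vs mitochondrial Rieske (petC and its
mitochondrial homologue) is the alternative eukaryote statistic. Raw
ratios can exceed 1 (psbO copies 1–2, petC 2–3, sampling noise); both the
raw value and a [0, 1]-clamped value are reported, and a zero denominator
yields an explicit undefined flag rather than NaN propagation. The Rieske
denominator is mitochondrial-only so the statistic parallels psbO/recA.

**miTags.** The simplified rRNA-fragment classifier keeps reads ≥ 100 bp
with no Ns, finds the reference with the fewest differences over a region
covering 100% of the read (unit-cost infix alignment), requires ≥ 80%
identity, and resolves ties by the last common ancestor (longest shared
rank prefix) of the tied references.

## Placement taxonomy

Environmental psbO fragments are translated in the best of six frames
(scored by local alignment against the profile consensus under BLOSUM62;
ties go to the lowest frame in the order +1, +2, +3, −1, −2, −3), aligned
to the fixed reference protein alignment (position-specific scores are the
mean substitution score against each column's residues; affine gaps
−11/−1; reference columns are never altered — query insertions are
penalised, counted and dropped), and attached to the pendant edge of the
nearest reference by Poisson-corrected mismatch distance
d = −ln(1 − p) over shared ungapped columns (≥ 20 required; ties go to the
smallest reference id). Classification walks rootward from the attachment
edge and returns the group label of the first internal node whose support
is **strictly** above the threshold (default 0.7) and whose tips carry
exactly one group label; otherwise "unclassified". Support exactly equal
to the threshold never classifies. Full per-batch tree re-inference is
deliberately replaced by this deterministic placement; the classification
rule itself is unchanged, and it is invariant to tip order and node
rotations.

## Community statistics

Shannon diversity H = −Σ p ln p (natural log). Spearman correlation uses
average ranks for ties; the p-value is an exact two-sided permutation
value (full n! enumeration) for n ≤ 9 and the two-sided t approximation
above — exactness where enumerable. Genetic distances (p-distance, K2P,
TN93) ignore gap/N columns pairwise and require ≥ 50 shared columns; the
software-specific "maximum composite likelihood" estimator used in the
original analyses is approximated by TN93 as the default (the two agree
closely at these divergences; p-distance and K2P are offered). The
barcoding-gap report gives per-species max-intraspecific vs
min-interspecific distances (local gap) and a global-gap verdict.
Biovolumes: spheres from flow-cytometry side scatter via the power-law
calibration d = a·sscᵇ — the calibration constants are
instrument-specific and must be supplied in config (no defaults are
bundled) — and prolate spheroids V = (π/6)·major·minor² from microscopy
axes.

## The simulator: what it emulates, and what it does not

`simulate_reference_set` evolves each gene from a random ancestral
sequence down one species tree under exact per-branch Jukes-Cantor
kernels; branch lengths are rescaled (scalar root-find) so the *expected*
mean pairwise difference equals the requested divergence. The topology is
a random-join coalescent; coalescence heights are spread evenly with ±25%
jitter rather than drawn from Kingman waiting times, because raw waiting
times routinely produce sister references that are >99% identical —
something a curated, redundancy-reduced reference database never contains,
and which would make taxa fundamentally indistinguishable to any read
recruiter. An optional group-structured mode makes each group label a
monophyletic clade (within-group heights ≤ 0.3 of the depth, between-group
≥ 0.6), which is the regime the placement classifier is designed for.
psbO ancestors are built from sense codons so frame +1 translates cleanly;
substitutions may still create internal stops, which are carried and
scored (BLOSUM62 includes `*`).

`simulate_reads` draws reads multinomially over (taxon, gene) with weight
cell_fraction × copies × length, uniform start positions, per-base
substitution errors, and 50% reverse-complementation, recording full
provenance. Indels, platform-specific error profiles, paired-end
structure, introns and expression levels are deliberately not modelled;
sequencing errors are substitutions only (keeping the alignment oracles
crisp). PCR amplification bias is available as an optional per-taxon
multiplicative factor on rRNA weights (default off) so copy-number and
primer effects can be separated. A green end-to-end test therefore
establishes that the *quantification machinery* is unbiased under the
stated abundance model — not that real oceans lack additional biases
(chimeras, contamination, unmodelled homologues).

Desk-scale defaults, chosen once: marker genes 450 nt (all genes share a
length per simulation; within the observed psbO catalogue range of
94–733 bp, close to its 473 bp mean — real recA and rRNA genes are longer,
a documented desk-scale simplification that does not affect rpkm-based
statistics because length enters both simulation and normalisation); reads
100 bp; reference divergence 15%; sequencing error 1%; the default
community is six taxa dominated by picocyanobacteria
(Pro .35 / Syn .20 / chloro .18 / hapto .12 / diatom .10 / dino .05) with
18S copy numbers 2 / 20 / 100 / 1000 across the eukaryotes and 16S at 2
per cyanobacterium — inside the published copy-number envelopes.

## Numerical choices and degenerate inputs

- Gap convention: gap of length k costs |open| + k·|extend| everywhere.
- Smith-Waterman tie-breaks: maximal cell at smallest (read, reference)
  index; traceback prefers diagonal, then gap-in-read, then gap-in-ref,
  closing gaps over extending. These conventions are mirrored by the
  independent pure-Python oracle in the tests, so "equality with the
  oracle" is exact, not approximate.
- Clustering identity is end-gap-free global identity
  (matches / alignment columns of the aligned core), greedy longest-first
  (ties by id), first-fit cluster assignment — the cd-hit convention.
  Nucleotide identity is used for the 80% cutoff.
- Zero denominators (recA, ribosomal means, relative-abundance totals)
  yield undefined-flagged results, never NaNs or exceptions.
- All randomness flows from a single integer seed per entry point; reruns
  are byte-identical. The read draw uses seed+1 so a community can be
  resampled with fixed references.
- Divergence 0 is allowed (identical references); divergence whose
  expected difference count is below one nucleotide is rejected.

## Known limitations

- The recruiter is exact but not a production short-read mapper; it is
  built for curated marker databases (10²–10⁴ references), not whole
  genomes.
- Placement distance ignores among-site rate variation; at high divergence
  (> ~30% aa) nearest-reference placement degrades before the supported
  clades do.
- The Spearman permutation p-value enumerates n! orderings and is
  restricted to n ≤ 9 by design.
- Absolute cell abundances per volume are out of scope (no spike-in
  model); everything is relative to a declared denominator.
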