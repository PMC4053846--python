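# Methods

## Conservation screen

**Windows.** Each candidate editing site contributes the genomic window of
2·f + 1 nt on the edited strand, f = 40 by default (81 nt, edited A at
center index 40). Minus-strand sites are reverse-complemented so windows
always read 5′→3′ on the edited strand. Sites closer than f to a contig
end are skipped with a logged warning in batch mode (padding would
fabricate sequence); in single-site mode they raise. Editing-site windows
must carry A at the center; SNP-control windows may carry any base.

**Alignment.** The all-vs-all search is an exact Smith–Waterman local
alignment with affine gaps, scored match +2, mismatch −3, gap open −5, gap
extend −2 (rewards in the range used by discontiguous-megablast searches).
The first base of a gap costs the open penalty and each further base the
extend penalty. N never matches anything, including N. The dynamic program
is JIT-compiled (numba) so desk-scale all-vs-all screens (≲10⁵ window
pairs) run in seconds; no external aligner binary is involved.

**Determinism conventions.** Co-optimal alignments can differ in their
identical-column count, so tie-breaking is part of the contract: the
traceback starts at the highest-scoring cell (ties to the smallest row,
then column), prefers diagonal over up over left, prefers closing a gap
over extending it, and stops when the running score reaches zero. The test
suite's independent plain-Python oracle implements the same stated
conventions.

**Hit criterion.** A window pair is a conserved hit when the alignment has
at least `min_identical` = 70 identical columns and the two center
positions are paired in one identically matching column. A query site with
any passing subject hit counts once as conserved; all passing pairs are
reported (no reciprocal-best filtering — any-hit is the documented choice,
since an E-value/best-hit policy is not part of the criterion). Raising
`min_identical` can only shrink the conserved set.

**SNP control.** The control screen reuses the identical machinery with
the center-must-be-A extraction check disabled; the center columns of the
two SNP windows must still align as an exact match. The normalized noise
estimate rescales raw control hits by both catalog-size ratios (see
README); the ratio is reported as infinite when the control yields zero
hits. Full database sizes can be supplied when the screen ran on a subset,
so either normalization is reproducible.

## Editing-level quantification

Pileup parsing consumes 6-column samtools-mpileup text: `^` (plus its
mapping-quality byte), `$`, and indel blocks are consumed; `>`/`<`
reference skips are ignored; `*` deletions count as N and never enter A/G
arithmetic; read-strand case is folded so counts are reference-strand base
counts. Bases with Phred+33 quality below 30 are discarded — one
mis-called base is indistinguishable from editing at these depths.

The level at a site is G/(A+G) on the edited strand: plus-strand sites use
the reference-strand A and G counts, minus-strand sites the T and C
counts. Coverage states: `no_data` below 3 quality-passing reads;
`edited` with ≥ 2 G reads at level ≥ 0.01; otherwise `covered_unedited`.
The evidence thresholds (2 reads, 1%) are a documented package default —
the profiling literature states the coverage floor but not the evidence
rule — and both are configurable. De-novo candidate calling uses the
stricter zebrafish-style rule: reference-A columns with **more than** 5
edited reads and level **higher than** 0.01 (both strict), scanning
plus-strand A columns only unless minus-strand calling is enabled
(unstranded pileups cannot assign strand).

Per-site summaries use the sample standard deviation (ddof = 1) over
samples with a defined level; the expression proxy is the read count in
the single deepest sample (maximal summed coverage), mirroring the use of
the highest-depth strain for expression. Group comparisons are exported
with their descriptive statistics; significance tests on them are standard
scipy tests and not a calibrated output of this package.

## Downstream statistics

**Accumulation curves.** Greedy minimal-addition order: first the smallest
strain set, then repeatedly the strain adding the fewest new sites, ties
broken lexicographically (the greedy rule is specified; the tie-break is a
convention). Equivalence with exhaustive stepwise-minimal search is tested
on all instances up to six samples.

**Motif matrix.** Empirical base frequencies at offsets ±10 around the
edited A; each row is a probability vector, the center row is degenerate
at A for editing input. Information content 2 + Σ p·log₂ p is available
for logo rendering; the TSV layout is consumable by standard logo tools.

**Region/recoding classification.** A CDS site is non-synonymous iff the
reference and alternate amino acids of its `p.` annotation differ (stop
gain counts as non-synonymous); CDS rows without a parseable annotation
are counted separately and excluded from the synonymy denominator. An
intronic site is "in a recoding gene" when its gene also carries a CDS
site in the same list. The packaged 59-site catalog has 38 CDS rows but
only 37 annotated ones, and the published percentage denominators are not
fully consistent with the row counts; the report therefore exposes raw
counts and both denominators rather than choosing.

**Reversion analysis.** For each editing site, the window at the
orthologous locus of the other genome is aligned to the site's own window;
with ≥ 70 identical columns, the base paired with the edited position is
its counterpart — the A↔A center requirement is deliberately dropped here,
because it would exclude exactly the reverted (G-counterpart) sites being
counted. Both G/all-matched and G/(A+G) fractions are reported, since
"matching position" admits either denominator. The control repeats the
lookup on the nearest non-edited A within ±20 nt on the edited strand
(upstream first on ties; the selection rule is a convention). The two
directions are compared in a 2×2 G vs non-G table with the sample odds
ratio and a two-sided Fisher exact p computed by exact integer
hypergeometric enumeration (tie tables are compared on integer numerators,
so the p equals an enumeration oracle to machine precision; scipy's
float-epsilon tie handling can differ, which is why the test is not
delegated). The published fold-enrichment figure (1.66) is not consistent
with the published 26%/18% fractions (≈1.44); the package reports the
fractions and their ratio and does not target the fold figure.

**ECS scan.** Secondary-structure prediction is replaced by a
sequence-level scan: the site's window is locally aligned against the
reverse complement of the locus sequence; every non-self interval with
≥ 70 identical columns is reported as a *candidate* ECS (no structure is
folded). Found intervals are masked with N and the scan repeats, so
multiple candidates are returned and lowering the threshold can only add
hits.

## Synthetic data

The generator emulates the structure the screen assumes. Two genomes:
the subject is the query mutated i.i.d. per base at background divergence
d = 0.05 (uniform target base, Jukes–Cantor-like; no indels by default
since the criterion is identity-count based), except inside conserved-site
windows, which mutate at d_c = 0.02 with the edited base preserved in both
species. The config validates (2f+1)(1−d_c) ≥ min_identical + 2 so planted
windows clear the threshold in expectation, and a post-generation
self-check aligns every planted pair and aborts if any fails the
criterion. Loci sit on a grid with ≥ 101 nt spacing, so windows never
overlap and SNPs are always > 100 nt from editing sites.

Default panel sizes are 10 conserved sites, 100 query-only decoys, 50
subject-only sites, 100 SNPs per species plus 2 shared SNP positions (the
shared pair gives the control screen a finite hit count; disjoint SNPs
produce none). Lineage-specific sites keep an A at their own center; the
counterpart center in the other genome is hardwired to G with probability
0.26 (query side) / 0.18 (subject side) and preserved as A otherwise —
preserving rather than re-mutating the non-reverted centers keeps the
planted counterpart distribution exactly Binomial and the null exactly
symmetric, which is what the reversion checks assume.

True editing levels are Beta-distributed per site and strain: conserved
Beta(12, 12) (mean 0.5, SD ≈ 0.1, echoing the ≈51% mean editing of the
conserved set), others Beta(0.125, 1.125) (mean 0.1, SD ≈ 0.2). Pileups
draw depth ~ Poisson(30) and edited reads ~ Binomial(depth, level), apply
a uniform mis-read at rate 0.001, and give 10% of bases a quality below
Phred 30 so the filter is exercised; strain panels include conserved sites
with probability 0.97 per strain (topped up to a ≥ 94% floor) and other
sites with probability 0.5. Identical configurations produce byte-identical
FASTA/TSV/mpileup output.

What the generator does *not* emulate: repeat-element sequence context
(Alu/B1/LINE), indels, read mapping ambiguity, fragment/duplicate
structure, or RNA secondary structure. Passing tests therefore demonstrate
the correctness and calibration of the screen and quantification machinery
under the stated model — not the false-positive structure of real
repeat-rich transcriptomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the screen at its default
conditions (110 query × 60 subject windows; 20 seeds for operating
characteristics), reversion analyses at 1,000 sites per side (500 per side
× 20 seeds for the null), motif recovery at 5,000 windows, and level
calibration at 1,000 binomial replicates of depth 50 — sizes chosen so
each Monte-Carlo check has comfortable statistical margin. The headline
"59-conserved-sites-from-1.4M" result is not recomputable from scratch
without the original species catalogs and genome assemblies; the catalog
itself ships as data, and the screen's behavior is validated on planted
synthetic data instead. For the symmetric reversion null, a per-seed 95%
CI fails ~5% of honest runs by construction, so the check requires the
pooled 20-seed table's exact CI to cover 1 and at least 17 of 20 per-seed
CIs to cover 1 (P ≈ 0.016 of a false alarm under the null).

JSON/TSV writers serialize floats at 6 decimals with deterministic column
order, so repeated runs diff byte-identically. All randomness flows
through `numpy.random.default_rng` seeded from the configuration.

## Known limitations

* Orthology between species is positional (same chromosome name and
  coordinate), which is exact for the synthetic genome pairs; real
  cross-species runs should supply pre-mapped coordinates.
* The ECS scan finds sequence-level reverse-complement conservation only;
  it neither folds structures nor estimates binding energies.
* Candidate calling on unstranded pileups cannot distinguish A→G on the
  plus strand from T→C artifacts without the optional minus-strand mode.
* The screen is quadratic in the number of windows; million-site catalogs
  need pre-filtering or batching, which is outside the tested scope.
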