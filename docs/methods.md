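# Methods

## Evidence model

A junction fragment produces a read pair: the ME Read identifies the
mobile element family, the Flanking Read localizes the insertion. The
pipeline consumes post-alignment evidence — BLAST tabular (outfmt 6)
scores for ME Reads and SAM alignments for Flanking Reads — rather
than raw FASTQ. The in-scope computation begins at read
classification; producing the alignments themselves (blastn, bwa mem)
is interchangeable upstream tooling, and the simulator emits evidence
at the same level so the whole stack is testable without an aligner.

All coordinates are 0-based half-open internally. SAM (1-based POS),
GTF (1-based inclusive) and VCF (1-based POS) are converted at the
I/O boundary and nowhere else.

## ME-Read scoring and family cutoffs

`score_me_read` computes a Smith–Waterman local alignment of the read
against the family consensus on both strands (the library chemistry
fixes orientation, but contaminating or simulated reads may arrive
flipped) and converts the raw score S to bits:

    bits = (λ·S − ln K) / ln 2

Scoring defaults mirror blastn-short: match +1, mismatch −3, gap open
5, gap extend 2 (a k-long gap costs open + k·extend), λ = 1.374,
K = 0.711. With these values a 30-bp perfect match scores ≈ 60 bits,
so the family cutoffs (AluYb 67, L1HS 56, SVA 48) correspond to
roughly 24–34 bp of effective identity. The production path normally
consumes bit scores already present in BLAST tabular input, so exact
engine parity is not required; the internal scorer exists for raw
sequence input and is verified against an independent Gotoh DP oracle
in the tests. Alignment is delegated to Biopython's PairwiseAligner
with an ACGTN substitution matrix in which N matches nothing.

The cutoff boundary is inclusive (score ≥ cutoff passes), matching
BLAST reporting conventions; a read with several HSPs contributes its
maximum.

`derive_bit_cutoff` selects the smallest threshold retaining ≥ 95% of
target-subfamily scores while admitting ≤ 5% of older-family scores
(both fractions are parameters). When the modes are N(35, 5) and
N(60, 4) this lands near 43 bits — just above the empirical 95th
percentile of the older mode, which is where the smallest feasible
threshold must sit. If no threshold satisfies both constraints the
least-contaminating threshold that preserves retention is returned
with a warning.

## Flanking-Read filtering

Two steps: (1) among all reported positions for a read (secondary and
supplementary alignments included), keep the single highest-MQ one,
breaking MQ ties deterministically by (chrom, start) so results are
independent of input order; (2) keep reads with MQ ≥ 30 (inclusive).
Perfect multi-mappers have MQ 0 and are always removed. Evidence is
then the read-id intersection of the ME-pass and flank-pass sets.

## Locus calling

Junction position: alignment end for plus-strand alignments, start
for minus strand — the flanking read's 3′ boundary abuts the element.
Clustering is single-linkage per (family, chromosome, strand): sorted
junction positions break into a new cluster when a gap exceeds the
window (500 bp default). This reading of a "sliding window" was
chosen over fixed anchored bins, which fragment loci at bin edges.
Opposite-strand clusters are never merged: the protocol sequences one
side of the insertion per family. Evidence from all samples is pooled
before clustering so one locus id spans the cohort — required for
cross-sample counting and trio logic.

The insertion position is the most ME-proximal junction (maximum for
plus-strand clusters, minimum for minus). Per-sample evidence:
read_count = member reads; UR = distinct alignment start positions
(after MQ filtering, within-cluster "uniqueness" can only mean
deduplicated fragment positions); TPM = read_count / total_mapped ×
10⁶. The TPM denominator defaults to the sample's fully filtered
evidence count (`mapped-filtered`), which makes TPM insensitive to
junk alignments and gives exact read-count conservation
(Σ per-locus counts = denominator); `mapped` (all mapped flanking
reads) is available as an option.

## Cutoff selection and presence calls

For each sample a 10 × 10 grid of (TPM, UR) cutoffs is evaluated
against the fixed-reference truth set: a truth interval counts as
recovered when a called locus lies within 100 bp (`match_tol`,
configurable; the matching tolerance is a design choice, not a
measured quantity) and the sample's evidence meets both cutoffs. The
selected cutoffs maximize t + u among grid points with sensitivity
strictly greater than 0.90 ("more than 90%"), ties broken toward
larger UR then larger TPM — "highest combination" is not well defined
on a 2-D grid, and this rule reproduces interior selections like
(4, 9)/(3, 10) rather than always returning a lexicographic extreme.
If no grid point exceeds the target, (1, 1) is returned with a
warning. Presence boundaries are inclusive: present ⇔ tpm ≥ cutoff
and ur ≥ cutoff.

## Annotation

Status precedence: reference > known_polymorphic > novel, matched
within 100 bp. Reference matching is family-aware; polymorphic-db
matching is family-agnostic because database family labels are
heterogeneous. Gene context tests the single-base insertion position
for containment with precedence CDS > UTR > exon_noncoding > intron >
intergenic. Chromatin-state densities divide locus counts per state by
the number of segments of that state (segment count, not base-pair
span — "locations" read literally; the alternative normalization is a
one-line change).

## Trio and somatic analytics

Inheritance error rate = (child loci absent from both parents) /
(all child loci); the denominator uses all child loci, and a
childless sample yields 0 by convention. The single-/both-parent
inheritance-rate analyses restrict to loci carried by ≥ 2 cohort
parents (damping parental false positives); trios with no qualifying
loci are excluded from averages rather than imputed. This carrier
filter applies only to the rate analyses, not to the error rate.
False-negative estimates are reported under two conventions — the
percentage-point difference r_max − r and the ratio 1 − r/r_max —
because neither alone is canonical when the best trio's rate is
below 100%.

De novo candidates default to strict-zero absence (zero supporting
reads in all other cohort members, not merely sub-cutoff), matching
the somatic screen's zero-read convention; a flag relaxes this to
cutoff-absence. Somatic candidates must be novel against the known-
polymorphic database, private to one individual, and present in
exactly one cell type with zero reads in every other cell type of
that individual.

## Simulator

Loci are placed uniformly with minimum spacing 2× the clustering
window (so distinct truth loci cannot merge); allele frequencies are
fixed, per-locus, or Beta-distributed; parental and unrelated
genotypes are Hardy–Weinberg draws, children receive one Mendelian
allele per parent (`transmit`: insertion transmitted with probability
copies/2). `forced_parent_genotypes` pins the parental state for
transmission-rate experiments. Read counts per (sample, locus) are
Poisson(depth_mean × copies/2); default depth_mean 20 reflects a
deeply covered targeted library where a heterozygous locus still
averages ~10 fragments. Junction offsets are Uniform(0, read_length),
emulating fragment-end geometry; bit scores draw from a two-mode
mixture (target mode above the family cutoff, older-subfamily mode
below); mapping noise includes MQ-0 multi-mappers, low-MQ tails,
uniform mismapping, and genome-wide background reads. Somatic events
emit reads only in their assigned cell type at Poisson(depth ×
cellular_fraction / 2).

Not modelled: base-level sequencing error, locus-specific PCR bias,
3′ transductions, and reference repeats that attract mismapped reads.
Consequently, passing tests demonstrate the correctness of the
filtering/clustering/selection logic under the stated statistical
model, not robustness to alignment artifacts around old repeats —
which is exactly the failure mode the trio error rate and somatic
screens are designed to expose on real data.

## Problem sizes and numerical choices

The bundled analyses use desk-scale cohorts chosen to make the
statistical expectations sharp: 10,000 trio loci give 3σ binomial
bands of ±1.5 pp around Mendelian rates; the cutoff-selection
benchmark uses 36 samples × 200 fixed loci at 20× depth, where
Poisson depth variation leaves each sample's selected-cutoff
sensitivity above 95% in practice. Clustering is O(n log n) in reads
and is verified against an O(n²) single-linkage oracle up to n = 200;
the alignment scorer is verified against an exhaustive DP for reads
≤ 40 bp against consensus ≤ 120 bp. All randomness flows from
explicit integer seeds; identical seeds give byte-identical simulator
output.

## Known limitations

Zygosity is not inferred (presence assays cannot separate 1/0 from
1/1 without depth modelling); breakpoints are cluster-level, not
base-pair refined; opposite-strand cluster pairs flanking the same
insertion are reported separately (a post-hoc merge flag exists but
is off by default); BAM/CRAM input is out of scope — plain SAM is the
contract the simulator and readers share.
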