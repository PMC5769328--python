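# Methods

## The problem

The classical HLA loci are the most polymorphic genes in the human genome:
a single gene can have thousands of documented alleles that differ by a
handful of substitutions, and distinct loci (HLA-A and the H/Y pseudogenes,
HLA-C and HLA-B) are themselves ~95% identical. Short reads captured from
these regions therefore map to many alleles at once, and two-field typing
(`GENE*group:protein`) amounts to deciding which diploid pair of alleles
per gene best explains the observed reads.

`hlacall` implements a capture-sequencing calling strategy built entirely
on *exact* contiguous matching. The aligner settings the approach relies on
(zero-mismatch end-to-end mapping; local alignment with mismatch and gap
penalties so large that any non-identity ends the alignment) reduce
mathematically to exact substring matching on both strands, so the engine
implements that contract directly — a hash index from fixed-length
substrings to placements, with consecutive-seed chaining to recover maximal
shared runs. Every mapping operation is verified set-identical to an
exhaustive offset-scanning oracle in the test suite.

## Pipeline

Reads are first collapsed by literal forward-strand sequence (PCR-duplicate
removal; multiplicities retained for reporting only). Calling then runs in
three stages per gene, followed by quality and null-allele checks.

**Stage 1 — tiling coverage.** Every large exon (>= 70 bp) of every allele
is decomposed into its 70-mers ("artificial reads"). A 70-mer is *matched*
when it, or its reverse complement, occurs inside at least one deduplicated
read. An allele survives only if, in each large exon, the union of matched
70-mer spans covers every exon base. A config switch (`stage1_rule: gaps`)
selects the weaker formulation that only bounds the distance between
adjacent matched 70-mers by 70 bp and therefore does not constrain the exon
ends; complete coverage is the default because it implies the gap rule and
matches the stated intent of removing alleles without full base coverage
inside large exons.

**Stage 2 — windowed first-base presence.** Whole reads (>= 100 bp
continuously mapped, i.e. end-to-end exact hits) are tabulated by the CDS
position of their first base into a per-gene matrix whose rows are the base
positions of the gene's longest candidate. Rows are raw CDS offsets; no
cross-allele registration is attempted (CDS indels are rare in these loci
and stage 3 re-tests survivors). Positions beyond a shorter allele's length
are "null" and count as covered when any other allele of the gene has a
read starting there. Non-overlapping 22 bp windows tile the rows (the
trailing short window is evaluated like any other; window stride is a
design choice — tiling is O(n) and deterministic). An allele is removed iff
some window gives it zero first-base presence while another allele of the
same gene has presence there. Single-candidate genes are left untouched.

**Stage 3 — reciprocal screening.** Surviving alleles are mapped locally
per exon: on exons >= 70 bp a read qualifies with a maximal exact shared
run >= 70 bp; exons of 30–69 bp must be contained entirely in the read.
For an unordered candidate pair, the *allele-specific reads* (ASR) of one
member are the reads mapping to it but not to the other. Stage 3 then:

1. seeds a *real allele pool* with every allele (all loci, including the
   H/Y companions) having >= 6 unique mapped reads — reads mapping to
   exactly one allele database-wide;
2. excludes *potential false alleles*: an allele with zero ASRs against a
   partner with some, or with >= 15-fold fewer ASRs than a partner, across
   any pairing — decided simultaneously from the pre-exclusion table;
3. scores every pair P of a gene: for each member instance of each
   evaluated pair of that gene, the instance's ASR set is *explained* by P
   when at most 8 of its reads fail to map to any allele of P or of the
   other loci's pool alleles; each explained instance earns P one point;
4. adds the top-scoring pair(s) of each gene to the pool and re-scores all
   genes, holding the pool fixed within a pass so results are independent
   of gene order, until the top pairs stabilise (cap: 5 passes; hitting the
   cap forces NOT PASS).

Pairing is exhaustive over all unordered pairs *including self-pairs* —
the original description pairs candidates randomly, but exhaustive
enumeration is deterministic, strictly more informative, and gives
homozygous genotypes a natural representation. All tied top-score pairs
are reported as the ambiguity set.

**Paralog correction.** For a reported HLA-A pair, if exactly one member's
entire ASR set maps into the surviving H/Y alleles, that member is an
artifact of cross-locus capture and is dropped (single-allele report); the
symmetric rule relates HLA-C to HLA-B. Both loci mappings are configurable
(`paralog_companions`), as is the set of never-reported companion loci
(`companion_genes`, default H and Y).

**Quality.** Per gene, `quality_value` = highest score / number of
evaluated pairs in the final pass. PASS requires the value to equal 2
exactly (checked in integer arithmetic: score == 2 x n_pairs), i.e. the
winning pair explains both allele-instances of every evaluated pair. The
final pass's pair universe is the denominator; with zero evaluated pairs
the gene is untypeable (value 0, NOT PASS).

**Null alleles.** Expressed-vs-null distinctions live in ~10 bp of
intron/exon boundary sequence. When a reported allele matches a trigger
(at equal or finer field resolution), the deduplicated reads are scanned
for the configured signature strings on either strand; the null allele is
flagged with more than three (>= 4) distinct supporting reads. Signature
matching is bare exact containment — the operational definition of
"supporting read" is not otherwise specified — and the signature table is
user-supplied (TSV: trigger_allele, null_name, signature); the package
ships no real signatures.

## Bait QC

A capture panel built from one long CDS bait per gene must pull down every
documented allele. `exon_identity` reports, per query exon longer than
23 bp (correspondence by exon index), the maximum number of matched bases
over all global alignments with unit match score and zero mismatch/gap
score — equivalently the longest-common-subsequence length — normalised by
the query exon length. `saturation_check` verifies that every query exon
base lies inside a contiguous exact match with the bait CDS of at least
`min_complementary` bases (default 20, the shortest stretch that supports
hybridization); verdicts are monotone non-increasing in the threshold.
`first_base_coverage` reports the capture-complexity metric: the fraction
of core-exon (2, 3, 4 by default) bases that are the 5' start of at least
one end-to-end hit.

## Synthetic data

`make_toy_database` builds a deterministic allele reference: per gene a
random ancestor CDS (default 800 bp) with a fixed exon tiling of lengths
73/50/200/276/…, chosen to include a sub-70 bp exon (exercising the
full-exon local rule) and several large exons; each allele carries exactly
`divergence` substitutions (default 4) at fresh random positions, re-drawn
on collision so all CDSs are distinct; paralog companions get a
95%-identical copy of the primary gene's ancestor. `simulate_reads` draws
error-free 100 bp single-end reads from the truth alleles' CDSs with
uniform start positions, optional PCR duplicates and substitution errors.
`depth` is the mean first-base coverage per allele copy — the expected
number of reads starting at each eligible position — so the expected read
count per copy is `depth x (len - read_len + 1)`; at the default depth 30
every start position is observed with probability ~1 - e^-30 and the
matching-based filters operate in their saturated regime, which is the
regime the capture protocol is designed to reach.

What the simulator deliberately does not model: intron/flank carry-over
(reads come from the CDS only), fragment-length and capture-efficiency
bias, indel errors, paired ends, and quality values (constant "I").
Passing tests therefore demonstrate the correctness of the decision logic
under its stated exact-matching contract, not robustness to the alignment
noise, contamination or uneven coverage of real libraries.

## Numerical and design choices

* All thresholds live in `PipelineConfig` with the published defaults:
  70 bp artificial reads and large-exon minimum, 30 bp local-exon minimum,
  >23 bp identity exons, 22 bp windows, 100 bp continuous mapping, 15-fold
  ASR exclusion, >= 6 unique reads for the pool, <= 8 unexplainable ASRs,
  > 3 null supporting reads, PASS value 2.
* Reads or alleles containing N are rejected/never match: exact matching
  is undefined on ambiguity codes.
* Reverse-strand hits report the CDS coordinate of the leftmost matched
  base (SAM convention).
* Exclusion uses the "exists a partner" quantifier, applied once from the
  simultaneous table; iterating to fixity is not done. A guard keeps the
  top-total-ASR allele if a gene would lose every candidate — provably
  unreachable (both rules require the partner's read set to be strictly
  larger, so a maximal-cardinality allele always survives) but retained
  defensively.
* Scoring is monotone in the pool, so pool growth can promote true pairs
  into ties but never demote a pair; ties are surfaced, not broken.
* Test and acceptance problem sizes — 3 genes x 12 alleles x 800 bp, 20
  heterozygous and 10 homozygous seeds, 200 randomized matcher instances —
  were chosen so the whole suite verifies every contract against
  brute-force oracles in about a minute on one core.

## Known limitations

* Candidate matrices align alleles by raw CDS offset; alleles with CDS
  indels relative to their gene mates can misregister in stage 2.
* Two alleles with identical CDS are inherently indistinguishable and are
  reported as a tied ambiguity set.
* Field-3/4 resolution, novel-allele discovery and genomic (intronic)
  references are out of scope; the only intron-derived evidence used is
  the null-allele signature check.
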