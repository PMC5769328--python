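# hlacall

Two-field HLA genotyping from hybridization-captured short reads, by
exact-match candidate filtration and reciprocal allele-pair scoring.

The classical HLA loci carry thousands of documented alleles differing by a
few substitutions, and whole loci (HLA-A vs the H/Y pseudogenes, HLA-C vs
HLA-B) are ~95% identical, so captured short reads map to many alleles at
once. `hlacall` decides, per gene, which diploid allele pair best explains
the reads, using only exact contiguous matching:

1. **Tiling coverage filter** — an allele survives only if every large
   exon (≥ 70 bp) is completely covered by the union of its 70-mers found
   exactly in the (PCR-deduplicated) reads.
2. **Window filter** — whole-read exact hits are tabulated by first-base
   position; an allele with an empty 22 bp window where another allele of
   the gene has hits is removed.
3. **Reciprocal screening** — for each candidate pair, *allele-specific
   reads* (ASR: reads mapping to one member but not the other) drive a
   15-fold/zero exclusion rule, then every pair P is scored: one point per
   allele-instance whose ASR set P explains (≤ 8 unexplainable reads)
   together with the other loci's *real allele pool* (alleles with ≥ 6
   unique mapped reads, grown iteratively with each gene's top pairs).
   A reported HLA-A (HLA-C) allele fully explained by the remaining H/Y
   (B) alleles is dropped as a cross-locus capture artifact.

A gene's call is marked **PASS** iff its quality value — top score divided
by the number of evaluated pairs — equals 2 exactly, i.e. the winning pair
explains both allele-instances of every evaluated pair. Null alleles,
distinguishable only by short intron/exon-boundary signatures, are flagged
when more than three deduplicated reads contain a configured signature.

The package also ships the surrounding tooling: an allele-reference model
reading IMGT-dialect CDS FASTA plus an exon table, a deterministic toy
database generator emulating HLA homology, a diploid read simulator with
known truth, bait-design QC (per-exon bait identity and saturation
coverage), and a CLI.

## Worked example

Generate a toy reference (3 genes × 12 alleles of 800 bp at divergence 4,
plus a 95%-identical pseudogene companion `H` of gene `A`), simulate a
diploid library, and type it:

```sh
hlacall makedb --genes 3 --alleles-per-gene 12 --cds-len 800 \
    --divergence 4 --paralog A:H --seed 7 --out db
hlacall simulate --alleles db/alleles.fasta --exons db/exons.tsv \
    --truth "A=A*03:01,A*09:01" --truth "B=B*02:01,B*07:01" \
    --truth "C=C*05:01,C*05:01" --truth "H=H*01:01,H*02:01" \
    --depth 30 --dup-rate 0.2 --seed 11 --out sim
hlacall type --reads sim/reads.fastq --alleles db/alleles.fasta \
    --exons db/exons.tsv --out typed
```

which prints

```
A	A*03:01/A*09:01	PASS
B	B*02:01/B*07:01	PASS
C	C*05:01/C*05:01	PASS
```

and writes `typed/genotype.tsv`:

```
gene	allele_1	allele_2	ambiguity	quality_value	quality	top_score	n_pairs	null_flags
A	A*03:01	A*09:01	A*03:01/A*09:01	2.0000	PASS	6	3	
B	B*02:01	B*07:01	B*02:01/B*07:01	2.0000	PASS	6	3	
C	C*05:01	C*05:01	C*05:01/C*05:01	2.0000	PASS	2	1	
```

All three genotypes match the simulated truth, including the homozygous
gene C (a self-pair: one evaluated pair, score 2). For genes A and B the
two surviving candidates yield three evaluated pairs (including the two
self-pairs) and the heterozygous truth pair explains both instances of all
three — score 6, quality value 6/3 = 2, hence PASS. The pseudogene `H`
takes part in mapping, unique-read counting and the allele pool but is
never reported. The same pipeline is available in-memory via
`hlacall.call_genotypes(db, reads, config)`.

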