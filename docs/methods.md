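# Methods

This note documents the models, parameter choices and numerical conventions
behind `tauvar`, and what the synthetic-data validation does and does not
demonstrate about real resequencing data.

## Calling model

Calling operates on per-site pileup counts downstream of read mapping; no
genotype-likelihood model is applied. Any site whose pileup contains a
non-reference allele is a candidate, and the decision is a conjunction of
three inclusive thresholds on the highest-count alternate allele:
depth ≥ `min_depth` (default 3), alternate reads ≥ `min_alt_reads`
(default 2), and alternate fraction ≥ `min_alt_fraction` (default 0.30).
Zygosity is a single cutoff on the same fraction: homozygous-alternate at
≥ `hom_fraction` (default 0.80), heterozygous below. Boundary conventions
are inclusive everywhere (a site at exactly 30% passes; a call at exactly
80% is homozygous) and are pinned by explicit boundary tests.

Multi-allelic sites are reduced to the single highest-count alternate;
count ties break to the lexicographically smallest allele token and are
logged. This biallelic reduction matches the behaviour of the
pileup-threshold callers this design descends from. Indels are represented
as atomized tokens (`+SEQ` insertion, `-SEQ` deletion, anchor excluded)
carried through identical thresholds; in VCF output they acquire the
conventional anchor base.

Rejected sites carry one reason code, evaluated in a fixed order:
`LOW_DEPTH`, then `NO_ALT` (no non-reference allele observed at all), then
`LOW_ALT`, then `LOW_FRACTION`. `NO_ALT` exists because a site with zero
alternate reads has no meaningful candidate allele to report against the
`LOW_ALT` threshold.

## Consequence annotation

Gene models are single-transcript: sorted non-overlapping exons, a CDS
interval whose spliced length is divisible by 3, genomic-orientation
coordinates (1-based inclusive). The annotation index holds per-chromosome
interval trees over gene bodies and flanks; splice windows and CDS segment
offsets are precomputed per gene, so a query is O(log n) in gene count.

A SNP inside a CDS is classified at its codon. The spliced CDS offset
determines codon index and position-in-codon; the alternate base
(complemented for minus-strand genes) is substituted into the reference
codon and both codons are translated with the standard genetic code
(Biopython, table 1). The classification is provably equivalent to mutating
the entire CDS and diffing the translated proteins — the test suite checks
this equivalence on 1,000 random coding SNPs per strand against exactly
that brute-force oracle, and a strand-symmetry test verifies that
reverse-complementing the genome, the models and the alleles leaves every
category unchanged. Stop-gain/loss changes are reported as `NONSYNONYMOUS`
with `*` recorded in the codon change, so finer classes remain recoverable.

Non-coding positions inside a gene are `SPLICE_SITE` when within
`splice_bp` intronic bases of an exon boundary (default 2, the canonical
GT/AG dinucleotides; the window is configurable because splice-region
conventions vary), `UTR` when exonic outside the CDS (the 5′/3′ side is
retained internally but reported as one category), otherwise `INTRON`.
Outside gene bodies, positions within `flank_bp` (default 5000) of a
transcript end are `UPSTREAM_5KB`/`DOWNSTREAM_5KB` relative to the gene's
strand; everything else is `INTERGENIC`.

Single assignment under overlap is resolved by severity precedence
`NONSYNONYMOUS > SYNONYMOUS > SPLICE_SITE > UTR > INTRON > UPSTREAM_5KB >
DOWNSTREAM_5KB > INTERGENIC` (indels: `SPLICE_SITE > EXON > INTRON >
FLANK_5KB > INTERGENIC`), with ties broken by lexicographic gene id. The
precedence order is a design choice — reported totals are single-count
partitions, and functional severity is the natural ordering — and the
deterministic tie-break makes annotation reproducible across runs. An
indel's affected interval is its anchor position through
`anchor + len(ref) − 1`; any overlap with a splice window classifies it
`SPLICE_SITE`.

## Synthetic data: what it emulates

The generator produces the regime this pipeline targets, as a pure function
of `(config, seed)`:

| parameter | default | meaning |
|---|---|---|
| `chromosome_lengths` | [1 Mb] | i.i.d. A/C/G/T sequence at `gc_fraction` (0.42, mammalian-like) |
| `n_genes` | 20 | non-overlapping genes, both strands, placed with ≥ `flank_bp` clearance |
| `mean_exons_per_gene` | 4 | exon count ~ 1 + Poisson(mean−1); exons 120–300 bp, introns 200–800 bp, UTRs 40–80 bp |
| `n_variants_per_category` | 30 | planted per category, ≥ 10 bp apart |
| `mean_depth` | 20 | site depth ~ Poisson(mean_depth) |
| `error_rate` | 0.005 | per-read substitution to a uniform other base |
| `het_fraction_mean` | 0.5 | alternate-read probability at heterozygous sites |
| `hom_fraction_mean` | 0.98 | alternate-read probability at homozygous sites |

Gene placement edits the reference so every CDS begins with ATG, ends with
a stop, and contains no internal stop on the coding strand; minus-strand
genes are edited through the reverse complement. Variant planting verifies
every position at planting time with a naive linear-scan classifier — a
deliberately separate implementation from the interval-tree annotator —
and, for synonymous/nonsynonymous plants, with a full-CDS
mutate-translate-diff. Planted variants are kept ≥ 10 bp apart so each
codon holds at most one variant; real data contain multi-variant codons,
but category totals count variants independently, so independence is the
regime being emulated.

Pileup simulation draws depth ~ Poisson(`mean_depth`) and alternate reads ~
Binomial(depth, p) with p set by planted zygosity; substitution errors
replace a base-carrying read's base with one of the three other bases at
`error_rate` (indel-supporting reads are not perturbed — the simplest model
that stresses the 30% fraction filter). Besides the truth sites,
`n_background_sites` (default 2000) variant-free positions are emitted with
reference-dominated counts to exercise false-positive behaviour; emitting
every genomic position would add runtime without adding information. The
depth track used for coverage summaries is generated separately
(vectorized Poisson field with ~7% zero-depth blocks of ~500 bp emulating
unmappable or highly diverged regions, so covered fraction sits near the
low-90s percent range seen in cross-breed resequencing rather than at
100%).

What passing the closed-loop tests does *not* show about real data: there
is no read-level simulation (no mapping ambiguity, indel-realignment
artifacts, base-quality structure, strand bias or PCR duplicates), no
repeat or satellite structure, and gene models are single-transcript.
Recovery rates on this generator are therefore upper bounds for real
pileups.

## Statistical behaviour of the filters

With depth ~ Poisson(20) and heterozygous alternate reads ~ Binomial(d,
0.5), the probability that a true heterozygous site fails the filter
conjunction has a closed form (enumerate depths, sum binomial tails below
`max(min_alt_reads, ceil(0.3 d))`): ≈ 3.9–4.0% per site, giving an expected
sensitivity of ≈ 0.980 over an even het/hom mix (homozygous failure is
negligible, < 10⁻⁶). The sensitivity test therefore checks the simulation
against this closed-form expectation within three standard errors rather
than against a point threshold that the expectation itself straddles.
Zygosity misclassification of called heterozygous sites (alternate
fraction reaching 0.80 by sampling noise) is ≈ 0.6% per het site at depth
20, so zygosity accuracy on called sites is expected ≈ 99.6%.

## Summaries and arithmetic conventions

All aggregations are conservative (window counts, histograms and partitions
sum exactly to their inputs; tested). Percentages use decimal half-up
rounding, one decimal for variant partitions and whole numbers for read
partitions, matching the precision such results are reported at. Partition
schemas form trees; internal totals are computed by summation when not
given, a child exceeding its parent is an error, and children are permitted
to under-sum their parent (published genic sub-partitions sometimes do).
Novelty matching is by position only (allele-aware matching is available on
the known-set reader side by supplying a VCF); a zero-call input yields an
explicit undefined-percentage flag rather than a number. Coverage is
`depth ≥ min_depth` (default 1) and fold-coverage averages over covered
positions only. Density windows are fixed 1-kb tiles, last window
truncated.

## Consensus policy

How heterozygous sites should appear in a consensus used for phylogenetics
is genuinely underdetermined, so all three policies are first-class:
`IUPAC` (default; ambiguity codes such as A/G → R preserve the information
and are understood by ML/Bayesian tools), `MAJOR_ALLELE` (alternate iff its
read fraction ≥ 0.5) and `ALT_ALLELE`. Indels are excluded by default so
output length equals region length; when included they are applied
right-to-left so earlier coordinates stay valid. Alignment across taxa is
assumed: per-gene sequences must be equal-length (the package concatenates
and exports; it does not align). Tree inference is out of scope — the
exports (FASTA, relaxed PHYLIP, `DNA, gene = start-end` partitions) are the
inputs to RAxML/MrBayes-class tools.

## Validation problem sizes

The test suite and acceptance script use a 1 Mb genome with 20 genes and
330 planted variants for the closed loop (runs in ~1 s), 1,000 planted
SNPs for the sensitivity/zygosity checks, 1,000 random coding SNPs per
strand for the codon-oracle equivalence, 2,000 random calls for density
conservation, and a 16-taxon × 10-gene (~10.5 kb) matrix for the
consensus/alignment invariants — sizes chosen so the complete validation
runs in seconds while every code path and both strands are exercised.

## Known limitations

- Biallelic reduction: a genuinely triallelic site reports only the
  dominant alternate.
- One transcript per gene; overlapping isoforms collapse to severity
  precedence rather than per-transcript consequence sets.
- The caller consumes pileup counts; producing those counts from BAM/SAM
  alignments is outside the package (any pileup engine emitting the TSV
  dialect works).
- No quality-, strand- or mapping-bias-aware filtering: the filter set is
  deliberately the minimal depth/count/fraction conjunction it documents.
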