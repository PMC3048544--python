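"""Consequence annotation of variants against single-transcript gene models.

Every variant receives exactly one category. For SNPs the label set is
NONSYNONYMOUS, SYNONYMOUS, SPLICE_SITE, UTR, INTRON, UPSTREAM_5KB,
DOWNSTREAM_5KB, INTERGENIC; for indels SPLICE_SITE, EXON, INTRON, FLANK_5KB,
INTERGENIC. When a position is claimable by several genes (overlapping genes,
a flank reaching into another gene's neighbourhood) the most severe label
wins, in the order above; equal severity resolves to the lexicographically
smallest gene_id, so annotation is deterministic.

Coding SNPs are classified at the codon: the variant's offset within the
spliced CDS locates its codon and position therein, the alternate base is
substituted (complemented for minus-strand genes) and both codons are
translated with the standard genetic code. A change that creates or removes
a stop codon is still NONSYNONYMOUS; the CodonChange records ``*`` so finer
classes remain recoverable.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import (
    INDEL_SEVERITY,
    SNP_SEVERITY,
    AnnotatedVariant,
    AnnotationParams,
    CodonChange,
    GeneModel,
    IndelCategory,
    SnpCategory,
    VariantCall,
    VariantType,
)

ReferenceLike = Mapping[str, object]  # chrom -> str or pyfaidx FastaRecord


def fetch_seq(ref: ReferenceLike, chromosome: str, start: int, end: int) -> str:
    """1-based inclusive substring of the reference (dict of str or pyfaidx)."""
    return str(ref[chromosome][start - 1 : end]).upper()


def translate(codon: str, table: int = 1) -> str:
    """Translate one codon with the standard genetic code; stop is ``*``."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return str(Seq(codon).translate(table=table))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cds_sequence(gene: GeneModel, ref: ReferenceLike) -> str:
    """Spliced CDS on the coding strand."""
    seq = "".join(
        fetch_seq(ref, gene.chromosome, s, e) for s, e in gene.cds_segments
    )
    return revcomp(seq) if gene.strand == "-" else seq


def cds_offset(gene: GeneModel, position: int) -> Optional[int]:
    """0-based offset of a genomic position within the spliced coding-strand CDS.

    Returns None when the position is not coding.
    """
    segments = gene.cds_segments
    offset = 0
    if gene.strand == "+":
        for s, e in segments:
            if s <= position <= e:
                return offset + (position - s)
            offset += e - s + 1
    else:
        for s, e in reversed(segments):
            if s <= position <= e:
                return offset + (e - position)
            offset += e - s + 1
    return None


def splice_windows(gene: GeneModel, splice_bp: int) -> list[tuple[int, int]]:
    """Intronic intervals adjacent to each exon-intron junction."""
    windows = []
    for intron_start, intron_end in gene.introns:
        span = intron_end - intron_start + 1
        w = min(splice_bp, span)
        windows.append((intron_start, intron_start + w - 1))
        if intron_end - w + 1 > intron_start + w - 1:
            windows.append((intron_end - w + 1, intron_end))
    return windows


class AnnotationIndex:
    """Interval-queryable structure over gene bodies and their flanks."""

    def __init__(self, genes: Sequence[GeneModel], params: AnnotationParams = AnnotationParams()):
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
        self.params = params
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._body: dict[str, IntervalTree] = {}
        self._flank: dict[str, IntervalTree] = {}
        self._splice: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            body = self._body.setdefault(g.chromosome, IntervalTree())
            # intervaltree is half-open; store [start, end+1)
            body.addi(g.tx_start, g.tx_end + 1, g.gene_id)
            if params.flank_bp > 0:
                flank = self._flank.setdefault(g.chromosome, IntervalTree())
                left = (max(1, g.tx_start - params.flank_bp), g.tx_start - 1)
                right = (g.tx_end + 1, g.tx_end + params.flank_bp)
                up_side = "left" if g.strand == "+" else "right"
                for side, (s, e) in (("left", left), ("right", right)):
                    if s > e:
                        continue
                    label = (
                        SnpCategory.UPSTREAM_5KB
                        if side == up_side
                        else SnpCategory.DOWNSTREAM_5KB
                    )
                    flank.addi(s, e + 1, (g.gene_id, label))
            self._splice[g.gene_id] = splice_windows(g, params.splice_bp)

    # -- queries ---------------------------------------------------------

    def genes_containing(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._body.get(chromosome)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.at(position)),
            key=lambda g: g.gene_id,
        )

    def genes_overlapping(self, chromosome: str, start: int, end: int) -> list[GeneModel]:
        tree = self._body.get(chromosome)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end + 1)),
            key=lambda g: g.gene_id,
        )

    def flanks_at(self, chromosome: str, start: int, end: int | None = None):
        """(gene_id, flank label) pairs whose flank interval meets [start, end]."""
        tree = self._flank.get(chromosome)
        if tree is None:
            return []
        end = start if end is None else end
        return sorted((iv.data for iv in tree.overlap(start, end + 1)),
                      key=lambda d: d[0])

    def splice_windows_of(self, gene_id: str) -> list[tuple[int, int]]:
        return self._splice[gene_id]


def build_index(
    genes: Sequence[GeneModel], params: AnnotationParams = AnnotationParams()
) -> AnnotationIndex:
    return AnnotationIndex(genes, params)


def _in_any(intervals: Iterable[tuple[int, int]], position: int) -> bool:
    return any(s <= position <= e for s, e in intervals)


def _overlaps_any(intervals: Iterable[tuple[int, int]], start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in intervals)


def _codon_change(
    gene: GeneModel, ref: ReferenceLike, position: int, alt_base: str
) -> CodonChange:
    offset = cds_offset(gene, position)
    assert offset is not None
    cds = cds_sequence(gene, ref)
    codon_index = offset // 3
    pos_in_codon = offset % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    coding_alt = alt_base if gene.strand == "+" else alt_base.translate(_COMPLEMENT)
    alt_codon = (
        ref_codon[:pos_in_codon] + coding_alt + ref_codon[pos_in_codon + 1 :]
    )
    return CodonChange(
        gene_id=gene.gene_id,
        codon_index=codon_index + 1,
        position_in_codon=pos_in_codon + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=translate(ref_codon),
        alt_aa=translate(alt_codon),
    )


def _snp_category_in_gene(
    gene: GeneModel, index: AnnotationIndex, position: int
) -> SnpCategory:
    """Label for a position inside a gene body, coding resolved elsewhere."""
    if cds_offset(gene, position) is not None:
        return SnpCategory.SYNONYMOUS  # placeholder for "coding"; refined by caller
    if _in_any(index.splice_windows_of(gene.gene_id), position):
        return SnpCategory.SPLICE_SITE
    if _in_any(gene.exons, position):
        return SnpCategory.UTR
    return SnpCategory.INTRON


def annotate_snp(
    call: VariantCall,
    index: AnnotationIndex,
    ref: ReferenceLike,
) -> AnnotatedVariant:
    """Assign the single consequence category of a SNP call."""
    if call.variant_type is not VariantType.SNP:
        raise ValueError("annotate_snp requires a SNP call")
    pos = call.position
    ref_base = fetch_seq(ref, call.chromosome, pos, pos)
    if ref_base != call.ref_allele:
        raise ValueError(
            f"{call.chromosome}:{pos}: call ref allele {call.ref_allele} "
            f"disagrees with reference base {ref_base}"
        )
    candidates: list[tuple[int, str, SnpCategory, Optional[CodonChange]]] = []
    for gene in index.genes_containing(call.chromosome, pos):
        cat = _snp_category_in_gene(gene, index, pos)
        change = None
        if cds_offset(gene, pos) is not None:
            change = _codon_change(gene, ref, pos, call.alt_allele)
            cat = (
                SnpCategory.SYNONYMOUS if change.synonymous else SnpCategory.NONSYNONYMOUS
            )
        candidates.append((SNP_SEVERITY[cat], gene.gene_id, cat, change))
    for gene_id, label in index.flanks_at(call.chromosome, pos):
        candidates.append((SNP_SEVERITY[label], gene_id, label, None))
    if not candidates:
        return AnnotatedVariant(call, SnpCategory.INTERGENIC.value)
    severity, gene_id, cat, change = min(candidates, key=lambda c: (c[0], c[1]))
    return AnnotatedVariant(call, cat.value, gene_id=gene_id, codon_change=change)


def annotate_indel(
    call: VariantCall,
    index: AnnotationIndex,
) -> AnnotatedVariant:
    """Classify an indel by its affected interval (anchor .. anchor+len(ref)-1)."""
    if call.variant_type is VariantType.SNP:
        raise ValueError("annotate_indel requires an INS or DEL call")
    start = call.position
    end = call.position + len(call.ref_allele) - 1
    candidates: list[tuple[int, str, IndelCategory]] = []
    for gene in index.genes_overlapping(call.chromosome, start, end):
        if _overlaps_any(index.splice_windows_of(gene.gene_id), start, end):
            cat = IndelCategory.SPLICE_SITE
        elif _overlaps_any(gene.exons, start, end):
            cat = IndelCategory.EXON
        else:
            cat = IndelCategory.INTRON
        candidates.append((INDEL_SEVERITY[cat], gene.gene_id, cat))
    for gene_id, _label in index.flanks_at(call.chromosome, start, end):
        candidates.append((INDEL_SEVERITY[IndelCategory.FLANK_5KB], gene_id,
                           IndelCategory.FLANK_5KB))
    if not candidates:
        return AnnotatedVariant(call, IndelCategory.INTERGENIC.value)
    _sev, gene_id, cat = min(candidates, key=lambda c: (c[0], c[1]))
    return AnnotatedVariant(call, cat.value, gene_id=gene_id)


def annotate_variants(
    calls: Iterable[VariantCall],
    index: AnnotationIndex,
    ref: ReferenceLike,
) -> list[AnnotatedVariant]:
    out = []
    for call in calls:
        if call.variant_type is VariantType.SNP:
            out.append(annotate_snp(call, index, ref))
        else:
            out.append(annotate_indel(call, index))
    return out


def category_counts(annotated: Iterable[AnnotatedVariant]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for av in annotated:
        counts[av.category] = counts.get(av.category, 0) + 1
    return counts
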