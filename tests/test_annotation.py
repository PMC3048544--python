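"""Consequence classification: codon examples, independent oracles,
strand symmetry, single-assignment partition."""

import random

import pytest

from tauvar import annotation
from tauvar.models import (
    AnnotationParams,
    GeneModel,
    IndelCategory,
    SnpCategory,
    VariantCall,
    VariantType,
    Zygosity,
)

# A second, hand-entered transcription of the standard genetic code,
# independent of the Biopython table the implementation uses.
HAND_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def snp(chrom, pos, ref, alt, zyg=Zygosity.HET):
    return VariantCall(chrom, pos, VariantType.SNP, ref, alt, 20, 10, zyg)


def indel(chrom, pos, ref, alt):
    vtype = VariantType.INS if len(alt) > len(ref) else VariantType.DEL
    return VariantCall(chrom, pos, vtype, ref, alt, 20, 10, Zygosity.HET)


class TestTranslate:
    def test_all_64_codons_match_hand_entered_table(self):
        for codon, aa in HAND_CODON_TABLE.items():
            assert annotation.translate(codon) == aa, codon

    @pytest.mark.parametrize("bad", ["AT", "ATGC", "ANG", "AUG"])
    def test_ambiguous_or_malformed_codon_rejected(self, bad):
        with pytest.raises(ValueError):
            annotation.translate(bad)


def _hand_gene():
    """Plus-strand gene on a hand-written 100 bp contig.

    Layout (1-based): exon1 11-40, intron 41-60, exon2 61-90.
    5'UTR 11-19 (9 bp), CDS 20-40 + 61-69 (30 bp = 10 codons), 3'UTR 70-90.
    """
    # CDS codons: ATG GCT GAT AAA CCC GGG TTT CAT CGA TAA
    cds = "ATGGCTGATAAACCCGGGTTTCATCGATAA"
    seq = (
        "T" * 10
        + "AGAGAGAGA"          # 5'UTR (11-19)
        + cds[:21]              # CDS part 1 (20-40)
        + "GTAAGTACGTACGTACGTAG"  # intron (41-60), GT..AG
        + cds[21:]              # CDS part 2 (61-69)
        + "C" * 21              # 3'UTR (70-90)
        + "A" * 10
    )
    gene = GeneModel(
        gene_id="g1",
        chromosome="chr1",
        strand="+",
        tx_start=11,
        tx_end=90,
        exons=((11, 40), (61, 90)),
        cds_start=20,
        cds_end=69,
    )
    return {"chr1": seq}, gene


class TestSnpAnnotationHandCases:
    def setup_method(self):
        self.ref, self.gene = _hand_gene()
        self.index = annotation.build_index([self.gene], AnnotationParams(flank_bp=5))

    def test_synonymous_third_position_wobble(self):
        # codon 2 is GCT (Ala) at 23-25; T->C at 25 gives GCC, still Ala
        av = annotation.annotate_snp(snp("chr1", 25, "T", "C"), self.index, self.ref)
        assert av.category == SnpCategory.SYNONYMOUS.value
        cc = av.codon_change
        assert (cc.ref_codon, cc.alt_codon) == ("GCT", "GCC")
        assert (cc.codon_index, cc.position_in_codon) == (2, 3)
        assert cc.ref_aa == cc.alt_aa == "A"

    def test_nonsynonymous_first_position(self):
        # codon 3 GAT (Asp) at 26-28; G->A at 26 gives AAT (Asn)
        av = annotation.annotate_snp(snp("chr1", 26, "G", "A"), self.index, self.ref)
        assert av.category == SnpCategory.NONSYNONYMOUS.value
        assert (av.codon_change.ref_aa, av.codon_change.alt_aa) == ("D", "N")

    def test_stop_gain_is_still_nonsynonymous_with_star_recorded(self):
        # codon 4 AAA (Lys) at 29-31; A->T at 29 gives TAA, a premature stop
        av = annotation.annotate_snp(snp("chr1", 29, "A", "T"), self.index, self.ref)
        assert av.category == SnpCategory.NONSYNONYMOUS.value
        assert (av.codon_change.ref_aa, av.codon_change.alt_aa) == ("K", "*")

    @pytest.mark.parametrize(
        "pos,category",
        [
            (15, SnpCategory.UTR.value),        # 5'UTR
            (75, SnpCategory.UTR.value),        # 3'UTR
            (41, SnpCategory.SPLICE_SITE.value),  # donor +1
            (42, SnpCategory.SPLICE_SITE.value),  # donor +2
            (59, SnpCategory.SPLICE_SITE.value),  # acceptor -2
            (60, SnpCategory.SPLICE_SITE.value),  # acceptor -1
            (50, SnpCategory.INTRON.value),     # deep intron
            (8, SnpCategory.UPSTREAM_5KB.value),   # within 5 bp flank
            (93, SnpCategory.DOWNSTREAM_5KB.value),
            (2, SnpCategory.INTERGENIC.value),
        ],
    )
    def test_non_coding_positions(self, pos, category):
        ref_base = self.ref["chr1"][pos - 1]
        alt = "A" if ref_base != "A" else "G"
        av = annotation.annotate_snp(snp("chr1", pos, ref_base, alt),
                                     self.index, self.ref)
        assert av.category == category, pos

    def test_ref_allele_mismatch_is_a_data_error(self):
        wrong = "G" if self.ref["chr1"][24] != "G" else "C"
        with pytest.raises(ValueError, match="disagrees"):
            annotation.annotate_snp(snp("chr1", 25, wrong, "A"), self.index, self.ref)


class TestMinusStrandCodon:
    def test_genomic_change_maps_through_reverse_complement(self):
        # minus-strand single-exon gene; coding strand = revcomp(genomic CDS)
        # coding CDS: ATG GAT TAA  -> genomic (revcomp): TTA ATC CAT
        genomic_cds = "TTAATCCAT"
        seq = "G" * 10 + "AAAA" + genomic_cds + "TTTT" + "G" * 10
        # gene: tx 11-31, exon 11-31, cds 15-23
        gene = GeneModel("gm", "chr1", "-", 11, 31, ((11, 31),), 15, 23)
        ref = {"chr1": seq}
        index = annotation.build_index([gene], AnnotationParams(flank_bp=2))
        assert annotation.cds_sequence(gene, ref) == "ATGGATTAA"
        # codon 2 GAT (Asp): coding offset 3 = genomic position 20 (C),
        # genomic C->T is coding G->A => AAT (Asn): nonsynonymous
        assert seq[19] == "C"
        av = annotation.annotate_snp(snp("chr1", 20, "C", "T"), index, ref)
        assert av.category == SnpCategory.NONSYNONYMOUS.value
        assert (av.codon_change.ref_codon, av.codon_change.alt_codon) == ("GAT", "AAT")
        assert (av.codon_change.ref_aa, av.codon_change.alt_aa) == ("D", "N")
        assert av.codon_change.position_in_codon == 1


class TestIndelAnnotation:
    def setup_method(self):
        self.ref, self.gene = _hand_gene()
        self.index = annotation.build_index([self.gene], AnnotationParams(flank_bp=5))

    def test_deletion_inside_exon(self):
        av = annotation.annotate_indel(indel("chr1", 30, "TG", "T"), self.index)
        assert av.category == IndelCategory.EXON.value

    def test_insertion_in_intergenic_space(self):
        av = annotation.annotate_indel(indel("chr1", 2, "T", "TAC"), self.index)
        assert av.category == IndelCategory.INTERGENIC.value

    def test_deletion_spanning_exon_intron_junction_touches_splice(self):
        # anchor 39 (exon), deletes 40-42: spans into donor window 41-42
        av = annotation.annotate_indel(indel("chr1", 39, "TTGT", "T"), self.index)
        assert av.category == IndelCategory.SPLICE_SITE.value

    def test_deep_intron_indel(self):
        av = annotation.annotate_indel(indel("chr1", 48, "G", "GTT"), self.index)
        assert av.category == IndelCategory.INTRON.value

    def test_flank_indel(self):
        av = annotation.annotate_indel(indel("chr1", 8, "A", "AT"), self.index)
        assert av.category == IndelCategory.FLANK_5KB.value

    def test_snp_rejected(self):
        with pytest.raises(ValueError):
            annotation.annotate_indel(snp("chr1", 5, "T", "A"), self.index)


class TestIndexAgainstLinearScan:
    def test_containment_queries_match_naive_scan(self):
        rng = random.Random(0)
        genes = []
        pos = 1000
        for i in range(300):
            length = rng.randrange(90, 300, 3)
            start = pos
            end = start + length - 1
            genes.append(
                GeneModel(
                    f"g{i:03d}", "chr1", rng.choice("+-"), start, end,
                    ((start, end),), start, start + (length // 3) * 3 - 1,
                )
            )
            pos = end + rng.randrange(50, 2000)
        index = annotation.build_index(genes, AnnotationParams(flank_bp=500))
        for _ in range(200):
            q = rng.randrange(1, pos)
            got = {g.gene_id for g in index.genes_containing("chr1", q)}
            want = {g.gene_id for g in genes if g.tx_start <= q <= g.tx_end}
            assert got == want

    def test_empty_gene_list_annotates_everything_intergenic(self):
        index = annotation.build_index([])
        ref = {"chr1": "ACGT" * 100}
        av = annotation.annotate_snp(snp("chr1", 17, ref["chr1"][16], "A"
                                         if ref["chr1"][16] != "A" else "C"),
                                     index, ref)
        assert av.category == SnpCategory.INTERGENIC.value


def _random_world(seed, strand_bias=None):
    from tauvar import simulate
    from tauvar.models import SimulationConfig

    cfg = SimulationConfig(
        seed=seed, chromosome_lengths=[400_000], n_genes=8,
        n_variants_per_category=0, error_rate=0.0, n_background_sites=0,
    )
    ref = simulate.generate_reference(cfg)
    genes = simulate.generate_gene_models(ref, cfg)
    return ref, genes


class TestFullCdsOracle:
    """Codon-local classification must equal mutate-whole-CDS-and-diff."""

    def _check_strand(self, strand, n_snps=1000):
        from Bio.Seq import Seq

        ref, genes = _random_world(21)
        genes = [g for g in genes if g.strand == strand]
        assert genes
        index = annotation.build_index(genes)
        rng = random.Random(42)
        cds_positions = [
            (g, p)
            for g in genes
            for s, e in g.cds_segments
            for p in range(s, e + 1)
        ]
        for _ in range(n_snps):
            g, p = rng.choice(cds_positions)
            ref_base = ref[g.chromosome][p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            av = annotation.annotate_snp(snp(g.chromosome, p, ref_base, alt),
                                         index, ref)
            # oracle: substitute in the chromosome, re-extract and translate CDS
            chrom_seq = ref[g.chromosome]
            mutated = {
                g.chromosome: chrom_seq[: p - 1] + alt + chrom_seq[p:]
            }
            before = str(Seq(annotation.cds_sequence(g, ref)).translate())
            after = str(Seq(annotation.cds_sequence(g, mutated)).translate())
            expected = (
                SnpCategory.SYNONYMOUS.value
                if before == after
                else SnpCategory.NONSYNONYMOUS.value
            )
            assert av.category == expected, (g.gene_id, p, ref_base, alt)

    def test_plus_strand(self):
        self._check_strand("+")

    def test_minus_strand(self):
        self._check_strand("-")


def _mirror_world(ref, genes):
    """Reverse-complement the genome and remap the gene models."""
    from tauvar.annotation import revcomp

    mirrored_ref = {c: revcomp(s) for c, s in ref.sequences.items()}
    L = {c: len(s) for c, s in ref.sequences.items()}

    def flip(c, p):
        return L[c] - p + 1

    mirrored_genes = []
    for g in genes:
        exons = tuple(
            sorted((flip(g.chromosome, e), flip(g.chromosome, s))
                   for s, e in g.exons)
        )
        mirrored_genes.append(
            GeneModel(
                g.gene_id, g.chromosome, "-" if g.strand == "+" else "+",
                flip(g.chromosome, g.tx_end), flip(g.chromosome, g.tx_start),
                exons,
                flip(g.chromosome, g.cds_end), flip(g.chromosome, g.cds_start),
            )
        )
    return mirrored_ref, mirrored_genes, flip


class TestStrandSymmetry:
    def test_categories_invariant_under_reverse_complement(self, small_world):
        from tauvar.annotation import revcomp
        from tauvar.models import VariantType as VT

        ref, genes, truth = small_world
        index = annotation.build_index(genes)
        mref, mgenes, flip = _mirror_world(ref, genes)
        mindex = annotation.build_index(mgenes)
        checked = 0
        for r in truth:
            if r.variant_type is not VT.SNP:
                continue
            call = snp(r.chromosome, r.position, r.ref_allele, r.alt_allele)
            cat = annotation.annotate_snp(call, index, ref).category
            mcall = snp(
                r.chromosome,
                flip(r.chromosome, r.position),
                revcomp(r.ref_allele),
                revcomp(r.alt_allele),
            )
            mcat = annotation.annotate_snp(mcall, mindex, mref).category
            if cat in (SnpCategory.UPSTREAM_5KB.value, SnpCategory.DOWNSTREAM_5KB.value):
                # up/downstream are strand-relative labels; they must map to
                # themselves because gene strands flip along with the genome
                assert mcat == cat
            else:
                assert mcat == cat, r
            checked += 1
        assert checked > 50


class TestPartitionProperty:
    def test_every_variant_gets_exactly_one_category(self, small_world, small_pileup):
        from tauvar import calling

        ref, genes, _ = small_world
        calls, _rej = calling.call_variants(small_pileup)
        index = annotation.build_index(genes)
        annotated = annotation.annotate_variants(calls, index, ref)
        assert len(annotated) == len(calls)
        counts = annotation.category_counts(annotated)
        assert sum(counts.values()) == len(calls)
        allowed = {c.value for c in SnpCategory} | {c.value for c in IndelCategory}
        assert set(counts) <= allowed
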