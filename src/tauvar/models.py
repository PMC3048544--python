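"""Core domain types shared across the pipeline.

All genomic coordinates are 1-based inclusive unless a function's docstring
says otherwise (BED12 I/O converts at the boundary). Alleles follow VCF
conventions: a SNP has single-base ref/alt; an insertion's alt and a
deletion's ref carry the anchor base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class VariantType(str, enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"


class SnpCategory(str, enum.Enum):
    """Closed consequence label set for SNPs, most severe first."""

    NONSYNONYMOUS = "NONSYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    SPLICE_SITE = "SPLICE_SITE"
    UTR = "UTR"
    INTRON = "INTRON"
    UPSTREAM_5KB = "UPSTREAM_5KB"
    DOWNSTREAM_5KB = "DOWNSTREAM_5KB"
    INTERGENIC = "INTERGENIC"


class IndelCategory(str, enum.Enum):
    """Closed consequence label set for indels, most severe first."""

    SPLICE_SITE = "SPLICE_SITE"
    EXON = "EXON"
    INTRON = "INTRON"
    FLANK_5KB = "FLANK_5KB"
    INTERGENIC = "INTERGENIC"


#: Severity rank used to resolve overlapping-gene conflicts (lower = wins).
SNP_SEVERITY = {c: i for i, c in enumerate(SnpCategory)}
INDEL_SEVERITY = {c: i for i, c in enumerate(IndelCategory)}


class NoCallReason(str, enum.Enum):
    LOW_DEPTH = "LOW_DEPTH"
    NO_ALT = "NO_ALT"
    LOW_ALT = "LOW_ALT"
    LOW_FRACTION = "LOW_FRACTION"


@dataclass(frozen=True)
class PileupSite:
    """Per-position allele-count evidence — the calling substrate.

    ``base_counts`` maps an observed allele to its read count. Keys are
    single bases for substitutions, ``+SEQ`` for insertions and ``-SEQ``
    for deletions (SEQ = inserted/deleted bases, anchor excluded).
    """

    chromosome: str
    position: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in "ACGT":
            raise ValueError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        if any(n < 0 for n in self.base_counts.values()) or self.depth < 0:
            raise ValueError("negative read counts")
        total = sum(self.base_counts.values())
        if total != self.depth:
            raise ValueError(
                f"{self.chromosome}:{self.position}: base_counts sum {total} != depth {self.depth}"
            )


@dataclass(frozen=True)
class FilterParams:
    """Post-caller filter thresholds.

    Defaults are the study's operating point: a site needs total depth of at
    least 3, at least 2 reads carrying the alternate allele, and the alternate
    must account for at least 30% of mapped reads; 80% or more alternate reads
    classifies the call homozygous. All thresholds are inclusive.
    """

    min_depth: int = 3
    min_alt_reads: int = 2
    min_alt_fraction: float = 0.30
    hom_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_alt_fraction <= self.hom_fraction <= 1):
            raise ValueError(
                "require 0 < min_alt_fraction <= hom_fraction <= 1, got "
                f"{self.min_alt_fraction}, {self.hom_fraction}"
            )
        if self.min_depth < 0 or self.min_alt_reads < 0:
            raise ValueError("negative thresholds")


@dataclass(frozen=True)
class VariantCall:
    """A filtered SNP or indel call with zygosity."""

    chromosome: str
    position: int
    variant_type: VariantType
    ref_allele: str
    alt_allele: str
    depth: int
    alt_reads: int
    zygosity: Zygosity

    @property
    def alt_fraction(self) -> float:
        return self.alt_reads / self.depth

    @property
    def is_snp(self) -> bool:
        return self.variant_type is VariantType.SNP


@dataclass(frozen=True)
class NoCall:
    chromosome: str
    position: int
    reason: NoCallReason


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene structure used for consequence annotation.

    ``exons`` are sorted, non-overlapping (start, end) pairs in genomic
    orientation; ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates regardless of strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] < self.tx_start or self.exons[-1][1] > self.tx_end:
            raise ValueError(f"{self.gene_id}: exons exceed transcript bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript")
        if self.cds_span_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_span_length} not divisible by 3"
            )

    @property
    def cds_segments(self) -> list[tuple[int, int]]:
        """Exonic sub-intervals covered by the CDS, genomic order."""
        segs = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs

    @property
    def cds_span_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        ]


@dataclass(frozen=True)
class TruthRecord:
    """A planted variant with its intended consequence — the test oracle."""

    chromosome: str
    position: int
    variant_type: VariantType
    ref_allele: str
    alt_allele: str
    planted_zygosity: Zygosity
    intended_category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_type is VariantType.SNP:
            ok = (
                len(self.ref_allele) == 1
                and len(self.alt_allele) == 1
                and self.ref_allele != self.alt_allele
            )
        elif self.variant_type is VariantType.INS:
            ok = len(self.alt_allele) > len(self.ref_allele)
        else:
            ok = len(self.ref_allele) > len(self.alt_allele)
        if not ok:
            raise ValueError(
                f"{self.chromosome}:{self.position}: alleles "
                f"{self.ref_allele}>{self.alt_allele} inconsistent with {self.variant_type}"
            )


@dataclass(frozen=True)
class CodonChange:
    """Codon-level description of a coding SNP on the coding strand."""

    gene_id: str
    codon_index: int
    position_in_codon: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


@dataclass(frozen=True)
class AnnotatedVariant:
    call: VariantCall
    category: str
    gene_id: Optional[str] = None
    codon_change: Optional[CodonChange] = None


@dataclass(frozen=True)
class AnnotationParams:
    """Parameters of the consequence classifier.

    flank_bp: distance (bp) from a gene body still reported as its
        upstream/downstream flank (default 5000, the study's 5-kb window).
    splice_bp: intronic bases at each exon-intron junction labelled
        SPLICE_SITE (default 2, the canonical GT/AG dinucleotides).
    """

    flank_bp: int = 5000
    splice_bp: int = 2

    def __post_init__(self) -> None:
        if self.splice_bp < 1:
            raise ValueError("splice_bp must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


class HetMode(str, enum.Enum):
    IUPAC = "IUPAC"
    MAJOR_ALLELE = "MAJOR_ALLELE"
    ALT_ALLELE = "ALT_ALLELE"


@dataclass(frozen=True)
class ConsensusPolicy:
    het_mode: HetMode = HetMode.IUPAC
    include_indels: bool = False


@dataclass
class SimulationConfig:
    """Parameters of the synthetic diploid resequencing experiment.

    The defaults describe the regime the pipeline targets: a diploid genome
    where heterozygous sites show ~50% alternate reads and homozygous-alternate
    sites ~98%, sequenced at moderate depth with a low substitution error rate.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_lengths: list[int] = field(default_factory=lambda: [1_000_000])
    gc_fraction: float = 0.42
    n_genes: int = 20
    mean_exons_per_gene: int = 4
    flank_bp: int = 5000
    n_variants_per_category: int = 30
    mean_depth: float = 20.0
    error_rate: float = 0.005
    het_fraction_mean: float = 0.5
    hom_fraction_mean: float = 0.98
    n_background_sites: int = 2000

    def __post_init__(self) -> None:
        if self.n_chromosomes != len(self.chromosome_lengths):
            raise ValueError("n_chromosomes must match chromosome_lengths")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not (0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.mean_exons_per_gene < 1:
            raise ValueError("mean_exons_per_gene must be >= 1")
        for name in ("het_fraction_mean", "hom_fraction_mean"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


#: Truth-table categories the planting module can realise, in planting order.
PLANTABLE_SNP_CATEGORIES = [
    SnpCategory.INTERGENIC.value,
    SnpCategory.UPSTREAM_5KB.value,
    SnpCategory.DOWNSTREAM_5KB.value,
    SnpCategory.INTRON.value,
    SnpCategory.UTR.value,
    SnpCategory.SPLICE_SITE.value,
    SnpCategory.SYNONYMOUS.value,
    SnpCategory.NONSYNONYMOUS.value,
]
PLANTABLE_INDEL_CATEGORIES = [
    "INDEL_INTRON",
    "INDEL_EXON",
    "INDEL_SPLICE",
]
PLANTABLE_CATEGORIES = PLANTABLE_SNP_CATEGORIES + PLANTABLE_INDEL_CATEGORIES

#: Maps a planted indel category to the annotation label it must receive.
INDEL_TRUTH_TO_ANNOTATION = {
    "INDEL_INTRON": IndelCategory.INTRON.value,
    "INDEL_EXON": IndelCategory.EXON.value,
    "INDEL_SPLICE": IndelCategory.SPLICE_SITE.value,
}
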