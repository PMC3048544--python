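"""Synthetic diploid resequencing experiments with planted ground truth.

The generator emulates the regime the pipeline targets: a diploid genome
carrying heterozygous variants (alternate-read fraction ~0.5) and
homozygous-alternate variants (~1.0), sequenced at a configurable mean depth
with a low per-base substitution error rate, against gene models with
exons/CDS/UTRs on both strands. Variants are planted at positions chosen so
that each carries a known consequence category, which downstream calling and
annotation must recover — the pipeline's closed-loop oracle.

Placement guarantees are verified at planting time by a naive linear scan
over all gene models plus, for coding SNPs, a full-CDS mutate-translate-diff
check; this verification path is deliberately separate from the
interval-tree/codon-local classifier in :mod:`tauvar.annotation`.

Every generator is a pure function of (config, seed): distinct substreams are
derived per stage, so regenerating any stage reproduces identical bytes.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation import revcomp, splice_windows
from .models import (
    INDEL_SEVERITY,
    INDEL_TRUTH_TO_ANNOTATION,
    PLANTABLE_CATEGORIES,
    SNP_SEVERITY,
    GeneModel,
    IndelCategory,
    PileupSite,
    SimulationConfig,
    SnpCategory,
    TruthRecord,
    VariantType,
    Zygosity,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_MIN_VARIANT_SPACING = 16  # anchors this far apart keep all events >10 bp clear


class ReferenceGenome(Mapping):
    """Chromosome name -> sequence, indexable like a pyfaidx Fasta."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(config: SimulationConfig) -> ReferenceGenome:
    """Random A/C/G/T sequence per chromosome at the requested GC fraction."""
    rng = _rng(config, 0)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for i, length in enumerate(config.chromosome_lengths, start=1):
        arr = rng.choice(alphabet, size=length, p=probs)
        sequences[f"chr{i}"] = arr.tobytes().decode("ascii")
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Gene model generation


def _spliced_positions(exons: Sequence[tuple[int, int]]) -> list[int]:
    """Genomic positions of the spliced transcript, left to right."""
    out: list[int] = []
    for s, e in exons:
        out.extend(range(s, e + 1))
    return out


def _draw_gene_structure(
    rng: np.random.Generator, mean_exons: int, max_span: int
) -> Optional[tuple[list[int], list[int], int, int]]:
    """Draw (exon_lengths, intron_lengths, utr5, utr3); None if it cannot fit."""
    for _ in range(20):
        n_exons = 1 if mean_exons == 1 else max(1, 1 + rng.poisson(mean_exons - 1))
        if n_exons == 1:
            exon_lens = [int(rng.integers(400, 701))]
        else:
            exon_lens = [int(rng.integers(120, 301)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(200, 801)) for _ in range(n_exons - 1)]
        total_exonic = sum(exon_lens)
        utr5 = int(rng.integers(40, 81))
        utr3 = int(rng.integers(40, 81))
        cds_len = total_exonic - utr5 - utr3
        cds_len -= cds_len % 3
        if cds_len < 30:
            continue
        utr3 = total_exonic - utr5 - cds_len
        span = total_exonic + sum(intron_lens)
        if span <= max_span:
            return exon_lens, intron_lens, utr5, utr3
    return None


def _embed_coding_sequence(
    chrom_arr: bytearray, gene: GeneModel
) -> None:
    """Rewrite the reference so the gene's CDS starts ATG, ends with a stop,
    and contains no internal stop codon on the coding strand."""
    positions = []
    for s, e in gene.cds_segments:
        positions.extend(range(s - 1, e))  # 0-based genomic indices
    coding = "".join(chr(chrom_arr[p]) for p in positions)
    if gene.strand == "-":
        coding = revcomp(coding)
    codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for i in range(1, len(codons) - 1):
        if codons[i] in _STOPS:
            codons[i] = "C" + codons[i][1:]  # TAA->CAA etc.: no longer a stop
    coding = "".join(codons)
    genomic = revcomp(coding) if gene.strand == "-" else coding
    for p, base in zip(positions, genomic):
        chrom_arr[p] = ord(base)


def generate_gene_models(
    ref: ReferenceGenome, config: SimulationConfig
) -> list[GeneModel]:
    """Place non-overlapping genes on both strands and edit the reference so
    every CDS translates cleanly (start codon, stop codon, no internal stop).

    Genes are laid out in per-chromosome slots with at least ``flank_bp``
    clearance on each side, so each gene's upstream/downstream flank never
    overlaps another gene body. The reference is modified in place.
    """
    rng = _rng(config, 1)
    lengths = config.chromosome_lengths
    total = sum(lengths)
    # proportional allocation of genes to chromosomes (largest remainder)
    quotas = [config.n_genes * length / total for length in lengths]
    counts = [int(q) for q in quotas]
    remainder = config.n_genes - sum(counts)
    order = sorted(range(len(lengths)), key=lambda i: quotas[i] - counts[i],
                   reverse=True)
    for i in order[:remainder]:
        counts[i] += 1

    genes: list[GeneModel] = []
    arrays = {name: bytearray(seq.encode()) for name, seq in ref.sequences.items()}
    gene_no = 0
    for ci, (name, length, k) in enumerate(
        zip(ref.sequences.keys(), lengths, counts)
    ):
        if k == 0:
            continue
        slot = length // k
        for j in range(k):
            slot_start = j * slot + 1
            max_span = slot - 2 * config.flank_bp - 2
            structure = _draw_gene_structure(
                rng, config.mean_exons_per_gene, max_span
            )
            if structure is None:
                raise ValueError(
                    f"chromosome {name} too short for a gene: slot of {slot} bp "
                    f"leaves {max_span} bp after {config.flank_bp} bp flanks"
                )
            exon_lens, intron_lens, utr5, utr3 = structure
            span = sum(exon_lens) + sum(intron_lens)
            jitter = int(rng.integers(0, slot - span - 2 * config.flank_bp - 1))
            tx_start = slot_start + config.flank_bp + jitter
            exons = []
            pos = tx_start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el - 1))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            tx_end = exons[-1][1]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            spliced = _spliced_positions(exons)
            cds_lo_spliced = utr5 if strand == "+" else utr3
            cds_len = len(spliced) - utr5 - utr3
            cds_start = spliced[cds_lo_spliced]
            cds_end = spliced[cds_lo_spliced + cds_len - 1]
            gene_no += 1
            gene = GeneModel(
                gene_id=f"gene{gene_no:04d}",
                chromosome=name,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
            _embed_coding_sequence(arrays[name], gene)
            genes.append(gene)
    ref.sequences = {name: arr.decode("ascii") for name, arr in arrays.items()}
    return genes


# ---------------------------------------------------------------------------
# Naive category oracles used to verify placement


def _translate_cds(genes_cds: str) -> str:
    return str(Seq(genes_cds).translate())


def _gene_cds(gene: GeneModel, ref: Mapping, mutate: Optional[tuple[int, str]] = None) -> str:
    """Coding-strand CDS, optionally with one genomic base substituted."""
    parts = []
    for s, e in gene.cds_segments:
        seg = str(ref[gene.chromosome][s - 1 : e])
        if mutate is not None and s <= mutate[0] <= e:
            i = mutate[0] - s
            seg = seg[:i] + mutate[1] + seg[i + 1 :]
        parts.append(seg)
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def _snp_is_synonymous(gene: GeneModel, ref: Mapping, pos: int, alt: str) -> bool:
    """Full-CDS oracle: mutate, translate both proteins, compare."""
    before = _translate_cds(_gene_cds(gene, ref))
    after = _translate_cds(_gene_cds(gene, ref, mutate=(pos, alt)))
    return before == after


def naive_snp_category(
    genes: Sequence[GeneModel],
    ref: Mapping,
    chromosome: str,
    position: int,
    alt: str,
    flank_bp: int = 5000,
    splice_bp: int = 2,
) -> str:
    """Linear-scan consequence classification (placement verifier / test oracle)."""
    candidates = []
    for g in genes:
        if g.chromosome != chromosome:
            continue
        cat = None
        if g.tx_start <= position <= g.tx_end:
            if any(s <= position <= e for s, e in g.cds_segments):
                cat = (
                    SnpCategory.SYNONYMOUS
                    if _snp_is_synonymous(g, ref, position, alt)
                    else SnpCategory.NONSYNONYMOUS
                )
            elif any(s <= position <= e for s, e in splice_windows(g, splice_bp)):
                cat = SnpCategory.SPLICE_SITE
            elif any(s <= position <= e for s, e in g.exons):
                cat = SnpCategory.UTR
            else:
                cat = SnpCategory.INTRON
        elif g.tx_start - flank_bp <= position < g.tx_start:
            cat = (
                SnpCategory.UPSTREAM_5KB if g.strand == "+" else SnpCategory.DOWNSTREAM_5KB
            )
        elif g.tx_end < position <= g.tx_end + flank_bp:
            cat = (
                SnpCategory.DOWNSTREAM_5KB if g.strand == "+" else SnpCategory.UPSTREAM_5KB
            )
        if cat is not None:
            candidates.append((SNP_SEVERITY[cat], g.gene_id, cat))
    if not candidates:
        return SnpCategory.INTERGENIC.value
    return min(candidates)[2].value


def naive_indel_category(
    genes: Sequence[GeneModel],
    chromosome: str,
    start: int,
    end: int,
    flank_bp: int = 5000,
    splice_bp: int = 2,
) -> str:
    candidates = []
    for g in genes:
        if g.chromosome != chromosome:
            continue
        cat = None
        if start <= g.tx_end and g.tx_start <= end:
            if any(s <= end and start <= e for s, e in splice_windows(g, splice_bp)):
                cat = IndelCategory.SPLICE_SITE
            elif any(s <= end and start <= e for s, e in g.exons):
                cat = IndelCategory.EXON
            else:
                cat = IndelCategory.INTRON
        elif g.tx_start - flank_bp <= end and start <= g.tx_end + flank_bp:
            cat = IndelCategory.FLANK_5KB
        if cat is not None:
            candidates.append((INDEL_SEVERITY[cat], g.gene_id, cat))
    if not candidates:
        return IndelCategory.INTERGENIC.value
    return min(candidates)[2].value


# ---------------------------------------------------------------------------
# Variant planting


class _Spacer:
    """Tracks planted anchors to keep variants well separated."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, set[int]] = {}

    def free(self, chromosome: str, position: int) -> bool:
        taken = self._by_chrom.get(chromosome, set())
        return all(
            position + d not in taken
            for d in range(-_MIN_VARIANT_SPACING, _MIN_VARIANT_SPACING + 1)
        )

    def reserve(self, chromosome: str, position: int) -> None:
        self._by_chrom.setdefault(chromosome, set()).add(position)


def _pick_gene(rng, genes, predicate=None):
    pool = [g for g in genes if predicate is None or predicate(g)]
    if not pool:
        return None
    return pool[int(rng.integers(0, len(pool)))]


def _utr_intervals(gene: GeneModel) -> list[tuple[int, int]]:
    utrs = []
    for s, e in gene.exons:
        if s < gene.cds_start:
            utrs.append((s, min(e, gene.cds_start - 1)))
        if e > gene.cds_end:
            utrs.append((max(s, gene.cds_end + 1), e))
    return utrs


def plant_variants(
    ref: ReferenceGenome,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    splice_bp: int = 2,
) -> list[TruthRecord]:
    """Plant ``n_variants_per_category`` variants for every category.

    Each record's position is verified at planting time to carry exactly the
    intended category (linear-scan classifier; full-CDS translation diff for
    synonymous/nonsynonymous). Raises if a category cannot be realised under
    the generated gene models (e.g. no gene has an intron).
    """
    rng = _rng(config, 2)
    spacer = _Spacer()
    records: list[TruthRecord] = []
    chrom_names = list(ref.sequences.keys())
    lengths = ref.lengths
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    if config.n_variants_per_category == 0:
        return []

    has_intron = any(g.introns for g in genes)
    needs_intron = {
        SnpCategory.INTRON.value,
        SnpCategory.SPLICE_SITE.value,
        "INDEL_INTRON",
        "INDEL_SPLICE",
    }

    def random_alt(ref_base: str) -> str:
        choices = [b for b in _BASES if b != ref_base]
        return choices[int(rng.integers(0, 3))]

    def propose(category: str) -> Optional[TruthRecord]:
        if category == SnpCategory.INTERGENIC.value:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            pos = int(rng.integers(20, lengths[chrom] - 20))
            ref_base = ref[chrom][pos - 1]
            alt = random_alt(ref_base)
            if naive_snp_category(genes, ref, chrom, pos, alt,
                                  config.flank_bp, splice_bp) != category:
                return None
            return _snp_record(chrom, pos, ref_base, alt, category, None)

        if category in (SnpCategory.UPSTREAM_5KB.value, SnpCategory.DOWNSTREAM_5KB.value):
            g = _pick_gene(rng, genes)
            upstream = category == SnpCategory.UPSTREAM_5KB.value
            before_start = upstream == (g.strand == "+")
            if before_start:
                lo, hi = max(2, g.tx_start - config.flank_bp), g.tx_start - 1
            else:
                lo, hi = g.tx_end + 1, min(lengths[g.chromosome] - 1, g.tx_end + config.flank_bp)
            if lo > hi:
                return None
            pos = int(rng.integers(lo, hi + 1))
            ref_base = ref[g.chromosome][pos - 1]
            alt = random_alt(ref_base)
            if naive_snp_category(genes, ref, g.chromosome, pos, alt,
                                  config.flank_bp, splice_bp) != category:
                return None
            return _snp_record(g.chromosome, pos, ref_base, alt, category, g.gene_id)

        if category == SnpCategory.INTRON.value:
            g = _pick_gene(rng, genes, lambda g: bool(g.introns))
            s, e = g.introns[int(rng.integers(0, len(g.introns)))]
            lo, hi = s + splice_bp + 2, e - splice_bp - 2
            if lo > hi:
                return None
            pos = int(rng.integers(lo, hi + 1))
            ref_base = ref[g.chromosome][pos - 1]
            alt = random_alt(ref_base)
            if naive_snp_category(genes, ref, g.chromosome, pos, alt,
                                  config.flank_bp, splice_bp) != category:
                return None
            return _snp_record(g.chromosome, pos, ref_base, alt, category, g.gene_id)

        if category == SnpCategory.UTR.value:
            g = _pick_gene(rng, genes, lambda g: bool(_utr_intervals(g)))
            if g is None:
                raise ValueError("category UTR impossible: no gene has UTR space")
            utrs = _utr_intervals(g)
            s, e = utrs[int(rng.integers(0, len(utrs)))]
            pos = int(rng.integers(s, e + 1))
            ref_base = ref[g.chromosome][pos - 1]
            alt = random_alt(ref_base)
            if naive_snp_category(genes, ref, g.chromosome, pos, alt,
                                  config.flank_bp, splice_bp) != category:
                return None
            return _snp_record(g.chromosome, pos, ref_base, alt, category, g.gene_id)

        if category == SnpCategory.SPLICE_SITE.value:
            g = _pick_gene(rng, genes, lambda g: bool(g.introns))
            windows = splice_windows(g, splice_bp)
            s, e = windows[int(rng.integers(0, len(windows)))]
            pos = int(rng.integers(s, e + 1))
            ref_base = ref[g.chromosome][pos - 1]
            alt = random_alt(ref_base)
            if naive_snp_category(genes, ref, g.chromosome, pos, alt,
                                  config.flank_bp, splice_bp) != category:
                return None
            return _snp_record(g.chromosome, pos, ref_base, alt, category, g.gene_id)

        if category in (SnpCategory.SYNONYMOUS.value, SnpCategory.NONSYNONYMOUS.value):
            want_syn = category == SnpCategory.SYNONYMOUS.value
            g = _pick_gene(rng, genes)
            cds_positions = [
                p
                for s, e in g.cds_segments
                for p in range(s, e + 1)
            ]
            # keep start and stop codons intact
            spliced = cds_positions if g.strand == "+" else cds_positions[::-1]
            inner = spliced[3:-3]
            if not inner:
                return None
            pos = inner[int(rng.integers(0, len(inner)))]
            ref_base = ref[g.chromosome][pos - 1]
            alts = [b for b in _BASES if b != ref_base]
            rng.shuffle(alts)
            for alt in alts:
                if _snp_is_synonymous(g, ref, pos, alt) == want_syn:
                    if naive_snp_category(genes, ref, g.chromosome, pos, alt,
                                          config.flank_bp, splice_bp) == category:
                        return _snp_record(g.chromosome, pos, ref_base, alt,
                                           category, g.gene_id)
            return None

        # indel categories
        length = min(int(rng.geometric(0.5)), 4)
        is_del = bool(rng.integers(0, 2))
        if category == "INDEL_INTRON":
            g = _pick_gene(rng, genes, lambda g: bool(g.introns))
            s, e = g.introns[int(rng.integers(0, len(g.introns)))]
            lo, hi = s + splice_bp + 1, e - splice_bp - length - 1
            if lo > hi:
                return None
            pos = int(rng.integers(lo, hi + 1))
        elif category == "INDEL_EXON":
            g = _pick_gene(rng, genes)
            s, e = g.exons[int(rng.integers(0, len(g.exons)))]
            hi = e - length if is_del else e
            if s > hi:
                return None
            pos = int(rng.integers(s, hi + 1))
        else:  # INDEL_SPLICE
            g = _pick_gene(rng, genes, lambda g: bool(g.introns))
            windows = splice_windows(g, splice_bp)
            s, e = windows[int(rng.integers(0, len(windows)))]
            pos = int(rng.integers(s, e + 1))
            if is_del and pos + length > lengths[g.chromosome]:
                return None
        chrom = g.chromosome
        anchor = ref[chrom][pos - 1]
        if is_del:
            ref_allele = ref[chrom][pos - 1 : pos + length]
            alt_allele = anchor
            vtype = VariantType.DEL
        else:
            inserted = "".join(
                _BASES[int(i)] for i in rng.integers(0, 4, size=length)
            )
            ref_allele = anchor
            alt_allele = anchor + inserted
            vtype = VariantType.INS
        end = pos + len(ref_allele) - 1
        got = naive_indel_category(genes, chrom, pos, end, config.flank_bp, splice_bp)
        if got != INDEL_TRUTH_TO_ANNOTATION[category]:
            return None
        return TruthRecord(
            chromosome=chrom,
            position=pos,
            variant_type=vtype,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            planted_zygosity=_draw_zygosity(),
            intended_category=category,
            gene_id=g.gene_id,
        )

    def _draw_zygosity() -> Zygosity:
        return Zygosity.HET if rng.integers(0, 2) == 0 else Zygosity.HOM

    def _snp_record(chrom, pos, ref_base, alt, category, gene_id) -> TruthRecord:
        return TruthRecord(
            chromosome=chrom,
            position=pos,
            variant_type=VariantType.SNP,
            ref_allele=ref_base,
            alt_allele=alt,
            planted_zygosity=_draw_zygosity(),
            intended_category=category,
            gene_id=gene_id,
        )

    for category in PLANTABLE_CATEGORIES:
        if category in needs_intron and not has_intron:
            raise ValueError(
                f"category {category} impossible: no generated gene has an intron"
            )
        planted = 0
        attempts = 0
        while planted < config.n_variants_per_category:
            attempts += 1
            if attempts > 500 * config.n_variants_per_category:
                raise RuntimeError(
                    f"could not place {config.n_variants_per_category} variants "
                    f"of category {category} (placed {planted})"
                )
            rec = propose(category)
            if rec is None or not spacer.free(rec.chromosome, rec.position):
                continue
            spacer.reserve(rec.chromosome, rec.position)
            records.append(rec)
            planted += 1

    records.sort(key=lambda r: (r.chromosome, r.position))
    return records


def truth_to_call(rec: TruthRecord, depth: int = 100) -> "VariantCall":
    """Idealised call at a truth site (for annotating planted variants
    directly, bypassing the pileup)."""
    from .models import VariantCall

    alt = depth if rec.planted_zygosity is Zygosity.HOM else depth // 2
    return VariantCall(
        chromosome=rec.chromosome,
        position=rec.position,
        variant_type=rec.variant_type,
        ref_allele=rec.ref_allele,
        alt_allele=rec.alt_allele,
        depth=depth,
        alt_reads=alt,
        zygosity=rec.planted_zygosity,
    )


# ---------------------------------------------------------------------------
# Pileup simulation


def _indel_token(rec: TruthRecord) -> str:
    if rec.variant_type is VariantType.INS:
        return "+" + rec.alt_allele[1:]
    return "-" + rec.ref_allele[1:]


def _error_split(rng, n_errors: int, excluded: str) -> dict[str, int]:
    """Distribute substitution errors uniformly over the three other bases."""
    out: dict[str, int] = {}
    if n_errors == 0:
        return out
    others = [b for b in _BASES if b != excluded]
    split = rng.multinomial(n_errors, [1 / 3] * 3)
    for base, n in zip(others, split):
        if n:
            out[base] = out.get(base, 0) + int(n)
    return out


def simulate_pileup(
    ref: ReferenceGenome,
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
) -> list[PileupSite]:
    """Per-site read evidence at every truth site plus background sites.

    Depth ~ Poisson(mean_depth); alternate-supporting reads ~
    Binomial(depth, het_fraction_mean or hom_fraction_mean); substitution
    errors replace a base-carrying read's base with one of the three other
    bases at ``error_rate``. Background sites carry reference-dominated
    counts with the same error process.
    """
    rng = _rng(config, 3)
    sites: list[PileupSite] = []
    truth_positions = {(r.chromosome, r.position) for r in truth}

    for rec in sorted(truth, key=lambda r: (r.chromosome, r.position)):
        depth = int(rng.poisson(config.mean_depth))
        p_alt = (
            config.het_fraction_mean
            if rec.planted_zygosity is Zygosity.HET
            else config.hom_fraction_mean
        )
        alt_n = int(rng.binomial(depth, p_alt)) if depth else 0
        ref_n = depth - alt_n
        ref_base = rec.ref_allele[0]
        counts: dict[str, int] = {}
        # reference-carrying reads, with substitution errors
        ref_err = int(rng.binomial(ref_n, config.error_rate)) if ref_n else 0
        if ref_n - ref_err:
            counts[ref_base] = ref_n - ref_err
        for b, n in _error_split(rng, ref_err, ref_base).items():
            counts[b] = counts.get(b, 0) + n
        # alternate-carrying reads
        if rec.variant_type is VariantType.SNP:
            alt_err = int(rng.binomial(alt_n, config.error_rate)) if alt_n else 0
            if alt_n - alt_err:
                counts[rec.alt_allele] = counts.get(rec.alt_allele, 0) + alt_n - alt_err
            for b, n in _error_split(rng, alt_err, rec.alt_allele).items():
                counts[b] = counts.get(b, 0) + n
        elif alt_n:
            token = _indel_token(rec)
            counts[token] = counts.get(token, 0) + alt_n
        sites.append(
            PileupSite(
                chromosome=rec.chromosome,
                position=rec.position,
                ref_base=ref_base,
                depth=depth,
                base_counts=counts,
            )
        )

    # background (non-variant) sites
    chrom_names = list(ref.sequences.keys())
    lengths = ref.lengths
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    background: set[tuple[str, int]] = set()
    while len(background) < config.n_background_sites:
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        pos = int(rng.integers(1, lengths[chrom] + 1))
        if (chrom, pos) in truth_positions or (chrom, pos) in background:
            continue
        background.add((chrom, pos))
    for chrom, pos in sorted(background):
        depth = int(rng.poisson(config.mean_depth))
        ref_base = ref[chrom][pos - 1]
        n_err = int(rng.binomial(depth, config.error_rate)) if depth else 0
        counts = {}
        if depth - n_err:
            counts[ref_base] = depth - n_err
        for b, n in _error_split(rng, n_err, ref_base).items():
            counts[b] = counts.get(b, 0) + n
        sites.append(
            PileupSite(
                chromosome=chrom,
                position=pos,
                ref_base=ref_base,
                depth=depth,
                base_counts=counts,
            )
        )

    sites.sort(key=lambda s: (s.chromosome, s.position))
    return sites


def simulate_depth_track(config: SimulationConfig,
                         dropout_fraction: float = 0.07,
                         dropout_block_bp: int = 500) -> dict[str, np.ndarray]:
    """Per-position depth: Poisson(mean_depth) with uncovered blocks.

    Contiguous zero-depth blocks emulate unmappable or diverged regions so
    that genome coverage sits below 100% (the regime of real resequencing).
    """
    rng = _rng(config, 4)
    tracks = {}
    for i, length in enumerate(config.chromosome_lengths, start=1):
        depth = rng.poisson(config.mean_depth, size=length)
        n_blocks = int(length * dropout_fraction / dropout_block_bp)
        for _ in range(n_blocks):
            start = int(rng.integers(0, max(1, length - dropout_block_bp)))
            depth[start : start + dropout_block_bp] = 0
        tracks[f"chr{i}"] = depth
    return tracks
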