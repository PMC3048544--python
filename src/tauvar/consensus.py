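"""Individual-specific consensus sequences and concatenated alignment export.

A consensus is the reference substring over a gene's intervals with the
individual's called variants injected: homozygous SNPs substitute the
alternate base; heterozygous SNPs carry an IUPAC ambiguity code by default
(policy-selectable: major allele or always-alternate instead). Indels are
ignored unless requested, in which case they are applied right-to-left so
earlier coordinates stay valid.

Per-taxon gene sequences can be concatenated into one matrix and exported as
FASTA and relaxed PHYLIP together with a RAxML-style partition table, the
inputs of partitioned maximum-likelihood / Bayesian tree estimation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ConsensusPolicy, HetMode, VariantCall, VariantType, Zygosity

#: Two-base ambiguity codes, unordered pairs.
IUPAC_2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


def _het_base(ref: str, alt: str, call: VariantCall, policy: ConsensusPolicy) -> str:
    if policy.het_mode is HetMode.IUPAC:
        return IUPAC_2[frozenset((ref, alt))]
    if policy.het_mode is HetMode.MAJOR_ALLELE:
        return alt if call.alt_fraction >= 0.5 else ref
    return alt  # ALT_ALLELE


def build_consensus(
    ref: Mapping,
    intervals: Sequence[tuple[str, int, int]],
    calls: Sequence[VariantCall],
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> str:
    """Consensus over a gene's (chromosome, start, end) intervals, 1-based
    inclusive. With ``include_indels`` false the output length equals the
    summed interval length."""
    pieces = []
    for chrom, start, end in intervals:
        seq = list(str(ref[chrom][start - 1 : end]).upper())
        in_range = [
            c
            for c in calls
            if c.chromosome == chrom and start <= c.position <= end
        ]
        snps = [c for c in in_range if c.variant_type is VariantType.SNP]
        indels = [c for c in in_range if c.variant_type is not VariantType.SNP]
        for c in snps:
            i = c.position - start
            if seq[i] != c.ref_allele:
                raise ValueError(
                    f"{chrom}:{c.position}: call ref {c.ref_allele} disagrees "
                    f"with reference base {seq[i]}"
                )
            if c.zygosity is Zygosity.HOM:
                seq[i] = c.alt_allele
            else:
                seq[i] = _het_base(c.ref_allele, c.alt_allele, c, policy)
        if policy.include_indels:
            for c in sorted(indels, key=lambda c: -c.position):
                i = c.position - start
                span = len(c.ref_allele)
                observed = "".join(seq[i : i + span])
                if observed != c.ref_allele:
                    raise ValueError(
                        f"{chrom}:{c.position}: call ref {c.ref_allele} disagrees "
                        f"with reference segment {observed}"
                    )
                seq[i : i + span] = list(c.alt_allele)
        pieces.append("".join(seq))
    return "".join(pieces)


def concatenate_and_export(
    taxa_genes: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str],
    out_prefix: str | Path,
) -> dict[str, tuple[int, int]]:
    """Concatenate per-taxon gene sequences and write alignment files.

    ``taxa_genes`` maps taxon -> {gene -> sequence}; every taxon must provide
    every gene in ``gene_order`` at equal per-gene length. Writes
    ``<prefix>.fasta``, ``<prefix>.phy`` (relaxed PHYLIP) and
    ``<prefix>.partitions`` (``DNA, gene = start-end`` lines). Returns the
    1-based inclusive partition ranges.
    """
    out_prefix = Path(out_prefix)
    gene_lengths: dict[str, int] = {}
    for gene in gene_order:
        lengths = {}
        for taxon, genes in taxa_genes.items():
            if gene not in genes:
                raise ValueError(f"taxon {taxon!r} missing gene {gene!r}")
            lengths[taxon] = len(genes[gene])
        if len(set(lengths.values())) != 1:
            raise ValueError(
                f"gene {gene!r} length mismatch across taxa: {lengths}"
            )
        gene_lengths[gene] = next(iter(lengths.values()))

    partitions: dict[str, tuple[int, int]] = {}
    offset = 1
    for gene in gene_order:
        partitions[gene] = (offset, offset + gene_lengths[gene] - 1)
        offset += gene_lengths[gene]

    records = [
        SeqRecord(
            Seq("".join(genes[g] for g in gene_order)), id=taxon, description=""
        )
        for taxon, genes in taxa_genes.items()
    ]
    alignment = MultipleSeqAlignment(records)
    SeqIO.write(records, f"{out_prefix}.fasta", "fasta")
    AlignIO.write(alignment, f"{out_prefix}.phy", "phylip-relaxed")
    with open(f"{out_prefix}.partitions", "w") as fh:
        for gene, (start, end) in partitions.items():
            fh.write(f"DNA, {gene} = {start}-{end}\n")
    return partitions


def read_alignment(path: str | Path, fmt: str = "fasta") -> dict[str, str]:
    """Re-read an exported alignment as taxon -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), fmt)}
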