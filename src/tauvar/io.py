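"""Readers and writers for the pipeline's on-disk formats.

Formats: FASTA (60-column), GFF3 (1-based inclusive) and BED12 (0-based
half-open) gene models, the pileup TSV dialect, truth tables, depth tracks,
and VCF 4.2. Pileup, truth and depth files are gzip-transparent on read.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    GeneModel,
    NoCall,
    PileupSite,
    TruthRecord,
    VariantCall,
    VariantType,
    Zygosity,
)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Gene models: GFF3 and BED12


def write_gff3(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.tx_start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\ttauvar\tgene\t{g.tx_start}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\ttauvar\tmRNA\t{g.tx_start}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\ttauvar\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for s, e in g.cds_segments:
                fh.write(
                    f"{g.chromosome}\ttauvar\tCDS\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


def read_gff3(path: PathLike) -> list[GeneModel]:
    """Read gene models from the GFF3 dialect written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    parent_of_mrna: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start), int(end)
            if ftype == "gene":
                genes[fields["ID"]] = {
                    "chromosome": chrom,
                    "strand": strand,
                    "tx_start": start,
                    "tx_end": end,
                    "exons": [],
                    "cds": [],
                }
            elif ftype == "mRNA":
                parent_of_mrna[fields["ID"]] = fields["Parent"]
            elif ftype in ("exon", "CDS"):
                gid = parent_of_mrna.get(fields["Parent"], fields["Parent"])
                key = "exons" if ftype == "exon" else "cds"
                genes[gid][key].append((start, end))
    out = []
    for gid, g in genes.items():
        cds = sorted(g["cds"])
        out.append(
            GeneModel(
                gene_id=gid,
                chromosome=g["chromosome"],
                strand=g["strand"],
                tx_start=g["tx_start"],
                tx_end=g["tx_end"],
                exons=tuple(sorted(g["exons"])),
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
        )
    out.sort(key=lambda g: (g.chromosome, g.tx_start, g.gene_id))
    return out


def write_bed12(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.tx_start)):
            block_sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            block_starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        str(g.tx_start - 1),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.cds_start - 1),
                        str(g.cds_end),
                        "0",
                        str(len(g.exons)),
                        block_sizes,
                        block_starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: PathLike) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    chromosome=chrom,
                    strand=strand,
                    tx_start=chrom_start + 1,
                    tx_end=chrom_end,
                    exons=exons,
                    cds_start=thick_start + 1,
                    cds_end=thick_end,
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.tx_start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Pileup TSV dialect

PILEUP_COLUMNS = ["chromosome", "position", "ref_base", "depth", "counts"]


def write_pileup(sites: Iterable[PileupSite], path: PathLike) -> None:
    """Write sites in the pileup TSV dialect.

    Columns: chromosome, position (1-based), ref_base, depth, and
    semicolon-separated allele:count pairs (e.g. ``A:7;G:3``).
    """
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for s in sites:
            counts = ";".join(
                f"{allele}:{n}" for allele, n in sorted(s.base_counts.items())
            )
            fh.write(f"{s.chromosome}\t{s.position}\t{s.ref_base}\t{s.depth}\t{counts}\n")


def read_pileup(path: PathLike) -> Iterator[PileupSite]:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PILEUP_COLUMNS:
            raise ValueError(
                f"{path}: bad pileup header {header!r}; expected {PILEUP_COLUMNS}"
            )
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, depth, counts = line.rstrip("\n").split("\t")
            base_counts = {}
            if counts:
                for pair in counts.split(";"):
                    allele, n = pair.rsplit(":", 1)
                    base_counts[allele] = int(n)
            yield PileupSite(
                chromosome=chrom,
                position=int(pos),
                ref_base=ref,
                depth=int(depth),
                base_counts=base_counts,
            )


# ---------------------------------------------------------------------------
# Truth table

TRUTH_COLUMNS = [
    "chromosome",
    "position",
    "type",
    "ref",
    "alt",
    "zygosity",
    "category",
    "gene_id",
]


def write_truth(records: Iterable[TruthRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chromosome,
                        str(r.position),
                        r.variant_type.value,
                        r.ref_allele,
                        r.alt_allele,
                        r.planted_zygosity.value,
                        r.intended_category,
                        r.gene_id or ".",
                    ]
                )
                + "\n"
            )


def read_truth(path: PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TruthRecord(
                chromosome=row.chromosome,
                position=int(row.position),
                variant_type=VariantType(row.type),
                ref_allele=row.ref,
                alt_allele=row.alt,
                planted_zygosity=Zygosity(row.zygosity),
                intended_category=row.category,
                gene_id=None if row.gene_id == "." else row.gene_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Depth track


def write_depth_track(depths: dict[str, "list[int]"], path: PathLike) -> None:
    """Write a per-position depth track (chromosome, position, depth)."""
    with _open_text(path, "wt") as fh:
        fh.write("chromosome\tposition\tdepth\n")
        for chrom, track in depths.items():
            fh.writelines(
                f"{chrom}\t{i}\t{d}\n" for i, d in enumerate(track, start=1)
            )


def read_depth_track(path: PathLike) -> dict[str, list[int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[int]] = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(1, len(sub) + 1)):
            raise ValueError(f"{path}: depth track for {chrom} is not contiguous from 1")
        out[str(chrom)] = [int(d) for d in sub["depth"]]
    return out


# ---------------------------------------------------------------------------
# VCF 4.2

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tauvar
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at site">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Reads supporting the alternate allele">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele read fraction">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity call (HET or HOM)">
##INFO=<ID=CAT,Number=1,Type=String,Description="Consequence category">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene of record">
##INFO=<ID=CODON,Number=1,Type=String,Description="Reference>alternate codon on the coding strand">
##INFO=<ID=AA,Number=1,Type=String,Description="Reference>alternate amino acid">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf_alleles(call: VariantCall) -> tuple[str, str]:
    return call.ref_allele, call.alt_allele


def write_vcf(calls, path: PathLike, annotations: "dict | None" = None,
              contigs: "dict[str, int] | None" = None) -> None:
    """Write calls as VCF 4.2 text.

    ``annotations`` optionally maps ``(chromosome, position)`` to an
    AnnotatedVariant; when present, CAT/GENE/CODON/AA INFO keys are added.
    """
    with open(path, "w") as fh:
        header = _VCF_HEADER
        if contigs:
            contig_lines = "".join(
                f"##contig=<ID={name},length={length}>\n"
                for name, length in contigs.items()
            )
            header = header.replace("#CHROM", contig_lines + "#CHROM", 1)
        fh.write(header)
        for call in sorted(calls, key=lambda c: (c.chromosome, c.position)):
            ref, alt = _vcf_alleles(call)
            info = (
                f"DP={call.depth};AD={call.alt_reads};"
                f"AF={call.alt_fraction:.4f};ZYG={call.zygosity.value}"
            )
            if annotations is not None:
                ann = annotations.get((call.chromosome, call.position))
                if ann is not None:
                    info += f";CAT={ann.category}"
                    if ann.gene_id:
                        info += f";GENE={ann.gene_id}"
                    if ann.codon_change is not None:
                        cc = ann.codon_change
                        info += (
                            f";CODON={cc.ref_codon}>{cc.alt_codon}"
                            f";AA={cc.ref_aa}>{cc.alt_aa}"
                        )
            fh.write(
                f"{call.chromosome}\t{call.position}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: PathLike) -> list[VariantCall]:
    """Read calls back from a VCF written by :func:`write_vcf` (via pysam)."""
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref
            alt = rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                vtype = VariantType.SNP
            elif len(alt) > len(ref):
                vtype = VariantType.INS
            else:
                vtype = VariantType.DEL
            calls.append(
                VariantCall(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    variant_type=vtype,
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=int(rec.info["DP"]),
                    alt_reads=int(rec.info["AD"]),
                    zygosity=Zygosity(rec.info["ZYG"]),
                )
            )
    return calls


def read_vcf_annotations(path: PathLike) -> pd.DataFrame:
    """Read an annotated VCF into a DataFrame of calls plus CAT/GENE columns."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                {
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "depth": int(rec.info["DP"]),
                    "alt_reads": int(rec.info["AD"]),
                    "zygosity": str(rec.info["ZYG"]),
                    "category": str(rec.info.get("CAT", ".")),
                    "gene_id": str(rec.info.get("GENE", ".")),
                }
            )
    return pd.DataFrame(rows)


def write_rejects(rejects: Iterable[NoCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\treason\n")
        for r in rejects:
            fh.write(f"{r.chromosome}\t{r.position}\t{r.reason.value}\n")


def read_known_set(path: PathLike) -> set[tuple[str, int]]:
    """Read a known-variant position set from a 2-column TSV or a VCF."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(path) as vf:
            return {(rec.chrom, rec.pos) for rec in vf}
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chromosome", "position"], usecols=[0, 1], header=None,
                     skiprows=_known_set_skiprows(path))
    return {(str(c), int(p)) for c, p in zip(df["chromosome"], df["position"])}


def _known_set_skiprows(path: str) -> int:
    with _open_text(path) as fh:
        first = fh.readline().split("\t")
    try:
        int(first[1])
        return 0
    except (ValueError, IndexError):
        return 1
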