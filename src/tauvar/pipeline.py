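"""End-to-end orchestration: simulate -> call -> annotate -> summarize ->
consensus, with a manifest per stage and full determinism under a fixed seed.

Outputs contain no timestamps, so a rerun with the same config and seed is
byte-identical; the manifest records input/output SHA-256 digests, parameter
echoes and row counts sufficient to reproduce any stage in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import annotation, calling, consensus, io, simulate, summarize
from .models import (
    AnnotationParams,
    ConsensusPolicy,
    FilterParams,
    HetMode,
    SimulationConfig,
    VariantType,
)


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    simulation: SimulationConfig
    filter_params: FilterParams = FilterParams()
    annotation_params: AnnotationParams = AnnotationParams()
    consensus_policy: ConsensusPolicy = ConsensusPolicy()
    known_fraction: float = 0.129
    known_variants: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = dict(raw.get("simulation", {}))
        sim.setdefault("seed", raw.get("seed", 0))
        cons = dict(raw.get("consensus", {}))
        if "het_mode" in cons:
            cons["het_mode"] = HetMode(cons["het_mode"])
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw["out_dir"]),
            simulation=SimulationConfig(**sim),
            filter_params=FilterParams(**raw.get("filter", {})),
            annotation_params=AnnotationParams(**raw.get("annotation", {})),
            consensus_policy=ConsensusPolicy(**cons),
            known_fraction=float(raw.get("known_fraction", 0.129)),
            known_variants=(
                Path(raw["known_variants"]) if raw.get("known_variants") else None
            ),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["known_variants"] = (
            str(self.known_variants) if self.known_variants else None
        )
        d["consensus_policy"]["het_mode"] = self.consensus_policy.het_mode.value
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all five stages; return (and write) the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    def record_stage(name: str, params: dict, outputs: list[Path], counts: dict):
        manifest["stages"].append(
            {
                "stage": name,
                "params": params,
                "outputs": {str(p.name): _sha256(p) for p in outputs},
                "counts": counts,
            }
        )

    # -- stage 1: simulate -------------------------------------------------
    sim = config.simulation
    ref = simulate.generate_reference(sim)
    genes = simulate.generate_gene_models(ref, sim)
    truth = simulate.plant_variants(ref, genes, sim,
                                    splice_bp=config.annotation_params.splice_bp)
    sites = simulate.simulate_pileup(ref, truth, sim)
    depth = simulate.simulate_depth_track(sim)
    ref_path, gff_path = out / "reference.fasta", out / "genes.gff3"
    bed_path, truth_path = out / "genes.bed12", out / "truth.tsv"
    pileup_path, depth_path = out / "pileup.tsv", out / "depth.tsv"
    io.write_fasta(ref.sequences, ref_path)
    io.write_gff3(genes, gff_path)
    io.write_bed12(genes, bed_path)
    io.write_truth(truth, truth_path)
    io.write_pileup(sites, pileup_path)
    io.write_depth_track({c: list(map(int, t)) for c, t in depth.items()}, depth_path)
    # known-variant set: supplied file, or a seeded sample of planted positions
    known_path = config.known_variants
    if known_path is None:
        rng = np.random.default_rng([config.seed, 5])
        known_path = out / "known.tsv"
        with open(known_path, "w") as fh:
            fh.write("chromosome\tposition\n")
            for r in truth:
                if rng.random() < config.known_fraction:
                    fh.write(f"{r.chromosome}\t{r.position}\n")
    record_stage(
        "simulate",
        dataclasses.asdict(sim),
        [ref_path, gff_path, bed_path, truth_path, pileup_path, depth_path],
        {"genes": len(genes), "truth_records": len(truth), "pileup_sites": len(sites)},
    )

    # -- stage 2: call -----------------------------------------------------
    calls, rejects = calling.call_variants(
        io.read_pileup(pileup_path), config.filter_params
    )
    vcf_path = out / "calls.vcf"
    io.write_vcf(calls, vcf_path, contigs=ref.lengths)
    rejects_path = out / "rejects.tsv"
    io.write_rejects(rejects, rejects_path)
    record_stage(
        "call",
        dataclasses.asdict(config.filter_params),
        [vcf_path, rejects_path],
        {"calls": len(calls), "rejects": len(rejects)},
    )

    # -- stage 3: annotate -------------------------------------------------
    genes_in = io.read_gff3(gff_path)
    index = annotation.build_index(genes_in, config.annotation_params)
    calls_in = io.read_vcf(vcf_path)
    annotated = annotation.annotate_variants(calls_in, index, ref)
    ann_path = out / "annotated.vcf"
    io.write_vcf(
        calls_in,
        ann_path,
        annotations={(a.call.chromosome, a.call.position): a for a in annotated},
        contigs=ref.lengths,
    )
    cat_counts = annotation.category_counts(annotated)
    cat_path = out / "category_counts.tsv"
    with open(cat_path, "w") as fh:
        fh.write("category\tcount\n")
        for cat, n in sorted(cat_counts.items()):
            fh.write(f"{cat}\t{n}\n")
    record_stage(
        "annotate",
        dataclasses.asdict(config.annotation_params),
        [ann_path, cat_path],
        {"annotated": len(annotated), **cat_counts},
    )

    # -- stage 4: summarize ------------------------------------------------
    known = io.read_known_set(known_path)
    snp_calls = [c for c in calls_in if c.variant_type is VariantType.SNP]
    indel_calls = [c for c in calls_in if c.variant_type is not VariantType.SNP]
    novelty = summarize.novelty_check(snp_calls, known)
    density = summarize.snp_density(snp_calls, ref.lengths)
    chrom_counts = summarize.per_chromosome_counts(calls_in)
    hist = summarize.indel_length_histogram(indel_calls)
    depth_in = io.read_depth_track(depth_path)
    coverage = summarize.coverage_fraction(depth_in, ref.lengths)
    zyg = {
        "heterozygous": sum(1 for c in snp_calls if c.zygosity.value == "HET"),
        "homozygous": sum(1 for c in snp_calls if c.zygosity.value == "HOM"),
    }
    report = summarize.partition_report(zyg, "snp_partition")
    density_path = out / "snp_density.tsv"
    density.to_csv(density_path, sep="\t", index=False)
    chrom_path = out / "per_chromosome.tsv"
    chrom_counts.to_csv(chrom_path, sep="\t", index=False)
    hist_path = out / "indel_lengths.tsv"
    with open(hist_path, "w") as fh:
        fh.write("length\tcount\n")
        for length, n in hist.items():
            fh.write(f"{length}\t{n}\n")
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(
            {
                "novelty": dataclasses.asdict(novelty),
                "coverage_pct": coverage.genome_pct_covered,
                "mean_fold_coverage": coverage.mean_fold_coverage,
                "snp_partition": {
                    "counts": report.counts,
                    "percentages": report.percentages,
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    record_stage(
        "summarize",
        {"known_set": str(known_path)},
        [density_path, chrom_path, hist_path, summary_path],
        {"snps": len(snp_calls), "indels": len(indel_calls)},
    )

    # -- stage 5: consensus ------------------------------------------------
    taxa: dict[str, dict[str, str]] = {"reference": {}, "sample": {}}
    gene_order = [g.gene_id for g in genes_in]
    for g in genes_in:
        intervals = [(g.chromosome, s, e) for s, e in g.exons]
        taxa["reference"][g.gene_id] = "".join(
            str(ref[g.chromosome][s - 1 : e]) for s, e in g.exons
        )
        taxa["sample"][g.gene_id] = consensus.build_consensus(
            ref, intervals, snp_calls, config.consensus_policy
        )
    prefix = out / "alignment"
    consensus.concatenate_and_export(taxa, gene_order, prefix)
    aln_paths = [Path(f"{prefix}.fasta"), Path(f"{prefix}.phy"),
                 Path(f"{prefix}.partitions")]
    record_stage(
        "consensus",
        {"het_mode": config.consensus_policy.het_mode.value,
         "include_indels": config.consensus_policy.include_indels},
        aln_paths,
        {"taxa": len(taxa), "genes": len(gene_order)},
    )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
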