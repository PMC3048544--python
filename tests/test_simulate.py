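"""Synthetic-data generator: determinism, composition guarantees, planting."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from tauvar import io as tio
from tauvar import simulate
from tauvar.annotation import cds_sequence
from tauvar.models import (
    SimulationConfig,
    TruthRecord,
    VariantType,
    Zygosity,
)


def make_config(**kwargs):
    base = dict(
        seed=3,
        chromosome_lengths=[200_000],
        n_genes=4,
        n_variants_per_category=5,
        error_rate=0.0,
        n_background_sites=50,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestReference:
    def test_length_and_alphabet(self):
        cfg = make_config(chromosome_lengths=[10_000], n_genes=1)
        ref = simulate.generate_reference(cfg)
        assert len(ref["chr1"]) == 10_000
        assert set(ref["chr1"]) <= set("ACGT")

    def test_deterministic_under_seed(self):
        cfg = make_config()
        assert (
            simulate.generate_reference(cfg).sequences
            == simulate.generate_reference(cfg).sequences
        )

    def test_gc_fraction_within_binomial_noise(self):
        n = 100_000
        cfg = make_config(chromosome_lengths=[n], n_genes=1, gc_fraction=0.5)
        seq = simulate.generate_reference(cfg)["chr1"]
        gc = seq.count("G") + seq.count("C")
        sd = math.sqrt(n * 0.5 * 0.5)
        assert abs(gc - n * 0.5) < 3 * sd

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(chromosome_lengths=[0])


class TestGeneModels:
    def test_single_exon_genes_keep_frame(self):
        cfg = make_config(mean_exons_per_gene=1)
        ref = simulate.generate_reference(cfg)
        genes = simulate.generate_gene_models(ref, cfg)
        assert genes
        for g in genes:
            assert len(g.exons) == 1
            assert g.cds_span_length % 3 == 0

    def test_cds_translates_cleanly_both_strands(self, small_world):
        """Full-translation oracle: ATG start, single terminal stop."""
        ref, genes, _ = small_world
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        for g in genes:
            cds = cds_sequence(g, ref)
            protein = str(Seq(cds).translate())
            assert cds.startswith("ATG")
            assert protein.endswith("*")
            assert "*" not in protein[:-1], g.gene_id

    def test_gene_intervals_disjoint(self):
        cfg = make_config(chromosome_lengths=[1_000_000], n_genes=2)
        ref = simulate.generate_reference(cfg)
        genes = simulate.generate_gene_models(ref, cfg)
        (a, b) = sorted(genes, key=lambda g: g.tx_start)
        assert a.tx_end < b.tx_start

    def test_chromosome_too_short_fails_loudly(self):
        cfg = make_config(chromosome_lengths=[2_000], n_genes=1)
        ref = simulate.generate_reference(cfg)
        with pytest.raises(ValueError, match="too short"):
            simulate.generate_gene_models(ref, cfg)


class TestPlanting:
    def test_each_category_gets_requested_count(self, small_config, small_world):
        _, _, truth = small_world
        from tauvar.models import PLANTABLE_CATEGORIES

        per_cat = {}
        for r in truth:
            per_cat[r.intended_category] = per_cat.get(r.intended_category, 0) + 1
        for cat in PLANTABLE_CATEGORIES:
            assert per_cat[cat] == small_config.n_variants_per_category

    def test_zero_per_category_gives_empty_truth(self):
        cfg = make_config(n_variants_per_category=0)
        ref = simulate.generate_reference(cfg)
        genes = simulate.generate_gene_models(ref, cfg)
        assert simulate.plant_variants(ref, genes, cfg) == []

    def test_planted_synonymous_preserve_amino_acid(self, small_world):
        """Mutate the whole CDS and translate — proteins must be identical."""
        ref, genes, truth = small_world
        by_id = {g.gene_id: g for g in genes}
        checked = 0
        for r in truth:
            if r.intended_category not in ("SYNONYMOUS", "NONSYNONYMOUS"):
                continue
            g = by_id[r.gene_id]
            before = str(Seq(cds_sequence(g, ref)).translate())
            mutated = dict(ref.sequences)
            s = mutated[g.chromosome]
            assert s[r.position - 1] == r.ref_allele
            mutated[g.chromosome] = (
                s[: r.position - 1] + r.alt_allele + s[r.position :]
            )
            after = str(Seq(cds_sequence(g, mutated)).translate())
            same = before == after
            assert same == (r.intended_category == "SYNONYMOUS"), r
            checked += 1
        assert checked > 0

    def test_splice_plants_sit_on_intronic_side_of_junction(self, small_world):
        _, genes, truth = small_world
        by_id = {g.gene_id: g for g in genes}
        n = 0
        for r in truth:
            if r.intended_category != "SPLICE_SITE":
                continue
            g = by_id[r.gene_id]
            assert not any(s <= r.position <= e for s, e in g.exons)
            dist = min(
                min(abs(r.position - e - 1), abs(r.position - s + 1))
                for s, e in g.exons
            )
            assert dist <= 1  # within 2 intronic bases of a boundary
            n += 1
        assert n > 0

    def test_variants_well_separated(self, small_world):
        _, _, truth = small_world
        by_chrom = {}
        for r in truth:
            by_chrom.setdefault(r.chromosome, []).append(r.position)
        for positions in by_chrom.values():
            positions.sort()
            gaps = np.diff(positions)
            assert gaps.min() > 10

    def test_intron_categories_impossible_without_introns(self):
        # single-exon genes have no introns, so intron planting must fail loudly
        cfg = make_config(mean_exons_per_gene=1, seed=9)
        ref = simulate.generate_reference(cfg)
        genes = simulate.generate_gene_models(ref, cfg)
        assert not any(g.introns for g in genes)
        with pytest.raises(ValueError, match="INTRON"):
            simulate.plant_variants(ref, genes, cfg)

    def test_truth_allele_shapes_validated(self):
        with pytest.raises(ValueError):
            TruthRecord("chr1", 10, VariantType.INS, "AC", "A", Zygosity.HET, "X")


class TestPileup:
    def test_degenerate_hom_site_all_alt(self):
        cfg = make_config(hom_fraction_mean=1.0, n_background_sites=0)
        ref = simulate.generate_reference(cfg)
        truth = [
            TruthRecord(
                "chr1", 500, VariantType.SNP, ref["chr1"][499],
                "G" if ref["chr1"][499] != "G" else "T",
                Zygosity.HOM, "INTERGENIC",
            )
        ]
        (site,) = simulate.simulate_pileup(ref, truth, cfg)
        assert site.base_counts == {truth[0].alt_allele: site.depth}

    def test_het_alt_fraction_matches_binomial_mean(self):
        cfg = make_config(
            chromosome_lengths=[200_000], mean_depth=20.0, n_background_sites=0
        )
        ref = simulate.generate_reference(cfg)
        truth = []
        for i in range(1000):
            pos = 100 + 30 * i
            rb = ref["chr1"][pos - 1]
            alt = "A" if rb != "A" else "C"
            truth.append(
                TruthRecord("chr1", pos, VariantType.SNP, rb, alt, Zygosity.HET,
                            "INTERGENIC")
            )
        sites = simulate.simulate_pileup(ref, truth, cfg)
        by_pos = {s.position: s for s in sites}
        fractions = [
            by_pos[r.position].base_counts.get(r.alt_allele, 0) / by_pos[r.position].depth
            for r in truth
            if by_pos[r.position].depth > 0
        ]
        mean = np.mean(fractions)
        # se of the mean of per-site binomial fractions at depth ~20
        se = math.sqrt(0.25 / 20 / len(fractions))
        assert abs(mean - 0.5) < 3 * se

    def test_pileup_tsv_bytes_reproducible(self, small_config, small_world, tmp_path):
        ref, _, truth = small_world
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        tio.write_pileup(simulate.simulate_pileup(ref, truth, small_config), a)
        tio.write_pileup(simulate.simulate_pileup(ref, truth, small_config), b)
        assert a.read_bytes() == b.read_bytes()

    def test_depth_counts_consistent(self, small_pileup):
        for s in small_pileup:
            assert sum(s.base_counts.values()) == s.depth
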