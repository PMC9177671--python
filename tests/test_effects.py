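"""Gene-model annotation: locating variants, codon changes, summaries."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bulkscan.effects import (
    GeneModel,
    annotate_variants,
    codon_change,
    locate_variant,
    read_gff3,
    summarize_region_effects,
    write_gff3,
)
from conftest import oracle_effect


class TestGeneModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c1", "*", exons=[(1, 10)])
        with pytest.raises(ValueError):
            GeneModel("g", "c1", "+", exons=[(10, 1)])
        with pytest.raises(ValueError):  # CDS outside exons
            GeneModel("g", "c1", "+", exons=[(1, 10)], cds=[(5, 20)])

    def test_cds_completeness(self):
        m = GeneModel("g", "c1", "+", exons=[(1, 30)], cds=[(1, 30)])
        assert m.complete_cds
        assert not GeneModel("g", "c1", "+", exons=[(1, 31)], cds=[(1, 31)]).complete_cds


class TestLocateVariant:
    def test_exon_intron_intergenic(self, toy_genome):
        _, models = toy_genome
        assert locate_variant(models, "chr1", 1100)[:2] == ("geneA", "exon")
        assert locate_variant(models, "chr1", 1200)[:2] == ("geneA", "intron")
        assert locate_variant(models, "chr1", 5000)[:2] == (None, "intergenic")
        assert locate_variant(models, "chr2", 1100)[:2] == (None, "intergenic")

    def test_overlapping_genes_report_all_hits(self, toy_genome):
        _, models = toy_genome
        models = dict(models)
        models["geneC"] = GeneModel("geneC", "chr1", "+", exons=[(1100, 1250)])
        gid, region, hits = locate_variant(models, "chr1", 1100)
        assert {h[0] for h in hits} == {"geneA", "geneC"}
        assert gid == "geneA" and region == "exon"  # first by id among exon hits


class TestCodonChange:
    def test_known_middle_position_change(self):
        # gene whose first codon is ACG on the forward strand
        seqs = {"c1": "ACGTTTAAA"}
        m = GeneModel("g", "c1", "+", exons=[(1, 9)], cds=[(1, 9)])
        out = codon_change(seqs, m, 2, "T")
        assert out == ("aCg", "aTg", "T", "M")  # Thr -> Met, non-synonymous

    def test_third_position_wobble_synonymous(self):
        seqs = {"c1": "CTGAAATTT"}
        m = GeneModel("g", "c1", "+", exons=[(1, 9)], cds=[(1, 9)])
        cref, calt, aref, aalt = codon_change(seqs, m, 3, "A")
        assert (cref, calt) == ("ctG", "ctA")
        assert aref == aalt == "L"  # Leu -> Leu

    def test_minus_strand_equals_mirrored_plus_twin(self, toy_genome):
        seqs, models = toy_genome
        seq = seqs["chr1"]
        minus = models["geneB"]
        # plus-strand twin on the reverse-complemented chromosome at
        # mirrored coordinates
        L = len(seq)
        rc = str(Seq(seq).reverse_complement())
        twin = GeneModel(
            "twin", "chr1", "+",
            exons=[(L - e + 1, L - s + 1) for s, e in reversed(minus.exons)],
            cds=[(L - e + 1, L - s + 1) for s, e in reversed(minus.cds)],
        )
        for pos in (2150, 2450, 2500):
            base = seq[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
            got = codon_change({"chr1": seq}, minus, pos, alt)
            mirror_alt = str(Seq(alt).complement())
            want = codon_change({"chr1": rc}, twin, L - pos + 1, mirror_alt)
            assert got == want

    def test_effects_match_retranslation_oracle(self, toy_genome):
        seqs, models = toy_genome
        seq = seqs["chr1"]
        rng = np.random.default_rng(13)
        for model in models.values():
            cds_positions = [
                p for s, e in model.cds for p in range(s, e + 1)
            ]
            for pos in rng.choice(cds_positions, size=40, replace=False):
                pos = int(pos)
                base = seq[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != base])
                _, _, aref, aalt = codon_change(seqs, model, pos, alt)
                mine = "sSNP" if aref == aalt else "nsSNP"
                assert mine == oracle_effect(seq, model, pos, alt), (model.gene_id, pos)

    def test_incomplete_terminal_codon_deferred(self):
        seqs = {"c1": "ACGTT" + "A" * 10}
        m = GeneModel("g", "c1", "+", exons=[(1, 5)], cds=[(1, 5)])
        with pytest.warns(UserWarning):
            assert codon_change(seqs, m, 5, "G") is None

    def test_position_outside_cds_rejected(self, toy_genome):
        seqs, models = toy_genome
        with pytest.raises(ValueError):
            codon_change(seqs, models["geneA"], 1010, "A")  # UTR exon


class TestAnnotateVariants:
    def test_utr_exon_is_noncoding(self, toy_genome):
        seqs, models = toy_genome
        base = seqs["chr1"][1010 - 1]
        alt = "A" if base != "A" else "G"
        df = pd.DataFrame(
            [("chr1", 1010, base, alt)], columns=["chrom", "pos", "ref", "alt"]
        )
        out = annotate_variants(df, models, seqs)
        assert out.iloc[0]["region"] == "exon"
        assert out.iloc[0]["effect"] == "non-coding"

    def test_partition_counts_sum(self, toy_genome):
        seqs, models = toy_genome
        rng = np.random.default_rng(21)
        pos = rng.choice(np.arange(1, 6001), size=60, replace=False)
        df = pd.DataFrame(
            [
                ("chr1", int(p), seqs["chr1"][p - 1],
                 {"A": "G", "C": "T", "G": "A", "T": "C"}[seqs["chr1"][p - 1]])
                for p in pos
            ],
            columns=["chrom", "pos", "ref", "alt"],
        )
        out = annotate_variants(df, models, seqs)
        summ = summarize_region_effects(out)
        assert summ["n_exon"] + summ["n_intron"] + summ["n_intergenic"] == summ["n_snps"]


class TestGff3RoundTrip:
    def test_write_then_read_recovers_models(self, toy_genome, tmp_path):
        _, models = toy_genome
        path = tmp_path / "genes.gff3"
        write_gff3(models, path)
        back = read_gff3(path)
        assert set(back) == set(models)
        for gid, m in models.items():
            assert back[gid].exons == m.exons
            assert back[gid].cds == m.cds
            assert back[gid].strand == m.strand


class TestRegionSummaries:
    def test_df_region_table_counts(self, df_candidate_table):
        summ = summarize_region_effects(df_candidate_table)
        assert summ["n_snps"] == 9
        assert summ["n_genes"] == 7
        assert summ["n_exon"] == 2
        assert summ["n_intron"] == 7

    def test_leaf_region_table_counts(self, leaf_candidate_table):
        summ = summarize_region_effects(leaf_candidate_table)
        assert summ["n_snps"] == 39
        assert summ["n_genes"] == 20
        assert summ["n_exon"] == 8
        assert summ["n_nsSNP"] == 4
        assert summ["n_sSNP"] == 4

    def test_empty_region_all_zero(self, df_candidate_table):
        class Region:
            chrom, start, end = "CcLG99", 1, 2

        summ = summarize_region_effects(df_candidate_table, Region)
        assert all(v == 0 for v in summ.values())
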