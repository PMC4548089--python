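"""CDS splicing, S/N classification, and the per-gene mutation table."""

import numpy as np
import pytest

from plastcomp import (
    Feature,
    ValidationError,
    make_genome,
    revcomp,
    splice_cds,
)
from plastcomp.coding import effect_of, gene_table, load_category_map, translate_codon
from plastcomp.events import SNP, gc_class, snp_kind
from plastcomp.io_genomes import synthesize_exons_introns

from conftest import toy_genome
from oracles import protein_effect


def snp_at(genome, pos, alt):
    ref = genome.seq[pos]
    return SNP(ref, alt, pos, pos, pos, snp_kind(ref, alt), gc_class(ref, alt))


class TestSplice:
    def test_plus_strand_single_exon(self):
        g = toy_genome("TT" + "ATGAAA" + "TT", [("g", "gene", "+", [(2, 8)])])
        assert splice_cds(g, "g") == "ATGAAA"

    def test_minus_strand_revcomp(self):
        g = toy_genome("TT" + "TTTCAT" + "GG", [("g", "gene", "-", [(2, 8)])])
        assert splice_cds(g, "g") == "ATGAAA"

    def test_two_exons_spliced(self):
        intron = "G" * 100
        g = toy_genome("AA" + "ATG" + intron + "TAA" + "CC",
                       [("g", "gene", "+", [(2, 5), (105, 108)])])
        assert splice_cds(g, "g") == "ATGTAA"

    def test_length_not_multiple_of_three_truncated(self, caplog):
        g = toy_genome("ATGAA" + "TT", [("g", "gene", "+", [(0, 5)])])
        assert splice_cds(g, "g") == "ATG"


class TestEffect:
    def test_synonymous_third_position(self):
        g = toy_genome("GCTAAA", [("g", "gene", "+", [(0, 6)])])
        eff = effect_of(snp_at(g, 2, "C"), g, "g")
        assert (eff.ref_codon, eff.alt_codon, eff.effect) == ("GCT", "GCC", "S")
        assert eff.ref_aa == eff.alt_aa == "A"

    def test_nonsynonymous_met_to_ile(self):
        g = toy_genome("ATGAAA", [("g", "gene", "+", [(0, 6)])])
        eff = effect_of(snp_at(g, 2, "A"), g, "g")
        assert (eff.ref_aa, eff.alt_aa, eff.effect) == ("M", "I", "N")

    def test_snp_outside_gene_rejected(self):
        g = toy_genome("ATGAAATT", [("g", "gene", "+", [(0, 6)])])
        with pytest.raises(ValidationError):
            effect_of(snp_at(g, 7, "A"), g, "g")

    def test_minus_strand_effect(self):
        # genomic TTTCAT is CDS ATGAAA on the minus strand; genomic position 2
        # maps to CDS index 3 (first base of the AAA codon); genomic T->C is
        # A->G on the coding strand: Lys -> Glu
        g = toy_genome("TTTCAT", [("g", "gene", "-", [(0, 6)])])
        eff = effect_of(snp_at(g, 2, "C"), g, "g")
        assert eff.ref_codon == "AAA" and eff.alt_codon == "GAA"
        assert (eff.ref_aa, eff.alt_aa, eff.effect) == ("K", "E", "N")

    def test_agrees_with_whole_protein_oracle_1000_snps(self):
        rng = np.random.default_rng(42)
        genome = make_genome(7)
        protein_genes = [f for f in genome.genes if f.kind == "gene"]
        checked = 0
        while checked < 1000:
            gene = protein_genes[int(rng.integers(len(protein_genes)))]
            a, b = gene.intervals[int(rng.integers(len(gene.intervals)))]
            pos = int(rng.integers(a, b))
            ref = genome.seq[pos]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            eff = effect_of(snp_at(genome, pos, alt), genome, gene)
            expected = protein_effect(genome.seq, gene.intervals, gene.strand, pos, alt)
            assert eff.effect == expected, (gene.name, pos, ref, alt)
            checked += 1

    def test_strand_invariance_of_sn_calls(self):
        genome = make_genome(8)
        n = len(genome)
        flipped_feats = []
        for f in genome.genes:
            ivs = tuple(sorted((n - b, n - a) for a, b in f.intervals))
            flipped_feats.append(
                Feature(f.name, f.kind, "-" if f.strand == "+" else "+", ivs)
            )
        from plastcomp import AnnotatedGenome
        flipped = AnnotatedGenome(
            id="flip", seq=revcomp(genome.seq),
            features=flipped_feats + synthesize_exons_introns(flipped_feats),
        )
        rng = np.random.default_rng(9)
        genes = [f for f in genome.genes if f.kind == "gene"]
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(200):
            gene = genes[int(rng.integers(len(genes)))]
            a, b = gene.intervals[0]
            pos = int(rng.integers(a, b))
            alt = "ACGT"[int(rng.integers(4))]
            if alt == genome.seq[pos]:
                continue
            eff = effect_of(snp_at(genome, pos, alt), genome, gene)
            fpos = n - 1 - pos
            falt = alt.translate(comp)
            # IR-duplicated genes share a name: match the flipped copy by span
            want = tuple(sorted((n - d, n - c) for c, d in gene.intervals))
            fgene = next(f for f in flipped.genes
                         if f.name == gene.name and f.intervals == want)
            feff = effect_of(snp_at(flipped, fpos, falt), flipped, fgene)
            assert eff.effect == feff.effect


class TestGeneTable:
    def test_empty_effects(self):
        df = gene_table([])
        assert list(df.iloc[-1][["ts", "tv", "s", "n"]]) == [0, 0, 0, 0]

    def test_totals_across_genes(self):
        g = toy_genome("GCTAAAGCA", [("psbA", "gene", "+", [(0, 6)]),
                                     ("rbcL", "gene", "+", [(6, 9)])])
        scored = [
            (snp_at(g, 2, "C"), effect_of(snp_at(g, 2, "C"), g, "psbA")),   # S
            (snp_at(g, 7, "T"), effect_of(snp_at(g, 7, "T"), g, "rbcL")),   # N
            (snp_at(g, 6, "C"), effect_of(snp_at(g, 6, "C"), g, "rbcL")),   # N
        ]
        df = gene_table(scored)
        total = df[df["gene"] == "total"].iloc[0]
        assert (total.s, total.n) == (1, 2)
        assert (total.ts + total.tv) == (total.s + total.n) == 3

    def test_per_gene_ts_tv_equals_s_n(self, synth_pair):
        from plastcomp import compare_pair
        res = compare_pair(synth_pair["ref"], synth_pair["alt"],
                           aln=synth_pair["aln"])
        df = res.gene_table
        body = df[~df["gene"].isin(["subtotal", "total"])]
        assert ((body.ts + body.tv) == (body.s + body.n)).all()
        total = df[df["gene"] == "total"].iloc[0]
        assert total.s + total.n == len(res.scored_coding)

    def test_unmapped_gene_goes_to_other(self):
        g = toy_genome("GCTAAA", [("mystery", "gene", "+", [(0, 6)])])
        eff = effect_of(snp_at(g, 2, "C"), g, "mystery")
        df = gene_table([(snp_at(g, 2, "C"), eff)])
        assert df.iloc[0]["category"] == "other"

    def test_default_map_covers_standard_genes(self):
        cmap = load_category_map()
        assert cmap["psbA"] == "photosynthetic apparatus"
        assert cmap["rbcL"] == "photosynthetic metabolism"
        assert cmap["rpoC2"] == "gene expression"
        assert cmap["ycf1"] == "other"

    def test_translate_codon_stops(self):
        assert translate_codon("TAA") == "*"
        assert translate_codon("ATG") == "M"
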