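"""The synthetic plastome-pair generator and recovery scoring."""

import math

import pytest

from plastcomp import (
    MutationSpectrum,
    ValidationError,
    detect_partition,
    find_ssrs,
    make_genome,
    mutate,
    score_recovery,
)

from conftest import call_all


class TestMakeGenome:
    def test_deterministic_per_seed(self):
        g1, g2 = make_genome(1), make_genome(1)
        assert g1.seq == g2.seq
        assert [f.intervals for f in g1.genes] == [f.intervals for f in g2.genes]
        assert g1.seq != make_genome(2).seq

    def test_partition_recovered_exactly(self):
        g = make_genome(1)
        part = detect_partition(g)
        assert part.lengths() == {"LSC": 20_000, "IRb": 4_000, "SSC": 5_000, "IRa": 4_000}

    def test_custom_dimensions(self):
        g = make_genome(2, lsc=8000, ir=2000, ssc=3000, n_genes=12)
        assert len(g) == 15_000
        assert detect_partition(g).lengths()["SSC"] == 3000

    def test_planted_ssrs_all_found(self):
        g = make_genome(3)
        found = {(s.start, s.end) for s in find_ssrs(g)}
        for t in g.metadata["planted_ssrs"]:
            assert (t["start"], t["end"]) in found, t

    def test_zero_density_leaves_only_chance_repeats(self):
        g = make_genome(3, ssr_density=0.0)
        assert g.metadata["planted_ssrs"] == []
        # spacer/intron sequence is run-broken below threshold, so any chance
        # repeat can only come from the codon draw inside exons
        for locus in find_ssrs(g):
            assert locus.context.compartment == "exon"

    def test_genes_have_valid_cds(self):
        from plastcomp import splice_cds
        from plastcomp.coding import translate_codon
        g = make_genome(4)
        for gene in g.genes:
            if gene.kind != "gene":
                continue
            cds = splice_cds(g, gene)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            assert translate_codon(cds[-3:]) == "*"
            inner = [translate_codon(cds[i:i + 3]) for i in range(3, len(cds) - 3, 3)]
            assert "*" not in inner

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValidationError):
            make_genome(1, lsc=1000, ir=1000, ssc=1000, n_genes=40)


class TestMutate:
    def test_zero_spectrum_is_identity(self):
        g = make_genome(5)
        spectrum = MutationSpectrum(n_snps=0, n_ssr_indels=0, n_nonssr_indels=0,
                                    n_inversions=0, seed=1)
        mutated, ledger = mutate(g, spectrum)
        assert mutated.seq == g.seq and ledger.events == []

    def test_ledger_matches_requested_counts(self):
        g = make_genome(5)
        mutated, ledger = mutate(g, MutationSpectrum(seed=2))
        assert ledger.counts() == {"snp": 50, "indel": 20, "inversion": 1}

    def test_events_respect_spacing(self):
        g = make_genome(5)
        _, ledger = mutate(g, MutationSpectrum(seed=3))
        positions = sorted(e.ref_pos for e in ledger.events)
        gaps = [q - p for p, q in zip(positions, positions[1:])]
        assert min(gaps) >= 20

    def test_snp_recovery_and_binomial_ts_count(self):
        g = make_genome(6)
        spectrum = MutationSpectrum(n_snps=50, ts_fraction=0.5, n_ssr_indels=0,
                                    n_nonssr_indels=0, n_inversions=0, seed=7)
        mutated, ledger = mutate(g, spectrum)
        _, _, snps, indels, invs = call_all(g, mutated)
        assert len(snps) == 50 and not indels and not invs
        ts = sum(1 for s in snps if s.kind == "Ts")
        # binomial(50, 0.5) 99% interval
        bound = 2.576 * math.sqrt(50 * 0.25)
        assert abs(ts - 25) <= bound + 0.5

    def test_inversion_recovered_at_ledger_position(self):
        g = make_genome(6)
        spectrum = MutationSpectrum(n_snps=0, n_ssr_indels=0, n_nonssr_indels=0,
                                    n_inversions=1, inversion_len=5, seed=8)
        mutated, ledger = mutate(g, spectrum)
        _, _, snps, indels, invs = call_all(g, mutated)
        assert len(invs) == 1 and not snps and not indels
        truth = ledger.by_type("inversion")[0]
        assert abs(invs[0].ref_pos - truth.ref_pos) <= 2
        assert invs[0].length == 5

    def test_polarity_truth(self, synth_pair):
        truth = {e.ref_pos: e.polarity for e in synth_pair["ledger"].by_type("indel")}
        for ind in synth_pair["indels"]:
            assert truth[ind.ref_pos] == ind.polarity

    def test_annotation_liftover_preserves_cds(self):
        from plastcomp import splice_cds
        from plastcomp.coding import translate_codon
        g = make_genome(6)
        # indels only: every lifted gene must still splice to a clean ORF
        spectrum = MutationSpectrum(n_snps=0, n_ssr_indels=5, n_nonssr_indels=5,
                                    n_inversions=0, seed=9)
        mutated, _ = mutate(g, spectrum)
        for gene in mutated.genes:
            if gene.kind != "gene":
                continue
            cds = splice_cds(mutated, gene)
            assert cds[:3] == "ATG" and translate_codon(cds[-3:]) == "*"

    def test_impossible_spacing_raises(self):
        g = make_genome(6, lsc=2000, ir=1000, ssc=1000, n_genes=2)
        with pytest.raises(ValidationError):
            mutate(g, MutationSpectrum(n_snps=500, seed=1))


class TestRoundTrip:
    def test_exact_recovery_across_20_seeds(self):
        for seed in range(20):
            g = make_genome(seed)
            mutated, ledger = mutate(g, MutationSpectrum(seed=seed + 1000))
            _, _, snps, indels, invs = call_all(g, mutated)
            report = score_recovery(snps, indels, invs, ledger)
            assert report.perfect(), (seed, report.to_dict())

    def test_classification_truth(self, synth_pair):
        truth_snp = {e.ref_pos: e.expected for e in synth_pair["ledger"].by_type("snp")}
        for s in synth_pair["snps"]:
            assert truth_snp[s.ref_pos]["kind"] == s.kind
        truth_ind = {e.ref_pos: e.expected["ssr_type"]
                     for e in synth_pair["ledger"].by_type("indel")}
        for ind in synth_pair["indels"]:
            assert truth_ind[ind.ref_pos] == ind.ssr_type


class TestScoreRecovery:
    def test_perfect_call_set(self, synth_pair):
        rep = score_recovery(synth_pair["snps"], synth_pair["indels"],
                             synth_pair["inversions"], synth_pair["ledger"])
        assert rep.perfect()
        assert all(not v["no_calls"] for v in rep.per_type.values())

    def test_one_dropped_snp_gives_recall_098(self, synth_pair):
        rep = score_recovery(synth_pair["snps"][1:], synth_pair["indels"],
                             synth_pair["inversions"], synth_pair["ledger"])
        assert rep.per_type["snp"]["recall"] == pytest.approx(0.98)
        assert rep.per_type["snp"]["precision"] == 1.0

    def test_empty_call_set_flagged(self, synth_pair):
        rep = score_recovery([], [], [], synth_pair["ledger"])
        for kind in ("snp", "indel"):
            assert rep.per_type[kind]["recall"] == 0.0
            assert rep.per_type[kind]["precision"] == 1.0
            assert rep.per_type[kind]["no_calls"]

    def test_spectrum_validation(self):
        with pytest.raises(ValidationError):
            MutationSpectrum(ts_fraction=1.5).validate()
        with pytest.raises(ValidationError):
            MutationSpectrum(nonssr_size_dist=((1, 0.5),)).validate()
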