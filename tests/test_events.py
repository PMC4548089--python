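"""SNP/indel/micro-inversion calling and event summaries."""

import itertools

import pytest

from plastcomp import (
    PairwiseAlignment,
    ValidationError,
    align_pair,
    build_map,
    call_indels,
    call_snps,
    detect_inversions,
    find_ssrs,
    make_genome,
    revcomp,
    summarize,
)
from plastcomp.events import SNP, Indel, gc_class, snp_kind
from plastcomp.io_genomes import LocusContext, locate

from conftest import call_all, random_seq


def aln_of(a, b):
    aln = PairwiseAlignment(["r", "q"], [a, b])
    return aln, build_map(aln)


class TestSnpClassification:
    def test_tv_at_class(self):
        aln, amap = aln_of("ACGT", "ACGA")
        snps = call_snps(aln, amap)
        assert len(snps) == 1
        s = snps[0]
        assert (s.ref_base, s.alt_base, s.kind, s.gc_class) == ("T", "A", "Tv", "AT<->TA")

    def test_ts_gc_changing(self):
        aln, amap = aln_of("AG", "GG")
        s = call_snps(aln, amap)[0]
        assert (s.ref_base, s.alt_base, s.kind, s.gc_class) == ("A", "G", "Ts", "GC-changing")

    def test_partition_exhaustive_and_exclusive(self):
        for ref, alt in itertools.permutations("ACGT", 2):
            kind = snp_kind(ref, alt)
            assert kind in ("Ts", "Tv")
            cls = gc_class(ref, alt)
            assert cls in ("AT<->TA", "CG<->GC", "GC-changing")
            # transitions always change GC content
            if kind == "Ts":
                assert cls == "GC-changing"

    def test_n_columns_excluded(self):
        aln, amap = aln_of("ANGT", "AAGT")
        assert call_snps(aln, amap) == []


class TestIndels:
    def test_ssr_slippage_insertion(self):
        a = "GCT" + "A" * 10 + "TCG"
        b = "GCT" + "A" * 12 + "TCG"
        aln = align_pair(a, b)
        amap = build_map(aln)
        ssrs = {0: find_ssrs(a), 1: find_ssrs(b)}
        events = call_indels(aln, amap, ssr_loci_by_row=ssrs)
        assert len(events) == 1
        e = events[0]
        assert (e.polarity, e.ssr_type, e.size, e.motif) == ("insertion", "SSR", 2, "AA")

    def test_nonssr_insertion_of_novel_motif(self):
        a = "ACGTGCTTGCAACGT"
        b = a[:8] + "TTCGAA" + a[8:]
        aln = align_pair(a, b)
        amap = build_map(aln)
        ssrs = {0: find_ssrs(a), 1: find_ssrs(b)}
        events = call_indels(aln, amap, ssr_loci_by_row=ssrs)
        assert [(e.polarity, e.ssr_type, e.size) for e in events] == \
            [("insertion", "non-SSR", 6)]

    def test_maximal_gap_run_is_one_event(self):
        aln, amap = aln_of("ACGTACGTACGT", "ACGT----ACGT")
        events = call_indels(aln, amap)
        assert [(e.polarity, e.size, e.motif) for e in events] == \
            [("deletion", 4, "ACGT")]

    def test_polarity_antisymmetry(self, synth_pair):
        aln = synth_pair["aln"]
        swapped = PairwiseAlignment(
            list(reversed(aln.names)), list(reversed(aln.rows))
        )
        fwd = call_indels(aln, build_map(aln))
        rev = call_indels(swapped, build_map(swapped))
        flip = {"insertion": "deletion", "deletion": "insertion"}
        assert sorted((e.motif, e.size, flip[e.polarity]) for e in fwd) == \
            sorted((e.motif, e.size, e.polarity) for e in rev)


class TestInversions:
    def test_five_bp_inversion_detected(self):
        left, right = "GATTACAGCT", "TGCATGGACT"
        a = left + "ACCTG" + right
        b = left + revcomp("ACCTG") + right
        assert revcomp("ACCTG") == "CAGGT"
        aln, amap = aln_of(a, b)
        invs, consumed = detect_inversions(aln, amap)
        assert len(invs) == 1
        inv = invs[0]
        assert (inv.length, inv.ref_segment, inv.alt_segment) == (5, "ACCTG", "CAGGT")
        assert consumed == set(range(10, 15))
        # consumed columns produce no SNPs
        assert call_snps(aln, amap, consumed=consumed) == []

    def test_palindrome_is_no_event(self):
        seg = "ACGT"  # its own reverse complement: zero mismatch columns
        a = "GATTACAGCT" + seg + "TGCATGGACT"
        aln, amap = aln_of(a, a)
        invs, consumed = detect_inversions(aln, amap)
        assert invs == [] and consumed == set()

    def test_single_mismatch_stays_a_snp(self):
        # a 1-bp "inversion" (A vs T) is also a valid substitution; the
        # min_mismatches=2 rule keeps it a SNP
        a = "GATTACAGCT" + "A" + "TGCATGGACT"
        b = "GATTACAGCT" + "T" + "TGCATGGACT"
        aln, amap = aln_of(a, b)
        invs, consumed = detect_inversions(aln, amap)
        assert invs == []
        assert len(call_snps(aln, amap, consumed=consumed)) == 1

    def test_span_cap_respected(self):
        seg = "ACCTGACCTGACCTG"
        a = "GATTACAGCT" + seg + "TGCATGGACT"
        b = "GATTACAGCT" + revcomp(seg) + "TGCATGGACT"
        aln, amap = aln_of(a, b)
        invs, _ = detect_inversions(aln, amap, max_inv_len=10)
        assert invs == []


class TestConservation:
    def test_every_difference_column_claimed_exactly_once(self, synth_pair):
        from oracles import difference_columns, event_footprint_columns

        aln = synth_pair["aln"]
        ra, rb = aln.rows
        diffs = difference_columns(ra, rb)
        claims = event_footprint_columns(
            synth_pair["snps"], synth_pair["indels"], synth_pair["inversions"],
            ra, rb,
        )
        claimed = set()
        for cols in claims:
            assert cols, "event with empty footprint"
            assert not (cols & claimed), "column claimed twice"
            claimed |= cols
        assert claimed == diffs

    def test_column_walker_on_random_small_alignments(self, rng):
        from oracles import difference_columns, event_footprint_columns

        for _ in range(10):
            a = random_seq(rng, 400)
            # sprinkle substitutions and small indels
            b = list(a)
            for pos in rng.choice(380, size=8, replace=False):
                b[pos] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            b = b[:100] + b[104:]                      # 4-bp deletion
            b = b[:200] + "TTCGA" + b[200:]            # 5-bp insertion
            aln = align_pair(a, b)
            amap = build_map(aln)
            invs, consumed = detect_inversions(aln, amap)
            indels = call_indels(aln, amap, consumed=consumed)
            snps = call_snps(aln, amap, consumed=consumed)
            diffs = difference_columns(*aln.rows)
            claims = event_footprint_columns(snps, indels, invs, *aln.rows)
            claimed = set()
            for cols in claims:
                assert not (cols & claimed)
                claimed |= cols
            assert claimed == diffs


class TestSummaries:
    def _snp_at(self, genome, pos):
        ref = genome.seq[pos]
        alt = "A" if ref != "A" else "G"
        return SNP(ref, alt, pos, pos, pos, snp_kind(ref, alt), gc_class(ref, alt),
                   locate(genome, pos))

    def test_empty_event_list(self):
        s = summarize([], [], [])
        assert s.total_events == 0
        assert s.region_percent["snp"] == {}

    def test_all_lsc_is_100_percent(self):
        g = make_genome(6)
        lsc = g.partition.lsc
        snps = [self._snp_at(g, lsc[0] + 200 + 40 * i) for i in range(10)]
        s = summarize(snps, [], [], g.partition)
        assert s.region_percent["snp"] == {"LSC": 100.0}

    def test_percentages_sum_to_100(self, synth_pair):
        s = summarize(synth_pair["snps"], synth_pair["indels"],
                      synth_pair["inversions"], synth_pair["ref"].partition)
        for kind in ("snp", "indel"):
            assert abs(sum(s.region_percent[kind].values()) - 100.0) <= 0.011
        assert s.total_events == s.counts["snp"] + s.counts["indel"] + s.counts["inversion"]

    def test_ir_duplicated_snp_counted_once(self):
        g = make_genome(6)
        (b0, b1) = g.partition.irb
        (a0, a1) = g.partition.ira
        p = b0 + 123
        mirror = a0 + (b1 - 1 - p)
        s = summarize([self._snp_at(g, p), self._snp_at(g, mirror)], [], [],
                      g.partition)
        assert s.counts["snp"] == 1
        assert s.region_counts["snp"] == {"IR": 1}

    def test_missing_context_rejected(self):
        g = make_genome(6)
        bare = SNP("A", "G", 0, 0, 0, "Ts", "GC-changing", None)
        with pytest.raises(ValidationError):
            summarize([bare], [], [], g.partition)
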