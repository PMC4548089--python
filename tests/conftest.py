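import numpy as np
import pytest

from plastcomp import (
    AnnotatedGenome,
    Feature,
    MutationSpectrum,
    align_pair,
    build_map,
    call_indels,
    call_snps,
    detect_inversions,
    find_ssrs,
    make_genome,
    mutate,
)
from plastcomp.io_genomes import synthesize_exons_introns


def toy_genome(seq, genes=(), gid="toy"):
    """AnnotatedGenome from a raw sequence and (name, kind, strand, intervals)."""
    feats = [Feature(n, k, s, tuple(iv)) for n, k, s, iv in genes]
    return AnnotatedGenome(
        id=gid, seq=seq, features=feats + synthesize_exons_introns(feats)
    )


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def call_all(ref, alt):
    """Align a genome pair and run the full event-calling cascade."""
    aln = align_pair(ref.seq, alt.seq, names=(ref.id, alt.id))
    amap = build_map(aln)
    inversions, consumed = detect_inversions(aln, amap, ref)
    ssrs = {0: find_ssrs(ref), 1: find_ssrs(alt)}
    indels = call_indels(aln, amap, ref, ssrs, consumed=consumed)
    snps = call_snps(aln, amap, ref, consumed=consumed)
    return aln, amap, snps, indels, inversions


@pytest.fixture(scope="session")
def synth_pair():
    """One reference synthetic pair with its ledger and called events."""
    genome = make_genome(0)
    mutated, ledger = mutate(genome, MutationSpectrum(seed=101))
    aln, amap, snps, indels, inversions = call_all(genome, mutated)
    return {
        "ref": genome, "alt": mutated, "ledger": ledger, "aln": aln,
        "amap": amap, "snps": snps, "indels": indels, "inversions": inversions,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
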