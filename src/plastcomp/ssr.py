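"""Microsatellite (SSR) detection: maximal mono- and di-nucleotide tandem
repeats at configurable unit-count thresholds (defaults: 8 units for
mononucleotide, 4 units for dinucleotide runs)."""

from __future__ import annotations

from dataclasses import dataclass

from ._util import ParameterError
from .io_genomes import AnnotatedGenome, LocusContext, locate


@dataclass(frozen=True)
class SSRLocus:
    """A maximal exact tandem repeat of a 1-2 bp motif, on the given strand."""

    motif: str
    unit_count: int
    start: int
    end: int
    context: LocusContext | None = None
    genome_id: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start

    def canonical_motif(self) -> str:
        """Rotation-invariant motif key (AT and TA describe the same tract)."""
        if len(self.motif) == 1:
            return self.motif
        rot = self.motif[1] + self.motif[0]
        return min(self.motif, rot)


def _mono_runs(seq: str):
    """Maximal runs (start, end, base) of a single A/C/G/T base."""
    n = len(seq)
    i = 0
    while i < n:
        b = seq[i]
        if b not in "ACGT":
            i += 1
            continue
        j = i + 1
        while j < n and seq[j] == b:
            j += 1
        yield i, j, b
        i = j


def _di_tracts(seq: str):
    """Maximal alternating tracts (start, end, motif) of two distinct bases;
    end - start may be odd (trailing half unit)."""
    n = len(seq)
    i = 0
    while i < n - 1:
        a, b = seq[i], seq[i + 1]
        if a == b or a not in "ACGT" or b not in "ACGT":
            i += 1
            continue
        j = i + 2
        while j < n and seq[j] == seq[j - 2] and seq[j] in "ACGT":
            j += 1
        yield i, j, a + b
        i = j - 1


def scan_ssrs(seq: str, mono_min: int = 8, di_min: int = 4) -> list[SSRLocus]:
    """All maximal mono/di SSRs in a raw sequence, sorted by start.

    Overlapping loci (a homopolymer bordering an alternating tract) are
    resolved by keeping the longer span.
    """
    if mono_min < 2 or di_min < 2:
        raise ParameterError("SSR thresholds must be >= 2 repeat units")
    seq = seq.upper()
    loci: list[SSRLocus] = []
    for start, end, base in _mono_runs(seq):
        units = end - start
        if units >= mono_min:
            loci.append(SSRLocus(base, units, start, end))
    for start, end, motif in _di_tracts(seq):
        units = (end - start) // 2
        if units >= di_min:
            loci.append(SSRLocus(motif, units, start, start + 2 * units))
    # longer span wins on overlap; deterministic order for ties
    loci.sort(key=lambda s: (-s.span, s.start, s.motif))
    kept: list[SSRLocus] = []
    for loc in loci:
        if all(loc.end <= k.start or loc.start >= k.end for k in kept):
            kept.append(loc)
    kept.sort(key=lambda s: s.start)
    return kept


def find_ssrs(
    genome: AnnotatedGenome | str, mono_min: int = 8, di_min: int = 4
) -> list[SSRLocus]:
    """SSR scan of a genome, with locus context attached when annotation and
    partition are available."""
    if isinstance(genome, str):
        return scan_ssrs(genome, mono_min, di_min)
    out = []
    for loc in scan_ssrs(genome.seq, mono_min, di_min):
        ctx = locate(genome, loc.start)
        out.append(SSRLocus(loc.motif, loc.unit_count, loc.start, loc.end,
                            context=ctx, genome_id=genome.id))
    return out


def pair_ssrs(ref_ssrs, alt_ssrs, amap, ref_row: int = 0, alt_row: int = 1):
    """Match SSR loci between two aligned genomes into Table-style rows.

    Loci pair when their alignment-column spans overlap and their canonical
    motifs agree. Returns a list of dicts with unit counts per genome (None
    where a locus is below threshold / absent in one genome).
    """
    def col_span(locus, row):
        p2c = amap.pos_to_col[row]
        return int(p2c[locus.start]), int(p2c[locus.end - 1]) + 1

    alt_free = list(alt_ssrs)
    rows = []
    for r in ref_ssrs:
        rc = col_span(r, ref_row)
        match = None
        for a in alt_free:
            if a.canonical_motif() != r.canonical_motif():
                continue
            ac = col_span(a, alt_row)
            if rc[0] < ac[1] and ac[0] < rc[1]:
                match = a
                break
        if match is not None:
            alt_free.remove(match)
        rows.append({
            "motif": r.motif,
            "ref_units": r.unit_count,
            "alt_units": match.unit_count if match else None,
            "ref_start": r.start,
            "context": r.context,
        })
    for a in alt_free:
        rows.append({
            "motif": a.motif,
            "ref_units": None,
            "alt_units": a.unit_count,
            "ref_start": None,
            "context": a.context,
        })
    rows.sort(key=lambda d: (d["ref_start"] is None, d["ref_start"] or 0))
    return rows


def write_ssr_tsv(ssrs: list[SSRLocus], path) -> None:
    """TSV mirroring the per-genome SSR table layout (1-based coordinates);
    ``path`` may be a filename or an open text stream."""
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        fh.write("genome\tmotif\tunits\tstart\tend\tregion\tcompartment\tlabel\n")
        for s in ssrs:
            ctx = s.context or LocusContext("", "", "")
            fh.write(
                f"{s.genome_id}\t{s.motif}\t{s.unit_count}\t{s.start + 1}\t{s.end}"
                f"\t{ctx.region}\t{ctx.compartment}\t{ctx.label}\n"
            )
    finally:
        if fh is not path:
            fh.close()
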