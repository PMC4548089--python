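"""Independent reference implementations used to cross-check the package.

These deliberately take different algorithmic routes from the library code:
top-down recursion instead of matrix DP for alignment scores, substring
enumeration for SSRs, whole-protein translation via Biopython feature
extraction for coding effects.
"""

from functools import lru_cache

from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation


def best_alignment_score(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Optimal global affine-gap score by exhaustive recursion over all
    alignments (memoized on suffix + gap state)."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # state: 0 none/diagonal, 1 gap in b open, 2 gap in a open
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            if a[i] == "N" or b[j] == "N":
                s = 0
            else:
                s = match if a[i] == b[j] else mismatch
            cand = s + rec(i + 1, j + 1, 0)
            best = cand if best is None else max(best, cand)
        if i < len(a):  # consume a, gap in b
            cost = gap_extend + (0 if state == 1 else gap_open)
            cand = cost + rec(i + 1, j, 1)
            best = cand if best is None else max(best, cand)
        if j < len(b):  # consume b, gap in a
            cost = gap_extend + (0 if state == 2 else gap_open)
            cand = cost + rec(i, j + 1, 2)
            best = cand if best is None else max(best, cand)
        return best

    return rec(0, 0, 0)


def naive_ssr_scan(seq, mono_min=8, di_min=4):
    """All maximal 1-2 bp tandem repeats by checking every substring start,
    with the longer-span rule applied to overlapping loci.

    Returns a set of (motif, units, start, end)."""
    seq = seq.upper()
    n = len(seq)
    found = []
    for m in (1, 2):
        for start in range(n - m + 1):
            unit = seq[start:start + m]
            if any(c not in "ACGT" for c in unit):
                continue
            if m == 2 and unit[0] == unit[1]:
                continue
            # count units to the right
            units = 0
            pos = start
            while seq[pos:pos + m] == unit:
                units += 1
                pos += m
            # maximal on the left?
            if start >= m and seq[start - m:start] == unit:
                continue
            threshold = mono_min if m == 1 else di_min
            if units >= threshold:
                found.append((unit, units, start, start + m * units))
    found.sort(key=lambda t: (-(t[3] - t[2]), t[2], t[0]))
    kept = []
    for cand in found:
        if all(cand[3] <= k[2] or cand[2] >= k[3] for k in kept):
            kept.append(cand)
    return set(kept)


def protein_effect(genome_seq, intervals, strand, ref_pos, alt_base):
    """S/N call by translating the whole spliced CDS before and after the
    substitution (Biopython feature extraction, table 11)."""
    def extract(seq):
        locs = [SimpleLocation(a, b, 1 if strand == "+" else -1)
                for a, b in intervals]
        if strand == "-":
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        cds = SeqFeature(loc).extract(Seq(seq))
        cds = cds[: len(cds) - len(cds) % 3]
        return str(cds.translate(table=11))
    before = extract(genome_seq)
    mutated = genome_seq[:ref_pos] + alt_base + genome_seq[ref_pos + 1:]
    after = extract(mutated)
    return "S" if before == after else "N"


def difference_columns(row_a, row_b):
    """Columns where the two rows differ (gap or base mismatch), Ns excluded."""
    out = set()
    for c, (x, y) in enumerate(zip(row_a, row_b)):
        if x == y or "N" in (x, y):
            continue
        out.add(c)
    return out


def event_footprint_columns(snps, indels, inversions, row_a, row_b):
    """Difference columns claimed by each called event, as a list of sets.

    SNPs claim their column; indels the columns of their gap run; inversions
    the mismatching columns inside their span.
    """
    claims = []
    for s in snps:
        claims.append({s.column})
    for ind in indels:
        cols = set()
        c = ind.column
        row = row_a if ind.polarity == "insertion" else row_b
        while c < len(row) and row[c] == "-":
            cols.add(c)
            c += 1
        claims.append(cols)
    for inv in inversions:
        cols = {
            c for c in range(inv.column, inv.column + inv.length)
            if row_a[c] != row_b[c]
        }
        claims.append(cols)
    return claims
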