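"""Pairwise global alignment and column<->genome coordinate maps.

The pipeline either ingests an externally produced alignment (aligned FASTA /
Clustal) or computes one itself. The internal aligner is a global affine-gap
Needleman-Wunsch (Gotoh) with deterministic tie-breaking; genome-scale pairs
are aligned by chaining unique exact k-mer anchors and running the full DP
only on the short segments between anchors, which is exact whenever the two
genomes are colinear and highly similar (the plastome case).

A gap run of length L costs gap_open + L * gap_extend. Columns where either
base is N score 0 (neither match nor mismatch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from ._util import ParseError, ValidationError

log = logging.getLogger(__name__)

NEG_INF = np.int32(-(2 ** 30))

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Scoring:
    """Integer alignment scores; a length-L gap costs gap_open + L*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch, dtype=np.int32)
        np.fill_diagonal(m, self.match)
        m[4, :] = 0
        m[:, 4] = 0
        return m


@dataclass
class PairwiseAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}; row ``reference_index``
    plays the reference role for polarity and coordinates downstream."""

    names: list[str]
    rows: list[str]
    reference_index: int = 0
    score: int | None = None

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValidationError("alignment needs >= 2 rows")
        if len(self.names) != len(self.rows):
            raise ValidationError("names/rows length mismatch")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ParseError("ragged alignment: rows have unequal lengths")
        if not 0 <= self.reference_index < len(self.rows):
            raise ValidationError("reference_index out of range")
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValidationError(f"alignment contains invalid symbols: {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def drop_allgap_columns(self) -> "PairwiseAlignment":
        arrs = [np.frombuffer(r.encode(), dtype="S1") for r in self.rows]
        stack = np.vstack(arrs)
        keep = ~(stack == b"-").all(axis=0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("removed %d all-gap columns", n_dropped)
            rows = ["".join(row) for row in stack[:, keep].astype(str)]
            return PairwiseAlignment(self.names, rows, self.reference_index, self.score)
        return self


@dataclass
class AlignmentMap:
    """Mutually inverse column->position and position->column maps per row;
    gap columns map to -1."""

    col_to_pos: list[np.ndarray] = field(default_factory=list)
    pos_to_col: list[np.ndarray] = field(default_factory=list)

    def ref_pos_at(self, row: int, column: int) -> int:
        """Position of `column` in row's sequence, or the last position
        before it if the column is a gap (-1 if none)."""
        pos = int(self.col_to_pos[row][column])
        if pos >= 0:
            return pos
        prev = self.col_to_pos[row][:column]
        prev = prev[prev >= 0]
        return int(prev[-1]) if prev.size else -1


def build_map(aln: PairwiseAlignment) -> AlignmentMap:
    amap = AlignmentMap()
    for row in aln.rows:
        arr = np.frombuffer(row.encode(), dtype="S1")
        isbase = arr != b"-"
        c2p = np.where(isbase, np.cumsum(isbase) - 1, -1).astype(np.int64)
        p2c = np.flatnonzero(isbase).astype(np.int64)
        amap.col_to_pos.append(c2p)
        amap.pos_to_col.append(p2c)
    return amap


def read_alignment(path, format: str = "fasta") -> PairwiseAlignment:
    """Read an aligned FASTA or Clustal file; all-gap columns are removed."""
    if format not in ("fasta", "clustal"):
        raise ParseError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as {format}: {exc}") from exc
    names = [rec.id for rec in msa]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in msa]
    aln = PairwiseAlignment(names, rows)
    return aln.drop_allgap_columns()


def write_alignment(aln: PairwiseAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# --------------------------------------------------------------------------
# Gotoh DP (exact, for segments); states: M diagonal, X gap-in-b (consumes a),
# Y gap-in-a (consumes b). Tie preference M > X > Y everywhere.
# --------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"sequence symbol outside ACGTN: {exc}") from exc


def _gotoh_matrices(ea, eb, sc: Scoring):
    n, m = len(ea), len(eb)
    sub = sc.matrix()
    go, ge = np.int32(sc.gap_open), np.int32(sc.gap_extend)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    M[0, 0] = 0
    if n:
        X[1:, 0] = go + ge * np.arange(1, n + 1, dtype=np.int32)
    if m:
        Y[0, 1:] = go + ge * np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        srow = sub[ea[i - 1], eb]                      # length m
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = srow + best_prev[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go + ge,
            X[i - 1, 1:] + ge,
        )
        # Y (horizontal) via running-max scan: Y[i,j] = ge*j + max_{k<j}(base[k]-ge*k)
        base = np.maximum(M[i], X[i]) + go            # open at column k
        jj = ge * np.arange(m + 1, dtype=np.int32)
        scan = np.maximum.accumulate(base - jj)
        Y[i, 1:] = scan[:-1] + jj[1:]
    return M, X, Y


def _gotoh_traceback(ea, eb, sc: Scoring, M, X, Y):
    sub = sc.matrix()
    go, ge = sc.gap_open, sc.gap_extend
    i, j = len(ea), len(eb)
    # final state preference: M (end on a mismatch/match) > X > Y
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j], s == "M", s == "X"))
    ops = []  # 'D' diagonal, 'X' gap in b, 'Y' gap in a
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                raise AssertionError("corrupt traceback")
            ops.append("D")
            target = M[i, j] - sub[ea[i - 1], eb[j - 1]]
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i, j] == target:
                    state = s
                    break
            else:
                raise AssertionError("corrupt traceback (M)")
        elif state == "X":
            ops.append("X")
            here = X[i, j]
            i -= 1
            if M[i, j] + go + ge == here:
                state = "M"
            elif X[i, j] + ge == here:
                state = "X"
            elif Y[i, j] + go + ge == here:
                state = "Y"
            else:
                raise AssertionError("corrupt traceback (X)")
        else:
            ops.append("Y")
            here = Y[i, j]
            j -= 1
            if M[i, j] + go + ge == here:
                state = "M"
            elif X[i, j] + go + ge == here:
                state = "X"
            elif Y[i, j] + ge == here:
                state = "Y"
            else:
                raise AssertionError("corrupt traceback (Y)")
    ops.reverse()
    return ops


def _gotoh_align(a: str, b: str, sc: Scoring) -> tuple[str, str, int]:
    if not a and not b:
        return "", "", 0
    if not a:
        return "-" * len(b), b, sc.gap_open + sc.gap_extend * len(b)
    if not b:
        return a, "-" * len(a), sc.gap_open + sc.gap_extend * len(a)
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_matrices(ea, eb, sc)
    n, m = len(a), len(b)
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    ops = _gotoh_traceback(ea, eb, sc, M, X, Y)
    ra, rb, ia, ib = [], [], 0, 0
    for op in ops:
        if op == "D":
            ra.append(a[ia]); rb.append(b[ib]); ia += 1; ib += 1
        elif op == "X":
            ra.append(a[ia]); rb.append("-"); ia += 1
        else:
            ra.append("-"); rb.append(b[ib]); ib += 1
    return "".join(ra), "".join(rb), score


# --------------------------------------------------------------------------
# Anchor chaining for long, colinear pairs
# --------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _anchor_chain(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Colinear non-overlapping exact anchors (ia, ib, length), by LIS over
    unique shared k-mers followed by merging of adjacent on-diagonal seeds."""
    ka, kb = _unique_kmers(a, k), _unique_kmers(b, k)
    pairs = sorted((ia, kb[km]) for km, ia in ka.items() if km in kb)
    if not pairs:
        return []
    # longest increasing subsequence in ib
    import bisect
    tails: list[int] = []
    tidx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (ia, ib) in enumerate(pairs):
        p = bisect.bisect_left(tails, ib)
        if p == len(tails):
            tails.append(ib); tidx.append(idx)
        else:
            tails[p] = ib; tidx[p] = idx
        parent[idx] = tidx[p - 1] if p > 0 else -1
    chain = []
    cur = tidx[-1]
    while cur != -1:
        chain.append(pairs[cur])
        cur = parent[cur]
    chain.reverse()
    # merge on-diagonal contiguous/overlapping seeds, drop off-chain overlaps
    anchors: list[list[int]] = []
    for ia, ib in chain:
        if anchors:
            pa, pb, pl = anchors[-1]
            if ia - ib == pa - pb and ia <= pa + pl:
                anchors[-1][2] = ia + k - pa
                continue
            if ia < pa + pl or ib < pb + pl:
                continue
        anchors.append([ia, ib, k])
    return [tuple(x) for x in anchors]


def align_pair(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    names: tuple[str, str] = ("ref", "alt"),
    max_dp_cells: int = 4_000_000,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two sequences.

    Pairs small enough for the full DP are aligned exactly; longer pairs are
    anchored on unique shared k-mers and the DP runs between anchors. Raises
    ValidationError for empty sequences or symbols outside ACGTN.
    """
    if not a or not b:
        raise ValidationError("align_pair: sequences must be non-empty")
    sc = scoring or Scoring()
    _encode(a), _encode(b)  # symbol validation up front
    ra, rb, score = _align_rec(a, b, sc, max_dp_cells, k=32)
    aln = PairwiseAlignment(list(names), [ra, rb], reference_index=0, score=score)
    assert aln.ungapped(0) == a and aln.ungapped(1) == b
    return aln


def _align_rec(a, b, sc, max_dp_cells, k):
    if (len(a) + 1) * (len(b) + 1) <= max_dp_cells:
        return _gotoh_align(a, b, sc)
    anchors = _anchor_chain(a, b, k) if k >= 8 else []
    if not anchors:
        if k >= 8:
            return _align_rec(a, b, sc, max_dp_cells, k=k // 2)
        return _edlib_align(a, b, sc)
    ra, rb, score = [], [], 0
    pa = pb = 0
    for ia, ib, length in anchors:
        if ia > pa or ib > pb:
            sa, sb, s = _align_rec(a[pa:ia], b[pb:ib], sc, max_dp_cells, max(8, k // 2))
            ra.append(sa); rb.append(sb); score += s
        ra.append(a[ia:ia + length]); rb.append(b[ib:ib + length])
        score += sc.match * length
        pa, pb = ia + length, ib + length
    if pa < len(a) or pb < len(b):
        sa, sb, s = _align_rec(a[pa:], b[pb:], sc, max_dp_cells, max(8, k // 2))
        ra.append(sa); rb.append(sb); score += s
    return "".join(ra), "".join(rb), score


def _edlib_align(a: str, b: str, sc: Scoring):
    """Unit-cost global alignment fallback for long low-identity segments."""
    import edlib

    log.info("edlib fallback for %d x %d segment", len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="path")
    ra, rb, ia, ib = [], [], 0, 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        L = int(num)
        num = ""
        if ch in "=XM":
            ra.append(a[ia:ia + L]); rb.append(b[ib:ib + L]); ia += L; ib += L
        elif ch == "I":   # consumes query a only
            ra.append(a[ia:ia + L]); rb.append("-" * L); ia += L
        elif ch == "D":   # consumes target b only
            ra.append("-" * L); rb.append(b[ib:ib + L]); ib += L
    ra, rb = "".join(ra), "".join(rb)
    return ra, rb, _score_alignment(ra, rb, sc)


def _score_alignment(ra: str, rb: str, sc: Scoring) -> int:
    """Score an existing alignment under the affine model (for reporting)."""
    score = 0
    gap_a = gap_b = False
    for x, y in zip(ra, rb):
        if x == "-":
            score += sc.gap_extend + (0 if gap_a else sc.gap_open)
            gap_a, gap_b = True, False
        elif y == "-":
            score += sc.gap_extend + (0 if gap_b else sc.gap_open)
            gap_a, gap_b = False, True
        else:
            gap_a = gap_b = False
            if x != "N" and y != "N":
                score += sc.match if x == y else sc.mismatch
    return score
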