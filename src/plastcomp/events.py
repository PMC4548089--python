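"""Mutation-event calling between two aligned plastomes.

Calling order matters: micro-inversions are detected first and their columns
flagged as consumed, so a 5-bp inversion is not miscounted as several SNPs;
indels are one event per maximal gap run; remaining mismatch columns are
per-site SNPs. Polarity (insertion vs deletion) is relative to the designated
reference row. Columns containing N in either row are excluded from calling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from ._util import ValidationError, revcomp
from .alignment import AlignmentMap, PairwiseAlignment
from .io_genomes import AnnotatedGenome, LocusContext, Partition, locate
from .ssr import SSRLocus

log = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def snp_kind(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    pair = {ref, alt}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "Ts"
    return "Tv"


def gc_class(ref: str, alt: str) -> str:
    """Non-strand-specific substitution class by GC-content effect."""
    pair = {ref, alt}
    if pair == {"A", "T"}:
        return "AT<->TA"
    if pair == {"C", "G"}:
        return "CG<->GC"
    return "GC-changing"


@dataclass(frozen=True)
class SNP:
    ref_base: str
    alt_base: str
    column: int
    ref_pos: int
    alt_pos: int
    kind: str
    gc_class: str
    context: LocusContext | None = None

    @property
    def type(self) -> str:
        return "snp"


@dataclass(frozen=True)
class Indel:
    motif: str
    size: int
    polarity: str              # insertion | deletion, relative to reference
    ssr_type: str              # SSR | non-SSR
    ref_pos: int               # insertion point / first deleted ref position
    alt_pos: int
    column: int                # first alignment column of the gap run
    context: LocusContext | None = None

    @property
    def type(self) -> str:
        return "indel"


@dataclass(frozen=True)
class Inversion:
    ref_segment: str
    alt_segment: str
    length: int
    ref_pos: int
    alt_pos: int
    column: int
    context: LocusContext | None = None

    @property
    def type(self) -> str:
        return "inversion"


def _pair_rows(aln: PairwiseAlignment, alt_row: int | None):
    ref = aln.reference_index
    if alt_row is None:
        alt_row = 1 if ref == 0 else 0
    if alt_row == ref or not 0 <= alt_row < len(aln.rows):
        raise ValidationError("invalid alternate row")
    return ref, alt_row


# --------------------------------------------------------------------------
# Micro-inversions
# --------------------------------------------------------------------------

def detect_inversions(
    aln: PairwiseAlignment,
    amap: AlignmentMap | None = None,
    ref_genome: AnnotatedGenome | None = None,
    min_inv_len: int = 3,
    max_inv_len: int = 50,
    min_mismatches: int = 2,
    alt_row: int | None = None,
    cluster_join: int = 5,
) -> tuple[list[Inversion], set[int]]:
    """Find micro-inversions as mismatch clusters whose alternate segment is
    the exact reverse complement of the reference segment.

    Mismatch columns separated by at most ``cluster_join`` matching columns
    (and no gaps or Ns) form a cluster; a cluster with >= min_mismatches
    mismatches is reported as an inversion if some gap-free span containing
    it (boundaries extended by up to 3 matching columns each side, total span
    within [min_inv_len, max_inv_len]) satisfies the reverse-complement
    identity. Returns the inversions and the set of consumed columns.
    """
    from .alignment import build_map

    ref_i, alt_i = _pair_rows(aln, alt_row)
    ra, rb = aln.rows[ref_i], aln.rows[alt_i]
    if amap is None:
        amap = build_map(aln)
    n = aln.width

    def usable(c):
        return ra[c] != "-" and rb[c] != "-" and ra[c] != "N" and rb[c] != "N"

    mismatches = [c for c in range(n) if usable(c) and ra[c] != rb[c]]
    # group into clusters
    clusters: list[list[int]] = []
    for c in mismatches:
        if (
            clusters
            and c - clusters[-1][-1] <= cluster_join + 1
            and all(usable(x) for x in range(clusters[-1][-1] + 1, c))
        ):
            clusters[-1].append(c)
        else:
            clusters.append([c])

    inversions: list[Inversion] = []
    consumed: set[int] = set()
    for cl in clusters:
        if len(cl) < min_mismatches:
            continue
        c1, c2 = cl[0], cl[-1]
        found = None
        for extra in range(0, 7):
            for a in range(extra + 1):
                b = extra - a
                s, e = c1 - a, c2 + b
                if s < 0 or e >= n:
                    continue
                span = e - s + 1
                if span < min_inv_len or span > max_inv_len:
                    continue
                if not all(usable(x) for x in range(s, e + 1)):
                    continue
                seg_r = ra[s:e + 1]
                seg_a = rb[s:e + 1]
                if seg_a == revcomp(seg_r):
                    found = (s, e, seg_r, seg_a)
                    break
            if found:
                break
        if not found:
            continue
        s, e, seg_r, seg_a = found
        ref_pos = amap.ref_pos_at(ref_i, s)
        alt_pos = amap.ref_pos_at(alt_i, s)
        ctx = locate(ref_genome, ref_pos) if ref_genome is not None else None
        inversions.append(
            Inversion(seg_r, seg_a, e - s + 1, ref_pos, alt_pos, s, ctx)
        )
        consumed.update(range(s, e + 1))
    return inversions, consumed


# --------------------------------------------------------------------------
# Indels
# --------------------------------------------------------------------------

def _is_unit_repeat(motif: str, unit: str) -> bool:
    """True if motif is a whole number of copies of unit or a rotation of it."""
    k = len(unit)
    if len(motif) % k:
        return False
    rotations = {unit[i:] + unit[:i] for i in range(k)}
    return any(motif == rot * (len(motif) // k) for rot in rotations)


def _ssr_support(motif: str, pos: int, loci: list[SSRLocus]) -> bool:
    """Does an SSR locus of the genome carrying the longer allele overlap
    (or touch) [pos, pos+len(motif)) with a compatible motif?"""
    end = pos + len(motif)
    for loc in loci:
        if loc.start - 1 <= end and pos <= loc.end + 1:
            if len(loc.motif) <= 2 and _is_unit_repeat(motif, loc.motif):
                return True
    return False


def call_indels(
    aln: PairwiseAlignment,
    amap: AlignmentMap | None = None,
    ref_genome: AnnotatedGenome | None = None,
    ssr_loci_by_row: dict[int, list[SSRLocus]] | None = None,
    alt_row: int | None = None,
    consumed: set[int] | None = None,
) -> list[Indel]:
    """One indel event per maximal gap run in either row.

    A gap in the reference row is an insertion (material present in the other
    genome); a gap in the alternate row is a deletion. An event is SSR-type
    iff a microsatellite locus of the longer-allele genome overlaps the event
    site with a motif whose length (1-2) divides the event size and whose
    repetition reproduces the event motif; otherwise non-SSR.
    """
    from .alignment import build_map

    ref_i, alt_i = _pair_rows(aln, alt_row)
    ra, rb = aln.rows[ref_i], aln.rows[alt_i]
    if amap is None:
        amap = build_map(aln)
    consumed = consumed or set()
    ssr_loci_by_row = ssr_loci_by_row or {}
    events: list[Indel] = []
    n = aln.width
    ref_seq, alt_seq = aln.ungapped(ref_i), aln.ungapped(alt_i)
    for row_i, row, polarity in ((ref_i, ra, "insertion"), (alt_i, rb, "deletion")):
        c = 0
        while c < n:
            if row[c] != "-":
                c += 1
                continue
            start = c
            while c < n and row[c] == "-":
                c += 1
            end = c  # [start, end) is a maximal gap run in this row
            if any(x in consumed for x in range(start, end)):
                continue
            other = rb if row_i == ref_i else ra
            motif = other[start:end].replace("-", "")
            if not motif:
                continue  # opposing gaps only; nothing inserted or deleted
            size = len(motif)
            if polarity == "insertion":
                # material lives in the alternate genome
                alt_pos = int(amap.col_to_pos[alt_i][start])
                ref_pos = amap.ref_pos_at(ref_i, start) + 1  # insertion point
                # left-normalize (VCF convention): an indel inside a repeat is
                # reported at the leftmost equivalent position
                while (alt_pos > 0 and ref_pos > 0
                       and alt_seq[alt_pos - 1] == alt_seq[alt_pos + size - 1]):
                    alt_pos -= 1
                    ref_pos -= 1
                motif = alt_seq[alt_pos:alt_pos + size]
                longer_loci = ssr_loci_by_row.get(alt_i, [])
                site = alt_pos
            else:
                ref_pos = int(amap.col_to_pos[ref_i][start])
                alt_pos = amap.ref_pos_at(alt_i, start) + 1
                while (ref_pos > 0
                       and ref_seq[ref_pos - 1] == ref_seq[ref_pos + size - 1]):
                    ref_pos -= 1
                    if alt_pos > 0:
                        alt_pos -= 1
                motif = ref_seq[ref_pos:ref_pos + size]
                longer_loci = ssr_loci_by_row.get(ref_i, [])
                site = ref_pos
            ssr_type = "SSR" if _ssr_support(motif, site, longer_loci) else "non-SSR"
            ctx = None
            if ref_genome is not None:
                ctx = locate(ref_genome, min(max(ref_pos, 0), len(ref_genome) - 1))
            events.append(
                Indel(motif, size, polarity, ssr_type, ref_pos, alt_pos, start, ctx)
            )
    events.sort(key=lambda e: e.column)
    return events


# --------------------------------------------------------------------------
# SNPs
# --------------------------------------------------------------------------

def call_snps(
    aln: PairwiseAlignment,
    amap: AlignmentMap | None = None,
    ref_genome: AnnotatedGenome | None = None,
    alt_row: int | None = None,
    consumed: set[int] | None = None,
) -> list[SNP]:
    """One SNP per column where both rows carry unequal non-gap, non-N bases
    and the column is not consumed by a detected inversion."""
    from .alignment import build_map

    ref_i, alt_i = _pair_rows(aln, alt_row)
    ra, rb = aln.rows[ref_i], aln.rows[alt_i]
    if amap is None:
        amap = build_map(aln)
    consumed = consumed or set()
    out: list[SNP] = []
    for c in range(aln.width):
        x, y = ra[c], rb[c]
        if x == y or "-" in (x, y) or "N" in (x, y) or c in consumed:
            continue
        ref_pos = int(amap.col_to_pos[ref_i][c])
        alt_pos = int(amap.col_to_pos[alt_i][c])
        ctx = locate(ref_genome, ref_pos) if ref_genome is not None else None
        out.append(SNP(x, y, c, ref_pos, alt_pos, snp_kind(x, y), gc_class(x, y), ctx))
    return out


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

def _ir_mirror(pos: int, part: Partition) -> int | None:
    """Mirror of a position under the IRb/IRa reverse-complement symmetry."""
    (b0, b1), (a0, a1) = part.irb, part.ira
    if b0 <= pos < b1:
        return a0 + (b1 - 1 - pos)
    if a0 <= pos < a1:
        return b0 + (a1 - 1 - pos)
    return None


def _dedupe_ir_events(events: list, part: Partition | None) -> list:
    """IR-duplicated events (mirror-image positions, same type/size) count once."""
    if part is None:
        return list(events)
    kept: list = []
    seen_mirrors: set[tuple] = set()
    for ev in events:
        mirror = _ir_mirror(ev.ref_pos, part)
        key = (ev.type, ev.ref_pos)
        if mirror is not None and (ev.type, mirror) in {
            (k.type, k.ref_pos) for k in kept
        } | seen_mirrors:
            seen_mirrors.add(key)
            continue
        kept.append(ev)
    return kept


@dataclass
class EventSummary:
    counts: dict = field(default_factory=dict)
    region_counts: dict = field(default_factory=dict)
    region_percent: dict = field(default_factory=dict)
    compartment_counts: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def total_events(self) -> int:
        return sum(self.counts.get(k, 0) for k in ("snp", "indel", "inversion"))

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "total_events": self.total_events,
            "region_counts": self.region_counts,
            "region_percent": self.region_percent,
            "compartment_counts": self.compartment_counts,
            "notes": self.notes,
        }


def summarize(
    snps: list[SNP],
    indels: list[Indel],
    inversions: list[Inversion],
    partition: Partition | None = None,
) -> EventSummary:
    """Counts by type and class, per-region site percentages (IRa+IRb pooled,
    IR-duplicated events counted once) and per-compartment counts."""
    s = EventSummary()
    snps = _dedupe_ir_events(snps, partition)
    indels = _dedupe_ir_events(indels, partition)
    inversions = _dedupe_ir_events(inversions, partition)
    s.counts = {
        "snp": len(snps),
        "indel": len(indels),
        "inversion": len(inversions),
        "snp_ts": sum(1 for x in snps if x.kind == "Ts"),
        "snp_tv": sum(1 for x in snps if x.kind == "Tv"),
        "indel_ssr": sum(1 for x in indels if x.ssr_type == "SSR"),
        "indel_nonssr": sum(1 for x in indels if x.ssr_type == "non-SSR"),
        "snp_gc_class": {
            k: sum(1 for x in snps if x.gc_class == k)
            for k in ("AT<->TA", "CG<->GC", "GC-changing")
        },
    }
    for name, events in (("snp", snps), ("indel", indels), ("inversion", inversions)):
        regions: dict[str, int] = {}
        comps: dict[str, int] = {}
        missing = [e for e in events if e.context is None]
        if missing and partition is not None:
            raise ValidationError(f"{len(missing)} {name} events lack locus context")
        for e in events:
            if e.context is None:
                continue
            region = e.context.region
            region = "IR" if region in ("IRa", "IRb") else region
            regions[region] = regions.get(region, 0) + 1
            comps[e.context.compartment] = comps.get(e.context.compartment, 0) + 1
        total = sum(regions.values())
        s.region_counts[name] = regions
        if total:
            s.region_percent[name] = {
                k: round(100.0 * v / total, 2) for k, v in sorted(regions.items())
            }
        else:
            s.region_percent[name] = {}
            s.notes.append(f"no localized {name} events; percentages undefined, reported empty")
        s.compartment_counts[name] = comps
    return s


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def _ctx_cols(ctx: LocusContext | None) -> str:
    ctx = ctx or LocusContext("", "", "")
    return f"{ctx.label}\t{ctx.region}\t{ctx.compartment}"


def write_snps_tsv(snps: list[SNP], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_pos\tref_base\talt_base\tkind\tgc_class\tlabel\tregion\tcompartment\n")
        for s in sorted(snps, key=lambda x: x.ref_pos):
            fh.write(
                f"{s.ref_pos + 1}\t{s.ref_base}\t{s.alt_base}\t{s.kind}\t{s.gc_class}"
                f"\t{_ctx_cols(s.context)}\n"
            )


def write_snps_vcf(snps: list[SNP], ref_id: str, alt_id: str, path) -> None:
    """Minimal VCF 4.2: CHROM is the reference genome id, POS 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={ref_id}\n")
        fh.write(f"##INFO=<ID=KIND,Number=1,Type=String,Description=\"Ts or Tv\">\n")
        fh.write(f"##INFO=<ID=ALTGENOME,Number=1,Type=String,Description=\"{alt_id}\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda x: x.ref_pos):
            fh.write(
                f"{ref_id}\t{s.ref_pos + 1}\t.\t{s.ref_base}\t{s.alt_base}\t.\t.\t"
                f"KIND={s.kind}\n"
            )


def write_indels_tsv(indels: list[Indel], inversions: list[Inversion], path) -> None:
    """Indels and micro-inversions, Table-3-style (Location, Region, Motif,
    Size, Direction)."""
    with open(path, "w") as fh:
        fh.write("ref_pos\tlabel\tregion\tcompartment\tmotif\tsize\tdirection\tssr_type\n")
        rows = [
            (e.ref_pos, e.motif.lower(), e.size, e.polarity.capitalize(), e.ssr_type, e.context)
            for e in indels
        ] + [
            (v.ref_pos, v.ref_segment.lower(), v.length, "Inversion", "-", v.context)
            for v in inversions
        ]
        for pos, motif, size, direction, ssr_type, ctx in sorted(rows):
            fh.write(
                f"{pos + 1}\t{_ctx_cols(ctx)}\t{motif}\t{size}\t{direction}\t{ssr_type}\n"
            )


def write_summary_json(summary: EventSummary, path, extra: dict | None = None) -> None:
    doc = summary.to_dict()
    if extra:
        doc = {**extra, "events": doc}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
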