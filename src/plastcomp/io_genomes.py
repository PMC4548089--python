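"""Genome and annotation I/O, quadripartite structure detection, locus naming.

A plastome is modelled as an :class:`AnnotatedGenome`: a linear view of the
circular molecule in its deposited orientation, carrying gene features and,
once detected, the canonical quadripartite :class:`Partition` into a large
single-copy region (LSC), two exactly reverse-complementary inverted repeats
(IRb, IRa) and a small single-copy region (SSC).

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._util import (
    ParseError,
    PartitionError,
    ValidationError,
    clean_sequence,
    gc_content,
    revcomp,
)

log = logging.getLogger(__name__)

GENE_KINDS = ("gene", "tRNA", "rRNA")

# Gaps between exon clusters larger than this are treated as trans-splicing
# (e.g. rps12) and not synthesized into intron features.
MAX_INTRON = 20_000


@dataclass(frozen=True)
class Feature:
    """A named genome feature with one or more half-open intervals.

    ``kind`` is one of gene/tRNA/rRNA (gene-level records, intervals = exons),
    or exon/intron (derived records, one interval each).
    """

    name: str
    kind: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.name}: bad strand {self.strand!r}")
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        if any(a >= b for a, b in ivs):
            raise ValidationError(f"feature {self.name}: empty or inverted interval")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ValidationError(f"feature {self.name}: overlapping intervals")
        object.__setattr__(self, "intervals", ivs)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Partition:
    """Quadripartite partition; the four intervals tile the genome exactly."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def lengths(self) -> dict[str, int]:
        return {name: b - a for name, (a, b) in self.regions().items()}

    def region_of(self, position: int) -> str:
        for name, (a, b) in self.regions().items():
            if a <= position < b:
                return name
        raise ValidationError(f"position {position} outside partition")

    def validate(self, genome: "AnnotatedGenome") -> None:
        ivs = sorted(self.regions().values())
        if ivs[0][0] != 0 or ivs[-1][1] != len(genome.seq):
            raise ValidationError("partition does not tile the genome")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 != a2:
                raise ValidationError("partition intervals overlap or leave gaps")
        ira = genome.seq[self.ira[0]:self.ira[1]]
        irb = genome.seq[self.irb[0]:self.irb[1]]
        if revcomp(ira) != irb:
            raise ValidationError("IRa is not the exact reverse complement of IRb")


@dataclass(frozen=True)
class LocusContext:
    """Where a position falls: region (LSC/IRb/SSC/IRa or ''), compartment
    (exon/intron/intergenic) and a human-readable locus label — the gene name,
    or 'geneA-geneB' for an intergenic spacer named by its flanking genes."""

    region: str
    compartment: str
    label: str

    @property
    def display(self) -> str:
        if self.compartment == "intron":
            return f"{self.label}(intron)"
        return self.label


@dataclass
class AnnotatedGenome:
    id: str
    seq: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    partition: Partition | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.seq)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"{self.id}: feature {f.name} ends at {f.end} > length {n}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)

    @property
    def genes(self) -> list[Feature]:
        """Gene-level features (kind gene/tRNA/rRNA), sorted by start."""
        return sorted(
            (f for f in self.features if f.kind in GENE_KINDS), key=lambda f: f.start
        )

    def gene_counts(self) -> dict[str, int]:
        """Distinct gene names per kind; IR-duplicated genes count once."""
        out = {}
        for kind in GENE_KINDS:
            out[kind] = len({f.name for f in self.features if f.kind == kind})
        return out

    def feature_by_name(self, name: str, kind: str | None = None) -> Feature:
        for f in self.features:
            if f.name == name and f.kind in (GENE_KINDS if kind is None else (kind,)):
                return f
        raise KeyError(name)


def synthesize_exons_introns(gene_features: list[Feature]) -> list[Feature]:
    """Derive explicit exon and intron features from gene-level records.

    Introns are exactly the gaps between consecutive exon intervals of the
    same gene; gaps wider than MAX_INTRON are assumed trans-spliced and
    skipped with a log note.
    """
    derived: list[Feature] = []
    for g in gene_features:
        for iv in g.intervals:
            derived.append(Feature(g.name, "exon", g.strand, (iv,)))
        for (a1, b1), (a2, b2) in zip(g.intervals, g.intervals[1:]):
            if a2 - b1 > MAX_INTRON:
                log.info("gene %s: gap %d-%d treated as trans-splicing", g.name, b1, a2)
                continue
            derived.append(Feature(g.name, "intron", g.strand, ((b1, a2),)))
    return derived


def _genbank_features(record) -> list[Feature]:
    wanted = {"CDS": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}
    genes: list[Feature] = []
    seen: set[tuple] = set()
    for feat in record.features:
        kind = wanted.get(feat.type)
        if kind is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        ivs = tuple((int(p.start), int(p.end)) for p in feat.location.parts)
        key = (name, kind, strand, tuple(sorted(ivs)))
        if key in seen:  # identical duplicate annotation rows
            continue
        seen.add(key)
        genes.append(Feature(name, kind, strand, ivs))
    return genes


def _read_annotation_tsv(path: str | Path) -> list[Feature]:
    """TSV fallback: columns gene, kind, strand, start, end (1-based inclusive);
    one row per exon, multi-exon genes repeat the gene name."""
    groups: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "kind", "strand", "start", "end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: annotation table needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                start = int(row["start"]) - 1
                end = int(row["end"])
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: non-integer coordinate") from exc
            key = (row["gene"], row["kind"], row["strand"])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((start, end))
    return [Feature(name, kind, strand, tuple(groups[(name, kind, strand)]))
            for name, kind, strand in order]


def read_genome(
    path: str | Path,
    format: str = "genbank",
    annotation_table: str | Path | None = None,
) -> AnnotatedGenome:
    """Read a genome from a GenBank flat file or FASTA (+ optional TSV annotation).

    Intron features are synthesized from multi-exon genes. A FASTA without an
    annotation table yields a feature-less genome (coding analyses unavailable).
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ParseError(f"unknown format {format!r}")
    try:
        record = SeqIO.read(str(path), format)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as {format}: {exc}") from exc
    seq, n_degraded = clean_sequence(str(record.seq), what=str(path))
    if n_degraded:
        log.warning("%s: %d ambiguity symbols degraded to N", path, n_degraded)
    genes: list[Feature] = []
    if format == "genbank":
        genes = _genbank_features(record)
    if annotation_table is not None:
        genes.extend(_read_annotation_tsv(annotation_table))
    features = genes + synthesize_exons_introns(genes)
    return AnnotatedGenome(id=record.id or path.stem, seq=seq, features=features)


# --------------------------------------------------------------------------
# Quadripartite structure
# --------------------------------------------------------------------------

def _maximal_inverted_matches(seq: str, min_len: int, k: int = 20):
    """All maximal exact inverted-repeat pairs of length >= min_len.

    Seed-and-extend between seq and its reverse complement, one extension per
    diagonal. Yields (a1, a2, b1, b2): seq[b1:b2] == revcomp(seq[a1:a2]),
    a1 < b1, disjoint.
    """
    n = len(seq)
    k = min(k, min_len)
    rc = revcomp(seq)
    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        index.setdefault(rc[j:j + k], []).append(j)
    covered: dict[int, int] = {}
    out = []
    for i in range(n - k + 1):
        for j in index.get(seq[i:i + k], ()):
            d = i - j
            if covered.get(d, -1) >= i:
                continue
            a, b = i, j
            while a > 0 and b > 0 and seq[a - 1] == rc[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = i + k, j + k
            while e1 < n and e2 < n and seq[e1] == rc[e2]:
                e1 += 1
                e2 += 1
            covered[d] = e1
            if e1 - a < min_len:
                continue
            # second copy in genome coordinates
            b1, b2 = n - e2, n - b
            a1, a2 = a, e1
            if a2 <= b1:  # keep the (first, second) orientation once
                out.append((a1, a2, b1, b2))
    return out


def detect_partition(genome: AnnotatedGenome, min_ir_len: int = 1000) -> Partition:
    """Find the quadripartite partition from the maximal inverted-repeat pair.

    The longer single-copy arc between the IRs is labelled LSC, the shorter
    SSC; IRb is the repeat copy that follows the LSC in genome order. Raises
    PartitionError if no exact inverted pair >= min_ir_len exists, or if a
    single-copy region would span the sequence origin (rotate the genome
    first; see rotate_genome).
    """
    n = len(genome.seq)
    if n < 4 * min_ir_len:
        raise PartitionError(
            f"genome length {n} < 4*min_ir_len ({4 * min_ir_len})"
        )
    matches = _maximal_inverted_matches(genome.seq, min_ir_len)
    if not matches:
        raise PartitionError(
            f"no quadripartite structure: no inverted repeat pair >= {min_ir_len} bp"
        )
    a1, a2, b1, b2 = max(matches, key=lambda m: (m[1] - m[0], -m[0]))
    mid = (a2, b1)                    # arc between the two IR copies
    outer_len = a1 + (n - b2)         # arc through the origin
    if a1 > 0 and b2 < n:
        raise PartitionError(
            "a single-copy region spans the sequence origin; rotate the genome "
            "(rotate_genome) so the origin falls inside a single-copy region"
        )
    outer = (b2 % n, a1) if b2 == n else (b2, n)  # one side is empty
    if outer == (0, 0):
        raise PartitionError("inverted repeats are adjacent; no single-copy arcs")
    mid_len = mid[1] - mid[0]
    if outer_len >= mid_len:
        lsc, ssc = outer, mid
        irb, ira = (a1, a2), (b1, b2)  # IR1 follows the outer arc
    else:
        lsc, ssc = mid, outer
        irb, ira = (b1, b2), (a1, a2)  # IR2 follows the mid arc (circularly)
    part = Partition(lsc=lsc, irb=irb, ssc=ssc, ira=ira)
    part.validate(genome)
    return part


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate the linear view of a circular genome so old position ``offset``
    becomes position 0. Features spanning the new origin are dropped with a
    log note."""
    n = len(genome.seq)
    offset %= n
    seq = genome.seq[offset:] + genome.seq[:offset]
    feats = []
    for f in genome.features:
        ivs = []
        ok = True
        for a, b in f.intervals:
            a2, b2 = (a - offset) % n, (b - offset - 1) % n + 1
            if a2 >= b2:
                ok = False
                break
            ivs.append((a2, b2))
        if ok:
            feats.append(Feature(f.name, f.kind, f.strand, tuple(ivs)))
        else:
            log.info("rotate: feature %s spans the new origin, dropped", f.name)
    return AnnotatedGenome(
        id=genome.id, seq=seq, circular=genome.circular, features=feats,
        metadata=dict(genome.metadata),
    )


# --------------------------------------------------------------------------
# Locus context
# --------------------------------------------------------------------------

def locate(genome: AnnotatedGenome, position: int) -> LocusContext:
    """Resolve a genome position to (region, compartment, label).

    Exon wins over intron where genes overlap; intergenic positions are named
    'upstreamGene-downstreamGene' by the flanking genes in genome order
    (wrapping around the circle at the ends).
    """
    n = len(genome.seq)
    if not 0 <= position < n:
        raise ValidationError(f"position {position} out of range [0, {n})")
    region = genome.partition.region_of(position) if genome.partition else ""
    exon = intron = None
    for f in genome.features:
        if f.kind == "exon" and f.start <= position < f.end:
            exon = f
            break
        if f.kind == "intron" and intron is None and f.start <= position < f.end:
            intron = f
    if exon is not None:
        return LocusContext(region, "exon", exon.name)
    if intron is not None:
        return LocusContext(region, "intron", intron.name)
    genes = genome.genes
    if not genes:
        return LocusContext(region, "intergenic", "")
    up = max((g for g in genes if g.end <= position), key=lambda g: g.end, default=None)
    down = min((g for g in genes if g.start > position), key=lambda g: g.start, default=None)
    if up is None:
        up = max(genes, key=lambda g: g.end)        # wraps: last gene on the circle
    if down is None:
        down = min(genes, key=lambda g: g.start)    # wraps: first gene
    return LocusContext(region, "intergenic", f"{up.name}-{down.name}")


def loci_in_range(genome: AnnotatedGenome, start: int, end: int) -> list[str]:
    """Ordered distinct locus display labels overlapping [start, end)."""
    labels: list[str] = []
    boundaries = {start}
    for f in genome.features:
        for a, b in f.intervals:
            if a < end and b > start:
                boundaries.add(max(a, start))
                if start < b < end:
                    boundaries.add(b)
    for pos in sorted(boundaries):
        lab = locate(genome, pos).display
        if lab and (not labels or labels[-1] != lab):
            labels.append(lab)
    return labels


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_fasta(genome: AnnotatedGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.seq), width):
            fh.write(genome.seq[i:i + width] + "\n")


def write_annotation_tsv(genome: AnnotatedGenome, path: str | Path) -> None:
    """Gene-level annotation as the TSV fallback format (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("gene\tkind\tstrand\tstart\tend\n")
        for g in genome.genes:
            for a, b in g.intervals:
                fh.write(f"{g.name}\t{g.kind}\t{g.strand}\t{a + 1}\t{b}\n")


def write_partition_bed(genome: AnnotatedGenome, path: str | Path) -> None:
    if genome.partition is None:
        raise ValidationError("genome has no partition")
    with open(path, "w") as fh:
        for name, (a, b) in genome.partition.regions().items():
            fh.write(f"{genome.id}\t{a}\t{b}\t{name}\n")


def genome_summary(genome: AnnotatedGenome) -> dict:
    """Table-1-style summary: lengths, GC by region, gene counts."""
    out: dict = {
        "id": genome.id,
        "length": len(genome.seq),
        "gc_percent": round(100 * genome.gc, 2),
    }
    if genome.partition is not None:
        lens = genome.partition.lengths()
        out["lsc_length"] = lens["LSC"]
        out["ir_length"] = lens["IRb"]
        out["ssc_length"] = lens["SSC"]
        for name, (a, b) in genome.partition.regions().items():
            out[f"gc_{name.lower()}_percent"] = round(
                100 * gc_content(genome.seq[a:b]), 2
            )
    counts = genome.gene_counts()
    out["n_genes"] = sum(counts.values())
    out["n_protein_genes"] = counts["gene"]
    out["n_trna_genes"] = counts["tRNA"]
    out["n_rrna_genes"] = counts["rRNA"]
    return out
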