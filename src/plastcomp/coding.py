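"""Synonymous/non-synonymous classification of coding SNPs and per-gene
mutation tables.

Codons are read on the gene's strand with introns spliced out and translated
with the bacterial/plastid genetic code (NCBI translation table 11). Each SNP
is scored independently against the reference codon: the alternate codon
substitutes only that SNP's base, with any other nearby variants held at the
reference state. Start codons get no special treatment — a substitution in
the initiator codon is scored by amino-acid identity like any other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml
from Bio.Data import CodonTable

from ._util import ValidationError, revcomp
from .events import SNP, snp_kind
from .io_genomes import AnnotatedGenome, Feature

log = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
COMP = str.maketrans("ACGT", "TGCA")

CATEGORIES = (
    "photosynthetic apparatus",
    "photosynthetic metabolism",
    "gene expression",
    "other",
)


def translate_codon(codon: str) -> str:
    """Single-codon translation under table 11; stop codons yield '*'."""
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValidationError(f"cannot translate codon {codon!r}")
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


@dataclass(frozen=True)
class CodingEffect:
    gene: str
    codon_index: int
    codon_pos: int           # 0, 1 or 2 within the codon, coding strand
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str              # S | N

    def __post_init__(self):
        assert self.effect == ("S" if self.ref_aa == self.alt_aa else "N")


def splice_cds(genome: AnnotatedGenome, gene: Feature | str) -> str:
    """Spliced coding sequence of a gene: exons concatenated in genome order,
    reverse-complemented for minus-strand genes. A spliced length not
    divisible by 3 is truncated with a warning."""
    if isinstance(gene, str):
        gene = genome.feature_by_name(gene)
    if not gene.intervals:
        raise ValidationError(f"gene {gene.name} has no exons")
    cds = "".join(genome.seq[a:b] for a, b in gene.intervals)
    if gene.strand == "-":
        cds = revcomp(cds)
    if len(cds) % 3:
        log.warning(
            "gene %s: spliced length %d not divisible by 3; trailing %d base(s) dropped",
            gene.name, len(cds), len(cds) % 3,
        )
        cds = cds[: len(cds) - len(cds) % 3]
    return cds


def _cds_offset(gene: Feature, ref_pos: int) -> int:
    """Offset of a genome position within the forward-concatenated exons."""
    off = 0
    for a, b in gene.intervals:
        if a <= ref_pos < b:
            return off + (ref_pos - a)
        off += b - a
    raise ValidationError(
        f"position {ref_pos} is not in an exon of gene {gene.name}"
    )


def effect_of(snp: SNP, genome: AnnotatedGenome, gene: Feature | str) -> CodingEffect:
    """Classify a SNP inside a gene's exons as synonymous or non-synonymous."""
    if isinstance(gene, str):
        gene = genome.feature_by_name(gene)
    fwd = _cds_offset(gene, snp.ref_pos)
    cds = splice_cds(genome, gene)
    if gene.strand == "-":
        total = sum(b - a for a, b in gene.intervals)
        idx = total - 1 - fwd
        alt_base = snp.alt_base.translate(COMP)
    else:
        idx = fwd
        alt_base = snp.alt_base
    if idx >= len(cds):
        raise ValidationError(
            f"SNP at {snp.ref_pos} falls in the truncated tail of gene {gene.name}"
        )
    ci, cp = divmod(idx, 3)
    ref_codon = cds[3 * ci:3 * ci + 3]
    if ref_codon[cp] != (snp.ref_base if gene.strand == "+" else snp.ref_base.translate(COMP)):
        raise ValidationError(
            f"SNP reference base disagrees with genome at {snp.ref_pos} in {gene.name}"
        )
    alt_codon = ref_codon[:cp] + alt_base + ref_codon[cp + 1:]
    ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
    return CodingEffect(
        gene.name, ci, cp, ref_codon, alt_codon, ref_aa, alt_aa,
        "S" if ref_aa == alt_aa else "N",
    )


def load_category_map(path=None) -> dict[str, str]:
    """Gene -> functional category map (YAML). Default: the shipped map of
    standard plastome genes in four groups."""
    if path is None:
        text = resources.files("plastcomp.data").joinpath("gene_categories.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, str] = {}
    for category, genes in raw.items():
        if category not in CATEGORIES:
            raise ValidationError(f"unknown gene category {category!r}")
        for g in genes:
            out[str(g)] = category
    return out


def gene_table(
    scored: list[tuple[SNP, CodingEffect]],
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene Ts/Tv and S/N counts with category subtotals and a grand total.

    Rows are sorted by category then gene name; genes absent from the map go
    to 'other' with a warning. For every gene ts+tv == s+n.
    """
    cmap = category_map if category_map is not None else load_category_map()
    per_gene: dict[str, dict[str, int]] = {}
    for snp, eff in scored:
        row = per_gene.setdefault(eff.gene, {"ts": 0, "tv": 0, "s": 0, "n": 0})
        row["ts" if snp_kind(snp.ref_base, snp.alt_base) == "Ts" else "tv"] += 1
        row["s" if eff.effect == "S" else "n"] += 1
    records = []
    for gene, row in per_gene.items():
        cat = cmap.get(gene)
        if cat is None:
            log.warning("gene %s missing from category map; assigned 'other'", gene)
            cat = "other"
        records.append({"category": cat, "gene": gene, **row})
    records.sort(key=lambda r: (CATEGORIES.index(r["category"]), r["gene"]))
    rows = []
    for cat in CATEGORIES:
        members = [r for r in records if r["category"] == cat]
        if not members:
            continue
        rows.extend(members)
        rows.append({
            "category": cat, "gene": "subtotal",
            **{k: sum(r[k] for r in members) for k in ("ts", "tv", "s", "n")},
        })
    rows.append({
        "category": "all", "gene": "total",
        **{k: sum(r[k] for r in records) for k in ("ts", "tv", "s", "n")},
    })
    df = pd.DataFrame(rows, columns=["category", "gene", "ts", "tv", "s", "n"])
    return df


def write_gene_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
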