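"""Synthetic annotated plastome pairs with a known mutation ledger.

`make_genome` builds a reduced-scale quadripartite genome (default LSC 20 kb,
IR 4 kb x2, SSC 5 kb) with frame-consistent protein genes (some multi-exon,
some minus-strand), tRNA genes, and planted mono/di microsatellite tracts.
`mutate` derives a second genome differing by an exactly known set of SNPs,
SSR-slippage indels, non-SSR indels and micro-inversions, returning the
ground-truth `MutationLedger` so every calling stage can be scored.

Events are spaced (default >= 20 bp) and placed in single-copy regions away
from exons (indels/inversions) so each is an isolated, unambiguously
alignable difference; event sites are chosen so the minimal alignment of the
pair cannot slide them by more than a couple of bases. All randomness flows
from a single seeded generator per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._util import ValidationError, revcomp
from .coding import COMP, load_category_map
from .io_genomes import (
    AnnotatedGenome,
    Feature,
    Partition,
    locate,
    synthesize_exons_introns,
)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


# --------------------------------------------------------------------------
# Spectrum and ledger
# --------------------------------------------------------------------------

@dataclass
class MutationSpectrum:
    """Counts and shapes of the planted divergence between a genome pair.

    Defaults are the reference desk-scale spectrum: 50 substitutions at
    Ts:Tv 1:1, 10 microsatellite slippage indels, 10 non-SSR indels with a
    size mix dominated by 1-7 bp plus occasional large (21-94 bp) events,
    and one 5-bp micro-inversion, all separated by at least 20 bp.
    """

    n_snps: int = 50
    ts_fraction: float = 0.5
    n_ssr_indels: int = 10
    n_nonssr_indels: int = 10
    nonssr_size_dist: tuple = (
        (1, 0.35), (2, 0.15), (3, 0.10), (4, 0.10), (5, 0.10),
        (6, 0.05), (7, 0.05), (10, 0.04), (21, 0.02), (22, 0.02), (94, 0.02),
    )
    n_inversions: int = 1
    inversion_len: int = 5
    min_spacing: int = 20
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_snps, self.n_ssr_indels, self.n_nonssr_indels,
               self.n_inversions) < 0:
            raise ValidationError("event counts must be >= 0")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValidationError("ts_fraction must be in [0, 1]")
        sizes = [s for s, _ in self.nonssr_size_dist]
        if any(not 1 <= s <= 100 for s in sizes):
            raise ValidationError("non-SSR indel sizes must be 1-100 bp")
        total = sum(w for _, w in self.nonssr_size_dist)
        if not np.isclose(total, 1.0):
            raise ValidationError("non-SSR size weights must sum to 1")


@dataclass
class LedgerEvent:
    type: str                 # snp | indel | inversion
    ref_pos: int
    alt_pos: int
    size: int
    motif: str
    polarity: str             # insertion | deletion | '' (snp, inversion)
    expected: dict = field(default_factory=dict)


@dataclass
class MutationLedger:
    events: list[LedgerEvent] = field(default_factory=list)

    def by_type(self, kind: str) -> list[LedgerEvent]:
        return [e for e in self.events if e.type == kind]

    def counts(self) -> dict[str, int]:
        return {k: len(self.by_type(k)) for k in ("snp", "indel", "inversion")}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.events], fh, indent=2)
            fh.write("\n")


# --------------------------------------------------------------------------
# Random sequence primitives
# --------------------------------------------------------------------------

def _nonrepetitive_seq(rng, length: int) -> str:
    """Random sequence with mono runs capped at 4 and alternations at 5 bases,
    so chance microsatellites never reach reporting thresholds."""
    out: list[str] = []
    for _ in range(length):
        banned = set()
        if len(out) >= 4 and out[-1] == out[-2] == out[-3] == out[-4]:
            banned.add(out[-1])
        if len(out) >= 5 and out[-1] == out[-3] == out[-5] and out[-2] == out[-4]:
            banned.add(out[-2])
        choices = [b for b in BASES if b not in banned]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _make_cds(rng, n_codons: int) -> str:
    """ATG + sense codons + stop, with internal repeats broken."""
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if a + b + c not in STOPS and a + b + c != "ATG"]
    codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(n_codons - 2)]
    codons.append(STOPS[rng.integers(3)])
    seq = list("".join(codons))
    # break runs that the codon draw may have produced
    for _ in range(10):
        changed = False
        s = "".join(seq)
        for i in range(len(s)):
            if i >= 5 and len(set(s[i - 5:i + 1])) == 1:
                ci = (i // 3) * 3
                if ci == 0 or ci + 3 > len(s) - 3:
                    continue
                repl = sense[rng.integers(len(sense))]
                seq[ci:ci + 3] = list(repl)
                changed = True
                break
        if not changed:
            break
    return "".join(seq)


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

def _gene_names(rng, n: int) -> list[str]:
    names = sorted(load_category_map().keys())
    order = list(rng.permutation(len(names)))
    picked = [names[i] for i in order[:n]]
    extra = n - len(picked)
    picked += [f"orf{100 + i}" for i in range(extra)]
    return picked


def _make_gene_block(rng, name: str, kind: str):
    """Returns (block_seq, exon_intervals_rel_to_block, strand)."""
    if kind == "tRNA":
        block = _nonrepetitive_seq(rng, int(rng.integers(70, 91)))
        strand = "+-"[rng.integers(2)]
        return block, [(0, len(block))], strand
    cds = _make_cds(rng, int(rng.integers(60, 181)))
    if rng.random() < 0.4:  # one intron
        t = int(rng.integers(30, len(cds) - 30))
        intron = _nonrepetitive_seq(rng, int(rng.integers(80, 151)))
        fwd_block = cds[:t] + intron + cds[t:]
        fwd_exons = [(0, t), (t + len(intron), len(fwd_block))]
    else:
        fwd_block = cds
        fwd_exons = [(0, len(cds))]
    if rng.random() < 0.4:
        L = len(fwd_block)
        block = revcomp(fwd_block)
        exons = sorted((L - b, L - a) for a, b in fwd_exons)
        return block, exons, "-"
    return fwd_block, fwd_exons, "+"


def _build_region(rng, length: int, genes: list[tuple[str, str]], ssr_density: float,
                  offset: int, features: list, planted: list) -> str:
    blocks = [(_make_gene_block(rng, name, kind), name, kind) for name, kind in genes]
    gene_total = sum(len(b[0]) for b, _, _ in blocks)
    n_spacers = len(blocks) + 1
    spacer_total = length - gene_total
    if spacer_total < 60 * n_spacers:
        raise ValidationError(
            f"infeasible packing: {len(blocks)} genes need more than {length} bp"
        )
    base_len, rem = divmod(spacer_total, n_spacers)
    parts: list[str] = []
    pos = offset
    spacer_slots: list[tuple[int, int]] = []  # (start_in_region_string, length)
    cursor = 0
    for i, (blk, name, kind) in enumerate(blocks + [(None, None, None)]):
        sp_len = base_len + (1 if i < rem else 0)
        parts.append(_nonrepetitive_seq(rng, sp_len))
        spacer_slots.append((cursor, sp_len))
        cursor += sp_len
        if blk is None:
            break
        block_seq, exons, strand = blk
        features.append(Feature(
            name, "gene" if kind == "gene" else kind, strand,
            tuple((pos + cursor + a, pos + cursor + b) for a, b in exons),
        ))
        parts.append(block_seq)
        cursor += len(block_seq)
    region = list("".join(parts))
    assert len(region) == length
    if ssr_density > 0:
        n_tracts = int(round(ssr_density * spacer_total / 1000.0))
        # plant only inside spacers: restrict by retrying into the widest slots
        # (tract placement rejects positions outside spacer slots)
        tract_seq = region
        allowed = np.zeros(length, dtype=bool)
        for s, L in spacer_slots:
            if L > 40:
                allowed[s + 8:s + L - 8] = True
        _plant_tracts_masked(rng, tract_seq, n_tracts, offset, planted, allowed)
    return "".join(region)


def _plant_tracts_masked(rng, seq, n_tracts, offset, planted, allowed):
    used: list[tuple[int, int]] = []
    tries = 0
    while len(used) < n_tracts and tries < 1000 * max(n_tracts, 1):
        tries += 1
        if rng.random() < 0.8:
            base = BASES[rng.integers(4)]
            units = int(rng.integers(8, 15))
            tract = base * units
        else:
            a, b = rng.choice(4, size=2, replace=False)
            units = int(rng.integers(4, 8))
            tract = (BASES[a] + BASES[b]) * units
        span = len(tract) + 2
        p = int(rng.integers(5, len(seq) - span - 5))
        if not allowed[p:p + span].all():
            continue
        if any(p < e + 10 and s - 10 < p + span for s, e in used):
            continue
        left = [c for c in BASES if c != tract[0] and c != seq[p - 1]]
        right = [c for c in BASES if c != tract[-1] and c != seq[p + span]]
        if len(tract) >= 2 and tract[0] != tract[1]:
            left = [c for c in left if c != tract[1]]
            right = [c for c in right if c != tract[-2]]
        if not left or not right:
            continue
        seq[p] = left[rng.integers(len(left))]
        seq[p + 1:p + 1 + len(tract)] = list(tract)
        seq[p + 1 + len(tract)] = right[rng.integers(len(right))]
        used.append((p, p + span))
        motif = tract[0] if len(set(tract)) == 1 else tract[:2]
        planted.append({
            "motif": motif, "units": units,
            "start": offset + p + 1, "end": offset + p + 1 + len(tract),
        })
    if len(used) < n_tracts:
        raise ValidationError("could not place all SSR tracts; lower ssr_density")


def make_genome(
    seed: int,
    lsc: int = 20_000,
    ir: int = 4_000,
    ssc: int = 5_000,
    n_genes: int = 40,
    ssr_density: float = 1.2,
) -> AnnotatedGenome:
    """Random annotated quadripartite genome with exact IRs and planted SSRs.

    ssr_density is the expected number of planted microsatellite tracts per
    kb of single-copy spacer sequence. Planted tracts are recorded in
    metadata['planted_ssrs']; the constructed partition in
    metadata['true_partition'] and genome.partition.
    """
    if min(lsc, ir, ssc) < 1000:
        raise ValidationError("each region must be >= 1 kb")
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    names = _gene_names(rng, n_genes)
    kinds = ["gene" if rng.random() > 0.2 else "tRNA" for _ in names]
    genes = list(zip(names, kinds))
    # allocate genes across regions by length share (IR gets few)
    n_ir = max(1, round(0.08 * n_genes)) if n_genes >= 5 else 0
    rest = n_genes - n_ir
    n_lsc = max(1, round(rest * lsc / (lsc + ssc)))
    n_ssc = rest - n_lsc
    g_lsc, g_ssc, g_ir = genes[:n_lsc], genes[n_lsc:n_lsc + n_ssc], genes[n_lsc + n_ssc:]

    features: list[Feature] = []
    planted: list[dict] = []
    lsc_seq = _build_region(rng, lsc, g_lsc, ssr_density, 0, features, planted)
    irb_seq = _build_region(rng, ir, g_ir, 0.0, lsc, features, planted)
    ssc_seq = _build_region(rng, ssc, g_ssc, ssr_density, lsc + ir, features, planted)
    # prevent chance extension of the IR match across the SSC boundary
    if ssc_seq[0] == ssc_seq[-1].translate(COMP):
        alt = [b for b in BASES if b != ssc_seq[1] and b != ssc_seq[-1].translate(COMP)]
        ssc_seq = alt[rng.integers(len(alt))] + ssc_seq[1:]
    ira_seq = revcomp(irb_seq)
    n = lsc + 2 * ir + ssc
    # mirror IRb gene annotations into IRa (flipped strand, same names)
    ira_off = lsc + ir + ssc
    irb_end = lsc + ir
    for f in [f for f in features if lsc <= f.start < irb_end]:
        ivs = tuple(sorted(
            (ira_off + (irb_end - b), ira_off + (irb_end - a)) for a, b in f.intervals
        ))
        features.append(Feature(f.name, f.kind, "-" if f.strand == "+" else "+", ivs))
    seq = lsc_seq + irb_seq + ssc_seq + ira_seq
    assert len(seq) == n
    part = Partition(
        lsc=(0, lsc), irb=(lsc, lsc + ir),
        ssc=(lsc + ir, lsc + ir + ssc), ira=(lsc + ir + ssc, n),
    )
    genome = AnnotatedGenome(
        id=f"synthetic_{seed}",
        seq=seq,
        features=features + synthesize_exons_introns(features),
        partition=part,
        metadata={"planted_ssrs": planted, "true_partition": part},
    )
    part.validate(genome)
    return genome


# --------------------------------------------------------------------------
# Mutation
# --------------------------------------------------------------------------

def _exon_intervals(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    return sorted(iv for f in genome.features if f.kind == "exon" for iv in f.intervals)


def _allowed_zones(genome: AnnotatedGenome, margin: int = 100):
    part = genome.partition
    if part is None:
        from .io_genomes import detect_partition
        part = detect_partition(genome)
    zones = []
    for a, b in (part.lsc, part.ssc):
        if b - a > 2 * margin:
            zones.append((a + margin, b - margin))
    return zones


class _Placer:
    """Rejection sampler for event footprints with a minimum spacing."""

    def __init__(self, rng, zones, min_spacing):
        self.rng = rng
        self.zones = zones
        self.min_spacing = min_spacing
        self.taken: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> bool:
        pad = self.min_spacing
        if any(start < e + pad and s - pad < end for s, e in self.taken):
            return False
        self.taken.append((start, end))
        return True

    def sample(self, footprint: int, forbid, tries: int = 400) -> int:
        for _ in range(tries):
            zi = int(self.rng.integers(len(self.zones)))
            a, b = self.zones[zi]
            if b - a <= footprint:
                continue
            p = int(self.rng.integers(a, b - footprint))
            if forbid(p, p + footprint):
                continue
            pad = self.min_spacing
            if any(p < e + pad and s - pad < p + footprint for s, e in self.taken):
                continue
            self.taken.append((p, p + footprint))
            return p
        raise ValidationError(
            "cannot place events with the requested spacing; use fewer events "
            "or a larger genome"
        )


def _overlaps(pos_a, pos_b, intervals) -> bool:
    return any(pos_a < b and a < pos_b for a, b in intervals)


def mutate(genome: AnnotatedGenome, spectrum: MutationSpectrum):
    """Derive a mutated genome differing from the input by exactly the
    returned ledger's events; annotation and planted-SSR records are lifted
    over the indels. The input genome is the reference for polarity."""
    spectrum.validate()
    rng = np.random.default_rng(spectrum.seed)
    seq = genome.seq
    exons = _exon_intervals(genome)
    exons_pad = [(a - 5, b + 5) for a, b in exons]
    tracts = [(t["start"] - 3, t["end"] + 3) for t in genome.metadata.get("planted_ssrs", [])]
    placer = _Placer(rng, _allowed_zones(genome), spectrum.min_spacing)
    ledger = MutationLedger()
    edits: list[tuple[int, str, object]] = []  # (pos, kind, payload)

    # --- SSR slippage indels: expand/contract planted tracts -------------
    cands = [t for t in genome.metadata.get("planted_ssrs", [])
             if any(a <= t["start"] < b for a, b in placer.zones)]
    if len(cands) < spectrum.n_ssr_indels:
        raise ValidationError("not enough planted SSR tracts for requested SSR indels")
    order = rng.permutation(len(cands))
    chosen = 0
    for idx in order:
        if chosen == spectrum.n_ssr_indels:
            break
        t = cands[int(idx)]
        unit = t["motif"]
        d = int(rng.integers(1, 3))           # 1 or 2 units
        contract = bool(rng.integers(2))
        if contract and t["units"] - d < max(2, 3):
            contract = False
        if not placer.reserve(t["start"] - 2, t["end"] + 2):
            continue
        size = d * len(unit)
        motif = unit * d
        p = t["start"]
        if contract:
            edits.append((p, "del", size))
            polarity = "deletion"
        else:
            edits.append((p, "ins", motif))
            polarity = "insertion"
        ledger.events.append(LedgerEvent(
            "indel", p, -1, size, motif, polarity,
            expected={"ssr_type": "SSR", "unit": unit},
        ))
        chosen += 1
    if chosen < spectrum.n_ssr_indels:
        raise ValidationError("could not reserve enough SSR tracts; lower event counts")

    def forbid_indel(a, b):
        return _overlaps(a, b, exons_pad) or _overlaps(a, b, tracts)

    # --- micro-inversions ------------------------------------------------
    L = spectrum.inversion_len
    for _ in range(spectrum.n_inversions):
        for _try in range(400):
            p = placer.sample(L, forbid_indel)
            seg = seq[p:p + L]
            if seg[0] != seg[-1].translate(COMP) and revcomp(seg) != seg:
                break
            placer.taken.remove((p, p + L))
        else:
            raise ValidationError("could not place inversion")
        edits.append((p, "inv", seg))
        ledger.events.append(LedgerEvent(
            "inversion", p, -1, L, seg, "", expected={}
        ))

    # --- non-SSR indels ---------------------------------------------------
    sizes = [s for s, _ in spectrum.nonssr_size_dist]
    weights = [w for _, w in spectrum.nonssr_size_dist]
    for _ in range(spectrum.n_nonssr_indels):
        size = int(rng.choice(sizes, p=weights))
        insertion = bool(rng.integers(2))
        if insertion:
            for _try in range(400):
                p = placer.sample(1, forbid_indel)
                motif = _nonrepetitive_seq(rng, size)
                if motif[0] != seq[p] and motif[-1] != seq[p - 1]:
                    break
                placer.taken.remove((p, p + 1))
            else:
                raise ValidationError("could not place insertion")
            edits.append((p, "ins", motif))
            ledger.events.append(LedgerEvent(
                "indel", p, -1, size, motif, "insertion",
                expected={"ssr_type": "non-SSR"},
            ))
        else:
            for _try in range(400):
                p = placer.sample(size, forbid_indel)
                motif = seq[p:p + size]
                if seq[p] != seq[p + size] and seq[p - 1] != seq[p + size - 1] \
                        and "N" not in motif:
                    break
                placer.taken.remove((p, p + size))
            else:
                raise ValidationError("could not place deletion")
            edits.append((p, "del", size))
            ledger.events.append(LedgerEvent(
                "indel", p, -1, size, motif, "deletion",
                expected={"ssr_type": "non-SSR"},
            ))

    # --- SNPs -------------------------------------------------------------
    def forbid_snp(a, b):
        return _overlaps(a, b, tracts)

    for _ in range(spectrum.n_snps):
        p = placer.sample(1, forbid_snp)
        ref = seq[p]
        is_ts = rng.random() < spectrum.ts_fraction
        if is_ts:
            alt = TS_PARTNER[ref]
        else:
            tv = [b for b in BASES if b != ref and b != TS_PARTNER[ref]]
            alt = tv[int(rng.integers(2))]
        expected = {"kind": "Ts" if is_ts else "Tv"}
        ctx = locate(genome, p)
        if ctx.compartment == "exon":
            try:
                gene = genome.feature_by_name(ctx.label)
                if gene.kind == "gene":
                    from .coding import effect_of
                    from .events import SNP, gc_class, snp_kind
                    snp = SNP(ref, alt, -1, p, -1, snp_kind(ref, alt), gc_class(ref, alt))
                    expected["effect"] = effect_of(snp, genome, gene).effect
                    expected["gene"] = gene.name
            except KeyError:
                pass
        edits.append((p, "snp", alt))
        ledger.events.append(LedgerEvent("snp", p, -1, 1, alt, "", expected))

    # --- apply edits ------------------------------------------------------
    edits.sort(key=lambda e: e[0])
    out: list[str] = []
    cursor = 0
    delta_at: dict[int, int] = {}
    delta = 0
    for p, kind, payload in edits:
        out.append(seq[cursor:p])
        delta_at[p] = delta
        if kind == "snp":
            out.append(payload)
            cursor = p + 1
        elif kind == "inv":
            out.append(revcomp(payload))
            cursor = p + len(payload)
        elif kind == "ins":
            out.append(payload)
            out.append(seq[p])
            cursor = p + 1
            delta += len(payload)
        elif kind == "del":
            cursor = p + payload
            delta -= payload
    out.append(seq[cursor:])
    mut_seq = "".join(out)

    indel_edits = sorted(
        (p, len(payload) if kind == "ins" else -payload)
        for p, kind, payload in edits if kind in ("ins", "del")
    )

    def lift(x: int, is_end: bool = False) -> int:
        d = 0
        for p, dd in indel_edits:
            if dd > 0:  # insertion before position p
                if p < x or (p == x and not is_end):
                    d += dd
            else:
                p_end = p - dd
                if x >= p_end:
                    d += dd
                elif x > p:
                    return p + d  # inside the deletion: collapse to junction
        return x + d

    for ev in ledger.events:
        ev.alt_pos = ev.ref_pos + delta_at[ev.ref_pos]

    lifted_genes = []
    for f in genome.genes:
        ivs = tuple((lift(a), lift(b, is_end=True)) for a, b in f.intervals)
        lifted_genes.append(Feature(f.name, f.kind, f.strand, ivs))
    lifted_planted = []
    for t in genome.metadata.get("planted_ssrs", []):
        # anchor on the left guard base so a slippage insertion at the tract
        # start stays inside the lifted tract
        start = lift(t["start"] - 1) + 1
        end = lift(t["end"], is_end=True)
        lifted_planted.append({
            "motif": t["motif"],
            "units": (end - start) // len(t["motif"]),
            "start": start,
            "end": end,
        })
    mutated = AnnotatedGenome(
        id=f"{genome.id}_mut",
        seq=mut_seq,
        features=lifted_genes + synthesize_exons_introns(lifted_genes),
        metadata={"planted_ssrs": lifted_planted},
    )
    ledger.events.sort(key=lambda e: e.ref_pos)
    return mutated, ledger


# --------------------------------------------------------------------------
# Recovery scoring
# --------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    per_type: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.per_type)

    def perfect(self) -> bool:
        return all(
            v["precision"] == 1.0 and v["recall"] == 1.0
            for v in self.per_type.values()
        )


def _match_positions(called: list[int], truth: list[int], tol: int):
    called = sorted(called)
    truth = sorted(truth)
    used = [False] * len(truth)
    tp = 0
    for c in called:
        for i, t in enumerate(truth):
            if not used[i] and abs(c - t) <= tol:
                used[i] = True
                tp += 1
                break
    return tp


def score_recovery(snps, indels, inversions, ledger: MutationLedger,
                   tol: int = 2) -> RecoveryReport:
    """Per-type precision/recall of called events against the ground truth,
    matching by reference position within +/- tol bp. With no calls for a
    type, precision is reported as 1.0 with a 'no_calls' flag."""
    report = RecoveryReport()
    groups = {
        "snp": [s.ref_pos for s in snps],
        "indel": [i.ref_pos for i in indels],
        "inversion": [v.ref_pos for v in inversions],
    }
    for kind, called in groups.items():
        truth = [e.ref_pos for e in ledger.by_type(kind)]
        tp = _match_positions(called, truth, tol)
        fp = len(called) - tp
        fn = len(truth) - tp
        precision = tp / len(called) if called else 1.0
        recall = tp / len(truth) if truth else 1.0
        report.per_type[kind] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall,
            "n_called": len(called), "n_truth": len(truth),
            "no_calls": not called,
        }
    return report
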