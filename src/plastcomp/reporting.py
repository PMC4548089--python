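"""End-to-end orchestration: configuration, the compare/simulate pipelines,
and deterministic report writing.

`compare_pair` is the library entry point (objects in, results out);
`run_compare` / `run_simulate` wrap it with file I/O for the CLI. Output
floats use fixed precision (Pi to 5 decimals, percentages to 2) so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._util import PlastcompError, ValidationError
from .alignment import (
    PairwiseAlignment,
    Scoring,
    align_pair,
    build_map,
    read_alignment,
    write_alignment,
)
from .coding import effect_of, gene_table, load_category_map, write_gene_table_tsv
from .diversity import call_hotspots, window_pi, write_hotspots, write_profile_tsv
from .events import (
    call_indels,
    call_snps,
    detect_inversions,
    summarize,
    write_indels_tsv,
    write_snps_tsv,
    write_snps_vcf,
    write_summary_json,
)
from .io_genomes import (
    AnnotatedGenome,
    detect_partition,
    genome_summary,
    read_genome,
    write_annotation_tsv,
    write_fasta,
    write_partition_bed,
)
from .ssr import find_ssrs, pair_ssrs, write_ssr_tsv
from .synthetic import MutationSpectrum, make_genome, mutate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    input_format: str = "genbank"
    annotation_tables: list | None = None
    reference: str | None = None          # id of the reference input (default: first)
    alignment_file: str | None = None     # external alignment; None = internal aligner
    alignment_format: str = "fasta"
    scoring: Scoring = field(default_factory=Scoring)
    mono_min: int = 8
    di_min: int = 4
    window_len: int = 600
    step: int = 200
    hotspot_threshold: float = 0.008
    min_inv_len: int = 3
    max_inv_len: int = 50
    min_mismatches: int = 2
    category_map: str | None = None
    coding_includes_rna: bool = False
    min_ir_len: int = 1000
    outdir: str = "plastcomp_out"
    seed: int = 0
    spectrum: MutationSpectrum | None = None
    genome_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.reference is not None and self.inputs:
            stems = [Path(p).stem for p in self.inputs]
            if self.reference not in stems and self.reference not in self.inputs:
                raise ValidationError(
                    f"reference {self.reference!r} does not name one of the inputs"
                )
        for name in ("mono_min", "di_min", "window_len", "step"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.hotspot_threshold <= 0:
            raise ValidationError("hotspot_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scoring" in raw:
            raw["scoring"] = Scoring(**raw["scoring"])
        if "spectrum" in raw:
            raw["spectrum"] = MutationSpectrum(**raw["spectrum"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class CompareResult:
    """In-memory bundle of everything the comparison computes."""

    ref: AnnotatedGenome
    alt: AnnotatedGenome
    aln: PairwiseAlignment
    amap: object
    ssrs: dict
    ssr_pairs: list
    snps: list
    indels: list
    inversions: list
    summary: object
    scored_coding: list
    gene_table: object
    coding_split: dict
    profile: object
    hotspots: list


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PlastcompError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def compare_pair(
    ref: AnnotatedGenome,
    alt: AnnotatedGenome,
    aln: PairwiseAlignment | None = None,
    config: RunConfig | None = None,
) -> CompareResult:
    """Full pairwise comparison of two annotated genomes.

    Detects partitions if absent, aligns (internal aligner) unless an
    alignment is supplied, then runs SSR scanning, inversion/indel/SNP
    calling, coding-effect classification, the event summary and the
    sliding-window diversity profile with hotspot calls.
    """
    cfg = config or RunConfig()
    for g in (ref, alt):
        if g.partition is None:
            try:
                g.partition = detect_partition(g, cfg.min_ir_len)
            except PlastcompError as exc:
                log.warning("%s: %s (region labels unavailable)", g.id, exc)
    if aln is None:
        aln = align_pair(ref.seq, alt.seq, cfg.scoring, names=(ref.id, alt.id))
    else:
        if aln.ungapped(aln.reference_index) != ref.seq:
            raise ValidationError(
                "external alignment reference row does not reproduce the reference sequence"
            )
    amap = build_map(aln)
    ssrs = {
        0: find_ssrs(ref, cfg.mono_min, cfg.di_min),
        1: find_ssrs(alt, cfg.mono_min, cfg.di_min),
    }
    ssr_rows = pair_ssrs(ssrs[0], ssrs[1], amap)
    inversions, consumed = detect_inversions(
        aln, amap, ref, cfg.min_inv_len, cfg.max_inv_len, cfg.min_mismatches
    )
    indels = call_indels(aln, amap, ref, ssrs, consumed=consumed)
    snps = call_snps(aln, amap, ref, consumed=consumed)
    summary = summarize(snps, indels, inversions, ref.partition)

    cmap = load_category_map(cfg.category_map)
    scored = []
    n_coding = 0
    for s in snps:
        if s.context is None or s.context.compartment != "exon":
            continue
        try:
            gene = ref.feature_by_name(s.context.label)
        except KeyError:
            continue
        if gene.kind == "gene":
            n_coding += 1
            scored.append((s, effect_of(s, ref, gene)))
        elif cfg.coding_includes_rna:
            n_coding += 1
    table = gene_table(scored, cmap)
    coding_split = {
        "coding_snps": n_coding,
        "noncoding_snps": len(snps) - n_coding,
    }
    profile = window_pi(aln, cfg.window_len, cfg.step)
    hotspots = call_hotspots(profile, cfg.hotspot_threshold, amap, ref)
    return CompareResult(
        ref, alt, aln, amap, ssrs, ssr_rows, snps, indels, inversions,
        summary, scored, table, coding_split, profile, hotspots,
    )


def _write_ssr_pair_tsv(rows, ref_id, alt_id, path):
    with open(path, "w") as fh:
        fh.write(f"label\tregion\tcompartment\tmotif\tunits_{ref_id}\tunits_{alt_id}\n")
        for r in rows:
            ctx = r["context"]
            lab = (ctx.label, ctx.region, ctx.compartment) if ctx else ("", "", "")
            ru = "" if r["ref_units"] is None else r["ref_units"]
            au = "" if r["alt_units"] is None else r["alt_units"]
            fh.write(f"{lab[0]}\t{lab[1]}\t{lab[2]}\t{r['motif']}\t{ru}\t{au}\n")


def run_compare(config: RunConfig) -> dict:
    """Read inputs, run the comparison, write the report bundle.

    On any stage error, partial outputs are removed and the error is
    re-raised with the stage name. Returns the summary dict.
    """
    config.validate()
    if len(config.inputs) < 2:
        raise ValidationError("compare needs >= 2 input genomes")
    tables = config.annotation_tables or [None] * len(config.inputs)
    genomes = [
        read_genome(p, config.input_format, t)
        for p, t in zip(config.inputs, tables)
    ]
    ref_idx = 0
    if config.reference is not None:
        stems = [Path(p).stem for p in config.inputs]
        ids = [g.id for g in genomes]
        for i, (s, gid, p) in enumerate(zip(stems, ids, config.inputs)):
            if config.reference in (s, gid, p):
                ref_idx = i
                break
    genomes.insert(0, genomes.pop(ref_idx))

    aln = None
    if config.alignment_file:
        aln = read_alignment(config.alignment_file, config.alignment_format)
        # reorder rows so the reference genome is row 0
        order = []
        for g in genomes:
            matches = [i for i, n in enumerate(aln.names) if n == g.id]
            if not matches:
                raise ValidationError(
                    f"alignment has no row named {g.id!r}"
                )
            order.append(matches[0])
        aln = PairwiseAlignment(
            [aln.names[i] for i in order], [aln.rows[i] for i in order], 0
        )
    elif len(genomes) > 2:
        raise ValidationError(
            "the internal aligner is pairwise; supply an external alignment "
            "for 3-way comparisons"
        )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        result = compare_pair(genomes[0], genomes[1], aln, config)
        ref, alt = result.ref, result.alt
        write_alignment(result.aln, out("alignment.fasta"))
        for g in (ref, alt):
            if g.partition is not None:
                write_partition_bed(g, out(f"partition_{g.id}.bed"))
        write_ssr_tsv(result.ssrs[0], out(f"ssr_{ref.id}.tsv"))
        write_ssr_tsv(result.ssrs[1], out(f"ssr_{alt.id}.tsv"))
        _write_ssr_pair_tsv(result.ssr_pairs, ref.id, alt.id, out("ssr_paired.tsv"))
        write_indels_tsv(result.indels, result.inversions, out("indels.tsv"))
        write_snps_tsv(result.snps, out("snps.tsv"))
        write_snps_vcf(result.snps, ref.id, alt.id, out("snps.vcf"))
        write_gene_table_tsv(result.gene_table, out("gene_table.tsv"))
        write_profile_tsv(result.profile, out("diversity.tsv"), result.amap)
        write_hotspots(result.hotspots, ref.id, out("hotspots.bed"), out("hotspots.tsv"))
        summary_doc = {
            "genomes": [genome_summary(g) for g in (ref, alt)],
            "coding_split": result.coding_split,
            "pi": {
                "mean": round(result.profile.mean_pi(), 5),
                "max": round(result.profile.max_pi(), 5),
                "n_windows": len(result.profile.windows),
            },
            "n_hotspots": len(result.hotspots),
            "parameters": {
                "mono_min": config.mono_min,
                "di_min": config.di_min,
                "window_len": config.window_len,
                "step": config.step,
                "hotspot_threshold": config.hotspot_threshold,
            },
        }
        write_summary_json(result.summary, out("summary.json"), extra=summary_doc)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    with open(outdir / "summary.json") as fh:
        return json.load(fh)


def run_simulate(config: RunConfig) -> dict:
    """Generate a genome pair + ledger into the output directory."""
    params = dict(config.genome_params)
    genome = make_genome(config.seed, **params)
    spectrum = config.spectrum or MutationSpectrum(seed=config.seed)
    mutated, ledger = mutate(genome, spectrum)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / f"{genome.id}.fasta")
    write_fasta(mutated, outdir / f"{mutated.id}.fasta")
    write_annotation_tsv(genome, outdir / f"{genome.id}.annotation.tsv")
    write_annotation_tsv(mutated, outdir / f"{mutated.id}.annotation.tsv")
    ledger.to_json(outdir / "ledger.json")
    return {
        "reference": genome.id,
        "mutated": mutated.id,
        "ledger_counts": ledger.counts(),
    }
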