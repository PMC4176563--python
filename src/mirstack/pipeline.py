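"""Configuration-driven pipeline: preprocess -> quantify -> discover -> classify.

The pipeline is a thin, deterministic orchestration of the library
modules.  A YAML run configuration (flat keys grouped into sections; see
:data:`CONFIG_SCHEMA`) names the references, one FASTQ per sample, and
every tunable threshold.  Outputs are plain TSV/GFF3/FASTA files plus a
machine-readable JSON manifest with per-stage read accounting; reruns
with an identical configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .preprocess import (FilterRuleSet, FilterReport, UniqueTag, read_fastq,
                         run_preprocess, write_collapsed_fasta,
                         write_filter_report)
from .align_quant import (ExpressionRecord, build_expression_matrix,
                          build_index, align_tags, count_known_mirnas,
                          partition_tags, read_fasta, read_mirna_gff3,
                          rpm_normalize, GenomicInterval, MiRNAAnnotation)
from .novel_discovery import (NovelCall, RuleThresholds, ScoreWeights,
                              cluster_stacks, consensus_and_name,
                              evaluate_window, excise_windows,
                              write_novel_gff3, write_structures)
from .expression_patterns import (PatternConfig, call_expressed,
                                  classify_matrix, venn_partition)

logger = logging.getLogger("mirstack")

__all__ = [
    "RunConfig",
    "CONFIG_SCHEMA",
    "validate_config",
    "run_known_pipeline",
    "run_novel_pipeline",
    "run_classify",
    "run_all",
]

#: section -> {key: default}; ``...`` marks a required key.
CONFIG_SCHEMA = {
    "paths": {
        "genome_fasta": ...,
        "mrna_fasta": ...,
        "mirna_fasta": ...,
        "mirna_gff3": ...,
        "samples": ...,  # mapping: sample label -> FASTQ path
    },
    "filter": {
        "adapter3": ...,
        "adapter5": None,
        "min_adapter_flank": 6,
        "max_adapter_flank": 18,
        "polya_min_run": 8,
        "max_ambiguous": 0,
        "min_len": 18,
        "max_len": 26,
        "max_adapter_mismatch": 0,
    },
    "alignment": {
        "max_mismatch": 0,
        "seed_k": 9,
        "rpm_scale": 1e9,
        "count_window_up": 2,
        "count_window_down": 5,
    },
    "discovery": {
        "max_gap": 30,
        "down_ext": 70,
        "up_ext": 15,
        "min_window": 40,
        "w_mature": 2.0,
        "w_consistent": 4.0,
        "w_fold": 10.0,
        "w_star": 3.0,
        "w_inconsistent": 6.0,
        "score_threshold": 5.0,
        "mature_min_len": 18,
        "mature_max_len": 26,
        "min_stem": 14,
        "min_loop": 3,
        "max_loop": 20,
        "min_fold_density": 0.25,
        "min_mature_count": 5,
        "max_inconsistent_fraction": 0.2,
        "max_loop_overlap": 2,
        "min_reciprocal_overlap": 0.5,
    },
    "patterns": {
        "expr_threshold": 100.0,
        "fc": 1.5,
        "cell_order": None,  # defaults to the sample labels in order
        "pseudocount": 1.0,
    },
    "run": {
        "output_dir": ...,
        "seed": 1,
        "log_level": "INFO",
    },
}


@dataclass
class RunConfig:
    """A fully validated, fully defaulted run configuration."""

    genome_fasta: Path
    mrna_fasta: Path
    mirna_fasta: Path
    mirna_gff3: Path
    samples: dict
    rules: FilterRuleSet
    output_dir: Path
    max_mismatch: int = 0
    seed_k: int = 9
    rpm_scale: float = 1e9
    count_window_up: int = 2
    count_window_down: int = 5
    max_gap: int = 30
    down_ext: int = 70
    up_ext: int = 15
    min_window: int = 40
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    min_reciprocal_overlap: float = 0.5
    patterns: PatternConfig = field(default_factory=PatternConfig)
    seed: int = 1
    log_level: str = "INFO"


def validate_config(source) -> tuple[Optional[RunConfig], list[str]]:
    """Validate a YAML file (or pre-parsed dict) against the schema.

    Returns ``(config, errors)``; ``config`` is ``None`` when errors were
    found.  Every unknown key is an error (nothing is silently ignored),
    as is every missing required key, dangling path or contradictory
    bound.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["configuration must be a mapping of sections"]

    for section in raw:
        if section not in CONFIG_SCHEMA:
            errors.append(f"unknown section {section!r}")
    merged: dict[str, dict] = {}
    for section, schema in CONFIG_SCHEMA.items():
        given = raw.get(section, {})
        if given is None:
            given = {}
        if not isinstance(given, dict):
            errors.append(f"section {section!r} must be a mapping")
            given = {}
        for key in given:
            if key not in schema:
                errors.append(f"unknown key {section}.{key!r}")
        out = {}
        for key, default in schema.items():
            if key in given:
                out[key] = given[key]
            elif default is ...:
                errors.append(f"missing required key {section}.{key!r}")
            else:
                out[key] = default
        merged[section] = out
    if errors:
        return None, errors

    paths = merged["paths"]
    samples = paths["samples"]
    if not isinstance(samples, dict) or not samples:
        errors.append("paths.samples must be a non-empty mapping label -> FASTQ")
        samples = {}
    if len(set(samples)) != len(samples):
        errors.append("sample labels must be unique")
    for role in ("genome_fasta", "mrna_fasta", "mirna_fasta", "mirna_gff3"):
        if not Path(paths[role]).exists():
            errors.append(f"paths.{role}: no such file {paths[role]!r}")
    for label, fq in samples.items():
        if not Path(fq).exists():
            errors.append(f"paths.samples.{label}: no such file {fq!r}")

    try:
        rules = FilterRuleSet(**merged["filter"])
    except (TypeError, ValueError) as err:
        errors.append(f"filter: {err}")
        rules = None

    d = merged["discovery"]
    weights = ScoreWeights(w_mature=d["w_mature"], w_consistent=d["w_consistent"],
                           w_fold=d["w_fold"], w_star=d["w_star"],
                           w_inconsistent=d["w_inconsistent"],
                           threshold=d["score_threshold"])
    thresholds = RuleThresholds(
        mature_min_len=d["mature_min_len"], mature_max_len=d["mature_max_len"],
        min_stem=d["min_stem"], min_loop=d["min_loop"], max_loop=d["max_loop"],
        min_fold_density=d["min_fold_density"],
        min_mature_count=d["min_mature_count"],
        max_inconsistent_fraction=d["max_inconsistent_fraction"],
        max_loop_overlap=d["max_loop_overlap"])

    p = dict(merged["patterns"])
    if p["cell_order"] is None:
        p["cell_order"] = list(samples)
    try:
        patterns = PatternConfig(expr_threshold=p["expr_threshold"], fc=p["fc"],
                                 cell_order=tuple(p["cell_order"]),
                                 pseudocount=p["pseudocount"])
        if not set(patterns.cell_order) <= set(samples):
            errors.append("patterns.cell_order must be a subset of sample labels")
    except ValueError as err:
        errors.append(f"patterns: {err}")
        patterns = None

    a = merged["alignment"]
    if a["max_mismatch"] not in (0, 1):
        errors.append("alignment.max_mismatch must be 0 or 1")
    r = merged["run"]
    if errors:
        return None, errors
    cfg = RunConfig(
        genome_fasta=Path(paths["genome_fasta"]),
        mrna_fasta=Path(paths["mrna_fasta"]),
        mirna_fasta=Path(paths["mirna_fasta"]),
        mirna_gff3=Path(paths["mirna_gff3"]),
        samples={k: Path(v) for k, v in samples.items()},
        rules=rules,
        output_dir=Path(r["output_dir"]),
        max_mismatch=a["max_mismatch"],
        seed_k=a["seed_k"],
        rpm_scale=float(a["rpm_scale"]),
        count_window_up=a["count_window_up"],
        count_window_down=a["count_window_down"],
        max_gap=d["max_gap"],
        down_ext=d["down_ext"],
        up_ext=d["up_ext"],
        min_window=d["min_window"],
        weights=weights,
        thresholds=thresholds,
        min_reciprocal_overlap=d["min_reciprocal_overlap"],
        patterns=patterns,
        seed=r["seed"],
        log_level=r["log_level"],
    )
    return cfg, []


def _atomic_write(path: Path, writer) -> None:
    """Write via ``writer(tmp_path)`` then atomically rename into place."""
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


@dataclass
class SampleResult:
    """Per-sample intermediate state shared between pipeline stages."""

    label: str
    report: FilterReport
    tags: list
    tag_counts: dict
    partition: object
    genome_hits: list
    unannotated_hits: list
    mapped_reads: int          # N: read mass of genome-mapped tags
    raw_counts: dict           # mature miRNA -> 1/M-weighted C


@dataclass
class KnownResult:
    samples: dict
    annotations: list
    counts_matrix: object
    rpm_matrix: object
    manifest: dict


def _setup_logging(cfg: RunConfig) -> None:
    level = getattr(logging, str(cfg.log_level).upper(), logging.INFO)
    logger.setLevel(level)
    if not logger.handlers:
        fmt = logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s")
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(cfg.output_dir / "run.log")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def run_known_pipeline(cfg: RunConfig) -> KnownResult:
    """Filter, collapse, partition and quantify known miRNAs per sample.

    Writes per-sample filter reports and collapsed-tag FASTA, the raw
    count and RPM matrices, and records a per-stage read-accounting chain
    in the manifest.  Counting uses fractional 1/M allocation across
    miRNA-region placements, so RPM normalisation is applied with M=1
    (allocating twice would double-discount multi-mappers).
    """
    _setup_logging(cfg)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(cfg.genome_fasta)
    genome_index = build_index(genome, k=cfg.seed_k, name="genome")
    mrna_index = build_index(read_fasta(cfg.mrna_fasta), k=cfg.seed_k,
                             name="mrna")
    mirna_index = build_index(read_fasta(cfg.mirna_fasta), k=cfg.seed_k,
                              name="mirna")
    annotations = read_mirna_gff3(cfg.mirna_gff3)
    ref_lengths = {c: len(s) for c, s in genome.items()}
    mature_names = sorted(n for a in annotations for n, _ in a.matures)

    manifest = {
        "tool": "mirstack",
        "version": __version__,
        "seed": cfg.seed,
        "settings": {
            "max_mismatch": cfg.max_mismatch,
            "seed_k": cfg.seed_k,
            "rpm_scale": cfg.rpm_scale,
            "filter_order": ["adapter5", "no_adapter3", "ambiguous",
                             "polya", "length"],
        },
        "samples": {},
    }
    samples: dict[str, SampleResult] = {}
    records: list[ExpressionRecord] = []
    count_records: list[ExpressionRecord] = []

    for label, fastq in cfg.samples.items():
        logger.info("sample %s: preprocessing %s", label, fastq)
        tags, report = run_preprocess(read_fastq(fastq), cfg.rules)
        if report.input_reads == 0:
            logger.warning("sample %s: empty FASTQ", label)
        _atomic_write(out / f"{label}.tags.fa",
                      lambda p, t=tags: write_collapsed_fasta(t, p))
        _atomic_write(out / f"{label}.filter_report.tsv",
                      lambda p, r=report: write_filter_report(r, p))
        tag_counts = {t.tag_id: t.count for t in tags}

        partition = partition_tags(tags, mrna_index, mirna_index,
                                   cfg.max_mismatch)
        genome_tags = [t for t in tags
                       if t.tag_id not in set(partition.mrna_tags)]
        hits = align_tags(genome_tags, genome_index, cfg.max_mismatch)
        mapped_ids = {h.tag_id for h in hits}
        mapped_reads = sum(tag_counts[t] for t in mapped_ids)
        unannot = set(partition.unannotated_tags)
        unannotated_hits = [h for h in hits if h.tag_id in unannot]

        raw = count_known_mirnas(hits, annotations, tag_counts,
                                 upstream=cfg.count_window_up,
                                 downstream=cfg.count_window_down,
                                 reference_lengths=ref_lengths)
        for name in mature_names:
            c = raw.get(name, 0.0)
            rpm = (rpm_normalize(c, 1, mapped_reads, cfg.rpm_scale)
                   if mapped_reads > 0 else 0.0)
            records.append(ExpressionRecord(name, c, rpm, label))
            count_records.append(ExpressionRecord(name, c, c, label))

        samples[label] = SampleResult(
            label=label, report=report, tags=tags, tag_counts=tag_counts,
            partition=partition, genome_hits=hits,
            unannotated_hits=unannotated_hits, mapped_reads=mapped_reads,
            raw_counts=raw)

        mass = {
            "known_mirna": sum(tag_counts[t] for t in partition.known_mirna_tags),
            "mrna": sum(tag_counts[t] for t in partition.mrna_tags),
            "unannotated": sum(tag_counts[t] for t in partition.unannotated_tags),
        }
        manifest["samples"][label] = {
            "fastq": str(fastq),
            "input_reads": report.input_reads,
            "discarded_by_rule": dict(report.discarded_by_rule),
            "kept_reads": report.kept_reads,
            "unique_tags": len(tags),
            "tag_read_mass": sum(tag_counts.values()),
            "partition_tags": {
                "known_mirna": len(partition.known_mirna_tags),
                "mrna": len(partition.mrna_tags),
                "unannotated": len(partition.unannotated_tags),
            },
            "partition_read_mass": mass,
            "genome_mapped_reads": mapped_reads,
            "mirna_assigned_mass": float(sum(raw.values())),
        }

    sample_order = list(cfg.samples)
    counts_matrix = build_expression_matrix(count_records, value="raw_count",
                                            sample_order=sample_order)
    rpm_matrix = build_expression_matrix(records, value="rpm",
                                         sample_order=sample_order)
    _atomic_write(out / "known_counts.tsv",
                  lambda p: counts_matrix.to_csv(p, sep="\t",
                                                 float_format="%.6g"))
    _atomic_write(out / "known_rpm.tsv",
                  lambda p: rpm_matrix.to_csv(p, sep="\t",
                                              float_format="%.6g"))
    result = KnownResult(samples=samples, annotations=annotations,
                         counts_matrix=counts_matrix, rpm_matrix=rpm_matrix,
                         manifest=manifest)
    _write_manifest(cfg, manifest)
    return result


def check_conservation(result: KnownResult, cfg: RunConfig) -> None:
    """Audit the manifest read chain; raises AssertionError on violation.

    Checks, exactly: input reads = kept + sum(discarded); collapsed tag
    mass = kept reads; and (recomputed with rational arithmetic) the
    1/M-weighted miRNA-assigned mass equals the read mass of tags with at
    least one miRNA-window placement.
    """
    for label, s in result.samples.items():
        m = result.manifest["samples"][label]
        assert (m["input_reads"] == m["kept_reads"]
                + sum(m["discarded_by_rule"].values())), label
        assert m["tag_read_mass"] == m["kept_reads"], label
        exact = count_known_mirnas(s.genome_hits, result.annotations,
                                   s.tag_counts,
                                   upstream=cfg.count_window_up,
                                   downstream=cfg.count_window_down,
                                   exact=True)
        assigned = sum(v for v in exact.values() if v)
        contributing = _mirna_assigned_tag_mass(s, result.annotations, cfg)
        assert assigned == contributing, (
            f"{label}: weighted miRNA mass {assigned} != "
            f"assigned tag mass {contributing}")


def _mirna_assigned_tag_mass(s: SampleResult, annotations, cfg) -> Fraction:
    windows = []
    for ann in annotations:
        for name, iv in ann.matures:
            windows.append(GenomicInterval(
                iv.chrom, max(0, iv.start - cfg.count_window_up),
                iv.end + cfg.count_window_down, iv.strand))
    by_tag: dict[str, list] = {}
    for h in s.genome_hits:
        by_tag.setdefault(h.tag_id, []).append(h)
    total = Fraction(0)
    for tag_id, placements in by_tag.items():
        if any(w.strand == h.interval.strand and w.contains(h.interval)
               for h in placements for w in windows):
            total += s.tag_counts[tag_id]
    return total


@dataclass
class NovelResult:
    calls: list                # every evaluated candidate window
    named: list                # consensus calls with miR-N names
    rpm_matrix: object
    manifest_steps: dict


def run_novel_pipeline(cfg: RunConfig, known: KnownResult) -> NovelResult:
    """Discover consensus novel miRNAs from pooled unannotated tags.

    Unannotated tag sequences are pooled across samples (counts summed),
    re-aligned to the genome, clustered into stacks, excised and folded;
    both predictors run on every window, and consensus calls are merged
    and named in genome order.  Per-sample expression of the named novel
    miRNAs is then quantified exactly like known miRNAs.
    """
    _setup_logging(cfg)
    out = cfg.output_dir
    genome = read_fasta(cfg.genome_fasta)
    genome_index = build_index(genome, k=cfg.seed_k, name="genome")

    pooled: dict[str, int] = {}
    for s in known.samples.values():
        unannot = set(s.partition.unannotated_tags)
        for t in s.tags:
            if t.tag_id in unannot:
                pooled[t.sequence] = pooled.get(t.sequence, 0) + t.count
    ordered = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    pooled_tags = [UniqueTag(f"n{i + 1}", seq, c)
                   for i, (seq, c) in enumerate(ordered)]
    tag_counts = {t.tag_id: t.count for t in pooled_tags}

    hits = (align_tags(pooled_tags, genome_index, cfg.max_mismatch)
            if pooled_tags else [])
    stacks = cluster_stacks(hits, tag_counts, cfg.max_gap)
    calls: list[NovelCall] = []
    n_windows = 0
    for stack in stacks:
        for locus, seq, arm in excise_windows(genome, stack,
                                              down_ext=cfg.down_ext,
                                              up_ext=cfg.up_ext,
                                              min_window=cfg.min_window):
            n_windows += 1
            calls.append(evaluate_window(stack, locus, seq,
                                         weights=cfg.weights,
                                         rules=cfg.thresholds))
    named = consensus_and_name(calls, cfg.min_reciprocal_overlap)
    logger.info("novel discovery: %d stacks, %d windows, %d consensus calls",
                len(stacks), n_windows, len(named))

    _atomic_write(out / "novel_calls.gff3",
                  lambda p: write_novel_gff3(named, p))
    _atomic_write(out / "novel_structures.txt",
                  lambda p: write_structures(named, p))
    _atomic_write(out / "novel_report.tsv",
                  lambda p: _write_novel_report(calls, p))

    # per-sample expression of named novel miRNAs
    novel_annotations = []
    for call in named:
        c = call.candidate
        matures = [(f"{call.name}-{c.mature_arm}", c.mature_interval)]
        if c.star_interval is not None and c.locus.contains(c.star_interval):
            other = "3p" if c.mature_arm == "5p" else "5p"
            matures.append((f"{call.name}-{other}", c.star_interval))
        novel_annotations.append(MiRNAAnnotation(
            precursor_name=call.name, precursor=c.locus, matures=matures))
    records = []
    for label, s in known.samples.items():
        raw = count_known_mirnas(s.unannotated_hits, novel_annotations,
                                 s.tag_counts,
                                 upstream=cfg.count_window_up,
                                 downstream=cfg.count_window_down)
        for name, c in raw.items():
            rpm = (rpm_normalize(c, 1, s.mapped_reads, cfg.rpm_scale)
                   if s.mapped_reads > 0 else 0.0)
            records.append(ExpressionRecord(name, c, rpm, label))
    rpm_matrix = build_expression_matrix(records, value="rpm",
                                         sample_order=list(cfg.samples))
    _atomic_write(out / "novel_rpm.tsv",
                  lambda p: rpm_matrix.to_csv(p, sep="\t",
                                              float_format="%.6g"))

    steps = {
        "pooled_unannotated_tags": len(pooled_tags),
        "genome_mapped_tags": len({h.tag_id for h in hits}),
        "read_stacks": len(stacks),
        "excised_windows": n_windows,
        "passA": sum(1 for c in calls if c.passA),
        "passB": sum(1 for c in calls if c.passB),
        "consensus": sum(1 for c in calls if c.passA and c.passB),
        "named_calls": len(named),
    }
    known.manifest["novel_discovery"] = steps
    _write_manifest(cfg, known.manifest)
    return NovelResult(calls=calls, named=named, rpm_matrix=rpm_matrix,
                       manifest_steps=steps)


def _write_novel_report(calls, path) -> None:
    cols = ["chrom", "start", "end", "strand", "arm", "mature_count",
            "star_count", "loop_count", "inconsistent_count", "fold_score",
            "longest_stem", "loop_size", "scoreA", "passA", "passB",
            "consensus", "name"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        ordered = sorted(calls, key=lambda c: (c.candidate.locus, -c.scoreA))
        for c in ordered:
            iv = c.candidate.locus
            fh.write("\t".join(str(v) for v in [
                iv.chrom, iv.start, iv.end, iv.strand,
                c.candidate.mature_arm, c.candidate.mature_count,
                c.candidate.star_count, c.candidate.loop_count,
                c.candidate.inconsistent_count, c.candidate.fold.score,
                c.candidate.fold.longest_stem, c.candidate.fold.loop_size,
                f"{c.scoreA:.4f}", c.passA, c.passB,
                c.passA and c.passB, c.name or "."]) + "\n")


def run_classify(cfg: RunConfig, known: KnownResult,
                 novel: Optional[NovelResult] = None) -> dict:
    """Expression calls, pattern classes and Venn partitions; writes TSVs."""
    _setup_logging(cfg)
    out = cfg.output_dir
    results = {}
    matrix = known.rpm_matrix
    patterns = classify_matrix(matrix, cfg.patterns) if len(matrix) else None
    if patterns is not None:
        _atomic_write(out / "known_patterns.tsv",
                      lambda p: patterns.to_csv(p, sep="\t",
                                                float_format="%.6g"))
    expressed = call_expressed(matrix[list(cfg.patterns.cell_order)],
                               cfg.patterns) if len(matrix) else None
    results["patterns"] = patterns
    results["expressed"] = expressed
    if expressed is not None:
        venn = venn_partition(expressed)
        results["venn_known"] = venn
        _atomic_write(out / "known_venn.tsv",
                      lambda p: _write_venn(venn, p))
    if novel is not None and len(novel.rpm_matrix):
        nov_expressed = call_expressed(
            novel.rpm_matrix[list(cfg.patterns.cell_order)], cfg.patterns)
        venn_n = venn_partition(nov_expressed)
        results["venn_novel"] = venn_n
        _atomic_write(out / "novel_venn.tsv",
                      lambda p: _write_venn(venn_n, p))
    return results


def _write_venn(venn: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcount\tmembers\n")
        for region, members in venn.items():
            fh.write(f"{region}\t{len(members)}\t{','.join(map(str, members))}\n")


def _write_manifest(cfg: RunConfig, manifest: dict) -> None:
    path = cfg.output_dir / "manifest.json"
    _atomic_write(path, lambda p: Path(p).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"))


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the stage result objects."""
    known = run_known_pipeline(cfg)
    check_conservation(known, cfg)
    novel = run_novel_pipeline(cfg, known)
    classified = run_classify(cfg, known, novel)
    return {"known": known, "novel": novel, "classify": classified}
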