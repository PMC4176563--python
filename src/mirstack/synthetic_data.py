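"""Deterministic synthetic small-RNA-seq data with ground truth.

The generator emulates the libraries this toolkit is designed for: three
endothelial-lineage cell types (early EPC, late EPC, mature EC), each a
single-end library whose reads are 18-24 nt mature miRNAs with
Drosha/Dicer-consistent stacking (a dominant mature product, a minor star
product with a 2-nt 3' overhang, <=1 nt 5' end wobble), plus
mRNA-degradation contaminants, poly-A artifacts and 3'-adapter
read-through.  Depth defaults to 5x10^4 reads per sample — a desk-scale
stand-in for multi-million-read libraries that preserves every property
the pipeline is tested on (stacking geometry, contaminant classes,
abundance rank structure), though not their absolute sensitivity.

All randomness flows from a single integer seed through explicit
per-stage generators, so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .align_quant import (GenomicInterval, MiRNAAnnotation,
                          reverse_complement, write_mirna_gff3)

__all__ = [
    "SimulationSpec",
    "TruthLocus",
    "SimulatedData",
    "DEFAULT_ADAPTER3",
    "make_hairpin",
    "build_genome",
    "simulate_reads",
    "write_simulation",
]

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_CELLS = ("early_EPC", "late_EPC", "EC")


@dataclass
class SimulationSpec:
    """Parameters of one simulated study (defaults are the study conditions).

    ``cell_profiles`` maps each cell type to per-locus abundance weights
    (known then novel miRNAs); when ``None``, independent log-normal
    weights (sigma 1.5, a typical miRNA abundance spread) are drawn per
    cell type from the seed.
    """

    seed: int = 1
    genome_length: int = 50_000
    n_known_mirnas: int = 30
    n_novel_mirnas: int = 5
    n_mrna_decoys: int = 50
    reads_per_sample: int = 50_000
    cell_types: tuple = _CELLS
    cell_profiles: Optional[dict] = None
    error_rate: float = 0.001
    jitter: int = 1
    adapter3: str = DEFAULT_ADAPTER3
    polya_artifact_frac: float = 0.01
    mrna_frac: float = 0.15
    star_frac: float = 0.08
    read_length: int = 36
    spacing: int = 200
    mature_len_range: tuple = (20, 24)
    loop_len_range: tuple = (4, 12)
    min_bulges: int = 1   # >= 1 keeps planted duplexes imperfect, as real
    max_bulges: int = 2   # miRNA duplexes are; a perfect duplex would make
                          # the mature its own reverse complement's match
    decoy_len_range: tuple = (100, 200)

    def __post_init__(self):
        for frac in (self.error_rate, self.polya_artifact_frac,
                     self.mrna_frac, self.star_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if len(self.cell_types) != 3:
            raise ValueError("exactly three cell types are required")
        for name in ("genome_length", "reads_per_sample", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthLocus:
    """Ground truth for one planted element."""

    kind: str                      # known | novel | decoy
    name: str
    precursor: GenomicInterval     # hairpin core plus 3 nt flanks
    mature: Optional[GenomicInterval]
    star: Optional[GenomicInterval]
    mature_seq: str = ""           # transcript-oriented DNA
    star_seq: str = ""
    sequence: str = ""             # full transcript (decoy) or precursor seq
    expected_counts: dict = dc_field(default_factory=dict)
    realized_counts: dict = dc_field(default_factory=dict)


@dataclass
class SimulatedData:
    """Genome, references, annotation and per-locus truth for one spec."""

    spec: SimulationSpec
    genome: dict
    annotations: list
    mirna_precursors: dict        # name -> transcript-oriented sequence
    decoy_transcripts: dict
    truth: list
    cell_profiles: dict

    def truth_by_kind(self, kind: str) -> list:
        return [t for t in self.truth if t.kind == kind]


_UNPAIRABLE = {"A": "C", "C": "C", "G": "G", "T": "C"}


def make_hairpin(rng: random.Random, mature_len: int = 22, loop_len: int = 8,
                 bulges: int = 0, arm: str = "5p") -> tuple[str, dict]:
    """Construct a hairpin core: mature arm + loop + imperfect complement.

    The passenger arm is the reverse complement of the mature with
    ``bulges`` positions (opposite the outer end of the mature) mutated to
    unpairable bases, so a maximum-pairing fold keeps a single stacked
    helix of at least ``mature_len - bulges`` pairs.  The loop is drawn
    from {A, C} only and therefore cannot pair internally, which pins the
    folded terminal-loop size to ``loop_len`` exactly.  ``arm`` selects
    whether the mature product is the 5' or the 3' arm.

    Returns the core DNA sequence and a layout dict with transcript-local
    ``mature``/``star``/``loop`` intervals; the star interval carries the
    2-nt 3' overhang of Dicer processing and may extend 2 nt beyond the
    core.
    """
    from .novel_discovery import fold_hairpin

    if not (20 <= mature_len <= 24 and 4 <= loop_len <= 12):
        raise ValueError("mature_len must be 20-24 and loop_len 4-12")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    for _attempt in range(100):
        mature = "".join(rng.choice("ACGT") for _ in range(mature_len))
        if mature.count("A") / mature_len >= 0.7:
            continue  # avoid accidental poly-A matures
        loop = "".join(rng.choice("AC") for _ in range(loop_len))
        passenger = list(reverse_complement(mature))
        # passenger[k] pairs mature[mature_len - 1 - k]; break the pairs
        # at the OUTER end of the stem, which is the passenger tail when
        # the passenger is the 3' arm but its head when it is the 5' arm
        for i in range(min(bulges, mature_len)):
            k = mature_len - 1 - i if arm == "5p" else i
            passenger[k] = _UNPAIRABLE[mature[mature_len - 1 - k]]
        passenger = "".join(passenger)
        core = (mature + loop + passenger if arm == "5p"
                else passenger + loop + mature)
        # verify the design contract against the actual folder: mutated
        # bases can occasionally re-pair elsewhere and restructure the
        # outer stem, so draws violating the contract are rejected
        fold = fold_hairpin(core)
        if (fold.is_hairpin and fold.loop_size == loop_len
                and fold.longest_stem >= mature_len - bulges - 2):
            break
    else:
        raise RuntimeError("could not construct a contract-satisfying hairpin")
    if arm == "5p":
        mature_iv = (0, mature_len)
        star_span = (mature_len + loop_len, len(core))
        star_iv = (star_span[0] + 2, star_span[1] + 2)  # 2 nt 3' overhang
    else:
        mature_iv = (len(core) - mature_len, len(core))
        star_span = (0, mature_len)
        star_iv = (star_span[0] - 2, star_span[1] - 2)
    layout = {
        "mature": mature_iv,
        "star": star_iv,
        "loop": (star_span[1], mature_iv[0]) if arm == "3p"
                else (mature_len, mature_len + loop_len),
        "arm": arm,
    }
    return core, layout


def _transcript_to_genomic(t_lo: int, t_hi: int, core_start: int,
                           core_end: int, chrom: str,
                           strand: str) -> GenomicInterval:
    if strand == "+":
        return GenomicInterval(chrom, core_start + t_lo, core_start + t_hi, "+")
    return GenomicInterval(chrom, core_end - t_hi, core_end - t_lo, "-")


def build_genome(spec: SimulationSpec) -> SimulatedData:
    """Plant known miRNAs, novel hairpins and decoy mRNAs in a toy genome.

    Known miRNA precursors are annotated (GFF3-ready); novel hairpins are
    recorded in the truth table only; decoy transcripts are genomic
    segments exported as a separate mRNA FASTA.  Planted elements are
    separated by at least ``spec.spacing`` nt of random background.
    """
    rng = random.Random(spec.seed)
    chrom = "chr1"

    elements = ([("known", i) for i in range(spec.n_known_mirnas)]
                + [("novel", i) for i in range(spec.n_novel_mirnas)]
                + [("decoy", i) for i in range(spec.n_mrna_decoys)])
    rng.shuffle(elements)

    genome = list("".join(rng.choice("ACGT")
                          for _ in range(spec.genome_length)))
    truth: list[TruthLocus] = []
    annotations: list[MiRNAAnnotation] = []
    mirna_precursors: dict[str, str] = {}
    decoy_transcripts: dict[str, str] = {}

    cursor = 0
    for kind, idx in elements:
        cursor += spec.spacing + rng.randint(0, 50)
        if kind == "decoy":
            length = rng.randint(*spec.decoy_len_range)
            start, end = cursor, cursor + length
            if end + spec.spacing > spec.genome_length:
                raise ValueError("planted elements overflow genome_length")
            name = f"decoy_mRNA_{idx + 1}"
            decoy_transcripts[name] = "".join(genome[start:end])
            truth.append(TruthLocus(
                kind="decoy", name=name,
                precursor=GenomicInterval(chrom, start, end, "+"),
                mature=None, star=None,
                sequence="".join(genome[start:end])))
            cursor = end
            continue

        mature_len = rng.randint(*spec.mature_len_range)
        loop_len = rng.randint(*spec.loop_len_range)
        bulges = rng.randint(spec.min_bulges, spec.max_bulges)
        arm = rng.choice(("5p", "3p"))
        strand = rng.choice("+-")
        core, layout = make_hairpin(rng, mature_len, loop_len, bulges, arm)
        start, end = cursor, cursor + len(core)
        if end + spec.spacing > spec.genome_length:
            raise ValueError("planted elements overflow genome_length")
        planted = core if strand == "+" else reverse_complement(core)
        genome[start:end] = list(planted)
        cursor = end

        name = f"mir-K{idx + 1}" if kind == "known" else f"mir-TRUE-N{idx + 1}"
        mature_iv = _transcript_to_genomic(*layout["mature"], start, end,
                                           chrom, strand)
        star_iv = _transcript_to_genomic(*layout["star"], start, end,
                                         chrom, strand)
        prec_iv = GenomicInterval(chrom, start - 3, end + 3, strand)
        locus = TruthLocus(kind=kind, name=name, precursor=prec_iv,
                           mature=mature_iv, star=star_iv, sequence=core)
        truth.append(locus)
        if kind == "known":
            mature_name = f"miR-K{idx + 1}-{arm}"
            annotations.append(MiRNAAnnotation(
                precursor_name=name, precursor=prec_iv,
                matures=[(mature_name, mature_iv)]))

    # fill sequences after all planting so flanks are final
    genome_seq = "".join(genome)
    for locus in truth:
        if locus.kind == "decoy":
            continue
        p = locus.precursor
        prec_seq = genome_seq[p.start:p.end]
        if p.strand == "-":
            prec_seq = reverse_complement(prec_seq)
        if locus.kind == "known":
            mirna_precursors[locus.name] = prec_seq
        locus.mature_seq = _extract(genome_seq, locus.mature)
        locus.star_seq = _extract(genome_seq, locus.star)

    profiles = spec.cell_profiles
    if profiles is None:
        n_loci = spec.n_known_mirnas + spec.n_novel_mirnas
        profiles = {}
        for ci, cell in enumerate(spec.cell_types):
            prng = np.random.default_rng([spec.seed, 1000 + ci])
            profiles[cell] = prng.lognormal(mean=0.0, sigma=1.5,
                                            size=n_loci).tolist()

    return SimulatedData(spec=spec, genome={chrom: genome_seq},
                         annotations=annotations,
                         mirna_precursors=mirna_precursors,
                         decoy_transcripts=decoy_transcripts,
                         truth=truth, cell_profiles=profiles)


def _extract(genome_seq: str, iv: GenomicInterval, shift: int = 0) -> str:
    """Transcript-oriented sequence of an interval shifted along transcript."""
    g_shift = shift if iv.strand == "+" else -shift
    seq = genome_seq[iv.start + g_shift: iv.end + g_shift]
    return seq if iv.strand == "+" else reverse_complement(seq)


def simulate_reads(data: SimulatedData) -> dict[str, list]:
    """Draw per-cell-type reads; returns {cell: [(id, seq, qual), ...]}.

    Per cell: miRNA reads are multinomial over planted loci with the
    cell's profile weights; a ``star_frac`` share of each locus's reads
    comes from the star product; 5' ends jitter by at most
    ``spec.jitter`` nt; substitution errors occur at ``error_rate`` per
    base; the 3' adapter is appended and the read clipped to
    ``read_length``.  mRNA-decoy reads are random 18-30 nt transcript
    fragments; ``polya_artifact_frac`` of reads are replaced by A-runs.
    Realized per-locus counts are recorded in the truth table.
    """
    spec = data.spec
    genome_seq = data.genome["chr1"]
    mir_loci = [t for t in data.truth if t.kind in ("known", "novel")]
    decoys = list(data.decoy_transcripts.values())
    libraries: dict[str, list] = {}

    for ci, cell in enumerate(spec.cell_types):
        rng = np.random.default_rng([spec.seed, ci])
        n = spec.reads_per_sample
        n_polya = int(round(n * spec.polya_artifact_frac))
        n_mrna = int(round(n * spec.mrna_frac))
        n_mir = n - n_polya - n_mrna

        weights = np.asarray(data.cell_profiles[cell], dtype=float)
        if len(weights) != len(mir_loci):
            raise ValueError("cell profile length != number of miRNA loci")
        counts = rng.multinomial(n_mir, weights / weights.sum())

        inserts: list[str] = []
        wsum = weights.sum()
        for li, (locus, c) in enumerate(zip(mir_loci, counts)):
            locus.expected_counts[cell] = float(n_mir * weights[li] / wsum)
            n_star = rng.binomial(c, spec.star_frac) if locus.star else 0
            n_mat = int(c) - int(n_star)
            locus.realized_counts[cell] = {"mature": n_mat, "star": int(n_star)}
            for iv, k in ((locus.mature, n_mat), (locus.star, int(n_star))):
                if k == 0:
                    continue
                jitters = rng.integers(-spec.jitter, spec.jitter + 1, size=k)
                for j in jitters:
                    inserts.append(_extract(genome_seq, iv, int(j)))
        for _ in range(n_mrna):
            t = decoys[int(rng.integers(len(decoys)))]
            length = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(t) - length + 1))
            inserts.append(t[start:start + length])
        for _ in range(n_polya):
            inserts.append("A" * int(rng.integers(20, 31)))

        # substitution errors, then adapter and clip
        lens = np.array([len(s) for s in inserts])
        n_err = rng.binomial(lens, spec.error_rate)
        reads = []
        for s, ne in zip(inserts, n_err):
            if ne:
                s = list(s)
                for pos in rng.choice(len(s), size=int(ne), replace=False):
                    alt = "ACGT".replace(s[pos], "")
                    s[pos] = alt[int(rng.integers(3))]
                s = "".join(s)
            reads.append((s + spec.adapter3)[: spec.read_length])

        order = rng.permutation(len(reads))
        libraries[cell] = [
            (f"{cell}_r{i + 1}", reads[int(oi)], "I" * len(reads[int(oi)]))
            for i, oi in enumerate(order)
        ]
        assert len(libraries[cell]) == n
    return libraries


def write_simulation(data: SimulatedData, outdir,
                     libraries: Optional[dict] = None) -> dict:
    """Write genome/mRNA/precursor FASTA, GFF3, truth TSV and FASTQ files.

    Returns a dict of written paths keyed by role (samples as a nested
    ``{cell: path}`` map).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _fasta(seqs: dict, path: Path):
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    paths["genome_fasta"] = outdir / "genome.fa"
    _fasta(data.genome, paths["genome_fasta"])
    paths["mrna_fasta"] = outdir / "mrna.fa"
    _fasta(data.decoy_transcripts, paths["mrna_fasta"])
    paths["mirna_fasta"] = outdir / "mirna_precursors.fa"
    _fasta(data.mirna_precursors, paths["mirna_fasta"])
    paths["mirna_gff3"] = outdir / "known_mirnas.gff3"
    write_mirna_gff3(data.annotations, paths["mirna_gff3"])

    paths["truth_tsv"] = outdir / "truth.tsv"
    with open(paths["truth_tsv"], "w") as fh:
        cells = list(data.spec.cell_types)
        fh.write("kind\tname\tchrom\tstart\tend\tstrand\t"
                 "mature_start\tmature_end\tstar_start\tstar_end\t"
                 "mature_seq\tstar_seq\t"
                 + "\t".join(f"expected_{c}" for c in cells) + "\n")
        for t in data.truth:
            m = t.mature
            s = t.star
            fh.write("\t".join(str(v) for v in [
                t.kind, t.name, t.precursor.chrom, t.precursor.start,
                t.precursor.end, t.precursor.strand,
                m.start if m else ".", m.end if m else ".",
                s.start if s else ".", s.end if s else ".",
                t.mature_seq or ".", t.star_seq or ".",
            ] + [f"{t.expected_counts.get(c, 0.0):.3f}" for c in cells])
                + "\n")

    if libraries is not None:
        sample_paths = {}
        for cell, reads in libraries.items():
            p = outdir / f"{cell}.fastq"
            with open(p, "w") as fh:
                for rid, seq, qual in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            sample_paths[cell] = p
        paths["samples"] = sample_paths
    return paths
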