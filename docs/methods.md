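# Methods

## Scope and model

`mirstack` analyses single-end small-RNA sequencing libraries from three
endothelial lineage states — early EPC, late EPC, mature EC — and covers
four computations: read filtration/collapsing, known-miRNA quantification,
consensus novel-miRNA discovery, and expression-pattern classification.
Everything downstream of the sequencer is modelled; library preparation,
wet-lab validation and patient statistics are out of scope.

## Read filtration

A read is the insert (the small RNA) followed by a 3' adapter. Rules are
applied in a fixed order — 5' adapter contamination, missing 3' adapter,
ambiguous bases, poly-A artifact, insert length — and each read increments
exactly one counter, so `input = kept + Σ discarded` holds exactly for
every library (asserted at run time).

* **3' adapter** (`find_adapter3`): the leftmost position whose suffix is
  either the full adapter followed by anything (read-through) or exactly a
  prefix of the adapter of 6–18 nt (`min_adapter_flank`/`max_adapter_flank`).
  Matching is exact by default; `max_adapter_mismatch` exposes a
  substitution tolerance but defaults to 0 so behaviour is reproducible
  and checkable against an exhaustive (position, flank-length) oracle.
* **Poly-A** operationalised as: insert ≥ 80% A overall (`polya_frac`), or
  a terminal A-run ≥ 8 nt (`polya_min_run`). Poly-A tails are a ligation
  artifact class, not a biological small RNA.
* **Length window** 18–26 nt: mature miRNAs are 18–24 nt; the default
  adds 2 nt slack for isomiR end variation. Configurable.
* Base qualities are parsed and validated but not used for filtering.

The filter order affects only per-rule attribution, never the kept set;
the manifest records the order used.

## Alignment and quantification

Tags are aligned full-length and ungapped with an exact k-mer seed index
(k = 9 by default) and verified placements on both strands at 0 (default)
or 1 mismatches. For 1 mismatch, pigeonhole seeding with the tag's first
and last k-mer is complete whenever 2k ≤ tag length (true for 18 nt tags
at k = 9); shorter tags fall back to a full scan. Coordinates are 0-based
half-open internally; GFF3 I/O converts to/from 1-based inclusive.

Partition precedence is miRNA > mRNA > unannotated: a tag matching a
known precursor is quantified even if it also matches an mRNA; mRNA-only
tags are treated as degradation products and excluded from everything
downstream. No multi-mapping placement cap is applied by default.

A placement is counted toward a mature miRNA when it falls entirely
within `[mature_start − 2, mature_end + 5]` on the same strand. The
asymmetric window absorbs the typical isomiR wobble (small 5' shifts,
longer templated/non-templated 3' extensions). A tag assigned M times
across mature windows contributes `count/M` per assignment, so assigned
mass exactly equals tag mass (verified with rational arithmetic in the
conservation audit).

**RPM.** Abundance is `C/(M·N) × 10⁹` with N the library's genome-mapped
read mass. Because counting already performs fractional 1/M allocation,
the pipeline calls the normaliser with M = 1 — applying M twice would
double-discount multi-mappers, and the pipeline asserts against it. The
literal two-factor form remains available for single-tag use. The ×10⁹
scale is kept exactly as the formula states even though such values are
conventionally reported per million (×10⁶); the scale is a configuration
knob (`alignment.rpm_scale`), and all thresholds in this package are
interpreted on the ×10⁹ scale. N counts reads whose tags survive the
mRNA filter and align to the genome.

## Novel-miRNA discovery

Unannotated tag sequences are pooled across samples (counts summed),
re-aligned, and clustered into stacks by single-linkage with a 30 nt gap
(mature and star reads of one precursor — separated by a 4–12 nt loop —
always co-cluster; distinct planted loci never do).

Around the dominant read, two windows are excised: assuming a 5' arm
mature (15 nt upstream + 70 nt downstream in transcript orientation) or a
3' arm mature (70 + 15). 70 nt is enough for the far arm plus loop of any
miRNA-sized precursor; windows shorter than 40 nt after clipping at
contig ends are skipped with a logged reason.

**Folding** is maximum-weight non-crossing base pairing (Nussinov-style
interval dynamic program): pair weights GC = 3, AU = 2, GU = 1, minimum
hairpin loop 3 nt, N unpairable, no pseudoknots. Traceback is
deterministic (on ties, pairing the left end beats leaving it unpaired,
and the rightmost co-optimal partner wins). This is deliberately *not* a
thermodynamic MFE model: the weighted objective has an exact brute-force
oracle by structure enumeration at small lengths, so every fold the tests
assert is independently checkable. The trade-off is degeneracy — random
flanking sequence pairs promiscuously, so the reported structure can
carry spurious side helices and the innermost stem pair can slide by
1–2 nt. Three design decisions absorb this: the main hairpin is the
highest-scoring single-loop branch of the structure; the star interval is
derived only from mature-position partners on the loop side of the
mature (stray local pairs are ignored), shifted 2 nt toward the star's 3'
end for the Dicer overhang; and the rule filter tolerates up to 2 nt of
mature/loop overlap. A thermodynamic folder can be substituted through
the `folder` hook of `evaluate_window` for cross-checks (ViennaRNA-style
tools produce comparable hairpins on these windows but have no exact
desk-scale oracle).

**Predictor A** (weighted additive score):
`2·log₂(1 + mature_reads) + 4·consistent_fraction + 10·fold_score/window_len
+ 3·[star_reads > 0] − 6·inconsistent_fraction ≥ 5.0`.
Reads are consistent when ≥ 80% of their span lies in the mature, star or
loop interval; the score is monotone in mature evidence.

**Predictor B** (hard rules, all required): mature length 18–26 nt;
mature on one arm (≤ 2 nt loop overlap); longest stacked helix ≥ 14 bp;
terminal loop 3–20 nt; fold score density ≥ 0.25 per window nt; mature
reads ≥ 5; inconsistent fraction ≤ 0.2.

Consensus requires **both** predictors — reproducing the
two-independent-algorithms architecture of miRDeep2/MIREAP-style
pipelines with simplified, fully specified analogues. The numeric scores
are not expected to match any external tool; only the
consensus-intersection design is reproduced. Overlapping consensus loci
(≥ 50% reciprocal overlap) merge keeping the higher score; survivors are
named `miR-N1…` in genome order, independent of input order. The report
TSV ranks every candidate with both verdicts, replacing manual inspection
with a machine-readable artefact.

All thresholds are configuration keys; the defaults were chosen so that
the planted-recovery property of the simulation holds with margin, not
taken from any external tool.

## Expression patterns

Expression requires RPM strictly greater than 100. Fold changes are
computed on RPM + 1 (pseudocount) so ratios are defined at zero; the
pseudocount and threshold scale together, making classification invariant
under joint rescaling. Classification order: cell-type specificity
(expressed in exactly one cell type) first, then monotonic up
(EC ≥ 1.5×late and late ≥ 1.5×early), monotonic down (mirror),
late-and-EC-high (late vs EC within 1.5×, both ≥ 1.5× early), then
not-expressed, else expressed-unclassified — exactly one class per miRNA
by construction. Specificity precedes the fold-change classes because
single-cell-type expression is the stronger, separately reported
statement.

The Mann–Whitney U test (independent groups) and Wilcoxon signed-rank
test (paired; zero differences dropped) use midranks and exact two-sided
p-values by complete enumeration — all C(n₁+n₂, n₁) labelings up to
n₁+n₂ = 10, all 2ⁿ sign vectors up to n = 12 — defined as the null
probability of a statistic at least as far from its mean as observed.
Larger samples use the normal approximation with tie and continuity
corrections. Two-sided p-values are reported throughout.

## Synthetic data

The generator emulates the target libraries at desk scale: 5×10⁴ reads
per sample instead of millions, which preserves every property the
pipeline is tested on (stacking geometry, contaminant classes, abundance
rank structure) but not absolute sensitivity — miRNAs below ~1/50,000
relative abundance are invisible here but would not be in a full-depth
library. A 50 kb single-chromosome genome hosts 30 known miRNAs
(annotated), 5 novel hairpins (ground truth only) and 50 mRNA decoy
transcripts (100–200 nt genomic segments exported as the mRNA reference),
all separated by ≥ 200 nt.

Planted hairpins are mature arm + {A,C}-only loop (4–12 nt, internally
unpairable, which pins the folded loop size) + imperfect reverse
complement with 1–2 broken pairs at the outer stem end. At least one
broken pair is required: a perfect duplex would make the mature read its
own reverse-complement's match and create mirror alignments on the
opposite strand. Each construct is verified against the actual folder
(single loop of the designed size, stem ≥ mature_len − bulges − 2) and
redrawn if degenerate pairing violates the contract. Mature arm (5p/3p)
and strand are randomised; precursor records carry 3 nt flanks so
jittered and star reads remain inside the precursor reference.

Per cell type, reads are multinomial over planted loci with log-normal
(σ = 1.5) abundance weights drawn independently per cell type — a typical
miRNA abundance spread that yields diverse expression patterns; star
reads are 8% of a locus's reads (within the 5–10% band where star
evidence exists but mature dominance is unambiguous); 5' ends jitter by
≤ 1 nt; substitutions occur at 10⁻³/base; 15% of reads are random
18–30 nt mRNA fragments and 1% poly-A artifacts; the 3' adapter is
appended and reads clipped to 36 nt, so 20–24 nt inserts always retain a
6–18 nt adapter flank. All randomness derives from one integer seed
through explicit per-stage generators; identical specs produce
byte-identical files. What the simulation does **not** model: realistic
quality-score error profiles, ligation bias, indels, isomiR 3' tailing,
cross-mapping miRNA families — so passing tests demonstrate correctness
of the pipeline's logic under clean assumptions, not performance on real
libraries.

## Pipeline and determinism

A YAML configuration (sections `paths`, `filter`, `alignment`,
`discovery`, `patterns`, `run`) is validated strictly: unknown keys,
missing required keys, dangling paths and contradictory bounds are all
errors; valid configs are fully defaulted. Outputs are written
atomically (write-then-rename); the JSON manifest records inputs,
settings, the seed and the per-stage read chain, and contains no
timestamps, so reruns with an identical configuration are byte-identical.
Empty input libraries are handled as warnings, not errors. Execution is
single-process.

## Verification sizes

The test suite checks the folding DP against exhaustive structure
enumeration (sequences ≤ 16 nt), the exact rank tests against independent
enumeration oracles (1,000 and 200 seeded cases), the aligner against a
naive full scan (500 tags, 50 kb, 0 and 1 mismatches), RPM against
rational arithmetic (10⁴ triples, < 10⁻¹² relative error), filtration
against a hand-verified 12-read fixture, and end-to-end recovery on the
default simulation (≥ 90% of planted novel hairpins with ≥ 10 reads,
≤ 2 false consensus calls, Spearman ≥ 0.95 between RPM and planted
weights). Most pipeline-level tests run on a 5,000-read-per-sample
reduction of the default conditions; the recovery check runs at the full
5×10⁴ depth.

## Known limitations

* Ungapped alignment only; no spliced placements, no indels, no isomiR
  cataloguing, no SAM/BAM emission.
* The folding model is combinatorial, not thermodynamic; fold *scores*
  are not free energies and are not comparable to MFE values.
* Novel discovery pools samples before calling, so per-sample discovery
  sensitivity is not modelled; per-sample novel expression is quantified
  after consensus calling.
* Exact tests are quadratic-to-exponential in sample size by design and
  switch to the corrected normal approximation beyond the enumeration
  bounds.
* The expression threshold (RPM > 100) is interpreted on the package's
  ×10⁹ RPM scale; users supplying their own matrices on a ×10⁶ scale
  should rescale the threshold accordingly.
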