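# mirstack

A small-RNA sequencing analysis toolkit for profiling known microRNAs and
discovering novel ones, built around the three-cell-type comparison of
endothelial lineage cells: early endothelial progenitor cells (early EPC),
late EPCs, and mature endothelial cells (EC/HUVEC).

## What it does

Small-RNA libraries are short single-end reads in which an 18–26 nt insert
(the small RNA) is followed by a 3' sequencing adapter. `mirstack`
implements the complete desk-side analysis:

1. **Preprocess** — reads are discarded when they contain a 5' adapter, no
   recognisable 3' adapter (a full read-through or a terminal flank of
   6–18 nt of the adapter's 5' end), ambiguous bases, a poly-A artifact,
   or an out-of-range insert; survivors are trimmed and collapsed into
   unique tags (sequence + read count), with exact per-rule accounting.
2. **Align & quantify** — tags are aligned ungapped and full-length (0 or
   1 mismatches, both strands) against known mRNAs, known miRNA precursors
   and the genome.  mRNA-only tags are degradation products and are
   dropped; known-miRNA tags are counted per annotated mature locus with
   fractional 1/M allocation across a tag's M miRNA-region placements;
   abundance is normalised as

   ```
   RPM = C / (M·N) × 10⁹
   ```

   with C the read mass on a mature miRNA region, M the multi-mapping
   factor and N the library's genome-mapped read total.
3. **Novel discovery** — unannotated tags are pooled, re-aligned, and
   clustered into genomic read stacks.  Around each stack's dominant read
   two candidate precursor windows are excised (dominant product on the
   5' or the 3' arm), folded with a maximum-weight base-pairing dynamic
   program (GC=3, AU=2, GU=1, minimum loop 3 nt), and the stack is
   partitioned into mature/star/loop evidence against the fold.  Two
   independent predictors — a weighted additive scorer and a hard
   structural rule filter — must **both** accept a candidate; consensus
   calls are merged and named `miR-N1`, `miR-N2`, … in genome order, with
   `-5p`/`-3p` product names.
4. **Expression patterns** — a miRNA is *expressed* at RPM > 100 (strict).
   Expressed miRNAs are classified at a 1.5× fold change into monotonic
   increase/decrease along the early EPC → late EPC → EC axis, a
   late-EPC-and-EC-jointly-high class, cell-type-specific classes, and a
   three-set Venn partition.  Group comparisons use the Mann–Whitney U
   test and the Wilcoxon signed-rank test with exact small-sample
   p-values by complete enumeration.
5. **Synthetic data** — a fully deterministic generator plants known
   miRNAs, novel hairpins and mRNA decoys in a toy genome and simulates
   per-cell-type FASTQ libraries (Dicer-consistent stacking, star reads
   with the 2-nt 3' overhang, 5' jitter, substitution errors, poly-A
   artifacts, adapter read-through) with a complete ground-truth table,
   so the whole pipeline is testable without external data.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
$ mirstack simulate -o demo --seed 1
simulation written to demo; config: demo/config.yaml
$ mirstack run-all -c demo/config.yaml
30 known miRNAs quantified; 5 consensus novel miRNAs; outputs in demo/results
```

`demo/results/known_rpm.tsv` holds the RPM matrix (here the planted
profiles make miR-K1-5p a late-EPC-enriched miRNA):

```
mirna      early_EPC    late_EPC     EC
miR-K1-5p  1.21898e+07  6.48706e+07  4.98492e+06
miR-K10-3p 8.61314e+06  1.18654e+07  1.92102e+07
```

(RPM values are large because the normalisation uses the ×10⁹ scale on
desk-scale libraries of 5×10⁴ reads.)

`demo/results/novel_report.tsv` lists every excised candidate window with
both predictor verdicts; only rows passing both become consensus calls:

```
chrom start end  strand arm mature_count star_count scoreA  passA passB consensus name
chr1  7461  7570 -      3p  3            0          16.5321 True  False False     .
chr1  7492  7601 +      3p  5169         466        41.1214 True  True  True      miR-N1
```

The first row is a weak mirror stack rejected by the rule filter; the
second is a genuine planted hairpin: 5169 mature reads, 466 star reads,
and both predictors agree.  Consensus calls are also written as GFF3
(`novel_calls.gff3`, precursor + mature features, scoreA in attributes)
and as plain-text dot-bracket structures (`novel_structures.txt`).
`manifest.json` records the per-stage read accounting (input = kept +
discarded at every step) and the discovery step chain
(stacks → windows → passA/passB → consensus → named).

## Layout

```
src/mirstack/
  preprocess.py           filtration cascade, adapter search, collapsing
  align_quant.py          seed index, alignment, partitioning, counting, RPM
  novel_discovery.py      stacks, excision, folding DP, predictors, consensus
  expression_patterns.py  expression calls, pattern classes, Venn, rank tests
  synthetic_data.py       deterministic simulator with ground truth
  evaluate.py             recovery/rank-fidelity metrics vs ground truth
  pipeline.py             config validation, orchestration, manifest
  cli.py                  mirstack simulate/preprocess/quantify/discover/
                          classify/run-all
docs/methods.md           model assumptions, parameters, limitations
scripts/acceptance.py     from-scratch reproduction of headline quantities
tests/                    unit, property and end-to-end acceptance tests
```
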