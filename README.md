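# termini

Nucleotide-resolution detection of **differential RNA 3′ (or 5′) ends** from
strand-specific, single-end bacterial RNA-seq alignments, plus comparison of
end sets across ribonuclease mutants and profiling of untemplated 3′ tails.

Given per-library SAM alignments, a genome FASTA, a GFF3 annotation and a
two-condition sample design, the pipeline:

1. builds per-nucleotide, per-strand **full** and **read-terminus** coverage
   tracks (the 3′-terminal *aligned* base of each read; soft clips never
   shift the terminus);
2. integrates both strands into one keyed end-count matrix across libraries;
3. filters candidate positions (end coverage ≥ 10 and end/full signal ratio
   > 0.05 jointly in at least one library);
4. normalizes with median-of-ratios size factors and tests every position
   with a transparent two-group negative-binomial Wald test
   (method-of-moments dispersion shared across positions, no shrinkage),
   followed by Benjamini–Hochberg adjustment;
5. keeps positions with |log2FC| ≥ 1 and adjusted p ≤ 0.05 and chain-merges
   them within 3 nt into differential ends (span = "distribution size",
   arithmetic-mean log2FC, direction by sign);
6. assigns ends strand-specifically to annotated features (priority
   tRNA > rRNA > ncRNA > CDS > other; no overlap → UTR) and can extract
   flanking sequence windows for downstream motif/structure analysis;
7. compares two end sets by windowed same-strand matching (default 1 nt),
   classifies matches into fold-change sign quadrants, and tests overlap
   enrichment with a log-space two-tailed Fisher's exact test against a
   genome-size-derived universe of possible ends;
8. extracts soft-clipped untemplated 3′ tails from locally aligned reads
   (≥ 10 nt contiguous 5′ anchor required) and summarizes tail lengths and
   positional base composition.

A synthetic-data module generates fully self-contained fixtures (genome,
GFF3, per-library SAM with negative-binomial planted end pileups,
condition-specific log2 effects, G-rich soft-clip tails, and a truth table),
so the entire pipeline is testable offline and recovery can be scored.

## Test

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests with independent oracles
(brute-force tallies, union-find merging, exact-rational Fisher
enumeration), property tests (conservation, dominance, monotonicity,
label-swap symmetry, determinism) and `tests/test_acceptance.py`, which
implements the acceptance criteria end to end on simulated data.

## CLI

```sh
termini simulate --seed 1 --out sim/                  # synthetic dataset + truth
termini run --design sim/design.tsv --gff sim/annotation.gff3 \
    --fasta sim/genome.fasta --out results/           # full calling chain
termini coverage --sam sim/reference_1.sam --out cov/ # bedGraph tracks
termini intersect --a run_a/ends.tsv --b run_b/ends.tsv --genome-length 4600000
termini tails --sam local_mode.sam --out-prefix tails/sample1
termini flanks --ends results/ends.tsv --fasta sim/genome.fasta --length 15 --out flanks.fasta
```

`termini run` writes `ends.bed` (BED6, score = mean log2FC), `ends.tsv`,
`positions.tsv` (per-position statistics), `annotated.tsv` and a
`manifest.json` with input checksums, configuration and per-stage row
counts. All defaults match the published cutoffs (coverage 10, ratio 0.05,
|log2FC| 1, α 0.05, merge 3 nt, window 1 nt, anchor 10 nt). Outputs are
byte-identical across repeated runs. Exit codes: 0 success (including empty
result sets), 2 input/format error, 3 configuration error.

## Library layout

| module               | contents                                               |
| -------------------- | ------------------------------------------------------ |
| `termini.formats`    | SAM/GFF3/FASTA/BED/bedGraph I/O, sample design         |
| `termini.coverage`   | coverage tracks, end-count matrix                      |
| `termini.endcall`    | filters, size factors, NB Wald test, BH, merging       |
| `termini.annotate`   | feature assignment, class summaries, flank windows     |
| `termini.intersect`  | windowed matching, quadrants, Fisher overlap test      |
| `termini.tails`      | soft-clip tail extraction and composition summaries    |
| `termini.synthetic`  | dataset simulator and recovery scoring                 |
| `termini.pipeline`   | orchestration, manifests, deterministic outputs        |
| `termini.cli`        | `termini` command-line interface                       |
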