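# racetails

Analysis of mRNA 3′-end non-templated additions (NTAs) from targeted
3′ RACE-seq amplicon sequencing — poly(A) tails, uridylated tails, and
tailless decay intermediates — with a library-chemistry simulator that
provides molecule-level ground truth for every pipeline stage.

## Who this is for

RNA decay and retrotransposon labs that sequence transcript 3′ ends with
a ligation-based protocol: a 5′-preadenylated adapter carrying a 15-nt
unique molecular identifier (UMI) and a fixed delimiter is ligated to
RNA 3′ ends, followed by reverse transcription with an indexed primer
(6-nt sample index) and nested transcript-specific PCR. Paired Illumina
reads then capture the templated 3′ end (R1, from the forward primer)
and the adapter side (R2), whose first base after the delimiter is the
complement of the molecule's 3′-terminal nucleotide.

## What it computes

Every 3′ end is classified into the four NTA classes

* **A** — a pure adenosine run,
* **AU** — an adenosine run appended with one or more uridines,
* **U** — a pure uridine run,
* **no tail** — a 3′ end with no NTA,

(sequences failing these patterns are tallied separately as OTHER and
excluded from four-class denominators). Tail lengths are estimated
within an observation window of 0–80 nt with explicit right-censoring:
a tail neither read spans is reported in the "≥ 81" category, while its
*class* usually survives censoring because the terminal bases are still
sequenced. An A that matches the reference at the 3′ terminus is
assigned to the template, not the tail (greedy templated extension), so
A-tail counts are not inflated by genomic adenosines.

PCR duplicates are collapsed by UMI (exact, or directional single-
mismatch clustering), so each molecule contributes one call. Summaries
reproduce the standard figure shapes: class fractions, the three A-tail
length classes (1–32 / 33–64 / > 64 nt), per-length histograms up to
"≥ 81", 10-nt total-length bins, U-length by total-length joint bins,
per-class medians, and between-sample statistics (Pearson chi-square on
class composition, two-sided Mann–Whitney on lengths — exact for tiny
samples). Reads from an endogenous LINE-1 consensus window can be
stratified by subfamily (L1-HS vs older L1-PA classes) using a
user-supplied table of diagnostic nucleotides.

## Worked example

The package ships a synthetic example configuration (synthetic
reference amplicons, a synthetic L1 diagnostic table, two samples).
Simulate 5 000 molecules per sample and run the pipeline:

```bash
cd $(python -c "import racetails, pathlib; print(pathlib.Path(racetails.__file__).parent/'data')")
racetails simulate --config example_config.yaml --n 5000 --seed 42 --out /tmp/demo/sim
racetails run --config example_config.yaml \
    --fastq /tmp/demo/sim/wildtype_R1.fastq /tmp/demo/sim/wildtype_R2.fastq \
    --fastq /tmp/demo/sim/xrn1_ko_R1.fastq /tmp/demo/sim/xrn1_ko_R2.fastq \
    --out /tmp/demo/results
```

`results/classes.tsv` then starts:

```
sample    stratum  class  count  fraction
wildtype  GAPDH    A        913  0.698546
wildtype  GAPDH    AU       193  0.147666
wildtype  GAPDH    U         39  0.029839
wildtype  GAPDH    NONE     162  0.123948
wildtype  GAPDH    OTHER      9
```

i.e. ~70 % of GAPDH molecules carry a pure A-tail, ~18 % are uridylated
(AU + U), and 12 % are tailless — matching the simulated class
proportions (0.70 / 0.15 / 0.02 / 0.13) at the default per-base error
rate of 0.001; the 9 OTHER calls are tails corrupted by simulated
sequencing errors. `medians.tsv` reports the per-class median lengths
(e.g. A-tail median 42 nt, the median of the simulated negative-
binomial poly(A) distribution), and `tests.tsv` holds the pairwise
chi-square and Mann–Whitney results. `manifest.json` carries a
read-conservation ledger: here all 29 991 read pairs are accounted for
(29 784 called, 207 rejected as unanchored at the default error rate).

With sequencing errors in the 15-nt UMI, exact grouping slightly
over-counts molecules (10 401 vs the simulated 10 000); directional
single-mismatch clustering (`racetails dedup --mode directional-1mm`)
recovers 10 066.

Stage-wise commands (`simulate`, `demux`, `call-tails`, `dedup`,
`summarize`, `compare`) expose the same steps individually; `run`
executes them end to end from one YAML config.

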