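# Methods

## The measurement problem

Ligation-based 3′ RACE-seq reads out, per molecule, the boundary
between templated transcript sequence and non-templated 3′ additions
(NTAs), the composition of the NTA, and its length. Three facts of the
chemistry drive the design:

1. **R2 starts at the 3′ terminus.** R2 is primed from the ligated
   adapter, so after the 15-nt UMI and the fixed delimiter, its first
   payload base is the complement of the molecule's 3′-terminal
   nucleotide. Terminal modification (uridylated or not) is therefore
   observable even when the tail is longer than the read.
2. **Lengths are right-censored.** A tail can only be measured if some
   read reaches through it — R2 into templated sequence, or R1 into
   the adapter. The observation window defaults to 80 nt; longer tails
   are reported in a "≥ 81" category, never as a numeric length.
3. **UMIs mark molecules.** PCR after ligation duplicates molecules
   unevenly; collapsing by the 15-nt UMI restores molecule counts.

## Anchoring and the greedy templated rule

Both read segments are oriented to the sense strand. R1 is
prefix-anchored at the known forward-primer offset and walked along the
reference; the walk ends at the reference 3′ terminus or after
`max_gap` (default 3) consecutive non-matching bases. The last
reference-matching base defines the anchor; everything 3′ of it is NTA.
Because a terminal adenosine that matches the reference *matches*, it
is automatically assigned to the template — the greedy rule that keeps
genomically encoded As out of tail lengths (for a reference ending
`…GAA`, a read ending `…GAAAA` has a 2-nt tail, not 4).

The R2 segment has no fixed anchor, so its leading `min_anchor`
(default 12) bases are placed on the reference by exact search (with a
single-mismatch fallback scan); a unique placement is then extended by
the same walk. Alignments are accepted when the mismatch rate over the
templated span is ≤ `max_mismatch_rate` (default 0.05). Substitution
errors only — the protocol's dominant error mode — are modelled;
indels are a known limitation (below).

An R2 segment that never reaches templated sequence but consists
entirely of A/T is treated as a pure-tail view: it supports
classification and censored length, not exact length.

## Classification

The NTA (sense-oriented, U≡T) is matched strictly: empty → no tail,
`A+` → A, `A+U+` → AU, `U+` → U, anything else → OTHER. OTHER is
reported but excluded from four-class fractions. Strictness is the
default (`tolerance 0`); with `tolerance t`, up to `t` isolated
non-conforming bases inside tails of ≥ 10 nt are corrected to the
flanking run's base first — an error-tolerant mode for real data. How
interleaved tails (AUA…A) or G/C-containing tails should be counted is
not externally constrained; the strict-pattern-plus-OTHER-bin rule is
this package's documented choice.

## Length estimation and censoring

Per pair: if the R2 view reaches templated sequence, lengths are exact
from R2; else if the R1 view reaches the adapter (located by the
reverse-complemented delimiter), lengths are exact from R1; else the
call is censored with total length pinned to the window. A fully
observed tail longer than the window is also capped and flagged
censored, so the "≥ 81" category is exhaustive for long tails. For
censored AU views the U-run length is still exact (the run ends at the
sequenced terminus); the A component absorbs the remainder of the
window. A censored all-U view is reported as class U — an AU tail
whose U-run exceeds the whole window is indistinguishable from a U
tail, a documented ambiguity that requires U-runs ≥ 81 nt to arise.
Medians include censored values at the window cap, matching how
medians within a fixed window are conventionally reported; the
resulting bias under heavy censoring is noted in output metadata by
the censored counts themselves.

## UMI deduplication

Default grouping is exact UMI identity: with 4^15 ≈ 1.07 × 10⁹ UMIs,
collisions are negligible at library scale. Directional single-mismatch
clustering (merge a UMI into a ≥ 2×-more-abundant Hamming-1 neighbour)
is available for data where sequencing errors inside the UMI inflate
molecule counts — on simulated data with a 0.001 per-base error rate it
recovers the true molecule count to within ~0.7 %, where exact mode
over-counts by ~4 %. Consensus per group: class by plurality, ties
broken toward the member with the longest uncensored evidence, then a
fixed class order for determinism; lengths are per-field medians of the
winning class; a consensus is censored only if all winning members are.
The dedup key is (sample, reference, UMI), not the anchor, since PCR
artifacts can shift apparent anchors.

## Statistics

Class composition between two samples: Pearson chi-square on the 2 × k
count table without continuity correction (df = k − 1); columns with a
zero total raise an error advising pooling. Length distributions:
two-sided Mann–Whitney U with tie correction — the exact null when
min(n₁, n₂) ≤ 8, normal approximation otherwise. Both are computed via
scipy.stats behind the module surface; the test suite cross-checks
them against an independent closed-form 2 × 2 formula and a full
rank-arrangement enumeration. No multiple-testing correction is applied
across strata by default (per-comparison reporting); a
Benjamini–Hochberg helper is provided.

## The simulator and what it does (not) emulate

The generator's defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| class probabilities (A/AU/U/none) | 0.70 / 0.15 / 0.02 / 0.13 | wild-type-like composition with ~17 % uridylation |
| A-length | negative binomial, mean 45, dispersion 5 | median ≈ 42–47 nt, long right tail |
| U-length | geometric, mean 2 | short uridine runs dominate |
| PCR copies | shifted Poisson, mean 3 | modest duplication from nested PCR |
| error rate | 0.001 per base | typical Illumina substitution rate |
| reads | R1 150 nt, R2 100 nt | R2 payload of 81 nt realises the 80-nt window |
| UMI / index / delimiter | 15 nt / 6 nt / 4-nt placeholder | protocol layout; the delimiter is config, never hard-coded |

Molecule UMIs are drawn uniformly **without replacement**: at library
scale (n ≪ 4¹⁵) this is statistically indistinguishable from i.i.d.
draws and guarantees the one-UMI-one-molecule regime that molecule
counting presupposes, so UMI-collision handling is deliberately not an
object under test.

Not emulated: indels and homopolymer slippage, RT stutter through long
poly(A) tracts, polymerase-dependent truncation of long tails,
amplification bias favouring tailless fragments, and base-quality
degradation along the read (qualities are constant; a mean-quality
floor flag exists but never fires on simulated data). Consequently,
passing tests demonstrate correctness of the *inference logic* under
substitution noise — not robustness to every artifact of real
libraries. Endogenous L1 subfamily diagnostics ship only as a clearly
labelled synthetic example; real analyses must supply the
experiment-specific diagnostic positions and bases via the TSV config.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  all files and reports.
* Demultiplexing assigns the unique nearest index within
  `max_index_mismatch` (default 1); ties are undetermined. Sample
  sheets must keep indices > 2 × max_index_mismatch apart.
* Reference assignment per read maximises identity of the
  primer-proximal 24 bases (≥ 80 % required); with one amplicon per
  library this is effectively exact.
* Every stage reports per-fate counts, and the run manifest asserts
  read conservation: parsed + rejected = input, called + rejected =
  parsed.
* All randomness flows from a single integer seed through numpy
  Generators; reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script run simulations of 2 000 to
50 000 molecules per scenario (up to ~60 000 read pairs), sizes at
which binomial sampling noise on fractions is ≤ 0.7 % and median
estimates are stable to ± 1 nt — ample for property-based validation
of the inference chain. Reproducing the published biological values
(e.g. the wild-type→KO shift in uridylated fractions and medians)
requires the deposited raw libraries and the experiment's exact adapter
layout and diagnostic tables, which are user-supplied inputs, not
package constants.
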