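# Methods

## Model and procedure

The pipeline treats a small-RNA library as a mixture of five read classes
relative to an annotated (hairpin, mature) pair: exact templated isoforms,
3′-tailed reads, reads with internal substitutions, spike-ins, and
unassignable reads.  The unit of analysis is the anchored, indel-free
comparison described in the README: candidate 5′ starts are restricted to a
±`anchor_window` (default 3 nt) band around the annotated mature start,
mismatches are counted per position, and the placement minimising
(mismatches, |5′ offset|, start) is classified by the shape of its mismatch
set.  Indels are not modelled: at miRNA read lengths, substitution-only
comparison against the correct precursor is the standard treatment and
keeps the tail definition unambiguous.

Key consequences of the rules:

* **Templated-extension precedence.**  A 3′ base equal to the next hairpin
  base is never called a tail.  This systematically under-counts tails that
  coincide with genomic sequence (a uniform-composition hairpin hides 1/4 of
  mono-tails); the simulator quantifies the effect via its
  `tail_indistinguishable` truth flag rather than pretending it away.
* **Overhang.**  Read positions past the hairpin 3′ end count as mismatches
  — there is nothing to match, and 3′-arm matures near the hairpin end
  could otherwise never be called tailed.
* **Multimapping.**  A read assignable to k matures receives k calls each
  flagged `multimap_n = k`; downstream statistics count every call once by
  default, with `unique_only` to restrict to unambiguous reads.  With
  random or real hairpin sets multimapping is rare; both analyses remain
  available.
* **N handling.**  `N` never matches any base, on either side.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `max_mismatches` | 2 | total mismatch budget per read; beyond it a read is unassigned |
| `tail_max` | 2 | longest terminal run called as a tail (mono/di additions) |
| `anchor_window` | 3 nt | allowed 5′ start shift; captures 5′ isomiRs while keeping arm assignment unambiguous |
| `min_len`/`max_len` | 18/24 nt | isoform tabulation range |
| adapter trimming | rate 0.1, min overlap 5, min length 18 | leftmost adapter-prefix match; length exactly 18 is kept |
| `min_guide_count` | 50 | guide enters the report only with templated count strictly above 50 |
| `focal_position` | 23 | terminal position for the fold statistic |

`tail_max` and `max_mismatches` are deliberately independent: with both at
their defaults a di-tail consumes the whole budget, while lowering
`tail_max` to 1 reserves one mismatch for an internal substitution.

Normalization is per-million scaling anchored on exact spike-in matches
(factor 10⁶ / matched spike reads), falling back to total classified
non-spike reads when no spikes are present.  All published-style quantities
(fractions, percentages, the fold) are scale-free, so normalization affects
only absolute count columns.

The guide cutoff is applied per library: each sample stands alone, matching
per-stage reporting.

## The synthetic generator

`simulate.make_reference` builds uniform-composition random hairpins
(60–90 nt) with one 5′-arm and one 3′-arm mature (22 nt) placed so that
every sampled (offset, length, tail) window stays on the hairpin;
`generate_library` then draws, per read: arm (guide:star 9:1), templated
length (defaults 0.05/0.10/0.70/0.10/0.05 over 20–24 nt), 5′ offset (mass
0.8 at 0, symmetric tails to ±2), a 3′ tail with probability 0.07
(mono:di = 0.9:0.1, nucleotides U/A/C/G = 0.55/0.30/0.10/0.05), the 3′
adapter, and uniform per-base substitution errors at 0.001 across the full
emitted read; 2% of reads are spike-ins.  Defaults are the package's fixed
reference conditions; the length/tail/error values match the simulation
conditions used throughout the acceptance suite, and the unreported
quantities (offset mass, mono:di split, spike fraction, depth per miRNA of
roughly 2,000 reads across 20 hairpins) were chosen once as typical of
real small-RNA libraries.  Quality strings are constant because nothing
downstream reads them.

Any tail base equal to the hairpin base at its aligned position makes the
read `tail_indistinguishable`: under the genome-mismatch definition some or
all of its tail is templated, so the intended call is unrecoverable in
principle.  `score_recovery` therefore excludes flagged reads from NTA
precision/recall and from the parameter comparisons — they would otherwise
bias the estimand itself, not the estimator.  Recovery is compared against
the truth table's *empirical* frequencies at a 4× binomial-SE bound, which
isolates classification error from the generator's own sampling noise.

What the generator does **not** emulate: ligation and PCR bias, quality
decay, secondary-structure-dependent effects, 5′ modifications, indels, and
cross-mapping between paralogous miRNA families.  Passing recovery tests
therefore certifies the classification and aggregation logic under the
stated noise model, not robustness to every artefact of real libraries.

### Closed-form fold expectation

Under the generator, terminal mono-additions at position 23 arise from
templated-22 reads with a distinguishable mono tail
(q₂₂ · tail_rate · w_mono · 3/4), while a single internal mismatch at
position p arises from untailed reads longer than p with exactly one error
there ((1 − tail_rate) · e · P(L > p)).  The expected fold is their ratio
with the denominator averaged over positions 1–22 (≈ 37 at the default
parameters).  The measured fold is required to sit within ±25% of this
value; second-order terms (errors on tailed reads, error-induced false
tails) perturb it by a few percent.

## Numerical and determinism choices

* Ties among equal-mismatch placements: smaller |offset|, then smaller
  start — deterministic and biased toward the canonical 5′ end.
* Collapsed reads are ordered by (descending count, sequence); table floats
  are serialised at 6 significant digits; gzip output pins mtime, so every
  artefact is byte-identical across runs on identical inputs.
* Degenerate inputs: empty libraries produce empty (header-only) tables;
  per-position percentages and the fold are NA (not 0) when their
  denominator is empty; normalization with neither spikes nor reads is an
  error rather than silent identity.
* Read-count conservation (spike + assigned + unassigned = kept input) is
  asserted at every stage boundary and recorded in the run manifest.

## Problem sizes

The reference simulation is 50,000 reads over 20 hairpins (the acceptance
script and recovery tests); end-to-end it takes ~2 s on one CPU because
identical sequences share cached trim and alignment results.  Oracle
certification uses 10,000 randomised instances against the exhaustive
aligner; determinism checks run the full pipeline twice on a 10,000-read
library.

## Known limitations

* 5′ nontemplated additions are out of scope; the anchor window treats all
  5′ variation as templated shifting.
* A di-tail whose first base coincides with the template is reported as a
  mono-tail one position later; whose second base coincides, as an internal
  mismatch.  Both are inherent to the genome-mismatch tail definition, are
  truth-flagged by the simulator, and are documented divergences rather than
  bugs.
* Genome-wide mapping and novel-miRNA discovery are not attempted: reads are
  only compared against provided hairpin annotations.
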