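# Methods

This note documents the models, conventions and design choices behind
the package, in the order the pipeline applies them.

## Coordinates and interval arithmetic

All internal coordinates are 0-based, half-open `[start, end)`.
1-based inclusive dialects (GFF3) are converted at the I/O boundary;
nothing downstream ever sees mixed conventions. Interval sets are
normalized on construction: sorted, validated (`start < end`,
coordinates ≥ 0) and merged, with *touching* intervals merged too
(`[0,100)` + `[100,200)` → `[0,200)`). Adjacency merging is what makes
the coverage identities exact, e.g.
`bp(A∪B) = bp(A) + bp(B) − bp(A∩B)`; the test suite checks all set
operations against a per-base boolean-array reference on randomized
small genomes, where the naive representation is affordable.

Chromosome names must be a subset of the declared chromosome-size
table; a chromosome absent from that table (e.g. the Y chromosome in a
mixed-sex design) is excluded from every denominator rather than
silently counted.

## Pericentromeric map

Pericentromeric heterochromatin is described by per-arm boundary
coordinates (the positions of euchromatin/heterochromatin transitions,
e.g. abrupt H3K9me2 drops) plus whole-chromosome flags for small,
fully heterochromatic chromosomes. A LEFT_OF_BOUNDARY arm contributes
`[0, boundary)`, RIGHT_OF_BOUNDARY `[boundary, length)`. Boundary
coordinates are a required configuration input: the package never
hard-codes "true" coordinates, because published boundary calls depend
on the upstream segmentation method and assembly. The shipped dm6
example config is labelled approximate for exactly that reason, and
inferring boundaries from signal is explicitly out of scope.

## Peak tables and gene sets

Differential peaks carry a direction (UP/DOWN) and the FDR tier at
which they were called, from the fixed vocabulary {0.05, 0.01, 0.001}.
Tier queries are nested: a 0.001 peak also counts at 0.01 and 0.05, so
counts are monotone across tiers. Overlapping records within one
(direction, tier) stratum are merged with a logged warning — they would
double-count bases; a span appearing in *both* directions is rejected
as malformed, since the upstream differential caller's strata are
exclusive by construction.

Differential-expression gene sets use strict inequalities:
`up = {log2FC > t ∧ sig < cutoff}`, `down = {log2FC < −t ∧
sig < cutoff}`. Boundary-equal values are excluded. The threshold
pair (|log2FC| and whether the significance column is a raw p-value or
an FDR) is configuration, not a constant: published analyses use
different pairs for the same data (e.g. ±1.5 with P < 0.003, or ±0.4
with FDR < 0.05), so the choice must stay visible in the config. The
example configs default to 0.4 / FDR 0.05.

## Peak→gene assignment

A curated regulatory-region map (ORegAnno-style) takes precedence: any
overlap ≥ 1 bp assigns the union of genes of all hit regions. Without
a curated hit, the peak gets the single gene minimizing the TSS
distance on the same chromosome.

The distance metric is edge-based and strand-agnostic: 0 when the TSS
lies inside the peak, otherwise the gap to the nearest peak edge
(`start − tss` or `tss − end + 1`). A midpoint-based metric was
rejected so that containment gives distance 0. Ties break to the
lexicographically smallest gene id, making assignment deterministic.
Distance bins are closed on the right: [0, 1000], (1000, 5000],
(5000, ∞); 5000 itself counts as proximal. For curated assignments the
reported distance is the minimum over the region's genes with a TSS on
the peak's chromosome; if none has one, the region is treated as
directly annotating its genes and the distance is 0. Peaks on a
chromosome with no genes and no curated hit receive an UNASSIGNED
sentinel and are dropped from gene sets (with a warning).

## Cross-classification

Each peak is assigned the chromatin colour covering the largest number
of its bases; zero overlap with all five states is UNASSIGNED (the
gray sector). Coverage ties break by the fixed priority
BLACK > BLUE > GREEN > YELLOW > RED. The state segmentation must be
non-overlapping — the source segmentations are partitions, so overlap
signals a malformed file.

"Expressed" is a pluggable predicate; the default derives it from a
TPM column with cutoff TPM ≥ 1. A peak counts as expressed when *any*
of its assigned genes is expressed (relevant only for multi-gene
curated assignments). Genes missing from the expression catalogue
count as not expressed, with a warning. Every breakdown table reports
raw counts and its denominator next to percentages (one decimal
place), so no fraction has an implicit denominator; empty denominators
are errors, never silent zeros.

## Enrichment statistics

Two chi-squared modes are computed for every (query stratum, region)
pair, because the field reports "% bp coverage" while honest inference
needs (approximately) independent units:

* **bp mode** — 2×2 base-pair contingency table, Pearson chi-squared,
  df 1, no Yates correction (counts are large in intended use; the
  correction is available as a flagged variant of the table if ever
  needed). Base pairs inside one peak are perfectly correlated, so
  these p-values are anticonservative and are reported as descriptive
  headline numbers only.
* **peak mode** — goodness-of-fit chi-squared of the overlapping-peak
  count against the region's genome fraction. This is the mode used
  for the enriched/not-enriched flag in the package's own qualitative
  checks.
* **permutation mode** — assumption-free alternative: peaks re-placed
  uniformly within their own chromosome, lengths preserved, collisions
  allowed; statistic is the summed per-peak overlap;
  `p = (1 + #{perm ≥ obs})/(n_perm + 1)`. The test suite verifies its
  type-I error is calibrated at α = 0.05 under the uniform null.

Benjamini–Hochberg runs over all (query, region) pairs of one report
invocation, separately per mode (each family then holds exactly one
p-value per pair); families are never pooled across invocations. The
chi-squared p-values come from the standard chi-squared survival
function and BH from statsmodels; both are cross-checked in the tests
against the closed-form statistic and a literal step-up computation.
Zero-marginal tables are rejected with a pointer to the permutation
mode.

## Synthetic-data generator

The generator emulates the *positional* structure of the study inputs,
not their sequence content: no reads, no signal tracks, no nucleotides.

* **Genome**: configurable chromosome lengths; default toy genome
  10 Mb over five chromosomes. One heterochromatin block per
  chromosome at its right end (centromere-proximal); per-chromosome
  block sizes are proportional with largest-remainder correction so the
  genome-wide heterochromatic fraction f_het (default 0.141) is exact
  to rounding. No in-scope statistic depends on block topology, so one
  block per chromosome is adequate.
* **Genes**: n_genes TSSs (default 400 on the toy genome) placed
  uniformly within a compartment chosen per gene: heterochromatin with
  probability tss_het_bias (default 0.02, reflecting the gene poverty
  of pericentromeric chromatin), euchromatin otherwise.
* **States**: each compartment is tiled with 2–10 kb segments;
  segments are dropped (UNASSIGNED) with the configured probability
  and otherwise draw BLACK/BLUE/GREEN in heterochromatin and
  YELLOW/RED in euchromatin from renormalized configured proportions.
* **Peaks**: per set, lengths are log-normal (median 500 bp, σ = 0.5 —
  a typical ATAC peak-length scale; clipped at ≥ 50 bp), compartment
  chosen per peak by Bernoulli(θ_het), placement uniform and fully
  inside the chosen compartment, so the realized per-peak
  heterochromatin rate is binomial in θ.
* **Tracks**: block unions (~2 kb blocks) constructed so that total
  coverage g and heterochromatic concentration h are exact to rounding
  (largest-remainder allocation across compartment intervals, gaps
  drawn multinomially). Specs with g·h > f_het are rejected as
  infeasible before any work.
* **Expression**: planted UP/DOWN genes (defaults 60/45) draw log2FC
  from N(±2.0, 0.3) with small FDRs; null genes from N(0, 0.3) with
  uniform FDRs; expressed genes (fraction 0.55) get log-normal TPMs
  ≥ 1-ish, silent genes TPM < 1.

The calibrated default spec plants the study-scale conditions:
f_het = 0.141; ATAC-UP 908 peaks at θ = 0.221 and ATAC-DOWN 653 at the
background 0.141 (UP/DOWN ratio 1.39); H3K27ac sets 400/350 at
background; HP1-like track g = 0.118 and H3K9me3-like g = 0.145, both
with h = 0.35; tier mix 0.42/0.28/0.30 reproducing nested tier counts.

Randomness: one root seed, split per artifact through a seed sequence
keyed by artifact name (CRC32), so adding a peak set leaves gene
placement untouched. Same spec + seed ⇒ byte-identical output files.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: GC/mappability bias, peak-width/signal
correlation, clustering of peaks along chromosomes, realistic gene
density gradients, multi-block heterochromatin geometry, and any
coupling between expression changes and peak placement. Conclusions
about a real dataset still require the real interval files and
measured boundary coordinates.

## Problem sizes and runtimes

The shipped verification uses genomes ≤ 10 kb for per-base oracle
checks (where the naive reference is exact and fast), the 10 Mb toy
genome for statistical checks, 500 replicates × 99 permutations for
null calibration, and 100 seeds for the qualitative enrichment-pattern
check; the full suite runs in about a minute on one core.

## Known limitations

* bp-mode chi-squared is anticonservative by construction (documented
  above); the enriched flag a user should trust comes from the
  peak-count or permutation mode.
* The nearest-TSS rule requires same-chromosome genes; inter-scaffold
  assignment is not attempted.
* No GC- or mappability-matched null model and no segmentation-aware
  sampling; the permutation null is uniform within chromosomes.
* Gene identifiers are opaque text; no symbol/ID mapping is attempted.
* No liftover between assemblies; interval sets from different
  assemblies must not be mixed (chromosome-name validation enforces
  this only nominally).
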