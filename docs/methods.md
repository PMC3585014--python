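# Methods

This note records the models, conventions and numerical choices behind
`mnasefrag`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Fragment model and coordinate conventions

A paired-end sequencing pair is treated as one MNase-protected interval,
the span from the leftmost to the rightmost aligned base. All internal
coordinates are 0-based half-open; BED dialects are honored on disk.
Midpoints use the floor convention `start + (end - start) // 2`. Duplicate
fragments are retained by default — recurring protections are signal in
MNase data — with an explicit `deduplicate()` opt-out. BEDPE mates on
different chromosomes cannot form a protected span; they are skipped and
counted, never silently dropped. Chromosome names are matched as exact
strings.

## Size-class statistics

Fragment lengths are integers, so the "area under the curve" of a
unit-normalized size distribution is a discrete sum over 1-bp bins; unit
area is then exactly sum-to-one, and class AUCs over inclusive ranges are
partial sums. Defaults: nucleosomal 141–250 bp, supernucleosomal
251–428 bp, both overridable. The enrichment ratio-of-ratios
(IP *S/N* over input *S/N*) is invariant to sequencing depth by
construction. Group comparisons use a two-sided Welch (unequal-variance)
t-test on per-sample ratios; the test is reported as undefined (an error)
when both groups are constant. Welch is a deliberate choice — the
experimental design it serves compares small groups of samples whose
variances there is no reason to pool.

## V-plots

Bin assignment follows `floor((d + x_half_width) / x_bin)` with the
distance interval closed at both ends and `d = +x_half_width` clamped into
the last bin. The default grid — x ∈ [−1000, 1000] at 5-bp bins (401
bins) by 400 consecutive 1-bp length bins from 25 bp — was chosen so the
bin total is 160,400, with 25 bp matching the smallest fragments the
library protocol this package targets can recover; the y window upper
bound (424 bp) is an inference, and every axis parameter is configurable.
Percent normalization divides by the number of contributing fragments
(×100), so a matrix totals 100; the stored-total check tolerates
6-decimal file rounding (5×10⁻⁷ per nonzero bin). A fragment near several
anchors is counted once per anchor. One caveat of the half-open bin
convention: reflecting all anchors to the minus strand mirrors the matrix
about x = 0 exactly at 1-bp x bins, but offsets interior to a wider bin
can land in the adjacent mirrored bin.

## Signal tracks and anchor summaries

Coverage counts, per base, the fragments containing that base; its
genome-wide total equals the summed fragment lengths. The log2(IP/input)
track first scales both coverage tracks to a common effective depth (the
mean of the two totals — the minimal reading of "input-normalized"), then
computes `log2((ip + c) / (input + c))` with pseudocount c = 0.5 (counts,
post-scaling, configurable); bases where both raw tracks are zero are
masked (NaN) as carrying no information. Ratios are computed per base and
then averaged across anchors, not the other way around; the alternative
(ratio of averaged coverages) weights high-coverage anchors more and is
not implemented.

Aggregate profiles average the track at each offset over anchors,
flipping offsets for minus-strand anchors so everything reads in the
direction of transcription; masked or out-of-bounds positions are
excluded from numerator and denominator alike. Quintile grouping ranks
anchors by mean window signal, splits remainders into the top groups and
breaks ties by the anchors' given order — all deterministic. Heatmaps
order rows by a named metric, descending, ties again by input order;
ranking by the pseudo-metric `"self"` (mean window signal) reproduces the
quintile ordering. Windowed coarsening tiles non-overlapping fixed
windows (40 bp suits lower-resolution turnover data) and takes the mean
of unmasked bases per window. The NDR analysis regresses each NDR's
maximum unmasked signal on its width (OLS R²): a large R² would indicate
that apparent binding merely tracks the amount of exposed DNA.

## Sequence features

Position frequency matrices count bases in anchor-centered windows,
reverse-complementing minus-strand windows; ambiguous bases are tallied
separately so columns always conserve the sequence count. Bendability
assigns each trinucleotide's value to its central base and smooths with
an odd window (default 39 bp); positions without a full window are
undefined, and ambiguous-base trinucleotides are dropped from the window
mean rather than poisoning it. Region classes are compared by Welch
t-test on per-region means of defined profile values; regions shorter
than the window are excluded and counted.

The packaged scale (`data/synthetic_bendability_scale.tsv`) is a
**synthetic** strand-symmetric table: values rise with G+C content plus a
small deterministic per-pair offset, encoding only the qualitative fact
that A+T-rich DNA is stiffer. It is a placeholder for a published
DNase-I-derived table, which the `BendabilityScale.from_tsv` hook accepts
verbatim; absolute bendability differences computed with the synthetic
scale are not comparable to published values. Only the bendability mode
is implemented (no curvature propensity).

## The chromatin simulator

The simulator emulates the statistical structure the analyses assume, not
sequencing itself (no read qualities, errors or aligner behavior).

**Genome.** Sequences are drawn i.i.d. per base at a background GC of
0.38 (budding-yeast-like), with feature intervals (centromeres, CDEII,
NDR sequence, etc.) re-drawn at their own A+T fraction; point centromeres
default to ~90% A+T with a CDEI/CDEII/CDEIII layout (8/84/25 bp, CDEII at
93% A+T). Same-class features must not overlap; validation reports the
offending coordinates.

**Chromatin.** Nucleosome arrays are tiled at a configurable repeat
(default 165 bp; core 147 bp; repeat − core = linker, 18 bp at the yeast
default, 7 bp at the 154 bp fission-yeast repeat). Every TFBS is centered
in an NDR (half-width default 90 bp, with optional seeded per-NDR jitter
of ±25 bp in the pipeline demo so NDR widths vary realistically). Arrays
abut the NDR boundaries they border and, for spans bounded by NDRs on
both sides, tile inward from both ends with one junction gap kept ≥ one
core; bare chromosomes are tiled with a half-repeat phase offset.
Remodeler-spanning protections run from a flanking nucleosome across the
TFBS, one per side; emission picks one side at random per event,
reflecting dynamic one-sided protection.

**Digestion.** Each protected unit is extended by an undigested overhang
(default 14 bp per side) and nibbled by `floor(Exp(extent))` bases per
end. `extent` (bp) is the single digestion parameter: the two-end total
trim is negative-binomial with mode ≈ extent, so the nucleosomal length
mode is 147 + 2·14 − extent — extent 5 gives a ~170 bp peak, extent 15 a
~160 bp peak, and mean length decreases strictly with extent. Emitted
lengths outside [25, 500] (configurable) are rejected and resampled.

**Enrichment.** Units are sampled with per-class weights; the input's
share of spanning protections is an explicit baseline parameter (default
0.05 — the upstream literature does not constrain it, so it is exposed
rather than fixed). The IP's spanning-class weight multiplier needed to
hit a target supernucleosomal/nucleosomal ratio-of-ratios is solved
analytically: the trim distribution's exact pmf gives each unit class's
probability of landing in either size range, and a one-dimensional root
find (brentq on the log multiplier) closes the design. No Monte Carlo
calibration is involved, so recovery tests measure sampling error only.

**Gene coupling.** Gene metrics (expression, turnover, transcription
rate, arbitrary linear-Gaussian units) are jointly Gaussian with a latent
designed enrichment at a requested Pearson coupling, so realized
correlations estimate the target unbiasedly. Demo genomes place a
promoter TFBS ~200 bp upstream of each ORF 5′ end, and
`couple_state_to_genes` rescales promoter protection occupancies by the
gene's designed enrichment (normalized to (0, 1], floored at 0.05).
Occupancy gates the **IP's** sampling weight only: immunoprecipitation
recovers a protection only when the remodeler occupies it, while the
input's residual spanning protection is modeled as a bulk baseline. (If
occupancy scaled both roles it would cancel in log2(IP/input) and no
per-gene signal could exist.)

**Determinism.** Every operation draws from
`numpy.random.default_rng([stream_id, seed])` with a documented stream id
per operation, so one integer seed makes all outputs byte-identical and
operations independently reproducible.

## What the synthetic tests show — and what they do not

Passing recovery tests demonstrates that the analysis code measures what
the generative model puts in: designed enrichment ratios, dyad offsets,
spanning-protection lengths, metric couplings and null behaviors are
recovered at the stated tolerances. They do not validate the biology of
real chromatin: real MNase has sequence bias, real arrays dephase with
distance from the NDR, real NDR widths correlate with promoter class, and
real IP efficiency varies — none of which the simulator reproduces.
Quantities tied to a specific deposited dataset (absolute enrichment
ranges, NDR R² values, bendability differences on real site classes) are
therefore outside what this package can reproduce from simulation.

## Problem sizes and defaults used in the shipped runs

Tests and the acceptance script use a 200 kb single-chromosome genome
with 8 TFBSs and 40 ORFs at 60,000–200,000 fragments per sample; the full
pipeline demo uses 1 Mb, 40 TFBSs, 200 ORFs and 200,000 fragments per
sample and completes in well under a minute on one CPU. These sizes give
sampling errors comfortably below the test tolerances (e.g. the designed
2.5× ratio-of-ratios is recovered within ±0.03 at n = 200,000 against a
±0.25 tolerance).

## Known limitations

- The simulator's fragment emission ignores inter-nucleosome steric
  exclusion and linker-length heterogeneity within an array.
- bedGraph writing drops masked positions; round trips preserve the mask
  but not any distinction between "masked" and "never covered".
- The packaged bendability scale is synthetic (see above).
- `windowed_track` returns per-bp vectors (coarse values broadcast across
  each window) for composability, at the cost of memory proportional to
  genome size.
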