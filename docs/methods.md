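# Methods

This note documents the statistical model, the synthetic-data
generator, the numerical choices, and the limitations of the
`cistrans` package.

## Classification model

### Test statistics

All tests operate on replicate-pooled, normalized integer counts per
channel (F0 strain A, F0 strain B, F1 allele A, F1 allele B).

**Binomial exact tests.** The F0 divergence test treats `f0_A` as a
draw from Binomial(`f0_A + f0_B`, 0.5); the F1 imbalance test does the
same for the hybrid allele counts.  Two-sidedness uses the
minimum-likelihood rule (sum the probabilities of all outcomes whose
point mass does not exceed the observed one).  At p₀ = 0.5 the pmf is
symmetric and unimodal, so the rule reduces exactly to
`P(X ≤ min(k, n−k)) + P(X ≥ max(k, n−k))`; ties occur only at the
mirror outcome and are included by construction.  The null is exact
when, conditional on the total, the count is binomial — true for
Poisson-distributed channel counts of equal normalized depth.

**Fisher exact test.** Trans components are detected as heterogeneity
of the 2×2 table `[[f0_A, f0_B], [f1_A, f1_B]]` under the
hypergeometric conditional law, again with the minimum-likelihood
two-sided rule.  Two code paths give identical answers where they
overlap: an exact integer-arithmetic path for table totals ≤ 400
(weights `C(r1,x)·C(r2,c1−x)` compared exactly, so ties are resolved
without floating-point ambiguity), and a vectorized float path for
genome-scale tables that exploits unimodality of the pmf — the
opposite-tail cut point is located by bisection in O(log support)
log-pmf evaluations, with a 1e-9 log-space tolerance absorbing
rounding noise on exact ties.  Tables with a zero margin are
degenerate point masses; they report p = 1 with a warning.

**FDR.** Benjamini–Hochberg step-up within each of the three families
separately (joint correction across families is not part of the
scheme).  NaN p-values (undefined tests, e.g. zero pooled totals) are
excluded from the ranking and propagate as NaN; a NaN q-value is never
significant.  Significance is strict: q < α with α = 0.01 by default.

### Category assignment

With S0/S1/SC the three significance calls:

| S0 | S1 | SC | category |
|----|----|----|----------|
| 1 | 1 | 0 | cis_only |
| 1 | 0 | 1 | trans_only |
| 1 | 1 | 1 | cis_trans (enhancing if same sign and \|log2 F0 ratio\| > \|log2 F1 ratio\|, else compensating) |
| 0 | 1 | 1 | compensatory |
| 0 | 0 | 0 | conserved |
| — | — | — | ambiguous (all other patterns) |

Collapsed reporting maps cis_only→cis, trans_only→trans, both
cis_trans subtypes→cis_trans, everything else→not_divergent.  Summary
percentages are over the *classified divergent* genes (the four
S0-true, non-ambiguous categories); compensatory genes are not
counted as divergent (their total F0 expression is conserved), and
ambiguous genes are excluded from denominators.  The divergent
fraction of the universe uses the same numerator.

A pseudocount of 0.5 is added to pooled counts for the display log2
ratios only — never inside a test — so scatter coordinates stay
finite.

### Filtering and normalization

A gene enters the analysis universe when at least one channel's mean
raw count across replicates strictly exceeds `min_count` (default 10).
The channel mean is robust to replicate count; strict `>` follows the
usual reading of "more than 10 reads".

Size factors use the DESeq median-of-ratios construction (each
library's factor is the median, over genes positive in every library,
of the count over the gene's geometric mean), rescaled to geometric
mean 1.  Factors are estimated **per library in two groups**:

* the six F0 libraries jointly — so the F0 binomial null of 0.5 means
  equal expression, not equal sequencing depth;
* the F1 libraries from their allele-summed totals, with the factor
  shared by both allele channels of a library — both alleles of a
  hybrid are sequenced in the same library, and a shared factor
  provably cannot distort the allelic ratio.

The groups are deliberately *not* forced onto a common scale.  Every
statistic is within-group (the two binomial tests) or conditions on
its row totals (the Fisher test), so cross-group scale is irrelevant;
and rescaling counts by a constant f far from 1 changes their
conditional variance to 1/f of the binomial null, which would make the
exact tests mis-calibrated (conservative for f > 1, anti-conservative
for f < 1).  This is measurable: forcing all twelve columns onto one
scale (which multiplies F0 counts by ≈√2 and F1 counts by ≈1/√2,
because F1 allele channels carry half a library's depth) destroys the
uniformity of null p-values.  Normalized counts are rounded
half-to-even to integers before pooling, since exact tests need
integer counts; banker's rounding avoids systematic upward bias.

When no gene is positive in every library the estimator has no
reference; an explicit `allow_pseudo_reference` flag switches to
per-gene geometric means over positive entries only.

### Replicate handling

The exact tests consume a single count per channel, so normalized
counts are summed across replicates before testing.  Replicate-level
biological variance therefore does not enter the per-gene test — a
property of this class of pooled exact-test pipelines, verified
instead through the simulation-based recovery and calibration checks.
A replicate-aware beta-binomial or negative-binomial GLM would relax
this but is a different method (see Limitations).

## Synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream property is verified.

**Count model.** Gene baselines are log2-normal (default mean 8, sd 2,
i.e. typical counts of a few hundred per library).  Categories are
apportioned deterministically from the configured proportions
(defaults: 80% conserved, 10% cis-only, 7% trans-only, 3% cis-trans —
a predominantly-cis architecture with ~20% divergence, matching the
design being emulated) and shuffled.  Effect magnitudes are drawn
uniformly from a configurable log2 range (default 0.5–2) with random
sign; cis effects attach to the B allele.  Channel means per library
with planted factor s:

```
F0_A = s·μ          F0_B = s·μ·2^(cis+trans)
F1_A = s·μ/2        F1_B = s·(μ/2)·2^cis
```

F1 per-allele baselines are μ/2 so a hybrid library's total depth
matches a parental library.  One factor is planted per *library*
(each F0 replicate is its own library; an F1 library spans both
allele channels), drawn from Uniform(0.7, 1.3).  Counts are negative
binomial with variance μ + α·μ² via the (1/α, 1/(1+αμ)) shape/p
parameterization; α = 0 degenerates to Poisson.  Three RNG streams
(counts, reads, motifs) are spawned from the master seed at fixed
offsets, so enlarging one simulation never perturbs another.

**Default dispersion α = 0.001.**  The pooled exact-test framework
models sampling noise only; its calibration and recovery guarantees
hold when extra-Poisson noise is a small fraction of sampling noise
(overdispersion inflates the Fisher heterogeneity statistic's standard
deviation by ≈ √(1 + α·n/3) at pooled depth n over three replicates).
The default emulates the technical-noise regime in which the method is
valid; α is a user parameter, and the consequences of raising it are a
documented limitation, not a correction the pipeline makes.

**Read simulator.** Per gene, two equal-length windows (default 24 nt)
differing at `snps_per_gene` positions are generated; each read embeds
exactly one allele's window at a random offset inside random flanking
sequence, with zero sequencing error and constant quality.  Allele B
receives round(depth · 2^cis/(1+2^cis)) reads per replicate — the
allelic ratio implied by the planted cis effect, planted exactly so
the counting round trip has an exact expected answer.  Read order is
shuffled.  Accidental window collisions in random flanks have
probability ≈ 4⁻²⁴ per position and are negligible at the simulated
scales.

**Motif simulator.** Hit counts are Poisson with rate
`bg_hit_rate · seq_len` per gene and motif; in the foreground set only,
one planted motif's rate is multiplied by `fg_rate_multiplier`.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: mapping bias and reference alignment
artifacts, sequencing error, probabilistic read-to-allele assignment
uncertainty, parent-of-origin (reciprocal-cross) effects, isoform
structure, correlated biological replicate variation, and GC/length
effects on counts.  Results on real data additionally depend on the
upstream mapping/assignment pipeline that produces the count matrix.

## Cross-condition comparison

Two fitted conditions are first harmonized: the universe is restricted
to genes expressed in both, and q-values are re-adjusted within the
shared universe (BH depends on the test family's size).  Trans-set
operations require identical universes by construction.  The
per-category contrast reports the percentage fold ratio and a
two-sided Fisher exact test on [category vs not] × [condition a vs b]
over divergent genes; that test is an addition of this implementation
(flagged in its output), because a proportion shift without any
uncertainty measure cannot be checked.

## Enrichment statistic

The dual statistic consumes externally produced motif-hit tables; no
motif scanning or background construction is performed here.  The
Z-score is the nucleotide-level binomial statistic with the background
rate as null (half-hit continuity correction when the background has
zero hits); the Fisher score is −ln of the one-tailed (enrichment)
hypergeometric p on gene-level presence.  Significance requires
Z > 10 and Fisher score > 7, both strict; results are ranked by Fisher
score.  These cutoffs are deliberately extreme: under the null fixture
the observed false-positive rate is far below 1%.

## Numerical choices and degenerate inputs

* Binomial/Fisher ties: resolved exactly (integer arithmetic) for
  small tables; 1e-9 log-space tolerance for large ones.
* Zero-margin Fisher tables: p = 1, warned.
* Zero-total binomial: NaN, propagated, never significant.
* Zero-variance allele fractions in the t-test: p = 1 if the common
  fraction is 0.5, else p = 0 (continuity of the decision rule);
  fewer than two usable replicates → `insufficient_data`.
* The allelic-balance verdict has four values: `allele_biased`
  (p < 0.001, the displayed significance level), `balanced`
  (p ≥ 0.05), `indeterminate` between, `insufficient_data`.
* Expression filter boundary: a channel mean exactly at the threshold
  is excluded (strict inequality).
* Floats in all emitted tables carry six significant digits; gene
  order is preserved from input; reruns are byte-identical.

## Problem sizes used in the verification suite

The acceptance checks run at sizes chosen to give stable statistics
on a single CPU: 5,000 genes × 50 seeds for null calibration (with
α = 0 — the matched conditional-binomial null, the regime in which
p-value uniformity is a meaningful check — and baseline log2 mean 11,
because exact-test p-values are discrete and approach uniformity only
as depth grows); 2,000 genes × 20 seeds for category recovery with
effects ≥ 1 log2 and pooled depth ≥ 500; 5,000 genes × 50 seed pairs
for the four-fold trans contrast; 100 genes × 1,000 reads for the
round trip; exhaustive enumeration up to row margins of 30 for the
exact-test oracles.

## Limitations

* Pooling across replicates ignores biological variance; with real
  between-animal overdispersion the binomial and Fisher tests are
  anti-conservative, inflating trans and cis-trans calls.  This is a
  property of the underlying classification scheme; users with
  replicate-rich data may prefer a count-GLM alternative for the
  significance calls while keeping this package's category logic.
* The F0 null of 0.5 after normalization assumes most genes are not
  divergent (median-of-ratios reference) — violated under global
  expression shifts.
* Exact substring counting requires error-free reads over the SNP
  window; real amplicon data needs upstream quality control, and
  windows shared between paralogs will warn but still double-count.
* The enrichment module trusts its input hit tables; biases of the
  scanner that produced them (motif thresholds, background choice,
  conservation filtering) pass through unexamined.
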