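# Methods

## Growth model

Each well's fluorescence-derived cell abundance is treated as exponential,
`N(t) = N0 · exp(k t)` with growth rate `k` [1/h] and doubling time
`DT = ln(2)/k` [h].  `k` is estimated by ordinary least squares on
`(t, ln N)` (via `numpy.polyfit`), using by default every time point with a
strictly positive value; non-positive values are dropped before the log
transform rather than floored, and a well with fewer than two positive
values carries a `too_few_points` flag instead of an estimate.  A fit
window (`fit_start_h`) can exclude early time points, e.g. the media-change
settling period; the default uses the whole trace.  A trace whose values
are all equal gets `k = 0` exactly and a `nonpositive_rate` flag; `DT` is
reported only for `k > 0`, and `DT·k = ln 2` holds to machine precision by
construction.

Subtractive normalization is exposed as a separate derived-trace operation
(per-timepoint subtraction of the matched untreated-well mean within the
same plate and line); doubling times are computed on raw treated traces,
since a log-linear fit of a background-subtracted signal would estimate the
rate of a different quantity.  Derived traces may be negative, so trace
non-negativity is enforced at ingest, not in the container.

## Replicate quality control

Three rules fire in a fixed order within each plate × line × condition
replicate set, and every removal is recorded with its rule:

1. *continuous growth*: a well must contain a contiguous run of weakly
   increasing values (each point ≥ its predecessor) spanning ≥ 48 h,
   bounds inclusive.  Weak rather than strict monotonicity is used because
   strict increase is fragile under multiplicative noise at adjacent time
   points.  Wells with no usable doubling time (too few positive points, or
   `k ≤ 0`) are removed in this pass under their own reason codes.
2. *Tukey IQR*: doubling times strictly outside
   `[q1 − 1.5·IQR, q3 + 1.5·IQR]` are removed, with quartiles computed by
   linear interpolation between order statistics (the common default
   sample-quantile convention); values exactly at a fence are kept.
3. *minimum count*: a set with fewer than 3 surviving doubling times is
   marked invalid and excluded from comparisons.

Rule 2 is applied exactly once on the survivors of rule 1; re-applying it
to its own output could remove further values (quartiles shift), so
idempotence is deliberately not claimed.

## Treatment comparisons

Doubling-time change (`DT_treated − DT_untreated`) and ratio are computed
only within a plate (cross-plate pairs are refused), from valid summaries'
mean kept doubling times.  Genotype-level differences in ΔDT use a
two-sided Mann-Whitney U test: exact by enumeration when both samples have
≤ 8 observations and no ties (delegated to `scipy.stats.mannwhitneyu`,
cross-checked in the tests against an independent full enumeration),
otherwise a midrank, tie-corrected normal approximation whose continuity
correction shrinks `|U − μ|` toward zero — so identical samples report
p = 1 rather than the slightly smaller value a naive correction gives.
The ratio-vs-untreated-DT association is a Pearson correlation with a
t-distribution p (n − 2 df), refusing inputs with fewer than 3 points or
zero variance.  Whole-curve treatment effects use a two-way fixed-effects
ANOVA (treatment × time with interaction, type II sums of squares) through
statsmodels; pingouin serves as an independent oracle in the test suite.

## DEG thresholding and concordance

A record passes thresholds when `p_adj ≤ p_max` and `|FC| ≥ fc_min`, both
boundaries inclusive; `fc_min` is per-molecule configuration (defaults:
genotype/fasudil 1.5, sphingosine 1.2, EGCG and apigenin 1.1, isoxsuprine
none, i.e. the FC condition is vacuous).  Fold-change direction is the sign
of the (linear or log2) fold change; `|FC| = 2^|log2FC|`, and a reader
accepts either column, deriving the other.  Classification of a treatment
DEG against the genotype set uses direction only: absent → novel, opposite
sign → corrected (bucketed corrected-down / corrected-up by the treatment
sign), same sign → worsened.  "Corrected" deliberately does not require the
expression level to return to euploid magnitude — the operational criterion
is opposition of direction.  A zero fold change has no direction and raises
an error naming the gene.  Gene identity is an exact, case-sensitive string
match; alias resolution is left to user-supplied column maps.  Percentages
are reported to one decimal: corrected and worsened over the overlap count,
novel over the full treatment DEG count; empty denominators report
undefined, never 0/0.

## Synthetic data

The growth simulator emulates the screen design: 120 h of culture imaged
every 12 h, 4 replicate wells per line × condition, euploid baseline
doubling times ~N(32, 3²) h and trisomic ~N(42, 6²) h (truncated positive),
an additive treatment effect on DT per genotype (defaults −3 h euploid,
−9 h trisomic), and multiplicative log-normal measurement noise with unit
mean and configurable CV (default 0.05).  A configurable fraction of wells
"fails": growth stops at the last imaging time before a failure time drawn
uniformly from [12, 44] h, followed by a 4%/h decline, so failing wells can
never satisfy the 48-h continuous-growth rule and the rule-1 removals can be
compared to planted flags exactly.  All draws come from one seeded generator
in a documented order (line DTs, fail flags, fail times, noise), so runs are
bit-reproducible and the Bernoulli procedure can be replayed independently.

The DEG simulator plants category counts by rounding the configured
fractions (a nonzero fraction that rounds to zero is a configuration
error): a genotype-dysregulated set, an overlapping treatment-responsive
subset split into corrected (opposite sign) and worsened (same sign), novel
treatment DEGs outside the signature, and null background genes with
|log2FC| < log2(1.5).  Planted DEGs draw adjusted p uniformly from
(1e-6, 0.049] and nulls from (0.05, 1], so only the ≤/> 0.05 relation is
meaningful — the pipeline thresholds on p and never interprets its
magnitude.  Effect sizes are normal in |log2FC| (mean 1.0, SD 0.35),
truncated at log2(1.5) so planted DEGs clear the default cut-off.  A
configurable gene subset is tagged chromosome "21" to exercise the
chromosome filter.  Exact-count constructors (`make_partition_tables`,
`make_shared_tables`) additionally build synthetic table pairs with an
exactly specified partition / shared-response structure, for exercising the
pipeline at the scale of published comparisons whose underlying tables are
not redistributed with the package.

What the simulators do *not* emulate: plate-position effects, time-varying
noise, media-change transients, partial-failure phenotypes (slowing rather
than stopping), correlated genes, p-value/effect-size coupling, or compositional
normalization artifacts in the expression tables.  Passing tests therefore
demonstrate correctness of the estimators and classification rules under
the stated model, not robustness to every artifact of real plates or
sequencing batches.

## Numerical choices and scales

Quantiles: `numpy.percentile` linear interpolation.  OLS: `numpy.polyfit`
degree 1.  Exact-zero slope is forced for flat traces to avoid
float-noise sign flips.  The Mann-Whitney asymptotic p is capped at 1.
Concordance sets are hash sets; record order never affects results.  Test
and verification problem sizes (20-seed sweeps, 3 lines per genotype and
4 replicates per simulated screen, 20 000-gene tables for the
published-scale checks, 1000-input oracle sweeps) were chosen so the full
suite exercises every rule at realistic scale while remaining quick to run
routinely.

## Known limitations

- The additive treatment effect on DT is constant per genotype, so the
  simulated ratio-vs-untreated-DT correlation does not reproduce
  effect-scaling-with-slowness phenotypes; the correlation operation is
  validated on constructed inputs instead.
- The exponential model is fitted to the entire (positive) trace; density
  saturation late in culture would bias `k` downward.  The configurable fit
  window is the provided mitigation.
- DEG tables are consumed, not produced: no differential testing,
  normalization, covariate correction or pathway enrichment is performed.
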