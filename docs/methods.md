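# Methods

## Model and procedure

`dmcap` detects differential methylation from MBD-capture sequencing by
comparing regional methylation intensities between a case and a control
group.  The intensity of a region is the total number of bases of aligned
short reads intersecting it (per-base, clipped at the region boundaries);
replicate intensities are averaged within each group before comparison.
The differential measure is the offset fold-change

    f = (I_case + βL) / (I_control + βL),     M = log2 f

where `L` is the read length and `β` an offset multiplier.  `βL` enters as a
single additive offset in bases.  It bounds the denominator away from zero
and shrinks the fold-change of weakly covered regions toward 1, so that
low-coverage noise cannot masquerade as strong differential methylation;
for intensities far above `βL` the statistic converges to the raw ratio.
`M = log2 f` is the minimal signed transform that makes hyper- and
hypomethylation symmetric about zero.  The statistic is deliberately
simple: with 2–3 replicates per group there is no information to fit
per-region variances, and all inferential weight is carried by the
permutation null.

### Segmentation into methylation units

Methylation of nearby CpG sites is spatially correlated, so single sites
are not independent test units, and fixed windows mis-match the variable
length of correlated blocks.  Segmentation proceeds in two deterministic
passes:

1. **Merge**: coordinate-sorted CpG sites are merged greedily into
   *methylation intervals*; a new interval starts whenever the gap to the
   previous site exceeds `gap_threshold` (or the chromosome changes).
2. **Split**: within an interval, the Pearson correlation of adjacent site
   intensity profiles is computed across *all* samples (groups pooled, so
   segmentation cannot leak label information into the null), and the
   interval is cut at every adjacent pair whose correlation falls below
   `corr_threshold`.  Units are the maximal uncut runs; they partition the
   interval's sites exactly.

Thresholding (rather than cutting only at local minima of the correlation
sequence) is the default break rule because it is deterministic,
order-free, and directly encodes "a unit contains highly correlated nearby
sites"; a `local_minimum` mode is available for sensitivity analysis.  A
pair with zero variance in either profile is assigned correlation 0 — an
undefined Pearson value must not silently join or split a unit.

### Permutation inference

The null distribution of `M` is estimated by permuting group labels over
samples (preserving group sizes) and recomputing `M` for every region.
Permuted scores are pooled across regions within **length strata**
(quantile bins on member-site count for units, bp length otherwise),
because background variability depends strongly on unit length: longer
units aggregate more reads, and their `M` is tighter around zero.  Strata
whose pool would fall below `min_stratum_null` values are merged with a
neighbor.  When the number of distinct label assignments is at most
`n_perm` (e.g. C(6,3) = 20 for 3 vs 3), all assignments are enumerated and
the estimate is exact; otherwise `n_perm` random permutations are drawn
from a seeded generator.

One-sided p-values use the add-one tail estimate
`p = (1 + #{null ≥ M}) / (1 + N)` (mirrored for hypomethylation), which is
strictly positive and retains finite-sample validity; ties count into the
rejection tail (conservative).  The null of `M` can be asymmetric, so the
two directions are tested separately; the sign of `M` routes each region
into exactly one direction.  Benjamini–Hochberg correction is applied per
direction over all regions of one role (one-sided p-values are marginally
uniform under the null, so the BH pool is valid); Bonferroni is available
by configuration.  Region roles (promoter, CpG island, CpG site, unit) are
never mixed in one null or one correction pool.

### Events-exclusive iteration

A permutation null estimated from all regions mixes sporadic fluctuations
(which obey the null) with true methylation events (which do not); the
events inflate the null's tails and make the test conservative.  The
detector therefore iterates: round 0 estimates the null from all regions;
each subsequent round excludes from the null-building pool the union of
all *events* observed so far and re-estimates.  The iteration stops when
the called set is unchanged between rounds, or after `max_iter` rounds
(flagged, not fatal).  `max_iter = 1` gives the single-pass scheme.

The exclusion set is the regions one-sided significant at `α₀` *before*
multiple-testing correction; reported calls still require the corrected
`q < α₀`.  This asymmetry is deliberate and is the one genuinely open
design point of the scheme.  The exclusion step's job is to remove
everything that plausibly deviates from the null — an estimation concern,
where a lenient criterion is appropriate — while the call step's job is
error control.  Excluding only corrected calls cannot bootstrap: with
3 vs 3 enumeration each region places exactly 1/20 of its null mass at its
own observed `M`, so with a planted fraction π the pooled-null tail weight
at the planted effect is π/20; at π = 5% this equals α₀·k/m at the BH
boundary and round 0 calls nothing, leaving the contamination in place
forever.  Raw-p exclusion removes it in one round at the cost of trimming
~α₀ of genuinely null regions from the pool, a mild and measured effect:
on exchangeable data the final call count stays at zero and the KS
distance of null p-values from uniform stays below 0.03, while on planted
mixtures the iteration raises sensitivity from near zero (single pass) to
>99% at an empirical FDR of ~0.06 (10 seeds, bound 1.5·α₀ = 0.075).

### Small-RNA differential expression

Counts per small-RNA feature are TPM-normalized: each count is divided by
the feature length in kb and the per-sample rates rescaled to sum to 10⁶.
Feature lengths default to 1 kb (TPM then reduces to counts-per-million),
appropriate because small-RNA species lengths are nearly constant within a
subtype.  The test statistic is the difference of group means of
`log2(TPM + 1)` — symmetric, robust at n = 4 per group, with the
pseudo-count declared in configuration.  Group labels are permuted
(enumeration when feasible, in which case the exact two-sided p is the
tail fraction including the identity assignment; add-one estimate when
sampling); BH q-values are computed over features and significance is
`q < 0.05`.  A model-based test variant and cross-sample
re-normalization / batch correction are intentionally out of scope.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `L` | 36 | bases | short-read length of the capture libraries |
| `β` | 10 | — | offset multiplier; `βL` = 360 bases damps weak signals |
| `gap_threshold` | 300 | bp | typical CpG clustering scale; larger gaps separate intervals |
| `corr_threshold` | 0.3 | — | weak-correlation floor below which adjacent sites separate |
| `min_samples_for_corr` | 4 | samples | below this, adjacent correlations are too noisy to segment on |
| `n_perm` | 1000 | — | permutations per round; enumeration replaces sampling when possible |
| `n_length_strata` | 5 | — | quantile bins on unit length |
| `min_stratum_null` | 50 | values | below this a stratum merges with its neighbor |
| `α₀` | 0.05 | — | corrected significance threshold |
| `max_iter` | 10 | rounds | iteration cap for the events-exclusive scheme |
| pseudo-count | 1 | TPM | stabilizes `log2` at low expression |

`gap_threshold`, `corr_threshold` and the break rule are mandatory
configuration entries precisely because they are judgment calls: results
always declare the values they were produced with.

## What the synthetic generator emulates — and what it does not

The generator produces the study conditions the pipeline is designed for:
non-overlapping promoters in fixed slots on toy chromosomes; CpG sites
clustered inside promoters with mostly small (10–150 bp) and occasionally
large (400–900 bp) gaps, so both the merge and the split paths are
exercised; negative-binomial read counts (dispersion 0.1 — capture assays
are overdispersed; Poisson as the analytic-check mode) at 3 replicates per
group; planted hyper/hypomethylated units with multiplicative effects and
a recorded truth.  Intra-unit correlation is induced by a shared
per-(unit, sample) gamma factor split from the per-site noise, with ρ
(default 0.7) setting the shared share of the overdispersion — this is
what makes correlation-based segmentation testable against known unit
boundaries.  Unit-level matrices scale mean intensity with member-site
count, reproducing the length-dependent background rates that motivate
stratification.  Small-RNA tables draw log-normal baseline abundances with
negative-binomial noise at 4 replicates per group, with subtype
composition profiles that are tRF-dominant ("sperm") or miRNA-dominant
("mammary").

The generator does **not** simulate raw sequences, base qualities, mapping
ambiguity, GC or capture-efficiency bias, chromosome-specific null
asymmetry, or batch structure.  Passing tests therefore demonstrate that
the statistics behave as designed under the stated noise model — they do
not certify performance on real libraries, where alignment artifacts and
covariates add failure modes outside this package's scope.

## Numerical choices

- Coordinates are 0-based half-open throughout; 1-based inputs are
  converted at the readers.
- Group aggregation is the replicate mean (not sum), keeping `f`
  comparable across unequal replicate counts.
- No between-sample depth normalization by default (an equal-total-bases
  rescaling is available behind a flag, off by default).
- Add-one p-values; ties into the rejection tail; `p` floor is
  `1/(1+N)`, so an `α₀ → 0` limit provably yields zero calls.
- Stratum quantile edges are computed once from all scored regions, so
  stratum membership is stable across iteration rounds.
- Degenerate inputs: zero-variance profiles get correlation 0; a
  single-site interval yields one single-site unit; zero-read samples
  produce all-zero columns with a warning; excluding every region from
  the null is an error.
- All randomness flows from one seeded `numpy` generator per run;
  identical configuration and seed give byte-identical output files (no
  timestamps are written).

## Problem sizes used in the checks

The bundled verification runs use 2000 units at 3 vs 3 replicates (where
label enumeration is exact at 20 assignments), 10 generator seeds for the
stochastic claims, 200 random instances for the per-base counting oracle,
exhaustive cut-set enumeration up to 12 sites, and 500-feature small-RNA
tables at 4 vs 4.  These sizes give stable estimates of the reported
rates; all checks are deterministic given the seed.

## Known limitations

- Replicate-level covariates, paired designs and chromosome-specific
  nulls are not modeled; asymmetry is handled only through one-sided
  testing.
- The M-score is defined here as `log2 f`; other capture-sequencing
  analyses may use a different signed transform of the fold-change, so
  the definition is isolated behind `m_score` for easy substitution.
- With very small designs (2 vs 2) the enumeration has only 6 assignments
  and p-values are coarse; pooling across regions within strata is then
  essential, and single-region inference is not meaningful.
- The small-RNA branch implements the permutation test only; model-based
  testing and batch correction are explicit non-goals.
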