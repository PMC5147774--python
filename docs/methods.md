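# Methods

This note documents the models, parameter choices and numerical conventions
behind `denovotrio`, and what the synthetic cohort does and does not emulate.

## Calling model

Seven criteria are evaluated in a fixed order and the first violation is
reported (useful for filter diagnostics); acceptance itself is
order-independent.  Comparisons follow the thresholds' wording exactly:
"more than" / "above" / "below" are strict, "at least" is inclusive, and the
ReadPosRankSum window [−6, 6] is inclusive at both ends.  The MQRankSum
bound is −6 by default — a Z-score bound symmetric with ReadPosRankSum —
and is configurable (`FilterThresholds.mq_rank_sum_min`).  Likelihood-ratio
thresholds are applied on the natural scale as stated (10^10, 200, 10^4)
but carried in log10 internally to avoid overflow.

## Callability

C_f(x) = P(a true de novo at x in family f passes the filters) is evaluated
by exact enumeration of the read model, conditional on the three members'
quality-read depths:

* child alt reads k ~ Binomial(d_child, ½); criteria 1 (likelihood ratio)
  and 5 (k ≥ 0.3·d) are deterministic functions of k; the both-strands
  criterion contributes P = 1 − 2^(1−k) for k ≥ 2 under an even strand
  split;
* each parent's alt reads j ~ Binomial(d_parent, ε), ε = 0.005 per read by
  default, with genotype likelihoods computed from the same binomial model;
* the depth floor (15 / 8 / 8) enters as a hard indicator;
* criteria 3 (population) and 7 (site metrics) are depth-independent and
  enter as constant pass probabilities, 1.0 by default and configurable.

Results are memoised per depth triple, so summing C_f over a genome
represented as piecewise-constant depth windows costs one enumeration per
distinct triple.  A Monte-Carlo sampler of the identical model serves as an
independent test oracle (agreement within ±0.003 at 2×10⁵ draws).

One counter-intuitive property is worth stating: callability is *not*
strictly monotone in depth.  The integer thresholds (k ≥ ⌈0.3·d⌉, fixed
likelihood-ratio cutoffs over a growing read count) produce a small
sawtooth — e.g. a parent at depth 9–15 passes slightly less often than at
depth 8, until the tolerated error-read count increments.  The dips are
below 0.05 and the coarse trend (doubling depths) is monotone; the property
test asserts exactly that.

Indel callability reuses the same enumeration with a higher per-read error
rate (0.01 by default), reflecting that indel evidence is noisier; it is
never above the SNV callability at the same depths.

## Rate estimation

Wilson score intervals are used for every count-based proportion and for
the rates (count over a fixed denominator), via
`statsmodels.stats.proportion.proportion_confint`; at boundary counts the
interval is clamped to [0, 1] exactly.  The parental-age model is ordinary
least squares of per-family counts on both ages jointly — the simplest
model consistent with a linear age effect; a Poisson GLM with identity link
is available (`poisson_age_regression`) for sensitivity checks.  Reported
rates are formatted to three significant digits.

## Clustering and null models

Distances live on a concatenated-chromosome axis (karyotype order, no
gaps), which fixes the length of the distance lists across simulation
replicates.  Forward-scan distance lists (next mutation from anyone / the
same individual / a different individual) reproduce the QQ construction;
per-rank medians are taken over replicates, truncating the
different-individual list to its common prefix length (its tail length can
vary by one or two entries at the end of the axis).

Clusters are single-linkage chains of same-individual mutations with
consecutive gaps strictly below 20 kb, so a cluster may span more than
20 kb through short links.  Clusters are additionally required to lie on
one chromosome; `same_chromosome=False` restores pure concatenated-axis
behaviour.  "Adjoining" means distance exactly 1; runs of three or more
adjacent SNVs count as a single multi-base event, and the pairs-to-events
halving applies only to isolated pairs.

The label-permutation null permutes individual identifiers with positions
fixed (median over rounds); the independence-simulation null redraws every
individual's per-context mutation counts at positions weighted by the
cohort-mean callability.  Subsampling to a target per-individual mean uses
per-mutation Bernoulli thinning at rate target/observed.  Permutation
p-values use the add-one convention with ≥ (conservative); a strict >
variant is available.

## Synthetic cohort

The generator's defaults are the study conditions: 283 trios; parental
ages bivariate normal with means 31.6 / 28.9 years, SDs 5.5 / 5.0 and
r² = 0.65, truncated at 15 years; per-family SNV counts Poisson around
intercept + 1.7·p + 0.34·m with the intercept set so the cohort mean is
62.9; indels Poisson around a 0.1 / 0.01 slope model with mean 4.53 and a
2.6:1 deletion:insertion ratio (geometric lengths, capped at 35 / 8 bp);
the six (context × transition/transversion) spectrum weights follow the
study's mutation-type table.  A fraction 0.031 of SNVs is emitted as MNM
clusters: sizes geometric on {2..8} (p = 0.79, mean ≈ 2.3), consecutive
gaps from a mixture (19% tandem, 10% uniform 2–10 bp, 28% log-uniform
10 bp–2 kb, 43% log-uniform 2–20 kb) giving a median clustered distance
near 525 bp; 20% of tandem pairs are forced to the polymerase-ζ signature.
The dispersion of counts beyond the age model is Poisson — the study data
do not constrain it further, so it is the parsimonious choice.

The genome is desk-scale by default — 50 Mb over two chromosomes at GC 0.41
with CpG dinucleotides thinned to 0.25 of their i.i.d. expectation — while
per-family *counts* stay at study scale.  Consequently absolute per-base
rates are ~50× the human value and, at 20 kb, incidental same-individual
clustering is ~5% rather than ~0.1%; scale-invariant quantities (slopes,
ratios, the clustered excess over the permutation null, spectra) are the
meaningful outputs, and the tests target those.  Bases are drawn i.i.d. at
a GC value pre-compensated by a fixed-point iteration so the post-thinning
GC matches the configuration.

Coverage is piecewise-constant over 10 kb windows (Gamma-Poisson across
windows, mean depth 35), and a site's depth equals its window's depth — so
the callability enumeration is exact for the simulated data, which is what
makes the recall-vs-callability calibration test sharp.  Observations at
truth sites carry heterozygous child evidence and error-only parental
reads; background sites are homozygous reference, with 10% turned into
inherited polymorphisms (one heterozygous parent, a high population
likelihood ratio) to exercise criteria 2 and 3.  Site metrics are drawn
from standard-normal (rank sums) and exponential (FS, mean 3) nulls, so
true sites fail criterion 7 with probability ~1.3×10⁻³.

Replication-timing tracks are sums of Mb-scale sinusoids (range ≈ 20–80,
high = early) shared across five simulated individuals plus small
individual deviations, with bin-to-bin changes clipped at a slope cap;
crossover bins are Gamma-length (mean 201 kb) intervals, Poisson 0.65 per
parent.  Mutation placement is independent of both tracks by default, so
the covariate analyses have a true null on the default cohort;
effect-recovery tests construct biased placements explicitly.

What the generator does **not** emulate: mapping artefacts and alignment
error (false positives arise only through the modelled read noise, so
specificity estimates are optimistic); mutation-rate heterogeneity along
the genome beyond the three context classes; sex chromosomes; recurrent
mutations shared between families; indel-specific alignment failure.
Passing tests therefore validate the statistical machinery, not the
behaviour of the filters on real sequencing artefacts.

## Covariate analyses

Replication signals are consumed as bedGraph intervals and averaged
positionwise across individuals, dropping positions with no data.  For the
association analyses the genome is aggregated per (signal value, context
class), with signal values rounded to two decimals to bound the design
size; deciles are defined on the callability-weighted signal distribution
(each decile holds ~10% of callable mass).  The logistic regression weights
the mutated fraction by the callable mass; the Cochran–Mantel–Haenszel
combined odds ratio over the three context strata uses the Mantel–Haenszel
estimate with the Robins–Breslow–Greenland interval, computed directly
because the "non-mutated" margins are non-integer callable masses (it
matches `statsmodels.StratifiedTable` exactly on integer tables).
Zero-margin strata drop out of the sums naturally; no continuity
correction is applied.

Crossover bins are half-open [start, end) in 0-based coordinates; a
1-based call at p overlaps iff start < p ≤ end.  The permutation test
reassigns whole per-family bin lists by a uniform random permutation
(derangements not enforced) over the families that have mapped bins;
all pairwise family-by-binlist overlap counts are precomputed so each
round is an index lookup.

## Problem sizes

Default test and acceptance runs use: a 50 Mb genome with 300 trios for
the end-to-end pipeline (~1 minute); 2000 families for age-slope recovery;
500 replicates for the study-scale independence null on the full 2.45 Gb
axis; 100–500 rounds for permutation tests inside the suite.  These sizes
keep every Monte-Carlo interval comfortably inside the asserted
tolerances.
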