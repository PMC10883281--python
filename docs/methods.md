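# Methods

## Hotspot definition and counting conventions

A hotspot is a unique genomic position carrying the same alternate allele in
two or more *distinct* samples (alternate-specific mode); position mode drops
the equal-alternate requirement. Mutation types (SNV, MNV, insertion,
deletion) are always grouped separately and never merged into one hotspot. A
sample reporting the same event twice counts once: recurrence is defined
across samples. For comparison against the expected models, hotspot counts
are collapsed to at most one hotspot per position (if both C>A and C>T recur
at a site, that is one hotspot), because the models compute per-position
hotspot probabilities.

Coordinates follow the two input conventions: mutation tables are 1-based,
all region files (BED) are 0-based half-open; conversion happens only at I/O
boundaries.

## QC filters

Mutations are removed, with the first failing rule recorded, in this order:
unknown contig; identical reference and alternate; reference allele
disagreeing with the genome; an ambiguous base within ±2 bp of the start
position; complex indels (mixed insertion/deletion such as GTG>GAAA); outside
the high-mappability mask; inside the blacklist; on a population-variant
position; inside a driver region. Duplicate samples are flagged when the
number of identical mutations between two samples exceeds 10% of the sum of
their burdens; the flag is reported, removal is the caller's decision.
Hypermutators are samples exceeding both 10,000 mutations and the Tukey upper
fence (P75 + 1.5·IQR) of the cohort's per-sample counts; both conditions must
hold, so a small cohort of uniformly heavy samples is not flagged.

## Bin system

Contigs are tiled into consecutive non-overlapping bins of a fixed width
(default 1 Mbp); a shorter trailing bin is emitted but flagged and excluded
from downstream selection. Mappable-bin selection computes each full-width
(autosomal, where contig metadata is provided) bin's fractional overlap with
the mappable region set and keeps bins strictly above the first quartile of
that distribution. The quartile uses linear interpolation; the strict
inequality and tie exclusion follow from reading "above the first quartile"
literally — the rule, not any particular bin count, is normative. Sub-bins
(500 Kbp down to 10 Kbp) partition each kept bin exactly, so a target width
must divide the parent width; children inherit the parent id, and census
totals are conserved channel-by-channel under any partition.

## Signature machinery

Catalogs count each SNV's pyrimidine-collapsed trinucleotide/alternate
channel (96 channels, COSMIC ordering). Exposure fitting is column-wise
non-negative least squares. The subset search enumerates all signature
combinations of size 1..kmax, fits each, and ranks by the Gaussian
least-squares AIC, `n_obs·ln(RSS/n_obs) + 2·k·n_samples` with
`n_obs = 96·n_samples`; the parameter count is the number of free exposures.
This AIC form is a design choice — a constrained least-squares fit has no
canonical likelihood — and is used only to rank models of identical data. A
consensus is also reported: how often each signature appears among the top-T
(default 100) solutions.

Attribution is Bayesian with exposures as priors:
`P(s|c) = E_s f_s(c)/Σ_t E_t f_t(c)`. A mutation is high-confidence when its
maximum probability strictly exceeds 0.5. Ties break lexicographically and
are flagged. Hotspots inherit the argmax of the arithmetic mean of their
members' probability vectors.

Profile entropy uses natural logarithms throughout (as does the AIC), with
0·log 0 := 0; profiles are first genome-normalized (channel frequency divided
by genomic triplet abundance, renormalized) so the entropy reflects
per-context mutability rather than genome composition.

## Observed propensity

Propensity is the number of hotspots formed by a fixed activity: each of 1000
iterations draws 100 qualifying samples (those with at least m eligible
mutations) without replacement, then m = 300 mutations per sample without
replacement, and counts recurrent equal-alternate positions (one hotspot per
position). The pooled mode (for datasets without per-sample assignment) draws
the total from the merged pool and counts positions hit twice. Because all
iterations resample one realized cohort, the iteration medians are highly
correlated; the matching model check therefore compares the observed median
against the central 95% band of the model's per-cohort count distribution
rather than against a standard error of the mean.

Conversion rates regress each sample's hotspot-membership count (the number
of hotspots its mutations participate in — "hotspots per individual" made
precise) on its burden across 1000 random 100-sample subsets; replicates with
degenerate burden variance are discarded and tallied. If at least 750
replicates yield a slope with p < 0.05, the rate is the inverse of the median
significant slope; inverting per replicate before aggregating is available as
an option. Signature enrichment compares per-sample normalized probability
shares inside vs outside hotspots; the cohort fold change is the median over
active samples, tested with a two-sided *paired* signed-rank test (the
observations are sample-paired) and BH-corrected at α = 0.01. Sample-signature
pairs with zero outside share are excluded and tallied.

## Expected-hotspot models

The models assume equal per-sample mutation rates and positional
independence. Given per-position, per-alternate probability `q`, one sample's
hit probability is the binomial approximation `π = 1 − (1−q)^n` (treating the
sample's n draws as independent; the true draws are without replacement), a
position forms no hotspot for that alternate with probability
`(1−π)^S + Sπ(1−π)^{S−1}`, and the position's hotspot probability is one
minus the product of the no-hotspot terms across its three alternates
(cross-alternate independence). Sums run class-wise: all positions sharing
(triplet, bin, methylation state) share `q`, so the expectation is
`Σ_classes N·h`. Both approximations are validated, not assumed: a
class-based Monte-Carlo simulator draws whole cohorts (events without
replacement within a sample, via sequential rejection, which reproduces exact
successive weighted sampling) and counts hotspots combinatorially; the test
suite requires agreement within 3 standard errors across 12 configurations
spanning uneven profiles, chunk-rate skew and methylation folds ρ ∈ {1, 2, 5}
(R = 2000 cohorts each). The configurations keep n small relative to class
sizes (n·q ≲ 0.01) — the regime the subsampling experiments also occupy; under
strong saturation (expected hotspots comparable to available positions) the
binomial approximation develops a visible bias and the closed form should not
be trusted without the oracle.

Weight-map resolutions: genome-wide `q = f(c→a)/N_c`; per-chunk
`q = r_k·f_k(c→a)/N_{c,k}` with chunk rates `r_k` estimated from
maximum-likelihood-attributed mutation counts (no pseudocount; a chunk
missing a context renormalizes `f` within the chunk so its total mass stays
`r_k`); methylation-aware, splitting NpCpG channels with
`q_meth = f·ρ/(ρN_m + N_u)` and `q_unmeth = f/(ρN_m + N_u)` so the channel
mass is preserved and ρ = 1 reduces exactly to the unsplit map. ρ is inferred
as the per-site odds ratio of mutation occurrence (site mutated at least
once) between methylated and unmethylated CpGs, with the Haldane–Anscombe 0.5
correction on zero cells (flagged). The explained fraction is
100·expected/observed-median; values above 100% are legal and flagged, and
arise naturally from sampling noise in the observed median.

Overdispersion of binned counts is fitted as an intercept-only NB2 negative
binomial (`v = μ + αμ²`) by maximum likelihood; α near zero is reported as
Poisson-consistent.

## Local features

Feature windows keep intervals of 200–600 bp with ≥90% mappable overlap and
centre a 2000-bp window (600-bp core, two 700-bp flanks) on the feature
midpoint with floor rounding; windows leaving the contig are dropped. The
enrichment statistic is (core count/core bp)/(flank count/flank bp) — per-bp
normalization is used on both sides, resolving the open choice of whether to
normalize before the ratio. The null redistributes the observed inside count
over all window positions with probability proportional to the profile's
total mutability of each position's triplet, so composition-driven enrichment
is absorbed. The p-value is the upper-tail mass of the observed fold change
under a Gaussian KDE fitted to the null fold changes (numerical integration
above the observation), floored at 1/n_rand; BH correction applies across
tested pairs at α = 0.01. The Savitzky–Golay smoothing of piled profiles
(window 101, polynomial order 3 — the order is a display-only choice) never
enters any statistic.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis assumes:
i.i.d. base composition with CpG dinucleotides thinned to a configurable
fraction δ of the independence expectation (default 0.2, the approximate
mammalian CpG deficit; thinning replaces the G of a kept-out CpG with A/T,
which cannot create a new CpG, so a single pass hits the analytic target in
expectation); a two-component Beta methylome with mixture weight π_m = 0.7
and sharp modes (Beta(12,3)/Beta(3,12), chosen so <1% of each mode crosses
the 0.5 classification line); chunk-level rate heterogeneity via a Dirichlet
concentration; a per-event generative model in which each event's signature is
drawn from the sample's exposures and its location stratum-wise with mass
`∝ N_s/N_{c,k}·r_k·f(c→a)·ρ^[meth]·m^[feature]`, renormalized — the same
exchangeable-positions construction the expected models use, so
model/generator agreement is exact rather than approximate when multipliers
are off. Samples draw events without replacement (a sample cannot carry one
event twice) and independently of each other.

Not emulated: realistic chromatin organisation, local sequence motifs beyond
trinucleotides, indel sequence context, inter-sample rate heterogeneity and
signature interference. Passing tests therefore demonstrate the correctness
and calibration of the machinery under the model's own assumptions, not that
real tumour cohorts satisfy those assumptions.

## Study conditions and problem sizes

The standard propensity experiment uses 100 samples × 300 subsampled
mutations (30,000 total) over the mappable megabase bins, 1000 subsampling
iterations, and a 20-Mbp synthetic genome for the end-to-end checks — large
enough that 30,000 mutations leave the hotspot regime unsaturated for both a
skewed and a uniform profile, while the whole experiment stays
single-CPU-friendly. The analysis scripts use an 8-Mbp genome with cohorts of
100 × 450 (propensity subsamples 300 of each sample's 450). The Monte-Carlo
oracle runs R = 2000 cohorts per small configuration and R = 200 for the
full-size count distribution. The acceptance script derives all sub-seeds
from a single `--seed`.

## Known limitations

* The closed form ignores without-replacement coupling within a sample and
  cross-alternate dependence at a position; both are negligible in the
  validated regime and grow with saturation.
* The AIC of a non-negative least-squares fit has no exact likelihood basis;
  rankings are meaningful, absolute AIC values are not.
* The KDE tail p-value is a smooth estimate of an empirical exceedance
  probability; with n_rand nulls it cannot resolve p below 1/n_rand.
* Conversion rates are undefined for cohorts with (near-)constant per-sample
  burdens; such replicates are discarded and reported.
* The duplicate-sample statistic uses the sum of both samples' burdens as the
  denominator, so two identical samples share 50%, not 100%.
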