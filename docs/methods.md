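# Methods

## Setting

A deep mutational scanning (DMS) experiment measures the relative activity of
thousands of sequence variants at once: a variant library is sequenced before
("input" sample) and after ("output" sample) a selection step, in `n`
replicate experiments. `dmsfit` estimates per-variant fitness from the count
tables, models the measurement error of those estimates, merges replicates,
and provides calibration diagnostics and simulators of common experimental
pathologies.

## Fitness scores

Fitness of variant `i` in replicate `r` is the natural-log enrichment
relative to the wild type:

    f_{r,i} = ln( (N_out_{r,i} / N_in_{r,i}) * (N_in_{r,wt} / N_out_{r,wt}) )

Entries with a zero input or output count get no score (no pseudocounts;
count-threshold filtering is the mechanism for dealing with unreliable
variants). A zero wild-type count is a fatal input error, since every score
in that sample is normalized by it. Error terms arising from the wild-type
normalization are omitted throughout: wild-type counts are orders of
magnitude larger than variant counts, so their contribution is negligible.

### Scale-and-shift normalization

Replicate selections can differ linearly (different selection strength or
baseline). Optionally (default on), a slope and offset per replicate are
fitted to minimize

    sum_i sum_r ( scale_r * f_{r,i} + shift_r  -  gbar_i )^2

where `gbar_i` is the per-variant mean of the corrected scores. The
unconstrained minimizer collapses all scores to a point, so the geometric
mean of the slopes is constrained to one, preserving the average scale of
the data. The problem is solved by alternating least squares (per-replicate
OLS against the current means, then re-normalizing the slopes) until the
relative objective change falls below 1e-12; convergence is typically a
handful of iterations. Finally all scores are shifted so the wild type's
average fitness across replicates is exactly zero. Only variants usable in
every replicate enter the fit (mixing threshold-masked entries into a linear
fit would bias it); the transformation is then applied to all entries, and
stored variances are multiplied by `scale_r^2` so they remain the variances
of the stored scores. Non-linear inter-replicate differences cannot be
corrected this way; affected replicates should be excluded
(`--retainedReplicates`).

## Error model

Measurement error variance is modelled per variant and replicate as

    sigma^2(f_{r,i}) = m_input_r / N_in_{r,i} + m_output_r / N_out_{r,i} + a_r

`1/N` is the Poisson baseline for the variance of a log count. The
multiplicative terms `m >= 1` capture over-dispersion that scales with
counting noise (bottlenecks upstream of sequencing, PCR variability); the
additive term `a >= 0` is a count-independent variance floor (replicate
handling differences) that dominates for high-count variants. The model has
`3n` free parameters and nests pure Poisson counting at `m = 1, a = 0`.

### Fitting

Parameters minimize the weighted squared deviation between the empirical
variance of fitness scores across replicates and the average model
prediction, summed over **all replicate subsets** `R` of size >= 2:

    sum_R sum_i w_{R,i} ( var(f_{R,i}) - (1/n_R) sum_{r in R} sigma^2(f_{r,i}) )^2

Empirical variances use denominator `n_R - 1`, matching the expectation of
the model mean for independent replicates. Using all subsets — not only the
full set — is what makes the *per-replicate* additive terms identifiable:
with two replicates only their sum is constrained and the model splits it
equally.

The weight is `w_{R,i} = n_R / vbar_{R,i}^2 / sqrt(max(n_m, sqrt(n_tot)))`,
with `vbar_{R,i}` the subset-averaged Poisson variance, `n_m` the number of
pool variants with the same substitution count and `n_tot` the pool size.
Dividing by the squared Poisson scale makes each summand a squared
*relative* deviation, so low-count variants do not dominate; dividing by the
class term shifts weight onto the typically few low-order mutants, which
carry most of the information about the additive terms.

Because the model mean is linear in the parameters, the bounded arg-min is
an exact bounded-variable weighted least-squares problem; it is solved with
`scipy.optimize.lsq_linear` (BVLS), so no starting values, convergence
criteria or restarts are involved. A vanishing per-column ridge (1e-10 of
each parameter's own curvature, pulling toward `m = 1, a = 0`) makes the
minimizer unique on exactly degenerate directions — notably the 2-replicate
additive split, which then comes out equal — without measurably moving
identifiable parameters.

The fit is repeated on `n_bootstraps = 100` bootstrap draws of at most
10,000 variants from the high-confidence pool; bootstrap means are the
operative estimates, and bootstrap sd / 5th–95th percentiles quantify their
uncertainty. All bootstrap randomness derives from a single seed.
`n_bootstraps = 0` requests a single fit on the full pool.

### High-confidence pool

The model is fitted only on variants that (a) have at least one output read
in every replicate and (b) have input counts large enough that the full
range of fitness scores is observable. Criterion (b) is made operational
as: `N_min_r = ceil( exp(-f_min) / depth_ratio_r )`, where `f_min` is the
1st percentile of provisional fitness scores and `depth_ratio_r` the
output/input total-read ratio — i.e. a variant depleted to `f_min` would
still produce >= 1 expected output read. `N_min` can be overridden. The
wild-type row is excluded from the pool: its score is the normalization
reference (identically zero before normalization), so its between-replicate
variance carries no error information, while its huge counts would give it
an enormous weight that drags the additive terms to zero.

### Merging

Replicates are combined by inverse-variance weighting,
`fbar_i = sum_r f_{r,i}/sigma^2_{r,i} / sum_r sigma^{-2}_{r,i}` with merged
variance `1 / sum_r sigma^{-2}_{r,i}`; single-replicate variants pass
through unchanged.

## Benchmark error models

Four comparators share the same interfaces:

* **variance-based** — merged error `var(f_i)/n`; held-out error
  `var/n * n/(n-1)`;
* **Bayesian-regularized variance** — `(d*prior + (n-1)*var) / ((d+n-2)*n)`;
  the prior is an OLS regression of log empirical variance on log minimum
  input count and mean fitness (`d = 3` by default, configurable) — the
  exact regression form is a documented package choice;
* **count-based** — pure Poisson, `1/N_in + 1/N_out`;
* **random-effects (Enrich2-style)** — count-based per-replicate variances
  inflated by a per-variant `s_i^2 >= 0` solved (monotone bisection,
  tolerance 1e-12) so the harmonic merge equals the empirical variance
  whenever the latter is larger; the held-out error adds the training
  `s^2` to the held-out replicate's count variance.

## Calibration diagnostics

If the error model is right, the standardized difference between a held-out
replicate and the merged remaining replicates,

    z_{j,i} = ( fbar_{r!=j,i} - f_{j,i} ) / sqrt( sigmabar^2_{r!=j,i} + sigma^2_{j,i} )

is standard normal. In leave-one-out cross-validation the model is refitted
without replicate `j` and the held-out variance is predicted from training
quantities only (for the multiplicative/additive model: training-averaged
`m` and `a` applied to the held-out counts). The pooled `1/sd(z)` is the
**relative error magnitude**: 1 means errors are estimated at the right
size, < 1 underestimated, > 1 overestimated. Reported verdicts use
`sd(z)` within [0.9, 1.1] as "calibrated" and `|mean(z)| > 0.1` as
"biased" (package choices); per-replicate breakdowns, two-sided P values,
a KS test of P-value uniformity and QQ coordinates are emitted alongside.
Pooling across held-out replicates and variants is the default aggregation.

## Synthetic data generator

`SyntheticSpec` defaults describe a small protein DMS library chosen to be
realistic for this assay class and fixed once:

* 10 mutated positions over the 20-letter amino-acid alphabet; all 190
  single mutants and 4,809 randomly chosen double mutants (5,000 variants);
* hierarchical abundance: wild type 10% of the library, singles 45%,
  doubles 45%, with lognormal within-order jitter (sigma 0.5) — each single
  is ~25x more abundant than each double, matching the orders-of-magnitude
  hierarchy of real libraries;
* bimodal true fitness: 60% neutral N(0, 0.15), 40% deleterious
  N(-2.0, 0.5), wild type pinned at 0 — the deleterious mode decorrelates
  input and output counts, which is what makes the input and output
  multiplicative terms separately identifiable;
* sequencing depth 5e6 reads per sample (counts: wild type ~5e5, singles
  ~1.2e4, doubles ~470).

Input counts are Poisson around `depth * freq`; output counts are Poisson
around depth times the selection-reweighted frequencies
`freq * exp(f_true + eps_{r,i})`. Additive pathology: `eps_{r,i}` is
zero-mean Gaussian noise with a per-replicate sd (zero for the wild type so
the reference stays clean — wild-type noise would shift all scores of a
replicate coherently, which is a shift, not independent error).
Multiplicative pathology: the *reported* count is the sampled count times
`m`, so the true sampling variance is `m`-fold the count-implied variance —
the same manipulation used for validation (multiplying one replicate's
input counts by 3 or 10 and checking the fitted term).

What the generator does **not** emulate: PCR jackpotting and UMI structure,
position- or codon-biased mutagenesis, epistasis in the fitness landscape,
non-linear replicate differences, and growth-competition dynamics beyond a
single multiplicative selection round. Passing recovery/calibration tests
on this generator therefore demonstrates correctness of the estimator under
its own assumptions, not robustness to every real-data pathology.

### Bottleneck simulators

A bottleneck of size `alpha` thins variant `i` by
`b_i = Pois(N_i * alpha) / N_i`, computed from replicate-averaged input
counts (library bottleneck), per-replicate input counts (replicate
bottleneck) or each sample independently (DNA-extraction bottleneck). Each
sample is then re-drawn from a multinomial at its original total depth with
probabilities proportional to `counts * b`, so per-sample totals are
conserved exactly. A sequencing-error cascade follows: within each sample
and for each substitution order `d` from the highest donor order downward,
`round(p * total reads of order d)` reads (default misread probability
p = 0.02) are removed without replacement proportionally to donor counts
and distributed uniformly among the order-`(d+1)` variants present; orders
without recipients keep their reads. The flat per-read probability is the
operative parameter (its per-base derivation, 126 nt at 1e-4, would give
~0.0126; 0.02 is the default and both are configurable).

`estimate_variant_flow` approximates the expected frequency of a specific
order-`d` variant arising purely from misreads of its ancestors as
`sum_{k<d} Fbar_k * (e/3)^(d-k) * (1-e)^(L-(d-k))`, with `Fbar_k` the
average observed frequency of order-`k` variants — a documented
approximation dominated by the direct-parent term.

## Numerical notes and limitations

* The fitted `m` for a manipulated replicate is systematically ~10% low
  (e.g. ~9.0 recovered for a true factor of 10): the regressors `1/N` are
  realized counts that share noise with the empirical variances
  (errors-in-variables attenuation), and the within-replicate input/output
  terms are collinear for neutral variants. This is a property of the
  estimator, quantified by the recovery tests, and well within the 25%
  recovery tolerance used throughout.
* Bootstrap means of bound-constrained parameters are biased upward when
  the truth lies on the bound (every bootstrap fit can only err upward);
  in leave-one-out calibration this makes the relative error magnitude run
  slightly above 1 (~1.05–1.09 on over-dispersed synthetic data).
* Empirical variances over 2–3 replicates are chi-square with 1–2 degrees
  of freedom; individual fits are correspondingly noisy, and all recovery
  statements are about averages or medians over seeds.
* Degenerate inputs: fewer than two replicates (no error model, no
  normalization), fewer than two complete-case variants (normalization
  error), a replicate with constant fitness (undefined slope), zero
  wild-type counts (fatal), empty high-confidence pool (fitting error).
* Problem sizes in the test-suite property checks are scaled-down versions
  of the 5,000-variant study conditions (500–1,500 variants at
  proportionally adjusted depth), chosen so per-variant counts stay in the
  regime where log-Poisson scores are near-normal.
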