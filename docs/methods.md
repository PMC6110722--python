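# Methods

## The problem

A single extended family in a population-scale sequencing cohort can
show extreme clustering of a disease such as intellectual disability
(ID). `segscan` implements the statistical machinery for asking, for
each rare coding variant observed in such a family, whether its
segregation pattern is stronger than chance given the family structure
— and for replicating a hit in carriers outside the family, both on a
binary diagnosis and on quantitative traits (IQ, brain morphometry)
measured in relatives of varying degrees.

## Penetrance model and pedigree likelihood

Each individual *i* has a baseline log-odds of being affected,
`f_i = logit P(A_i | x_i)`, fitted by ordinary logistic regression of
affection status on nuisance covariates (sex, year of birth, county of
birth, lifespan in the intended application; encodings are
configurable, defaulting to one-hot for categoricals and standardized
linear terms for numerics). A dominant risk variant with carrier status
`g in {0,1}` shifts the log-odds additively:

    logit P(A_i | g_i, x_i) = f_i + beta * g_i.

Dominant carrier coding means homozygotes collapse to `g = 1`.

The likelihood of the observed affection statuses (and any observed
genotypes) given covariates and `beta` sums over latent carrier states
by *peeling*: variable elimination over the parent–child factor graph,
eliminating individuals leaves-first. With binary states this is exact
and matches brute-force enumeration to floating-point precision (tested
to 1e-10 on random pedigrees, including looped ones). Transmission is
Mendelian-dominant for a rare variant: a carrier parent transmits with
probability 1/2, two noncarrier parents produce noncarriers, double
transmission collapses to carrier. There are no de novo events inside a
pedigree; a de novo origin is represented by making the mutation-origin
individual a founder.

Founder carrier states need a prior. Two modes are provided:

* `single-introduction` (default): condition on exactly one founder
  carrying the variant, uniform over founders. This matches the
  rare-variant setting where the variant is known to be present in the
  family exactly once. Under this conditioning a fully genotyped,
  all-noncarrier family is a zero-probability observation and raises a
  Mendelian-inconsistency error — variants absent from the family carry
  zero family segregation evidence and are scored from outside carriers
  only.
* `iid-founders`: each founder carries independently with probability
  `carrier_prior` (default 1e-4, a single-digit-per-ten-thousand
  carrier rate typical of the rare loss-of-function variants this
  analysis targets; configurable).

`beta` is estimated by quasi-Newton maximization (L-BFGS-B with central
finite differences, step 1e-6) inside bounds [-10, 10]. The bounds
matter: small pedigrees frequently separate perfectly (every carrier
affected), where the unbounded MLE is infinite because the penetrance
saturates; estimates at a bound are flagged. A flat likelihood (no
informative carriers) returns `beta_hat = 0`, `LLR = 0` with a
degenerate-fit flag. `fit_beta` accepts several pedigrees and sums
their log-likelihoods; per-pedigree MLEs on ~10-member pedigrees are
boundary-censored and systematically uninformative about the magnitude
of `beta`, so parameter-recovery claims in the test suite are made for
the joint MLE across many simulated pedigrees, which is consistent.

The evidence statistic is the log-likelihood ratio
`LLR = log L(beta_hat) - log L(0) >= 0`. When every genotype is
observed the LLR reduces to a closed form in which affected carriers
contribute `log sigma(f+beta) - log sigma(f) >= 0`, unaffected carriers
contribute `log(1-sigma(f+beta)) - log(1-sigma(f)) <= 0` (for
`beta >= 0`), and noncarriers contribute nothing (`llr_observed`).
Carriers outside the family enter the same way with their own `f_i`,
so affected outside carriers strengthen a variant and unaffected ones
weaken it.

## Variant score and empirical genome-wide significance

The scan score of marker *m* is
`score(m) = LLR(m) - log P(coding effect of m)`. Only the offset
between impact classes is externally calibrated: a loss-of-function
variant scores exactly 2.96 log-likelihood units above a
moderate-impact variant at equal LLR, reflecting the relative rates of
the two mutation classes. The absolute penalty level (default
`-log 0.01` for moderate impact) cancels in ranking and in the
empirical P-value. Variants are pre-filtered to at most 30 sequenced
carriers in the cohort (configurable), the high-penetrance search
space; the filter is applied before scoring.

Genome-wide significance is empirical: affection statuses and
covariates are frozen at their observed values, and only variant
segregation is resimulated. Each null genome scan draws, per marker, an
impact class and founder carrier states from a configurable frequency
spectrum (standing in for resampling founder genotypes from a sequenced
cohort pool), gene-drops the marker through the pedigree, scores it,
and records the genome-wide maximum. The genome-wide P is the fraction
of null scans whose maximum reaches the observed top score (ties count;
no +1 correction by default, since the estimator is defined as a plain
exceedance fraction — a flag enables `(r+1)/(n+1)`). The default
spectrum puts carriers at 1e-4 per marker with a LoF:moderate mix of
`exp(-2.96) : 1`, the same ratio that calibrates the score offset; the
CLI defaults to 20,000 simulated markers and 1,000 scans per run (the
reference analysis used 100,000 scans against an empirical cohort
pool), all overridable. With a fixed seed the whole null distribution
is bit-reproducible. Implementation note: markers are processed in flat
batches across simulations and the per-marker MLE is evaluated once per
distinct carrier pattern, which makes the desk-scale calibration runs
(hundreds of thousands of scans) take minutes.

## Replication statistics

**Case–control.** Logistic regression of disease status on genotype
counts (0/1/2) plus nuisance covariates; the genotype term is tested
with a 1-df likelihood-ratio chi-square. Complete separation raises a
named error advising that the odds ratio be reported as a bound.

**Quantitative traits.** The trait is modelled as
`y ~ N(alpha + beta*g, 2*sigma^2*phi)` where `phi` is the genealogical
kinship matrix. We take `phi_ii = 1/2` and `phi_ij = k_ij`, the
pairwise kinship coefficient, so `2*phi` is the numerator relationship
matrix and positive semi-definite. (A scaling that doubles the
off-diagonal instead would give parent–child pairs correlation 1 and an
indefinite covariance for any nuclear family; it cannot be fitted.)
The kinship coefficients come from the standard genealogical
recurrence, `k_ij = (k_i,father(j) + k_i,mother(j))/2` processed in
topological order, with founders unrelated. The diagonal is forced to
1/2 exactly even for inbred individuals — inbreeding enters only
off-diagonal — and a warning flags related matings, where this choice
understates the inbred variance (positive semi-definiteness is then no
longer guaranteed). Half-siblings fall out of the recurrence naturally;
parents of unknown sex are accepted as long as each child has two
recorded parents.

`gls_assoc` profiles `sigma^2` by maximum likelihood (`reml=True`
divides by n−p instead) and reports a two-sided Wald test and normal
95% interval for `beta`. Near-singular `2*phi` (e.g. duplicated rows)
gets a 1e-8 ridge with a logged warning. With `phi = I/2` the estimate
equals OLS exactly, which is tested.

**Trait preprocessing.** Quantitative traits are inverse-normal
transformed with Blom's rank offset `(r - 3/8)/(n + 1/4)` (the offset
convention is not externally fixed; Blom is the common default and ties
get average ranks), then residualized on adjustment covariates fitted
on controls only, then shifted/scaled so controls have mean 0, SD 1.
Intracranial volume adjusts volumes (not itself) and surface areas,
never thickness. An optional per-trait direction flag flips signs so
higher always means more impaired. Volumetric headline numbers use
`percent_deficit = 100*(1 - carrier_mean/control_mean)`, reported to
the nearest integer percent. `bonferroni_threshold(alpha, m)` is
`alpha/m`.

## Synthetic cohorts

No individual-level data from the motivating study are publicly
available, so every consumer of the package is exercised on synthetic
cohorts with known ground truth. The generator produces:

* a multi-generation pedigree grown founders-down (defaults: one
  founder couple, 4 generations, mean sibship 2.5 truncated at 5,
  spouses marry in as founders with probability 0.6 — averaging ~19
  members, the scale of the discovery family);
* a rare dominant variant introduced in the first founder and
  gene-dropped;
* affection statuses drawn from the penetrance model (defaults:
  baseline prevalence 2%, sex and birth-year effects on the logit
  scale, `beta = 3`);
* covariates: sex, birth year in a 60-year window structured by
  generation, an 8-level county, a lifetime-overlap indicator;
* an unrelated sequenced pool (default 2,000 members; carrier
  frequency 1e-4) for replication and founder-spectrum duty;
* a quantitative trait drawn from `N(alpha + beta_trait*g,
  2*sigma^2*phi)` (defaults `beta_trait = -1.6` control SDs,
  `sigma^2 = 1`), blockwise: dense kinship inside the pedigree, iid for
  the pool, so pool size never forces a dense cohort-wide matrix.

Everything is written as plain text (PED, VCF with an `IMPACT` INFO
tag, TSVs) and parses back through the package's own readers; the
generating parameters are saved alongside (`truth.json`).

What the generator does **not** emulate: genotyping error, imputation
uncertainty, realistic allele-frequency spectra, ascertainment of the
discovery family (pedigrees are simulated prospectively, not
conditioned on case clustering), assortative mating, or shared
environment beyond additive kinship covariance. Passing calibration and
recovery tests on these cohorts therefore demonstrates correctness of
the statistical machinery under its own assumptions, not robustness to
those real-data complications.

## Test-scale choices and calibration design

The package's own validation uses scaled-down problem sizes chosen to
make Monte-Carlo checks sharp at desk scale: the uniformity check of
the empirical genome-wide P uses 200 self-simulation replicates of 500
null scans over 100 markers on a ~36-member two-couple pedigree
(smaller pedigrees make the max-score distribution visibly discrete —
few distinct carrier configurations — and a plain exceedance P over a
discrete score cannot be uniform); GLS type-I error uses 2,000 null
replicates on a ~170-member multi-family cohort; parameter recovery
pools 500 simulated pedigrees per effect size (joint MLE) plus a
50-pedigree joint fit through the peeling path with 40% of genotypes
hidden.

## Numerical choices

* Peeling multiplies factors in linear space with per-elimination
  rescaling (the running log-scale accumulates), so likelihoods far
  below float range are handled.
* The per-marker MLE on fully observed genotypes uses bisection on the
  score function (the log-likelihood is concave in `beta`), 80
  iterations inside [-10, 10].
* Logistic fits go through IRLS with gradient tolerance 1e-8, max 100
  iterations; divergence (|coef| > 30 or fitted probabilities at 0/1)
  is reported as perfect separation.
* Trait covariance factorization tries Cholesky with a 1e-12 jitter and
  falls back to eigenvalue clipping at zero with a warning.
* Ranking ties break deterministically by (contig, position, alt).

## Known limitations

The headline results of the motivating study — the genome-wide
corrected P = 0.022 for the discovery frameshift variant, the
replication odds ratio OR = 69.6 and the IQ effect of −23.07 points,
and the per-trait effect estimates of its summary tables — depend on
the underlying Icelandic cohort (whole-genome sequences, genealogy,
phenotype registries), which is not publicly available. This package
therefore does not reproduce those numbers; they are covered indirectly
by the calibration and recovery suites on synthetic data, plus the
worked-number checks that recompute the arithmetic of the published
summary tables (percent deficits, carrier IQ average, Bonferroni
thresholds, the 2.96 score offset). Further limitations: the peeling
implementation is exact but not optimized for very large or heavily
looped pedigrees (variable elimination in reverse topological order
can produce large intermediate factors on dense marriage loops);
inference for `beta` near a search bound is reported as a bound, not an
interval; and the GLS assumes a single variance component proportional
to kinship — no separate environmental or dominance components.
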