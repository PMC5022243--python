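# Methods

## Model

The observation model for a corrected phenotype vector `y_c` is

    y_c = X b + sum_t M_t q_t + Z l + e,       t in {a, d, i},

with birth-year fixed effects `b` (flat prior; there is no separate
intercept — it is absorbed into the year effects to avoid rank
deficiency), litter effects `l ~ N(0, I s2_l)`, residuals
`e ~ N(0, I s2_e)` and per-SNP effects `q_t` for the effect types included
in the model (`A`, `AD`, `AI`, `ADI`; additive always present). The
corrected phenotype is assumed pre-adjusted for all other non-genetic
effects (herd-year-season, sex, pen), so birth year is the only fixed
effect carried by the model.

Each `q_t` has the mixture prior
`pi_1 N(0, v_1) + pi_2 N(0, v_2) + pi_3 N(0, v_3) + pi_4 N(0, v_4)` with
known proportions (default 0.889 / 0.1 / 0.01 / 0.001) and estimated class
variances under the strict ordering `v_1 < v_2 < v_3 < v_4`, separately
per effect type. Litter and residual variances carry flat priors.

### Codings and parental origin

Phased genotypes are stored as paternal/maternal allele matrices; **the
paternal allele is always the first allele of a phased VCF pair** (`a|b`).
This convention is a package-level contract — upstream pedigree-based
phasing tools do not encode it — and is stated in every writer/reader.
"A2" is the allele whose frequency is called `p`; allele code 1 maps to
A2. The additive coding is the frequency-centered allele count, the
dominance coding the centered heterozygosity contrast, and the imprinting
coding the signed reciprocal-heterozygote contrast (+1 when the paternal
allele is A1). Swapping the parental matrices negates `M_i` and leaves
`M_a`, `M_d` unchanged; relabeling alleles negates `M_a` and `M_i` and
leaves `M_d` unchanged — both are tested.

Centering frequencies are always recomputed from the analyzed (training)
individuals, never taken from the validation set; validation genotypes are
coded with the training frequencies. Residual missing genotypes after QC
code to the column expectation (zero for all three codings), which leaves
column means unchanged.

### Genetic variances

Class variances convert to genetic variances on the phenotypic scale via
the population variance of the coding column:
`s2_t = sum_j w_t(p_j) * sum_i pi_i v_{t,i}` with weights
`w_a = 2p(1-p)`, `w_d = (2p(1-p))^2`, `w_i = 2p(1-p)`. Only the additive
weight has a canonical printed form; the dominance and imprinting weights
are derived as the coding-column variances under Hardy-Weinberg
proportions and random mating, and are cross-checked in the tests by
genotype-class enumeration and by Monte Carlo. This matters because
alternative dominance parameterizations in the literature imply different
weights. Variance components and their proportions are computed **per
saved MCMC sample and then averaged** (posterior mean of the function),
which is exact for these linear-in-variance formulas and matches using
posterior means as point estimates.

Narrow-sense heritability is the parent-of-origin-independent additive
share of phenotypic variance; broad-sense heritability is the total
genetic share (additive + dominance + imprinting).

## Sampler

A single Gibbs chain (default length 50 000, burn-in 20 000, thinning 10)
scans, in fixed order: year effects, litter effects, SNP effects (per
effect type, per SNP: class indicator sampled with the effect integrated
out — the marginal likelihood of each class — then the effect from its
normal conditional), class variances, litter variance, residual variance.
Residuals are updated incrementally after every effect change and
re-synchronized from scratch every 1000 iterations (the deviation is
tracked and asserted < 1e-6 in tests). Identical seed and data give
identical output.

### Class-variance updates

Under a flat prior the conditional of a class variance with `k` assigned
effects and sum of squares `S` is `S / chi2(k-2)`: improper for `k <= 2`
and without a finite mean for `k <= 4`. At realistic SNP counts (tens of
thousands, so hundreds of SNPs even in the rarest class) this never
matters; at the reduced scales a desk study can afford, sparsely occupied
classes would otherwise make excursions that dwarf the data and wreck the
variance formula, which multiplies the two largest class variances by
fixed prior weights. The updates therefore run per class between the
neighboring class variances (so the strict ordering holds at every saved
state, by construction):

* `k >= 5`: flat-prior Gibbs draw `S / chi2(k-2)`, rejected into the
  interval (<= 100 redraws, else the previous value is kept);
* `1 <= k <= 4`: draw `S / chi2(k+2)`, whose mean is exactly `S / k` —
  the mean square of the currently assigned effects — keeping a sparse
  class tied to its data (an inverse-square-prior conditional);
* `k == 0`: uniform redraw between the lower neighbor and twice the
  lower neighbor.

All class variances live in `[1e-12 * var(y), var(y)]`; the ceiling
encodes that no single-SNP effect variance beyond the phenotypic variance
is meaningful and makes the flat prior proper.

### Escape from variance collapse

The full-conditional cycle has a well-known absorbing region: once all
effects of a type and their class variances are near zero, each
conditional regenerates the collapsed state (effects are shrunk to
nothing, so the variance conditional sees nothing). Every 10 iterations
the chain therefore attempts a parameter-expansion move per effect type:
propose `q -> sqrt(g) q`, `v -> g v` with `g` log-uniform in [1/4, 4],
accepted with probability `min(1, g^4 exp((|e|^2-|e'|^2)/(2 s2_e)))`.
The move leaves the posterior invariant (the effect-density terms cancel
against the Jacobian; `g^4` is the volume factor of the four class
variances). In the collapsed state residuals barely change and upward
scalings are accepted freely; in equilibrium the likelihood term governs.
Without this move, chains at a few hundred observations were absorbed at
the variance floor in a substantial fraction of seeds.

### Initialization

Year effects start at year means; litter and SNP effects at zero;
residual variance at half the phenotypic variance (floored for degenerate
input), litter variance at 5 %. Class variances start on the geometric
ladder `base * 10^(c-3)` with `base` chosen so the implied genetic
variance of each type is half the phenotypic variance: starting the
hierarchy orders of magnitude below the data risks immediate absorption
(see above), while starting high only costs burn-in.

### Convergence

The time-series standard error of each variance component is estimated by
batch means (`floor(sqrt(T))` batches), cross-checked in the tests against
arviz's ESS-based MCSE. A component is flagged converged when the SE is
below 5 % of the absolute posterior mean; for a zero mean the posterior SD
is the reference (the summary notes which). This is the package's reading
of the usual "time-series SE below 5 %" mixing rule, which does not say
5 % of what.

## Model comparison and validation

Per-observation conditional predictive ordinates are estimated by the
harmonic mean, over saved iterations, of `N(y_i; fitted_i, s2_e)`;
CPOs are computed on the training observations (the standard choice for
pseudo Bayes factors). `2lnK` between two models is twice the difference
of their log pseudo-marginal likelihoods, labeled on the conventional
bands: < 0 negative, 0–2 weak, 2–6 positive, 6–10 very strong, > 10
decisive (values beyond the printed bands get the outer labels for
completeness).

Validation splits by birth date (born before the cutoff train, on/after
validate). Reliability divides the squared correlation with `y_c` by
`h2_yc = s2_a / (s2_a + s2_l + s2_e)` taken **once from the additive-model
fit** and reused for every model, so it scales but never reorders the
comparison; the definition does not cap at 1. Reliability differences
against the additive baseline use the Hotelling-Williams t test
(df = n-3) applied to the correlations — not the squared correlations —
because the test concerns two dependent correlations sharing `y_c`;
p-values are two-sided. Bias is the OLS regression of `y_c` on the
predictions (slope 1, intercept 0 = unbiased), with the intercept also
reported relative to the mean phenotype.

## Synthetic populations

The generator emulates a pig breeding study: litters of full sibs (litter
sizes shifted-Poisson with minimum 1, mean 2.44), founder parents drawn
per litter with Hardy-Weinberg gametes, Mendelian inheritance with no
linkage between SNPs, allele frequencies uniform on (0.05, 0.95),
phenotypes from birth-year effects (SD 0.2, a modest year trend for a
corrected phenotype), mixture-distributed SNP effects, litter effects and
residuals. Default sizes mirror the emulated study (8113 individuals,
33 004 SNPs, 17 birth years, 23 % validation tail); default variance
targets are the backfat profile (additive 0.341, dominance 0.045,
imprinting 0.015, litter 0.059, residual 0.657, in phenotype units
squared). Birth dates are assigned per litter (littermates share a date)
and the generator reports the cutoff date that realizes the requested
validation fraction.

SNP effects are drawn from the four-class mixture (relative class
variances 1e-3/1e-2/1e-1/1) and then rescaled so the analytic genetic
variance `sum_j w_j q_j^2` hits the target exactly, which makes recovery
tests sharp rather than only unbiased. Stored per-individual genetic
values are exact design-matrix products.

What the generator does **not** emulate: linkage disequilibrium beyond
family structure, half-sib structure across litters (each litter has its
own sire and dam), selection, sex chromosomes, genotyping-intensity
artifacts. Passing recovery tests therefore shows the estimation machinery
is correct under the stated generative model, not that real LD-structured
data would be estimated with the same accuracy.

## Problem sizes used by the tests

The emulated study (8113 x 33 004, chains of 50 000) is far beyond a unit
suite, so the tests exercise the same code paths at reduced scale, chosen
so every tolerance is still meaningful: parameter recovery at n = 2000,
m = 1500 with 12 000-iteration chains over three independent populations
(tolerance ±0.05 per variance proportion, unchanged); the closed-form
Gibbs oracle at n = 200, m = 50; pseudo-Bayes-factor separation at
n = 800, m = 400 with dominance at 10 % of phenotypic variance; Williams
test calibration over 10^4 replicates at n = 200. The acceptance script
runs its synthetic study at n = 1200, m = 800 with 8000-iteration chains.

A caution on desk-scale variance recovery: when the SNP count approaches
the number of individuals, the likelihood cannot fully separate the
genetic variance from the residual (the design matrices span most of the
observation space), and under near-flat variance priors the posterior
moves variance from the residual into the genetic components. At
n = m = 2000 this shifts the residual proportion down by 0.06-0.14
depending on the population draw; at n = 2000, m = 1500 the distortion is
within the test tolerance for most draws. Estimates at the emulated
study's own size are not affected in the same way by n/m alone, but this
is the reason the recovery test holds m below n.

## Known limitations

* Single-chain diagnostics only (batch-means SE); no R-hat across chains.
* The sparse-class variance conditional (`S/chi2(k+2)` for `k <= 4`) is a
  pragmatic regularization of an improper flat-prior conditional; it is
  exercised only when a mixture class holds fewer than five SNPs, which
  does not occur at realistic SNP counts.
* CPO by the harmonic-mean estimator can be noisy for observations with
  poor fit; non-positive CPOs raise rather than being silently clipped.
* With `n` approaching the number of model effects, variance components
  are weakly identified and posterior means of small components (litter,
  imprinting) carry visible positive skew; tests use sizes where this is
  within the stated tolerances.
* Imprinting estimation requires correctly phased genotypes; phase errors
  attenuate `M_i q_i` toward zero and are not modelled.
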