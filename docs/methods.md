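# Methods

## Data model and coding

Genotypes are additive codes 0/1/2 counting copies of a per-SNP *counted
allele*, with an explicit missing sentinel. When a PLINK `.ped` is read, the
counted allele is the alphabetically first allele observed at the SNP, so
the coding is deterministic; when panels from several lines are joined,
`intersect_panels` re-harmonises every shared SNP to one counted allele
(flipping codes 0<->2 where needed). Cross-line consistency matters because
crossbred breeding values combine one line's genotypes with the other
line's allele frequencies; a per-line minor-allele coding would silently
corrupt that combination. Positions are carried as metadata only.

## Quality control

SNP filters, in attribution order: call rate < 90 %, MAF < 1 %, missing
fraction > 2 %, Hardy-Weinberg 1-df chi-square p < 1e-7 (expected counts
p^2, 2pq, q^2 with p from the same genotypes; monomorphic SNPs return p = 1).
Animals with > 10 % missing genotypes are removed. All inequalities are
strict, so a SNP at exactly MAF 0.01 or an animal at exactly 10 % missing
survives. Frequencies, HWE and modal-genotype imputation are computed
within line; on multi-line tables a SNP fails MAF only if it fails in every
line, so SNPs merely monomorphic in one line remain available for a
combined-line reference. Missing genotypes are imputed to the modal
genotype of the SNP within the animal's line, ties broken toward the lowest
code for determinism. The surviving SNP set is invariant to filter order;
only the attribution in the report changes.

## BayesC sampler

Single-site Gibbs sampling for MA (additive) and MAD (additive +
dominance). Each effect class has a point-mass-at-zero mixture: effect
included with probability pi (Beta(1,1) prior, sampled; optionally fixed)
and drawn from N(0, sigma2_class) when included. Class and residual
variances have scaled-inverse-chi-square full conditionals with df 5.
Prior scales are set so the prior-mean variance explained by markers is
r2 = 0.5 of var(y), split equally across the model's effect classes and
spread over half the markers; the residual prior scale matches
(1 - r2) var(y). These hyper-parameters are this package's declared
defaults, in the spirit of general-purpose Bayesian regression software
default rules; none of the reported quantities are sensitive to them at
the default MCMC length. Effects are updated in fixed index order and all
randomness flows from one seed, so chains are bitwise reproducible.
Defaults are 100 000 iterations, 10 000 burn-in, thinning 10 (thinning is
a memory-control addition; posterior means over thinned and full chains
agree within Monte-Carlo error). Constant genotype columns are
unidentifiable; their effect stays 0 and inclusion is sampled from the
prior.

Model fit is compared by DIC (mean posterior deviance plus p_D, Gaussian
likelihood) and by an approximate likelihood-ratio test: chi-square =
2 (logL_MAD - logL_MA) at plug-in posterior means, referred to 1 df. This
is not a maximised likelihood ratio; it is documented as the approximation
it is. Convergence can be checked with a Geweke z-score whose segment-mean
variances use Bartlett-windowed spectral density estimates at frequency
zero; a constant chain returns z = 0 by convention.

## Breeding values

A boar's breeding value is the expected mean genotypic value of its
offspring under random mating. Per-SNP contributions (frequencies p, q of
the mate population): AA -> p a + q d; Aa -> 0.5(p-q) a + 0.5 d;
aa -> -q a + p d. Own-line frequencies give GEBV, opposite-line
frequencies give GEBV-C; passing own-line frequencies to the crossbred
routine is an error unless explicitly overridden (useful for testing the
substitution identity). With all d = 0 the value equals
0.5 sum_j X_ij a_j minus a constant, hence correlation 1 and regression
slope 0.5 against the reduced form — the package's exact analytic
acceptance identity. The intercept is never added: only ranking and
covariance with progeny means are used downstream. Frequencies default to
those observed in all genotyped animals of the relevant line.

## Variance components, GBLUP, back-solving

W_a entries are 2-2p / 1-2p / -2p and W_d entries -2q^2 / 2pq / -2p^2 for
genotypes AA / Aa / aa, with G = W_a W_a' / (2 sum pq) and
D = W_d W_d' / (4 sum p^2 q^2). This is the breeding-model (classical)
parameterisation: under Hardy-Weinberg proportions the dominance-deviation
coding is orthogonal to the allele-substitution coding, so sigma2_a and
sigma2_d are comparable to pedigree-based components. The frequency used
is that of the counted allele — the element formulas require it even when
the counted allele happens to be the major allele. Frequencies default to
the analysed animals' own.

REML maximises the restricted likelihood of y = mu + u + v + e with
V = sigma2_a G + sigma2_d D + sigma2_e I by average-information updates.
A ridge of 1e-6 is added to G and D diagonals. When an AI step would make
a component negative, that component is shrunk geometrically (x0.1) toward
the floor of 1e-10 while the others keep their AI update; components
pinned near zero for three consecutive iterations are fixed at the floor,
reported as 0 with a boundary flag and no SE. (A full EM-REML step is the
fallback only if the AI system cannot be solved; pure EM was tried first
and needs hundreds of iterations whenever a component heads to zero.)
Convergence is a log-likelihood change < 1e-8; SEs come from the inverse
of the final AI matrix over non-boundary components.

GBLUP solves the dense mixed-model equations for [mu, u, v] with
G^-1 sigma2_e/sigma2_a and D^-1 sigma2_e/sigma2_d shrinkage. SNP effects
are back-solved as a = W_a' (W_a W_a')^- u with a Moore-Penrose inverse
(column-centred W_a is always rank n-1, so the pseudo-inverse path is the
normal one; a warning reports the rank).

## Validation statistics

Accuracy = corr(breeding value, progeny mean) / mean_i sqrt(n_i/(n_i+k)),
k = (4 - h^2)/h^2, the classical accuracy of an n-daughter half-sib mean.
The h^2 entering k defaults to the simulation's true narrow-sense value
(0.10) or a user-supplied estimate. The accuracy SE is a seeded
nonparametric bootstrap over boars (2000 resamples by default) — the
method behind published SEs for such accuracies is rarely stated, so the
bootstrap is declared rather than assumed. Unbiasedness is the OLS slope
of progeny means on breeding values with its analytic SE. Five-fold
cross-validation splits are seeded partitions with fold sizes differing by
at most one; top-k ranking overlap breaks ties by ascending animal id.

## Synthetic data generator

The generator emulates a reciprocal two-line crossbreeding design:
ancestral allele frequencies p0 ~ U(0.05, 0.95); line frequencies drawn
from Beta distributions with mean p0 and variance F p0 q0 (drift
parameter F = 0.15 by default), clamped to [0.01, 0.99]; genotypes
Binomial(2, p) in linkage equilibrium; QTL effects a ~ N(0,1) at a random
6 % of SNPs with dominance d = delta |a|, delta ~ N(0.5, 0.5) (partial,
predominantly directional dominance of the kind that produces litter-size
heterosis). Effects are rescaled so the additive (allele-substitution)
variance sum 2pq alpha^2 with alpha = a + d(q-p) equals 1 simulation unit
against line-1 frequencies, the dominance-deviation variance
sum (2pq d)^2 is 15 % of it, and the residual variance then sets the
narrow-sense heritability to 0.10 — matching litter size in commercial pig
lines. Phenotypes are y = 15 + X a + Z d + e, kept continuous (they stand
for pre-corrected records, not raw counts). Crossbred daughters receive a
paternal gamete sampled from the boar genotype and a maternal allele
Bernoulli(p) from the opposite line's frequencies; a boar's record is the
mean phenotype of its 30 daughters. Ground truth includes per-boar
purebred and crossbred breeding values; the expected daughter phenotype
equals mu + sum_j a_j + true GEBV-C, an identity used as the
law-of-large-numbers oracle in the tests.

Reference scenario: 5000 SNPs, 300 QTL, 2000 training sows and 200
validation boars per line, 30 daughters per boar.

What linkage equilibrium does not emulate: LD between markers and QTL,
consistency of LD phase across lines, and pedigree relatedness. Passing
tests therefore demonstrate the estimators' correctness and the
frequency-dependence mechanism of crossbred merit, not the accuracy levels
achievable on real SNP-chip data, where marker-QTL LD is the main source
of predictive signal and relationship variance is roughly an order of
magnitude larger.

## Problem sizes used by the test suite

Statistical tests run at sizes chosen so the whole suite completes in
minutes on one CPU while keeping each check's power:

- accuracy-ordering surface: 600 SNPs with the reference 6 % QTL fraction
  (36 QTL), 2000 sows/line, 200 boars x 30 daughters, BayesC 1500
  iterations (300 burn-in), accuracies averaged over 5 seeds x 2 lines;
- REML parameter recovery at the strong-signal unit-test scale
  (n = 400, m = 150) plus an independent EM-REML cross-check; the
  (0.8, 0.12, 9.0) recovery surface runs at its stated n = 1000, m = 3000
  with 20 replicates;
- G-diagonal normalisation at n = 500, m = 2000.

## Known limitations

- Identifiability of sigma2_d at realistic magnitudes (about 1 % of
  phenotypic variance) requires relationship variance that
  linkage-equilibrium genotypes of unrelated animals cannot supply; at
  the simulated scales its single-replicate SE is of order 0.7, so
  REML point estimates of sigma2_d are essentially prior-free noise
  truncated at zero. The estimator itself is unbiased, as the
  informative-design tests show.
- The likelihood-ratio comparison uses plug-in posterior means, not
  maximised likelihoods; its p-values are heuristic.
- No LD, no multi-generation pedigree, no selection; phenotype
  pre-correction (contemporary groups, parity, service sire) is assumed
  already done and is out of scope.
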