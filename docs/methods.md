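# Methods

## The metaprotein factor model

Label-free LC-MS quantitation yields isotope-group intensities that proxy
protein abundance through several noise channels: residual quantitation
noise, wrong or shared peptide identifications, and post-translationally
modified peptides whose trend differs from the protein's proteotypic
peptides. The metaprotein model addresses all three with one mechanism:
peptides are grouped by *co-expression*, anchored on — but not restricted
to — the protein assignment.

Per seed protein (any protein with >= 2 identified isotope groups), over
samples i and candidate peptides j:

    x_ij = mu_j + rho_j * lambda_j * f_i + eps_ij,   eps_ij ~ N(0, psi_j)
    f_i ~ N(0,1),   lambda_j ~ N(0, tau),   rho_j ~ Bernoulli(pi_j)

`pi_j = pi_seed` for the seed protein's peptides, `pi_other` for every
other feature in the table (identified elsewhere or not). Factors are
fitted independently per seed, so one peptide may join several
metaproteins; this per-seed formulation is an interpretive choice — a joint
multi-factor model over all proteins would be the main alternative — and is
what makes the fit embarrassingly parallel and deterministic.

### Inference

Variational EM with a factorized posterior q(f) q(lambda_j, rho_j):

- q(f_i) is Gaussian with precision `1 + sum_j p_j E[lambda_j^2]/psi_j`
  (missing entries simply drop out of the sums — MAR, no imputation);
- q(lambda_j | rho_j=1) is the Gaussian slab posterior, and the inclusion
  probability p_j comes from the Bernoulli–Gaussian *marginal* likelihood
  ratio, `logit p_j = logit pi_j + 0.5[log(s_j/tau) + m_lambda_j^2/s_j]`.
  Integrating the loading out matters: if the loading were a fitted
  parameter, the likelihood-ratio term would be nonnegative at its optimum
  and no peptide could ever fall below its prior — exclusion of discordant
  peptides would be impossible. The `log(s_j/tau)` Occam penalty is what
  lets an uninformative peptide drop out.
- The M-step updates mu_j and psi_j in closed form.

Each update is an exact coordinate maximizer of the evidence lower bound,
so the tracked objective is non-decreasing; convergence is declared when
the ELBO gain falls below `tol * (1 + |ELBO|)`. Initialization is
deterministic: f starts at the first principal component of the
mean-imputed seed-peptide block, so identical inputs and hyperparameters
give bit-identical fits. The score sign is aligned so the mean seed-member
loading is positive (low score = low inferred protein level), and scores
are standardized to mean 0, unit (population) variance.

### Hyperparameters

| name | default | meaning |
|---|---|---|
| `pi_seed` | 0.95 | prior inclusion for the seed protein's own peptides — a strong but non-dogmatic tie to the identification |
| `pi_other` | 0.001 | prior inclusion for foreign/unidentified features — recruitment must be earned by a large likelihood ratio |
| `tau` | 1.0 | prior loading variance (intensities are on log2 scale, scores unit variance) |
| `membership_threshold` | 0.5 | posterior probability defining factor membership |
| `max_iter`, `tol` | 500, 1e-6 | EM budget and relative ELBO tolerance |

With `pi_seed` at its default, a seed peptide is excluded only under
overwhelming evidence; the exclusion mechanism becomes visible at weaker
seed priors (the test suite demonstrates it at `pi_seed = 0.55`). Each
factor reports `% coverage` (share of the seed protein's identified
peptides that are members) and `% signature` (share of members that come
from the seed protein).

## Association

Association is OLS with a two-sided t-test on the genotype coefficient:
additive coding is the C-allele count 0/1/2, recessive coding the
indicator 1{non-CC}, both adjusted for sex (male=1) and race
(Caucasian=1). The additive t-test is the trend version of the one-way
ANOVA; an unordered 3-level genotype F-test (`anova3`) is available behind
a flag. Variance explained is reported in two forms: the primary
definition is the R^2 of the score on the genotype term *alone*, with the
covariate-adjusted partial R^2 as a secondary field — the two can differ
substantially, and which one a published "variance explained" refers to is
often ambiguous. Scans apply Bonferroni control at `family_alpha / K` over
the K factors tested; QQ coordinates use the midpoint rule
`expected_i = -log10((i - 0.5)/K)`.

Degenerate inputs are explicit errors: a constant genotype term is an
undefined test, a rank-deficient design names the dependent columns, and a
constant response returns beta 0, p 1 rather than a 0/0 t-statistic.

## Mediation

The attenuation comparison fits three covariate-adjusted logistic models
on one common sample set: outcome ~ mediator, outcome ~ genotype
(recessive indicator), and the joint model. P-values are likelihood-ratio
tests of dropping the predictor and the primary CI is profile-likelihood;
Wald intervals are emitted alongside. This choice is deliberate: at n ~ 40
with odds ratios far from 1, Wald intervals and LRT p-values disagree (a
CI crossing 1 with p < 0.05 is a typical symptom), and the LRT/profile
pair is the internally consistent one. Quasi-separation (detected by
failed convergence or |coefficient| > 15) flags the ML result and attaches
a Firth bias-reduced fit (Jeffreys-prior penalized likelihood, penalized
LRT p) clearly labelled as such — never silently substituted.

Verdict rule at level alpha = 0.05, applied only when both marginal fits
are significant: `independent` if the mediator loses significance in the
joint model while genotype keeps it; `mediates` if the genotype is the one
attenuated; otherwise `ambiguous`.

## The synthetic-data generator

`SimConfig` defaults are the study conditions the pipeline targets: a
41-sample cohort, C-allele frequency 0.707 (CC ~49% under HWE), sex ~61%
male, race ~78% Caucasian, 10 proteins x 5 peptides (a tenth of the real
proteome scale), loadings uniform on [0.8, 1.2] around log2-intensity
intercepts N(20, 2), residual sd 0.5, 5% missingness, 2% promiscuous
peptides that also load on a random foreign protein. The pQTL protein's
latent score is `1.16 * (centered C-allele count) + N(0,1)`; the outcome
is logistic with intercept 3.0 and a recessive genotype effect of
log(0.03) ~ -3.5 by default (the pleiotropy scenario: no direct protein
effect). The intercept reproduces a ~63% response margin given that
genotype effect. For the full-mediation scenario the direct genotype
effect is zeroed and the protein effect set to 3.5, chosen so the total
genotype-to-outcome signal matches the pleiotropy scenario's magnitude;
peptide-level variance components have no published reference values, so
the residual sd and loading range are plausible desk-scale choices, not
estimates.

Randomness is split into purpose-specific streams (genotypes, covariates,
outcome, scores, loadings, noise, masking, metadata) under one seed, so
changing e.g. the missing rate does not perturb the genotypes.

What the generator does *not* emulate: retention-time drift and alignment
error, isotope-envelope structure, intensity-dependent missingness
(censoring), identification FDR structure beyond random promiscuity, and
linkage with other variants. Passing recovery tests therefore show the
estimator works when the model's assumptions hold; they do not certify
behaviour under informative missingness or systematic misidentification.

## Problem sizes and what the checks show

- Membership/score recovery: 3 datasets at n = 50, 10 x 5 peptides,
  residual sd 0.5; recovery is the fraction of peptides whose fitted
  membership set equals the generating one.
- Slope recovery: 200 replicate cohorts at n = 41; 95% CI coverage of the
  injected additive slope 1.16.
- Calibration: 1000 null association tests (type-I error and KS
  uniformity), 200 replicates of a K = 110 null scan for family-wise error
  under Bonferroni.
- Mediation logic: 200 replicate cohorts per scenario. At n = 200 the
  verdict matches the generating scenario in ~95% of replicates; at the
  study size n = 41 the same scenarios yield ~56% `independent` and ~83%
  `mediates` — with n = 41 and borderline marginal associations the
  attenuation pattern is often unresolvable, which is itself a finding
  about what such a design can support. Both sizes are reported by
  `scripts/acceptance.py`.

## Known limitations

- Per-seed factors ignore correlation between proteins; a peptide shared
  by two co-regulated proteins inflates both factors' membership.
- The variational posterior underestimates score uncertainty; downstream
  tests treat scores as observed, as the original analysis chain does.
- Whether deposited workspace scores were standardized affects the scale
  (not the p-value) of score-on-genotype betas when replicating from a
  workspace that carries precomputed scores.
- Profile-likelihood CIs are bounded searches; under separation the
  relevant bound is reported as infinite and the Firth fallback is the
  usable summary.
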