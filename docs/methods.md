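# Methods

This note documents the models and procedures implemented in `herbivar`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## The experimental design being modelled

The package targets clonal reciprocal-transplant count data: genotypes
collected from source populations in two countries (the plant's native range,
US, and its introduced range, JP), propagated clonally, and replicated in
common gardens in both countries.  The default `DesignSpec` is two US plus
three Japanese source populations with ten genotypes each, five gardens (two
US, three Japanese), and five ramets of every genotype in every garden —
1,250 plants, 250 per source population.  Crossing plant origin with garden
country yields four analysis groups of (genotypes × replicates-per-genotype)
= (20, 10), (20, 15), (30, 10) and (30, 15).

Two traits are scored per plant: a lace-bug damage score — leaves are binned
into four damage levels and counted, and the per-level counts are combined
with weights (0, 1, 2, 3) — and the number of leaves damaged by other
herbivores.  Per-leaf indices (score / total leaves) are computed for
reporting; the regression model consumes the raw counts with log total
leaves as a covariate, which is what a Poisson model with an offset-style
term implies.

The 0–3 integer weights are a declared default, not an inference: ordinal
level scores keep the Poisson response integer-valued, and the weights are
configurable everywhere (an all-ones weighting reduces the score to the
damaged-leaf total).

## Synthetic-data generator

For plant *i* and trait *t* the generator draws

    eta_it = intercept_t + c · log(L_i) + u_{g(i),t} + p_{pop(i),t}
             + q_{gard(i),t} + e_it,        z_it ~ Poisson(exp(eta_it))

with total leaves L_i ~ NegBin(mean 40, dispersion 8) truncated to ≥ 1,
breeding values u ~ N(0, G_lat), population effects p ~ N(0, P_pop), garden
effects q ~ N(0, Q_garden) and residuals e ~ N(0, R_lat).  Defaults:
intercepts (−1.5, −2.5) giving mean counts of roughly 9 and 3 per plant at
40 leaves, c = 1, G_lat = [[0.3, −0.15], [−0.15, 0.3]] (genetic correlation
−0.5, the negative-covariance regime the pipeline is designed to detect),
P_pop = 0.05·I, Q_garden = 0.1·I, R_lat = 0.2·I.  These are moderate,
realistic magnitudes for damage-count GLMMs; all are overridable.

The simulated lace-bug count is the *score*; it is decomposed into
per-level damaged-leaf counts by drawing a level (default probabilities
0.5/0.3/0.2 for the three damaged levels) for one leaf at a time, restricted
to choices that keep the remaining score representable within the remaining
leaf capacity.  The weighted level counts therefore reconstruct the score
exactly, and the generator's output exercises the same preprocessing path as
real data.  This exactness requires integer weights for the damaged levels
including a weight-1 level; the score is capped at (max weight) × (leaf
count), which at the default parameters is a ≈ 10⁻⁶-probability event.

Two optional mechanisms let the generator reproduce the scientific scenarios
of interest: `origin_G` draws breeding values from an origin-specific G
(genetic divergence), and `env_G` draws them independently per garden
country (environmentally triggered change in G, i.e. genotype × environment
interaction in the strongest form — no cross-environment correlation).
Because each fitted group contains a single garden country, the fitted model
remains correctly specified within each group under `env_G`.

What the generator does **not** emulate: spatial structure within gardens,
plant mortality or missingness, temporal repeated measures, within-population
genetic structure, or leaf-level dependence between the two damage types
beyond the latent covariances.  Passing recovery tests therefore show the
estimator is correct *under the model*, not that the model captures every
feature of field data.

## The bivariate Poisson animal model

    z_it ~ Poisson(exp(eta_it))
    eta_it = beta_t + beta_L,t · log(L_i) + u_{g(i),t} + p_{pop(i),t}
             + q_{gard(i),t} + e_it

with u ~ N(0, G), p ~ N(0, P_pop), q ~ N(0, Q_garden), e ~ N(0, R), all
unstructured 2×2.  Genotypes are treated as unrelated (identity relationship
matrix): with clonal replication the genotype variance is a broad-sense
genetic component.  A random component observed at a single level (e.g. one
garden) is dropped with a notice, since its variance is unidentifiable.

*Leaf term.*  The leaf count enters as a per-trait fixed covariate
beta_L,t · log(L_i) with a diffuse normal prior by default; `pin_offset=True`
fixes beta_L = 1 (a true offset).  Both readings are supported because an
"offset" with a prior on its coefficient is a contradiction — a fitted
coefficient is the more general model and contains the offset as a special
case.

*Priors.*  Fixed effects N(0, 10⁸).  Covariances: inverse-Wishart with
nu = 2.002 and scale 0.002·I by default — a standard weakly-informative
choice for 2×2 components — explicit in `PriorSpec`, recorded in every run
manifest, and overridable per component.

*Sampler.*  Metropolis-within-Gibbs.  The latent predictors eta are the only
non-conjugate block: each observation/trait scalar is updated by random-walk
Metropolis under its conditional Gaussian prior (conditioning on the other
trait through R) times its Poisson likelihood, vectorized across
observations.  Proposal scales adapt every 25 iterations during burn-in
toward 0.44 acceptance and are frozen afterwards to preserve detailed
balance; post-burn-in acceptance outside [0.1, 0.7] attaches a warning to
the result.  Given eta, everything is conjugate: location effects
(genotype/population/garden vectors and fixed effects) have Gaussian full
conditionals, and each covariance component is drawn from
IW(nu + n, V + S) with S the cross-product of its effect vectors, via a
Bartlett-decomposition Wishart draw.  Retained draws are symmetrized and
eigenvalue-clipped at zero if numerical error produces a tiny negative
eigenvalue; repairs are counted and reported (none occur in practice).

*Prior-only mode.*  `prior_only=True` removes the likelihood, turning the
sampler into a valid Gibbs chain on the joint prior; the covariance
marginals then reproduce the inverse-Wishart prior mean, which is how the
conditional updates are verified.

*Schedules.*  The default is 65,000 iterations, 15,000 burn-in, thin 50 —
1,000 retained draws; thinning every 5,000 retains 10.  The pipeline's demo
schedule (6,500 / 1,500 / 5, also 1,000 draws) and the test schedule
(6,000 / 2,000 / 4) were chosen as the smallest runs at which two-chain
Gelman–Rubin diagnostics for the G entries sit below 1.1 and replicate-level
HPD coverage is nominal; they make a four-group pipeline run take well under
a minute.  Effective sample sizes (arviz) for G entries at the test schedule
are in the hundreds; the population component, identified from only 2–3
levels, mixes more slowly and is treated as a nuisance.

## Latent-to-observed-scale transformation

Posterior covariances live on the log-link scale.  The observed-scale
genetic covariance is

    G_obs[s,t] = Psi_s · G_lat[s,t] · Psi_t,
    Psi_t = (1/n) Σ_i exp(mu_it + sigma²_t / 2),

where mu_it is the fixed part of the linear predictor (intercept plus leaf
covariate, averaged over the empirical distribution of plants rather than a
single grand mean) and sigma²_t is the *total* latent variance
(G + P + Q + R), since the expected inverse-link derivative depends on the
full latent distribution.  This is the covariance of the additive component
of the expected counts — the part linear in the breeding values — which is
the quantity that enters the multivariate breeder's equation.

The Monte-Carlo oracle (`mc_oracle_transform`) estimates the same quantity
without the lognormal moment identity: it simulates breeding values and
latent noise, forms genotype-level expected counts by brute-force averaging,
regresses them on the breeding values, and takes the covariance of the
fitted values.  The regression step matters: the *raw* covariance of the
exponentiated genotype means is the full genotypic covariance, which exceeds
the additive covariance by a factor (e^g − 1)/g per entry and is therefore
not the estimand of the Psi-scaling; projecting onto the linear span of the
breeding values makes the two routes agree at any variance scale (observed
worst disagreement ≈ 1% at 10⁶ draws over 50 random parameter sets).

Properties that follow and are property-tested: the transform is linear in
G_lat at fixed latent summary (scaling by c > 0 scales G_obs by exactly c),
and sign-preserving (Psi factors are positive).  The observed-scale
phenotypic covariance uses the bivariate lognormal-Poisson identity
cov(z_s, z_t) = λ_s λ_t (exp(Σ_st) − 1) + [s=t]·λ_t, whose diagonal always
exceeds λ (overdispersion).

`transform_posterior` maps every retained draw by default; `sub_thin=100`
reproduces a ten-matrix observed-scale posterior (mirroring analyses where
the transform is expensive), and the tests check the two agree in posterior
median.  Both modes are provided because results should not depend on which
is used.

## Krzanowski shared-subspace comparison

With two traits the recommended subspace dimension is k = 1 (at most half
the trait dimension), so each group contributes its leading eigenvector a_t
and H = a₁a₁ᵀ + a₂a₂ᵀ.  In closed form the eigenvalues are 1 ± |cos θ| for
leading eigenvectors at angle θ: 2 indicates identical orientation, 1 an
orthogonal one.  trace(H) = m·k exactly and eigenvalues lie in [0, m];
both are enforced and property-tested, as is invariance to eigenvector sign
flips.  Eigenvectors use a canonical sign (first nonzero component positive);
exactly degenerate spectra fall back to the lexicographically smallest
canonical-sign basis vectors and are counted in the result.

The observed eigenvalue posterior pairs draw i of group A with draw i of
group B — the chains are independent, so any pairing is valid; index pairing
is deterministic and declared.  The randomization null follows the
pooled-breeding-value construction: per retained draw, the two groups'
genotype breeding-value vectors are pooled, genotypes are randomly
reassigned to groups of the observed sizes (one shuffle per draw by default,
configurable), each group's G is recomputed as the sample covariance of its
vectors, and the H eigenvalues recorded.  Genotypes are the randomization
unit because they are the entities carrying breeding values.  The null
operates on latent-scale breeding values (what the sampler produces);
comparisons can be run on latent-scale G draws (default) or observed-scale
transforms via configuration — the transform preserves eigenvector
orientation structure up to the positive Psi rescaling, and both options are
exposed because the choice is not determined by the method itself.

*Verdict.*  Each eigenvalue is judged "shared" when the 95% HPD intervals of
its observed and randomized samples overlap, "diverged" otherwise; the
overall verdict is diverged if any eigenvalue diverges.  Interval overlap is
tested with an absolute slack of 10⁻⁶, which absorbs floating-point
eigenvalue error in the degenerate case of literally identical subspaces
(where the observed posterior is a point mass at 2 and the null approaches
it to within ~10⁻⁹) while remaining three orders of magnitude below any
scientifically meaningful separation.  No p-value is synthesized.

*HPD intervals* are the shortest contiguous window containing ⌈p·n⌉ sorted
samples, ties resolved to the lowest start; the implementation is
cross-checked against arviz's HDI on continuous samples.  On the integers
1..100 at 95% every window ties and the interval is [1, 95].

*Operating characteristics* (measured by simulation, 30 genotypes and 100
draws per group, 20 replicates): under a common G with a clear leading
direction the shared verdict rate is 100%; with orthogonal leading
eigenvectors and strongly unequal total variance (so the pooled covariance
retains an eigengap) the diverged rate is 100%.  Power degrades by
construction when the pooled covariance is near-isotropic — with no
eigengap, sample leading eigenvectors of the shuffled groups decorrelate and
the null widens; this is a property of the method, not the implementation.

## Pipeline

`run_pipeline` simulates (or loads) a dataset, fits the four groups with
seeds derived deterministically from one master seed (`SeedSequence` spawns,
kept below 2³¹), transforms each posterior, and runs the four
reciprocal-transplant contrasts: same origin across garden countries
(environment effect, two contrasts) and different origins within a garden
country (origin effect, two contrasts).  Run directories are write-once;
posterior CSVs are byte-identical across reruns of the same configuration;
the manifest records config, derived seeds and package version.
`make_report` renders a Table-style summary (posterior median plus 95% HPD
per observed-scale G entry, variances labelled explicitly) and an
eigenvalue-HPD comparison figure, and is idempotent.

An end-to-end regression test simulates environmentally triggered G change
(`env_G` with orthogonal orientations between garden countries: strong
lace-bug variance in JP gardens, other-herbivore variance in US gardens) and
checks the verdict pattern: garden contrasts diverged, origin contrasts
shared.

## Known limitations

- Two traits only; no pedigree beyond the identity matrix; no reduced-rank
  or parameter-expanded covariance formulations.
- The population component is estimated from 2–3 levels per fit and is prior
  sensitive; it is included for structural fidelity, not interpretation.
- The latent residual R and Poisson noise are weakly separated at low
  counts; G recovery is unaffected in the tested regimes but R intervals are
  wide.
- The observed-scale phenotypic covariance formula averages the fixed parts
  inside λ and ignores between-plant variance of mu in the (exp(Σ)−1) term;
  it is exact for a common mu and an approximation otherwise.
- The subspace test's power depends on the pooled covariance retaining an
  eigengap (see above).
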