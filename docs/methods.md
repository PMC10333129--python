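# Methods

This note documents the models implemented in `symphy`, the choices made
where the design was genuinely open, what the synthetic-data generators
emulate, and what the validation studies do and do not establish.

## Scientific setting

The package targets family-level comparative questions about obligate
insect-microbe symbiosis: a family is characterized by the number of
species examined and the number of those with obligate symbionts, its
feeding niche, standardized per-gram nutrient concentrations of its diet,
species richness, age, and metabolism (holo- vs hemimetabolous).
Everything phylogenetic runs on a single time-calibrated ultrametric
family tree (branch lengths in Myr); host-symbiont analyses add a
symbiont phylogeny and an association table.

## Trait-table construction

Nutrients flow through a five-step median cascade: (1) food types used by
each species are recorded per life stage; (2) each food type is
summarized by the median of its example foods, nutrient by nutrient; (3)
amounts are standardized to per-gram by dividing by the food type's mean
item weight; (4) a species' value is the median of its adult-stage and
juvenile-stage values, each a median over that stage's foods - except
omnivores, which average over all foods; (5) a family's value is the
median over its species. Medians with even counts take the mean of the
two middle order statistics. Nutrients missing in more than 30% of
families are excluded (strictly greater; a nutrient at exactly the
threshold stays). Continuous traits are z-transformed with the sample
(n-1) standard deviation over non-missing entries.

Discretizations for the transition-rate models: a family is "obligate"
iff strictly more than half of its sampled species (unresolved species
excluded from numerator and denominator) have obligate symbionts;
nutrients are coded low/high at the 25% and 50% across-family quantiles
(linear-interpolation quantiles; values exactly at the cut count as low).
Family niches: omnivore if any species is omnivorous; specialist niches
require strictly more than half of classified species (configurable).

## Trees

Newick parsing/writing is delegated to dendropy; internally trees are
flat parent/length arrays. Writing normalizes child order, so round
trips preserve topology, labels and branch lengths but not child
enumeration order. Families absent from the published tree are grafted
onto a named sister clade's stem, by default at half its length (option:
at its top), with the new branch length chosen to preserve
ultrametricity; zero-length branches created this way are perturbed by
1e-8 Myr so covariance matrices stay positive definite. Grafted tips are
flagged and excluded from age-sensitive (richness) analyses by default.
Phylogenetic covariance matrices hold shared root-to-MRCA path lengths,
optionally including internal nodes (auto-labelled `N<preorder index>`).

## Discrete-trait engine

The Mk likelihood uses Felsenstein pruning with per-branch transition
matrices from a single eigendecomposition of Q (scaling-and-squaring
expm fallback when the eigenbasis is ill-conditioned); partial
likelihoods are rescaled per node to avoid underflow, and the inner loop
is numba-compiled. The root prior defaults to uniform over states
(option: stationary distribution of Q).

Rate posteriors use random-walk Metropolis on log rates with independent
exponential priors whose mean defaults to the Fitch parsimony change
count divided by total tree length; the proposal step adapts during
burn-in toward ~30% acceptance.

Stochastic character maps sample node states from the conditional scaled
likelihoods (root first, then children given parents), then branch
histories by uniformization conditioned on endpoint states: the event
count is drawn from its exact conditional distribution through powers of
R = I + Q/mu, event times are uniform order statistics, and event states
are sampled backward through the remaining powers; virtual (self) jumps
collapse into dwell segments. Exact marginal ancestral posteriors (an
outside-inside pass) serve as the calibration oracle for map
frequencies.

Node summaries follow two rules: for binary traits a state is assigned
only when its map frequency strictly exceeds 0.5 (ties and splits are
"uncertain" and excluded from origin/loss edges); multi-state niche
summaries use the modal state. Origins and losses are counted on edges
between assigned nodes.

## Correlated evolution of two binary traits

The joint process lives on four combined states (00, 01, 10, 11) with
simultaneous double transitions forbidden. The independent model has 4
rates (each trait's gain/loss, unaffected by the other); the dependent
model has 8 (each conditional on the other trait's state); the dependent
model with tied rates collapses exactly to the independent one (a tested
identity). Rates carry exponential priors whose mean m has a
uniform(0, 10) hyper-prior. The published description seeds "the mean
and variance" of an exponential from that uniform; a one-parameter
exponential cannot take both, so only the mean is seeded. The joint
(rates, m) posterior has a funnel that random-walk MH cannot cross; m is
therefore Gibbs-sampled from its conditional, a truncated
inverse-gamma(n_rates - 1, sum of rates), which is valid at any
power-posterior temperature because m never enters the likelihood.

Marginal likelihoods come from stepping-stone sampling along powers
beta_k = (k/K)^(1/0.3) (quantiles of Beta(0.3, 1)), annealing from the
posterior toward the prior with warm starts between stones; each stone
contributes a log-mean-exp of (beta_{k+1}-beta_k) x log-likelihood.
Evidence is reported as BF = 2(lnML_complex - lnML_simple) with the
2/5/10 thresholds for positive/strong/very strong. Model-comparison
practice at full scale uses 100 stones x 1000 iterations (the setting
validated against the conjugate Beta-Bernoulli toy to < 0.1 nats);
the simulation studies use 24 x 250, which piloting showed loses little
discrimination at 150 tips.

## Phylogenetic mixed models

A latent Gaussian model underlies all three response families: each
observation's latent value is fixed effects + covariance-structured
random effects + residual. Gaussian responses are their own latents
(missing values imputed from their conditionals); binomial counts use a
logit link with the latent updated by adaptive random-walk Metropolis
(target ~40% acceptance, per-response step adapted in burn-in); Poisson
uses a log link likewise. The fixed effects and the first random term are drawn jointly from
their exact Gaussian conditional (separate blocks mix very slowly when a
high-variance phylogenetic field can trade off against clade-aligned
fixed effects); remaining random terms update block-wise, each one
Cholesky per iteration. Fixed effects are initialized at the least-
squares fit of the initial latents; variance components update by inverse-Wishart
(unstructured across responses) or inverse-gamma ("idh", independent per
response) conditionals with the weak (V = I, nu = dim - 1 + 0.002)
prior convention. Parameter-expanded priors were considered and not
implemented: at the problem sizes used here plain conditionals mix well
enough that planted-parameter credible intervals calibrate correctly
(94-96% empirical coverage at nominal 95%; see the validation studies).
The binomial residual variance is not identifiable and is fixed at 1 on
the latent scale; binomial fixed effects get the roughly
probability-flat prior variance 1 + pi^2/3. Unstructured *residual*
covariances are supported only for all-Gaussian models; mixed-family
models use diagonal residuals, and cross-trait conclusions rest on the
unstructured phylogenetic covariance.

Derived quantities: intraclass correlations ICC = V_term / (sum of
V_random + V_e + link variance), with link variance pi^2/3 for logit and
0 otherwise; phylogenetic heritability is the phylogenetic term's ICC;
phylogenetic correlations are cov/sqrt(var x var) per draw from the
unstructured term. Summaries report KDE (Silverman) posterior modes,
95% highest-density intervals (quantile intervals available), and
pMCMC = 2 min(#{<=0}+1, #{>=0}+1)/(N+1), capped at 1. Multi-chain
convergence uses the Gelman-Rubin PSRF (flagged above 1.1) and ESS via
arviz.

Ancestral node prediction kriges the phylogenetic effects: internal-node
effects are conditional multivariate normal given tip effects under the
tips+nodes covariance, drawn once per retained iteration ("marginal"
mode; a "plugin" conditional-mean mode exists for smoke tests), added to
the intercept and inverse-linked. Covariance matrices are scaled to unit
height and jittered by 1e-8 before inversion.

## Host-symbiont analyses

Variance partitioning operates on the full grid of host x symbiont
combinations (the contrast between occurring and non-occurring
combinations is what identifies interaction structure) with binomial
counts of species with/without each symbiont. Four random structures:
h (exchangeable host effects), [h] (host phylogenetic covariance), [s]
(symbiont phylogenetic covariance), [hs] (Schur product of the two,
PSD by the Schur product theorem, capturing co-evolutionary matching).
The host-level structures are parameterized at host/symbiont level -
expanding a host covariance to combination rows makes it rank-deficient
and numerically unusable - while [hs] lives on rows. Vertically
transmitted symbionts are excluded by default since they inflate
co-phylogenetic signal through inheritance rather than recruitment.

ParaFit: principal coordinates of the two patristic distance matrices
(Lingoes correction when negative eigenvalues appear), global statistic
= sum of squared entries of B_s' A' B_h, p-value from permutations that
reassign each symbiont's host links uniformly, p = (1 + #{perm >=
obs})/(n_perm + 1), default 1000 permutations. The implementation was
cross-checked against an independent R implementation during
development (statistics agree to 8 significant figures).

## Before/after analysis of nutrient transitions

Internal nodes are classified by their state and their immediate
descendants' states into NonToNon, NonToOb (precedes an origin), ObToOb
(maintenance) and ObToNon (precedes a loss); ties at the 0.5 posterior
probability go to the ancestral (non-obligate) state. Classification
uncertainty propagates by repeating the downstream model over resampled
classifications (default 100), each thresholding one posterior draw of
the node-state field at 0.5 - a joint, spatially coherent sample, so
transition boundaries move together between resamples (independent
per-node Bernoulli sampling is available as an option). Each resample
pairs its classification with one posterior draw of the kriged node
nutrient values (per-draw conditional means), so posterior uncertainty
in the ancestral field propagates as well; adding the node-wise
conditional simulation noise on top is supported but swamps the
category signal at desk scale and is off by default. Per resample, a Gaussian
multi-response model of node B5/B9 with the category factor (no
intercept) and the internal-node phylogenetic covariance retains ~10
draws (desk-scale 1100 iterations thinned by 100, mirroring the shape
of full-length runs at 1/100 cost; full-scale settings are a parameter);
pooled draws (resamples x retained) yield the origin (NonToOb -
NonToNon), maintenance (ObToOb - NonToNon) and loss (ObToNon - ObToOb)
contrasts with pMCMC values. Contrast direction is later-minus-earlier
category throughout. The node nutrient values are reconstruction
output, not data, so these contrasts inherit the usual caveat of
two-step ancestral analyses: effects are attenuated near classification
boundaries, and significance rests on the number of independent origins
rather than the number of nodes.

## Diversification

Species richness is modelled directly (never converted to
diversification rates): a multi-response model of the obligate
proportion (binomial) and richness (Poisson) with standardized family
age and metabolism as fixed effects and an unstructured phylogenetic
covariance, whose off-diagonal is the headline symbiosis-richness
correlation; focal-vs-background Poisson refits per niche x symbiosis
cell; a Poisson sister-pair model (two rows per cherry) with
empirical-logit percentage obligate (eps = 0.5/n) and pair age as fixed
effects and pair identity + pair node (linked to the internal-node
covariance) as random effects; and a Gaussian model of log2 richness
ratios over pairs that differ in percentage obligate, oriented so the
higher-percentage member is the numerator (estimates are invariant to
reorientation, a tested antisymmetry). Grafted families are excluded
by default.

## Synthetic data

Generators are deterministic under a seed and emit truth sidecars.
Trees: birth-death conditioned on the tip count (defaults birth 1.0,
death 0.5), rescaled to a 400-Myr root age echoing the insect timescale;
the simulator stops exactly at a birth event, so all tip branches are
extended by one exponential waiting time (memoryless continuation) to
remove the zero-length cherry. Discrete traits: exact CTMC simulation
with retained histories. Continuous traits: multivariate Brownian
phylogenetic effects with a specified cross-trait correlation matrix
plus independent noise to hit per-trait heritabilities (defaults 0.8,
within the 0.7-0.96 range typical of dietary nutrients); the binary
symbiosis trait is generated exactly as the binomial-logit model
assumes - liability = intercept + phylogenetic effect + unit-variance
residual, per-family counts Binomial(n_sampled, logistic(liability)),
n_sampled ~ 1 + Poisson(3). A second, Mk-based binary generator serves
the discrete-engine tests. Host-symbiont associations: a mirrored
symbiont tree with each link kept with probability `signal` else
reassigned at random. Richness: Poisson with log-rate = base + age +
trait + phylogenetically structured clade effect, truncated at 1 with
the truncation count recorded. The state-linked nutrient generator adds
to Brownian motion a shift proportional to the lineage's dwell time in
the derived state (saturating at a configurable horizon, default a
quarter of tree height): diets specialize gradually after symbiosis is
acquired, so ancestors immediately preceding an origin carry no shift.

What the generators do not emulate: real taxon sampling, the marginal
distributions of real nutrient data, literature-driven measurement
error, or correlated missingness. Passing validation studies therefore
demonstrates statistical correctness and power under the stated
generative assumptions, not agreement with any empirical dataset.

## Validation studies and problem sizes

The slow tier (tests/test_acceptance.py, mirrored by
scripts/acceptance.py) runs: exactness of pruning vs enumeration (100
random trees of 3-5 tips, relative error < 1e-9); stochastic-map
calibration (20 instances x 50 tips x 1000 maps; at least 99% of
node-state cells consistent with the analytic marginals at the 3-SE
level, judged by exact central binomial intervals since the normal
approximation breaks down at tiny probabilities - a perfect sampler
gives 99.73%, and a literal all-cells bound would fail by chance); stepping-stone error on the Beta-Bernoulli toy (< 0.1 nats
at 100 x 1000); Bayes-factor discrimination on 150-tip trees (20 + 20
simulations); credible-interval coverage of a planted phylogenetic
correlation (-0.4) and heritability (0.8) over 100 bivariate fits of
80-tip datasets (band 85-99%); the before/after transition pattern over
20 conditioned replicates (80-tip trees, post-origin decline of 7
standard-deviation units saturating over 0.6 of tree height); ParaFit under perfect congruence and under
the null (200 simulations); and [hs] dominance over planted interaction
fields. Replicate datasets for the transition study are conditioned on
at least 3 independent origins, intermediate prevalence, and realized
dietary specialization among obligate tips - the informative regime the
empirical data occupy (16 origins, 89/402 families) - because with a
single origin the origin contrast has one phylogenetically independent
datum and no analysis can separate it from clade-level drift.

## Known limitations

- Beyond the first random term, location effects update in separate
  Gibbs blocks; models with several confounded covariance structures mix
  more slowly than a fully joint update would.
- No reversible-jump exploration of rate-equality partitions in the
  correlated-evolution models; no covarion/hidden-rate models; no
  polymorphic tip states.
- Mixed-family residual covariances are diagonal (see above).
- The before/after analysis is two-step by construction; a joint model
  of trait and nutrient evolution is deliberately out of scope.
- Node-prediction and transition analyses assume the fitted tree is the
  true tree; topological uncertainty is not propagated.
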