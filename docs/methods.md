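# Methods

## Problem

A panel of fully inbred recombinant strains (typically n ≈ 29) is genotyped
at p markers (typically ≈ 770 across 20 chromosomes) and a transcript's
expression is measured in q tissues (q = 1 single-tissue, q = 4 joint).
The goal is multi-locus eQTL mapping: identify the small subset of markers
whose founder alleles jointly explain the expression of a probe, shared
across tissues, together with calibrated uncertainty.

## Model

Let Y be the column-centred n × q expression matrix and X the n × p matrix
of founder genotype codes (−0.5 / +0.5; fractional values for imputed
calls). A binary indicator vector γ selects a subset of markers. Given γ,

    Y = X_γ B_γ + E,    rows of E iid N(0, Σ),

with a matrix-variate conjugate prior: B_γ | Σ ~ matrix normal with row
covariance τ (X_γᵀX_γ)⁻¹ (a g-prior) and column covariance Σ, and
Σ inverse-Wishart with scale Q = k I_q and shape δ (Dawid's convention;
E[Σ] = Q/(δ − 2)). Integrating B and Σ analytically gives the marker-set
score, up to a γ- and τ-free constant,

    log f(Y | γ, τ) = −(q·p_γ/2)·log(1+τ)
        − ((n+δ+q−1)/2)·log det( Q + YᵀY − τ/(1+τ)·YᵀP_γY ),

where P_γ is the orthogonal projector onto the column span of X_γ.
At q = 1 this reduces exactly to the familiar single-response g-prior
marginal, which is unit-tested against an independent QR-based
implementation and against direct Monte-Carlo integration of the
un-integrated model.

### Priors

* **Model size.** γ is exchangeable given its size; the size follows a
  Beta-Binomial distribution whose (a, b) are solved in closed form from a
  prior expected size e (default 2) and variance v (default 2). Each model
  of size k carries weight size-prior(k) / C(p, k), so total prior mass is
  spread over sizes, not over individual models — at p in the hundreds this
  makes the null the preferred model on pure noise.
* **Shrinkage τ.** A single τ shared by all markers with density
  ∝ (1+τ)^(−3/2) truncated to (0, max(n, p²)]. τ is discretised on a
  geometric grid; each grid point receives mass proportional to density ×
  log-space cell width (trapezoid rule). Weighting by density alone would
  add an implicit 1/τ factor on a geometric grid and systematically
  over-shrink effect estimates; the width-corrected measure reproduces the
  continuous distribution's interval probabilities to ~1e−3 at the default
  grid size (100 points).
* **Scale.** k = 0.1 × mean per-tissue sample variance by default, a
  weakly-informative inverse-Wishart scale; δ = 3, the smallest shape with
  a finite prior mean.

## Sampler

Posterior exploration over (γ, τ) uses an evolutionary stochastic search:
a small population of chains at geometrically spaced temperatures, each
sweep performing

1. a local add / delete / swap Metropolis move per chain (with exact
   Hastings corrections at the size boundaries),
2. with fixed probability, a uniform or one-point crossover between two
   random chains (accepted jointly),
3. an adjacent-pair temperature exchange,
4. a Gibbs draw of the shared τ from its grid posterior given the cold
   chain's model.

The temperature-ladder ratio adapts by stochastic approximation toward a
target exchange rate during burn-in and is frozen afterwards, keeping the
post-burn-in chain Markovian. A convergence warning (never an error) is
emitted if the cold chain's best joint score is still improving in the
final 10% of sweeps.

All post-burn-in cold-chain models are recorded. Reported posterior
quantities are computed by **renormalising the exact τ-integrated
posterior over the unique visited models** rather than from raw visit
frequencies, which removes Monte-Carlo noise for every quantity restricted
to the visited set. The trace is additionally Rao-Blackwellised: the null
model and every feasible single-marker model always enter the visited set
with their exact weight, so marginal inclusion probabilities resolve
markers the chains never visited instead of tying them at zero.

## Declarations and FDR calibration

Per probe the headline outputs are the marginal posterior probability of
inclusion (MPPI) per marker, the posterior over model sizes, the best
(maximum posterior) model, and the log10 Bayes factor of the best model
against the null. A probe is declared an eQTL when that Bayes factor
clears a cutoff linear in model size, base + increment × (size − 1).
The cutoff is calibrated empirically: strain rows of each expression panel
are reshuffled jointly across tissues (severing genotype–phenotype links
while preserving cross-tissue covariance), the model is refit, and among a
small family of dimension-linear rules the one declaring the most
real-data positives subject to (null positives / real positives) ≤ the
target FDR is chosen.

## Post-processing

* **Collapsing.** Included markers within 5 cM on the same chromosome are
  collapsed to one control point represented by the highest-MPPI member;
  clusters at least 10 cM apart count as distinct eQTLs.
* **cis / trans.** A control point within 10 Mbp (inclusive) of the probe
  on the same chromosome is cis, otherwise trans.
* **Noticeable markers.** Cluster members carrying at least a fraction κ
  of the declared models' weight are flagged.
* **Effect sizes.** Per-tissue effects are summarised by draws from the
  exact conditional posterior of (Σ, B) given the declared model, with τ
  marginalised over its grid posterior; the posterior mean equals a
  τ-weighted ridge estimate and is verified against that closed form.
* **Residual correlation.** The posterior mean of the residual correlation
  matrix diagnoses how much apparent cross-tissue correlation the genetic
  model explains.

## Comparators

Classical single-marker methods for benchmarking: a two-sample Hotelling
T² scan across tissues (groups by founder allele, F-transformed p-values,
Box's M covariance-homogeneity flag), a univariate marker-regression scan
with permutation genome-wide p-values (add-one corrected), a two-stage
sequential search for up to two additive loci gated by Storey q-values,
and a Storey q-value implementation with the cubic-smoother π₀ estimate.

## Simulator

Two-founder recombinant-inbred genotypes are simulated as a two-state
Markov chain along each chromosome with per-interval switch probability
R = 4r/(1 + 6r), where r is the Haldane recombination fraction of the
marker interval — the standard inflation of the recombination fraction for
inbreeding by sibling mating. Expression scenarios plant cis and/or trans
effects shared across tissues on exchangeably correlated residual noise
(correlation 0.7 / 0.4 / 0.1 for strong / medium / weak). Effects are
standardized: an effect of size e contributes genetic standard deviation
e in residual-sd units, so the regression coefficient is 2e under the
±0.5 coding. Defaults: cis 1.5, trans 0.5, n = 29, q = 4, 20 chromosomes ×
39 markers at 2.5 cM.

The simulator is a study-condition generator, not a fit-for-purpose
emulator of array data: probe-level noise, normalisation artefacts and
founder-allele frequency skew are out of scope.

## Numerical choices

* Scores are computed from cached sufficient statistics (YᵀY, per-model
  QR projections); the τ grid likelihood per model is cached, making the
  τ-Gibbs step and evidence summation O(grid) after first evaluation.
* Rank-deficient marker subsets (duplicate genotype columns are common at
  tight linkage with n ≈ 29) raise an explicit error naming the collinear
  members at scoring time; the sampler auto-rejects such proposals.
* All stochastic entry points accept either a seed or a Generator;
  identical seeds give byte-identical outputs end-to-end.

## Known limitations

* The τ prior shrinks effect estimates: at n = 29 with unit planted
  effects and moderate noise, posterior-mean effects sit several percent
  below the generating values, so recovery checks use calibrated posterior
  intervals rather than raw point-estimate windows.
* Weak, distributed signals (several ≈ 0.5-sd trans effects) may not enter
  the best model at realistic marker counts: the size prior's multiplicity
  cost grows like log p while a shared weak effect's evidence is bounded —
  and strong positive residual correlation *reduces* the information that
  q tissues carry about a shared mean shift (effective tissue count
  q/(1 + (q−1)ρ)). Full-curve marker-ranking comparisons against an
  unpenalised multivariate scan can therefore favour the scan in
  weak-signal regimes, even when the Bayesian model is better at
  declaring sparse, well-supported eQTLs at controlled FDR.
* The Box's M check and Hotelling scan require both allele groups to have
  at least q + 1 strains; markers failing this are reported as skipped,
  not dropped silently.
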