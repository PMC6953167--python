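# Methods

## Model

Each condition k ∈ {1, 2} is described by a linear structural equation
model over p genes and q cis-eQTLs observed on n individuals:

    Y(k) = Y(k) B(k) + X(k) F(k) + E(k),

with Y(k) the n×p expression matrix, B(k) the p×p matrix of directed
regulatory effects (zero diagonal: no self-regulation), X(k) the n×q
genotype matrix, F(k) the q×p cis-eQTL effect matrix with known support
(which eQTL feeds which gene is assumed established beforehand), and
E(k) i.i.d. Gaussian noise. The known, gene-specific eQTL supports act as
instruments: they render the directed network identifiable, including for
cyclic topologies, where purely observational expression data could not
distinguish members of an equivalence class.

The target of inference is the pair (B(1), B(2)) and their difference
ΔB = B(1) − B(2), whose support is the set of rewired or re-weighted
regulatory interactions between the conditions.

## Per-gene integrated regression

Because column i of B only enters the i-th structural equation, the two
SEMs decompose into p paired regressions. For gene i, condition k:

    y_i(k) = Y_-i(k) b_i(k) + X_Si(k) f_i(k) + e_i(k),

with Y_-i the expression matrix without gene i's column and X_Si the
genotype columns of gene i's eQTL support S_i (q_i = |S_i|). The two
conditions are merged into one regression of dimension 2 p_i
(p_i = p − 1 + q_i):

    y_i = W_i β_i + e_i,   y_i = y_i(1) + y_i(2),
    W_i = [W_i(1), W_i(2)],  β_i = [β_i(1); β_i(2)],

i.e. a summed response against the horizontally concatenated designs.
This is implemented literally; the residual e_i = e_i(1) + e_i(2) is a
single Gaussian vector whose variance σ² is estimated as the residual
variance of the integrated model (so its posterior concentrates near
twice the per-condition noise variance). Both conditions must have the
same sample size; this is a structural constraint of the summed-response
formulation. The coordinate pairing (k, p_i + k) identifies the same
regressor under the two conditions, so the fused penalty on
β_{p_i+k} − β_k shrinks cross-condition differences.

## Fused shrinkage prior and its exact joint

Sparsity of both the networks and their difference is encoded by a fused
lasso–type prior, expressed as a scale mixture of normals: each
coefficient β_j carries a local variance τ_j² ~ Exp(ψ_{1,j}), and each
cross-condition difference carries a fusion variance ω_k² ~ Exp(ψ_{2,k}).
Conditionally on the scales, β is Gaussian with precision

    Σ_β⁻¹ = diag(1/τ_j²) + fusion terms,

whose only off-diagonal entries are −1/ω_k² at the pairs (k, p_i + k).
Adaptive per-coordinate Gamma(a, b) hyperpriors on the ψ's take the role
of the lasso tuning parameters (one per penalized term, as in the
adaptive lasso), and σ² gets an Inverse-Gamma(ν₀/2, η₀/2) prior.

A point that matters for correctness: the scale-mixture construction
produces 3 p_i Gaussian kernels for the 2 p_i coefficients (one per
coefficient plus one per difference), so the "hierarchy" is unnormalized
as written — the product of kernels is not a normalized density in
(β, τ², ω²) jointly. We define the model's joint distribution as that
product (globally normalized), which is the joint whose full conditionals
are exactly the standard ones:

* β | · ~ N(A⁻¹Wᵀy, σ²A⁻¹), A = WᵀW + Σ_β⁻¹;
* σ² | · ~ InvGamma(ν/2, η/2) with **ν = n + 3 p_i + ν₀** and
  η = ‖y − Wβ‖² + βᵀΣ_β⁻¹β + η₀. The 3 p_i term counts every Gaussian
  kernel tied to σ²; a smaller count is not invariant for any proper
  joint with these conditionals (empirically the chain's σ² then drifts
  without bound in the joint-distribution test);
* 1/τ_j² | · ~ InvGauss(√(2ψ_{1,j}σ²/β_j²), 2ψ_{1,j}), and analogously
  1/ω_k² with the squared difference in place of β_j²;
* ψ_{1,j} | · ~ Gamma(a + 1, rate b + τ_j²), analogously ψ_{2,k}.

Under this joint the nominal hyperpriors are slightly tilted: σ² is
marginally InvGamma((ν₀ + p_i)/2, η₀/2), each ψ_{2,k} gains a √ψ factor,
and coefficient pairs are coupled by a Laplace factor on their
difference. These tilts are closed-form, which is what makes the exact
prior sampler in `diffsem.checks` possible: σ² and ψ are drawn from their
tilted marginals, the scaled coefficient pair (u_a, u_b) = β-pair/σ by
rejection from independent Laplace proposals with acceptance weight
exp(−√(2ψ₂)|u_b − u_a|), and the scales from their exact conditionals.

## Gibbs sampler and convergence

Each per-gene posterior is explored with `n_chains = 3` independent
chains from overdispersed starts (chain one at β = 0, the others at
jittered ridge estimates; all scales 1; σ² at the sample variance of y).
A sweep updates β, σ², the scales, then the ψ's. Every
`check_interval = 500` sweeps the classic potential scale reduction
factor R̂ is computed over the second half of each chain for every β
coordinate and σ²; once max R̂ < 1.1 the sampler draws
`post_draws = 1000` further sweeps per chain and pools them for the
posterior mean and the 95% equal-tailed interval (2.5%/97.5% sample
quantiles). If `max_iter = 20000` sweeps pass without convergence the
run returns with a warning flag rather than failing. Geometric
ergodicity holds for n > 3, so convergence is typically reached at the
first or second check.

Numerical guards: the reciprocal scales are clamped to [1e−10, 1e10] and
the inverse-Gaussian conditional mean is capped at 1e10 when a
coefficient (or difference) is numerically zero — the strong-shrinkage
regime — so chains remain finite and strictly positive indefinitely. A
failed Cholesky factorization of A is retried once with 1e−8·I jitter.
β is drawn via the Cholesky factor of A; no matrix inverse is formed.

Defaults a = 1, b = 0.1, ν₀ = η₀ = 1 make the hyperpriors essentially
noninformative; all are configurable.

## Sparsification and differential edges

Shrinkage posteriors have no exact zeros, so point estimates are
thresholded: entries with |value| strictly greater than t = 0.2 are
retained verbatim. The differential network is the entrywise difference
of the two thresholded matrices, itself sparsified at the same t —
without this, sampling noise leaves a (tiny) nonzero difference at every
shared edge and the differential support would be meaningless. A
consequence worth knowing: a true weight change smaller than t is
undetectable by construction, even from exact estimates.

For noisy cohort data two further filters are available: a
relative-change criterion retaining (i, j) iff
|B₁ᵢⱼ − B₂ᵢⱼ| > min(|B₁ᵢⱼ|, |B₂ᵢⱼ|)/5 (absolute values — a signed
minimum would make the bound vacuous for sign-mixed pairs), and
bootstrap stability: individuals are resampled with replacement
(independently per condition; the cohorts are treated as unpaired, with
paired resampling behind a flag), inference is re-run on each of
`n_boot = 100` resamples, and an edge is kept iff detected strictly more
than `keep_count = 80` times.

## Synthetic-data generator

The simulator emulates a genetical-genomics design. Condition 1's
topology is a random DAG (uniform node permutation, edges uniform in the
induced strict upper triangle) or DCG (edges uniform off-diagonal,
redrawn until a cycle exists) with n_e·p edges. Condition 2 rewires
n_d = round(0.1·nnz) cells (rounded to the nearest even integer, floor
2): n_d/2 deletions and n_d/2 additions, additions in DAG mode
restricted to the original topological order. Edge weights are drawn
uniformly from (−1, −0.5) ∪ (0.5, 1); of the edges shared between the
conditions, n_d/2 are re-drawn in condition 2 (weight-only differential
edges) and the rest copied. Each gene receives exactly two unit-effect
cis-eQTLs (F is a random row permutation of two stacked identity
matrices, shared by both conditions); genotypes are i.i.d. draws from
{1, 2, 3} with probabilities (0.25, 0.5, 0.25), the 1:2:1 segregation of
an F2 cross, drawn independently for the two cohorts. Expression solves
the SEM exactly: Y = (XF + E)(I − B)⁻¹ with E ~ N(0, σ²); weight draws
with cond(I − B) > 1e8 are rejected and re-drawn.

What the generator does not emulate: measurement noise beyond i.i.d.
Gaussian errors, non-genetic confounding, linkage between eQTLs,
allele-frequency variation, unequal cohort sizes, or misspecified eQTL
supports. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not
robustness to their violation.

## Evaluation protocol

PD (power of detection) is the fraction of true edges recovered and FDR
the fraction of reported edges that are false, computed on supports
(signs and magnitudes ignored), with FDR defined as 0 for an empty
estimate. The paired-network metrics pool true/false positives over both
conditions; the differential metrics compare the support of the
thresholded ΔB estimate with the exact set of entries where the true
networks differ. Replicated studies average these metrics over
independently seeded simulations.

The bundled acceptance script uses p = 10, n = 200, n_e = 1, σ² = 0.01,
t = 0.2 with 5 replicates per topology class — a deliberately compact
version of the replicated-study protocol that preserves its qualitative
regime (network PD ≈ 1, FDR ≈ 0) at a few minutes of single-core
runtime.

## Known limitations

* Equal sample sizes per condition are required by the summed-response
  formulation.
* The threshold t is subjective; smaller t trades FDR for PD. Weight
  changes below t are invisible to the differential network.
* For large p/n the sampler can mix slowly despite geometric ergodicity,
  and interval estimates inherit shrinkage bias toward zero for small
  coefficients (intervals for strongly shrunk null coefficients are not
  calibrated confidence intervals).
* Per-gene regressions are inferred independently; the joint coherence
  of the assembled network (e.g. global acyclicity for DAG data) is not
  enforced.
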