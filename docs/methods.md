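# Methods

## Model

A landscape is a function `f` from genotypes to a real phenotype. We place a
zero-mean Gaussian-process prior over landscapes with covariance `k(x, x′)`
and assume Gaussian measurement noise, so observed phenotypes are
`y = f(x) + ε`, `ε ~ N(0, σ_x² + σ_n²)` with `σ_x²` a known per-measurement
assay variance (zero when unavailable) and `σ_n²` a learned uniform term.
Predictions use the standard conditional-Gaussian identities: with training
kernel matrix `K`, noise covariance `E = diag(σ_x²) + σ_n² I` and
cross-covariances `k_x`,

```
mean(x) = k_xᵀ (K + E)⁻¹ y
var(x)  = k(x, x) − k_xᵀ (K + E)⁻¹ k_x .
```

Everything is exact and dense (Cholesky); there is no inducing-point or
iterative machinery. The intended regime is up to a few thousand training
sequences, which covers complete combinatorial landscapes for short
sequences and subsampled designs for longer ones.

## Kernels and their parameters

The product-family kernels multiply one factor per differing site:

- **geometric** — `σ²(1−δ)^d`, a single shared decay factor. Parameterized
  as `1−δ` rather than a decay base `β` so that the reduction to the
  site-specific family is literal (`β = 1−δ`).
- **connectedness** — site-specific `δ_p`. `1−δ_p` is exactly the prior
  correlation in phenotypes and in mutational effects between two
  backgrounds differing only at site `p`; factors multiply across sites.
  The classical epistatic-probability parameterization `μ_p` maps onto decay
  factors via `δ_p = αμ_p / (1 + (α−1)μ_p)` (`mu_to_delta`); the alphabet
  size enters as an explicit argument since the map is per-site.
- **Jenga** — allele-specific `δ_p^a`; a differing site contributes the
  geometric mean `√((1−δ_p^a)(1−δ_p^{a′}))`. This is the unique
  symmetric-in-alleles form that (i) collapses to the connectedness factor
  when all alleles at a site share one δ, (ii) gives exactly zero covariance
  whenever either allele has δ = 1, recovering the House-of-Cards kernel
  `σ² I` in the all-ones limit, and (iii) matches an automatic-relevance-
  determination kernel on one-hot encodings. Jenga decay factors are
  restricted to [0, 1]: the geometric-mean form has no real value when
  exactly one factor exceeds 1.
- **general product** — mutation-specific symmetric `δ_p^{a,a′}` with zero
  diagonal; the most general homoscedastic product kernel. A Jenga kernel
  embeds via `δ_p^{a,a′} = 1 − √((1−δ_p^a)(1−δ_p^{a′}))`.
- **VC** — isotropic, `k(d) = Σ_{k=0}^{ℓ} λ_k W_k(d)` with normalized
  Krawtchouk polynomials `W_k(0) = 1`, so `λ_k` is literally the expected
  order-`k` variance and `Σλ_k = σ²`. The order-0 (constant) component is
  carried but defaults to 0 for zero-mean priors. Uniform alphabets only;
  mixed-alphabet spaces get the product families.

### Positive definiteness

For geometric/connectedness kernels, decay factors in [0, 1] are sufficient:
each per-site factor matrix (`1` on the diagonal, `1−δ` off it) has
eigenvalues `δ` and `1 + (α−1)(1−δ)`, both nonnegative. The full kernel
matrix over the complete space is the Kronecker product of the per-site
factor matrices, so per-site PSD-ness is sufficient at any space size. For
the general-product family the [0, 1] range alone is **not** sufficient once
`α ≥ 3` (example: pair deltas (1, 0, 0) on three alleles give a factor
matrix with determinant −1); `validate_psd(..., "domain_check")` therefore
eigen-checks each `α×α` factor matrix directly. Some decay factors above 1
still yield valid kernels (anticorrelated, "egg-box" landscapes); these are
opt-in (`allow_extended=True`) and validated by `eigen_check`, a full-space
eigenvalue test available for spaces up to 4096 genotypes with tolerance
`min eig ≥ −1e−9 · max eig`. The exact admissible region beyond [0, 1] is
not characterized here; `eigen_check` is the conservative arbiter.

## Variance components

On a uniform-alphabet space the Hamming graph's adjacency algebra decomposes
landscape space into orthogonal eigenspaces `V_0 … V_ℓ`, one per interaction
order, with `dim V_k = C(ℓ,k)(α−1)^k` and projectors
`P_k(x,x′) = (dim V_k / α^ℓ) W_k(d(x,x′))`. The expected order-`k` variance
of any kernel is `λ_k = trace(P_k K)/α^ℓ`. Two routes are implemented and
cross-checked: brute-force projection of the full-space kernel matrix (works
for anisotropic kernels, spaces ≤ 4096 genotypes) and the inverse Krawtchouk
transform of the distance profile (isotropic kernels, any length). The
brute-force projector formula is taken as the defining contract for
anisotropic kernels; any future closed form must match it.

Krawtchouk values are computed from the exact integer sum
`K_k(d) = Σ_q (−1)^q (α−1)^{k−q} C(d,q) C(ℓ−d,k−q)` normalized by
`K_k(0)`, with the final division the only floating-point step — adequate
through `ℓ ≈ 60` before binomial growth erodes precision, far beyond the
enumerable regime where the values are consumed.

## Fitting

Hyperparameters maximize the log marginal likelihood
`−½ yᵀ(K+E)⁻¹y − ½ log|K+E| − (n/2) log 2π`, computed by Cholesky
factorization with escalating jitter (`1e−10 σ²`, ×10 per retry, failing
beyond `1e−4 σ²`). Optimization runs in an unconstrained reparameterization
(`σ² = e^θ`, `σ_n² = e^θ`, `δ = logistic(θ)`, VC `λ_k = e^{θ_k}`) with
L-BFGS-B and finite-difference gradients, bounded to |θ| ≤ 30 to keep the
maps away from overflow; correctness is defined by the evidence value (cross
-checked against a dense multivariate-normal log-density oracle to 1e−8),
not by the gradient path. The reference first-order settings (learning rate
0.02, 500 iterations) are recorded in `FitConfig` as metadata; the contract
is "best evidence over `restarts` runs, deterministic given seed".

Initialization: `σ²` = empirical phenotype variance; uniform decay factors
with `(1−δ₀)^D = 0.1` at the maximal Hamming distance `D = ℓ` of the space
(so correlation decays to 0.1 across the space's diameter); the VC spectrum
initializes to the geometric-equivalent transform of that profile; the noise
term starts at 5% of the phenotype variance (a small, data-scaled value; the
reference description does not specify one). Five independent restarts
(first from the deterministic initialization, the rest perturbed by seeded
N(0, 0.5²) noise in θ) guard against local optima; the best evidence wins.
Because δ passes through a logistic map, δ = 1 is reached only
asymptotically — irrelevant at the ±0.1 recovery tolerances used here.
Constant-phenotype inputs return a near-zero-variance model with a warning.
A list of genotype tables sharing one sequence set is fit jointly as
independent replicate landscapes (the evidence adds; one Cholesky serves all
tables) — this is how the simulation-recovery studies pool landscape draws.

## Simulation

A landscape draw is `f = V √Λ z` with `K = V Λ Vᵀ` the full-space kernel
eigendecomposition (negative round-off eigenvalues clipped at zero, so
rank-deficient kernels like the constant landscape sample correctly) and
`z` standard normal. Dataset simulation seeds three independent sub-streams
(landscape, subsampling, noise) from one `SeedSequence`, so each stage is
reproducible in isolation; subsampling is without replacement. The generator
emulates complete or subsampled genotype–phenotype tables with independent
heteroskedastic Gaussian noise. It does **not** emulate read-count sampling,
replicate structure, batch effects, or genotyping error — passing recovery
tests shows the generative-inferential loop is consistent under the model's
own assumptions, not that real assays satisfy them.

## Preprocessing

Selection-count data: `y_x = log((c_sel+0.5)/(c_in+0.5))` anchored at the
designated wild type, with delta-method variance
`Σ 1/(c+0.5)` over the four counts; natural logarithm throughout (the
delta-method variance matches only under natural log). Replicate data:
`σ_x² = (e^{s²}−1)e^{2y+s²}` (log-normal variance), with sequences having
fewer than two strictly-positive replicates falling back on the median `s²`
across qualifying sequences; the bias-corrected phenotype estimate itself is
accepted as input. Segregant data: genome uncertainty
`U_x = (4/ℓ) Σ_i p_{x,i}(1−p_{x,i})`, retention of the `keep_fraction`
(default 0.20) of individuals with lowest `U` (stable-order ties), and hard
calls `p ≥ 0.5 → 1`.

## Epistasis analytics

The γ statistic is implemented as the Pearson correlation between paired
mutational effects across background pairs that differ exactly at the focal
site(s), pooled over landscape draws when given an ensemble; under the
connectedness prior its expectation is `∏(1−δ_p)` over the separating sites,
which the Monte-Carlo tests confirm to ±0.05. This operational definition is
the package's contract; finer-grained generalized-γ variants reduce to it on
complete data. Hyperparameter counts report decay factors and the two
scalars (σ², σ_n²) separately, because published counts mix conventions
(site-specific counts typically exclude the scalars; allele- and
mutation-specific counts include them); `include_scalars` makes the choice
explicit. Sub-landscape reconstruction enumerates all allele combinations at
chosen focal sites on a fixed background (capped at 2²⁰ genotypes by
default) and reports the posterior mean/variance per genotype plus Hamming
distances to a reference.

## Numerical conventions and edge cases

- Posterior variances are clipped at zero; values below `−1e−9 σ²` trigger a
  warning (they indicate a conditioning problem, not round-off).
- Distance-correlation estimates suppress classes with fewer than 2 pairs
  and subsample uniformly (seeded) beyond 5×10⁶ pairs.
- Enumeration refuses spaces above 2²⁴ genotypes with the exact size in the
  message; eigen-based operations (projectors, `eigen_check`) cap at 4096.
- Duplicate sequences in a table are kept as distinct replicate rows; the
  noise model resolves them.
- Sequence symbols are single characters; parsing uppercases by default.
- Site labels are user-facing strings ("39", "−3", "+2"); all internal
  indexing is 0-based.

## Problem sizes in the shipped studies

The simulation studies run at desk scale by design: recovery studies pool
200 full-space landscapes on 32-genotype (connectedness, ℓ=5 biallelic) and
27-genotype (Jenga, ℓ=3 three-allele — chosen because allele-specific
factors are unidentifiable on biallelic data, where only the per-site
product of allele factors enters the kernel) spaces; γ statistics use
500-draw ensembles on ℓ=4 biallelic spaces; the model-comparison study fits
Jenga and geometric kernels on 10 seeded half/half train-test splits of
81-genotype Jenga-simulated datasets. These sizes give Monte-Carlo error
comfortably inside the stated tolerances (±0.1 decay-factor MAE, ±0.05 on
correlations, ±0.03 on sampled covariances).

## Known limitations

- No non-Gaussian likelihoods or global-epistasis link functions; a strong
  measurement nonlinearity must be handled upstream or absorbed by
  higher-order components of the posterior.
- Exact dense inference only; no GPU, Lanczos, or trace-estimation path.
- The VC family requires a uniform alphabet.
- Priors are homoscedastic (constant prior variance σ² across sequence
  space) even though real landscapes often have quieter and louder regions;
  the posterior can still represent such structure given data.
- `eigen_check` decides extended-domain (δ > 1) validity only on enumerable
  spaces; no closed-form admissible region is provided.
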