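# Methods

## The model chain

`genosem` estimates and tests latent genetic factor models in three
stages. Every stage is exercised by simulation, so the whole chain is
checkable without external data.

### 1. Generative model for summary statistics

For SNP j with LD score ℓ_j (panel of M SNPs), the k-vector of per-trait
GWAS Z-statistics is drawn independently across SNPs from

    Z_j ~ N(0, C_j),      C_j = (ℓ_j / M) · G + E,

    G[i,m] = √(N_i N_m) · r_G[i,m] · √(h²_i h²_m),
    E[i,m] = N_s[i,m] · ρ_p[i,m] / √(N_i N_m),    E[i,i] = 1,

where r_G = ΛΨΛᵀ + Θ is the genetic correlation matrix implied by the
factor architecture (loadings Λ, factor correlations Ψ with unit
diagonal, residual genetic covariance Θ; unit-diagonal and PSD are
enforced), h² the SNP heritabilities, N the GWAS sample sizes, N_s the
pairwise overlapping sample counts and ρ_p the phenotypic correlations.
These are exactly the first and second moments LD score regression fits,
i.e. the weakest generative structure under which the downstream
estimator is consistent: the tests validate the estimator, not a
particular trait biology. Sampling uses the decomposition
Z_j = √(ℓ_j/M)·G^{1/2}u_j + E^{1/2}v_j (symmetric PSD square roots, a
documented 1e-10 diagonal jitter before rejecting indefinite inputs),
which is exact and vectorizes over SNPs.

What the generator emulates: LDSC-consistent polygenic signal, realistic
LD-score dispersion (ℓ = 1 + Gamma(shape 2) with configurable mean),
cross-trait genetic covariance, sample overlap acting through the
sampling — not the genetic — term, and allele-coding noise handled at
alignment. What it does not emulate: genotype-level LD (scores are i.i.d.
rather than spatially autocorrelated; block jackknife validity is exact
here and only approximate on real genomes), allele-frequency–dependent
architectures, effect-size sparsity (the implied architecture is
infinitesimal/Gaussian), case–control liability scales, and population
stratification (intercepts deviate from 1 only through overlap). Passing
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to their violation.

Summary statistics are read and written in the standard munged layout
(`SNP A1 A2 N Z`, one file per trait). Alignment to the panel's reference
alleles drops SNPs absent from the panel and strand-ambiguous pairs
(A/T, C/G; configurable), flips Z where A1/A2 are swapped directly or on
the complementary strand, and drops irreconcilable allele pairs.

### 2. LD score regression and the (S, V) pair

Each of the c = k(k+1)/2 unique trait pairs (i,m) yields one weighted
regression of Z_iZ_m on √(N_iN_m)·ℓ/M with free intercept; the slope
estimates the genetic covariance (heritability when i = m) and the
intercept absorbs N_s·ρ_p/√(N_iN_m). Intercepts are estimated freely for
every pair and never folded into S.

**Weights.** Default is the field-standard two-step scheme: an unweighted
first pass per trait gives h²₀, then w_j = 1/(ℓ_j(1+N_i h²₀ᵢℓ_j/M)(1+N_m
h²₀ₘℓ_j/M)). This presumes genome-scale panels where N h²/M ≲ 0.1. On a
desk-scale synthetic panel (M = 2·10⁴ with N up to 9·10⁵) the factor
N h²ℓ/M reaches the hundreds, the weights concentrate on a handful of
low-LD SNPs, and the jackknife V becomes unstable in a few directions —
empirically inflating the downstream model χ² by ~60% with no bias in S.
The synthetic pipeline therefore runs unweighted (`weights="unit"`), and
likewise disables the Z² > max(80, 0.001N) outlier filter, which at
desk-scale per-SNP noncentrality would truncate genuine signal (mean
Z² ≈ 50 under the k = 2 validation conditions). Both knobs remain
available and default on for genome-scale inputs.

**Jackknife.** All c regressions are re-solved under the same
leave-one-block-out deletions (per-block sufficient statistics make each
deletion an exact subtraction), and

    V = ((n_b − 1)/n_b) Σ_b (θ_(b) − θ̄)(θ_(b) − θ̄)ᵀ

over the c-vector of delete-one slopes — the joint pass is what captures
the cross-element sampling dependencies that sample overlap induces.
vech ordering is fixed throughout: lower triangle, column-major. Two
design requirements follow from how V is consumed: the residual-based χ²
inverts V, so the number of blocks must well exceed c; and per-block
slope estimates should be near-Gaussian, so blocks should hold tens of
SNPs. The packaged validation experiments use M = 20,000–40,000 with
1,000 blocks; the one-shot pipeline default is M = 20,000, n_b = 1,000.

**Standardization.** S is converted to correlation metric by
S'_{im} = S_{im}/√(S_{ii}S_{mm}); V transforms by the exact delta-method
Jacobian of that map (verified against numerical differentiation), after
which diagonal elements are exactly 1 with zero sampling variance.
Traits with nonpositive heritability estimates are refused with a named
error.

### 3. DWLS structural equation modeling

Models are written in path syntax (`F =~ a + b + c`, `y ~ x1 + x2`,
`a ~~ b`; numeric prefixes fix, shared alphabetic prefixes equate) and
compiled to the RAM parameterization Σ = F(I−A)⁻¹S₀(I−A)⁻ᵀFᵀ.

**Identification and profiled variances.** Default identification is
unit-variance (exogenous latent variances fixed to 1; unit-loading is
selectable). In correlation metric the diagonal of S is exact, so the
diagonal slots are excluded from the residual vector and every free
variance — observed residual or latent disturbance — is *profiled*:
derived, in topological order through the directed paths, so that the
implied total variance of its variable is exactly 1. Degrees of freedom
are counted as (off-diagonal moments) − (optimized parameters), which
equals the usual (all unique moments) − (all free parameters including
variances); reported free-parameter counts include profiled variances.
This scheme makes the combined correlated-factors and multiple-regression
models exact reparameterizations (identical χ² and df), because both then
parameterize the same standardized 8×8 construct correlation block with
the same number of free quantities. Residual variances are unbounded;
negative values raise a Heywood warning, not an error.

**Estimation.** θ̂ minimizes (s−σ(θ))ᵀD⁻¹(s−σ(θ)) with D = diag(V) via a
damped Gauss–Newton (Levenberg) iteration with a Nelder–Mead fallback;
start values are 0.5 for loadings, 0 for covariances and regressions;
convergence requires gradient sup-norm < 1e-8 (relative). The Jacobian
Δ = ∂σ/∂θ is computed by central finite differences of the complete
mapping — profiled variances are implicit functions of θ, so the pure
analytic RAM derivative would be incomplete; the FD Jacobian is
cross-checked against closed-form factor-model derivatives in the tests.
Non-PSD S (possible after jackknifing) is eigenvalue-clipped at 1e-8 and
rescaled to unit diagonal, with a warning.

**Uncertainty.** The parameter covariance is the sandwich
(ΔᵀD⁻¹Δ)⁻¹ΔᵀD⁻¹VD⁻¹Δ(ΔᵀD⁻¹Δ)⁻¹, correcting for D ≠ V⁻¹. Wald z, two-sided
normal p and 95% CIs follow. In simulation the sandwich SE of the SU–SUD
correlation matches the empirical spread of the estimate within a few
percent.

**Model χ².** The residual-based statistic
T = (s−σ̂)ᵀ[V⁺ − V⁺Δ(ΔᵀV⁺Δ)⁻¹ΔᵀV⁺](s−σ̂) (eigenvalue pseudo-inverse,
tolerance 1e-10) is asymptotically χ²_df under a correct model even
though the fitting weights are diagonal. Because V is itself estimated
from n_b blocks, quadratic forms in V̂⁺ inherit the inverse-Wishart bias
E[V̂⁻¹] = ν/(ν−p−1)·V⁻¹ (ν = n_b−1, p = rank inverted); T is rescaled by
(ν−p−1)/ν — the Hotelling-T² correction — whenever ν > p+1 and the block
count is known. With this correction, the free 16-trait combined model
at its generating architecture has mean χ² 78.9 on df = 78 and the
1-df equality test rejects at 0.053 under its null (M = 40,000, n_b =
1,000, 150–200 replicates). A mean-scaled alternative statistic is not
provided; the corrected residual statistic is used uniformly, including
for the independence model underlying CFI.

**Fit indices.** CFI = clamp(((χ²₀−df₀)−(χ²−df))/(χ²₀−df₀), 0, 1) against
an all-covariances-zero independence model fitted by the same machinery;
SRMR = RMS of correlation-metric residuals over all unique elements;
RMSEA = √(max(0, (χ²−df)/(df(N−1)))) with a 90% CI from inverting the
noncentral χ² at 0.05/0.95 (one convention among several; the CIs are
informational); AIC = χ² + 2·(free parameters). The RMSEA sample size N
defaults to the smallest GWAS among the fitted model's own indicators; a
global override is accepted, since published analyses sometimes use one
study-wide smallest N for all models. With df = 0, RMSEA is reported as 0
with a defined-ness flag.

**Nested tests and multiplicity.** Δχ² = max(χ²_c − χ²_f, 0) with
Δdf = df_c − df_f and a central χ² upper-tail p (nesting violations
raise). Facet equality tests constrain the facet–SU and facet–SUD
covariances through one shared label (Δdf = 1 by construction).
Benjamini–Hochberg FDR is applied jointly across all free parameters of
all fitted models plus the equality tests (the pipeline default);
per-model adjustment is available, since the appropriate family is a
study-level choice.

## The packaged study architecture

The 16-trait preset mirrors a published impulsivity / substance-use
design: nine impulsivity traits (five single-item facets; a Premeditation
factor indicated by three Barratt subscales plus UPPS-P lack of
premeditation) and seven substance traits (SU: drinks per week, smoking
initiation, lifetime cannabis use; SUD: problematic alcohol, tobacco,
cannabis and opioid use disorders, with three within-substance residual
correlations of 0.42 / 0.30 / 0.10). Construct correlations use the
design's headline values — SU–SUD 0.77; facet–SU / facet–SUD pairs
0.50/0.46 (premeditation), 0.30/0.38 (negative urgency), 0.40/0.42
(positive urgency, placeholder within the reported band), 0.10/0.05
(perseverance), 0.27/0.10 (sensation seeking), 0.21/0.31 (delay
discounting). Factor loadings (0.7), within-impulsivity construct
correlations, heritabilities (0.04–0.08) and the impulsivity-cohort
phenotypic correlation (0.3, full overlap among the nine impulsivity
GWAS) are placeholders chosen once as realistic for these phenotypes and
to keep the implied matrix positive definite; sample sizes are the source
GWAS sizes (133,517–903,147). `preset_architecture(equalize_facet=...)`
replaces one facet's SU/SUD correlations by their mean, giving an exact
null for equality-test calibration.

## Numerical choices and degenerate inputs

- Ties/degeneracies: constant LD scores make the slope unidentified
  (error); fewer SNPs than twice the block count refuses to jackknife;
  duplicated traits are legal and give exactly duplicated S/V entries.
- ld_mean = 1 is the degenerate Gamma limit: all scores exactly 1.
- Seeds: every stochastic routine takes an explicit integer seed; equal
  seeds give bit-identical outputs, and pipeline report bundles are
  byte-identical across reruns (no timestamps in provenance).
- Equality-labeled variances are never profiled (they stay optimized), so
  labels always mean what they say; none of the packaged models label
  variances.
- V of reduced rank is handled by pseudo-inverse throughout; the χ²
  correction uses the realized rank.

## Validation problem sizes

Desk-scale runs keep the full sample sizes but compress the genome:
M = 20,000 SNPs (40,000 for χ²-tail calibration), 200–1,000 jackknife
blocks, 20–200 replicates depending on the quantity. At these sizes the
full acceptance computation takes a few minutes on one core.

## Known limitations

- The i.i.d. LD-score panel cannot probe sensitivity to real LD
  structure, MAF-dependent architectures, or misspecified reference
  panels; `read_ld_panel` accepts real LD-score files but block
  assignments are then positional, not genomic.
- The χ² small-sample correction treats the jackknife V as Wishart; with
  very small blocks (heavy-tailed per-block slopes) residual inflation of
  a few percent remains.
- DWLS only; no maximum likelihood, mean structures, multi-group models,
  or per-SNP (multivariate GWAS) extensions.
- The profiled-variance scheme presumes recursive (acyclic) directed
  structures; cyclic models are rejected.
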