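# Methods

## Model

`pcreml` fits the multivariate linear mixed ("animal") model
`y = Xβ + Zu + e` for `q` traits, with observations and genetic effects
ordered traits-within-individual. Fixed effects are categorical factors per
trait (overall means, contemporary groups, ...). Each random term `u_t`
(direct genetic, maternal genetic, maternal permanent environment) has
`Var(u_t) = H_t ⊗ Σ_t`, where `H_t` is a relationship matrix over the term's
levels — the pedigree numerator matrix `A`, the single-step joint matrix
`H`, or the identity — and `Σ_t` is a trait covariance matrix to be
estimated. Residuals are independent between animals with
`Var(e_i) = Σe[S_i, S_i]` for the subset `S_i` of traits recorded on animal
`i`; records missing all traits are dropped at load. Direct and maternal
genetic terms are separate, uncorrelated terms sharing a relationship
matrix. `X` is made full rank by convention: within each trait, every factor
after the first drops its first level.

Assumptions worth stating: multivariate normality; a single record per
animal per trait; homogeneous residual covariance across records (up to
missing-trait subsetting); no genetic groups; full-rank `Σ_t` (no
reduced-rank fitting).

## Relationship matrices

* `A⁻¹` is assembled directly by Henderson's rules with exact inbreeding
  from the Meuwissen–Luo recursion; the pattern is diagonal +
  parent–offspring + mate pairs, and exact numeric cancellations are kept as
  explicit entries so the pattern is purely structural.
* `A22`, the `A` submatrix for genotyped animals, is obtained by solving
  `A⁻¹ y = e_g` per genotyped column with a sparse LU — exact, and reuses
  the `A⁻¹` builder.
* `G` is the allele-count cross-product GRM: counts centred by twice the
  observed allele frequency, denominator `2 Σ p(1−p)`, SNPs with minor
  allele frequency strictly below 2% removed. Frequencies are computed on
  all SNPs before filtering (the alternative — after filtering — is
  identical here because the filter is frequency-based).
* `G* = a + bG` matches the mean diagonal and overall mean of `A22`
  (two-moment alignment). If `G*` fails a Cholesky it is blended once,
  `G* ← 0.99 G* + 0.01 A22` (weight configurable).
* `H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹]`, stored as one merged sparse lower
  triangle; the genotyped-block scaling factors are fixed at 1.

## Likelihood, derivatives, average information

Minus twice the REML log-likelihood (constant dropped identically in both
parameterisations) is evaluated through the MME:

* MV: `log|R| + Σ_t [q_t log|H_t| + n_t log|Σ_t|] + log|C| + y'Py`
* PC: `log|R| + Σ_t q_t log|H_t| + log|C*| + y'P*y`

with `y'Py = y'R⁻¹y − rhs·sol` from the MME solution and `log|H_t|` computed
once per relationship matrix (Cholesky of the stored inverse, negated).
`Py = R⁻¹(y − Xβ̂ − Zû)` is kept on the observation scale.

Gradients of −2 logL use the trace identity
`tr(C⁻¹ ∂C/∂θ)` evaluated from the Takahashi selected inverse of `C`
restricted to the pattern of `∂C/∂θ`:

* residual parameters: per-record blocks `∂W = −W ∂Σe W` traced against the
  per-pattern sums of `D_r C⁻¹ D_r'`, plus `∂log|R|` and
  `−(Py)' ∂R (Py)`;
* MV genetic parameters: `∂C = H⁻¹ ⊗ ∂(Σ⁻¹)` traced via the `q×q`
  aggregates `Σ_ab H⁻¹_ab (C⁻¹)_block(a,b)`, plus `n_t tr(Σ⁻¹ ∂Σ)` and
  `−û'(H⁻¹ ⊗ Σ⁻¹ ∂Σ Σ⁻¹)û` (the data-part derivative written through the
  BLUP identity `Z'Py = (H⁻¹ ⊗ Σ⁻¹)û`, so the dense `H` is never needed);
* PC genetic parameters: only the design matrix depends on θ
  (`∂C* = Ḋ'R⁻¹D + D'R⁻¹Ḋ` with `Ḋ` carrying `∂Q`), giving
  `2 tr(R⁻¹D C*⁻¹ Ḋ')` and `−2 (P*y)'Ż û*`; the `H⁻¹ ⊗ I` part has zero
  derivative — the source of the method's per-iterate advantage.

The average information matrix is `AI_ij = ½ f_i' P f_j` with working
vectors `f_i = (∂V/∂θ_i) Py`; each `P f` costs one extra solve against the
already-factored MME (no explicit projection matrix). `f` for PC genetic
parameters needs one application of `H` per parameter, done by solving with
the cached Cholesky of `H⁻¹`.

Both parameterisations estimate the same θ — elements of the Cholesky
factors of every `Σ` (column-major lower triangle, log-transformed
diagonals) — so their gradients, AI matrices and iterate sequences are
directly comparable; the test suite asserts they agree to near machine
precision against a dense `V/P` oracle and central finite differences.

## Sparse linear algebra

Simplicial LDL' Cholesky (up-looking, elimination-tree based), with:

* **Ordering**: multiple minimum degree on the symmetric pattern, with a
  block variant that collapses the `q` equations of each (term, level) to
  one quotient-graph node before ordering and keeps them consecutive — both
  parameterisations then inherit the same animal-level elimination order.
  Among candidate orderings (plain, block, natural) the one with the fewest
  factor non-zeros by symbolic count wins, so the result is never worse than
  the natural order. Reverse Cuthill–McKee is available as an option.
* **Selected inverse**: Erisman–Tinney/Takahashi recurrences on the pattern
  of `L`. Because the MME pattern is fixed across iterates, the gather
  positions of every recurrence term are resolved once per symbolic
  factorisation and replayed as a flat indexed kernel; above ~3·10⁸ pairs
  (≈1.3 GB of int32 indices) a memory-free binary-search kernel is used
  instead.
* **Pattern discipline**: the coefficient matrix is assembled onto a
  canonical structural pattern computed from all-positive placeholders.
  This matters: at particular parameter values individual coefficients
  cancel *exactly* (e.g. proportional starting `Σu` and `Σe` make
  `Σe⁻¹ Q` triangular), sparse arithmetic then prunes the entries, and a
  pattern that breathes across iterates silently invalidates the cached
  symbolic factorisation. A pattern-equality guard raises if a mismatched
  matrix reaches a cached factorisation.
* Positive-pivot check at `1e−12 ×` the running diagonal maximum, reporting
  the offending equation (via the equation map) on failure.

## Optimisation

Damped Newton on θ: `θ ← θ + ω AI⁻¹ s`, `s = ∂logL/∂θ`, starting at
`ω = 1` and halving up to 10 times until −2 logL does not increase; a trust
region caps each θ component change at 2 log-units (a near-singular AI can
otherwise propose steps of thousands); if no Newton step improves, a
Levenberg-style ridge on the AI diagonal is escalated
(λ ∈ {1e−4, 1e−2, 1, 1e2}) and finally a scaled gradient step. Accepted
−2 logL values are non-increasing by construction.

Starting values: half the pairwise-complete phenotypic covariance to the
residual, the other half split equally over the random terms
(eigenvalue-floored to stay positive definite). Convergence: −2 logL change
below `5e−4` together with max logL-gradient below `1e−3`, **or** three
consecutive sub-tolerance likelihood changes. The second clause handles
boundary maxima — when a genetic covariance drifts towards singularity the
likelihood flattens but the gradient on the Cholesky-log scale does not
vanish, so a gradient-based rule alone never terminates there. Default
iteration cap 50. Standard errors come from the inverse AI at convergence,
mapped to the covariance scale by the analytic Jacobian of `Σ = LL'`.

## Synthetic data

The generator emulates a generation-structured livestock population:
discrete generations, random mating among selected sires and dams, progeny
counts per generation; the default profile has 21,000 recorded individuals
in eight generations (2,100 progeny of 100 sires and 1,000 dams in
generations 1–4; 3,150 of 150 and 1,500 in 5–8), 301 contemporary groups per
generation, 32,000 unlinked SNPs gene-dropped from founder haplotypes with
`p ~ U(0.05, 0.95)`, and genotypes retained for 10/30/40/50% of generations
5–8. Defaults for the trait architecture: constant-correlation covariance
matrices with genetic variance 0.4 (correlation 0.5) and residual variance
0.6 (correlation 0.3) per trait — heritability 0.4, a typical moderate value
for production traits; contemporary-group effects N(0, 0.5²); no missing
records unless configured.

Breeding values follow the infinitesimal model via Mendelian-sampling
recursion; the within-family variance is `Σu/2` by default, with a flag for
the exact `(1/2 − (F_s + F_d)/4)` inbreeding adjustment. What the generator
does *not* emulate: linkage and LD structure, selection, mutation, QTL
architecture (the gene-dropped SNPs inform the GRM but do not generate the
phenotypes). Passing tests therefore demonstrate estimator and
implementation correctness under the stated model — not robustness to
model misspecification in real data.

The `studies` module freezes two analyses built on the generator: the
MV-vs-PC equivalence study (eleven two-generation datasets pairing each
trait count with a record number at which its covariance structure is
estimable — q ≤ 2 at N ∈ {200, 2000} with and without genomic information,
q = 3 at N = 200 both ways, q = 5 at N = 2,000 with pedigree relationships;
per-dataset seeds are a fixed function of the condition) and a 20-replicate
parameter-recovery study (bivariate, N = 2,000 records, ~200 sires). The
two-generation design uses about 10 sires and 25 dams per 100 progeny —
paternal half-sib families of about ten, the classical information source
for genetic covariances.

## Numerical choices and limitations

* Problem sizes in the shipped studies (hundreds to a few thousand
  animals) were chosen so the full verification battery — including dense
  oracles — runs in minutes; the engine itself has no hard-coded size
  limits, but the simplicial factorisation and selected inverse make it a
  reference implementation, not a competitor to supernodal production
  solvers, and very dense genotyped blocks (thousands of genotyped animals
  at high trait counts) will be slow.
* Missing genotype calls are rejected rather than imputed.
* Identity-relationship terms (permanent environment) densify their levels
  from the data; genetic terms span the full pedigree.
* Ties in orderings and level codings are broken by original index /
  lexicographic order for reproducibility; reports are byte-stable across
  runs at a fixed seed.
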