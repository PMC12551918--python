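# Methods

## Model and canonical form

The package fits the Gaussian linear model y = β₀ + Xβ + μ with n
observations and p numeric predictors, n > p. All penalty selection happens
on a standardized scale:

* each predictor column is centered and divided by its centered Euclidean
  norm (= sd·√(n−1)), so the standardized design X\* satisfies
  X\*ᵀX\* = R, the sample correlation matrix of the predictors;
* the response is centered but not scaled.

With the eigendecomposition R = EΛEᵀ (eigenvalues λ₁ ≥ … ≥ λₚ > 0,
Σλᵢ = p), the model rotates to y_c = Zα + μ with Z = X\*E, and

* OLS: α̂ᵢ = (Zᵀy_c)ᵢ / λᵢ,
* ridge: α̂ᵢ(k) = λᵢ/(λᵢ+k)·α̂ᵢ — a per-coordinate contraction, so
  ‖α̂(k)‖ is strictly decreasing in k and k = 0 reproduces OLS exactly.

Coefficients return to original units by β̂_scaled = Eα̂(k),
β̂ⱼ = β̂_scaled,ⱼ / ‖x_cⱼ‖, and β̂₀ = ȳ − Σβ̂ⱼx̄ⱼ.

The unit-norm (correlation-form) dialect was chosen over the unit-variance
dialect because the diagnostics (VIF, condition number, Farrar–Glauber) are
defined on the correlation matrix, and the penalty formulas use λ's on that
scale; it is also the unique choice under which the back-transformation
above exactly inverts the standardization.

The residual variance feeding every penalty formula is the OLS residual
variance of the centered fit with divisor **n − p** (the p slopes are the
only estimated parameters of the centered model; the intercept is recovered
afterwards from the stored means).

## The penalty catalog

With σ̂² the OLS residual variance, α̂ the canonical OLS coefficients,
α̂²_max = maxᵢ α̂ᵢ², and λ_max, λ_min the extreme eigenvalues:

| rule | k |
| --- | --- |
| OLS  | 0 |
| HK   | σ̂²/α̂²_max |
| HKB  | pσ̂²/Σα̂ᵢ² |
| LW   | pσ̂²/Σλᵢα̂ᵢ² |
| HSL  | σ̂²Σλᵢ²α̂ᵢ² / (Σλᵢα̂ᵢ²)² |
| KAM  | (σ̂²/p)Σ1/α̂ᵢ² |
| KGM  | σ̂²/(Πα̂ᵢ²)^{1/p} |
| KMED | medianᵢ σ̂²/α̂ᵢ² |
| KS   | σ̂²λ_max / ((n−p)σ̂² + λ_maxα̂²_max) |
| KMS  | (λ_max/Σ\|α̂ᵢ\|)·σ̂²/α̂²_max |
| KAG  | 5σ̂²/(λ_maxΣα̂ᵢ²) |
| SCI  | (p+1)σ̂² |
| NEW1 | n·k_KAG·(λ_max/λ_min)^{1/(2p)} |
| NEW2 | n·k_KAG·(λ_max/λ_min)^{1/2} |

Design choices that were genuinely open:

* **Eigenvalue-ratio orientation in NEW1/NEW2.** The rules are motivated as
  penalties that grow with the severity of multicollinearity; only the
  orientation r = λ_max/λ_min achieves that (and makes NEW2 the stronger
  rule of the two, NEW2/(n·KAG) being exactly the condition number). The
  inverted orientation is available behind the `literal_ratio` flag for
  audit, under which both rules shrink *less* as collinearity worsens.
* **KMED with even p** uses the midpoint of the two central order
  statistics.
* **KGM** is evaluated in log space to avoid under/overflow of the product.
* Rules that divide by individual α̂ᵢ (KAM, KGM, KMED) raise on an exactly
  zero coefficient (a measure-zero event on continuous data) rather than
  returning ±inf.

Scale behaviour (tested): rescaling the response y → c·y multiplies σ̂² and
α̂ᵢ² by c², leaving every rule invariant except SCI (k → c²k) and
KMS (k → k/c).

## Collinearity diagnostics

From the correlation matrix R (all validated symmetric, unit-diagonal,
positive definite):

* VIFⱼ = (R⁻¹)ⱼⱼ, with ΣVIFⱼ = Σ1/λᵢ (trace identity, tested);
* condition number √(λ_max/λ_min);
* Farrar–Glauber statistic −(n − 1 − (2p+5)/6)·ln det R, the chi-square
  test of mutual independence, with the log-determinant computed through
  the eigenvalues.

The packaged reference matrices (13 anthropometric predictors of body fat,
n = 50; 5 livestock-population predictors, n = 18) are transcriptions of
published 4-decimal tables. The smallest eigenvalue of the livestock matrix
is ~1.3e−5, comparable to the rounding perturbation bound p·5e−5, so
diagnostics that depend on λ_min (its condition number especially) are
intrinsically unstable at that printing precision; the tests therefore use
wide (±10%) bands for that matrix.

## Monte Carlo comparison

One scenario is (ρ, p, σ, n, N): predictors drawn once from N(0, Σ(ρ)) with
Σ(ρ) the equicorrelation matrix (unit diagonal, all off-diagonals ρ;
eigenvalues 1+(p−1)ρ and 1−ρ), a unit-norm slope vector β (default
`equal`: every entry 1/√p; `eigvec_max` — the leading eigenvector of the
realized design correlation — coincides with it for equicorrelated
designs), intercept 0. Per replication, errors μ ~ N(0, σ²I) are redrawn,
y is formed, all 14 estimators are fitted through the canonical pipeline,
and the squared slope error ‖β̂ − β‖² in original units is accumulated; the
EMSE is its average over N replications and the Monte Carlo standard error
is reported alongside.

Choices and contracts:

* **Fixed design by default.** X is drawn once per scenario and held fixed
  across replications (`redraw_X=True` redraws it). Under a fixed design,
  EMSE(OLS) has the exact closed form σ²·tr((X_cᵀX_c)⁻¹), which the test
  suite uses as an oracle.
* With a fixed design, the standardization and eigenstructure of X are
  computed once per scenario and only response-side quantities are redone
  per replication — algebraically identical to rerunning the full pipeline,
  just cheaper.
* RNG contract: a single seeded generator draws the design first, then one
  error vector per replication; the stream does not depend on which methods
  are requested, so per-replication draws are reproducible from the seed
  alone. Grid runs derive per-scenario seeds from a master seed via
  `numpy.random.SeedSequence.spawn`.
* Replications producing an exactly degenerate fit are skipped and counted;
  more than 1% skips aborts the scenario rather than silently regularizing.
* EMSE accumulates over the p slopes only (the intercept is identically 0
  in the generator and excluded).

Problem sizes: the default for a full study is N = 10000 replications per
cell; the package's own acceptance grid runs the 8 cells
ρ ∈ {0.85, 0.99} × p ∈ {4, 8} × n ∈ {30, 100} at σ = 2 with N = 2000,
which bounds the Monte Carlo standard errors well below the between-method
gaps being compared while keeping the default suite fast.

**What the generator does and does not emulate.** It reproduces the stated
study conditions exactly: equicorrelated Gaussian predictors, Gaussian
errors, unit-norm coefficients. It does not emulate non-Gaussian or
heteroscedastic errors, unequal predictor variances, or non-exchangeable
correlation structures — so passing tests certify behaviour under the
exchangeable-Gaussian design, not on arbitrary real data. Under these
conditions the condition-number-driven NEW2 rule dominates at severe
collinearity (ρ = 0.99), but at moderate collinearity its penalty can
overshoot the EMSE-optimal shrinkage and the milder NEW1/KGM/KMED rules
take the row minimum in some cells; the acceptance suite records this
pattern as computed.

## Single-dataset evaluation

Without repeated sampling the comparison uses:

* **Plug-in MSE** (per-method): σ̂²Σλᵢ/(λᵢ+k)² + k²Σα̂ᵢ²/(λᵢ+k)², reducing
  to σ̂²Σ1/λᵢ at k = 0. The variance term is computed as
  (λ/(λ+k))·(1/(λ+k)) so the k = 0 identity holds bit for bit.
* **Shrinkage**: AS = ‖β̂_OLS‖² − ‖β̂_ridge‖², RS = AS/‖β̂_OLS‖², computed
  on the standardized-coefficient scale where the canonical contraction
  guarantees AS ≥ 0 for every k > 0 (the scale is orthogonally equivalent
  to the canonical one).
* **CPPI**: the percentage of the n fitting observations whose response
  falls inside ŷⱼ ± t(α/2, n−p)·√(σ̂²(1 + hⱼ)), with leverage
  hⱼ = x\*ⱼᵀ(X\*ᵀX\*)⁻¹x\*ⱼ from the *unpenalized* standardized design for
  every method (keeping the interval geometry common across methods), and
  σ̂² from each method's own residuals by default (`pi_sigma="ols"` uses
  the OLS variance everywhere instead). The count is normalized by n so the
  result is a percentage in [0, 100]. Coverage is in-sample; with the
  (1 + hⱼ) width it runs slightly above the nominal 1 − α, which the
  coverage simulation in the acceptance suite quantifies.
* α defaults to 0.05. A `scale_y` option divides reported standardized
  coefficients by ‖y_c‖ for fully standardized coefficient tables.

## Numerical choices

* Eigendecomposition via symmetric `eigh`; eigenvalues stored descending;
  eigenvector signs fixed by making each column's largest-magnitude entry
  positive, so canonical coefficients are reproducible across platforms.
* A design with λ_min/λ_max < 1e−12 raises "singular design" rather than
  silently pseudo-inverting; constant predictor columns are rejected by
  name, and n ≤ p is rejected as underdetermined.
* CSV ingestion rejects any row containing a non-numeric or missing cell,
  reporting the row index.

## Known limitations

* No standard errors or inference for ridge coefficients, no weighted
  least squares, no per-coordinate (generalized) ridge.
* Prediction-interval coverage is in-sample only.
* The condition-number diagnostics inherit the instability of λ_min when a
  correlation matrix is supplied at low printing precision (see above).
* The NEW1/NEW2 rules assume the correlation-form eigenvalue scale; their
  absolute penalty values are not comparable across standardization
  dialects.
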