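# Methods

## Model

Molecular (or any Markovian) dynamics admit feature transformations
χ₀, χ₁ whose expectations evolve approximately linearly over a lag time τ:
E[χ₁(x_{t+τ})] ≈ Kᵀ E[χ₀(x_t)]. For given features the least-squares
propagator is K = C₀₀⁻¹C₀₁, with

- C₀₀ = E[χ₀(x_t) χ₀(x_t)ᵀ] (instantaneous),
- C₀₁ = E[χ₀(x_t) χ₁(x_{t+τ})ᵀ] (time-lagged),
- C₁₁ = E[χ₁(x_{t+τ}) χ₁(x_{t+τ})ᵀ],

averaged over all transition pairs within trajectories (pairs never span a
trajectory boundary). The quality of the features themselves is measured
by the VAMP-2 score, the squared Frobenius norm of the whitened
time-lagged covariance A = C₀₀^(−1/2) C₀₁ C₁₁^(−1/2); its singular values
are canonical correlations between the instantaneous and lagged feature
spaces, and the score is maximal when the features span the dominant
Koopman singular subspaces. Since the constant function is always a
singular function with singular value 1, training uses mean-free
covariances (divisor T−1, each series centred with its own mean) plus an
explicit +1; raw covariances (divisor T) are used where the
transition-matrix interpretation matters.

Both lobes share one parameter set (clones): fully connected layers, ReLU
hidden units, Softmax output, so each frame is mapped to a probability
vector over n_out fuzzy metastable states. The training gradient is the
analytic gradient of the score with respect to the lobe outputs,
back-propagated through the shared network and summed over the two lobes.
For VAMP-2 this is the closed-form pair

gradX = 2/(T−1) C̄₀₀⁻¹C̄₀₁C̄₁₁⁻¹ (Ȳ − C̄₀₁ᵀC̄₀₀⁻¹X̄),
gradY = 2/(T−1) C̄₁₁⁻¹C̄₀₁ᵀC̄₀₀⁻¹ (X̄ − C̄₀₁C̄₁₁⁻¹Ȳ);

for the VAMP-1 (nuclear-norm) score used during pre-training it is the
time-lagged analogue of the deep-CCA total-correlation gradient. Both are
verified against central finite differences in the test suite. The full
Frobenius-norm gradient is used regardless of the configured truncation k:
a Softmax lobe's mean-free features have rank at most n_out − 1 ≤ k in
every configuration exercised here, so the truncated and full gradients
coincide; k only affects reported scores.

## Training protocol

- 90%/10% random split of the shuffled transition pairs into training and
  validation sets (fresh split per run).
- The first third of the epochs maximises VAMP-1 (pre-training), the rest
  VAMP-2. "Epoch" means one pass over the training pairs; minibatch
  covariances drive the gradients, full-split covariances produce the
  reported per-epoch scores (evaluation mode, dropout off).
- Adam, initial learning rate 0.05; divided by 10 after 10 epochs without
  validation-score improvement.
- Defaults: batch size 4000 (clipped to the training-set size), dropout
  10% on the first two hidden layers and none elsewhere, L2 weight decay
  1e-7 on hidden and 1e-8 on output layers, 100 epochs (the toy studies
  here use 60, which the score traces show is converged for these
  systems).
- The returned parameters are those with the best validation score, not
  the final ones — the same criterion used for hyper-parameter selection.
- Ensembles: n independent runs (independent seeds and splits), ranked by
  validation score; the best and worst `trim` fraction are discarded as
  outliers before statistics (mean, percentile 95% CI) are computed.
  Study-level model selection takes the retained run with the best
  validation score.

Layer widths follow the constant-reduction rule n_i/n_{i+1} =
(n_in/n_out)^(1/d) with round-half-away-from-zero and the last layer
pinned at n_out; explicit width lists bypass the rule (the double-well
study uses 1-5-10-5 lobes, which widen before narrowing).

## Numerical choices

- All matrix inverse square roots and pseudo-inverses in score/gradient
  computations use eigendecomposition with a relative spectral cutoff of
  1e-6. This is mandatory, not cosmetic: Softmax features sum to one, so
  their mean-free instantaneous covariance is exactly rank-deficient.
- The raw-mode Koopman matrix is obtained with a direct positive-definite
  solve, which preserves the row-sum identity K·1 = 1 of
  partition-of-unity features to machine precision; the spectrally
  truncated pseudo-inverse is a fallback for numerically singular
  covariances (and then row sums may deviate — flagged by a warning, never
  clipped).
- C₀₀ and C₁₁ are symmetrised as (M + Mᵀ)/2 before decomposition.
- Eigenvalues are sorted by modulus descending; implied timescales drop
  the eigenvalue closest to 1 (the stationary process) and convert the
  next ones via t = −τ/ln|λ|; |λ| ≥ 1 yields +inf with a warning, |λ| = 0
  yields 0. Complex eigenpairs contribute |λ|, and eigenfunctions of
  complex pairs return the real part with a warning.
- Eigenfunction sign convention: the eigenvector entry of largest
  magnitude is made positive.
- The score with k beyond the available rank pads with zeros and warns
  (requesting k = n_out on a Softmax lobe is legal but the last singular
  value is structurally zero). The normalised-Frobenius variant (full sum
  divided by the matrix dimension) is available as a reporting mode; it
  never changes the optimiser's ranking at fixed k.
- Statistical uncertainty of Koopman-derived quantities (implied
  timescales, Chapman–Kolmogorov deviations) is obtained by bootstrap
  resampling of transition pairs; CK deviations compare against the
  standard error of the difference with both lags resampled
  independently.

## Synthetic data

The Brownian-dynamics generator integrates overdamped Langevin dynamics
with forward Euler–Maruyama, x ← x − Δt ∇U/kT + √(2ΔtD)·w, in
dimensionless units D = kT = 1. Two potentials are bundled:

- **Asymmetric double well**, U(x) = x⁴ − 6x² + 2x: a deep basin near
  x = −1.81 and a shallow one near x = 1.64 separated by a saddle near
  x = 0.17. Trajectories start in the shallow basin; study length 50,000
  steps.
- **5D folding model**, U(r) = −2.5(r−3)² for r < 3 and 0.5(r−3)³ − (r−3)²
  for r ≥ 3 with r = |x|: enthalpically favoured "folded" configurations
  at small r versus an entropically stabilised "unfolded" basin near
  r = 13/3, barrier at r = 3. Trajectories start at the origin; study
  length 100,000 steps.

The default time step is Δt = 0.05 for both systems. This was chosen by
measuring barrier-crossing statistics: at Δt = 0.01 the study-length
trajectories show almost no transitions (the 5D model frequently never
unfolds at all), whereas Δt = 0.05 yields ~50–140 crossings while the
Euler scheme remains stable over the visited range. The
equilibrium-validation test uses Δt = 0.001, where the Euler stationary
distribution is indistinguishable from Boltzmann within sampling error.
For the harmonic well U = |x|²/2 the Euler recursion has the exact
stationary variance 1/(1 − Δt/2) per coordinate; the integrator test
pools 25 independent coordinates of one 10⁶-step isotropic trajectory to
push the sampling error of the variance estimate well below the 1%
comparison band.

What the toys do *not* emulate: high-dimensional rugged landscapes,
metastability hierarchies with many comparable timescales, anisotropic
diffusion, or the featurization noise of real molecular coordinates.
Passing these studies demonstrates that the estimator chain (score →
training → K → validation) is correct and internally consistent, not that
the architecture defaults are optimal for real proteins.

## Known limitations and open choices

- Slow-timescale agreement between a trained net and the fine-grid
  reference is itself a stochastic quantity: at the study lengths the
  slowest timescale is estimated from a few dozen barrier crossings, so
  the net/reference ratio fluctuates by several percent across data
  realisations (both estimators see the same trajectory, but they respond
  differently to how the transition region was sampled).
- The learning-rate schedule interprets "training iterations" as epochs,
  since the validation score is only meaningful once per epoch.
- Trimming of ensemble outliers is applied once, by validation score, and
  the retained set is reused for every derived quantity.
- The Chapman–Kolmogorov estimate at lag nτ uses all available pairs at
  that lag (not a strided subset).
- The contact featurizer's minimum sequence separation defaults to 3,
  which reproduces the conventional 666 features for a 39-residue chain;
  it is configurable because the convention varies between studies.
- Reversible reweighting of K, PCCA+ coarse-graining, Bayesian MSM error
  bars, and convolutional/transferable lobes are out of scope.
- Only cloned (shared-parameter) lobes are implemented. Every study and
  validation quantity in scope uses them, and an independent-lobe training
  path would be untestable dead code behind the same public surface; the
  covariance and score machinery itself is already general in χ₀/χ₁.
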