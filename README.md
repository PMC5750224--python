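# vampnet

Kinetic models of molecular dynamics, learned end to end.

Classical Markov-state-model (MSM) analysis of molecular simulation data is
a hand-crafted pipeline: choose structural features, reduce dimension,
cluster, estimate a transition matrix, coarse-grain. Every step demands
expertise and every poor choice degrades the model. A **VAMPnet** replaces
the whole pipeline with a single learning problem: a pair of identical
("twin-lobe") neural networks transforms the instantaneous frame x_t and
the time-lagged frame x_{t+τ}, and the shared parameters are trained by
maximizing the **VAMP-2 score**

&emsp; R̂₂ = ‖C₀₀^(−1/2) C₀₁ C₁₁^(−1/2)‖²_F (+ 1 for the constant singular function),

where C₀₀, C₀₁, C₁₁ are the (mean-free) instantaneous, time-lagged and
lagged-instantaneous covariance matrices of the transformed coordinates.
By the variational principle for Markov processes, this score is maximal
exactly when the learned features span the dominant singular subspaces of
the Koopman operator — the slowest collective processes of the dynamics.

Because the output layer is a Softmax, the learned features are fuzzy
membership probabilities of a few metastable states, and the least-squares
propagator **K = C₀₀⁻¹C₀₁** estimated from them (raw covariances) is
directly the transition matrix of a few-state fuzzy MSM. The model is then
validated like any MSM: implied timescales t_i(τ) = −τ/ln|λ_i(τ)| should
be flat in τ, and the Chapman–Kolmogorov identity K(nτ) = K(τ)ⁿ should
hold within statistical uncertainty.

The package is aimed at people building kinetic models from trajectory
data — molecular-simulation practitioners and method developers. It ships
with Brownian-dynamics simulators for two standard toy systems (an
asymmetric 1D double well and a 5D "protein-folding" model), a contact-map
featurizer for protein structures, and a brute-force fine-grid MSM
reference, so every claim can be checked without external data. The
network, its backward pass and the Adam optimiser are implemented directly
on numpy arrays; the training signal is the closed-form gradient of the
VAMP score, so no autodiff framework is involved.

## Worked example: the asymmetric double well

```python
import numpy as np
from vampnet import (
    LaggedDataset, LobeSpec, SimulationConfig, TrainingConfig,
    brownian_trajectory, discretize_grid, eigenfunction_values,
    estimate_koopman, implied_timescales, reference_spectrum, train,
    transition_matrix,
)

# 1. simulate the double well U(x) = x^4 - 6x^2 + 2x (50,000 steps)
traj = brownian_trajectory(SimulationConfig(potential="double-well",
                                            n_steps=50_000, seed=7))
x = traj - traj.mean(axis=0)                      # mean-free input

# 2. train a VAMPnet with 1-5-10-5 lobes at lag 1
data = LaggedDataset.from_trajectory(x, lag=1)
model = train(data, LobeSpec(n_in=1, n_out=5, widths=[1, 5, 10, 5]),
              TrainingConfig(k=4, epochs=60, seed=1))
print(f"validation VAMP-2 score: {model.best_val_score:.3f}")

# 3. fuzzy-MSM transition matrix and slowest relaxation timescale
K = estimate_koopman(model.lobe, data, mode="raw")
t2 = implied_timescales(model.lobe, data, lags=[1]).timescales[0, 0]
print(f"slowest implied timescale: {t2:.0f} frames")

# 4. compare with a 200-bin grid MSM on the same trajectory
dtraj = discretize_grid(traj[:, 0], 200)
tm = transition_matrix(dtraj, 1)
ref = reference_spectrum(tm.matrix, 1)
psi = eigenfunction_values(K, model.lobe, x, indices=[1])[:, 0]
ref_psi = np.real(ref.right_eigenvectors[:, 1])[tm.states_of(dtraj)]
print(f"reference timescale:       {ref.timescales[0]:.0f} frames")
print(f"eigenfunction correlation: {abs(np.corrcoef(psi, ref_psi)[0, 1]):.4f}")
```

Output:

```
validation VAMP-2 score: 2.951
slowest implied timescale: 558 frames
reference timescale:       539 frames
eigenfunction correlation: 0.9996
```

The validation score (up to 1 + Σσ_i² ≤ 5 for five output states) says how
much of the slow spectrum the five fuzzy states capture. The net's slowest
implied timescale — the barrier-crossing relaxation time, in frames —
agrees with the 200-bin reference to a few percent, and the learned slow
eigenfunction is essentially identical to the reference eigenvector
(correlation 0.9996): five soft states resolve what the fine grid needed
two hundred bins for.

The same workflow is available from the shell:

```sh
vampnet simulate --potential double-well --steps 50000 --seed 7 --out dw.h5
vampnet train dw.h5 --lag 1 --outputs 5 --widths "1 5 10 5" --k 4 --out model.h5
vampnet its dw.h5 --model model.h5 --lags "1 2 5 10" --out its.csv
vampnet ck-test dw.h5 --model model.h5 --tau 1 --out ck.csv
vampnet oracle dw.h5 --bins 200 --lags "1 2 5 10" --out ref.csv
```

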