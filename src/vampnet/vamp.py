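"""Covariance estimation and VAMP variational scores.

The variational approach for Markov processes (VAMP) scores a pair of
feature transformations chi0, chi1 of a time series by how well the
time-lagged evolution of the transformed coordinates is captured by a
single linear operator.  The VAMP-2 score is the squared Frobenius norm of
the whitened time-lagged covariance

    A = C00^(-1/2) C01 C11^(-1/2),

whose singular values are the canonical correlations between the
instantaneous and time-lagged feature spaces.  Maximising the score over
the feature transformation pushes the features towards the dominant
singular subspaces of the Koopman operator, i.e. towards the slowest
collective processes of the dynamics.

This module contains the estimators for the covariance matrices, the
scores (VAMP-1 and VAMP-2, with the constant-function augmentation), and
the analytic gradients of both scores with respect to the feature time
series, which the network trainer back-propagates through the lobes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LaggedDataset",
    "CovarianceSet",
    "ScoreReport",
    "estimate_covariances",
    "regularized_inverse_sqrt",
    "regularized_inverse",
    "vamp_score",
    "vamp2_gradients",
    "vamp1_gradients",
    "validation_score",
]

#: Relative eigenvalue cutoff used by every regularised matrix inverse in
#: the package.  Softmax features sum to one, so their mean-free
#: instantaneous covariance is rank deficient by construction and a cutoff
#: is mandatory, not optional.
DEFAULT_EPSILON = 1e-6


# ---------------------------------------------------------------------------
# Lagged data container
# ---------------------------------------------------------------------------

@dataclass
class LaggedDataset:
    """Transition pairs ``(x_t, x_{t+lag})`` drawn from one or more trajectories.

    Parameters
    ----------
    trajectories
        List of ``(n_frames_i, dim)`` float arrays.  Pairs are formed with a
        sliding window inside each trajectory; no pair spans a trajectory
        boundary.
    lag
        Lag time in frames.  ``lag == 0`` pairs every frame with itself,
        which is occasionally useful for diagnostics.
    """

    trajectories: list[np.ndarray]
    lag: int

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        trajs = []
        dim = None
        for traj in self.trajectories:
            arr = np.asarray(traj, dtype=np.float64)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.ndim != 2:
                raise ValueError("trajectories must be (n_frames, dim) arrays")
            if dim is None:
                dim = arr.shape[1]
            elif arr.shape[1] != dim:
                raise ValueError("all trajectories must share one dimension")
            trajs.append(arr)
        self.trajectories = trajs
        if self.n_pairs == 0:
            raise ValueError("no pairs: dataset is empty at this lag")

    @classmethod
    def from_trajectory(cls, traj: np.ndarray, lag: int) -> "LaggedDataset":
        return cls([np.asarray(traj)], lag)

    @property
    def dim(self) -> int:
        return self.trajectories[0].shape[1]

    @property
    def n_pairs(self) -> int:
        return sum(max(len(t) - self.lag, 0) for t in self.trajectories)

    @property
    def boundaries(self) -> list[int]:
        """Cumulative frame counts marking trajectory ends."""
        ends, total = [], 0
        for t in self.trajectories:
            total += len(t)
            ends.append(total)
        return ends

    def with_lag(self, lag: int) -> "LaggedDataset":
        """Same trajectories re-paired at a different lag."""
        return LaggedDataset(self.trajectories, lag)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the instantaneous and lagged frame arrays, each (T, dim)."""
        xs, ys = [], []
        for t in self.trajectories:
            if len(t) > self.lag:
                if self.lag == 0:
                    xs.append(t)
                    ys.append(t)
                else:
                    xs.append(t[: -self.lag])
                    ys.append(t[self.lag :])
        return np.concatenate(xs), np.concatenate(ys)

    def subset(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pairs restricted to the given pair indices (for splits/bootstraps)."""
        x, y = self.pairs()
        return x[indices], y[indices]


# ---------------------------------------------------------------------------
# Covariances
# ---------------------------------------------------------------------------

@dataclass
class CovarianceSet:
    """Instantaneous (C00), time-lagged (C01) and lagged-instantaneous (C11)
    covariance matrices of a feature time series, together with the feature
    means of the two series and the number of transition pairs."""

    C00: np.ndarray
    C01: np.ndarray
    C11: np.ndarray
    mean0: np.ndarray
    mean1: np.ndarray
    mean_free: bool
    T: int

    @property
    def dim(self) -> int:
        return self.C00.shape[0]


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"invalid input: non-finite values in {what}")


def _covariances_from_matrices(
    X: np.ndarray, Y: np.ndarray, mean_free: bool
) -> CovarianceSet:
    """Covariances from (T, m) feature matrices.

    Mean-free covariances divide by (T - 1) after removing each series' own
    time mean; raw covariances divide by T.
    """
    T = X.shape[0]
    if T < 2:
        raise ValueError("insufficient samples: need at least 2 pairs")
    mean0 = X.mean(axis=0)
    mean1 = Y.mean(axis=0)
    if mean_free:
        Xc = X - mean0
        Yc = Y - mean1
        denom = T - 1
    else:
        Xc, Yc = X, Y
        denom = T
    C00 = Xc.T @ Xc / denom
    C01 = Xc.T @ Yc / denom
    C11 = Yc.T @ Yc / denom
    # remove floating-point asymmetry before any eigendecomposition
    C00 = 0.5 * (C00 + C00.T)
    C11 = 0.5 * (C11 + C11.T)
    return CovarianceSet(C00, C01, C11, mean0, mean1, mean_free, T)


def estimate_covariances(
    dataset: LaggedDataset,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    mean_free: bool = True,
) -> CovarianceSet:
    """Estimate C00, C01, C11 from all transition pairs of ``dataset``.

    ``transform`` maps an ``(n, dim)`` frame array to ``(n, m)`` features and
    is applied identically to the instantaneous and lagged frames (shared
    lobes); ``None`` uses the frames themselves.
    """
    x, y = dataset.pairs()
    if transform is not None:
        x = np.asarray(transform(x), dtype=np.float64)
        y = np.asarray(transform(y), dtype=np.float64)
    if x.ndim == 1:
        x, y = x[:, None], y[:, None]
    _check_finite(x, "features")
    _check_finite(y, "lagged features")
    return _covariances_from_matrices(x, y, mean_free)


# ---------------------------------------------------------------------------
# Regularised matrix inverses
# ---------------------------------------------------------------------------

def regularized_inverse_sqrt(
    M: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Inverse square root of a symmetric PSD matrix with spectral truncation.

    Eigenpairs with eigenvalue below ``epsilon`` times the largest
    eigenvalue are discarded, so the result acts as a pseudo-inverse square
    root on the retained subspace.
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix is not symmetric")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    evals, evecs = np.linalg.eigh(0.5 * (M + M.T))
    lmax = evals.max(initial=0.0)
    if lmax <= 0 and np.all(np.abs(evals) < 1e-14):
        raise ValueError("rank zero: all eigenvalues below cutoff")
    if evals.min() < -1e-8 * max(lmax, 1e-300):
        raise ValueError("not PSD: negative eigenvalue beyond tolerance")
    keep = evals > epsilon * lmax
    if not np.any(keep):
        raise ValueError("rank zero: all eigenvalues below cutoff")
    V = evecs[:, keep]
    return V @ np.diag(evals[keep] ** -0.5) @ V.T


def regularized_inverse(M: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Spectrally truncated pseudo-inverse of a symmetric PSD matrix."""
    R = regularized_inverse_sqrt(M, epsilon)
    return R @ R


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    """A VAMP score together with the singular values that compose it."""

    order: int
    k: int | str
    value: float
    singular_values: np.ndarray = field(repr=False)
    includes_constant: bool = False
    normalized: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "k": self.k,
                "value": float(self.value),
                "singular_values": [float(s) for s in self.singular_values],
                "includes_constant": self.includes_constant,
            }
        )


def _whitened_singular_values(
    cov: CovarianceSet, epsilon: float
) -> np.ndarray:
    """Singular values of C00^(-1/2) C01 C11^(-1/2), descending.

    Degenerate covariances (all-zero, e.g. from a constant feature) yield an
    empty spectrum rather than an error: they carry no dynamical signal.
    """
    if np.abs(cov.C00).max() < 1e-300 or np.abs(cov.C11).max() < 1e-300:
        return np.zeros(0)
    L0 = regularized_inverse_sqrt(cov.C00, epsilon)
    L1 = regularized_inverse_sqrt(cov.C11, epsilon)
    A = L0 @ cov.C01 @ L1
    sv = np.linalg.svd(A, compute_uv=False)
    return np.sort(np.clip(sv, 0.0, None))[::-1]


def vamp_score(
    cov: CovarianceSet,
    order: int = 2,
    k: int | str = "full",
    include_constant: bool = False,
    normalized: bool = False,
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreReport:
    """VAMP score of a covariance set.

    ``order=2`` sums squared singular values of the whitened time-lagged
    covariance, ``order=1`` sums the singular values themselves.  ``k``
    truncates the sum to the top-k singular values ("full" keeps all);
    requesting more singular values than the matrix rank supplies pads with
    zeros and warns.  ``include_constant`` adds the +1 contribution of the
    constant singular function and requires mean-free covariances.
    ``normalized`` divides the full order-2 sum by the matrix dimension
    (the normalised Frobenius norm convention); it is reported for
    completeness and never changes the optimiser's ranking at fixed k.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if include_constant and not cov.mean_free:
        raise ValueError("the constant augmentation requires mean-free covariances")
    sv = _whitened_singular_values(cov, epsilon)
    if k == "full":
        k_used = len(sv)
        sv_used = sv
    else:
        k_used = int(k)
        if k_used < 0:
            raise ValueError("k must be >= 0")
        if k_used > len(sv):
            warnings.warn(
                f"requested k={k_used} singular values but only {len(sv)} "
                "available; the remainder are treated as zero",
                stacklevel=2,
            )
        sv_used = sv[:k_used]
    if order == 2:
        value = float(np.sum(sv_used**2))
        if normalized:
            if k != "full":
                raise ValueError("normalized mode applies to the full spectrum")
            n = cov.dim
            value /= n
    else:
        if normalized:
            raise ValueError("normalized mode is defined for order 2 only")
        value = float(np.sum(sv_used))
    if include_constant:
        value += 1.0
    return ScoreReport(order, k, value, sv, include_constant, normalized)


def validation_score(
    transform: Callable[[np.ndarray], np.ndarray] | None,
    heldout: LaggedDataset,
    k: int | str = "full",
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreReport:
    """VAMP-2 validation score: Eq.-(12)-style score of held-out pairs.

    Covariances are computed only from the held-out dataset, mean-free, and
    scored with the constant augmentation.
    """
    if heldout.n_pairs < 2:
        raise ValueError("no validation data: need at least 2 held-out pairs")
    cov = estimate_covariances(heldout, transform, mean_free=True)
    return vamp_score(cov, order=2, k=k, include_constant=True, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Analytic gradients
# ---------------------------------------------------------------------------

def _centered(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def vamp2_gradients(
    X: np.ndarray, Y: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the VAMP-2 score with respect to the feature matrices.

    ``X`` and ``Y`` are (m, T) instantaneous and lagged feature matrices.
    Returns ``(gradX, gradY)`` of the same shape,

        gradX = 2/(T-1) C00^-1 C01 C11^-1 (Yc - C01^T C00^-1 Xc)
        gradY = 2/(T-1) C11^-1 C01^T C00^-1 (Xc - C01 C11^-1 Yc),

    with mean-free covariances and centred matrices Xc, Yc.  Rank-deficient
    covariances are handled by the spectrally truncated pseudo-inverse.
    For cloned lobes the caller sums both gradients.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError("X and Y must share a shape")
    m, T = X.shape
    if T < 2:
        raise ValueError("insufficient samples: need T >= 2")
    Xc, Yc = _centered(X), _centered(Y)
    C00 = Xc @ Xc.T / (T - 1)
    C01 = Xc @ Yc.T / (T - 1)
    C11 = Yc @ Yc.T / (T - 1)
    C00i = regularized_inverse(0.5 * (C00 + C00.T), epsilon)
    C11i = regularized_inverse(0.5 * (C11 + C11.T), epsilon)
    pref = 2.0 / (T - 1)
    gradX = pref * (C00i @ C01 @ C11i) @ (Yc - C01.T @ C00i @ Xc)
    gradY = pref * (C11i @ C01.T @ C00i) @ (Xc - C01 @ C11i @ Yc)
    return gradX, gradY


def vamp1_gradients(
    X: np.ndarray, Y: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the VAMP-1 score (nuclear norm of the whitened
    time-lagged covariance) with respect to the (m, T) feature matrices.

    This is the time-lagged analogue of the total-correlation gradient of
    deep CCA: with A = C00^(-1/2) C01 C11^(-1/2) = U S V^T,

        gradX = 1/(T-1) (2 D00 Xc + D01 Yc),   D01 = C00^(-1/2) U V^T C11^(-1/2)
        D00 = -1/2 C00^(-1/2) U S U^T C00^(-1/2)

    and symmetrically for Y.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError("X and Y must share a shape")
    m, T = X.shape
    if T < 2:
        raise ValueError("insufficient samples: need T >= 2")
    Xc, Yc = _centered(X), _centered(Y)
    C00 = Xc @ Xc.T / (T - 1)
    C01 = Xc @ Yc.T / (T - 1)
    C11 = Yc @ Yc.T / (T - 1)
    L0 = regularized_inverse_sqrt(0.5 * (C00 + C00.T), epsilon)
    L1 = regularized_inverse_sqrt(0.5 * (C11 + C11.T), epsilon)
    A = L0 @ C01 @ L1
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    D01 = L0 @ U @ Vt @ L1
    D00 = -0.5 * L0 @ U @ np.diag(S) @ U.T @ L0
    D11 = -0.5 * L1 @ Vt.T @ np.diag(S) @ Vt @ L1
    pref = 1.0 / (T - 1)
    gradX = pref * (2.0 * D00 @ Xc + D01 @ Yc)
    gradY = pref * (2.0 * D11 @ Yc + D01.T @ Xc)
    return gradX, gradY
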