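"""Brute-force grid MSM reference ("oracle") and discrete-chain utilities.

A fine uniform discretization of a one-dimensional coordinate, a
sliding-window count matrix, and its spectral analysis give a direct
numerical approximation of the slow eigenfunctions and timescales — the
baseline every VAMPnet result is compared against.  The estimator is the
plain non-reversible maximum-likelihood one (row-normalised counts); no
detailed-balance constraint is applied.

Also contains the discrete Markov-chain sampler used as a synthetic data
source throughout the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "DiscreteTrajectory",
    "TransitionMatrixResult",
    "ReferenceSpectrum",
    "discretize_grid",
    "transition_matrix",
    "reference_spectrum",
    "sample_markov_chain",
]


@dataclass
class DiscreteTrajectory:
    """State index per frame plus the grid that produced it (if any)."""

    states: np.ndarray
    n_states: int
    edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.min(initial=0) < 0 or self.states.max(initial=0) >= self.n_states:
            raise ValueError("state indices out of range")
        if self.edges is not None:
            self.edges = np.asarray(self.edges, dtype=np.float64)
            if np.any(np.diff(self.edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")


def discretize_grid(
    values: np.ndarray,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
) -> DiscreteTrajectory:
    """Uniform half-open binning of a 1D series.

    Bins are [edge_i, edge_{i+1}) with the last bin closed; out-of-range
    values clamp to the edge bins.  ``value_range=None`` uses the observed
    min/max.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    lo, hi = value_range if value_range is not None else (values.min(), values.max())
    if lo >= hi:
        raise ValueError("range lower bound must be below upper bound")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    return DiscreteTrajectory(idx, n_bins, edges)


@dataclass
class TransitionMatrixResult:
    """Row-stochastic transition matrix over the active (visited) states.

    ``active_states`` maps the rows/columns of ``matrix`` back to the
    original state indices; states with no outgoing count at the lag were
    removed.
    """

    matrix: np.ndarray
    active_states: np.ndarray
    counts: np.ndarray
    lag: int

    def states_of(self, dtraj: DiscreteTrajectory) -> np.ndarray:
        """Map a discrete trajectory onto active-state row indices (-1 if
        the frame's state was dropped)."""
        lookup = -np.ones(int(self.active_states.max()) + 1, dtype=np.int64)
        lookup[self.active_states] = np.arange(len(self.active_states))
        safe = np.clip(dtraj.states, 0, len(lookup) - 1)
        out = lookup[safe]
        out[dtraj.states >= len(lookup)] = -1
        return out


def transition_matrix(
    dtraj: DiscreteTrajectory, lag: int, connected: bool = False
) -> TransitionMatrixResult:
    """Sliding-window count matrix at ``lag``, row-normalised.

    Every frame starts a pair (maximal data use, matching the covariance
    estimators).  Rows with zero outgoing counts are removed and reported
    via ``active_states``; ``connected=True`` additionally restricts to the
    largest strongly connected set of the count graph.
    """
    s = dtraj.states
    if len(s) <= lag:
        raise ValueError("no pairs: trajectory shorter than the lag")
    n = dtraj.n_states
    C = np.zeros((n, n))
    np.add.at(C, (s[:-lag] if lag > 0 else s, s[lag:]), 1.0)
    active = np.where(C.sum(axis=1) > 0)[0]
    if connected:
        import scipy.sparse.csgraph as csgraph

        sub = C[np.ix_(active, active)]
        n_comp, labels = csgraph.connected_components(sub > 0, connection="strong")
        largest = np.argmax(np.bincount(labels))
        active = active[labels == largest]
    C = C[np.ix_(active, active)]
    T = C / C.sum(axis=1, keepdims=True)
    return TransitionMatrixResult(T, active, C, lag)


@dataclass
class ReferenceSpectrum:
    """Eigendecomposition of a reference transition matrix.

    Eigenpairs are sorted by eigenvalue modulus descending.  Right
    eigenvectors are scaled to unit maximum absolute entry with that entry
    positive.  ``timescales`` converts the non-stationary eigenvalues via
    t_i = -lag / ln|lambda_i|.
    """

    eigenvalues: np.ndarray
    left_eigenvectors: np.ndarray
    right_eigenvectors: np.ndarray
    timescales: np.ndarray
    lag: int


def reference_spectrum(T: np.ndarray, lag: int = 1) -> ReferenceSpectrum:
    """Spectral analysis of a row-stochastic matrix."""
    T = np.asarray(T, dtype=np.float64)
    if np.abs(T.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("matrix is not row-stochastic")
    evals, left, right = scipy.linalg.eig(T, left=True, right=True)
    order = np.argsort(-np.abs(evals))
    evals, left, right = evals[order], left[:, order], right[:, order]
    right = right.copy()
    for i in range(right.shape[1]):
        r = right[:, i]
        lead = np.argmax(np.abs(r))
        r = r / r[lead] * np.abs(r[lead]) if r[lead] != 0 else r
        right[:, i] = r / max(np.abs(r).max(), 1e-300)
    ts = np.empty(len(evals) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, lam in enumerate(evals[1:]):
            mod = abs(lam)
            if mod >= 1.0:
                ts[i] = np.inf
            elif mod == 0.0:
                ts[i] = 0.0
            else:
                ts[i] = -lag / np.log(mod)
    return ReferenceSpectrum(evals, left, right, ts, lag)


def sample_markov_chain(
    P: np.ndarray, n_steps: int, seed: int, init: int | None = None
) -> np.ndarray:
    """Sample a discrete-state trajectory from transition matrix ``P``.

    ``init=None`` draws the initial state from the stationary distribution.
    """
    P = np.asarray(P, dtype=np.float64)
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-10:
        raise ValueError("P must be row-stochastic")
    rng = np.random.default_rng(seed)
    n = P.shape[0]
    if init is None:
        evals, evecs = scipy.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        stat = np.abs(stat) / np.abs(stat).sum()
        state = int(rng.choice(n, p=stat))
    else:
        state = int(init)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = state
    for t in range(n_steps - 1):
        state = int(np.searchsorted(cum[state], u[t]))
        out[t + 1] = state
    return out
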