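"""Koopman / fuzzy-MSM estimation and kinetic validation.

Given a fixed feature transformation chi (typically a trained VAMPnet
lobe), the best linear propagator of the transformed coordinates over the
lag time is K = C00^-1 C01.  When chi is a Softmax partition of unity, the
raw-covariance K is the transition matrix of a fuzzy Markov state model:
rows sum to one and K^T propagates state probability vectors.

Validation follows standard MSM practice with the transformation held
fixed: implied timescales t_i(tau) = -tau / ln|lambda_i(tau)| should be
flat in tau, and the Chapman-Kolmogorov identity K(n tau) = K(tau)^n
should hold within statistical uncertainty.  Bootstrap resampling of
transition pairs supplies that uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .vamp import (
    DEFAULT_EPSILON,
    LaggedDataset,
    estimate_covariances,
    regularized_inverse,
    regularized_inverse_sqrt,
)

__all__ = [
    "KoopmanModel",
    "CKReport",
    "TimescaleTable",
    "estimate_koopman",
    "implied_timescales",
    "ck_test",
    "eigenfunction_values",
    "propagate",
]

Transform = Callable[[np.ndarray], np.ndarray] | None


@dataclass
class KoopmanModel:
    """An estimated Koopman matrix with its spectral decomposition.

    ``mode`` is ``"raw"`` (uncentered covariances; the fuzzy-MSM transition
    matrix) or ``"augmented"`` (mean-free construction with the constant
    function appended, used for spectral/score quantities).  Eigenvalues
    are sorted by modulus descending with their right eigenvectors as
    matching columns; ``feature_means`` is set in augmented mode so that
    eigenfunctions can be evaluated on raw features.
    """

    K: np.ndarray
    lag: int
    mode: str
    eigenvalues: np.ndarray = field(repr=False)
    right_eigenvectors: np.ndarray = field(repr=False)
    singular_values: np.ndarray = field(repr=False)
    frame_time: float = 1.0
    feature_means: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.K.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        return self.K.sum(axis=1)


def _sorted_eig(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = scipy.linalg.eig(K)
    order = np.argsort(-np.abs(evals))
    return evals[order], evecs[:, order]


def _features(transform: Transform, frames: np.ndarray) -> np.ndarray:
    out = frames if transform is None else np.asarray(transform(frames))
    out = np.asarray(out, dtype=np.float64)
    if out.ndim == 1:
        out = out[:, None]
    return out


def estimate_koopman(
    transform: Transform,
    dataset: LaggedDataset,
    lag: int | None = None,
    mode: str = "raw",
    epsilon: float = DEFAULT_EPSILON,
    frame_time: float = 1.0,
) -> KoopmanModel:
    """Estimate K = C00^-1 C01 from all pairs of ``dataset`` at ``lag``.

    Raw mode uses uncentered covariances of the features themselves — for
    partition-of-unity features this is the fuzzy-MSM transition matrix.
    Augmented mode appends the constant function to the mean-free features,
    which exposes the trivial eigenvalue 1 alongside the whitened
    non-trivial spectrum.  Inverses are spectrally regularised; singular
    values are always reported from the mean-free whitened construction.
    """
    if mode not in ("raw", "augmented"):
        raise ValueError("mode must be 'raw' or 'augmented'")
    ds = dataset if lag is None or lag == dataset.lag else dataset.with_lag(lag)
    cov_raw = estimate_covariances(ds, transform, mean_free=False)
    cov_mf = estimate_covariances(ds, transform, mean_free=True)

    # non-trivial singular spectrum from the whitened mean-free covariances
    try:
        L0 = regularized_inverse_sqrt(cov_mf.C00, epsilon)
        L1 = regularized_inverse_sqrt(cov_mf.C11, epsilon)
        sv = np.linalg.svd(L0 @ cov_mf.C01 @ L1, compute_uv=False)
        sv = np.sort(np.clip(sv, 0.0, None))[::-1]
    except ValueError:
        sv = np.zeros(0)

    if mode == "raw":
        # a direct solve preserves the exact row-sum identity K 1 = 1 for
        # partition-of-unity features; fall back to the spectrally
        # regularised inverse only if C00 is numerically singular
        try:
            K = scipy.linalg.solve(cov_raw.C00, cov_raw.C01, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            warnings.warn(
                "singular instantaneous covariance; using the regularised "
                "pseudo-inverse (row sums may deviate from 1)",
                stacklevel=2,
            )
            try:
                C00i = regularized_inverse(cov_raw.C00, epsilon)
            except ValueError as err:
                raise ValueError(f"degenerate features: {err}") from err
            K = C00i @ cov_raw.C01
        feature_means = None
    else:
        try:
            Kbar = regularized_inverse(cov_mf.C00, epsilon) @ cov_mf.C01
        except ValueError as err:
            raise ValueError(f"degenerate features: {err}") from err
        m = Kbar.shape[0]
        K = np.zeros((m + 1, m + 1))
        K[0, 0] = 1.0
        K[1:, 1:] = Kbar
        sv = np.concatenate([[1.0], sv])
        feature_means = cov_mf.mean0
    evals, evecs = _sorted_eig(K)
    return KoopmanModel(
        K=K,
        lag=ds.lag,
        mode=mode,
        eigenvalues=evals,
        right_eigenvectors=evecs,
        singular_values=sv,
        frame_time=frame_time,
        feature_means=feature_means,
    )


# ---------------------------------------------------------------------------
# Implied timescales
# ---------------------------------------------------------------------------

@dataclass
class TimescaleTable:
    """Implied timescales per lag, optionally with bootstrap uncertainty.

    ``timescales`` is (n_lags, n_timescales), sorted descending within each
    lag; ``stderr``/``ci`` are filled when bootstrapping was requested.
    Times are in ``frame_time`` units.
    """

    lags: np.ndarray
    timescales: np.ndarray
    frame_time: float = 1.0
    stderr: np.ndarray | None = None
    ci: tuple[np.ndarray, np.ndarray] | None = None


def _timescales_from_eigenvalues(
    evals: np.ndarray, lag: float, n_timescales: int
) -> np.ndarray:
    """Drop the eigenvalue closest to 1 (the stationary process), convert the
    next ``n_timescales`` by modulus via t = -lag / ln|lambda|."""
    evals = np.asarray(evals)
    stat = int(np.argmin(np.abs(evals - 1.0)))
    rest = np.delete(evals, stat)
    rest = rest[np.argsort(-np.abs(rest))][:n_timescales]
    out = np.empty(len(rest))
    for i, lam in enumerate(rest):
        mod = abs(lam)
        if mod >= 1.0:
            warnings.warn(
                f"eigenvalue modulus {mod:.6g} >= 1; timescale reported as inf",
                stacklevel=2,
            )
            out[i] = np.inf
        elif mod == 0.0:
            out[i] = 0.0
        else:
            out[i] = -lag / np.log(mod)
    return out


def _bootstrap_koopman(
    feats_x: np.ndarray,
    feats_y: np.ndarray,
    rng: np.random.Generator,
    epsilon: float,
) -> np.ndarray:
    T = len(feats_x)
    idx = rng.integers(0, T, size=T)
    X, Y = feats_x[idx], feats_y[idx]
    C00 = 0.5 * (X.T @ X + (X.T @ X).T) / T
    C01 = X.T @ Y / T
    try:
        return scipy.linalg.solve(C00, C01, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError):
        return regularized_inverse(C00, epsilon) @ C01


def implied_timescales(
    transform: Transform,
    dataset: LaggedDataset,
    lags: Sequence[int],
    n_timescales: int = 1,
    epsilon: float = DEFAULT_EPSILON,
    frame_time: float = 1.0,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> TimescaleTable:
    """Implied timescales of the raw-mode Koopman model at each lag.

    The transformation is held fixed (trained at its own lag); only the
    covariance estimates change with the lag.  With ``n_bootstrap > 0``,
    transition pairs at each lag are resampled with replacement to obtain
    per-timescale standard errors and percentile 95% intervals.
    """
    lags = np.asarray(sorted(int(l) for l in lags))
    rows, errs, lo, hi = [], [], [], []
    rng = np.random.default_rng(seed)
    for lag in lags:
        ds = dataset.with_lag(int(lag))
        model = estimate_koopman(transform, ds, mode="raw", epsilon=epsilon)
        rows.append(
            _timescales_from_eigenvalues(
                model.eigenvalues, lag * frame_time, n_timescales
            )
        )
        if n_bootstrap > 0:
            x, y = ds.pairs()
            fx, fy = _features(transform, x), _features(transform, y)
            reps = []
            for _ in range(n_bootstrap):
                Kb = _bootstrap_koopman(fx, fy, rng, epsilon)
                evb = np.linalg.eigvals(Kb)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    reps.append(
                        _timescales_from_eigenvalues(
                            evb, lag * frame_time, n_timescales
                        )
                    )
            reps = np.array(reps)
            finite = np.where(np.isfinite(reps), reps, np.nan)
            errs.append(np.nanstd(finite, axis=0))
            lo.append(np.nanpercentile(finite, 2.5, axis=0))
            hi.append(np.nanpercentile(finite, 97.5, axis=0))
    table = TimescaleTable(lags, np.array(rows), frame_time)
    if n_bootstrap > 0:
        table.stderr = np.array(errs)
        table.ci = (np.array(lo), np.array(hi))
    return table


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKReport:
    """Chapman-Kolmogorov comparison K(tau)^n vs K(n tau).

    ``deviations[i] = |predicted[i] - estimated[i]|`` entrywise;
    ``stderr`` holds bootstrap standard errors of the difference when
    requested.  Multiples lacking data are dropped with a warning.
    """

    tau: int
    multiples: list[int]
    predicted: list[np.ndarray]
    estimated: list[np.ndarray]
    deviations: list[np.ndarray]
    stderr: list[np.ndarray] | None = None

    @property
    def max_abs_deviation(self) -> np.ndarray:
        return np.array([d.max() for d in self.deviations])


def ck_test(
    transform: Transform,
    dataset: LaggedDataset,
    tau: int,
    multiples: Sequence[int],
    epsilon: float = DEFAULT_EPSILON,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> CKReport:
    """Chapman-Kolmogorov test with the transformation held fixed.

    ``predicted`` is the matrix power of the raw-mode K estimated at
    ``tau``; ``estimated`` is a fresh raw-mode estimate using all available
    pairs at lag ``n * tau``.  Bootstrap resamples pairs independently at
    both lags and reports the standard error of the entrywise difference.
    """
    model = estimate_koopman(transform, dataset, lag=tau, mode="raw", epsilon=epsilon)
    rng = np.random.default_rng(seed)
    x1, y1 = dataset.with_lag(tau).pairs()
    fx1, fy1 = _features(transform, x1), _features(transform, y1)

    kept: list[int] = []
    predicted, estimated, deviations, stderr = [], [], [], []
    for n in sorted(int(n) for n in multiples):
        if n < 1:
            raise ValueError("multiples must be >= 1")
        try:
            ds_n = dataset.with_lag(n * tau)
        except ValueError:
            warnings.warn(f"no pairs at lag {n * tau}; multiple {n} skipped", stacklevel=2)
            continue
        if ds_n.n_pairs < 2:
            warnings.warn(f"insufficient pairs at lag {n * tau}; multiple {n} skipped", stacklevel=2)
            continue
        est = estimate_koopman(transform, ds_n, mode="raw", epsilon=epsilon)
        pred = np.linalg.matrix_power(model.K, n)
        kept.append(n)
        predicted.append(pred)
        estimated.append(est.K)
        deviations.append(np.abs(pred - est.K))
        if n_bootstrap > 0:
            xn, yn = ds_n.pairs()
            fxn, fyn = _features(transform, xn), _features(transform, yn)
            diffs = []
            for _ in range(n_bootstrap):
                K1b = _bootstrap_koopman(fx1, fy1, rng, epsilon)
                Knb = _bootstrap_koopman(fxn, fyn, rng, epsilon)
                diffs.append(np.linalg.matrix_power(K1b, n) - Knb)
            stderr.append(np.std(np.array(diffs), axis=0))
    return CKReport(
        tau=tau,
        multiples=kept,
        predicted=predicted,
        estimated=estimated,
        deviations=deviations,
        stderr=stderr if n_bootstrap > 0 else None,
    )


# ---------------------------------------------------------------------------
# Eigenfunctions and propagation
# ---------------------------------------------------------------------------

def eigenfunction_values(
    model: KoopmanModel,
    transform: Transform,
    frames: np.ndarray,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Evaluate the approximated Koopman eigenfunctions on frames.

    The i-th eigenfunction is the linear combination of the features with
    the entries of the i-th right eigenvector, psi_i(x) = sum_j r_ij
    chi_j(x).  The sign is fixed so the eigenvector entry of largest
    magnitude is positive; complex eigenpairs contribute their real part
    with a warning.  Returns an (n_frames, len(indices)) array.
    """
    chi = _features(transform, np.asarray(frames, dtype=np.float64))
    if model.mode == "augmented":
        chi = np.hstack([np.ones((len(chi), 1)), chi - model.feature_means])
    if chi.shape[1] != model.dim:
        raise ValueError("transform dimension does not match the model")
    if indices is None:
        indices = range(model.dim)
    cols = []
    for i in indices:
        r = model.right_eigenvectors[:, i]
        if np.abs(r.imag).max() > 1e-12 * max(np.abs(r).max(), 1e-300):
            warnings.warn(
                f"eigenvector {i} is complex; returning the real part",
                stacklevel=2,
            )
        r = r.real
        lead = np.argmax(np.abs(r))
        if r[lead] < 0:
            r = -r
        cols.append(chi @ r)
    return np.column_stack(cols)


def propagate(model: KoopmanModel, p0: np.ndarray, n: int) -> np.ndarray:
    """Propagate a state probability vector: p_n = (K^T)^n p0.

    Requires a raw-mode model (the fuzzy-MSM transition matrix); the entry
    sum of ``p0`` is preserved up to estimation error in K.
    """
    if model.mode != "raw":
        raise ValueError("probability propagation requires a raw-mode model")
    if n < 0:
        raise ValueError("n must be >= 0")
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != (model.dim,):
        raise ValueError("p0 does not match the model dimension")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must be a probability vector")
    return np.linalg.matrix_power(model.K.T, n) @ p0
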