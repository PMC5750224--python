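"""Twin-lobe network construction and the VAMPnet training protocol.

A VAMPnet consists of two lobes that transform the instantaneous and the
time-lagged frames of a trajectory; here the lobes are identical clones
sharing one parameter set.  Each lobe is a fully connected network with
ReLU hidden layers and a Softmax output layer, so every output activation
is non-negative and the activations sum to one: the network performs a
fuzzy assignment of each frame to one of ``n_out`` metastable states.

The network, its backward pass, dropout, L2 weight decay and the Adam
optimiser are implemented directly on numpy arrays.  Only dense-layer
back-propagation is required because the training signal — the gradient of
the VAMP score with respect to the lobe outputs — is available in closed
form (see :mod:`vampnet.vamp`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .vamp import (
    DEFAULT_EPSILON,
    LaggedDataset,
    ScoreReport,
    estimate_covariances,
    vamp1_gradients,
    vamp2_gradients,
    vamp_score,
)

__all__ = [
    "LobeSpec",
    "Lobe",
    "TrainingConfig",
    "TrainedVAMPnet",
    "EnsembleResult",
    "size_layers",
    "build_lobe",
    "train",
    "run_ensemble",
    "success_filter",
]


# ---------------------------------------------------------------------------
# Layer sizing
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def size_layers(n_in: int, n_out: int, d: int) -> list[int]:
    """Layer widths that shrink by a constant factor from ``n_in`` to ``n_out``.

    The ratio between consecutive widths is held at ``(n_in/n_out)**(1/d)``
    where ``d`` counts layers excluding the input layer; intermediate widths
    are rounded half-away-from-zero and the final layer is pinned at
    ``n_out``.  ``n_out > n_in`` gives an expanding network (ratio < 1).
    """
    if d < 1:
        raise ValueError("depth d must be >= 1")
    if n_in < 1 or n_out < 1:
        raise ValueError("node counts must be >= 1")
    ratio = (n_in / n_out) ** (1.0 / d)
    widths = [n_in]
    for _ in range(d - 1):
        widths.append(_round_half_away(widths[-1] / ratio))
    widths.append(n_out)
    return widths


# ---------------------------------------------------------------------------
# Lobe specification and network
# ---------------------------------------------------------------------------

@dataclass
class LobeSpec:
    """Architecture of one network lobe.

    ``widths`` may be given explicitly to bypass the constant-reduction
    sizing rule (e.g. the 1-5-10-5 lobes used for the double-well system);
    otherwise it is derived from ``(n_in, n_out, depth)``.  ``dropout``
    holds one rate per hidden layer; the default switches 10% dropout on
    for the first two hidden layers and none elsewhere.  Weight decay
    defaults to 1e-7 on hidden layers and 1e-8 on the output layer.
    """

    n_in: int
    n_out: int
    depth: int | None = None
    widths: list[int] | None = None
    dropout: list[float] | None = None
    l2_hidden: float = 1e-7
    l2_output: float = 1e-8

    def __post_init__(self) -> None:
        if self.widths is None:
            if self.depth is None:
                raise ValueError("provide either depth or explicit widths")
            self.widths = size_layers(self.n_in, self.n_out, self.depth)
        else:
            self.widths = [int(w) for w in self.widths]
            self.depth = len(self.widths) - 1
        if self.widths[0] != self.n_in or self.widths[-1] != self.n_out:
            raise ValueError("widths must start at n_in and end at n_out")
        if any(w < 1 for w in self.widths):
            raise ValueError("layer widths must be >= 1")
        n_hidden = self.depth - 1
        if self.dropout is None:
            self.dropout = [0.1 if i < 2 else 0.0 for i in range(n_hidden)]
        if len(self.dropout) != n_hidden:
            raise ValueError("need one dropout rate per hidden layer")
        if any(not (0.0 <= p < 1.0) for p in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")

    @property
    def n_parameters(self) -> int:
        return sum(
            self.widths[i] * self.widths[i + 1] + self.widths[i + 1]
            for i in range(self.depth)
        )


class Lobe:
    """One VAMPnet lobe: a differentiable map from frames to Softmax features.

    Calling the lobe runs it in evaluation mode (dropout off); the
    ``forward``/``backward`` pair is used by the trainer.
    """

    def __init__(self, spec: LobeSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(spec.depth):
            fan_in, fan_out = spec.widths[i], spec.widths[i + 1]
            # He initialisation for the ReLU stack, Glorot for the Softmax layer
            if i < spec.depth - 1:
                scale = math.sqrt(2.0 / fan_in)
            else:
                scale = math.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match architecture")
        for p, s in zip(params, state):
            p[...] = s

    # -- forward / backward ----------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the lobe on ``(n, n_in)`` input; returns output and cache."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        acts = [x]
        masks: list[np.ndarray | None] = []
        h = x
        d = self.spec.depth
        for i in range(d - 1):
            z = h @ self.weights[i] + self.biases[i]
            h = np.maximum(z, 0.0)
            if training and self.spec.dropout[i] > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                p = self.spec.dropout[i]
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        z = h @ self.weights[d - 1] + self.biases[d - 1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=1, keepdims=True)
        return out, {"acts": acts, "masks": masks, "out": out}

    def backward(
        self, cache: dict, grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Back-propagate a gradient w.r.t. the Softmax output.

        Returns per-layer weight and bias gradients (no regularisation term).
        """
        acts, masks, out = cache["acts"], cache["masks"], cache["out"]
        d = self.spec.depth
        gW = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        # softmax jacobian: dz = p * (g - <g, p>)
        inner = np.sum(grad_out * out, axis=1, keepdims=True)
        delta = out * (grad_out - inner)
        for i in range(d - 1, -1, -1):
            h_prev = acts[i]
            gW[i] = h_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0.0)
        return gW, gb

    def __call__(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x, training=False)
        return out


def build_lobe(spec: LobeSpec, seed: int) -> Lobe:
    """Construct a lobe with reproducible, seed-determined parameters."""
    return Lobe(spec, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyper-parameters of the training protocol.

    ``k`` is the number of singular values of the whitened mean-free
    covariance entering the reported scores (the constant singular function
    contributes a separate +1).  A Softmax lobe with ``n_out`` states spans
    only ``n_out - 1`` non-trivial directions, so values of ``k`` up to
    ``n_out`` are accepted but anything beyond ``n_out - 1`` is structurally
    zero.  The learning rate starts at 0.05 and is divided by 10 whenever
    the validation score fails to improve for ``lr_patience`` consecutive
    epochs.  The first third of the epochs pre-trains with the VAMP-1
    score; the remainder maximises VAMP-2.
    """

    k: int = 2
    epochs: int = 100
    batch_size: int = 4000
    learning_rate: float = 0.05
    lr_patience: int = 10
    lr_factor: float = 0.1
    val_fraction: float = 0.1
    pretrain_epochs: int | None = None
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def resolved_pretrain(self) -> int:
        return self.epochs // 3 if self.pretrain_epochs is None else self.pretrain_epochs


@dataclass
class TrainedVAMPnet:
    """A trained lobe with its provenance and per-epoch score traces."""

    lobe: Lobe
    spec: LobeSpec
    lag: int
    k: int
    train_scores: list[float]
    val_scores: list[float]
    learning_rates: list[float]
    best_epoch: int
    best_val_score: float
    seed: int

    @property
    def transform(self) -> Callable[[np.ndarray], np.ndarray]:
        return self.lobe


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.cfg = cfg
        self.lr = cfg.learning_rate

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_eps
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _split_score(
    lobe: Lobe, x: np.ndarray, y: np.ndarray, k: int, epsilon: float
) -> float:
    from .vamp import _covariances_from_matrices  # local: internal helper

    cov = _covariances_from_matrices(lobe(x), lobe(y), mean_free=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = vamp_score(cov, order=2, k=k, include_constant=True, epsilon=epsilon)
    return rep.value


def train(
    dataset: LaggedDataset, spec: LobeSpec, config: TrainingConfig | None = None
) -> TrainedVAMPnet:
    """Train a twin-lobe VAMPnet on the transition pairs of ``dataset``.

    The pairs are shuffled and split 90%/10% into training and validation
    sets.  Minibatch covariances drive the analytic VAMP gradients, which
    are back-propagated through both (cloned) lobes and applied with Adam;
    reported per-epoch scores are computed on the full splits in
    evaluation mode.  The parameters with the best validation VAMP-2 score
    are returned, not the final-epoch parameters.
    """
    config = config or TrainingConfig()
    if spec.n_in != dataset.dim:
        raise ValueError("spec.n_in does not match the dataset dimension")
    if config.k > spec.n_out:
        raise ValueError(
            "k exceeds n_out: a Softmax lobe spans only n_out - 1 "
            "non-trivial directions"
        )
    if config.k == spec.n_out:
        warnings.warn(
            "k equals n_out; the smallest requested singular value is "
            "structurally zero for Softmax features",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    x_all, y_all = dataset.pairs()
    T = len(x_all)
    order = rng.permutation(T)
    n_val = max(int(round(T * config.val_fraction)), 2)
    if T - n_val < 2:
        raise ValueError("dataset too small to split")
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_va, y_va = x_all[val_idx], y_all[val_idx]

    lobe = build_lobe(spec, seed=int(rng.integers(2**31 - 1)))
    params = lobe.parameters()
    adam = _Adam(params, config)
    batch = min(config.batch_size, len(x_tr))
    n_pre = config.resolved_pretrain()

    reg = [spec.l2_hidden] * (spec.depth - 1) + [spec.l2_output]
    best_state = lobe.get_state()
    best_val = -np.inf
    best_epoch = -1
    since_improve = 0
    train_scores: list[float] = []
    val_scores: list[float] = []
    lrs: list[float] = []

    for epoch in range(config.epochs):
        grad_fn = vamp1_gradients if epoch < n_pre else vamp2_gradients
        perm = rng.permutation(len(x_tr))
        for start in range(0, len(perm), batch):
            idx = perm[start : start + batch]
            if len(idx) < 2:
                continue
            xb, yb = x_tr[idx], y_tr[idx]
            chi0, cache0 = lobe.forward(xb, training=True, rng=rng)
            chi1, cache1 = lobe.forward(yb, training=True, rng=rng)
            if not (np.all(np.isfinite(chi0)) and np.all(np.isfinite(chi1))):
                raise RuntimeError("training diverged: non-finite lobe output")
            gX, gY = grad_fn(chi0.T, chi1.T, epsilon=config.epsilon)
            # maximise the score: descend the negative gradient
            gW0, gb0 = lobe.backward(cache0, -gX.T)
            gW1, gb1 = lobe.backward(cache1, -gY.T)
            gW = [a + b + r * w for a, b, r, w in zip(gW0, gW1, reg, lobe.weights)]
            gb = [a + b for a, b in zip(gb0, gb1)]
            adam.step(params, gW + gb)

        tr_score = _split_score(lobe, x_tr, y_tr, config.k, config.epsilon)
        va_score = _split_score(lobe, x_va, y_va, config.k, config.epsilon)
        if not (np.isfinite(tr_score) and np.isfinite(va_score)):
            raise RuntimeError("training diverged: non-finite score")
        train_scores.append(tr_score)
        val_scores.append(va_score)
        lrs.append(adam.lr)
        if va_score > best_val:
            best_val = va_score
            best_state = lobe.get_state()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.lr_patience:
                adam.lr *= config.lr_factor
                since_improve = 0

    lobe.set_state(best_state)
    return TrainedVAMPnet(
        lobe=lobe,
        spec=spec,
        lag=dataset.lag,
        k=config.k,
        train_scores=train_scores,
        val_scores=val_scores,
        learning_rates=lrs,
        best_epoch=best_epoch,
        best_val_score=float(best_val),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Ensembles and the success filter
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Outcome of repeated independent training runs.

    Runs are ranked by validation score; a fraction ``trim`` is discarded
    from each tail of the ranking before any statistic is computed.  When a
    ``quantity`` function was supplied, ``mean`` and ``ci`` summarise its
    values over the retained runs (percentile 95% confidence interval).
    """

    models: list[TrainedVAMPnet]
    val_scores: np.ndarray
    trim: float
    retained_indices: np.ndarray
    quantities: np.ndarray | None = None
    mean: np.ndarray | float | None = None
    ci: tuple | None = None

    @property
    def best_model(self) -> TrainedVAMPnet:
        retained = [self.models[i] for i in self.retained_indices]
        scores = self.val_scores[self.retained_indices]
        return retained[int(np.argmax(scores))]


def run_ensemble(
    dataset: LaggedDataset,
    spec: LobeSpec,
    config: TrainingConfig | None = None,
    n_runs: int = 100,
    trim: float = 0.05,
    quantity: Callable[[TrainedVAMPnet], float | np.ndarray] | None = None,
) -> EnsembleResult:
    """Repeat training ``n_runs`` times with independent seeds and splits.

    Each run reshuffles and re-splits the data.  The best and worst
    ``trim`` fraction of runs (by validation score) are discarded as
    outliers; remaining runs contribute to the mean and percentile 95%
    confidence interval of the requested ``quantity``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim must lie in [0, 0.5)")
    config = config or TrainingConfig()
    models: list[TrainedVAMPnet] = []
    for i in range(n_runs):
        cfg_i = replace(config, seed=config.seed + i)
        try:
            models.append(train(dataset, spec, cfg_i))
        except RuntimeError as err:  # diverged run: drop, keep going
            warnings.warn(f"run {i} failed: {err}", stacklevel=2)
    if not models:
        raise RuntimeError("ensemble empty: all runs failed")
    scores = np.array([m.best_val_score for m in models])
    n = len(models)
    n_cut = int(round(n * trim))
    ranking = np.argsort(scores)  # ascending
    retained = np.sort(ranking[n_cut : n - n_cut]) if n_cut > 0 else np.arange(n)
    result = EnsembleResult(models, scores, trim, retained)
    if quantity is not None:
        vals = np.array([np.asarray(quantity(models[i]), dtype=float) for i in retained])
        result.quantities = vals
        result.mean = vals.mean(axis=0)
        result.ci = (
            np.percentile(vals, 2.5, axis=0),
            np.percentile(vals, 97.5, axis=0),
        )
    return result


def success_filter(
    timescales: Sequence[float], thresholds: Sequence[float]
) -> bool:
    """Did a run resolve the slow processes?

    ``timescales`` are sorted descending, ``thresholds`` ascending; the run
    succeeds iff the i-th slowest timescale exceeds the i-th largest
    threshold for every i.  Fewer timescales than thresholds is a failure;
    an empty threshold list is a vacuous success.
    """
    thresholds = list(thresholds)
    timescales = list(timescales)
    if len(timescales) < len(thresholds):
        return False
    return all(
        t > thr for t, thr in zip(timescales, sorted(thresholds, reverse=True))
    )
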