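"""Probabilistic prototype classification on SPD matrices with a learnable
log-domain metric tensor, plus the minimum-distance-to-mean baseline.

The classifier keeps ``M = C * N`` labeled prototypes ``W_j`` (stored by
their matrix logarithms), a metric tensor ``Q = Omega Omega^T`` and a
fixed bandwidth ``sigma^2``.  The squared prototype distance is

    delta(X, W_j, Q) = Tr[ Q (logX - logW_j)(logX - logW_j) ]

and the class posterior is a Gaussian-mixture responsibility built from
``f = -delta / (2 sigma^2)`` with fixed uniform component priors.
Training is stochastic gradient descent on the negative log-likelihood:
per sample, the prototype rule moves the correct-class prototype
toward ``logX`` and others away; the raw term ``Q (logX - logW)`` is
symmetrized to ``(Q D + D Q)/2`` so that prototypes stay in the symmetric
space — the symmetrized term is exactly the cost gradient restricted to
that space (checked against finite differences in the test suite).

The metric update follows the quotient-geometry rule on ``Omega``; after
each update ``Q`` is rescaled to ``Tr(Q) = n`` to pin the scale
degeneracy between ``Q`` and ``sigma^2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import geometry as geo
from .data import SPDDataset
from .exceptions import DimensionMismatchError, InvalidInputError

__all__ = [
    "PLVQModel",
    "LearningSchedule",
    "plvq_distance",
    "plvq_posteriors",
    "plvq_cost",
    "plvq_update_step",
    "plvq_fit",
    "plvq_predict",
    "MDRMModel",
    "mdrm_fit",
    "mdrm_predict",
    "grid_search_cv",
]


@dataclass
class LearningSchedule:
    """Annealed learning rates for prototype and metric updates.

    With matrix dimension ``n`` and ``xi`` prototypes per class::

        alpha(t) = (n * xi / 100)   * 0.01 ** (t / T)
        eta(t)   = (n * xi / 10000) * 0.01 ** ((t - t0) / (T - t0))

    so ``eta(t) < alpha(t)`` throughout; metric learning starts at epoch
    ``t0`` (default 1, i.e. immediately).
    """

    n: int
    xi: int
    T: int = 100
    t0: int = 1

    def __post_init__(self):
        if self.T < 1 or not (1 <= self.t0 <= self.T):
            raise InvalidInputError("schedule requires 1 <= t0 <= T")

    def alpha(self, t: int) -> float:
        return (self.n * self.xi / 100.0) * 0.01 ** (t / self.T)

    def eta(self, t: int) -> float:
        if self.T == self.t0:
            return self.n * self.xi / 10000.0 * 0.01
        return (self.n * self.xi / 10000.0) * 0.01 ** ((t - self.t0) / (self.T - self.t0))


@dataclass
class PLVQModel:
    """Prototype model: log-prototypes, their labels, metric factor Omega,
    bandwidth sigma^2 and fixed uniform priors."""

    log_prototypes: np.ndarray  # (M, n, n), symmetric
    proto_labels: np.ndarray  # (M,), values in 1..C
    omega: np.ndarray  # (n, n)
    sigma2: float
    priors: np.ndarray  # (M,), sums to 1
    n_per_class: int
    cost_trace: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        self.log_prototypes = np.asarray(self.log_prototypes, dtype=float)
        self.proto_labels = np.asarray(self.proto_labels, dtype=int)
        self.omega = np.asarray(self.omega, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.sigma2 <= 0:
            raise InvalidInputError("sigma2 must be positive")
        if np.any(self.priors < 0) or not np.isclose(self.priors.sum(), 1.0):
            raise InvalidInputError("priors must be non-negative and sum to 1")

    @property
    def q(self) -> np.ndarray:
        """Metric tensor ``Q = Omega Omega^T`` (symmetric PSD)."""
        return self.omega @ self.omega.T

    @property
    def n_classes(self) -> int:
        return int(self.proto_labels.max())

    @property
    def dim(self) -> int:
        return self.log_prototypes.shape[1]

    def copy(self) -> "PLVQModel":
        return PLVQModel(
            self.log_prototypes.copy(),
            self.proto_labels.copy(),
            self.omega.copy(),
            self.sigma2,
            self.priors.copy(),
            self.n_per_class,
            list(self.cost_trace),
        )

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "log_prototypes": self.log_prototypes.tolist(),
            "proto_labels": self.proto_labels.tolist(),
            "omega": self.omega.tolist(),
            "sigma2": self.sigma2,
            "priors": self.priors.tolist(),
            "n_per_class": self.n_per_class,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLVQModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            np.asarray(d["log_prototypes"]),
            np.asarray(d["proto_labels"]),
            np.asarray(d["omega"]),
            d["sigma2"],
            np.asarray(d["priors"]),
            d["n_per_class"],
        )


def _delta_log(log_x: np.ndarray, log_w: np.ndarray, Q: np.ndarray) -> float:
    D = log_x - log_w
    return float(np.trace(Q @ D @ D))


def plvq_distance(X, W, Q) -> float:
    """Squared metric-tensor distance ``Tr[Q (logX - logW)^2]``; reduces to
    the squared log-Euclidean distance at ``Q = I``."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if X.shape != W.shape or Q.shape != X.shape:
        raise DimensionMismatchError(
            f"shapes differ: X {X.shape}, W {W.shape}, Q {Q.shape}"
        )
    return _delta_log(geo.sym_logm(X), geo.sym_logm(W), Q)


def _log_responsibilities(log_x: np.ndarray, model: PLVQModel) -> np.ndarray:
    """log[P(j) exp(f_j)] for every prototype, unnormalized."""
    Q = model.q
    f = np.array(
        [
            -_delta_log(log_x, lw, Q) / (2.0 * model.sigma2)
            for lw in model.log_prototypes
        ]
    )
    return np.log(model.priors) + f


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _posteriors_from_log(log_x: np.ndarray, model: PLVQModel):
    log_r = _log_responsibilities(log_x, model)
    proto_probs = _softmax(log_r)
    C = model.n_classes
    class_probs = np.array(
        [proto_probs[model.proto_labels == y].sum() for y in range(1, C + 1)]
    )
    return class_probs, proto_probs, log_r


def plvq_posteriors(X, model: PLVQModel):
    """Class posterior vector (index ``y-1`` is class ``y``) and the
    per-prototype assignment probabilities ``P(j | X)``.

    Log-sum-exp stabilized; the class vector sums to 1.
    """
    log_x = geo.sym_logm(np.asarray(X, dtype=float))
    class_probs, proto_probs, _ = _posteriors_from_log(log_x, model)
    return class_probs, proto_probs


def plvq_cost(model: PLVQModel, dataset: SPDDataset) -> float:
    """Negative log-likelihood of the labels under the mixture:
    ``sum_i [ log sum_j P(j) e^f - log sum_{j: c_j = y_i} P(j) e^f ]``."""
    if dataset.labels is None:
        raise InvalidInputError("plvq_cost requires a labeled dataset")
    logs = geo.log_stack(dataset)
    return _cost_from_logs(model, logs, dataset.labels)


def _cost_from_logs(model: PLVQModel, logs: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for log_x, y in zip(logs, labels):
        log_r = _log_responsibilities(log_x, model)
        all_lse = _logsumexp(log_r)
        correct_lse = _logsumexp(log_r[model.proto_labels == y])
        total += all_lse - correct_lse
    return float(total)


def _logsumexp(a: np.ndarray) -> float:
    m = a.max()
    return float(m + np.log(np.exp(a - m).sum()))


def _gradients(
    log_protos: np.ndarray,
    proto_labels: np.ndarray,
    omega: np.ndarray,
    priors: np.ndarray,
    sigma2: float,
    log_x: np.ndarray,
    y: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample cost gradients w.r.t. the log-prototypes and Omega.

    The prototype gradient carries the symmetrized term
    ``(Q D + D Q)/2``; a plain gradient step at rates ``alpha`` / ``eta``
    reproduces the classical stochastic update rules.
    """
    Q = omega @ omega.T
    deltas = log_x[None] - log_protos  # (M, n, n)
    f = np.einsum("ij,mjk,mki->m", Q, deltas, deltas) / (-2.0 * sigma2)
    log_r = np.log(priors) + f
    p_all = _softmax(log_r)
    correct = proto_labels == y
    p_y = np.zeros_like(p_all)
    p_y[correct] = _softmax(log_r[correct])

    coeff = np.where(correct, p_all - p_y, p_all)
    grad_w = np.empty_like(log_protos)
    grad_omega = np.zeros_like(omega)
    for l in range(len(log_protos)):
        QD = Q @ deltas[l]
        grad_w[l] = coeff[l] * (QD + QD.T) / (2.0 * sigma2)
        D2 = deltas[l] @ deltas[l]
        grad_omega += ((p_y[l] if correct[l] else 0.0) - p_all[l]) * (D2 @ omega)
    grad_omega /= sigma2
    return grad_w, grad_omega


def _update_inplace(
    log_protos: np.ndarray,
    proto_labels: np.ndarray,
    omega: np.ndarray,
    priors: np.ndarray,
    sigma2: float,
    log_x: np.ndarray,
    y: int,
    alpha: float,
    eta: float,
    learn_metric: bool,
) -> np.ndarray:
    """One stochastic update; mutates log_protos / omega, returns omega."""
    n = log_protos.shape[1]
    grad_w, grad_omega = _gradients(
        log_protos, proto_labels, omega, priors, sigma2, log_x, y
    )
    log_protos -= alpha * grad_w
    if learn_metric:
        omega -= eta * grad_omega
        trq = np.trace(omega @ omega.T)
        if trq <= 0:
            raise InvalidInputError("metric tensor collapsed to zero trace")
        omega *= np.sqrt(n / trq)
    return omega


def plvq_update_step(
    model: PLVQModel,
    X,
    y: int,
    alpha: float,
    eta: float = 0.0,
    learn_metric: bool = False,
) -> PLVQModel:
    """Apply the per-sample stochastic update and return a new model."""
    if not (0 <= alpha < 1) or not (0 <= eta < 1):
        raise InvalidInputError("learning rates must lie in [0, 1)")
    if y < 1 or y > model.n_classes:
        raise InvalidInputError(f"label {y} outside 1..{model.n_classes}")
    out = model.copy()
    log_x = geo.sym_logm(np.asarray(X, dtype=float))
    out.omega = _update_inplace(
        out.log_prototypes,
        out.proto_labels,
        out.omega,
        out.priors,
        out.sigma2,
        log_x,
        y,
        alpha,
        eta,
        learn_metric,
    )
    return out


def _init_model(
    train: SPDDataset, n_per_class: int, sigma2: float, rng: np.random.Generator
) -> PLVQModel:
    """Prototypes at class log-means, with a small seeded symmetric jitter
    (Frobenius norm 0.01) to break symmetry when n_per_class > 1."""
    if train.labels is None:
        raise InvalidInputError("training data must be labeled")
    n = train.dim
    C = train.n_classes
    log_protos, labels = [], []
    for k in range(1, C + 1):
        idx = train.class_indices(k)
        if idx.size < n_per_class:
            raise InvalidInputError(
                f"class {k} has {idx.size} samples, fewer than "
                f"{n_per_class} prototypes"
            )
        class_log_mean = geo.log_stack(train.subset(idx)).mean(axis=0)
        for j in range(n_per_class):
            proto = class_log_mean.copy()
            if n_per_class > 1:
                J = geo.symmetrize(rng.standard_normal((n, n)))
                proto += 0.01 * J / np.linalg.norm(J, "fro")
            log_protos.append(proto)
            labels.append(k)
    M = len(log_protos)
    return PLVQModel(
        np.stack(log_protos),
        np.asarray(labels),
        np.eye(n),  # Tr(Q) = n already
        sigma2,
        np.full(M, 1.0 / M),
        n_per_class,
    )


def plvq_fit(
    train: SPDDataset,
    n_per_class: int = 1,
    sigma2: float = 1.0,
    schedule: LearningSchedule | None = None,
    seed: int = 0,
    learn_metric: bool = True,
) -> PLVQModel:
    """Train by epochs of seeded-shuffled stochastic updates.

    Metric learning starts at the schedule's ``t0`` (default epoch 1).
    The fitted model carries a per-epoch ``cost_trace``.
    """
    rng = np.random.default_rng(seed)
    model = _init_model(train, n_per_class, sigma2, rng)
    if schedule is None:
        schedule = LearningSchedule(n=train.dim, xi=n_per_class)
    logs = geo.log_stack(train)
    labels = train.labels
    for t in range(1, schedule.T + 1):
        alpha = schedule.alpha(t)
        eta = schedule.eta(t)
        do_metric = learn_metric and t >= schedule.t0
        order = rng.permutation(len(train))
        for i in order:
            model.omega = _update_inplace(
                model.log_prototypes,
                model.proto_labels,
                model.omega,
                model.priors,
                model.sigma2,
                logs[i],
                int(labels[i]),
                alpha,
                eta,
                do_metric,
            )
        model.cost_trace.append(_cost_from_logs(model, logs, labels))
    return model


def plvq_predict(model: PLVQModel, dataset: SPDDataset) -> np.ndarray:
    """Argmax-posterior labels; ties break to the lowest class index."""
    logs = geo.log_stack(dataset)
    out = np.empty(len(dataset), dtype=int)
    for i, log_x in enumerate(logs):
        class_probs, _, _ = _posteriors_from_log(log_x, model)
        out[i] = int(np.argmax(class_probs)) + 1  # argmax returns first max
    return out


# ---------------------------------------------------------------------------
# Minimum distance to Riemannian mean (baseline)
# ---------------------------------------------------------------------------


@dataclass
class MDRMModel:
    class_means: dict[int, np.ndarray]
    metric: str = "lem"


def mdrm_fit(train: SPDDataset, metric: str = "lem") -> MDRMModel:
    """Per-class geometric means under the chosen metric."""
    if train.labels is None:
        raise InvalidInputError("training data must be labeled")
    means = {}
    for k in range(1, train.n_classes + 1):
        idx = train.class_indices(k)
        if idx.size == 0:
            raise InvalidInputError(f"class {k} is empty")
        sub = train.subset(idx)
        means[k] = geo.lem_mean(sub) if metric == "lem" else geo.airm_mean(sub)
    return MDRMModel(means, metric)


def mdrm_predict(model: MDRMModel, dataset: SPDDataset) -> np.ndarray:
    """Nearest class mean; ties break to the lowest class index."""
    dist = geo.lem_distance if model.metric == "lem" else geo.airm_distance
    classes = sorted(model.class_means)
    out = np.empty(len(dataset), dtype=int)
    for i, X in enumerate(dataset.matrices):
        d = [dist(model.class_means[k], X) for k in classes]
        out[i] = classes[int(np.argmin(d))]
    return out


# ---------------------------------------------------------------------------
# Hyper-parameter selection
# ---------------------------------------------------------------------------


def grid_search_cv(
    train: SPDDataset,
    grid_n: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    grid_sigma2: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    folds: int = 5,
    seed: int = 0,
    schedule_T: int = 100,
    learn_metric: bool = True,
) -> tuple[int, float, float]:
    """Stratified k-fold CV over the (N, sigma^2) grid, selecting the
    maximum mean kappa; ties break to smaller N, then smaller sigma^2.

    Returns ``(best_n, best_sigma2, best_kappa)``.
    """
    from .evaluation import kappa as kappa_score

    if train.labels is None:
        raise InvalidInputError("grid search requires labeled data")
    counts = np.bincount(train.labels)[1:]
    if counts.min() < folds:
        raise InvalidInputError(
            f"need at least {folds} samples per class, got minimum {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(train)), train.labels))
    C = train.n_classes
    best = None
    for n_protos in sorted(grid_n):
        for s2 in sorted(grid_sigma2):
            scores = []
            for fold_i, (tr, te) in enumerate(splits):
                sched = LearningSchedule(n=train.dim, xi=n_protos, T=schedule_T)
                model = plvq_fit(
                    train.subset(tr),
                    n_per_class=n_protos,
                    sigma2=s2,
                    schedule=sched,
                    seed=seed + fold_i,
                    learn_metric=learn_metric,
                )
                pred = plvq_predict(model, train.subset(te))
                scores.append(kappa_score(train.labels[te], pred, C))
            mean_kappa = float(np.mean(scores))
            # strict > keeps the first (smallest N, sigma2) of any tie
            if best is None or mean_kappa > best[2] + 1e-12:
                best = (n_protos, s2, mean_kappa)
    return best
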