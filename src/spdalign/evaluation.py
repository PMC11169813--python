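"""Evaluation protocols: chance-corrected kappa, cross-session and
cross-subject transfer experiments, repetition bookkeeping and CPU-time
comparison.

Kappa for balanced classes is ``(D - 1/C) / (1 - 1/C)`` with ``D`` the
accuracy: 1 at perfect prediction, 0 at chance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment as al
from . import plvq
from .data import SPDDataset
from .exceptions import InvalidInputError

__all__ = [
    "EvaluationResult",
    "kappa",
    "accuracy_score",
    "confusion_matrix",
    "split_sessions",
    "run_cross_session",
    "run_cross_subject",
    "run_repeated",
    "timing_comparison",
]

logger = logging.getLogger("spdalign")


def _check_labels(y_true, y_pred, n_classes: int):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise InvalidInputError("empty label arrays")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 1 or arr.max() > n_classes:
            raise InvalidInputError(f"{name} has labels outside 1..{n_classes}")
    return y_true, y_pred


def accuracy_score(y_true, y_pred, n_classes: int) -> float:
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    return float(np.mean(y_true == y_pred))


def kappa(y_true, y_pred, n_classes: int) -> float:
    """Balanced-class chance-corrected agreement:
    ``(D - 1/C) / (1 - 1/C)`` with accuracy ``D`` and ``C`` classes."""
    D = accuracy_score(y_true, y_pred, n_classes)
    return (D - 1.0 / n_classes) / (1.0 - 1.0 / n_classes)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    M = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(M, (y_true - 1, y_pred - 1), 1)
    return M


@dataclass
class EvaluationResult:
    kappa: float
    accuracy: float
    confusion: np.ndarray
    cpu_time: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0

    def to_row(self) -> dict:
        row = {
            "kappa": self.kappa,
            "accuracy": self.accuracy,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        for stage, secs in self.cpu_time.items():
            row[f"cpu_{stage}"] = secs
        return row


def config_hash(config: dict | None) -> str:
    text = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def split_sessions(dataset: SPDDataset, seed: int = 0) -> tuple[SPDDataset, SPDDataset]:
    """Stratified random halves emulating two sessions of one recording."""
    if dataset.labels is None:
        raise InvalidInputError("session splitting requires labels")
    rng = np.random.default_rng(seed)
    first, second = [], []
    for k in range(1, dataset.n_classes + 1):
        idx = rng.permutation(dataset.class_indices(k))
        half = len(idx) // 2
        first.extend(idx[:half])
        second.extend(idx[half:])
    return dataset.subset(np.sort(first)), dataset.subset(np.sort(second))


def _train_predict(classifier: str, train: SPDDataset, test: SPDDataset, config: dict, seed: int):
    cfg = dict(config or {})
    if classifier == "plvq":
        schedule = plvq.LearningSchedule(
            n=train.dim,
            xi=cfg.get("n_per_class", 1),
            T=cfg.get("T", 100),
            t0=cfg.get("t0", 1),
        )
        t0 = time.process_time()
        model = plvq.plvq_fit(
            train,
            n_per_class=cfg.get("n_per_class", 1),
            sigma2=cfg.get("sigma2", 1.0),
            schedule=schedule,
            seed=seed,
            learn_metric=cfg.get("learn_metric", True),
        )
        t_train = time.process_time() - t0
        t0 = time.process_time()
        pred = plvq.plvq_predict(model, test)
    elif classifier == "mdrm":
        t0 = time.process_time()
        model = plvq.mdrm_fit(train, metric=cfg.get("metric", "lem"))
        t_train = time.process_time() - t0
        t0 = time.process_time()
        pred = plvq.mdrm_predict(model, test)
    else:
        raise InvalidInputError(f"unknown classifier {classifier!r}")
    t_predict = time.process_time() - t0
    return pred, t_train, t_predict


def run_cross_session(
    source: SPDDataset,
    target: SPDDataset,
    method: str = "none",
    classifier: str = "mdrm",
    config: dict | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """Align (unsupervised), train on aligned source, score on aligned
    target.  ``method='none'`` skips alignment.  Target labels are used
    for scoring only."""
    if target.labels is None or source.labels is None:
        raise InvalidInputError("source and target need labels (target: scoring only)")
    cfg = dict(config or {})
    align_kwargs = cfg.pop("align", {})
    t0 = time.process_time()
    if method == "none":
        src_aligned, tgt_aligned = source, target
    else:
        t_src, t_tgt = al.fit_alignment(
            source.without_labels(), target.without_labels(), method, **align_kwargs
        )
        src_aligned = source.with_matrices(
            al.apply_transform(t_src, source.without_labels()).matrices
        )
        tgt_aligned = target.with_matrices(
            al.apply_transform(t_tgt, target.without_labels()).matrices
        )
    t_align = time.process_time() - t0
    pred, t_train, t_predict = _train_predict(
        classifier, src_aligned, tgt_aligned, cfg, seed
    )
    C = source.n_classes
    result = EvaluationResult(
        kappa=kappa(target.labels, pred, C),
        accuracy=accuracy_score(target.labels, pred, C),
        confusion=confusion_matrix(target.labels, pred, C),
        cpu_time={"align": t_align, "train": t_train, "predict": t_predict},
        config_hash=config_hash(
            {"method": method, "classifier": classifier, **cfg, "align": align_kwargs}
        ),
        seed=seed,
    )
    logger.info(
        "cross-session %s/%s seed=%d kappa=%.4f (align %.3fs train %.3fs predict %.3fs)",
        method, classifier, seed, result.kappa, t_align, t_train, t_predict,
    )
    return result


def run_cross_subject(
    datasets: dict[str, SPDDataset],
    method: str = "none",
    classifier: str = "mdrm",
    config: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full directed pairing: every subject is tested once against each
    other subject as the training domain.  Returns one row per directed
    pair plus per-test-subject mean/sd columns merged in."""
    if len(datasets) < 2:
        raise InvalidInputError("cross-subject evaluation needs at least 2 subjects")
    rows = []
    for test_name, test_ds in datasets.items():
        for train_name, train_ds in datasets.items():
            if train_name == test_name:
                continue
            res = run_cross_session(train_ds, test_ds, method, classifier, config, seed)
            rows.append(
                {
                    "test_subject": test_name,
                    "train_subject": train_name,
                    **res.to_row(),
                }
            )
    table = pd.DataFrame(rows)
    stats = (
        table.groupby("test_subject")["kappa"].agg(["mean", "std"]).fillna(0.0)
    )
    table = table.merge(
        stats.rename(columns={"mean": "kappa_mean", "std": "kappa_sd"}),
        on="test_subject",
    )
    return table


def run_repeated(experiment, n_runs: int = 10, base_seed: int = 0) -> dict:
    """Run ``experiment(seed)`` for seeds ``base_seed..base_seed+n_runs-1``.

    ``experiment`` returns either a float or an :class:`EvaluationResult`;
    reports mean and (population) standard deviation of the kappas.
    """
    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    kappas = []
    for seed in range(base_seed, base_seed + n_runs):
        out = experiment(seed)
        kappas.append(out.kappa if isinstance(out, EvaluationResult) else float(out))
    kappas = np.asarray(kappas)
    return {
        "mean": float(kappas.mean()),
        "sd": float(kappas.std()),
        "per_run": kappas.tolist(),
        "n_runs": n_runs,
        "base_seed": base_seed,
    }


def timing_comparison(
    source: SPDDataset,
    target: SPDDataset,
    methods: tuple[str, ...] = ("rpa_airm", "rpa_lem"),
    repeats: int = 10,
) -> dict:
    """Average process-CPU seconds to fit each alignment method, plus the
    pairwise ratio when exactly two methods are timed."""
    if repeats < 1:
        raise InvalidInputError("repeats must be >= 1")
    out: dict = {}
    for method in methods:
        times = []
        for _ in range(repeats):
            t0 = time.process_time()
            al.fit_alignment(source.without_labels(), target.without_labels(), method)
            times.append(time.process_time() - t0)
        out[method] = float(np.mean(times))
        logger.info("timing %s: %.4fs mean over %d repeats", method, out[method], repeats)
    if len(methods) == 2:
        a, b = methods
        out["ratio"] = out[a] / out[b] if out[b] > 0 else float("inf")
    return out
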