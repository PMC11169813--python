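"""Data containers: stacks of labeled SPD matrices and epoched EEG trials.

Matrices are carried as plain ``numpy`` arrays; the containers only add
light validation and convenience accessors so that the numerical modules
can stay function-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["SPDDataset", "EpochedEEG"]


def _validate_labels(labels: np.ndarray, n_items: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n_items,):
        raise InvalidInputError(
            f"labels have shape {labels.shape}, expected ({n_items},)"
        )
    present = np.unique(labels)
    expected = np.arange(1, present.max() + 1) if present.size else present
    if present.size == 0 or not np.array_equal(present, expected):
        raise InvalidInputError(
            f"labels must cover a contiguous index set 1..C, got {present}"
        )
    return labels


@dataclass
class SPDDataset:
    """An ordered stack of same-size SPD matrices with optional class labels.

    Parameters
    ----------
    matrices : ndarray of shape (N, n, n)
        The sample of SPD matrices.
    labels : ndarray of shape (N,), optional
        Integer class labels covering a contiguous set ``{1..C}``.
    domain_id : str
        Free-form tag identifying the session/subject the sample came from.
    """

    matrices: np.ndarray
    labels: np.ndarray | None = None
    domain_id: str = ""

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise InvalidInputError(
                f"matrices must have shape (N, n, n), got {self.matrices.shape}"
            )
        if len(self.matrices) == 0:
            raise InvalidInputError("dataset must contain at least one matrix")
        if self.labels is not None:
            self.labels = _validate_labels(self.labels, len(self.matrices))

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def dim(self) -> int:
        """Matrix dimension n."""
        return self.matrices.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise InvalidInputError("dataset has no labels")
        return int(self.labels.max())

    def class_indices(self, k: int) -> np.ndarray:
        if self.labels is None:
            raise InvalidInputError("dataset has no labels")
        return np.flatnonzero(self.labels == k)

    def subset(self, index) -> "SPDDataset":
        """Row-select; skips label-contiguity re-validation since a
        subset (e.g. one class) legitimately breaks it."""
        index = np.asarray(index)
        out = object.__new__(SPDDataset)
        out.matrices = self.matrices[index]
        out.labels = None if self.labels is None else self.labels[index]
        out.domain_id = self.domain_id
        if len(out.matrices) == 0:
            raise InvalidInputError("subset selects no items")
        return out

    def without_labels(self) -> "SPDDataset":
        return SPDDataset(self.matrices, None, self.domain_id)

    def with_matrices(self, matrices: np.ndarray) -> "SPDDataset":
        """Same labels/domain, new matrix stack (order preserved)."""
        return SPDDataset(np.asarray(matrices, dtype=float), self.labels, self.domain_id)

    # -- serialization ----------------------------------------------------

    def save_npz(self, path: str | Path) -> None:
        payload = {"matrices": self.matrices, "domain_id": np.asarray(self.domain_id)}
        if self.labels is not None:
            payload["labels"] = self.labels
        np.savez(path, **payload)

    @classmethod
    def load_npz(cls, path: str | Path) -> "SPDDataset":
        with np.load(path, allow_pickle=False) as f:
            labels = f["labels"] if "labels" in f else None
            domain = str(f["domain_id"]) if "domain_id" in f else ""
            return cls(f["matrices"], labels, domain)


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: trials x channels x samples.

    ``tmin`` is the start of the epoch window relative to the cue, in
    seconds; ``tmax`` is derived from the sample count.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    tmin: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"data must have shape (trials, channels, samples), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("data contains non-finite values")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.labels is not None:
            self.labels = _validate_labels(self.labels, self.data.shape[0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        return self.tmin + self.n_samples / self.fs

    def with_data(self, data: np.ndarray, tmin: float | None = None) -> "EpochedEEG":
        return EpochedEEG(
            data, self.fs, self.labels, self.tmin if tmin is None else tmin
        )

    def save_npz(self, path: str | Path) -> None:
        payload = {
            "data": self.data,
            "fs": np.asarray(self.fs),
            "tmin": np.asarray(self.tmin),
        }
        if self.labels is not None:
            payload["labels"] = self.labels
        np.savez(path, **payload)

    @classmethod
    def load_npz(cls, path: str | Path) -> "EpochedEEG":
        with np.load(path, allow_pickle=False) as f:
            labels = f["labels"] if "labels" in f else None
            return cls(f["data"], float(f["fs"]), labels, float(f["tmin"]))
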