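"""Epoched EEG -> SPD covariance representation.

The pipeline is: extract the analysis window, zero-phase bandpass filter,
then per-trial sample covariance ``X = E E^T / (l - 1)`` with no channel
mean subtraction (the bandpass removes DC; a flag restores subtraction
for unfiltered inputs).
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from . import geometry as geo
from .data import EpochedEEG, SPDDataset
from .exceptions import InvalidInputError, SingularMatrixError

__all__ = ["bandpass_filter", "extract_window", "trial_covariance"]


def bandpass_filter(
    epochs: EpochedEEG,
    low: float = 10.0,
    high: float = 30.0,
    order: int = 5,
    zero_phase: bool = True,
) -> EpochedEEG:
    """Butterworth bandpass per channel.

    Zero-phase (forward-backward) by default, with reflective padding of
    roughly one filter length at the epoch edges; ``zero_phase=False``
    gives the causal single-pass variant.  The design order is the
    per-pass order.
    """
    nyq = epochs.fs / 2.0
    if not (0 < low < high < nyq):
        raise InvalidInputError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    if zero_phase:
        padlen = min(6 * (order + 1), epochs.n_samples - 1)
        out = scipy.signal.sosfiltfilt(
            sos, epochs.data, axis=-1, padtype="even", padlen=padlen
        )
    else:
        out = scipy.signal.sosfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(out)


def extract_window(epochs: EpochedEEG, start: float, end: float) -> EpochedEEG:
    """Cut the sub-window ``[start, end)`` seconds (cue-relative, same
    reference as ``tmin``); yields ``round((end - start) * fs)`` samples."""
    if end <= start:
        raise InvalidInputError("window end must exceed its start")
    if start < epochs.tmin - 1e-9 or end > epochs.tmax + 1e-9:
        raise InvalidInputError(
            f"window [{start}, {end}] s outside recorded epoch "
            f"[{epochs.tmin}, {epochs.tmax}] s"
        )
    i0 = int(round((start - epochs.tmin) * epochs.fs))
    length = int(round((end - start) * epochs.fs))
    if i0 + length > epochs.n_samples:
        raise InvalidInputError("window extends past the end of the epoch")
    return epochs.with_data(epochs.data[:, :, i0 : i0 + length], tmin=start)


def trial_covariance(
    epochs: EpochedEEG,
    regularize: bool = False,
    epsilon: float | None = None,
    subtract_mean: bool = False,
) -> SPDDataset:
    """Per-trial sample covariance ``E E^T / (l - 1)``.

    ``subtract_mean`` removes the per-channel mean first (for inputs that
    were not bandpass filtered).  With ``regularize`` a ridge
    ``epsilon * I`` is added (default ``1e-10 * trace / n`` per trial);
    otherwise any trial failing the positive-definiteness check raises,
    naming the trial.
    """
    l = epochs.n_samples
    if l < 2:
        raise InvalidInputError("need at least 2 samples per trial")
    mats = []
    for i, E in enumerate(epochs.data):
        if subtract_mean:
            E = E - E.mean(axis=1, keepdims=True)
        X = geo.symmetrize(E @ E.T / (l - 1))
        if regularize:
            X = geo.regularize(X, epsilon)
        try:
            geo._spd_eigh(X, f"trial {i} covariance")
        except SingularMatrixError as err:
            raise SingularMatrixError(
                f"trial {i}: covariance is singular ({err}); "
                "pass regularize=True to ridge-load"
            ) from err
        mats.append(X)
    return SPDDataset(np.stack(mats), epochs.labels)
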