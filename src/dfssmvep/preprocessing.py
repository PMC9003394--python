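"""EEG trial container and pre-processing (band-pass filtering, epoching)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["EEGTrial", "bandpass_filter", "epoch_window"]


@dataclass
class EEGTrial:
    """One multi-channel EEG trial.

    Attributes
    ----------
    data : numpy.ndarray
        channels x samples matrix, microvolt scale.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
    onset : float
        Start time of this trial/epoch relative to its parent recording, s.
    true_target : int or None
        Ground-truth target index (0-based) when known.
    subject, session, run : identifiers, optional.
    """

    data: np.ndarray = field(repr=False)
    fs: float
    channel_labels: tuple
    onset: float = 0.0
    true_target: int | None = None
    subject: int | str | None = None
    session: int | str | None = None
    run: int | str | None = None

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if data.shape[1] < 1:
            raise ValueError("trial must contain at least one sample")
        if not np.all(np.isfinite(data)):
            raise ValueError("trial data must be finite")
        labels = tuple(str(c) for c in self.channel_labels)
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{data.shape[0]} channels but {len(labels)} channel labels"
            )
        self.data = data
        self.channel_labels = labels

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def replace(self, **changes) -> "EEGTrial":
        return dataclasses.replace(self, **changes)


def _design_bandpass(low: float, high: float, fs: float, order: int,
                     ripple_db: float) -> np.ndarray:
    return signal.cheby1(order, ripple_db, [low, high], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(trial: EEGTrial, low: float = 2.0, high: float = 40.0,
                    order: int = 4, ripple_db: float = 0.5) -> EEGTrial:
    """Zero-phase Chebyshev type-I band-pass, applied per channel.

    The filter is run forward and backward (``sosfiltfilt``) so the net
    phase response is zero and passband components keep their timing; the
    magnitude response is applied twice, so the effective passband ripple
    is ``2*ripple_db`` and stopband attenuation doubles.  Defaults pass
    2-40 Hz, covering SSmVEP fundamentals up to ~10 Hz plus their first
    harmonics and the sum frequency while rejecting drift and line noise.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= trial.fs / 2:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency "
            f"{trial.fs / 2} Hz"
        )
    sos = _design_bandpass(low, high, trial.fs, order, ripple_db)
    # sosfiltfilt's default edge padding; trials must comfortably exceed it
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if trial.n_samples <= 3 * padlen:
        raise ValueError(
            f"trial of {trial.n_samples} samples is too short for zero-phase "
            f"filtering (needs > {3 * padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, trial.data, axis=1)
    return trial.replace(data=filtered)


def epoch_window(trial: EEGTrial, start: float, length: float) -> EEGTrial:
    """Extract the contiguous sub-trial [start, start+length) in seconds.

    Sample counts round down (half-open window, 0-based indexing); all
    metadata is preserved and ``onset`` advances by ``start``.
    """
    if start < 0 or length <= 0:
        raise ValueError("start must be >= 0 and length > 0")
    i0 = int(np.floor(start * trial.fs))
    n = int(np.floor(length * trial.fs))
    if i0 + n > trial.n_samples:
        raise ValueError(
            f"window [{start}, {start + length}) s exceeds the "
            f"{trial.duration:.3f} s trial"
        )
    return trial.replace(data=trial.data[:, i0:i0 + n],
                         onset=trial.onset + start)
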