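"""Frequency recognition by canonical correlation.

Standard CCA decoding scores a trial against stacked sin/cos harmonic
references at each candidate stimulation frequency and picks the argmax of
the first canonical correlation.  The bifold variant (BCCA) exploits the
dual-frequency design: each target owns a *triplet* of reference sets —
one per pair frequency plus a combined set that also carries the sum
frequency f1+f2 — and the target score is the average rho_a of the three
first canonical correlations.  Averaging protects against trials where only
one of the two evoked peaks is prominent, the failure mode of
single-frequency CCA on dual-frequency stimuli.

Welch power-spectral-density helpers are included for harmonic inspection
(choosing the harmonic count Nh empirically, verifying evoked peaks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .preprocessing import EEGTrial
from .stimulus import FREQ_TOL, FrequencyPlan

__all__ = [
    "ReferenceSet",
    "BCCAFeature",
    "DecodingResult",
    "PSDEstimate",
    "harmonic_references",
    "first_canonical_correlation",
    "cca_classify",
    "bcca_reference_triplet",
    "bcca_classify",
    "decode_trials",
    "welch_psd",
    "select_harmonics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSet:
    """Stacked sin/cos reference rows for CCA.

    ``rows`` is (2*Nh*|frequencies| [+2 for a combined set]) x m; rows come
    in cos/sin pairs evaluated at t = 1/fs ... m/fs.  ``row_frequencies``
    records the frequency of each row (used for de-duplication in combined
    sets).  ``kind`` is "single" for one stimulation frequency or
    "combined" for a bifold y_c set.
    """

    frequencies: tuple
    rows: np.ndarray = field(repr=False)
    row_frequencies: tuple
    fs: float
    nh: int
    kind: str = "single"

    @property
    def m(self) -> int:
        return self.rows.shape[1]


def _sin_cos_rows(freqs, fs: float, m: int):
    """cos/sin row pairs at each frequency, t = 1/fs ... m/fs."""
    t = np.arange(1, m + 1) / fs
    rows, row_freqs = [], []
    for f in freqs:
        w = 2 * np.pi * f * t
        rows.append(np.cos(w))
        rows.append(np.sin(w))
        row_freqs += [f, f]
    return np.vstack(rows), row_freqs


def harmonic_references(f: float, nh: int, fs: float, m: int) -> ReferenceSet:
    """Sin/cos references at f, 2f, ..., Nh*f (2*Nh rows of m samples)."""
    if f <= 0 or nh < 1:
        raise ValueError("need f > 0 and Nh >= 1")
    if f * nh >= fs / 2:
        raise ValueError(
            f"harmonic {nh}*{f} = {nh * f} Hz aliases at fs = {fs} Hz "
            f"(Nyquist {fs / 2} Hz)"
        )
    if m < 2 * nh:
        raise ValueError("need m >= 2*Nh samples")
    freqs = [h * f for h in range(1, nh + 1)]
    rows, row_freqs = _sin_cos_rows(freqs, fs, m)
    return ReferenceSet(frequencies=(f,), rows=rows, row_frequencies=tuple(row_freqs),
                        fs=fs, nh=nh, kind="single")


def first_canonical_correlation(X, Y, ridge: float = 1e-10):
    """Largest canonical correlation between row spaces of X and Y.

    Solves the CCA eigenproblem through Cholesky whitening of the (ridge-
    regularised) auto-covariances followed by an SVD of the whitened
    cross-covariance; the leading singular value is the first canonical
    correlation.  A ridge of ``ridge * trace/dim`` on each auto-covariance
    keeps short or rank-deficient windows (duplicated rows, constant
    channels) well-posed instead of crashing; it is kept tiny (1e-10
    relative) because any ridge perturbs rho by its own order and would
    otherwise erode the invariance of rho under channel mixing.

    Returns ``(rho, w_x, w_y)`` with rho clipped to [0, 1] and weight
    vectors such that corr(w_x @ X, w_y @ Y) = rho.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    m = X.shape[1]
    if m <= X.shape[0] + Y.shape[0]:
        raise ValueError(
            f"need more samples ({m}) than total rows "
            f"({X.shape[0]} + {Y.shape[0]})"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("inputs must be finite")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / (m - 1)
    Cyy = Yc @ Yc.T / (m - 1)
    Cxy = Xc @ Yc.T / (m - 1)

    def _regularise(C):
        d = C.shape[0]
        tr = np.trace(C)
        eps = ridge * tr / d if tr > 0 else ridge
        return C + eps * np.eye(d)

    Lx = linalg.cholesky(_regularise(Cxx), lower=True)
    Ly = linalg.cholesky(_regularise(Cyy), lower=True)
    K = linalg.solve_triangular(Lx, Cxy, lower=True)
    K = linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = linalg.svd(K, full_matrices=False)
    rho = float(np.clip(s[0], 0.0, 1.0))
    w_x = linalg.solve_triangular(Lx.T, U[:, 0], lower=False)
    w_y = linalg.solve_triangular(Ly.T, Vt[0], lower=False)
    return rho, w_x, w_y


@dataclass(frozen=True)
class BCCAFeature:
    """Per-target bifold feature vector v = (rho1, rho2, rhoc)."""

    rho1: float
    rho2: float
    rhoc: float

    @property
    def rho_a(self) -> float:
        return (self.rho1 + self.rho2 + self.rhoc) / 3.0


@dataclass(frozen=True)
class DecodingResult:
    """Scores per target and the argmax prediction (0-based).

    ``scores[i]`` is rho for plain CCA or rho_a for BCCA; ``features`` holds
    the full bifold triplets when BCCA produced the result.
    """

    scores: np.ndarray
    predicted: int
    method: str
    features: tuple | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", scores)


def _argmax_lowest(scores: np.ndarray) -> int:
    best = int(np.argmax(scores))
    ties = np.flatnonzero(scores == scores[best])
    if ties.size > 1:
        logger.info("score tie between targets %s; picking lowest index", ties.tolist())
    return best


def cca_classify(trial: EEGTrial, target_frequencies, nh: int = 2) -> DecodingResult:
    """Standard CCA recognition: argmax of rho over candidate frequencies."""
    freqs = list(target_frequencies)
    if not freqs:
        raise ValueError("need at least one candidate frequency")
    scores = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        refs = harmonic_references(f, nh, trial.fs, trial.n_samples)
        scores[i], _, _ = first_canonical_correlation(trial.data, refs.rows)
    return DecodingResult(scores=scores, predicted=_argmax_lowest(scores), method="cca")


def bcca_reference_triplet(pair, nh: int, fs: float, m: int):
    """Reference triplet (y1, y2, yc) for one dual-frequency target.

    y1 and y2 are harmonic references at the pair frequencies; yc stacks
    both plus a cos/sin pair at the sum frequency f1+f2 (4*Nh+2 rows).
    Rows whose frequencies collide within 1e-9 Hz (degenerate pairs) are
    dropped from yc so it stays full rank.
    """
    f1, f2 = (float(pair[0]), float(pair[1]))
    if f1 + f2 >= fs / 2:
        raise ValueError(
            f"sum frequency {f1 + f2} Hz aliases at fs = {fs} Hz"
        )
    y1 = harmonic_references(f1, nh, fs, m)
    y2 = harmonic_references(f2, nh, fs, m)
    sum_rows, sum_freqs = _sin_cos_rows([f1 + f2], fs, m)
    rows = np.vstack([y1.rows, y2.rows, sum_rows])
    row_freqs = list(y1.row_frequencies) + list(y2.row_frequencies) + sum_freqs
    # de-duplicate colliding frequencies, keeping first occurrence of each
    # (cos, sin) pair
    keep, seen_cos, seen_sin = [], [], []
    for idx, rf in enumerate(row_freqs):
        seen = seen_cos if idx % 2 == 0 else seen_sin
        if any(abs(rf - s) <= FREQ_TOL for s in seen):
            continue
        seen.append(rf)
        keep.append(idx)
    yc = ReferenceSet(
        frequencies=(f1, f2, f1 + f2),
        rows=rows[keep],
        row_frequencies=tuple(row_freqs[i] for i in keep),
        fs=fs, nh=nh, kind="combined",
    )
    return y1, y2, yc


def bcca_classify(trial: EEGTrial, plan: FrequencyPlan, nh: int = 2) -> DecodingResult:
    """Bifold CCA recognition over a dual-frequency plan.

    For each target pair the trial is scored against y1, y2 and yc
    separately; the target score is rho_a = (rho1 + rho2 + rhoc)/3 and the
    prediction is the argmax over targets.
    """
    features = []
    scores = np.empty(plan.n_targets)
    for i, pair in enumerate(plan.pairs):
        y1, y2, yc = bcca_reference_triplet(pair, nh, trial.fs, trial.n_samples)
        rho1, _, _ = first_canonical_correlation(trial.data, y1.rows)
        rho2, _, _ = first_canonical_correlation(trial.data, y2.rows)
        rhoc, _, _ = first_canonical_correlation(trial.data, yc.rows)
        feat = BCCAFeature(rho1=rho1, rho2=rho2, rhoc=rhoc)
        features.append(feat)
        scores[i] = feat.rho_a
    return DecodingResult(scores=scores, predicted=_argmax_lowest(scores),
                          method="bcca", features=tuple(features))


def decode_trials(trials, plan: FrequencyPlan, method: str = "bcca",
                  nh: int = 2, frequencies=None):
    """Decode a sequence of trials; returns a list of DecodingResult.

    ``method`` is "bcca" or "cca".  For plain CCA the candidate frequency
    of target i defaults to the plan's secondary (rotation) frequency b_i;
    pass ``frequencies`` to score another per-target frequency set (e.g.
    the primaries).
    """
    if method not in ("cca", "bcca"):
        raise ValueError(f"unknown method {method!r}")
    results = []
    for trial in trials:
        if method == "bcca":
            results.append(bcca_classify(trial, plan, nh))
        else:
            freqs = plan.secondary_frequencies if frequencies is None else frequencies
            results.append(cca_classify(trial, freqs, nh))
    return results


@dataclass(frozen=True)
class PSDEstimate:
    """Welch PSD: averaged window-power-normalised periodogram."""

    frequencies: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    segment_length: int
    n_segments: int
    window: str
    p0: float

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def welch_psd(x, fs: float, segment_length: int | None = None,
              overlap: float = 0.5, window: str = "hamming") -> PSDEstimate:
    """Welch power spectral density of a single channel.

    Periodograms of ``M`` overlapping segments of length ``L`` are averaged
    after normalising by the window power P0 = mean(|w(n)|^2); the grid
    spacing is fs/L.  Defaults: Hamming window, L = fs samples (1 s
    segments), 50% overlap — the usual trade of variance against the
    resolution needed to separate frequencies ~0.5 Hz apart.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single channel")
    L = int(round(fs)) if segment_length is None else int(segment_length)
    if L > x.size:
        raise ValueError(f"segment length {L} exceeds signal length {x.size}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(L * overlap)
    freqs, power = signal.welch(x, fs=fs, window=window, nperseg=L,
                                noverlap=noverlap, detrend="constant",
                                scaling="density")
    win = signal.get_window(window, L)
    p0 = float(np.mean(win ** 2))
    n_segments = 1 + (x.size - L) // (L - noverlap) if L < x.size else 1
    return PSDEstimate(frequencies=freqs, power=power, segment_length=L,
                       n_segments=n_segments, window=window, p0=p0)


def select_harmonics(psd: PSDEstimate, f: float, max_nh: int,
                     floor_factor: float = 3.0) -> int:
    """Pick the harmonic count Nh from a Welch PSD.

    Returns the largest h <= max_nh such that every multiple j*f (j <= h)
    rises above the local noise floor — the median PSD within +/-5 Hz of
    the harmonic, excluding the peak bins — by ``floor_factor``.  Clamped
    to [1, max_nh]; multiples beyond the frequency grid are treated as
    absent.
    """
    if max_nh < 1:
        raise ValueError("max_nh must be >= 1")
    freqs, power = psd.frequencies, psd.power
    df = psd.df
    nh = 1
    for h in range(1, max_nh + 1):
        target = h * f
        if target > freqs[-1]:
            break
        near = np.abs(freqs - target) <= 1.5 * df
        neigh = (np.abs(freqs - target) <= 5.0) & ~near
        if not near.any() or not neigh.any():
            break
        peak = power[near].max()
        floor = np.median(power[neigh])
        if floor <= 0 or peak < floor_factor * floor:
            break
        nh = h
    return max(1, nh)
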