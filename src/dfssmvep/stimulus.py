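"""Dual-frequency stimulus coding for SSmVEP targets.

A motion stimulus rendered on a monitor with refresh rate ``Rr`` can only
reverse direction on frame boundaries, so a target frequency ``f`` is
realised as a binary frame sequence (+1 expansion / -1 contraction) sampled
from a square wave.  For an N-target dual-frequency paradigm, each target
carries two simultaneous motion frequencies: a *primary* frequency drawn
from the base set f_1 < ... < f_N and a *secondary* frequency drawn from the
midpoints g_i of consecutive base frequencies (plus one extra midpoint
g_N = f_N + M above the band).  The assignment is chosen so that no two
targets share more than one spectrally adjacent frequency, which keeps the
canonical-correlation scores of distinct targets separable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSequence",
    "FrequencyPlan",
    "AdjacencyAudit",
    "binary_stimulus_sequence",
    "max_target_frequency",
    "compute_midpoints",
    "assign_dual_frequencies",
    "adjacency_audit",
]

#: absolute tolerance (Hz) used when comparing plan frequencies
FREQ_TOL = 1e-9


@dataclass(frozen=True)
class StimulusSequence:
    """Binary frame sequence realising one motion frequency.

    Attributes
    ----------
    frequency : float
        Motion inversion frequency in Hz.
    refresh_rate : float
        Monitor refresh rate in frames/s.
    frames : numpy.ndarray
        Ordered array of +1/-1 frame values; index origin is frame 0.
    """

    frequency: float
    refresh_rate: float
    frames: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int8)
        if frames.ndim != 1 or frames.size < 1:
            raise ValueError("frames must be a non-empty 1-D array")
        if not np.all(np.isin(frames, (-1, 1))):
            raise ValueError("frame values must be +1 or -1")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.size


def binary_stimulus_sequence(f: float, rr: float, n_frames: int) -> StimulusSequence:
    """Sample the square wave square(2*pi*f*i/Rr) at frame indices i = 0..n-1.

    The square wave is +1 on the half-open phase interval [0, pi) of each
    cycle and -1 on [pi, 2*pi) — the convention of ``scipy.signal.square``
    with 50% duty — so when f divides Rr evenly each half-cycle spans
    exactly Rr/(2f) frames.  For f not dividing Rr the half-cycles come out
    asymmetric (unequal frame counts), which is how non-divisor frequencies
    are realised on a fixed refresh rate.
    """
    if f <= 0 or rr <= 0:
        raise ValueError("frequency and refresh rate must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if f > rr / 2:
        raise ValueError(
            f"frequency {f} Hz is not representable at refresh rate {rr} "
            f"(requires f <= Rr/2 = {rr / 2})"
        )
    i = np.arange(n_frames)
    # fractional position within the cycle; exact for the rational f/Rr
    # values a monitor can realise
    phase = np.mod(f * i / rr, 1.0)
    frames = np.where(phase < 0.5, 1, -1).astype(np.int8)
    return StimulusSequence(frequency=float(f), refresh_rate=float(rr), frames=frames)


def max_target_frequency(rr: float, k: int) -> float:
    """Highest representable motion frequency given >= k frames per half-cycle.

    A half-cycle renders one expansion or one contraction; below ``k``
    frames the motion stops being perceptually smooth, bounding usable
    frequencies by f <= Rr/k.
    """
    if rr <= 0:
        raise ValueError("refresh rate must be positive")
    if not float(k).is_integer() or k < 1:
        raise ValueError("k must be a positive integer")
    return rr / k


def _check_strictly_increasing(freqs: np.ndarray) -> None:
    if freqs.ndim != 1 or freqs.size < 2:
        raise ValueError("need at least two frequencies")
    if np.any(np.diff(freqs) <= FREQ_TOL):
        raise ValueError("frequencies must be strictly increasing (no duplicates)")


def compute_midpoints(base_frequencies) -> tuple[np.ndarray, float]:
    """Midpoints g_i of consecutive base frequencies and the margin M.

    g_i = (f_i + f_{i+1})/2 for i < N and g_N = f_N + M, where
    M = min_i (f_{i+1} - f_i)/2 is half the smallest gap.  Returns
    ``(g, M)`` with ``g`` the same length as the input.
    """
    f = np.asarray(base_frequencies, dtype=float)
    _check_strictly_increasing(f)
    margin = float(np.min(np.diff(f)) / 2.0)
    g = np.empty_like(f)
    g[:-1] = (f[:-1] + f[1:]) / 2.0
    g[-1] = f[-1] + margin
    return g, margin


@dataclass(frozen=True)
class FrequencyPlan:
    """Dual-frequency assignment for N targets.

    ``pairs[i] = (a_i, b_i)`` gives the primary (radial-zoom) frequency a_i
    and secondary (rotation) frequency b_i of target i.  The a-values are a
    permutation of the base frequencies and the b-values a permutation of
    the midpoints.
    """

    base_frequencies: tuple
    midpoints: tuple
    margin: float
    pairs: tuple
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        f = np.asarray(self.base_frequencies, dtype=float)
        g = np.asarray(self.midpoints, dtype=float)
        _check_strictly_increasing(f)
        if g.shape != f.shape:
            raise ValueError("midpoints must match base frequencies in length")
        if f[0] < self.fmin - FREQ_TOL or f[-1] > self.fmax + FREQ_TOL:
            raise ValueError("base frequencies outside [fmin, fmax]")
        g_expect, m_expect = compute_midpoints(f)
        if not np.allclose(g, g_expect, atol=FREQ_TOL) or abs(self.margin - m_expect) > FREQ_TOL:
            raise ValueError("midpoints/margin inconsistent with base frequencies")
        pairs = tuple((float(a), float(b)) for a, b in self.pairs)
        if len(pairs) != f.size:
            raise ValueError("one pair required per target")
        a_vals = sorted(p[0] for p in pairs)
        b_vals = sorted(p[1] for p in pairs)
        if not np.allclose(a_vals, f, atol=FREQ_TOL):
            raise ValueError("pair a-values must be a permutation of base frequencies")
        if not np.allclose(b_vals, np.sort(g), atol=FREQ_TOL):
            raise ValueError("pair b-values must be a permutation of midpoints")
        all_freqs = np.sort(np.concatenate([f, g]))
        if np.any(np.diff(all_freqs) <= FREQ_TOL):
            raise ValueError("plan frequencies are not pairwise distinct")
        object.__setattr__(self, "base_frequencies", tuple(float(x) for x in f))
        object.__setattr__(self, "midpoints", tuple(float(x) for x in g))
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_targets(self) -> int:
        return len(self.pairs)

    @property
    def primary_frequencies(self) -> tuple:
        return tuple(p[0] for p in self.pairs)

    @property
    def secondary_frequencies(self) -> tuple:
        return tuple(p[1] for p in self.pairs)

    def to_dict(self) -> dict:
        return {
            "base_frequencies": list(self.base_frequencies),
            "midpoints": list(self.midpoints),
            "margin": self.margin,
            "pairs": [list(p) for p in self.pairs],
            "fmin": self.fmin,
            "fmax": self.fmax,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyPlan":
        return cls(
            base_frequencies=tuple(d["base_frequencies"]),
            midpoints=tuple(d["midpoints"]),
            margin=float(d["margin"]),
            pairs=tuple(tuple(p) for p in d["pairs"]),
            fmin=float(d["fmin"]),
            fmax=float(d["fmax"]),
        )


def assign_dual_frequencies(base_frequencies, fmin: float | None = None,
                            fmax: float | None = None) -> FrequencyPlan:
    """Assign a (primary, secondary) frequency pair to each of N >= 5 targets.

    With midpoints g_i, the assignment is

        a = (f_1, f_3, f_4, ..., f_N, f_2)
        b = (g_{N-1}, g_1, g_2, ..., g_{N-2}, g_N)

    i.e. target 1 keeps the lowest base frequency but takes a high midpoint,
    the middle targets shift their base frequency up by one slot and take
    the midpoint two slots below, and the last target takes f_2 with the
    out-of-band midpoint g_N.  This staggering guarantees that any two
    targets share at most one adjacent frequency (see
    :func:`adjacency_audit`).
    """
    f = np.asarray(base_frequencies, dtype=float)
    _check_strictly_increasing(f)
    n = f.size
    if n < 5:
        raise ValueError(
            f"the dual-frequency coding algorithm requires N >= 5 targets, got N={n}"
        )
    g, margin = compute_midpoints(f)
    a = np.empty(n)
    b = np.empty(n)
    a[0], b[0] = f[0], g[n - 2]
    a[1:n - 1] = f[2:n]
    b[1:n - 1] = g[0:n - 2]
    a[n - 1], b[n - 1] = f[1], g[n - 1]
    return FrequencyPlan(
        base_frequencies=tuple(f),
        midpoints=tuple(g),
        margin=margin,
        pairs=tuple(zip(a, b)),
        fmin=float(f[0] if fmin is None else fmin),
        fmax=float(f[-1] if fmax is None else fmax),
    )


@dataclass(frozen=True)
class AdjacencyAudit:
    """Result of the shared-adjacency audit of a frequency plan."""

    passed: bool
    counts: dict
    offenders: tuple

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _freq_in(value: float, pool) -> bool:
    return any(abs(value - p) <= FREQ_TOL for p in pool)


def adjacency_audit(plan: FrequencyPlan) -> AdjacencyAudit:
    """Check that no two targets share more than one adjacent frequency.

    Each midpoint g_i (i < N) is adjacent to its flanking base frequencies
    f_i and f_{i+1}; the out-of-band midpoint g_N is adjacent to f_N only.
    For every unordered pair of targets the audit counts cross adjacencies
    between one target's two frequencies and the other's; the plan passes
    iff every count is <= 1.  Report-only: an offending plan is returned,
    not raised.
    """
    f = plan.base_frequencies
    g = plan.midpoints
    n = len(f)
    adjacency = [(f[i], g[i]) for i in range(n - 1)]
    adjacency += [(f[i + 1], g[i]) for i in range(n - 1)]
    adjacency.append((f[n - 1], g[n - 1]))

    def adjacent(x: float, y: float) -> bool:
        return any(
            (abs(x - u) <= FREQ_TOL and abs(y - v) <= FREQ_TOL)
            or (abs(x - v) <= FREQ_TOL and abs(y - u) <= FREQ_TOL)
            for u, v in adjacency
        )

    counts: dict = {}
    offenders = []
    for (i, pi), (j, pj) in itertools.combinations(enumerate(plan.pairs), 2):
        c = sum(adjacent(x, y) for x in pi for y in pj)
        counts[(i, j)] = c
        if c > 1:
            offenders.append((i, j))
    return AdjacencyAudit(passed=not offenders, counts=counts, offenders=tuple(offenders))
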