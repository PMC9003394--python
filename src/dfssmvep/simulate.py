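"""Synthetic SSmVEP-like EEG with ground truth.

The generator emulates the structure of a dual-frequency motion-BCI
recording session: for each attended target it synthesises an evoked
component — sinusoids at both pair frequencies and their harmonics with
geometrically decaying amplitudes and random per-trial phases — embedded in
realistic background EEG noise.  The noise model combines 1/f ("pink")
activity with a low-frequency spectral knee, a white sensor-noise fraction,
a 10 Hz occipital alpha rhythm, and spatial correlation across channels
(volume conduction), because spatially coherent background activity is what
limits how much a multi-channel decoder can gain by combining channels.
The evoked/noise power ratio is set in dB on the average channel.

Amplitude imbalance beta < 1 attenuates the secondary pair frequency,
mimicking trials where only one of the two evoked peaks is prominent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import EEGTrial
from .stimulus import FrequencyPlan

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_trial", "simulate_dataset"]

DEFAULT_CHANNELS = ("Po3", "Po4", "Po7", "Po8", "Pz", "Oz")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model parameters.

    Defaults mirror a 10-subject dual-frequency protocol: 6 parieto-
    occipital channels at 500 Hz, 3.5 s trials, evoked fundamentals plus a
    half-amplitude second harmonic.  ``snr_db`` is evoked power over total
    noise power on the average channel; ``amplitude_imbalance`` (beta)
    scales the secondary pair frequency relative to the primary.
    """

    fs: float = 500.0
    n_channels: int = 6
    channel_labels: tuple = DEFAULT_CHANNELS
    trial_length: float = 3.5
    nh_signal: int = 2
    harmonic_decay: float = 0.5
    amplitude_imbalance: float = 1.0
    snr_db: float = 0.0
    pink_exponent: float = 1.0
    pink_knee_hz: float = 1.0
    white_fraction: float = 0.2
    alpha_freq: float = 10.0
    alpha_amplitude: float = 0.5
    spatial_noise_corr: float = 0.6
    sum_frequency_amplitude: float = 0.0
    channel_gain_sigma: float = 0.2
    subject_snr_jitter_db: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")
        for name in ("harmonic_decay", "amplitude_imbalance", "alpha_amplitude",
                     "sum_frequency_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.white_fraction <= 1:
            raise ValueError("white_fraction must be in [0, 1]")
        if not 0 <= self.spatial_noise_corr <= 1:
            raise ValueError("spatial_noise_corr must be in [0, 1]")
        if self.fs <= 0 or self.trial_length <= 0 or self.nh_signal < 1:
            raise ValueError("fs, trial_length must be positive; nh_signal >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_length))


def _pink_noise(n: int, fs: float, exponent: float, knee_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, flat below the knee frequency."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(f, knee_hz) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _background_noise(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """channels x samples noise matrix with ~unit average channel power."""
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    def colored() -> np.ndarray:
        pink = _pink_noise(n, cfg.fs, cfg.pink_exponent, cfg.pink_knee_hz, rng)
        white = rng.standard_normal(n)
        return (np.sqrt(1 - cfg.white_fraction) * pink
                + np.sqrt(cfg.white_fraction) * white)

    c = cfg.spatial_noise_corr
    shared = colored()
    noise = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        noise[ch] = np.sqrt(c) * shared + np.sqrt(1 - c) * colored()
    if cfg.alpha_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        alpha = np.sin(2 * np.pi * cfg.alpha_freq * t + phase)
        amps = cfg.alpha_amplitude * rng.uniform(0.5, 1.5, size=cfg.n_channels)
        noise += amps[:, None] * alpha[None, :]
    power = np.mean(noise ** 2)
    return noise / np.sqrt(power)


def _evoked_component(cfg: SimulationConfig, pair, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale harmonic evoked waveform for one dual-frequency target."""
    f1, f2 = float(pair[0]), float(pair[1])
    nyquist = cfg.fs / 2.0
    if cfg.nh_signal * max(f1, f2) >= nyquist:
        raise ValueError(
            f"evoked harmonic {cfg.nh_signal * max(f1, f2)} Hz aliases at "
            f"fs = {cfg.fs} Hz"
        )
    if cfg.sum_frequency_amplitude > 0 and f1 + f2 >= nyquist:
        raise ValueError("sum frequency aliases at this sampling rate")
    t = np.arange(cfg.n_samples) / cfg.fs
    evoked = np.zeros(cfg.n_samples)
    for base_amp, f in ((1.0, f1), (cfg.amplitude_imbalance, f2)):
        for h in range(1, cfg.nh_signal + 1):
            amp = base_amp * cfg.harmonic_decay ** (h - 1)
            evoked += amp * np.sin(2 * np.pi * h * f * t + rng.uniform(0, 2 * np.pi))
    if cfg.sum_frequency_amplitude > 0:
        evoked += cfg.sum_frequency_amplitude * np.sin(
            2 * np.pi * (f1 + f2) * t + rng.uniform(0, 2 * np.pi))
    return evoked


def simulate_trial(config: SimulationConfig, pair, rng: np.random.Generator,
                   channel_gains=None, snr_db: float | None = None,
                   true_target: int | None = None, subject=None,
                   session=None, run=None) -> EEGTrial:
    """Synthesise one trial attending the given (f1, f2) pair.

    ``rng`` drives every random draw, so a generator seeded identically
    reproduces the trial bit for bit.  ``channel_gains`` (default all 1)
    scale the evoked component per channel; ``snr_db`` overrides the
    config value (``-inf`` yields pure noise).
    """
    evoked = _evoked_component(config, pair, rng)
    noise = _background_noise(config, rng)
    gains = (np.ones(config.n_channels) if channel_gains is None
             else np.asarray(channel_gains, dtype=float))
    if gains.shape != (config.n_channels,):
        raise ValueError("channel_gains must have one entry per channel")
    level = config.snr_db if snr_db is None else snr_db
    if np.isneginf(level):
        scale = 0.0
    else:
        target_power = 10.0 ** (level / 10.0)  # noise power is ~1
        evoked_power = np.mean(evoked ** 2) * np.mean(gains ** 2)
        scale = np.sqrt(target_power / evoked_power)
    data = gains[:, None] * (scale * evoked)[None, :] + noise
    return EEGTrial(data=data, fs=config.fs, channel_labels=config.channel_labels,
                    true_target=true_target, subject=subject, session=session,
                    run=run)


@dataclass(frozen=True)
class SimulatedDataset:
    """Ground-truthed trial collection plus its generating plan/config."""

    trials: tuple
    plan: FrequencyPlan
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.trials)

    def manifest_records(self) -> list:
        return [
            {
                "subject": t.subject, "session": t.session, "run": t.run,
                "target": t.true_target,
                "pair": list(self.plan.pairs[t.true_target]),
                "fs": t.fs, "duration": t.duration,
            }
            for t in self.trials
        ]


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one independent generator per trial."""
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def simulate_dataset(config: SimulationConfig, plan: FrequencyPlan,
                     n_subjects: int = 10, n_sessions: int = 2,
                     n_trials_per_target: int = 4) -> SimulatedDataset:
    """Full protocol: subjects x sessions x targets x trials.

    Per subject, channel gains are drawn once (lognormal, sigma =
    ``channel_gain_sigma``) and the SNR is jittered by a normal offset
    (``subject_snr_jitter_db``); every trial then gets its own counter-
    derived random substream, so any single trial is reproducible without
    generating the rest.  Defaults give 10 x 2 x N x 4 trials (400 for a
    5-target plan).
    """
    if min(n_subjects, n_sessions, n_trials_per_target) < 1:
        raise ValueError("dataset dimensions must be >= 1")
    trials = []
    for subj in range(n_subjects):
        srng = _trial_rng(config.seed, 1, subj)
        gains = np.exp(srng.normal(0.0, config.channel_gain_sigma,
                                   config.n_channels))
        snr = config.snr_db + (srng.normal(0.0, config.subject_snr_jitter_db)
                               if np.isfinite(config.snr_db) else 0.0)
        for sess in range(n_sessions):
            for target in range(plan.n_targets):
                for k in range(n_trials_per_target):
                    rng = _trial_rng(config.seed, 2, subj, sess, target, k)
                    trials.append(simulate_trial(
                        config, plan.pairs[target], rng, channel_gains=gains,
                        snr_db=snr, true_target=target, subject=subj,
                        session=sess, run=k))
    return SimulatedDataset(trials=tuple(trials), plan=plan, config=config)
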