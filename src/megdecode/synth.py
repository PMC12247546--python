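"""Synthetic MEG session generator.

Emulates the statistical structure of a same-hand movement decoding session:
~204 planar-gradiometer-like channels sampled at 500 Hz, 2-s epochs centered
on task onset, five balanced classes (four movements + rest, 60 trials each),
class-specific narrowband oscillatory sources in the alpha (8-12 Hz) or beta
(13-30 Hz) range whose power is suppressed from ~200 ms before onset
(event-related desynchronization), a 1/f background plus white sensor noise,
a shared non-informative evoked component, and two accelerometer channels
carrying movement bursts (movement sessions) or baseline noise only
(imagery/control sessions).

Every quantity is deterministic given the config seed, and the generator
returns its own ground truth (mixing matrix, per-trial source traces, true
onsets) so downstream recovery can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochSet

__all__ = [
    "SessionConfig",
    "SimulatedSession",
    "sensor_layout",
    "make_mixing_matrix",
    "simulate_epochs",
    "simulate_accelerometer",
    "simulate_null_session",
]

#: default per-class (center Hz, bandwidth Hz); None = rest, no class source
DEFAULT_BANDS: tuple = (None, (9.0, 2.0), (11.0, 2.0), (19.0, 6.0), (25.0, 6.0))


@dataclass(frozen=True)
class SessionConfig:
    """Generative parameters of one synthetic session.

    ``erd_depth`` is the fractional *power* suppression of the class source
    after ``erd_onset`` (0 = no modulation, 1 = complete suppression); the
    amplitude envelope drops by ``sqrt(1 - erd_depth)`` accordingly.
    ``snr`` is the ratio of class-signal variance at the class's focal sensor
    to the per-channel noise variance.
    """

    n_channels: int = 204
    sfreq: float = 500.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    n_classes: int = 5
    trials_per_class: int = 60
    class_source_bands: tuple = DEFAULT_BANDS
    erd_depth: float = 0.5
    erd_onset: float = -0.2
    erd_transition: float = 0.1
    topography_smoothness: float = 2.0
    snr: float = 5.0
    noise_exponent: float = 1.0
    onef_fraction: float = 0.5
    evoked_amplitude: float = 1.0
    accel_mode: str = "movement"
    accel_noise: float = 1.0
    accel_burst_amplitude: float = 20.0
    onset_latency_mean: float = 0.0213
    onset_latency_sd: float = 0.1761
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if len(self.class_source_bands) != self.n_classes:
            raise ValueError("class_source_bands needs one entry per class")
        if self.accel_mode not in ("movement", "imagery", "control"):
            raise ValueError(f"unknown accel_mode {self.accel_mode!r}")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")
        n_samp = (self.epoch_window[1] - self.epoch_window[0]) * self.sfreq
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("sfreq x window length must be an integer sample count")
        n_sources = sum(b is not None for b in self.class_source_bands)
        if n_sources > self.n_channels:
            raise ValueError("more class sources than channels")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq))

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) / self.sfreq


@dataclass
class SimulatedSession:
    """Generated session plus ground truth for recovery tests."""

    epochs: EpochSet
    mixing: np.ndarray               # channels x n_classes, unit-norm columns
    source_traces: np.ndarray        # trials x n_classes x samples (active row only)
    accel: np.ndarray                # trials x 2 x samples
    true_onsets: np.ndarray | None   # per-trial sample index, movement mode only
    config: SessionConfig

    def focal_channel(self, klass: int) -> int:
        """Channel with the largest absolute sensor gain for class ``klass``."""
        return int(np.argmax(np.abs(self.mixing[:, klass])))

    def save(self, epochs_path: str, truth_path: str | None = None) -> None:
        """Write epochs to HDF5 and ground truth to a sibling NPZ."""
        self.epochs.to_hdf5(epochs_path)
        if truth_path is not None:
            np.savez(
                truth_path,
                mixing=self.mixing,
                source_traces=self.source_traces.astype(np.float32),
                accel=self.accel.astype(np.float32),
                true_onsets=(
                    np.array([]) if self.true_onsets is None else self.true_onsets
                ),
            )


def sensor_layout(n_channels: int) -> np.ndarray:
    """Fixed 2-D grid of sensor positions (units: grid spacing).

    A near-square row-major grid standing in for the planar-gradiometer
    array; adjacent channels are distance 1 apart.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    n_cols = int(math.ceil(math.sqrt(n_channels)))
    idx = np.arange(n_channels)
    return np.column_stack([idx % n_cols, idx // n_cols]).astype(float)


def make_mixing_matrix(
    n_channels: int, n_sources: int, smoothness: float, seed: int
) -> np.ndarray:
    """Spatially smooth unit-norm source topographies over the sensor grid.

    Each column is a squared-exponential-smoothed white-noise field sampled
    on the fixed 2-D layout (a Gaussian-process-like profile), normalized to
    unit Euclidean norm. ``smoothness`` is the correlation length in
    channel-grid units; larger values give flatter topographies.
    """
    if n_channels < 1 or n_sources < 1:
        raise ValueError("dimensions must be positive")
    if n_sources > n_channels:
        raise ValueError("n_sources must not exceed n_channels")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    pos = sensor_layout(n_channels)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-0.5 * d2 / smoothness**2)
    cols = kernel @ rng.standard_normal((n_channels, n_sources))
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    return cols


def _one_over_f(rng: np.random.Generator, shape: tuple, n_samples: int,
                sfreq: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _erd_envelope(cfg: SessionConfig) -> np.ndarray:
    """Amplitude envelope: 1 before erd_onset, sqrt(1-depth) after,
    raised-cosine transition of erd_transition seconds starting at erd_onset."""
    t = cfg.times
    lo = math.sqrt(1.0 - cfg.erd_depth)
    env = np.ones_like(t)
    t0, t1 = cfg.erd_onset, cfg.erd_onset + cfg.erd_transition
    ramp = (t >= t0) & (t < t1)
    phase = (t[ramp] - t0) / max(t1 - t0, 1e-12)
    env[ramp] = lo + (1.0 - lo) * 0.5 * (1.0 + np.cos(np.pi * phase))
    env[t >= t1] = lo
    return env


def _evoked_waveform(cfg: SessionConfig) -> np.ndarray:
    """Shared evoked-like transient: Gaussian-windowed 3 Hz burst after onset."""
    t = cfg.times
    return np.sin(2 * np.pi * 3.0 * (t - 0.15)) * np.exp(-0.5 * ((t - 0.15) / 0.1) ** 2)


def _draw_onsets(cfg: SessionConfig, rng: np.random.Generator,
                 n_trials: int) -> np.ndarray:
    """Per-trial movement-onset sample indices, Normal latency truncated
    to [window start, window end - 0.2 s] so bursts fit in-window."""
    lo, hi = cfg.epoch_window[0], cfg.epoch_window[1] - 0.2
    lat = rng.normal(cfg.onset_latency_mean, cfg.onset_latency_sd, size=n_trials)
    lat = np.clip(lat, lo, hi)
    return np.round((lat - cfg.epoch_window[0]) * cfg.sfreq).astype(int)


def simulate_accelerometer(
    config: SessionConfig,
    true_onsets: np.ndarray | None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-channel accelerometer traces for every trial.

    Movement mode injects a windowed high-amplitude burst starting at each
    trial's true onset on top of white baseline noise; imagery and control
    modes return baseline noise only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_trials = config.n_trials if true_onsets is None else len(true_onsets)
    n_samp = config.n_samples
    traces = config.accel_noise * rng.standard_normal((n_trials, 2, n_samp))
    if config.accel_mode != "movement":
        return traces
    if true_onsets is None:
        raise ValueError("movement mode requires true_onsets")
    # instant-attack burst (movement jerk) with a Hann decay, so the true
    # onset sample is recoverable to +-1 sample by threshold detection
    burst_len = int(round(0.3 * config.sfreq))
    tb = np.arange(burst_len) / config.sfreq
    shape = np.cos(2 * np.pi * 8.0 * tb) * np.hanning(2 * burst_len)[burst_len:]
    amp = config.accel_burst_amplitude * max(config.accel_noise, 1e-12)
    if config.accel_noise == 0:
        amp = config.accel_burst_amplitude
    for i, onset in enumerate(np.asarray(true_onsets, dtype=int)):
        stop = min(onset + burst_len, n_samp)
        seg = shape[: stop - onset]
        jitter = 1.0 + 0.1 * rng.standard_normal(2)
        traces[i, 0, onset:stop] += amp * jitter[0] * seg
        traces[i, 1, onset:stop] += amp * jitter[1] * seg
    return traces


def _balanced_labels(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    rng.shuffle(labels)
    return labels


def _base_noise_and_evoked(
    cfg: SessionConfig, rng: np.random.Generator, n_trials: int,
    noise_var: float,
) -> np.ndarray:
    """Background 1/f + white sensor noise + shared evoked, for all trials.

    Per-channel noise variance equals ``noise_var``: a fraction
    ``onef_fraction`` of it is temporally 1/f-colored, the rest white. The
    shared evoked component is identical in expectation for every class and
    therefore carries no label information.
    """
    n_ch, n_samp = cfg.n_channels, cfg.n_samples
    sd_1f = math.sqrt(cfg.onef_fraction * noise_var)
    sd_w = math.sqrt((1.0 - cfg.onef_fraction) * noise_var)
    data = sd_1f * _one_over_f(rng, (n_trials, n_ch), n_samp, cfg.sfreq,
                               cfg.noise_exponent)
    data += sd_w * rng.standard_normal((n_trials, n_ch, n_samp))
    if cfg.evoked_amplitude > 0:
        topo = make_mixing_matrix(n_ch, 1, cfg.topography_smoothness,
                                  cfg.seed + 7919)[:, 0]
        topo = topo / np.max(np.abs(topo))
        wave = _evoked_waveform(cfg)
        data += cfg.evoked_amplitude * math.sqrt(noise_var) * topo[None, :, None] \
            * wave[None, None, :]
    return data


def simulate_epochs(config: SessionConfig) -> SimulatedSession:
    """Generate one class-structured session.

    Each non-rest class k has a single narrowband source: a sinusoid at the
    class's center frequency with a fresh random phase per trial, whose
    amplitude envelope drops by sqrt(1 - erd_depth) from ``erd_onset`` on
    (event-related desynchronization), projected through column k of a smooth
    unit-norm mixing matrix. Rest trials carry background + shared evoked
    only. Noise is scaled so that class-signal variance at the focal sensor
    over the whole epoch is ``snr`` times the per-channel noise variance.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_trials, n_ch, n_samp = cfg.n_trials, cfg.n_channels, cfg.n_samples
    labels = _balanced_labels(cfg, rng)
    mixing = make_mixing_matrix(n_ch, cfg.n_classes, cfg.topography_smoothness,
                                cfg.seed + 101)

    env = _erd_envelope(cfg)
    t = cfg.times
    # class-signal variance at each class's focal sensor, whole-epoch
    sig_var = []
    for k, band in enumerate(cfg.class_source_bands):
        if band is None:
            continue
        focal = np.argmax(np.abs(mixing[:, k]))
        sig_var.append(mixing[focal, k] ** 2 * 0.5 * np.mean(env**2))
    mean_sig_var = float(np.mean(sig_var)) if sig_var else 1.0
    noise_var = 0.0 if np.isinf(cfg.snr) else mean_sig_var / cfg.snr

    source_traces = np.zeros((n_trials, cfg.n_classes, n_samp), dtype=np.float64)
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    for i in range(n_trials):
        band = cfg.class_source_bands[labels[i]]
        if band is None:
            continue
        f0 = band[0]
        source_traces[i, labels[i]] = np.sin(2 * np.pi * f0 * t + phases[i]) * env

    if noise_var > 0:
        data = _base_noise_and_evoked(cfg, rng, n_trials, noise_var)
    else:
        data = np.zeros((n_trials, n_ch, n_samp))
    data += np.einsum("cs,nst->nct", mixing, source_traces)

    if cfg.accel_mode == "movement":
        true_onsets = _draw_onsets(cfg, rng, n_trials)
    else:
        true_onsets = None
    accel = simulate_accelerometer(cfg, true_onsets, rng)

    epochs = EpochSet(
        data=data,
        labels=labels,
        sfreq=cfg.sfreq,
        window=cfg.epoch_window,
        class_names=["rest"] + [f"movement_{k}" for k in range(1, cfg.n_classes)],
        accel=accel,
    )
    return SimulatedSession(epochs=epochs, mixing=mixing,
                            source_traces=source_traces, accel=accel,
                            true_onsets=true_onsets, config=cfg)


def simulate_null_session(config: SessionConfig) -> SimulatedSession:
    """Session with no class-dependent structure whatsoever.

    Every trial, whatever its label, is background noise plus the same
    shared evoked-like component; labels are assigned independently of the
    data, so any decoder's accuracy is chance by construction. Setting
    ``evoked_amplitude=0`` yields pure noise epochs.
    """
    cfg = config if config.accel_mode != "movement" \
        else replace(config, accel_mode="control")
    rng = np.random.default_rng(cfg.seed)
    n_trials, n_ch, n_samp = cfg.n_trials, cfg.n_channels, cfg.n_samples
    labels = _balanced_labels(cfg, rng)
    mixing = make_mixing_matrix(n_ch, cfg.n_classes, cfg.topography_smoothness,
                                cfg.seed + 101)
    data = _base_noise_and_evoked(cfg, rng, n_trials, noise_var=1.0)
    accel = simulate_accelerometer(cfg, None, rng)
    epochs = EpochSet(
        data=data, labels=labels, sfreq=cfg.sfreq, window=cfg.epoch_window,
        class_names=["rest"] + [f"movement_{k}" for k in range(1, cfg.n_classes)],
        accel=accel,
    )
    return SimulatedSession(
        epochs=epochs, mixing=mixing,
        source_traces=np.zeros((n_trials, cfg.n_classes, n_samp), dtype=np.float32),
        accel=accel, true_onsets=None, config=cfg,
    )
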