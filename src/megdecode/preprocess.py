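"""Epoch extraction, standardization and movement-onset detection.

Mirrors the acquisition-side contract of the decoding pipeline: continuous
recordings are zero-phase band-pass filtered and decimated, epochs of fixed
window are cut around task onsets, each epoch is standardized by a single
pooled mean/SD over all of its channels and samples, and (for movement
sessions) the task onset is realigned to the first sample where the combined
accelerometer magnitude exceeds 10x the pre-stimulus SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "OnsetDetectionConfig",
    "DegenerateBaselineError",
    "DegenerateEpochError",
    "bandpass_downsample",
    "detect_movement_onset",
    "extract_epochs",
    "standardize_epoch",
    "standardize_epochs",
    "realign_to_movement_onset",
]

logger = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """Pre-stimulus accelerometer SD is zero — threshold undefined."""


class DegenerateEpochError(ValueError):
    """Epoch is constant — pooled SD is zero, cannot standardize."""


@dataclass(frozen=True)
class OnsetDetectionConfig:
    """Accelerometer onset-detection rule.

    The two accelerometer channels are combined by root-mean-square per
    sample; the onset is the first post-cue sample where that magnitude
    strictly exceeds ``threshold_factor`` times the SD of the combined
    magnitude over ``prestim_window`` (seconds relative to the cue).
    """

    prestim_window: tuple[float, float] = (-1.0, 0.0)
    threshold_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.prestim_window[0] >= self.prestim_window[1]:
            raise ValueError("prestim_window must be an increasing pair")
        if self.prestim_window[1] > 0:
            raise ValueError("prestim window must precede the cue")


def bandpass_downsample(
    continuous: np.ndarray,
    sfreq_in: float,
    band: tuple[float, float],
    sfreq_out: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass then integer-factor decimation.

    A Butterworth band-pass (forward-backward, so effectively order
    ``2*order`` and zero phase) is followed by anti-aliased decimation by the
    integer factor ``sfreq_in / sfreq_out``. Output length is
    ``floor(n_samples * sfreq_out / sfreq_in)``.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    lo, hi = band
    if hi >= sfreq_out / 2:
        raise ValueError("band upper edge must be below the output Nyquist")
    if sfreq_out > sfreq_in:
        raise ValueError("sfreq_out must not exceed sfreq_in")
    q = sfreq_in / sfreq_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError("sfreq_in / sfreq_out must be an integer factor")
    q = int(round(q))
    # cascade of separate high-pass and low-pass sections: a single
    # band-pass with a very low lower edge (e.g. 0.1 Hz at 1 kHz) puts
    # poles too close to the unit circle and is numerically unstable
    sos_lp = signal.butter(order, hi, btype="lowpass", fs=sfreq_in,
                           output="sos")
    filtered = signal.sosfiltfilt(sos_lp, continuous, axis=-1, padtype="even")
    if lo > 0:
        sos_hp = signal.butter(max(order // 2, 1), lo, btype="highpass",
                               fs=sfreq_in, output="sos")
        filtered = signal.sosfiltfilt(sos_hp, filtered, axis=-1,
                                      padtype="even")
    if q > 1:
        filtered = signal.decimate(filtered, q, ftype="iir", zero_phase=True,
                                   axis=-1)
    n_out = int(continuous.shape[-1] * sfreq_out // sfreq_in)
    return filtered[..., :n_out]


def _combined_magnitude(accel: np.ndarray) -> np.ndarray:
    """Per-sample RMS magnitude across the accelerometer channels."""
    accel = np.atleast_2d(accel)
    return np.sqrt(np.mean(accel**2, axis=0))


def detect_movement_onset(
    accel: np.ndarray,
    cue_sample: int,
    cfg: OnsetDetectionConfig,
    sfreq: float,
) -> int | None:
    """First post-cue sample where combined acceleration exceeds threshold.

    Returns the first sample index at/after ``cue_sample`` where the RMS
    magnitude across the two accelerometer channels strictly exceeds
    ``threshold_factor`` x SD (population) of that magnitude over the
    pre-stimulus window, or ``None`` if the threshold is never exceeded.
    """
    mag = _combined_magnitude(accel)
    i0 = cue_sample + int(round(cfg.prestim_window[0] * sfreq))
    i1 = cue_sample + int(round(cfg.prestim_window[1] * sfreq))
    if i0 < 0 or i1 > mag.size or i0 >= i1:
        raise ValueError("pre-stimulus window not fully inside the trace")
    sd = float(np.std(mag[i0:i1]))  # population (1/N) convention
    if sd == 0.0:
        raise DegenerateBaselineError(
            "zero pre-stimulus SD: baseline has no noise floor"
        )
    above = mag[cue_sample:] > cfg.threshold_factor * sd  # strictly greater
    hits = np.flatnonzero(above)
    return None if hits.size == 0 else int(cue_sample + hits[0])


def extract_epochs(
    continuous: np.ndarray,
    events: list[tuple[int, int]],
    window: tuple[float, float],
    sfreq: float,
    class_names: list[str] | None = None,
) -> EpochSet:
    """Cut fixed-window epochs around per-trial onset samples.

    ``events`` is a list of ``(onset_sample, label)``. Epoch slices are
    half-open ``[onset + window0*sfreq, onset + window1*sfreq)``. Trials
    whose window does not fit inside the recording are dropped with a logged
    warning; the drop count is recorded on the returned set as
    ``n_dropped``.
    """
    if len(events) == 0:
        raise ValueError("empty event list")
    continuous = np.atleast_2d(continuous)
    n_total = continuous.shape[-1]
    off0 = int(round(window[0] * sfreq))
    off1 = int(round(window[1] * sfreq))
    epochs, labels, dropped = [], [], 0
    for onset, label in events:
        a, b = onset + off0, onset + off1
        if a < 0 or b > n_total:
            dropped += 1
            continue
        epochs.append(continuous[:, a:b])
        labels.append(label)
    if dropped:
        logger.warning("extract_epochs: dropped %d/%d trials whose window "
                       "exceeded the recording", dropped, len(events))
    if not epochs:
        raise ValueError("all events fell outside the recording")
    out = EpochSet(
        data=np.stack(epochs),
        labels=np.asarray(labels),
        sfreq=sfreq,
        window=window,
        class_names=class_names or [],
    )
    out.n_dropped = dropped
    return out


def standardize_epoch(epoch: np.ndarray) -> np.ndarray:
    """Scale one epoch to pooled mean 0 and SD 1.

    A single scalar mean and (population) SD are computed over all channels
    and samples of the epoch; the whole epoch is shifted and scaled by them.
    Idempotent, and invariant to any affine transform ``c + s*Z`` (s > 0).
    """
    epoch = np.asarray(epoch, dtype=float)
    mu = epoch.mean()
    sd = epoch.std()  # population (1/N)
    if sd == 0.0:
        raise DegenerateEpochError("constant epoch: pooled SD is zero")
    return (epoch - mu) / sd


def standardize_epochs(epochs: EpochSet) -> EpochSet:
    """Apply :func:`standardize_epoch` to every trial independently."""
    data = np.empty_like(epochs.data, dtype=float)
    for i in range(epochs.n_trials):
        data[i] = standardize_epoch(epochs.data[i])
    return EpochSet(data=data, labels=epochs.labels, sfreq=epochs.sfreq,
                    window=epochs.window, class_names=list(epochs.class_names),
                    accel=epochs.accel)


def realign_to_movement_onset(
    epochs: EpochSet,
    cfg: OnsetDetectionConfig | None = None,
    cue_time: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Detect per-trial movement onsets from the attached accelerometers.

    Returns the detected onset sample per trial (-1 where no onset was
    found) and the count of undetected trials. Realignment is only
    meaningful for movement sessions; imagery epochs stay cue-locked.
    """
    if epochs.accel is None:
        raise ValueError("EpochSet carries no accelerometer traces")
    cfg = cfg or OnsetDetectionConfig()
    cue = int(round((cue_time - epochs.window[0]) * epochs.sfreq))
    onsets = np.full(epochs.n_trials, -1, dtype=int)
    misses = 0
    for i in range(epochs.n_trials):
        found = detect_movement_onset(epochs.accel[i], cue, cfg, epochs.sfreq)
        if found is None:
            misses += 1
        else:
            onsets[i] = found
    return onsets, misses
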