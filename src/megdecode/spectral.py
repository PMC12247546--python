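"""Standard MEG validation analyses.

Global field power of the evoked response, Morlet time-frequency responses
expressed as percent change from a baseline period, and band-limited power
topographies — the conventional views used to confirm that the simulated
(or recorded) physiology shows the expected event-related
desynchronization in the alpha/beta bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

__all__ = ["TFR", "global_field_power", "tfr_morlet", "band_power_topography"]


@dataclass
class TFR:
    """Time-frequency response as percent change from baseline.

    ``power[f, t] = 100 * (P(f, t) - P_base(f)) / P_base(f)`` per frequency
    row; the edge-cropped region is excluded from ``times``. ``power_raw``
    keeps the trial-averaged power before baselining (same cropped grid).
    """

    frequencies: np.ndarray
    times: np.ndarray
    power: np.ndarray
    power_raw: np.ndarray
    baseline_window: tuple[float, float]
    n_trials_averaged: int


def global_field_power(
    epochs: EpochSet,
    picks: np.ndarray | list[int] | None = None,
    lowpass: float | None = None,
) -> np.ndarray:
    """RMS across picked channels of the trial-averaged (evoked) signal.

    ``picks`` selects the channel cluster (all channels when None); with
    ``lowpass`` set, the evoked signal is zero-phase low-pass filtered
    first to highlight slow phase-locked activity.
    """
    if picks is None:
        picks = np.arange(epochs.n_channels)
    picks = np.asarray(picks)
    if picks.size == 0:
        raise ValueError("picks must be non-empty")
    evoked = epochs.data[:, picks, :].mean(axis=0)
    if lowpass is not None:
        sos = sps.butter(4, lowpass, btype="lowpass", fs=epochs.sfreq,
                         output="sos")
        evoked = sps.sosfiltfilt(sos, evoked, axis=-1)
    return np.sqrt(np.mean(evoked**2, axis=0))


def tfr_morlet(
    epochs: EpochSet,
    fmin: float,
    fmax: float,
    fstep: float = 1.8,
    cycles_factor: float = 0.5,
    baseline: tuple[float, float] = (-1.0, -0.5),
    crop: float = 0.2,
    picks: np.ndarray | list[int] | None = None,
) -> TFR:
    """Morlet-wavelet TFR averaged over trials (and picked channels).

    The wavelet grid runs from ``fmin`` to ``fmax`` in steps of ``fstep``
    with the number of cycles proportional to frequency
    (``n_cycles = cycles_factor * f``, i.e. f/2 by default). ``crop``
    seconds are removed at both epoch edges to discard wavelet edge
    effects; power is expressed as percent change from the mean power in
    the ``baseline`` window per frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    if fstep <= 0:
        raise ValueError("fstep must be positive")
    t0, t1 = epochs.window
    if not (t0 <= baseline[0] < baseline[1] <= t1):
        raise ValueError("baseline must lie inside the epoch window")
    if baseline[0] < t0 + crop or baseline[1] > t1 - crop:
        warnings.warn("baseline overlaps the edge-cropped region",
                      stacklevel=2)
    freqs = np.arange(fmin, fmax + 1e-9, fstep)
    n_cycles = np.maximum(cycles_factor * freqs, 1.0)
    data = epochs.data if picks is None else epochs.data[:, np.asarray(picks), :]
    power = tfr_array_morlet(data, sfreq=epochs.sfreq, freqs=freqs,
                             n_cycles=n_cycles, output="avg_power",
                             verbose="error")
    power = power.mean(axis=0)                       # channels -> (freqs, times)
    times = epochs.times
    keep = (times >= t0 + crop) & (times <= t1 - crop)
    base = (times >= baseline[0]) & (times <= baseline[1])
    p_base = power[:, base].mean(axis=1, keepdims=True)
    pct = 100.0 * (power - p_base) / p_base
    return TFR(frequencies=freqs, times=times[keep], power=pct[:, keep],
               power_raw=power[:, keep], baseline_window=baseline,
               n_trials_averaged=epochs.n_trials)


def band_power_topography(
    epochs: EpochSet,
    band: tuple[float, float],
    window: tuple[float, float],
    baseline: tuple[float, float],
) -> np.ndarray:
    """Per-channel band power in a window vs baseline, percent change.

    Epochs are zero-phase band-pass filtered, squared, and averaged within
    each time window per trial; the trial-averaged window power is compared
    against the trial-averaged baseline power channel by channel.
    """
    nyq = epochs.sfreq / 2.0
    if band[1] >= nyq:
        raise ValueError("band upper edge must be below Nyquist")
    t0, t1 = epochs.window
    for name, win in (("window", window), ("baseline", baseline)):
        if not (t0 <= win[0] < win[1] <= t1):
            raise ValueError(f"{name} must lie inside the epoch")
    if band[0] > 0:
        sos = sps.butter(4, band, btype="bandpass", fs=epochs.sfreq,
                         output="sos")
    else:
        sos = sps.butter(4, band[1], btype="lowpass", fs=epochs.sfreq,
                         output="sos")
    filt = sps.sosfiltfilt(sos, epochs.data.astype(float), axis=-1)
    times = epochs.times
    sel_w = (times >= window[0]) & (times < window[1])
    sel_b = (times >= baseline[0]) & (times < baseline[1])
    p_w = (filt[:, :, sel_w] ** 2).mean(axis=(0, 2))
    p_b = (filt[:, :, sel_b] ** 2).mean(axis=(0, 2))
    return 100.0 * (p_w - p_b) / p_b
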