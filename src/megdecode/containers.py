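"""Shared data containers.

``EpochSet`` is the universal currency between modules: a stack of epoched
multichannel recordings (trials x channels x samples) with integer class
labels, sampling-rate metadata and the epoch window relative to task onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochSet", "load_epochs_hdf5", "epochs_from_fif"]


@dataclass
class EpochSet:
    """Epoched multichannel time series with labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched signal. Units are arbitrary after per-epoch standardization.
    labels : ndarray of int, shape (n_trials,)
        Class index per trial, in ``[0, n_classes)``.
    sfreq : float
        Sampling frequency in Hz.
    window : tuple of float
        Epoch window in seconds relative to task onset, e.g. ``(-1.0, 1.0)``.
    class_names : list of str
        Human-readable class names; index matches the label value.
    accel : ndarray or None, shape (n_trials, 2, n_samples)
        Optional accelerometer traces aligned with the epochs.
    """

    data: np.ndarray
    labels: np.ndarray
    sfreq: float
    window: tuple[float, float]
    class_names: list[str] = field(default_factory=list)
    accel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must be one integer per trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        expected = int(round((self.window[1] - self.window[0]) * self.sfreq))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window/sfreq imply {expected} samples, data has {self.data.shape[2]}"
            )
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.n_classes)]

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
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to task onset."""
        return self.window[0] + np.arange(self.n_samples) / self.sfreq

    def subset(self, idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to trial indices ``idx``."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            sfreq=self.sfreq,
            window=self.window,
            class_names=list(self.class_names),
            accel=None if self.accel is None else self.accel[idx],
        )

    def exclude_class(self, klass: int) -> "EpochSet":
        """Drop one class (e.g. rest) and relabel the rest contiguously.

        Supports the four-class reanalysis variant without a separate code
        path.
        """
        keep = self.labels != klass
        out = self.subset(np.flatnonzero(keep))
        out.labels = np.where(out.labels > klass, out.labels - 1, out.labels)
        out.class_names = [c for i, c in enumerate(self.class_names)
                           if i != klass]
        return out

    def to_hdf5(self, path: str) -> None:
        """Write the container to HDF5 (float32 data, attrs for metadata)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data.astype(np.float32))
            f.create_dataset("labels", data=self.labels)
            if self.accel is not None:
                f.create_dataset("accel", data=self.accel.astype(np.float32))
            f.attrs["sfreq"] = float(self.sfreq)
            f.attrs["window"] = np.asarray(self.window, dtype=float)
            f.attrs["class_names"] = [str(c) for c in self.class_names]


def load_epochs_hdf5(path: str) -> EpochSet:
    """Read an :class:`EpochSet` previously written by :meth:`EpochSet.to_hdf5`."""
    with h5py.File(path, "r") as f:
        accel = f["accel"][()] if "accel" in f else None
        return EpochSet(
            data=f["epochs"][()],
            labels=f["labels"][()],
            sfreq=float(f.attrs["sfreq"]),
            window=tuple(np.asarray(f.attrs["window"], dtype=float)),
            class_names=[str(c) for c in f.attrs["class_names"]],
            accel=accel,
        )


def epochs_from_fif(path: str, label_from_event: bool = True) -> EpochSet:
    """Adapter: import epoched data from an MNE FIF file as an EpochSet."""
    import mne

    ep = mne.read_epochs(path, preload=True, verbose="error")
    labels = ep.events[:, 2] if label_from_event else np.zeros(len(ep), dtype=int)
    labels = labels - labels.min()
    return EpochSet(
        data=ep.get_data(copy=True),
        labels=labels,
        sfreq=float(ep.info["sfreq"]),
        window=(float(ep.tmin), float(ep.tmin) + len(ep.times) / ep.info["sfreq"]),
        class_names=sorted(ep.event_id) if ep.event_id else [],
    )
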