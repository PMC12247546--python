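"""Interpretation of trained LFCNN weights.

Three complementary views of what informs the classification:

* **component contributions** ``c[k, j]`` — the mean (over validation
  epochs) activation of the output-layer nodes addressing component ``k``
  for class ``j``, i.e. the inner product of the component's pooled
  activations with its output weights. Summed over components (plus the
  class bias) these recover the mean pre-softmax logit exactly.
* **spatial activation patterns** ``a_k = Sigma^T w_k`` — the covariance
  (Haufe) transform of the spatial demixing filters. Unlike the raw filter
  weights, these are interpretable as source topographies.
* **spectral fingerprints** — the Welch PSD of each component's latent time
  course multiplied by the squared-magnitude frequency response of the
  component's temporal kernel, normalized to percent of total power.

Class-conditional combined patterns weight each component's spatial pattern
and fingerprint by its contribution to the class and average across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import welch

from .containers import EpochSet
from .lfcnn import LFCNNConfig, LFCNNParams, forward

__all__ = [
    "DataCovariance",
    "InterpretationResult",
    "compute_covariance",
    "component_contributions",
    "spatial_patterns",
    "spectral_fingerprint",
    "spectral_fingerprints",
    "class_patterns",
    "interpret_model",
]


@dataclass
class DataCovariance:
    """Spatial (channels x channels) covariance pooled over trials and time."""

    sigma: np.ndarray
    n_trials: int
    n_samples: int

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
            raise ValueError("sigma must be symmetric")


def compute_covariance(epochs: EpochSet) -> DataCovariance:
    """Pooled spatial covariance of the epochs, per-trial mean removed."""
    x = epochs.data.astype(float)
    x = x - x.mean(axis=2, keepdims=True)
    n, c, t = x.shape
    flat = x.transpose(1, 0, 2).reshape(c, n * t)
    sigma = flat @ flat.T / (n * t)
    sigma = 0.5 * (sigma + sigma.T)
    return DataCovariance(sigma=sigma, n_trials=n, n_samples=t)


def component_contributions(
    params: LFCNNParams,
    val_epochs: EpochSet,
    cfg: LFCNNConfig,
    conditional: bool = True,
) -> np.ndarray:
    """Per-component class contributions, bias excluded.

    ``c[k, j]`` is the mean inner product between the output weights
    addressing component ``k``'s pooled nodes and those nodes' activations.
    With ``conditional=True`` (default) the mean for class ``j`` is taken
    over validation epochs *of class j* — the contribution to the class's
    conditional mean — which is what makes a component that is only active
    during class-j trials stand out. With ``conditional=False`` the mean is
    over all validation epochs.

    The class bias ``b_out`` is class-level, not per-component, and is
    reported separately; consequently ``sum_k c[k, j] + b_out[j]`` equals
    the (class-conditional, resp. overall) mean pre-softmax logit of class
    ``j``.
    """
    if val_epochs.n_trials == 0:
        raise ValueError("empty validation set")
    _, cache = forward(val_epochs.data.astype(float), params, cfg,
                       training=False, return_cache=True)
    pooled = cache["pooled"]                      # (n, K, P)
    n, k, p = pooled.shape
    w = params.w_out.reshape(k, p, -1)            # component-major rows
    n_classes = w.shape[2]
    if not conditional:
        return np.einsum("kp,kpj->kj", pooled.mean(axis=0), w)
    c = np.empty((k, n_classes))
    for j in range(n_classes):
        sel = val_epochs.labels == j
        mean_pooled = pooled[sel].mean(axis=0) if sel.any() \
            else pooled.mean(axis=0)
        c[:, j] = np.einsum("kp,kp->k", mean_pooled, w[:, :, j])
    return c


def spatial_patterns(w_dmx: np.ndarray, sigma: DataCovariance) -> np.ndarray:
    """Covariance-projected spatial filters: ``a_k = Sigma^T w_k``.

    No additional normalization is applied; any scaling is display-time
    only.
    """
    w = np.asarray(w_dmx)
    if sigma.sigma.shape[0] != w.shape[0]:
        raise ValueError("covariance and filters have inconsistent channels")
    return sigma.sigma.T @ w


def _latent_time_courses(params: LFCNNParams, epochs: EpochSet) -> np.ndarray:
    x = epochs.data.astype(float)
    n, c, t = x.shape
    k = params.w_dmx.shape[1]
    return (x.transpose(0, 2, 1).reshape(n * t, c) @ params.w_dmx) \
        .reshape(n, t, k).transpose(0, 2, 1)


def spectral_fingerprints(
    params: LFCNNParams,
    val_epochs: EpochSet,
    cfg: LFCNNConfig,
    psd_window_sec: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprints of all components: (freqs, K x n_bins percent spectra).

    Welch PSD (Hann taper, ``psd_window_sec`` segments, 50% overlap) of each
    spatially filtered time course, averaged over validation epochs, is
    multiplied binwise by the squared magnitude of the component kernel's
    frequency response (kernel zero-padded to the PSD resolution), then
    normalized so each component's spectrum sums to 100%.
    """
    nperseg = int(round(psd_window_sec * val_epochs.sfreq))
    if val_epochs.n_samples < nperseg:
        raise ValueError("epoch shorter than the PSD window")
    s = _latent_time_courses(params, val_epochs)   # (n, K, T)
    freqs, psd = welch(s, fs=val_epochs.sfreq, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2, axis=2)
    psd = psd.mean(axis=0)                         # (K, n_bins)
    h = np.fft.rfft(params.kernels, n=nperseg, axis=1)
    fp = psd * np.abs(h) ** 2
    total = fp.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return freqs, 100.0 * fp / total


def spectral_fingerprint(
    params: LFCNNParams,
    val_epochs: EpochSet,
    k: int,
    cfg: LFCNNConfig,
    psd_window_sec: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprint of component ``k`` only; see :func:`spectral_fingerprints`."""
    if not 0 <= k < params.w_dmx.shape[1]:
        raise ValueError("component index out of range")
    freqs, fp = spectral_fingerprints(params, val_epochs, cfg, psd_window_sec)
    return freqs, fp[k]


def class_patterns(
    contributions: list[np.ndarray],
    patterns: list[np.ndarray],
    fingerprints: list[np.ndarray],
    sign_align: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class combined spatial pattern and spectrum, averaged over folds.

    For each fold, ``class_pattern[:, j] = sum_k c[k, j] * a[:, k]`` and
    likewise for the spectra; the final result is the arithmetic mean over
    folds. Component sign is not identifiable, so patterns of opposite sign
    across folds can cancel; ``sign_align=True`` flips each fold's class
    pattern (and its spectrum) to match the first fold by correlation sign
    before averaging. Off by default.
    """
    if not contributions:
        raise ValueError("need at least one fold's parts")
    if not (len(contributions) == len(patterns) == len(fingerprints)):
        raise ValueError("per-fold lists must have equal length")
    spat, spec = [], []
    for c, a, fp in zip(contributions, patterns, fingerprints):
        c, a, fp = np.asarray(c), np.asarray(a), np.asarray(fp)
        if a.shape[1] != c.shape[0] or fp.shape[0] != c.shape[0]:
            raise ValueError("fold shape mismatch between c, a, fingerprints")
        spat.append(a @ c)          # channels x classes
        spec.append(c.T @ fp)       # classes x bins
    if sign_align and len(spat) > 1:
        ref = spat[0]
        for f in range(1, len(spat)):
            for j in range(ref.shape[1]):
                if np.dot(spat[f][:, j], ref[:, j]) < 0:
                    spat[f][:, j] *= -1.0
                    spec[f][j] *= -1.0
    return np.mean(spat, axis=0), np.mean(spec, axis=0)


@dataclass
class InterpretationResult:
    """All interpretation artifacts for one trained model family."""

    contributions: np.ndarray          # K x classes (last fold or mean)
    spatial: np.ndarray                # channels x K
    fingerprints: np.ndarray           # K x bins, each row sums to 100
    freqs: np.ndarray
    class_spatial: np.ndarray          # channels x classes
    class_spectra: np.ndarray          # classes x bins
    bias: np.ndarray
    folds_averaged: int = 1
    metadata: dict = field(default_factory=dict)

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for name in ("contributions", "spatial", "fingerprints", "freqs",
                         "class_spatial", "class_spectra", "bias"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["folds_averaged"] = self.folds_averaged


def interpret_model(
    params: LFCNNParams,
    val_epochs: EpochSet,
    cfg: LFCNNConfig,
    psd_window_sec: float = 1.0,
    cov_epochs: EpochSet | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One fold's interpretation parts: (c, a, freqs, fingerprints).

    Contributions and fingerprints use the validation epochs; the spatial
    covariance for the Haufe transform uses ``cov_epochs`` when given
    (typically the whole standardized session, for a better-conditioned
    estimate at high channel counts), falling back to the validation
    epochs otherwise.
    """
    c = component_contributions(params, val_epochs, cfg)
    sigma = compute_covariance(cov_epochs if cov_epochs is not None
                               else val_epochs)
    a = spatial_patterns(params.w_dmx, sigma)
    freqs, fp = spectral_fingerprints(params, val_epochs, cfg, psd_window_sec)
    return c, a, freqs, fp
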