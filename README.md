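# megdecode

Decoding multiple same-hand movements from multichannel MEG with an
interpretable compact CNN — as a tested, reusable pipeline.

Non-invasive motor BCIs (e.g. for post-stroke rehabilitation) need to tell
apart several intended or imagined movements of the *same* hand from
magnetoencephalography. The discriminative signal is subtle: modulations of
alpha (8–12 Hz) and beta (13–30 Hz) sensorimotor rhythms starting ~200 ms
before movement onset, with class-specific sensor topographies. This
package provides, for researchers building or evaluating such decoders:

- **`megdecode.synth`** — a seeded generator of MEG-like sessions
  (204-channel planar-gradiometer-like epochs, five balanced classes,
  class-specific narrowband sources with event-related desynchronization,
  1/f + white noise, accelerometer traces, null/control sessions) with full
  ground truth for recovery testing;
- **`megdecode.preprocess`** — band-pass/decimation, epoch extraction,
  per-epoch standardization, accelerometer-based movement-onset detection;
- **`megdecode.lfcnn`** — the LFCNN classifier, implemented from scratch in
  NumPy: spatial demixing `s_k = w_k^T x`, one temporal convolution kernel
  per latent component, ReLU, temporal pooling, dropout and a dense softmax
  readout, trained with Adam and early stopping; plus an RBF-SVM baseline;
- **`megdecode.evaluation`** — nested 9-fold cross-validation with a fixed
  holdout, leave-one-subject-out evaluation, confusion aggregation,
  binomial and empirical chance levels, paired accuracy tests;
- **`megdecode.interpret`** — what the decoder learned: per-component class
  contributions `c_kj = w_kj^out · h_kj`, spatial activation patterns via
  the covariance (Haufe) transform `a_k = Σ^T w_k^dmx`, spectral
  fingerprints (Welch PSD of the latent time course × the kernel's squared
  frequency response), and class-conditional combined patterns;
- **`megdecode.spectral`** — global field power, Morlet time–frequency
  responses as percent change from baseline, band-power topographies.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a session, run the nested cross-validation with per-fold weight
interpretation, and inspect the results:

```python
from dataclasses import replace
import numpy as np
from megdecode.benchmarks import RECOVERY_MODEL, RECOVERY_SESSION
from megdecode.synth import simulate_epochs
from megdecode.preprocess import standardize_epochs
from megdecode.lfcnn import train
from megdecode.interpret import interpret_model

cfg = replace(RECOVERY_SESSION, seed=1)      # 204 ch, 60 trials/class, snr 5
sess = simulate_epochs(cfg)
epochs = standardize_epochs(sess.epochs)

rng = np.random.default_rng(1)
idx = rng.permutation(epochs.n_trials)
train_set, val_set = epochs.subset(idx[60:]), epochs.subset(idx[:60])
params, hist = train(train_set, val_set, replace(RECOVERY_MODEL, seed=1))
print(f"validation accuracy {hist.val_accuracy[hist.best_epoch]:.2f}")

c, a, freqs, fp = interpret_model(params, val_set, RECOVERY_MODEL,
                                  cov_epochs=epochs)
for j in range(1, cfg.n_classes):
    k = int(np.argmax(c[:, j]))            # top-contributing component
    r = abs(np.corrcoef(a[:, k], sess.mixing[:, j])[0, 1])
    peak = freqs[np.argmax(fp[k])]
    print(f"class {j}: pattern |r| = {r:.2f} vs true topography, "
          f"fingerprint peak {peak:.0f} Hz "
          f"(injected {cfg.class_source_bands[j][0]:.0f} Hz)")
```

Output:

```
validation accuracy 1.00
class 1: pattern |r| = 0.99 vs true topography, fingerprint peak 9 Hz (injected 9 Hz)
class 2: pattern |r| = 0.83 vs true topography, fingerprint peak 11 Hz (injected 11 Hz)
class 3: pattern |r| = 0.89 vs true topography, fingerprint peak 19 Hz (injected 19 Hz)
class 4: pattern |r| = 0.83 vs true topography, fingerprint peak 25 Hz (injected 25 Hz)
```

The decoder separates the five classes perfectly at this SNR; its
covariance-projected spatial patterns recover the true source topographies
(classes whose random topographies or bands overlap another's cap their
single-component correlation — see the limitation discussion in the methods
note), and the spectral fingerprints hit the injected source frequencies
exactly.

The same pipeline is available from the shell:

```bash
megdecode simulate --out session.h5 --seed 1
megdecode preprocess --in session.h5 --out epochs.h5
megdecode evaluate --epochs epochs.h5 --out report.json --seed 1
megdecode run-all --out-dir out --seed 1      # everything + manifest
```

A decode of a *null* session (labels independent of the data by
construction) stays inside the binomial chance band — the package's
empirical-chance machinery:

```python
from megdecode.benchmarks import null_calibration
cal = null_calibration(n_sessions=5, base_seed=0)
print(cal["mean_cv_accuracy_pct"], "% vs threshold",
      cal["threshold_alpha05_pct"], "%")
```

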