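# szcast

Bayesian convolutional seizure-risk forecasting on multichannel scalp EEG,
with auxiliary-signal fusion and explicit decision-uncertainty quantification.

The package implements the full pipeline:

1. **`szcast.synth`** — synthetic multichannel EEG generator: 1/f-shaped
   background noise, seizure schedules drawn from a configurable hour-of-day
   mixture, and a controllable 1–4 Hz ("slow activity") preictal power
   signature, plus per-patient bookkeeping tables.
2. **`szcast.preprocess`** — EDF / `.npz` recording I/O, leading-seizure
   merging (<30 min onset gaps collapse into one event), preictal/interictal
   timeline labeling (35–5 min before onset vs ≥4 h away), 30-s windows with
   50% overlap, and the trimmed magnitude STFT: 1-s cosine-tapered frames at
   50% overlap give a 59×129 grid per channel, trimmed to 56 frames and 128
   bins (edge frames and DC removed) — final shape `(n, 56, 128)`.
3. **`szcast.network`** — a mean-field variational CNN implemented directly
   on NumPy (no deep-learning framework required): Gaussian weight
   posteriors `N(mu, softplus(rho)^2)`, standard-normal priors, closed-form
   KL, reparameterized mini-batch ELBO training with Adam, and Monte-Carlo
   prediction (default 500 forward passes per input).
4. **`szcast.fusion`** — Gaussian-kernel KDE priors (Scott bandwidth,
   circular 24-h wrapping) for auxiliary observations such as seizure
   time-of-day, and the multiplicative Bayesian modulator that scales the
   preictal pre-softmax output by the likelihood ratio `p(d|z')/p(d)`.
5. **`szcast.uncertainty`** — uncertainty level
   `std(samples) / |mean(samples) − 0.5|` (display-capped at 10) and the
   confident-correct / confident-wrong / uncertain prediction taxonomy.
6. **`szcast.evaluate`** — segment-level ROC AUC, seizure-period
   cross-validation folds that never train on the tested period's preictal
   data, and uncertainty-gated risk timelines (gate 1.0, 50-step backward
   moving average).
7. **`szcast.attention`** — the biomarker probe: for high-confidence
   preictal predictions (level < 0.1, mean score > 0.9), time-resolved
   attention profiles from the rectified first-layer feature maps averaged
   over 100 posterior draws.

## CLI

One entry point with subcommands:

```bash
szcast synth --config cfg.yaml --out data/            # recordings + annotations + metadata
szcast preprocess --recording data/synth1.edf \
       --annotations data/annotations.csv --out segments.h5
szcast fit-prior --events data/annotations.csv --out prior.json
szcast train --segments segments.h5 --width-scale 0.25 --out model.h5 [--prior prior.json]
szcast predict --ckpt model.h5 --segments segments.h5 --samples 500 --out pred.csv
szcast evaluate --predictions pred.csv --out report.json
szcast timeline --predictions pred.csv --gate 1.0 --window 50 --out timeline.csv
szcast attention --ckpt model.h5 --segments segments.h5 --out attention.csv
```

## Notes

- The deterministic-CNN baseline is the `sigma -> 0`, `kl_weight = 0` limit
  of the same code path.
- Reference training defaults follow the mean-field-VI conventions
  (lr 1e-3, batch 32, sigma init 0.05, KL weight 1/examples-per-epoch); the
  test suite uses a faster desk-scale configuration (see
  `tests/conftest.py::desk_train_config`).
- Synthetic fixtures are generated programmatically at test time; the only
  bundled data file is the plain-text CSV cohort table.
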