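# dictpair

Projection dictionary pair learning (PDPL) for subject-independent EEG
classification, with genetic-algorithm hyperparameter search.

The package implements:

- **`dictpair.features`** — log-spectral-power EEG features: order-8
  zero-phase Butterworth band-pass filters over five bands (delta+theta
  1–8 Hz, alpha 8–12 Hz, beta 12–35 Hz, gamma-1 35–70 Hz, gamma-2
  70–100 Hz), then the natural log of the RMS over nonoverlapping 1 s
  windows, per band and channel. Bands that cannot fit below the Nyquist
  limit (upper edge clipped to 0.99 × fs/2) are dropped with a warning.
- **`dictpair.pdpl`** — the PDPL model: per class k a synthesis block D_k
  (atoms constrained to unit norm) and an analysis block P_k, trained by
  alternating closed-form code/analysis updates and an ADMM
  synthesis-dictionary update, stopping when the energy change drops below
  0.01. Classification is by minimum reconstruction residual
  ‖f − D_k P_k f‖².
- **`dictpair.ga`** — a generational GA over the four hyperparameters
  (m, τ, λ, γ): 36-bit Gray-coded chromosomes (four 9-bit substrings with
  arithmetic scaling and per-bound inclusion flags), stochastic universal
  sampling, single-point crossover, bit-flip mutation and elitist
  reinsertion. Fitness is mean leave-one-subject-out accuracy.
- **`dictpair.evaluation`** — leave-one-subject-out cross-validation,
  accuracy, Student-t 95% confidence intervals, and the plain-text dataset
  layout shared by all commands.
- **`dictpair.synthetic`** — synthetic multi-subject generators:
  class-subspace feature datasets (per-subject offsets + Gaussian noise)
  and raw oscillatory EEG-like trials.

## CLI

All commands are under a single entry point:

```sh
# generate a synthetic feature dataset
dictpair simulate subspace --classes 3 --p 60 --r 8 --subjects 10 \
    --n 40 --noise 0.1 --seed 7 --out data/

# generate raw oscillatory trials and extract features from them
dictpair simulate eeg --channels 14 --fs 128 --classes 2 --out raw/
dictpair extract-features --input raw/ --fs 128 --out data/

# train / predict / evaluate with explicit hyperparameters
dictpair train --dataset data/ --m 32 --tau 0.03 --lam 0.003 \
    --gam 0.0001 --seed 1 --out model.json
dictpair predict --model model.json --dataset data/ --out preds/
dictpair evaluate --dataset data/ --m 32 --seed 1 --out report/

# GA hyperparameter search (writes ga_trace.tsv, best_params.json,
# best_model.json)
dictpair optimize --dataset data/ --max-gen 50 --pop 20 --ggap 0.9 \
    --pmut 0.7 --m-ub 310 --seed 1 --out results/
```

Dataset layout: a directory with `manifest.json` (feature dimension p,
class count K, feature index, subject list) and one sub-directory per
subject containing `features.tsv` (p × n, tab-delimited) and `labels.tsv`
(one integer per line, classes 1..K).

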