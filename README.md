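# harspectrum

Label-efficient representation learning for wearable-sensor human activity
recognition (HAR), spanning the whole supervision spectrum in one tested
library + CLI:

1. **supervised** — residual temporal convolutional network (TCN) classifier
   trained with cross-entropy on raw sensor windows;
2. **unsupervised** — residual autoencoder on handcrafted statistical
   features, trained by reconstruction;
3. **weakly supervised (single-task)** — Siamese TCN trained from pairwise
   same/different-activity constraints with a margin contrastive loss;
4. **weakly supervised (multi-task)** — two-head Siamese TCN learning
   activity and person-identity metrics jointly;
5. **self-supervised** — autoencoder whose reconstruction is additionally
   pulled toward its temporal neighbors and its k-nearest feature-space
   neighbors (temporal and feature consistency);
6. **weakly self-supervised** — two stages: self-supervised pretraining on all
   data, then fine-tuning with a contrastive term on pairs drawn from a small
   label budget (1–10% of windows).

A synthetic multichannel IMU-like stream generator with per-activity
stationary signatures and per-person nuisance variation makes every loss,
trainer and evaluation exercisable without downloads.

## The core objectives

For an encoder `f`, decoder `g`, reconstruction `x~ = g(f(x))` and embedding
distance `D = ‖f(xa) − f(xb)‖`:

* reconstruction: `Φae = (1/N) Σ ‖xᵢ − x~ᵢ‖²`
* contrastive (pair label y, margin δ): `Σ [ y·D²/2 + (1−y)·max(0, δ−D)²/2 ]`
* multi-task: `α·Φ_act + β·Φ_pers`
* temporal consistency: `Φtc(xₜ) = (1/|P|) Σ_{p∈P_t} ‖x_p − x~ₜ‖²` with
  `P_t = {t−2…t+2}`
* feature consistency: `Φfc(xᵢ) = (1/|Q|) Σ_{q∈Q_i} ‖x_q − x~ᵢ‖²` with `Q_i`
  the k=5 nearest neighbors in the handcrafted-feature space
* self-supervised joint loss: `Σᵢ (1−α−β)·Φae + α·Φtc + β·Φfc`
* weakly self-supervised stage 2 adds `γ·Φ_contrastive` over both branches of
  a Siamese autoencoder.

Representations are scored by k-means with k = #classes, optimal
(Hungarian) cluster-to-class mapping, and mapped accuracy / macro-F1.

The neural networks run on a compact, self-contained float64 autodiff engine
(`harspectrum.nn`: tensors, causal dilated conv, batch norm, max-pool, Adam),
whose gradients are verified against central finite differences in the test
suite.

## Worked example

```python
import harspectrum as h
from harspectrum.evaluation import run_experiment

cfg = h.SynthConfig()          # 3 activities, 4 persons, 3 channels, ~680 windows
df = run_experiment(["unsupervised", "selfsup", "weak_single"],
                    fractions=[], synth_cfg=cfg, seeds=[1])
print(df[["paradigm", "acc", "f1"]].to_string(index=False))
```

prints

```
    paradigm      acc       f1
unsupervised 0.480349 0.452888
     selfsup 0.689956 0.689107
 weak_single 0.998544 0.998544
```

Read: on one synthetic replicate the plain autoencoder recovers 48% of
activity labels after cluster mapping, adding the temporal/feature
consistency objectives lifts this to 69%, and pairwise weak supervision —
which consumes same/different constraints rather than explicit labels — is
nearly perfect.  Means over several seeds (see `docs/methods.md`) follow the
same ordering.

The same pipeline is scriptable from the shell:

```bash
harspectrum synth --out streams.csv
harspectrum window --in streams.csv --rate 25 --window-s 2.56 --step-s 1.28 --out windows/
harspectrum features --in windows/ --out features.csv
harspectrum train --paradigm weak_selfsup --data windows/ --label-fraction 0.1 --seed 1 --out run/
harspectrum evaluate --model run/ --data windows/ --out results.csv
harspectrum ablate --seeds 1,2,3 --out ablation.csv
```

## Layout

```
src/harspectrum/
  nn/             autodiff engine, layers, optimizers
  data_synth.py   synthetic streams, windowing, CSV I/O
  features.py     7-statistic features, temporal/kNN neighborhoods
  models.py       TCN encoder, residual autoencoder, Siamese wrappers
  losses.py       all objectives as pure functions
  training.py     constraint sampling, label budgets, six trainers
  evaluation.py   embeddings, k-means + Hungarian scoring, experiment grids
  cli.py          `harspectrum` command group
docs/methods.md   models, assumptions, defaults, limitations
```
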