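# biosigfusion

Classification of EEG-like biosignals built from four pieces that are
usually published separately: a **fusion finite-mixture model (FHM)** for
observation-level feature extraction, a **hybrid DE → PSO → ABC swarm
optimizer (HDPAB)** for wrapper feature selection, and two classifiers —
a **zero-inflated Poisson mixture regression model (ZIPMRM)** and a
**bidirectional LSTM** — evaluated under stratified 10-fold
cross-validation.  It is aimed at researchers who want a tested, seeded,
fully reproducible reference implementation of this pipeline that runs on
synthetic surrogate data out of the box and on Bonn-style text recordings
of their own.

## The models

**Fusion mixture (FHM).**  Each normalised observation *z* is modelled as

```
f(z; Ψ) = (1 − π) f0(z; Ψ0) + π f1(z; Ψ1)
```

where `f0` is a single normal (NUDGE) or a Q-component normal mixture
(eNUDGE, GNG) for the central bulk, and `f1` captures overdispersed
observations: a uniform on the data range (NUDGE/eNUDGE) or two
exponential tails anchored at the innermost points ±ξ (GNG,
"gamma-normal-gamma").  Fitting maximises the weighted likelihood
`Σ_k wei_k log f(z_k; Ψ)` by EM, where `wei_k ∈ (0, 1]` is a one-sided
Huber-style weight of the observation's SVD-derived intensity:
`wei(v) = 1` for `v > −g`, `g/|v|` otherwise (g = 1.5).  Q is chosen by
BIC within a class, the class winner by AIC.  Components with
`|μ_q| + 2σ_q > 1.5·IQR` are flagged *differential*, each observation gets
a local false-discovery score `FDR(z) = f_nondiff(z)/f(z)`, and
observations with `FDR(z_k)/wei_k ≤ y0` are retained.

**HDPAB.**  One population is pushed through differential-evolution
mutation/crossover/greedy selection (`Y = A_x + G(A_z − A_w)`, binomial
crossover at rate CR), a deterministic particle-swarm update
(`Velo ← q·Velo + w1(pbest − A) + w2(gbest − A)`), and the artificial-bee-colony
scout rule that re-seeds members stagnant for `limit` sweeps — with the
best-ever solution archived after every phase (elitism).  For feature
selection, positions decode to subsets through a sigmoid threshold and are
scored by nearest-centroid balanced accuracy under internal CV plus a
sparsity penalty.

**ZIPMRM.**  Counts follow
`ψ·1{u=0} + (1 − ψ) Σ_q π_q|v2 · Poisson(u; exp(β0q + v1′β_q))` with
multinomial-logit concomitant weights; EM with per-component Newton
Poisson regressions.  One model per class, Bayes posterior for
classification.

**Bi-LSTM.**  Standard gate equations (σ input/output/forget gates, tanh
candidate), forward and backward passes concatenated into a softmax
layer; cross-entropy + L2 trained with Adam (lr 0.01, batch 40, 80 hidden
units, L2 10⁻⁴).  Implemented in numpy with hand-derived backpropagation
through time, verified against finite differences.

## Worked example

```python
import numpy as np
from biosigfusion import (SyntheticSpec, gen_two_class_signals,
                          build_feature_matrix, select_model)
from biosigfusion.fhm import svd_intensity, observation_weights
from biosigfusion.hdpab import select_features
from biosigfusion.pipeline import PipelineConfig, run_pipeline

records = gen_two_class_signals(SyntheticSpec(seed=0))   # 2 x 60 segments
fm = build_feature_matrix(records)                        # 120 x 6, z-scored

v = svd_intensity(np.stack([r.samples for r in records]))[fm.source_mask]
wei = observation_weights(v)
z = fm.values.mean(axis=1); z = (z - z.mean()) / z.std()
fitted = select_model(z, wei, Q_max=3, seed=0)

mask, _ = select_features(fm.values, np.asarray(fm.labels), seed=0)
report = run_pipeline(PipelineConfig(classifier="both", seed=0))
```

prints

```
feature matrix: 120 windows x 6 descriptors
fusion model: NUDGE with Q=1, pi=0.234, BIC=-351.7
retained 1/120 observations at y0=0.05
selected features: ['variance']
bilstm: mean 10-fold CV accuracy 0.992
zipmrm: mean 10-fold CV accuracy 0.983
```

The surrogate data contain a healthy-like background class and an
ictal-like class with quasi-periodic spike bursts; both classifiers
separate them almost perfectly, and the label-shuffled permutation null
sits at chance (~0.5).  The fusion mixture here judges the bimodal
two-class score sharply — at the default `y0 = 0.05` almost nothing
passes the retention rule, so the cross-validation driver falls back to
all training rows for that fold (the retention threshold is a config
knob; see `docs/methods.md`).  The six descriptors are mean, variance,
skewness, excess kurtosis, sample entropy and permutation entropy per
window; `variance` alone already separates the classes.

The same stages are scriptable from a shell:

```
biosig simulate --out data/            # Bonn-style text files + labels.csv
biosig extract  --out features.csv
biosig run-all  --seed 1 --out report.json
```

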