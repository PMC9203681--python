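# Methods

This note records the models, the concrete numerical choices, and the
places where the design was genuinely open and we had to pick a reading.

## Fusion mixture model

The observation model is a two-part mixture
`f(z) = (1−π) f0(z) + π f1(z)` over normalised scalars z.

* **f0** — the central bulk: a single normal (NUDGE) or a Q-component
  normal mixture with weights γ_q (eNUDGE, GNG).
* **f1** — the overdispersion part: a uniform on `[i, j]` for
  NUDGE/eNUDGE, or for GNG a ρ-blend of two exponentials supported on
  `z < −ξ1` and `z > ξ2`, each a proper shifted density anchored at its
  tail cut.  The anchors are plug-ins, `ξ1 = |max(z<0)|`,
  `ξ2 = |min(z>0)|`, held fixed during EM.  The uniform bounds are also
  plug-ins fixed at the observed data range — the standard treatment for
  uniform-plus-normal "differential observation" mixtures, and the only
  one that keeps EM monotone without constrained optimisation.

**Weighted EM.**  The objective is `Σ_k wei_k log f(z_k)` with
prespecified weights.  Responsibilities use the weighted densities; the
M-step is in closed form for π, γ, μ, σ and for the GNG tail blend ρ and
scales β (weighted MLEs of shifted exponentials).  Stopping:
`‖Ψ(t+1) − Ψ(t)‖ < ε` with ε = 1e-8, at most T = 1000 sweeps.  A σ floor
of 1e-4 × SD(z) guards against component collapse (the event is logged;
the monotonicity slack in the tests is 1e-9).  Initialisation:
quantile-spread means with a small seeded jitter, pooled-SD sigmas,
uniform γ, π₀ = 0.1.

**Intensity weights.**  Observations come with a window (epoch) of raw
samples.  Each window is mean-centred (removing its DC offset), the
windows-by-samples matrix is decomposed by SVD, and each observation's
magnitude along the leading singular direction (|U_k1|·s_1) is its
intensity.  The weight is a one-sided Huber-style function of the
z-scored log intensity: `wei = 1` above the knee −g, `g/|v|` below, with
g = 1.5.  Faint epochs therefore count less in the likelihood.  The
definition of "intensity" was an open design point; mean-centring per
observation is the reading under which identical windows get equal
weights and a uniformly scaled-down window is always the faintest,
which is what a per-epoch amplitude weighting should do.

**Selection and feature calling.**  Q maximises BIC within eNUDGE/GNG
(BIC and AIC computed from the weighted log-likelihood, with parameter
counts 5 / 3Q+3 / 3Q+4 for NUDGE / eNUDGE / GNG — plug-ins excluded);
the overall class winner maximises AIC, ties broken toward fewer
parameters.  A normal component is *differential* when
`|μ_q| + 2σ_q > 1.5·IQR(z)`.  The per-observation score
`FDR(z) = f_nondiff(z) / f(z)` (a local false-discovery-rate analogue,
not Benjamini–Hochberg) drives retention: keep k iff
`FDR(z_k)/wei_k ≤ y0`.  y0 defaults to 0.05 and is a config knob; there
is no canonical value, and on strongly bimodal data the rule is sharp —
see the pipeline fallback below.  Whether "observations" are rows or
columns was ambiguous; we retain rows (epochs).

## HDPAB optimizer

Each iteration applies, to one shared population: a DE sweep (rand/1
mutant from three distinct partners excluding the target, binomial
crossover at rate CR with *no* forced crossover index — so CR = 0 leaves
a member unchanged — and strictly greedy replacement), a PSO sweep, and
the ABC scout rule (members whose trial counter reached `limit` are
re-seeded uniformly in the box).  Trial counters increment when a member
fails to improve over a full DE+PSO sweep and reset on any improvement.
The best-ever solution is archived after every phase, so the elite
trajectory is non-increasing by construction.  Bounds are enforced by
clipping.

**The deterministic velocity rule and its consequences.**  The PSO update
is `Velo ← q·Velo + w1(pbest − A) + w2(gbest − A)` with *no* stochastic
multipliers (an optional flag restores canonical Uniform(0,1) factors).
Two choices follow from taking that rule seriously:

* *Attraction ranges.*  Canonical PSO multiplies c1 = c2 = 2 by U(0,1)
  factors of mean 1/2, so the deterministic analogue of the canonical
  attraction is w ≈ 1.  Control parameters left unset are drawn from
  G ∈ [0.4, 0.9], CR ∈ [0.1, 0.9], q ∈ [0.4, 0.9], w1, w2 ∈ [0.5, 1.0].
  Keeping w1 + w2 ≤ 2 also guarantees the damped-oscillator stability
  condition w1 + w2 < 2(1 + q) for every draw; with w up to 4 the
  deterministic swarm oscillates without damping and never refines.
* *Per-iteration redraw.*  The draws are repeated every iteration
  (`redraw_each_iter=False` restores a single draw per run).  Under the
  deterministic rule a single unlucky draw is an absorbing state — the
  swarm collapses onto gbest, difference vectors vanish, and scouts
  cannot refine because their difference vectors are box-sized — whereas
  varying the draw restores robust convergence (on the 10-d sphere: all
  of 20 seeds below 1e-2 with redraw, versus 3–4 stalled without).
* Velocities are clamped to 0.2 × the box width per dimension so
  particles clipped at a bound cannot accumulate runaway velocity.

`limit` defaults to NP·dims/2.  Non-finite fitness values are treated as
+∞ and logged, never propagated.

**Feature selection wrapper.**  Positions live in [−4, 4]^d; feature j is
selected iff sigmoid(position_j) > 0.5 (an empty mask falls back to the
single best-scoring feature).  Subset fitness (minimised) is
`1 − balanced accuracy of nearest-centroid under stratified 5-fold CV +
λ·(selected/total)`, λ = 0.01.  Nearest-centroid is deliberately cheap
and deterministic; the wrapper cost is NP × iterations × CV fits.

## ZIP mixture regression

`u ~ ψ·δ0 + (1−ψ) Σ_q π_q|v2 Poisson(exp(β0q + v1′β_q))` with
multinomial-logit concomitant weights (last component's coefficients
fixed at 0 for identifiability).  ψ is covariate-free — the minimal
completion of the dual zero-generating mechanism; a logistic ψ(v2) would
be a drop-in extension.  EM: the E-step computes structural-zero
posteriors and component responsibilities; the M-step updates ψ in
closed form, solves per-component weighted Poisson regressions by damped
Newton iteration (run to 1e-10, so the degenerate K=1/ψ=0 case agrees
with an independent GLM fit to machine precision), and refits the
concomitant logit by L-BFGS on the exact gradient.  Empty components
(responsibility mass < 1e-8) are re-seeded from a random data quantile
and logged.  Stopping: relative log-likelihood change < 1e-6, at most
200 sweeps.  Label switching in recovery comparisons is resolved by
sorting components on β0.

**Classification.**  One ZIPMRM per class; multi-feature count vectors
use the long format (one count per observation-feature pair) with
feature-identity dummies as both v1 and v2, so a single regression per
class captures per-feature rates and weights.  Class posteriors multiply
per-feature densities (conditional independence given the class) with
empirical class priors.  Continuous features become counts by
equal-frequency binning (default 16 levels in the library, 8 in the
pipeline where training folds are small); bin edges derive from training
rows only and are reused on held-out rows.

## Bi-LSTM

Gates exactly as stated: `i, o, f = σ(W·[h, x] + b)`,
`C_t = f∘C_{t−1} + i∘tanh(W_c·[h, x] + b_c)`, `h_t = o∘tanh(C_t)`.
Forward and backward passes run over the sequence; the concatenation of
the two final hidden states feeds a fully connected softmax layer.  Each
selected-feature vector is treated as a length-T sequence of scalars
(T = number of selected features, D = 1).  Training: cross-entropy plus
`(λ/2)‖W‖²` on the weight matrices (λ = 1e-4), Adam with lr 0.01 and
batch 40 (a flag selects the literal SGD update `W ← W − η ∂L/∂W`),
80 hidden units, early stopping on validation loss with patience 10
(pipeline: patience 8, ≤ 40 epochs), best weights restored.  Gradients
are hand-derived BPTT — there is no autodiff dependency — and are checked
against central finite differences in the tests (the cell additionally
against scalar hand arithmetic at 1e-12).  Forget-gate biases start
at +1, the usual remedy against early forgetting.  A NaN loss aborts
with diagnostics rather than training on.

## Synthetic data

The surrogate emulates a two-class resting-vs-ictal contrast:

* class 0 — stationary AR(2) background (coefficients (0.5, −0.3),
  unit-SD innovations) plus a 10 Hz sinusoid, 256-sample segments at a
  Bonn-like 173.61 Hz;
* class 1 — the same background plus quasi-periodic spike bursts:
  16-sample rhythmic discharges (8-sample period, Hanning envelope,
  per-segment polarity, amplitude 6 × background SD, ±30% jitter)
  recurring every 56 ± 16 samples.  Burst onsets are quasi-periodic
  rather than Bernoulli because seizure discharges recur rhythmically;
  with independent per-sample onsets a material fraction of "ictal"
  windows would contain no abnormality at all, which does not happen in
  real ictal recordings.

This yields the intended descriptor contrast (higher variance and
kurtosis, lower sample entropy in class 1; verified across seeded
replicates) and near-ceiling separability, consistent with how easily
real normal-vs-ictal segment collections are classified.  What it does
*not* model: 1/f spectra, non-stationarity, artifacts, inter-channel
structure, or any physiological validity — so a passing pipeline here
demonstrates plumbing and statistical correctness, not clinical
performance.

Also provided: exact samplers for the fusion mixture and the ZIP count
model (used by the recovery tests, with latent indicators returned), and
the sphere/Rastrigin/Rosenbrock benchmarks with known optima.

## Cross-validation driver

Outer stratified 10-fold CV over observation windows gives test
estimates; within each training fold an 8:1 split supplies the
validation set for early stopping, so the overall partition matches an
80/10/10 train/validation/test scheme.  Everything training-derived —
normalisation constants, the fitted mixture, the retention mask, the
selected features, count-bin edges — is computed from training rows only
and applied frozen to the held-out fold; a test perturbs held-out rows
and asserts all artefacts are bit-identical.

The FHM stage models the leading principal-component score of the
normalised training features (a scalar summary per observation) with
intensity weights from the training windows.  If the retention rule
leaves fewer than 10 rows or fewer than 5 rows of any class — which
happens when the two-class structure makes the score sharply bimodal and
y0 strict — the fold falls back to all training rows with a logged
notice; classification is undefined on a one-class training set, and
silently proceeding would be worse than not filtering.

Problem sizes used by the default run and the acceptance script: 60
segments per class (120 windows), Q_max = 3, HDPAB with NP = 12 and 12
iterations over 6 features, ≤ 40 Bi-LSTM epochs — sizes at which the
full 10-fold run takes on the order of a minute while every stage stays
statistically meaningful.  Recovery studies use n = 5000 (mixture),
n = 2000 × 20 replicates (BIC), n = 3000 (ZIP).

## Known limitations

* The FHM scalar summary (PC1 score) is one defensible reduction of a
  multi-feature matrix to the univariate object the mixture models;
  modelling each feature column separately would be an alternative.
* The deterministic PSO rule, even stabilised, is weaker than canonical
  stochastic PSO on multimodal objectives; the `stochastic_pso` flag
  exists for that reason.
* ψ in the ZIPMRM is covariate-free; no negative-binomial variants.
* No artifact removal is implemented; `preprocess_identity` is a
  pass-through hook where ICA or filtering would go.
* Baseline comparison classifiers (KNN, naive Bayes, AdaBoost, LDA,
  SVM-RBF, QDA, HMM, GMM) are delegated to scikit-learn/hmmlearn and are
  comparison plumbing, not part of the method.
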