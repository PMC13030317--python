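# Methods

This note documents the models, conventions and design choices behind
`femg-xdyn`: a pipeline that classifies facial expressions from multi-channel
facial-EMG amplitude signals, infers continuous expression sequences over VR
task scenes, summarizes them as expression-dynamics features, and relates
those features to subjective workload ratings with mixed-effects models.
Because real recordings of this kind are rarely shareable, the pipeline ships
with — and is validated against — a synthetic cohort generator that plants
known structure for every downstream stage to recover.

## Signals and channels

The signal model is a rectified, filtered **amplitude** envelope, not raw
oscillatory EMG: commercial fEMG mask systems export exactly this
representation. Seven channels in fixed order cover four muscle groups:

| index | channel | muscle group |
|---|---|---|
| 0 | corrugator_center | corrugator (brow lowering) |
| 1–2 | frontalis_left/right | frontalis (brow raising) |
| 3–4 | orbicularis_left/right | orbicularis oculi (eye closure) |
| 5–6 | zygomaticus_left/right | zygomaticus major (lip-corner raising) |

Four expression classes are modeled — neutral, smile, frown, raised eyebrow —
with a fixed class order (neutral first) used for probability vectors and
argmax tie-breaking. The FACS-based involvement map drives both generation
and interpretation: smile engages orbicularis + zygomaticus, frown engages
frontalis + corrugator, a raised eyebrow engages frontalis only.

## Synthetic cohort generator

Per participant, a physiology profile draws a per-channel resting tone
(uniform on 0.05–0.2 amplitude units) and an MVIC amplitude (uniform on
0.8–1.5), with the MVIC range strictly above the tone range.

**Expression scripts** are a two-state renewal process at window granularity
(default 1 s steps): from the neutral background a burst starts at each step
with a scene-specific onset probability; its class follows a scene-specific
mixture and its length is uniform on 2–5 steps. Default onset probabilities
(baseline 0.06, emotional 0.07, cognitive 0.02, physical 0.14, dual 0.15)
produce non-neutral occupancy ordered cognitive < baseline ≈ emotional <
physical ≈ dual — expressive suppression under cognitive demand and elevated,
smile-dominated expressiveness under physical and dual demand; emotional
bursts are enriched in raised eyebrows. These rates are free design choices:
no quantitative description of spontaneous burst statistics was available to
estimate them from, so they are set once to what is physiologically plausible
and are not data fits.

**Rendering**: each maximal non-neutral run becomes one burst; the involved
channels receive a raised-cosine (Hann) rise-and-fall envelope spanning the
run and peaking at 70% (±10% lognormal-free Gaussian jitter) of that
channel's dynamic range — a transient peak that rises and returns to
baseline, the empirically observed shape of spontaneous activations.
Zero-mean Gaussian noise with sd = peak/snr (default snr = 20; the device
exports heavily filtered data) is added and the signal rectified at zero.
Cross-talk between channels is off by default and available as a mixing
coefficient for robustness experiments.

**Calibration sessions** alternate neutral blocks with held maximal
expressions (smile, frown, eyebrow raise), three repetitions of 4 s blocks,
with a trapezoid envelope (10% rise, 80% plateau at the full dynamic range,
10% fall). The plateau is what makes a percentile-based MVIC estimator
well-posed.

**Ratings**: eight NASA-TLX subscales (mental, physical, temporal,
performance, effort, frustration, emotional, overall — the instrument's six
canonical dimensions plus emotional and overall, since this study variant
uses eight) on a 0–10 scale. Each rating is intercept (4.0) + subscale ×
scene shift + participant random intercept (sd 1.0) + Σ planted β × z-scored
feature + noise (sd 0.5), truncated to [0, 10]. The default planted effect is
β = −1.0 from smile occupancy (`ratio_smile`) to the physical-demand
subscale: higher smile occupancy, lower perceived physical demand — the
qualitative direction the statistics stage is expected to recover. The
intercept and shifts are chosen so the truncation bound is essentially
inactive under defaults.

Every generator output is a pure function of (config, seed); seeds fan out
through `numpy.random.SeedSequence` so each participant/stage is
independently reproducible.

## Normalization

Two successive steps collapse to one affine map per channel:
`x' = (x − neutral) / (mvic − neutral)`. Neutral correction removes
inter-individual resting tone; MVIC scaling expresses activation as a
fraction of individual maximal capacity. Conventions:

* neutral baseline = per-channel **median** over all neutral calibration
  blocks (robust to transients; mean would be pulled by blinks/artifacts);
* MVIC = per-channel **95th percentile** over all maximal-expression blocks
  pooled (robust to single-sample spikes, unlike the raw max);
* normalization is applied per session, with one profile per participant;
* the usable dynamic range must exceed 1e-6, otherwise the channel is a hard
  error rather than a silent divide;
* normalized values are **not clipped** — spontaneous activity may
  legitimately exceed the calibration maximum;
* sample indices are 0-based and event intervals half-open `[start, end)`.

## Windowing

Signals are cut into fixed windows of `w` samples with stride `s` (defaults:
1 s windows, zero overlap, i.e. `s = w`). Only complete windows are kept; a
segment of `T ≥ w` samples yields exactly `floor((T − w)/s) + 1` windows.
Calibration windows inherit a label only when all their samples share it;
windows never span two differently-labeled segments. The 1 s default
balances burst resolution against window stability and keeps the window
count arithmetic transparent; both `w` and `s` are configurable.

## Classifier

The default architecture has three blocks operating on `(w × 7)` windows in
`(channels × time)` layout:

1. **CNN block** — two stages of 1-D convolution along time across all seven
   channels (kernel 5; 32 then 64 filters), batch normalization, ReLU and
   max-pool 2. This captures inter-channel (spatial) activation patterns.
2. **TCN block** — three residual blocks of two dilated causal convolutions
   each (kernel 3, 64 filters, dilations 1/2/4, dropout 0.2, 1×1 skip when
   channel counts change). Receptive field = 1 + 2·(k−1)·Σd = 29 pooled
   samples, covering the full pooled window at the default sizes.
3. **FC block** — global average pooling, a 64-unit hidden layer and a 4-way
   softmax.

Baselines (CNN, TCN, LSTM, GRU, CNN-LSTM) share the same training and
evaluation contract; the recurrent heads read the last hidden state
(hidden size 32).

The layers are implemented in a compact numpy stack with manual
backpropagation (`femg_xdyn.nn`), verified against finite-difference
gradients for every layer type. Training uses Adam (lr 1e-3, batch 64) on
**inverse-frequency class-weighted** cross-entropy — calibration sets are
neutral-heavy, and weighting preserves temporal data density where
resampling would not. Early stopping monitors validation weighted F1
(patience 10 by default); the best parameters are restored. Initialization,
shuffling and dropout are all seeded, so training is bit-reproducible at a
fixed thread count.

## Evaluation protocol

**LOPO**: each participant's calibration windows are the test set exactly
once. Within each fold the validation subset is **participant-disjoint**
from training (two rotating held-out participants) — a random window split
would leak near-duplicate neighboring windows between train and validation.
Metrics: accuracy; macro and class-frequency-weighted precision/recall/F1
(precision of a never-predicted class is 0); one-vs-rest macro ROC-AUC
(classes absent from the truth are excluded with a warning); 4×4 row-
normalized confusion matrix. After cross-validation the model is retrained
on the pooled calibration data (random 10% window hold-out for monitoring)
and this single shared model is used for all inference.

The chance floor is a balanced permutation null: classes are subsampled to
equal counts and the macro-F1 of the predictions is averaged over label
permutations, concentrating near 0.25 for four classes.

## Inference and scene summaries

Scene recordings are normalized with the participant's own profile and
windowed exactly as in training (zero-overlap; partial trailing windows
discarded). Each window's argmax label joins the continuous expression
sequence. No temporal smoothing is applied by default — the downstream
features depend on the raw transition structure — though a majority filter
is available. Scene summaries report the four occupancy proportions, the
non-neutral proportion, and per-participant deltas against that
participant's own baseline scene (the baseline's own delta is identically
zero, and the four class deltas sum to zero).

## Expression-dynamics features

Each participant × scene sequence yields 81 named scalars: 4 occupancy
ratios; 4 class counts + total frames; 3 neutral→non-neutral transition
counts; 3 average non-neutral burst lengths; Shannon entropy of the 4-class
distribution and its normalized form H/2; switches, switch rate and
persistence (T / number of runs); dominance and a Gini-like inequality of
the non-neutral mass; 3 latency indices; the full 4×4 transition count and
row-normalized probability matrices (32); and per-class run-length
descriptors {count, mean, median, min, max, population std} (24).

Published descriptions of this taxonomy give a per-category tally of 61 but
state 81 features in total; the unique natural reading that reaches 81 —
adopted here — expands the burst-statistics category to six descriptors for
each of the four classes. Conventions for degenerate cases: descriptors of
an absent class are 0; dominance/inequality are 0 when no non-neutral frame
exists; the latency sentinel is 1.0; probability rows of never-visited
states stay all-zero (no invented mass); a single run has std 0. The latency
index is the relative position of the first window of a class preceded
anywhere earlier by a neutral window — one specific reading of "first
occurrence after neutral", documented rather than inferred. Every feature is
checked against an independent brute-force implementation, exhaustively for
all 4⁶ sequences of length 6.

## Statistics

Features are z-scored with the **population** SD across all participant ×
scene rows; zero-variance columns are dropped and logged. PCA runs on the
standardized matrix; components are ordered by explained variance with the
sign fixed so each component's largest-magnitude loading is positive.

Scene contrasts fit `score ~ scene` (baseline reference) with a participant
random intercept. Feature–workload models fit, for each (feature, subscale),
`rating ~ feature × scene + (1 | participant)` by REML with Powell's
derivative-free optimizer (statsmodels MixedLM). Because features are
z-scored, β is the change in rating (0–10) per one SD of the feature.
Convergence failures and collinear features are flagged in the results
table, never silently dropped.

The BH-FDR family defaults to all feature-effect p-values jointly across
subscales — the feature main effect and each feature × scene interaction;
scene main effects are nuisance terms outside the family. A per-subscale
family is available. Non-finite p-values (degenerate fits) cannot enter the
family. q < 0.05 is the default significance threshold.

## Validation experiments and problem sizes

The validation runners (`femg_xdyn.validation`) use desk-scale conditions:
12-participant cohorts sampled at 100 Hz with 1 s windows, 60 s stressor
scenes, a 120 s baseline, and a reduced epoch budget (12 epochs, patience 3)
— the synthetic task converges within a few epochs. Burst rates, class
mixtures, physiology ranges and planted rating effects stay at generator
defaults. Mixed-model recovery uses 50 simulated cohorts of 100 participants
(script features and ratings only; rendering does not enter the rating
model), and type-I calibration uses 200 null cohorts.

## What the synthetic validation does and does not show

The generator reproduces the structural assumptions of the pipeline:
participant-specific affine amplitude scaling, FACS-consistent channel
activation, burst-like transients, scene-dependent expressiveness, and a
linear mixed-effects rating model. It does **not** emulate motor-unit
physiology, movement or breathing artifacts, electrode drift, cross-scene
expression idiosyncrasies, or non-linear feature–rating relationships.
Passing tests therefore demonstrate that the implementation is correct and
that the statistical machinery recovers planted structure at realistic
noise levels — not that the classifier would reach the same performance on
human recordings, where near-ceiling LOPO scores on the clean synthetic
cohort should not be expected.

## Known limitations

* The numpy network trains on CPU only and is sized for desk-scale cohorts.
* Weak bursts rendered near their envelope edges can be classified neutral,
  compressing scene deltas toward zero relative to the ground-truth scripts
  (the planted ordering is preserved).
* MixedLM Wald p-values are asymptotic; at very small cohort sizes the
  type-I rate is only approximately nominal.
* The full 81 × 8 model family is expensive at desk scale; the pipeline's
  stats stage defaults to a configurable feature subset (`stats_features`,
  `'all'` for the full family).
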