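# Methods

## The problem and the model

Gesture decoding from surface EMG is a small-sample multiclass problem: a
recording session gives a few repetitions of each gesture per subject, while
the spectrogram representation of even a short trial has 10⁴–10⁵ dimensions.
The pipeline addresses the mismatch in two ways — it enlarges the training
set with virtual samples drawn from a class-conditional Gaussian model, and
it compresses the representation with unsupervised sparse autoencoders before
any classifier sees it.

### Virtual-sample generation

For each class c and feature j the training fold supplies a sample mean
μ[c,j] and sample standard deviation η[c,j] (denominator N−1). Continuous
features of a virtual row are drawn independently as N(μ[c,j], η[c,j]²) —
a diagonal-covariance model; no cross-feature covariance is estimated.
Discrete (integer-coded) features are never perturbed: they take the
within-class mode, which is exactly the degenerate draw from N(mode, 0).
The replication factor R produces R virtual rows per original row, all from
the row's class model, so class balance is preserved; originals are kept
alongside. R = 1000 in the full profile; tests and the acceptance script use
R = 10 so the whole suite runs on one CPU in well under the half-hour mark —
a smaller R weakens the augmentation effect but exercises identical code
paths.

Replicating per original row from the *class* Gaussian (rather than
jittering each row around itself) is a deliberate reading: the generative
model is fitted per class and per feature, and class-conditioning is the only
way the virtual labels stay meaningful.

Augmentation is applied strictly to training folds. Augmenting before or
after standardization is equivalent for the Gaussian fit (both operations are
affine per feature); the pipeline standardizes first so the autoencoder and
the virtual-sample model see the same scale.

### Spectrogram front end

Window 200 ms, hop 50 ms, 1024-point DFT, one-sided spectrum (513 bins).
Frame t covers samples [tH, tH+W), frames indexed from 0, giving
⌊(L−W)/H⌋+1 frames — no padding, so every frame is fully supported by data.
The taper is a Hamming window (the sEMG default; the representation is not
sensitive to this choice at these window lengths) and the default scale is
log-power with a 1e-12 floor before the log, which keeps the autoencoder
inputs bounded and roughly symmetric. The `power` scale is normalized so a
rectangular-window frame's one-sided bin powers sum to frame energy / W;
this Parseval anchor is what the tests pin down.

### Tensor stage

A trial's spectrogram is carried as a (channel × frequency × time) tensor
with lossless row-major flatten/unflatten and mode-n unfold/fold (last axis
fastest, documented so serialized tensors are portable). The pipeline's
coordinate transform defaults to the identity — the tensor stage is then an
axis-structured view, nothing more — but `CoordinateTransform` objects carry
a forward map with its Jacobian and compose by the chain rule, so a
domain-specific change of coordinates can be slotted in without touching the
pipeline.

### Sparse autoencoders

Each layer minimises

    1/(2N) Σ‖x̂−x‖² + λ/2 (‖W₁‖² + ‖W₂‖²) + β Σⱼ KL(ρ ‖ ρ̂ⱼ)

with a linear decoder. Defaults: two layers of 1200 and 900 hidden units,
λ = 0.001, β = 4, ρ = 0.05, purely linear encoder transfer; logistic and
positive-saturating-linear transfers are available. With a linear encoder the
activations are unbounded, so ρ̂ⱼ is computed on logistic-squashed
activations — the KL term stays defined for every transfer and reduces to
the usual mean activation when the transfer is logistic.

Training is full-batch on the exact analytic gradient. The default optimizer
is L-BFGS (deterministic given the Glorot-range init seed; line search makes
the recorded loss trace non-increasing); a plain fixed-step gradient-descent
mode is kept for step-by-step inspection and for the monotone-descent
property test. The stack is trained greedily — layer 2 fits layer 1's codes —
with no joint fine-tuning. Standardization statistics always come from the
training fold.

### Classifier bank and per-class fusion

Three families compete on the autoencoder codes:

- **ELM** — random hidden layer, W, b ~ Uniform(−1, 1), output weights by
  ridge least squares on one-hot targets (pseudoinverse when ridge = 0).
  Five candidate activations: sine, triangular-basis max(0, 1−|x|),
  radial-basis exp(−x²), logistic, hard-limit. The first three are the
  canonical choices for this architecture; logistic and hard-limit complete
  the set of five as the standard remaining options.
- **SVM** — six named kernels: linear, quadratic, cubic (polynomial with
  unit offset), and fine/medium/coarse Gaussian with kernel scales √d/4, √d,
  4√d (d = feature count), i.e. γ = 1/scale².
- **SL** — a softmax (multinomial logistic) head, the conventional partner
  of stacked autoencoders.

Within ELM and SVM the variant with the best validation accuracy is kept
(ties to the first declared). Per-class validation accuracies (recall of
each class) then assign every class to its best family, ties broken by the
fixed priority ELM > SVM > SL. Fused prediction gates scores: class c's
fused score is the softmax-normalized score from c's assigned family, and
the argmax wins (lowest class index on ties). All families expose scores
that row-normalize to 1, which is what makes the cross-family comparison
meaningful; the rule degenerates exactly to a single classifier when that
classifier owns every class.

Selection uses an inner validation split — a stratified 25 % of the original
(non-virtual) training rows; candidates train on the remaining originals
plus all virtual rows, and the chosen variants are refitted on the full
augmented fold. Selecting on training predictions instead would
systematically favour the interpolating ELM.

### Evaluation protocol

Threefold cross-validation, stratified by repetition within each
(subject, class) group, so each fold tests on 2 of 6 repetitions of every
group and all windows of a trial stay on one side of the split (windows
within a 5 s trial are heavily correlated; splitting below the trial level
would leak). Accuracy is computed per subject and the overall figure is the
unweighted mean across subjects. Every stage seed fans out from one master
seed through `SeedSequence` spawning in a fixed order, so a run is exactly
reproducible, and each fold records the trial ids seen by every fitting
stage as an auditable leakage guard.

## The simulator

`simulate_emg_dataset` emits, per (subject, class, repetition, force level),
a trial of band-emphasized noise: white noise through a second-order resonant
peak filter centred on the class's band centre (defaults spread over
60–400 Hz, inside the conventional 20–450 Hz sEMG band), scaled by a strictly
positive class × channel gain pattern, a log-normal per-subject gain
(sd 0.1), and a per-trial force factor; additive white sensor noise
(sd 0.05 relative to the unit-variance shaped signal) and a hardware-style
amplification of 1000 complete the trial. Rest segments are noise only and
excluded from classification by default.

What it emulates: class-specific spectral signatures, channel amplitude
ratios, subject-level gain variability, trial-count arithmetic
(subjects × classes × repetitions), and force-level amplitude variation with
gesture-only labels. What it does not: motor-unit action potentials,
nonstationarity within a contraction, electrode shift, crosstalk, fatigue.
Passing tests therefore demonstrate that the pipeline recovers class
structure planted in band location and channel gains — not that it would
reach any particular accuracy on real recordings.

## Numerical choices and problem sizes

- Log-power floor 1e-12; KL ρ̂ clamp [1e-6, 1−1e-6] with a warning.
- ELM ridge default 1e-6 (pure pseudoinverse at ridge = 0 is reserved for
  the interpolation analyses).
- Test/CI problem sizes, chosen so the full suite and the acceptance script
  each finish in a few minutes on one CPU: toy benchmark 3 classes × 20 rows,
  R = 10, hidden sizes [40, 20]; simulated EMG 2 subjects × 3 classes ×
  6 repetitions, 1 s trials, 512-point DFT. The `full_profile` restores
  R = 1000 and hidden sizes [1200, 900].
- Degenerate inputs: all-zero gains produce silent trials; η = 0 everywhere
  produces identical virtual rows; R = 0 augmentation is the identity;
  m = 0 virtual draws return an empty table with intact schema.

## Known limitations

- Diagonal-covariance virtual samples cannot reproduce feature correlations
  within a class; strongly correlated spectrogram bins are treated as
  independent.
- Greedy layer-wise autoencoder training has no joint fine-tuning pass.
- The inner-split selection accuracies are high-variance on very small
  folds; with ≤ 2 validation rows per class, family assignment can be
  effectively arbitrary among near-ties (the fixed priority makes it
  deterministic).
- Leave-one-subject-out generalization is out of scope; the protocol is
  within-subject throughout.
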