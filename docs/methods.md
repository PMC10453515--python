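# Methods

## The elimination cascade

The core method reduces open-set activity recognition to a sequence of
closed binary problems. With known activities *A* = {a₁, …, a_k}, level
*i*:

1. relabels the remaining training pool 1 for aᵢ, 0 for everything else;
2. fits a binary base classifier;
3. predicts the remaining test pool — records predicted 1 get final label
   aᵢ and leave the test pool;
4. removes training records whose *true* label is aᵢ from the training
   pool.

Records surviving all k levels are the outlier set. Two asymmetries are
deliberate and worth stating plainly:

- **Test-pool removal is prediction-driven, training-pool removal is
  true-label-driven.** Test records carry no usable labels at run time, so
  only the classifier's verdict can remove them; training records are
  labelled, so the level's own class is removed exactly.
- **Training labels outside A are permanent negatives.** A 70/30 random
  split of a stream containing unknown-activity bouts leaves some of those
  windows in the training split. They are never the positive class and are
  never removed, so they anchor the "everything else" side of every level.
  This is what makes distance-based bases work: an unknown test window's
  nearest neighbours are unknown training windows, which vote 0 at every
  level, so the window survives to the residual set. Removing such rows
  from training would make k-NN assign every unknown window to its nearest
  known class instead.

The per-level metrics (ACC, PP, SE, SP) are computed on the records still
in play at that level, against the binary truth "is this record really
aᵢ". Activity order is a seeded uniform shuffle by default (results are
order-dependent); an explicit order can be passed. A level with an empty
test pool is a recorded no-op. A level whose activity has no remaining
training positives raises, naming the level.

Base classifiers and their fixed settings: k-NN with 7 neighbours; CART
with unlimited depth; SVM with library defaults; Gaussian naive Bayes
(continuous features); logistic regression capped at 500 iterations.
Features are standardized (training-pool mean/sd, reapplied to the test
pool) for the scale-sensitive bases (k-NN, SVM, LR); CART and NB see raw
features. An `oracle` base (predicts 1 iff the true label equals the
current activity) exists for testing the cascade logic independently of
learning quality and is not offered on the CLI.

## Windows and features

Streams are segmented into windows of *w* samples overlapping by fraction
*p*; the step is `max(1, round(w·(1−p)))` with half-away rounding (so
144 samples at 80% overlap step by 29), and trailing samples that do not
fill a window are discarded. Presets: `inertia` (40, 50%), `wisdm`
(144, 80%), `uci` (128, 50%). Windows get the majority per-sample label,
ties going to the earliest-occurring label — deterministic and seed-free.
Boundary-spanning windows are kept and majority-labelled; they are
precisely the ambiguous segments the method is meant to confront.

Each window keeps one base feature per channel (the per-window mean — the
simplest collapse that preserves the published base-feature counts) and
adds ten statistics per acceleration axis, giving base + 30 columns
(3 → 33, 12 → 42). Conventions, chosen where the feature names admit more
than one reading:

- **std** — population form (ddof 0);
- **energy** — mean of squares, (1/w)·Σx², the common HAR convention;
- **IQR** — Q3 − Q1 with linear-interpolation quantiles;
- **entropy** — Shannon entropy in bits of the 10-bin histogram of the
  window over its own range; 0 for a constant window. A histogram entropy
  was preferred over spectral entropy for determinism without FFT
  conventions;
- **correlation** — Pearson r with the cyclic partner axis (x→y, y→z,
  z→x); defined as 0 when either axis is constant;
- **SMA** — mean of the trailing 5-sample moving-average series
  (partial windows at the start use the samples available), reducing the
  named moving-average feature to one scalar per axis.

These satisfy: std, IQR, energy ≥ 0; min ≤ median ≤ max; r ∈ [−1, 1];
entropy ∈ [0, log₂10]; scaling an axis by c > 0 scales
mean/median/max/min/std/SMA by c and energy by c², and leaves correlation
unchanged. The test suite checks each statistic against an independent
loop-and-formula recomputation on random windows.

## Synthetic streams: what they emulate, and what they do not

Each activity is a per-axis signal model

    baseline + amplitude·sin(2π·frequency·t + phase) + N(0, noise_sd)

with fixed axis phases (0, π/3, 2π/3) so the axes are cross-correlated.
Static activities (sitting, standing) are distinct offsets with small
noise; dynamic ones (walking, jogging) add sinusoids of different
amplitude and cadence. Outlier bouts are injected by *replacing* seeded
random non-overlapping spans (insertion would break the uniform sampling
grid) and relabelling them.

Default study conditions (used by the acceptance script and the recovery
tests; chosen once, as what a field practitioner would call a realistic
desk-scale stand-in): 20 Hz sampling (0.05 s), four known activities
cycling in 30 s bouts over 1200 s (~24,000 samples, ~1,200 windows at the
40/50% preset), plus three injected 60 s bouts of a fifth activity
(stair climbing). Outlier bouts are long relative to the window because
unknown activities in recorded datasets occur as sustained bouts, not
single windows; this also keeps boundary-mixed windows a small fraction
of the outlier windows. Splits are 70/30, seeded, train size
round-half-away.

What the generator does **not** emulate: real biomechanics (gait
harmonics, orientation drift, gravity decomposition), sensor artefacts
(clipping, dropped samples, jitter), inter-subject variability, and
class overlap. Passing the recovery tests therefore shows the cascade and
features are implemented correctly and behave as designed on separable
data; it does not certify detection rates on real recordings, where class
overlap drives both misses and overdetection.

## Raw-data cleaning

The raw accelerometer dialect is `user,activity,timestamp_ns,x,y,z` with
a trailing `;`. Cleaning never fails a file: blank lines, rows whose
field count differs from 6 (this covers duplicated columns and stray
separators), and rows with non-numeric numeric fields are dropped and
counted; exact duplicates (field-level equality after separator
normalisation, all six fields — no narrower key is defined by the format)
are dropped keeping the first. Cleaning an already-clean file drops
nothing. Processed tables only have their numeric labels mapped to text;
an unmapped label or ragged row is an error naming the row.

## The feed-forward comparator

A rectangular net — six hidden layers of 100 rectifier units — classifies
windows into the full multiclass label set *including* an explicit
outlier class, so unlike the cascade it needs labelled outlier examples
at training time; the two methods answer slightly different questions and
this semantic difference is documented rather than reconciled. Training:
adam with default rate, categorical cross-entropy, batch size 40, at most
100 epochs, early stopping when a seeded 10% validation split fails to
improve for 2 consecutive epochs. The early-stopping monitor is the
validation *score* (accuracy), the convention of the underlying
estimator; the alternative (validation loss) was left aside as the
tracked quantity is not fixed by the method description. Per-epoch loss
and validation-accuracy curves are returned for inspection and CSV
export.

## Evaluation conventions

ACC = (TP+TN)/(TP+TN+FP+FN), PP = TP/(TP+FP), SE = TP/(TP+FN),
SP = TN/(TN+FP). A measure with a zero denominator is reported as 0; an
all-zero matrix is an error. Multiclass tables reduce one-vs-rest to
per-class binary counts. Outlier accounting: a test record is a true
outlier iff its label lies outside A; `n_detected` = |predicted ∩ true|,
`n_overdetected` = |predicted \ true| (the negative statistic —
over-flagging known activity is the method's characteristic failure
mode), `detection_pct` = 100·detected/true (0 with an explicit flag when
no true outliers exist). Printed tables use two decimals with half-away
rounding.

## Problem sizes and determinism

The default synthetic conditions above (~1,200 windows, ~360 test
records) are the problem sizes the acceptance script and heavier tests
run at; property suites use small random datasets (tens of records)
because the invariants they check are size-independent. Every stochastic
step — generation, injection placement, splits, activity order, estimator
seeds — flows from a single integer seed, and a fixed seed reproduces
reports byte-for-byte.

## Known limitations

- Detection quality is order-dependent; the default random order matches
  the method's definition but a poor order can hurt real-data results.
- k-NN's detection hinges on unknown-activity rows being present in the
  training split as permanent negatives (see above); streams whose test
  split contains an activity absent from training entirely will be
  detected only insofar as the known classifiers reject it.
- The WISDM reader ingests one concatenated stream ordered by
  (user, timestamp); per-user stream splitting is left to the caller.
- No probability calibration, cost-sensitive thresholds, ROC/AUC, or
  majority-vote stabilisation.
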