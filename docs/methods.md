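# Methods

## Task model and scoring

The Emotion Hexagon task arranges the six basic emotions on a hexagon in
the cyclic order happiness–surprise–fear–sadness–disgust–anger, each
vertex adjoining the emotions it is most easily confused with
(anger–happiness adjoin to close the ring). Stimuli are blends of two
adjacent emotions at ratios 90:10, 70:30, 50:50, 30:70 and 10:90. The
majority ("dominant") emotion is the correct response; 50:50 blends have
no correct answer and are excluded from every derived measure. Each
emotion is dominant on exactly two continua at each intensity, so the
high-intensity (90%) and low-intensity (70%) accuracies aggregate over
both. Percentages are kept unrounded internally. A participant with zero
scored presentations in any of the 12 cells triggers an explicit
missing-cell error rather than a silent zero.

"Remote" errors are scored-trial errors whose response is neither the
dominant emotion nor one of its two hexagon neighbours; since the blend
partner is always a neighbour of the dominant emotion, a remote response
comes from the three unrelated vertices. The full 60-cell confusion set
(each (target, intensity) mislabelled as each other emotion) is exposed
together with a user-supplied subset selector; accuracy plus the
confusion percentages sum to exactly 100 per cell.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any individual-level ground truth:

- **Groups** — defaults 248 CD/HCU, 230 CD/LCU, 785 TD. ICU totals
  (0–72) are drawn from truncated normals (HCU 46 ± 6 on [39, 72], LCU
  22 ± 5 on [0, 29], TD 17 ± 8 on [0, 72]) and rounded, so the 39/29
  tertile cut-offs always hold by construction.
- **Covariates** — per-group means for age (years), total IQ (points,
  truncated at the study's IQ ≥ 70 inclusion bound), SES (z-units) and
  the female proportion mirror the published demographics; site is drawn
  uniformly from seven labels. Covariates act on the logit of the
  correct-response probability through configurable slopes (default 0),
  which keeps probabilities bounded.
- **Responses** — on scored blends the participant answers the dominant
  emotion with probability logit⁻¹(logit(p_correct[group, emotion,
  intensity]) + covariate terms). Default p_correct values put happiness
  highest and fear lowest (0.95 down to 0.78 at high intensity), drop
  uniformly by 0.06 at low intensity, and give small group deficits
  (HCU −4.5/−2.2 and LCU −2.5/−1.2 percentage points at high/low
  intensity) — a small overall group effect with a group × intensity
  interaction in which TD youths benefit most from added intensity.
  Errors put a `confusion_bias` mass (default 0.6) split equally on the
  dominant emotion's two neighbours and the remainder uniformly on the
  other three labels. 50:50 blends split (1 − noise) equally between the
  two blended labels with noise (default 0.1) uniform over all six.
- **Trial counts** — `reps_per_blend` (default 5) presentations of each
  of the 30 blend × ratio combinations per participant; the count
  identity n_participants × 30 × reps always holds exactly.
- One fixed facial identity is assumed (the task uses a single poser);
  there is no reaction-time or block-structure model.

All draws flow from one integer seed through `numpy.random.SeedSequence`
spawning, so identical specs give byte-identical tables.

What the generator does *not* emulate: item-level difficulty within a
blend, response biases that differ by participant, practice or fatigue
effects, site-by-group confounding, and any true association between CU
traits and recognition ability beyond the group-level offsets. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes, not that the structure holds in real cohorts.

## Residualization

Each feature column is OLS-residualized against an intercept,
mean-centred age/IQ/SES, sex (female = 1) and site indicators (first
level alphabetically dropped), then divided by the residual SD (n − 1
denominator). The default `pooled` mode fits on the whole sample before
any splitting, replicating the adjust-then-classify order of the
original analysis; because this leaks test-set information into the
adjustment, a `fold_safe` mode estimates coefficients and scale on a
training index set only and applies them to held-out rows. Both modes
are tested; pooled is the default and is what the resampled evaluation
uses. Rank-deficient designs and features fully explained by covariates
(residual SD < 1e-8) are rejected with specific errors; missing
covariates are rejected rather than imputed.

## Angle-GMLVQ

Dissimilarity d(x, w) = (1 − cos_Λ(x, w))/2 with Λ = ΩᵀΩ; the cosine is
invariant to positive rescaling of x, w and Λ, so predictions are
invariant to per-row rescaling of the features and the unit-trace
normalization of Λ is purely a reporting convention. Training minimizes
the Sato–Yamada cost Σ (dJ − dK)/(dJ + dK) with identity transfer, one
prototype per class by default, prototypes initialized at class means
plus seeded N(0, 0.01) jitter and Ω at I/√d.

Optimization is full-batch gradient descent on per-sample-mean analytic
gradients (so learning rates are independent of n) with defaults:
300 epochs, prototype rate 0.05, Ω rate 0.005, both decayed ×0.99 per
epoch. An epoch whose step would increase the cost is rejected and both
rates are halved, which makes the recorded cost trajectory
non-increasing by construction; Λ is re-normalized to unit trace after
each epoch (cost-neutral). Numerical guards: generalized norms below
ε = 1e-12 raise a degenerate-vector error (vectors are rejected, never
perturbed); dJ + dK below ε raises a degenerate-geometry error;
non-finite cost raises a divergence error naming the epoch. Prediction
ties (within 1e-12) go to the first class in sorted label order.

Relevance read-outs: the default schedule optimizes accuracy well but
stops while the metric is still adapting, which understates how
concentrated Λ's diagonal becomes. Analyses whose *object* is the
relevance profile (the relevance-recovery tests and the feature-ranking
stage) therefore train to convergence with 1000 epochs and decay 0.999,
otherwise identical settings. Analytic gradients are verified against
central finite differences at 1e-4 relative tolerance.

## Evaluation protocol

Stratified random 75/25 train/test holdout repeated 100 times; per-class
training counts are the class size × fraction rounded half-up, and every
class must appear in both partitions. Class imbalance is handled by
macro-averaged accuracy = (TPR + TNR)/2 rather than by rebalancing.
PPV/NPV/TPR/TNR with zero denominators are flagged missing, never
reported as zero. The chance test is an exact two-sided binomial test of
the test classifications pooled across the 100 runs against p₀ = 0.5 (a
convention; the per-run counts are exported so any other pooling can be
recomputed). Metric means carry normal-approximation 95% CIs across
runs. Relevance profiles are averaged over runs with macro accuracy at
or above the retention threshold — default 0.5, with 0.6 supported as a
stricter variant (both thresholds appear in the source literature on
such filters; the discrepancy is surfaced, not resolved) — and an empty
aggregate is an explicit error. Kruskal–Wallis comparisons of
per-feature relevance distributions use mid-ranks with tie correction
(via scipy) and a χ² reference distribution.

## Problem sizes in the test and acceptance suites

The chance-level pipeline property runs on a null cohort (identical
recognition probabilities in all groups, zero covariate slopes) at the
study-scale sizes 248/230/785 with `reps_per_blend = 10` — the same
conditions under which the generator's own null properties are stated.
At `reps_per_blend = 5` each cell rests on only 20 scored trials, the
features live on a 5-point grid with point masses at the 100% ceiling,
and the smallest comparison (HCU–LCU, n = 478) shows a genuine 2–4
percentage-point pessimistic resampling bias; this coarse-feature
behaviour is a limitation worth knowing about when the task is
administered with few presentations per blend. Relevance-recovery and
signal-injection checks use 2-class samples of 200–320 and 10–20 seeds.

## Known limitations

- The angle dissimilarity discards vector magnitude: a deficit that
  shifts *all* features equally changes mostly the magnitude and only
  mildly the direction of a residualized profile, and the comparison
  group's prototype (its class mean, near the origin in residualized
  space) has no stable direction. A uniform −1 SD shift therefore yields
  mean macro accuracy around 0.73 rather than the ~0.96 a
  magnitude-sensitive linear classifier would reach; the model is by
  design most sensitive to emotion-specific patterns.
- Pooled residualization leaks test information into the covariate
  adjustment; `fold_safe` exists precisely for sensitivity analyses.
- One prototype per class, no multi-class training beyond the four
  two-class tasks, no probabilistic outputs, no nested model selection.
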