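# Methods

`kage` implements an analysis pipeline for automated home-cage cognitive
phenotyping of singly housed mice, together with a synthetic-cohort
generator that emulates the data such a cage produces. This note records
the models, parameter choices, and numerical conventions behind each
stage, and what the synthetic validation does and does not demonstrate.

## The task structure being analyzed

A smart home cage couples three cognitive assays to passive monitoring:

- **Alternation task ("smart T-maze").** Two water spouts sit at the ends
  of two corridors; only the spout *opposite* the previously visited one
  dispenses water. A visit is *rewarded* iff its side differs from the
  previous visit's side. Because visits are self-paced, the inter-trial
  interval (ITI, the gap between successive visits) spans seconds to
  hours, and the success fraction as a function of ITI traces a working
  memory curve.
- **Novel-object / object-in-place recognition (NOR/OPR).** Two wall
  panels can each show one of 8 textures, rotated by drums once every two
  days during the dark phase. A NOR change presents a pattern new to the
  animal; an OPR change moves the pattern previously shown on the
  opposite wall. Recognition is quantified by panel exploration around
  the change.
- **Passive monitoring.** Wheel running, general locomotion, and
  quiescence ("naps": complete, continuous immobility lasting at least
  5 min), all split by the 12:12 light cycle (lights on 09:00, off 21:00).

## Synthetic cohort generator

The generator defines the study conditions for every downstream test.
All randomness flows from a master seed through `numpy.SeedSequence`
spawning, so cohorts are bit-reproducible and per-mouse streams are
independent.

**Alternation memory model.** The probability that a visit alternates
after an ITI of `t` minutes is

    P(t) = 0.5 + (p_max − 0.5 + c) · exp(−t / τ) − c

with asymptotic short-ITI success `p_max`, memory decay constant `τ`
(minutes), and perseveration offset `c`. The curve crosses chance and
settles at `0.5 − c` below chance at long ITI — mice tend to return to
the same spout once the previous choice is forgotten. The memory time
span (ITI at 50% performance) is `τ · ln((p_max − 0.5 + c)/c)`; the
control preset (`p_max = 0.78, τ = 5.3, c = 0.05`) puts it at 10.0 min.
No generative model is claimed by the assay itself; a single-exponential
decay is the minimal form with the right qualitative shape.

**Visit timing.** Drinking is a phase-modulated Poisson process of bout
initiations (light/dark rates per preset) with geometric follow-up visits
at short exponential gaps (p = 0.55, mean 40 s), because real mice drink
in bursts — this is what populates the sub-minute ITI bins. When the nap
process is supplied (the default in `make_cohort`), the visit rate is
zero during naps and compensated by the awake fraction of each phase, so
daily visit counts still match the preset.

**Quiescence.** An alternating renewal process per phase: exponential
awake gaps with phase-specific hazard (re-drawn at light/dark boundaries,
exact for a piecewise-constant hazard thanks to memorylessness) and nap
durations of 5 min plus a Gamma(3) excess whose mean hits the preset
phase mean. Naps never span a visit; a nap truncated below 5 min by an
upcoming visit is dropped. The renewal expectation reproduces the preset
phase fractions to within a few percent (light-phase total ≈ 0.8 × 720 =
576 min/day for the control preset); naps that start late in one phase
spill into the next, which slightly inflates dark-phase totals.

**Wheel, panel, locomotion bouts.** Marked Poisson processes with
phase-weighted rates (dark-biased), Gamma or exponential bout durations,
and rates inflated by `1/(1 − quiescent fraction)` because bouts landing
inside already-claimed time are trimmed away. After each drum change the
changed side's panel-bout rate is multiplied by
`1 + (boost − 1)·exp(−Δt/decay)`, and (when `boost > 1`) a first "notice"
bout is injected at an exponential latency (mean `notice_latency_mean`).
Overlaps are resolved by priority T-maze > quiescence > wheel > panel >
other-mobile, trimming lower-priority bouts; quiescence fragments under
5 min are discarded so the nap definition survives the merge.

**Pose rendering.** 2 Hz trajectories consistent with the ethogram:
anchored behaviors hold the body at the corresponding cage landmark
(corridors, panels, wheel, nest) with bout-scale jitter — sub-threshold
(< 2 mm summed over parts) during quiescence, a few mm otherwise — and
other-mobile/unlabeled segments follow a reflected random walk inside the
390 × 320 mm floor. Eight body parts are laid out along the heading with
fixed anatomical offsets. Rendering is deterministic given the seed.

**Group presets.** Preset means are anchored to the reported group
statistics wherever the source assay reports them (post-lesion values for
the lesion groups; late-period values for the amyloid model): the
hippocampal-lesion profile has low `p_max` (0.583), ~150 visits/day, high
locomotion (685 min/day), low wheel (61 min/day) and reduced quiescence;
the amyloid profile has low exploration, long light-phase naps, low
locomotion; the entorhinal profile is control-like except for markedly
shorter naps. Where the real-data contrasts are too small to support a
recovery benchmark at n = 5/group (the entorhinal group's nap shortening
in particular), the preset amplifies the contrast while keeping its
direction; the synthetic recovery experiment therefore demonstrates that
the pipeline recovers *separable* groups, not that real entorhinal mice
are this separable. Inter-mouse individuality is a multiplicative
lognormal jitter (CV 6%) on rates/durations and additive jitter on
probabilities.

## Behavioral labeling

- **Frame features.** 32 values per frame: (x, y) and (|vx|, |vy|) for 8
  body parts. Speeds are one-frame forward differentials (mm/frame),
  absolute value, then a centered rolling median over 81 frames (~40 s at
  2 Hz). At sequence edges the window shrinks rather than padding, so
  edge frames use genuine data only.
- **Quiescence rule.** A frame is motionless when the summed displacement
  of all 8 parts since the previous frame is strictly below 2 mm (the
  default threshold; configurable — the definition gives no number).
  Runs must be *continuously* motionless: a single supra-threshold frame
  splits the run, and only runs of at least 300 s are kept.
- **T-maze rule.** Beam-break events merge into one trial when less than
  2 s apart on the same side (sub-second spout re-entries are part of one
  drinking attempt; 2 s is conservative and configurable). A trial is
  accepted only if the snout is inside the corresponding corridor zone,
  and the interval expands over the full corridor dwell; beam events with
  the animal elsewhere are rejected and reported.
- **Classifier.** Panel exploration (L/R), wheel running and other
  locomotion are assigned by a random forest tuned with randomized 3-fold
  CV over a documented grid (trees 100–300, depth ∞/10/20, features per
  split sqrt/0.25/0.5, leaf size 1/2/5), trained on a seeded stratified
  80% split and scored (per-class precision/recall/F1) on the held-out
  20%. Full-ethogram assembly smooths frame predictions by majority vote
  over 1-min windows and overlays the rule-based labels with priority
  T-maze > quiescence > classifier.

## Phenotype metrics and the 32-feature table

ITI bins are log-spaced, 12 bins from 0.25 to 240 min; a bin is reliable
with ≥ 20 trials (configurable). Each bin gets an exact two-sided
binomial test against 0.5. The memory time span is the first downward
50% crossing, interpolated linearly between adjacent reliable bin centers
on a log-ITI axis; a curve that never exceeds or never crosses 0.5 yields
NaN. Calendar days run lights-on to lights-on. Quiescence intervals are
split at phase boundaries before accumulation; per-phase bout statistics
are computed on the split segments. Movement is time under the mobile
labels (wheel, panels, other-mobile), excluding T-maze dwell; speed and
distance come from the trajectory when one is available and are NaN
otherwise.

The 32 features (8 per category — alternation, NOR/OPR, quiescence,
wheel/locomotion) are fixed in `FEATURE_CATEGORIES`. The composition is
this package's own canonical stand-in: every statistic the source assays
report per animal is included, and the remainder are natural companions
of the same category. Undefined entries are imputed with the across-mice
median of the feature (zero if no mouse defines it), with an audit log.

## Statistics

Paired comparisons apply a Shapiro-Wilk gate (α = 0.05) to the paired
*differences*: parametric → paired t, otherwise exact two-tailed Wilcoxon
signed-rank (zeros dropped; exact null up to n = 25, normal approximation
with continuity correction beyond). Independent comparisons default to
Welch's t with a pooled-variance switch. Benjamini-Hochberg FDR
adjustment is applied independently within each behavioral category.
The binomial test is exact; the two-sided p sums outcomes no more
probable than the observed count.

The Wilcoxon sample-size calculation uses the asymptotic-relative-
efficiency method: the test is treated as a one-sample t test on an
effective sample of `n · 3/π` observations (normal parent), i.e.
df = n·ARE − 1 and noncentrality d·√(n·ARE), and the smallest integer n
with power ≥ target is returned by bisection on the monotone power curve.
At d = 2.5, α = 0.05 two-tailed, power 0.8 this gives n = 4. Note the
*exact* two-tailed signed-rank test cannot reject at α = 0.05 with n = 4
(minimum attainable p = 0.125); n = 4 is a property of the ARE
approximation, reported as such and not "corrected".

## Correlation analysis

Pearson correlations over all 32 features across mice; constant columns
are excluded with a warning. Significance thresholds per pair are the
95th percentile of |r| over surrogate tables in which every feature
column is permuted across mice independently — each feature is compared
only against shuffled values of itself, so feature types are never mixed.
A stricter whole-row block shuffle is available behind a flag. PCA runs
on z-scored features (unscaled PCA would be dominated by unit choices,
so the variance-explained figure is not comparable to analyses with
unknown scaling).

## Clustering and stability

Features are z-scored (population SD; constant columns → 0) before
Euclidean clustering. The semi-supervised search samples (algorithm,
hyperparameter) combinations across k-means, Bayesian Gaussian mixtures,
agglomerative linkage, OPTICS, spectral clustering and affinity
propagation (cluster counts 2–8), and retains only clusterings that place
all a-priori-known control animals in a single cluster — co-membership,
not purity, since the control cluster may legitimately absorb other
unlabeled normal animals. Candidates are ranked by mean Silhouette
(singleton clusters score 0).

**Final-model choice.** Raw Silhouette ranking systematically prefers
the coarsest split when one group lies much farther out than the rest
(here the hippocampal group), merging the remaining groups. The default
final model is therefore agglomerative ward/Euclidean with its cluster
count chosen by the gap statistic — log within-cluster dispersion
compared against column-permuted surrogates, with the one-standard-error
rule (elbow of the gap curve when no plateau exists). If the ward model
at the chosen count splits the known controls, the best-Silhouette
*sampled* candidate with the same cluster count is used instead (other
algorithms often keep the controls together where ward does not), then
nearby cluster counts, and finally the top-Silhouette candidate. This
is the package's automated stand-in for a final choice the original
workflow made after unblinding, which a reusable tool cannot do.

**Stability.** Leave-one-animal-out: each simulation removes one
uniformly drawn mouse (with replacement across simulations), re-fits the
same model, and records the re-fit's mean Silhouette and its ARI against
the original labels on the retained mice. Chance thresholds are the 95th
percentiles of the same statistics on column-shuffled surrogates.
Confusion matrices map clusters to groups by accuracy-maximizing
bipartite assignment; unmatched groups score 0 and are flagged. New
animals are assigned to the group with the smallest mean Euclidean
distance to member rows, after standardizing with the *reference*
table's means and SDs.

## Standard memory-test battery

d2 = (novel − familiar)/(novel + familiar). The familiarisation discard
rule uses the same normalization, |e1 − e2|/(e1 + e2) > 0.30 (strict),
since the rule's denominator is not specified by its source; a pair with
zero total exploration is discarded with a flag. Impairment thresholds
(performance < 0.70, |d2| < 0.04 NOR / 0.06 OPR) are strict, matching
"below"; a discarded task yields an absent flag, not False. The
performance band boundary 0.70 falls in the 60–70% band (fixed,
documented, otherwise arbitrary).

## Validation scale and limitations

The packaged validation workflows run at desk scale: the classifier
benchmark uses 4 mice × 2 days at 2 Hz with classes capped at 8,000
frames and 4 CV draws; the clustering recovery uses 10 cohorts of
4 groups × 5 mice × 30 days with 120 sampled clustering configurations
per cohort. Larger numbers sharpen the same conclusions.

What the synthetic data does not emulate: pose-estimation noise and
identity swaps, nest-dependent anchor drift, within-day nonstationarity
beyond the light cycle, sub-second nose-poke structure (visits are point
events), reward-volume effects, and correlated behavior (e.g. a mouse
that drinks more does not automatically nap less beyond the shared-time
constraint). Classifier F1 near 1.0 on rendered trajectories therefore
bounds pipeline correctness, not field performance on real video; the
same caveat applies to clustering accuracy, which depends on the preset
contrasts discussed above.
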