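# Methods

`efbdba` selects a small discriminative feature subset (candidate
biomarkers) from a labelled expression matrix with far more features than
samples. It is a two-stage hybrid: a statistics-only ensemble filter cuts
the dimensionality, then a wrapper search scored by a classifier picks
the final subset.

## Preprocessing

Order is fixed: duplicate-id averaging → Tukey outlier flagging → KNN
imputation → z-score.

* **Duplicate averaging.** Columns sharing a feature id are replaced by
  their per-sample mean; missing cells are excluded from the mean and a
  cell missing in every duplicate stays missing. First-occurrence order
  is kept.
* **Tukey fences** (`tukey_k`, default 1.5 — the classic inner fences;
  the source method names the test but not the multiplier). Quartiles use
  linear interpolation, the most common convention. Values outside
  `[Q1 − k·IQR, Q3 + k·IQR]` are re-flagged as missing. Features with
  fewer than 4 observed values are skipped. A constant feature has
  IQR = 0 and closed fences, so nothing is flagged.
* **KNN imputation** (`knn_impute_k`, default 5). Each hole is filled
  with the mean of the feature over the k nearest samples that have it
  observed. Distance is the root-*mean*-square difference over mutually
  observed features — the mean (not the sum) keeps samples with
  different missingness comparable. One pass on the original values:
  fills never feed back into distances, so the result is
  order-independent and deterministic.
* **z-score** uses the population SD (the transform plays a scaling
  role, not an inferential one). Zero-variance features become
  all-zeros rather than NaN.

## Stage 1 — ensemble filter

Two independent rankings are combined.

**Improved FCBF.** Relevance of a feature to the label is
`r_cf = 0.8·(1 − r_pn)` where `r_pn` is the absolute Pearson correlation
between the feature's positive-class and negative-class value vectors.
Unequal class sizes are first equalised by a SMOTE-style oversampler
whose interpolation is `s_i + rand·|s_i − s_j|` with an *elementwise
absolute* difference — the method's published variant, deliberately kept
instead of conventional SMOTE's signed step (`smote_k = 5` neighbours).
Because Pearson needs paired vectors and no pairing is canonical, both
class vectors are sorted ascending before correlating; this is the only
permutation-stable choice. The 0.8 weight guards against deleting
borderline features, and bounds `r_cf` in [0, 0.8].

Candidates with `r_cf` above a threshold (by default the 80th quantile,
i.e. the top 20% of features — `relevance_keep_fraction`; an absolute
`relevance_threshold` can be set instead) are processed in decreasing
relevance: the best remaining candidate becomes *salient*; every
remaining candidate whose |Pearson| with it reaches the candidate's own
relevance is eliminated (approximate Markov blanket); among each round's
eliminated features the one most *complementary* to the salient feature
is kept in a complementary set. Complementarity of a pair is the average
Manhattan distance, over `comp_draws = 20` randomly drawn samples,
between the sample and its heterogeneous (opposite-class) nearest
neighbour restricted to the two feature dimensions. The heterogeneous
neighbour is the opposite-class sample closest *in sample index* (ties to
the lower index), following the source's wording; a Euclidean variant is
available (`hetero_neighbor="euclidean"`).

**Fisher score.** `J = S_B / (S_w + 1e-12)` with the usual between- and
within-class variances; the top `fisher_top_k = 100` features are kept.

**Pool.** The candidate pool handed to the wrapper is the intersection of
the FCBF selection and the Fisher top-k; if the intersection is empty the
union is used (with a warning), because the wrapper needs a non-empty
pool.

### An honest note on the relevance score

Pearson correlation subtracts each vector's own mean, so `r_cf` is
*location-invariant*: a feature whose two class distributions differ only
in mean has the same `r_cf` distribution as pure noise. On synthetic data
built from class mean-shifts (this package's generator, and arguably most
planted-signal benchmarks) the FCBF branch therefore ranks features
essentially at random, and recovery of planted features is carried by the
Fisher branch — typically via the empty-intersection union fallback,
because the handful of FCBF survivors rarely lands inside the Fisher
top-k when the feature count is large. The ground-truth recovery harness
(100 samples × 1000 features, 20 informative, effect size 2) recovers all
planted informative features through exactly this mechanism; at smaller
feature counts the intersection is more often non-empty and recovery can
drop sharply. Passing recovery tests therefore demonstrates the ensemble
behaviour as specified, not that `r_cf` detects mean-shift markers — on
real microarray data, where class-conditional distributions differ in
shape and scale as well as location, the relevance score has more to work
with.

## Stage 2 — hybrid wrapper (BDBA)

Individuals are binary masks over the pool (1 = feature selected).
Published operating point: `G = 500` iterations, population `NP = 30`,
`P1 = 0.6`, `P2 = 0.4`, `alpha = 0.9`, scaling bounds
`f_min = 0.1`, `f_max = 0.9`. Initial masks are Bernoulli(0.5); an
all-zero mask (anywhere) is repaired by setting one random bit.

**Fitness.** `f = acc − β·num/L` while `β < 0.9`, else `f = acc`, where
`acc` is the stratified 5-fold CV accuracy of an SVM on the masked
features, `num` the popcount and `L` the pool size.
`β = ⌊g/100⌋·100/G + 0.1` steps up every 100 generations, shifting
pressure from subset size to pure accuracy in the endgame. Folds are
fixed once per run from the seed, so fitness is a pure function of the
mask and is cached by mask bytes. The SVM kernel is **linear with
C = 1** — the single most consequential unknowable of this
reimplementation, since the source never states its kernel; linear is
the field default for n ≪ p expression data (RBF via `svm_kernel`).

**IBDE step.** Scaling factor `F = f_min + ((G−g+1)/G)(f_max−f_min)`
(the printed form divides by `g`, which explodes early and contradicts
the stated requirement F ∈ [0,1]; the divisor is G, clamped). Mutation:
`diff_j = F·x_r1,j` where donors r1,r2 disagree, else 0; the trial bit is
1 iff `tanh(diff_j) ≥ rand` *and* `x_r3,j = 1` — so the mutant's support
is a subset of the third donor's and its expected size is at most
`popcount(x_r3)·tanh(F)`: sparsity pressure by construction. Crossover
uses `CR = α·2e^{−g/G}/(e^{g/G}+e^{−g/G})`, decaying from ≈α to 0.2384α,
with one guaranteed trial coordinate (jrand, the standard DE
convention). Selection is greedy at the current β; ties keep the
incumbent. Donors are drawn without replacement, excluding the target.

**BAVOA step.** During the first 40% of iterations
(`bavoa_fraction`) each individual draws a starvation rate
`SR = (2·rand+1)·z·(1−g/G) + t`, `z ~ U(−1,1)`,
`t = h·(sin^2.5(πg/2G) + cos(πg/2G) − 1)`, `h ~ U(−2,2)` (the original
vulture-optimizer form; the source delegates these formulas to its
citation). If `|SR| ≥ 1` the individual takes an IBDE step; otherwise a
vulture move: with `|SR| ≥ 0.5`, exploration — toward the leader
(`x_best − |2·rand·x_best − x|·SR`) with probability P1, else random
roaming (`x + (2·rand·x_r1 − x_r2)·SR`); with `|SR| < 0.5`, a transition
move — siege fight with probability P2, else a rotating flight around
the leader. The leader is chosen by random opposition: flip ⌊L/2⌋ random
bits of the best-fitness mask and keep the original with probability
equal to its (clamped) fitness. Continuous positions are binarized by a
shifted sigmoid `s = 1/(1+e^{−x−2})` with bit = 1 iff `rand > s` — note
the *inverted* inequality, kept verbatim from the published form; it
makes high positions unlikely to be selected and acts as another
sparsity pressure. Vulture children then compete with their parents
through the same greedy selection rather than replacing them, which
keeps the inversion from destroying good masks.

**Global best.** Archived separately from the population and ranked
lexicographically: higher CV accuracy, then fewer features, then first
found. The β-weighted fitness is time-varying, so raw fitness values are
not comparable across generations, but the archived accuracy trace is
non-decreasing by construction. Shared-vector `rand` draws (one scalar
per call) are used in the vulture moves, matching the scalar notation of
the update rules; `shared_rand_per_dim=True` switches to per-dimension
draws.

## Evaluation and biomarker statistics

Final metrics (accuracy, recall, precision, F1; positive class =
disease) are computed per CV fold and averaged; zero-denominator ratios
are 0 by convention. Per selected feature the report carries the
absolute Welch t statistic
`t = |mean_pos − mean_neg| / √(s²_pos/n_pos + s²_neg/n_neg)` (sample
variances, two-sided p on Welch–Satterthwaite df) and the fold change
`FC = mean_pos/mean_neg`. These are computed on the imputed,
pre-z-score matrix — fold changes of z-scored values are meaningless.
`FC` is reported as missing when the negative-class mean is zero.

## Synthetic data generator

Emulates the microarray regime (n ≪ p, binary labels, optional
imbalance): informative features are class mean-shifted Gaussians
(means ±effect_size/2, SD noise_sd); redundant features are near-copies
of informative ones (additive noise at 0.1·noise_sd); complementary
pairs are individually class-symmetric ±a mixtures whose joint sign
pattern carries the label (component signs agree in one class, oppose in
the other) — separable only jointly, which is what the complementarity
measure exists for; remaining features are label-independent noise.
Missing cells and 10-spread outliers are injected at given rates.
Defaults (100 samples, 1000 features, 20 informative, 10 redundant, 5
complementary pairs, effect size 2, unit noise, balanced classes) define
the standard recovery conditions used in the tests. What it does *not*
emulate: probe-level noise models, batch effects, heavy-tailed or
class-heteroscedastic distributions, correlated noise blocks — so
passing recovery tests here says nothing about those phenomena (see the
relevance-score note above).

## Numerical choices and degenerate inputs

* Pearson of a constant vector is defined as 0; Fisher scores are
  regularised by +1e-12 in the denominator.
* Welch t with zero pooled SE: (0, p=1) for equal means, (∞, p=0)
  otherwise.
* Empty masks score −1 (repair sentinel); repairs set one random bit.
* Quantile-based relevance threshold is clipped just below 0.8 so a
  degenerate all-equal relevance vector still yields candidates.
* All randomness flows from one `numpy` Generator seeded by
  `rng_seed`; the RNG draw order inside the evolution loop is documented
  in `efbdba.bdba` and relied on by a regression oracle test. Identical
  config + seed reproduces reports byte-for-byte.

## Problem sizes in the test suite

Unit and property tests run on toy instances (≤ 100 samples, ≤ 1000
features). The end-to-end search check uses 60 samples × 100 pool
features with `G = 100`, `NP = 20` — the wrapper dynamics (sparsification
then refinement) are fully exercised there while keeping the suite quick;
the published operating point `G = 500`, `NP = 30` is the config default.

## Known limitations

* The relevance score's location-invariance (discussed above) is
  inherited from the published design, not fixed here.
* Binary labels only; multi-class relevance is out of scope.
* The vulture moves implement the exploration and transition phases
  only; the original optimizer's late-exploitation phase is deliberately
  absent from the hybrid.
* No GEO/SOFT parsing or probe-to-gene annotation; inputs are plain
  CSV/TSV matrices.
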