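# efbdba

Two-stage biomarker (feature) selection for labelled expression
matrices — the microarray regime where features vastly outnumber
samples. For bioinformaticians who want a small, highly discriminative
gene panel out of a samples × features table with binary class labels.

**Stage 1 — ensemble filter.** An improved fast correlation-based filter
(FCBF): per-feature relevance `r_cf = 0.8·(1 − r_pn)` (with `r_pn` the
absolute Pearson correlation of the feature's class-wise value vectors,
class sizes equalised by SMOTE-style oversampling
`s_k = s_i + rand·|s_i − s_j|`), approximate-Markov-blanket redundancy
pruning (a candidate is dropped when its |Pearson| with a selected
salient feature reaches its own relevance), and a Manhattan-distance
complementarity measure that rescues, per pruning round, the eliminated
feature most complementary to the salient one. The FCBF selection is
intersected with the top-100 features by Fisher score
`J = S_B / S_w`; an empty intersection falls back to the union.

**Stage 2 — hybrid wrapper (BDBA).** Binary differential evolution with
a sparsity-inducing mutation (`u_j = 1` iff `tanh(F·x_r1,j) ≥ rand` and
`x_r3,j = 1`, with inertial scaling `F` decaying 0.9 → 0.1), an adaptive
crossover factor `CR = α·2e^{−g/G}/(e^{g/G}+e^{−g/G})` decaying from ≈α
to 0.2384·α, and greedy selection under the segmented fitness

```
f = acc − β·(num/L)   while β < 0.9,   f = acc  afterwards,
β = (⌊g/100⌋·100)/G + 0.1
```

where `acc` is stratified 5-fold CV accuracy of a linear SVM on the
masked features. During the first 40% of the iterations, individuals
with starvation rate |SR| < 1 instead take a binary African-vultures
move (opposition-based leader choice, exploration/transition position
updates, shifted-sigmoid binarization) and compete with their parents.
Defaults: `G=500`, `NP=30`, `P1=0.6`, `P2=0.4`, `α=0.9`.

Two published formulas are kept or corrected deliberately:

* the scaling-factor schedule is implemented with divisor `G`
  (`F = f_min + ((G−g+1)/G)(f_max−f_min)`): the printed divisor `g`
  yields F ≫ 1 early on, contradicting the stated requirement
  F ∈ [0, 1];
* the binarization threshold is kept verbatim as `bit = 1 iff rand > s`,
  `s = 1/(1+e^{−x−2})` — inverted relative to the usual transfer-function
  convention, and acting as a sparsity pressure.

See `docs/methods.md` for the full model description, parameter
meanings and known limitations.

## Worked example

Generate a small synthetic microarray-like dataset (60 samples × 200
features with planted informative, redundant and complementary
features) and run the full pipeline:

```sh
$ efbdba synth --out data --preset small --seed 0
wrote data/synthetic_small.csv (60 samples x 200 features) and data/synthetic_small_truth.json

$ efbdba run --input data/synthetic_small.csv --seed 0 --out results \
             --generations 60 --population 12
selected 5 features: g018, g064, g012, g176, g181
accuracy: 0.9000
recall: 0.9333
precision: 0.8881
f1: 0.9045
report: results/run_report.json
```

The run selected a 5-feature panel whose linear SVM reaches 0.90
five-fold CV accuracy (recall 0.93, precision 0.89, F1 0.90) on this
instance. `results/selected_features.tsv` lists each selected feature
with its absolute Welch t statistic, two-sided p-value and fold change
(computed on the imputed, pre-normalisation values), e.g. `g012` here has
t = 8.35, p ≈ 2·10⁻¹¹ — a planted marker recovered with strong
univariate support. `results/run_report.json` carries the config echo,
the per-generation best-fitness trace and the (monotone) best-accuracy
trace.

`efbdba filter` runs stage 1 alone and writes per-feature
`r_cf`/Fisher-score tables; the same functionality is available as a
library (`efbdba.build_pool`, `efbdba.evolve`, `efbdba.run_pipeline`).
Identical config + seed reproduces every artifact byte-for-byte.

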