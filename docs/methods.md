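# Methods

## The classifier

`deltamem` implements a difference-based associative-memory classifier for
labelled clinical tables, in two stages.

**Translation preprocessing.** Associative memories suffer from *cross-talk*:
interference between stored associations, driven by an order relation among
the stored patterns (a shared magnitude component), that saturates the memory
and degrades recall. Because cross-talk depends only on the patterns'
location, it can be removed by a pure per-attribute translation of the
fundamental set — the training set of associations
{(x^μ, y^μ) | μ = 1..p} — applied before learning:

    x_j  →  x_j − t_j ,   j = 1..n.

A translation changes no pairwise difference between patterns and no central
moment of any attribute, so the data's representation and distributional
shape are untouched; only the location moves. Three offset rules are
provided:

| mode     | offset t_j                    | notes                               |
|----------|-------------------------------|-------------------------------------|
| `mean`   | per-attribute mean (default)  | centres each attribute at zero      |
| `min`    | per-attribute minimum         | zero floor; exact on integer data   |
| `custom` | caller-supplied vector        | hook for any alternative rule       |

Mean-centering is the default because it removes the shared location
component directly and is idempotent. The transform is always fitted on
training data only and applied with the *training* offsets to held-out
patterns, so no test-set statistic leaks into evaluation.

**Delta associative memory.** Learning is single-pass storage: the memory M
keeps every translated association, grouped by class. Classification of a
query x^ω computes, for every stored pattern, the difference score

    d_μ(x) = Σ_j |x_j − x^μ_j|        (L1 aggregation)

and a *dynamic threshold* θ(x) recomputed fresh for each query. Under the
default **min-difference** policy, θ(x) = min_μ d_μ(x); the candidate set is
every stored pattern attaining θ(x), the predicted label is the majority
class among candidates, and ties break toward the smallest class index. The
difference operator is a pluggable strategy slot (`difference_fn` on
`DeltaMemory`), so a component-wise operator other than the absolute
difference can be substituted without touching learning or evaluation; L1
was chosen as the simplest operator faithful to a model "based on the
differences between patterns of different classes", and it keeps all
arithmetic exact on integer-coded attributes.

Because every stored pattern is at zero difference from itself, recall of a
conflict-free fundamental set is perfect — the classical correctness
contract for an associative memory, and the first property the test suite
asserts.

An alternative **scaled-magnitude** policy sets θ(x) = τ · (1/n) Σ_j |x_j|
and takes as candidates all stored patterns within that bound. Together with
`reject_enabled` it yields rejection behaviour: a query whose nearest stored
pattern is farther than the bound is returned unlabelled instead of forced
into a class. Rejection is off by default because benchmark protocols force
a binary decision for every test pattern; note that under the
scaled-magnitude bound predictions become sensitive to the absolute location
of the data, hence to the translation stage, whereas under pure
min-difference a global translation of both memory and query leaves
predictions unchanged.

Whether the memory should aggregate stored patterns into a single matrix or
retain them individually was a genuinely open design point; the stored-set
representation was chosen because perfect fundamental-set recall is then
provable and the brute-force oracle stays exact.

## Evaluation protocol

Binary diagnostic performance is reported as percentages from the pooled
confusion matrix (positive class = `presence` of disease, configurable):

    sensitivity (TPR) = 100·tp/(tp+fn)
    specificity (TNR) = 100·tn/(tn+fp)
    accuracy          = 100·(tp+tn)/total

A zero denominator yields NaN, never a silent zero. Printed reports round to
two decimals; full precision is kept internally. A rejected test pattern
counts as an error against its true class.

Generalization is assessed by k-fold cross-validation, k = 10 by default.
Folds are **stratified** even though plain k-fold would be the literal
protocol: sensitivity and specificity are class-conditional, and an
unstratified fold can contain no positives, leaving them undefined
(`stratified=False` restores the literal reading). Fold assignment shuffles
indices within each class with the run seed and deals the class blocks
round-robin with a single continuous counter, which guarantees both that
total fold sizes differ by at most one and that per-class counts per fold
differ by at most one (e.g. p = 270, k = 10 gives ten folds of 27;
p = 135 gives five folds of 14 and five of 13). The headline aggregate is
the pooled (summed) confusion matrix over folds — every pattern is tested
exactly once, so pooled totals equal p — with the mean of per-fold metrics
reported alongside; which aggregate a given published table used is often
unstated, so both are emitted.

The only randomness anywhere is the fold shuffle (and the synthetic
generator); learning and classification are fully deterministic, so a run
is reproducible from (data, k, seed, config) alone.

## Synthetic data generator

The generator emulates two binary coronary-artery-disease screening schemas
so the whole stack runs without any external download:

* `ehealth-like` — six attributes: age (years), sex (0/1), maximum heart
  rate achieved (bpm), resting ECG category {0,1,2}, fasting blood sugar
  > 120 mg/dL flag, resting blood pressure (mmHg); default 135 samples.
* `heart-like` — thirteen numeric/categorical attributes in the same style
  (adds chest-pain type, cholesterol, exercise-induced angina, ST
  depression/slope, vessel count, thalassemia code); default 270 samples.
* `toy` — two Gaussian attributes for hand-checkable examples.

The class-conditional model is deliberately simple: attributes are sampled
independently, truncated normals for numerics (integer-rounded where the
quantity is integer-coded) and categorical draws for discrete codes. The
`separation` knob shifts the diseased class by that many standard deviations
on maximum heart rate (down) and resting blood pressure (up) and tilts the
categorical probabilities proportionally; `separation = 0` makes the two
class-conditional distributions identical, so accuracy must sit at the
majority rate. Value ranges (age 25–80, heart rate 70–200, blood pressure
90–190) are plausibility fixtures, **not** estimates from any real cohort;
the default class balance of 0.5 is likewise a fixture.

What passing tests therefore show: the classifier's contracts (recall,
oracle equivalence, protocol invariants) and its monotone response to class
separation under an independence model. What they do not show: performance
on real clinical data, whose attributes are correlated, whose class balance
is unknown, and whose noise is not truncated-normal. No attempt is made to
match real marginals.

## Numerical choices

* Candidate-set membership uses exact equality when memory and query are
  all-integral (the clinical encodings), and tolerance 1e−9·n otherwise, so
  candidate sets are reproducible across platforms.
* Offsets are stored at full double precision, never rounded. Translation
  preserves pairwise differences *bit-exactly* whenever values and offsets
  are exactly representable (integer data with min-shift or integer custom
  offsets). Mean offsets are arbitrary reals, so each translated value
  rounds once and differences can move by a few ulp at the data's
  magnitude; tests bound this at 4 ulp. Central moments agree to machine
  precision at the magnitude of scaleᵏ.
* Tie-breaks: majority vote within the candidate set, then smallest class
  index — deterministic and independent of storage order.
* Degenerate inputs: an empty fundamental set, a single-class training set,
  a class with fewer than k members under stratification, and dimension
  mismatches all raise typed errors; metric ratios with zero denominators
  return NaN.

## Problem sizes used in the checks

The property suite and the acceptance script run entirely on generated
data: 100 random fundamental sets up to p = 200, n = 13 for the recall
contract; 1000 (memory, query) instances up to p = 50, n = 10 against the
brute-force oracle; the exhaustive confusion-matrix grid up to counts of
30; and 10-fold cross-validation on 135-sample cohorts averaged over 20
generator seeds for the separation sweep. The whole suite completes in a
few seconds on one CPU.

## Known limitations

* The stored-set memory is O(p·n) per query; no indexing is attempted
  (p is at most a few hundred in the intended setting).
* Only binary classification is exercised by the evaluation stack, although
  the memory itself stores any number of classes.
* ARFF support covers numeric and nominal attributes only; strings and
  dates are rejected.
* With the default min-difference policy the classifier is equivalent to a
  1-nearest-neighbour rule under the L1 metric with majority tie-breaking;
  the translation stage then matters for serialization, for the
  scaled-magnitude/rejection bound, and for cross-talk removal in any
  substituted difference operator, but cannot change min-difference
  predictions themselves.
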