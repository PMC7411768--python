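# Methods

This note records the model, the defaults and the design decisions behind
`eagafs`, in the spirit of a model-documentation page: what the selector
assumes, which knobs matter, and what the test evidence does and does not
show.

## Problem setting and encoding

The selector operates on a tabular dataset: an ordered schema of numeric
and/or categorical attributes, row-major values with an explicit missing
marker, and a binary class label (1 = disease present). Candidate attribute
subsets are fixed-length binary chromosomes over the schema; the all-zero
chromosome (empty subset) is inadmissible everywhere — any operator result
that would be all-zero has one uniformly chosen bit set instead, because
the wrapper fitness is undefined on an empty subset.

## Initialization stage

Numeric columns are binarized against a threshold equal to the rounded
column mean (cell ≥ threshold ⇒ 1); categorical columns against their modal
token (highest occurrence rate ⇒ 1). Rounding follows print conventions:
integer-valued columns round to the nearest integer, real-valued columns to
one decimal (configurable to no rounding; numpy half-to-even applies at
exact ties). Missing cells binarize to 0 by default — absence of evidence
of the symptom — with mean-imputation available as a switch; missing cells
are always excluded from the mean itself.

The attribute with the minimum per-column 1's count is then eliminated
deterministically (ties: leftmost column). The same elimination-by-count
rule is applied once more to the final population at the end of a run, and
the survivors are ranked by descending count with the same leftmost
tie-break. The initial population is drawn uniformly without replacement
from the 2ⁿ − 1 admissible bitstrings by rejection sampling, so it contains
no duplicates and no all-zero mask.

## Fitness

fn(x) = MPR + ff · z/n, with MPR the misprediction rate (1 − held-out
accuracy) of a classifier trained on the selected columns, z the number of
excluded attributes and ff = 0.5. The penalty is normalized by the
chromosome length n: with raw z and ff = 0.5 every mask missing even one
attribute would score ≥ 0.5, swamping any error signal; the normalized form
keeps the two terms on comparable scales. A `normalize_z=False` switch
restores the raw form. Note the penalty's direction: it charges for
*excluded* attributes, so dropping a column must pay for itself through
accuracy.

The inner evaluation protocol is a seeded stratified 60/40 holdout split
(resubstitution available for stubs and diagnostics). The default inner
classifier is a standardized perceptron run for 10 epochs: wrapper
selection cost is dominated by fitness calls, and a few-epoch linear
learner is a deliberate fast surrogate for the full MLP used at evaluation
time. Any sklearn-style estimator factory can be substituted. Fitness is
deterministic given (dataset, config), so evaluations are memoized per
mask; an audit log of first evaluations (chromosome, MPR, z, fn) is kept.

Ranking is ascending in fn (lower fitness = higher priority), with ties
broken by fewer zeros, then lexicographic bit order, making ranks a
deterministic bijection onto 1..P.

## Search loop

Per generation: (1) evaluate and rank; (2) pair the top ⌈CRR·P⌉ (rounded up
to even, capped at P) chromosomes in rank order and apply 2-point crossover
with uniformly drawn cut pair 0 ≤ c1 < c2 ≤ n exchanging the half-open
segment [c1, c2); (3) elitist variants merge the pre- and post-crossover
populations and keep the best P (duplicates collapse to their better
record, with best-first re-admission to restore size); (4) ⌈MRR·P⌉
uniformly chosen chromosomes get a 1-bit flip. Population size is constant
throughout.

In the elitist variants the current best chromosome is exempt from the
mutation draw. This is the package's own choice: without it a flip could
destroy the retained optimum and the defining guarantee of elitism —
best-so-far fitness never worsens — would fail.

Rate adaptation: each crossover logs |fn(parent₁) − fn(parent₂)| (COV),
each mutation |fn(new) − fn(old)| (MTV); absolute values make the
per-generation means CMα and MMα interpretable as mean operator effect
sizes. At generation close, CMα > MMα raises CRR by q and lowers MRR by w;
CMα < MMα does the reverse; exact equality changes nothing. Rates are
clamped to [0.05, 0.95]. A generation with no events of a kind contributes
a mean of 0 by convention. Defaults: CRR₀ = MRR₀ = 0.20, q = w = 0.05, all
configurable — initial rates of 20% match the method's stated operating
point, and 0.05 steps let the controller traverse the full bound range
within a typical 100-generation budget.

Restrict mutate (EAGA, final generation only, all chromosomes): if a
chromosome's fn is below the threshold — default the median fn of the final
population — its leftmost (highest-order) zero bit is set; otherwise its
rightmost (lowest-order) zero bit; all-ones chromosomes pass through.
"Upturn" is read as set-to-1, never clear.

Termination is a fixed k generations (default 100); no convergence
early-exit.

Variant matrix: GA = neither elitism nor adaptation; E-GA = elitism only
(fixed 20% rates); A-GA = adaptation only (no elitist merge — its
pseudo-code omits it, so we exclude it); EAGA = both plus restrict mutate.
All four end with the final 1's-count elimination and ranking, so results
have a uniform shape.

## Evaluation harness

The reference classifier is an MLP with one hidden layer of
⌈(attributes + 2)/2⌉ units by default, SGD with learning rate 0.1 and
momentum 0.9, inputs standardized, trained for a fixed epoch budget
(default 100; non-convergence is not an error). Every weight and bias is
projected into [−0.5, 0.5] after each epoch — an overfitting control by
bounded network complexity. The projection is applied per epoch rather than
per weight update because the underlying library exposes epoch-level
`partial_fit`, not per-update hooks; the invariant |w| ≤ 0.5 still holds at
every epoch boundary and at the end of training.

Metrics: accuracy = (tp+tn)/total, precision = tp/(tp+fp), recall =
tp/(tp+fn), F = 2PR/(P+R), all reported in percent; zero-denominator ratios
are reported as 0 with an explanatory flag rather than NaN. Latency = model
build time + prediction time, reported but never asserted (hardware
dependent). k-fold cross-validation reports per-fold metrics plus their
arithmetic mean (summed confusion kept for audit); folds whose training
share lacks a class are skipped with a warning. Every emitted report
satisfies the F-score and accuracy identities by construction — this is
checked by test rather than assumed.

The accuracy comparison test is the pooled two-proportion one-sided z-test
on the proportion scale: S = (ā₁ − ā₂)/√(2ā(1−ā)/m) with ā = (y₁+y₂)/2m,
rejecting at S < −z₁₋α. With equal per-model sample sizes this is
algebraically the standard pooled z-test, which an independent library
implementation cross-checks in the test suite. The statistic is undefined
(and reported as such) when ā ∈ {0, 1}. Mixing percentage-scale accuracies
into the proportion-scale variance inflates |S| by a factor of ~100; the
implementation therefore keeps every quantity on the proportion scale.

## Synthetic data generator

`generate` emulates a small clinical screening table: labels drawn
Bernoulli(class_balance); informative columns class-conditional Gaussians
N(μⱼ, σⱼ) vs N(μⱼ + d·σⱼ, σⱼ) with per-column location μⱼ ~ U(10, 150) and
scale σⱼ ~ U(5, 40) drawn once per table (clinically plausible magnitudes
for vitals-like measurements); noise columns class-independent; optional
integer rounding with clipping at 0 for count-like columns; missing cells
injected completely at random. Defaults — 800 rows, 5 informative at effect
size d = 1.5, 10 noise, balanced classes (the conventional default when no
prevalence is modelled), no missing cells — define the package's standard
recovery benchmark.

What the generator does *not* emulate: inter-attribute correlation,
informative missingness, heavy tails, label noise, or categorical
attributes. Passing recovery tests therefore show the selector separates
independent mean-shifted signal from independent noise; they do not
establish performance under correlated or non-Gaussian clinical data.

The 15-row worked-example table is packaged verbatim as a fixture. It has
no class column; its labels default to an all-zero placeholder (label-free
operations only), and a synthetic plasma-glucose-threshold labelling rule —
explicitly a stand-in, not clinical truth — is available where fitness
evaluation needs two classes.

## Problem sizes used in the shipped checks

The acceptance-style checks run EAGA at 50 generations with population 20:
against exhaustive search over all 63 subsets of 6 attributes (20 seeds),
and for planted-attribute recovery on the 800 × 15 benchmark (20 seeds).
Elitism monotonicity is checked over 100 generations × 20 seeds on a
deterministic fitness stub. These sizes exercise every code path at full
method strength while keeping a complete test run on a single CPU
comfortable.

## Known limitations

- The wrapper's default perceptron surrogate can mis-rank subsets whose
  value is non-linear; substitute the full MLP factory when fidelity
  matters more than speed.
- The zero-count penalty biases the selector toward larger subsets by
  design; it eliminates attributes through the final count rule rather
  than through sparse masks.
- Binary classification only; no multi-class labels, regression targets or
  sparse formats.
- The initialization elimination is data-driven and happens before the GA
  sees fitness; on weakly structured data it can discard a genuinely
  informative attribute, which the GA cannot recover.
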