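# Methods

## The model

The architecture is a neural additive model over DNA sequence: `U`
independent units, each a single-filter convolutional network emitting one
scalar per sequence, combined by one linear layer with `T` outputs and a
per-task bias. A unit is

    conv(1 filter, 4 × W, valid, no bias) → batch norm → exponential
    → max pool(kernel 7, stride 7)
    → FC(100) → batch norm → ReLU → dropout(0.3)
    → FC(1) → batch norm → ReLU

with `W = 19` by default. The exponential activation after the convolution
sharpens the correspondence between filters and motifs; the final ReLU makes
unit outputs non-negative, so the sign of a unit's task contribution lives
entirely in the final-layer weight. The convolution carries no bias term:
batch normalization follows immediately and its shift parameter absorbs any
offset. The convolution is un-padded (valid), so its output length is
`L − W + 1`; dropout is applied only after the first FC layer's ReLU, as in
the unit definition above. Batch-norm parameters are strictly per-unit —
unit independence (nullification, importance, pluggability) requires that no
parameter is shared across units.

A `global_max_pool` variant replaces everything after the exponential with a
global max over positions, reducing each unit to an independent motif-scan
score. It is the ablation used to localize where positional/cooperative
information is learned (in the FC layers).

The forward pass, hand-derived backpropagation, and Adam are implemented in
NumPy (float64). The architecture is fixed and small, so a framework adds
nothing; the backward pass is verified against central finite differences in
the test suite. The exponential's pre-activation is clipped at 20; after
batch normalization pre-activations are order-1, so the clip never binds in
practice (it exists to make pathological parameter states non-fatal).

Evaluation mode uses batch-norm running statistics (momentum 0.1, unbiased
variance, eps 1e-5) and disables dropout; evaluation is therefore
deterministic and supports single-sequence inference. Training batches of
size 1 are skipped (batch statistics would be degenerate).

## Training

Adam, learning rate 0.003, batch size 100. Losses: binary cross-entropy on
post-sigmoid outputs for binary multi-task labels, softmax cross-entropy for
multiclass (e.g. selection cycle as class), mean squared error for
regression. The model's final layer stays linear in all cases; squashing
lives in the loss. Training and validation sets are augmented with the
reverse complement of every sequence (same labels). Sequences containing N
are discarded, never imputed. Early stopping monitors validation loss with
patience 10 (configurable); the returned model is from the best validation
epoch. Validation loss rather than a task metric is monitored so the same
rule covers all task types. `max_epochs` defaults to 100. Runs are
deterministic given the seed (single-threaded).

PBM-style intensities can be rank-mapped to uniform quantiles
(`quantile_normalize`): rank r of n maps to (r − 0.5)/n, ties by average
rank.

## Interpretation

Filter visualization: for each unit, record the position and value of its
maximum post-exponential activation per sequence (ties to the lowest
position; evaluation-mode batch norm); the unit's dataset-wide maximum is
taken over the interpretation set itself, including reverse complements when
they are part of it. Sequences that are correctly predicted and reach ≥ 50%
of that maximum contribute their aligned W-mer to the unit's PFM. PFMs are
converted to PWMs with a pseudocount of 1 distributed uniformly
(0.25/base) and log2 odds against a uniform 0.25 background.

"Correctly predicted" is per task for binary labels (post-sigmoid ≥ 0.5
equals the label; a sequence qualifies for PFM construction if correct on at
least one task — configurable to all tasks); argmax agreement for
multiclass; for multi-task regression, per-sequence Pearson across tasks
≥ 0.75; for single-task regression (not covered by the multi-task
convention) a sequence qualifies if its absolute residual is at or below the
median — the better-predicted half. All predicates are exposed as options.

Unit importance for (u, t) is the median of `f_u(x) · w_{u,t}` over
sequences correct on task t that activate u's filter at ≥ 50% of its
maximum. Empty qualifying sets yield an explicitly undefined (NaN) median,
never 0. Nullifying a unit zeroes its final-layer weights on a copy; by
linearity the per-sequence prediction change is exactly
`−f_u(x)·w_{u,t}`, which makes nullification an exact oracle for the
importance scores — the test suite asserts the identity to 1e-5 and the rank
agreement (Spearman) between median importance and mean nullification impact
over the same qualifying population. Weight heatmaps must be read jointly
with importance: a unit can carry a sizable weight yet near-zero importance
when the model does not actually use it, and such units can have
counter-intuitive weight signs.

Annotation against a motif database uses, by default, an internal
similarity: best Pearson correlation of probability columns over all offsets
(minimum overlap 5 columns) and both strands, threshold 0.8. An external
Tomtom backend (q ≤ 0.05) is wired in for environments that have the binary;
its absence produces an error that points to the internal backend.

## De novo motif discovery

Train one model (default 100 units) on the labeled set, extract one PWM per
unit from the validation sequences, drop units with empty PFMs, rank by unit
importance (positive class for binary; last cycle for multiclass; the single
output for regression), and evaluate each PWM by best-hit scanning — the
maximum sum of log2 odds over all windows on both strands — scored by AUPRC
(classification) or Pearson against the signal (regression). The best PWM is
chosen on validation. AUPRC uses step integration over distinct score
thresholds (no linear interpolation), pinned by an exhaustive-threshold
oracle in the tests.

## Filter initialization from motif databases

Profiles are resized to the filter width: wider profiles keep the
maximum-information-content window (ties leftmost; a center-trim strategy is
also provided since the choice is not canonical), narrower ones are padded
with uniform columns, the extra column on the right. Redundancy is removed
by farthest point sampling on a motif-similarity matrix (distance
1 − similarity; first pick maximizes mean distance, later picks maximize the
minimum distance to the selected set, ties by id). The internal PWM
similarity supplies the matrix by default; externally computed similarities
can be imported from TSV. Each selected profile and its reverse complement
initialize one filter as `probabilities − 0.25` (zero column sums).
Freezing is implemented as gradient nullification: frozen filters receive
zero gradients and remain bit-identical through training while the FC and
final layers keep learning.

## Cooperativity analysis

For motifs A and B and a predictor f, embed A's consensus at the center of
random GC-0.5 backbones, place B (or the control 5-mer GGGCT) at signed
edge-to-edge distance d, and compute per backbone

    residual(d) = f(AB) − f(A) − f(B at d) + f(backbone)

with fold change 2^residual (a ratio-scale alternative is exposed for
strictly positive outputs; the double difference is exact for log-scale
outputs). Additive predictors give residual 0 at every distance — a property
test asserts this to 1e-6. Profiles store per-backbone residuals; the
summary statistic is the near-vs-far window contrast (mean residual at
|d| ≤ window minus |d| > 25). Overlapping or out-of-bounds placements are
skipped and reported. Default 256 backbones, distance grid every 1 bp.

Flatness (no distance dependence) is judged by the window contrast against
the per-distance standard error across backbones. Two deliberate choices:
deviations are measured as a contrast rather than a max over ~60 per-distance
z-scores (a max over many correlated comparisons flags pure noise), and the
SE scale is the per-distance SE rather than the backbone-paired SE of the
contrast — the pairing cancels shared-backbone noise so completely that
systematic offsets below 0.01 log2 units (sub-1% fold changes) would read as
significant.

## Synthetic data

Sequences are i.i.d. draws from a GC-parameterized background; motif
instances are embedded at controlled frequencies and positions and recorded
in a ledger (sequence, motif, start, strand, instance string). Labels follow
the declared rule exactly — presence, linear counts, or linear counts plus a
pairwise proximity bonus — with optional Gaussian noise; the rule parameters
are emitted alongside for parameter-recovery checks. GC-matched negatives
are drawn per 5-percentage-point GC bin with adjacent-bin borrowing (logged;
an exhausted pool raises with a per-bin deficit report). Dinucleotide
shuffling uses the Altschul–Erickson Eulerian-walk construction, preserving
the exact dinucleotide count multiset, length, and first base.

For the pairwise rules the generator plants structured pairs: with
probability `pair_prob` a pair at a distance drawn from `pair_distances`,
otherwise a single instance or background. Heterotypic datasets additionally
include homotypic pairs (A+A, B+B) *without* the bonus, so that mere
proximity of two activation peaks cannot predict the label — the
identifiability structure the heterotypic claim rests on.

What the generator does not emulate: ChIP-seq peak shape and read-level
noise, chromatin context, motif grammar beyond pairwise proximity, and
genomic background correlations beyond GC content. Passing benchmarks
demonstrate correctness of the machinery and recoverability under the
declared generative model, not performance on real data.

## Benchmark conditions

The standard experiments (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: an 8-bp planted motif with consensus-base
probability 0.95 — sharp enough that the ground-truth PWM itself separates
planted from background sequences (best-hit AUPRC ≈ 0.97), so recovery
quality rather than motif degeneracy is what is measured; 5,000 sequences of
100 bp for recovery (10 units, ≤ 30 epochs); 10,000 sequences for the
cooperativity datasets (20 units, ≤ 40 epochs), with 12-bp motifs so that
two instances cannot fit inside one 19-bp filter — otherwise even the
global-max-pool ablation can detect tight pairs through a single composite
filter, which would test filter width rather than the FC layers; training
instances for count-based labels are planted as consensus so the planted
count is an identifiable function of the sequence (a PWM-sampled degenerate
instance changes the label while being nearly invisible); 2,000 sequences
for the initialization benchmark (8 units, 8 epochs, 3 seeds); 6,000 for
linear effect-size recovery (20 units). These sizes keep each experiment in
the minutes range on one CPU with comfortable statistical margins.

## Known limitations

- A unit applies its nonlinearity to *one* filter's scan, but a single
  filter can respond to two different motifs at once (its weights can
  approximate the average of both consensus patterns). In a clean two-motif
  task the summed peak heights then distinguish an A–B pair from A–A or B–B,
  and the measured heterotypic window contrast is ≈ 0.3 of a 1.0 bonus —
  the architecture partially captures heterotypic proximity even though its
  units are independent. The corresponding acceptance assertion expects a
  flat heterotypic profile and is left failing deliberately; the behavior is
  a genuine property of the architecture under these conditions.
- Receptive fields are limited to one convolution plus pooling; analyses
  requiring long-range context are out of scope.
- Checkpoints cover native models; plugged-in submodels are reconstructed in
  code, not serialized.
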