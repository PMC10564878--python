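# Methods

## Model

The network is a strictly layered feed-forward classifier built on a
knowledge DAG. Layer 0 holds input feature nodes — three per gene
(mutation, copy-number amplification, copy-number deletion indicators);
layer 1 holds gene nodes; deeper layers hold pathway nodes. Edges only run
from layer *L* to layer *L* + 1, and each transition's weight matrix is
element-wise masked by the DAG's adjacency, so a hidden node receives
input exclusively from its known biological parents. Hidden activations
are tanh (bounded and sign-carrying, which suits secant-slope
attribution); a single sigmoid head follows the last hidden layer. The
head is modeled as an extra unmasked transition in the layer list, which
doubles as the hook where per-layer auxiliary heads could be attached; the
prediction output is *not* a DAG node, and centrality is computed over
input and hidden nodes only, so that gene-layer reachability has its
textbook value (indegree + 1 = 4 with three feature types).

Training minimizes binary cross-entropy with minibatch Adam
(lr 0.01, batch 32, β₁ = 0.9, β₂ = 0.999, up to 150 epochs). Early
stopping watches validation loss with patience 15 and restores the
best-validation weights, which stabilizes importance scores across
replicates. Masks are re-applied after every update, so masked entries are
exactly zero at all times, not merely small. Optional L2 weight decay
(default 0) is available; note that decay shrinks the never-used random
weights that carry part of the structural bias signal, so switching it on
changes what the deterministic control measures. All randomness flows from
two named seeds — `split_seed` (partitioning) and `init_seed` (weights and
minibatch order) — making every run bit-reproducible. The implementation
operates directly on numpy arrays: the networks in scope have thousands of
weights, and keeping forward, backward and update arithmetic explicit is
what lets the attribution code walk the identical graph backwards.

Weights initialize uniformly on ±1/√fan-in, with fan-in the *masked*
in-degree of each unit (minimum 1); biases start at zero.

## Attribution

Hidden-node importance uses the rescale rule: each nonlinearity gets the
multiplier (f(z) − f(z₀)) / (z − z₀) between actual and reference
pre-activations, with the exact gradient substituted when
|z − z₀| < ε = 1e-7. Multipliers chain backwards through the linear
layers; a node's per-sample contribution is its activation delta times its
multiplier to the output. Because linear layers propagate deltas exactly,
each layer's contributions sum to output(x) − output(x₀) (completeness);
the test suite enforces this within 1e-6 relative on random and trained
networks. The reference input is all zeros — no mutation, neutral copy
number, a wild-type patient — and is configurable.

Per-node scores default to the mean absolute contribution over the test
partition: unseen samples avoid rewarding memorization, and the absolute
value is robust to the sign flips replicate networks frequently show.
Signed-mean and sum-of-absolutes aggregation are selectable and recorded.
Scores are then degree-normalized (divided by indegree + outdegree) by
default, mirroring the normalization such models conventionally apply to
damp hub nodes; it is a local correction and demonstrably leaves the
global, reachability-driven bias in place, which is the point of the
controls.

## Control setups

**Deterministic inputs.** Every positive-class sample receives the
per-block fill value in every gene (mutation 1, raw copy-number 2 — above
the +1.5 amplification cutoff); every negative-class sample is wild-type
zeros. On an already-thresholded cohort the amplification indicator is
filled with 1 and the deletion indicator stays 0 in both classes
(positives are "mutated and amplified", so deletion features carry no
signal, exactly as the raw construction implies after thresholding). Each
raw feature alone then separates the classes perfectly, training is
trivial (AUC ≈ 1), and any spread in node importance reflects network
structure alone. The transform is idempotent and label-preserving.

**Shuffled labels.** Labels are *re-drawn*, not permuted: ⌊n/2⌋ samples of
one class and ⌈n/2⌉ of the other, uniformly over such labelings given the
shuffle seed; for odd n the positive class takes the extra sample (a
deterministic, documented tie-break). A permutation mode that preserves
the original class ratio is provided for imbalanced cohorts. After
relabeling, the train/validation/test split is re-drawn from `split_seed`
so stratification still holds.

## Experiment grid

A plan is setups × replicate seeds. Each integer replicate seed expands
via a splitmix64 stream (mixed with the plan's `base_seed`) into
(split_seed, init_seed, shuffle_seed), so one seed column identifies a run
completely. Runs write JSON manifests keyed on (setup, seed, config hash);
re-running a finished grid retrains nothing, and a failed run is recorded
while the grid continues. Importance matrices (node × `setup:seed`
column), a metrics table and per-run ROC curves are exported as CSV.

## Score analysis

Quantile normalization follows the limma `normalizeQuantiles` semantics:
each column is replaced by the row-mean of the column-sorted matrix,
mapped back by rank, with within-column ties receiving the mean of the
values their ranks span. It is applied **jointly** to the concatenated
original + control columns over all hidden nodes (a per-layer variant is a
one-liner via `DataFrame.groupby`; global is the default because the
importance scale differences between setups are exactly what the
normalization must remove). Averaging across replicates happens *after*
normalization; differential = mean normalized original − mean normalized
control, with shuffled labels as the default control and a per-layer rank
attached. The operation is antisymmetric by construction.

Cross-setup comparison uses Pearson correlation between importance
columns, complete-linkage clustering on 1 − r, and a newick export of the
dendrogram (leaf labels quoted, since `setup:seed` contains newick
metacharacters). Betweenness uses directed fractional counting
(σ_st(v)/σ_st, unnormalized) — the convention of the standard graph
libraries; whether an undirected view would be preferable is genuinely
open, so a raw-count variant and Spearman diagnostics are exposed but not
default. Importance–centrality correlations are computed per layer and
per measure; a measure constant within a layer yields an explicit missing
value (empty CSV cell), never zero, because "no variance to correlate
against" is not "no correlation".

## Synthetic benchmark

The generator emulates patient-genomics inputs: a gene layer in which
every gene has the three feature inputs, pathway layers whose in-degrees
are Pareto(2.0)-tailed (a few hubs, many sparse nodes), and
Pareto-weighted preferential selection of source nodes so that
*out*-degrees are heavy-tailed too — hub genes exist, which matters
because the bias-vs-signal analyses need an uninformative but
well-connected gene. Every source node is guaranteed at least one forward
edge, so all nodes stay connected to the output side.

Cohorts have balanced binary labels; a planted gene subset is mutated with
probability `p_pos` in positives and `p_neg` in negatives against a
`p_bg` background, and its copy-number values are mean-shifted in
positives (background N(0, 0.5)). Planted genes are sampled stratified
across the out-degree distribution, decorrelating signal from hubness by
construction. Everything is a pure function of (spec, seed).

Default conditions — 100 genes, pathway layers (50, 20), 600 samples, 25
planted genes, p_pos/p_neg/p_bg = 0.22/0.12/0.12, copy-number shift 0.5 —
were chosen so the original task is *hard*: trained test AUC lands near
0.8, the regime of real patient cohorts. This matters scientifically: when
the planted effect is strong the data pin down a unique solution, replicate
networks agree almost perfectly, and the robustness problem the controls
exist to measure disappears. Under the default conditions the
deterministic-control importance profile is more consistent across
replicates than the original-setup profile, and replicate-mean importance
under deterministic inputs correlates positively with reachability
(Spearman ρ ≈ 0.6 pooled over hidden nodes) — the structural-bias
phenomenon, reproduced on ground-truthed data. The strong-effect setting
(p_pos = 0.9, p_neg = 0.1, 20 planted of 200 genes) is used where a
recoverability ceiling is wanted rather than a hard task.

In the recovery benchmark, the baseline against which the differential
score is judged is the raw importance of a **single** network (the
designated original-seed replicate): that is what a practitioner has
without the control framework. Replicate-averaged raw importance is
already close to the ranking ceiling under these synthetic conditions —
the planted signal dominates the structural bias — so averaging alone
recovers planted genes well, and the differential's additional value shows
up (a) against the single-network baseline and (b) in diagnosing the
uninformative hub, whose differential is non-positive while its raw score
is inflated.

What the generator does *not* emulate: mutational signatures, co-mutation
linkage between genes, subclonal copy-number structure, covariate shift
between partitions, class imbalance (available but not default). Passing
tests therefore demonstrate that the machinery behaves as designed on data
with known ground truth, not that any particular real-cohort finding is
correct.

## Numerical choices and degenerate inputs

- Attribution fallback ε = 1e-7; completeness tolerance 1e-6 relative.
- Quantile normalization demands complete matrices and ≥ 2 columns;
  missing entries are an error, not silently dropped.
- Zero-variance importance columns make Pearson undefined and are rejected
  with the offending column named.
- A node with total degree 0 cannot be degree-normalized (error), and a
  hidden node with no incoming mask entry is a structural error naming the
  node.
- Partition sizes use largest-remainder apportionment, so each partition
  is within one sample of n × fraction; stratified splitting errors out if
  any partition would lose a class.
- ROC on a single-class partition is undefined and raises, rather than
  returning 0.5.
- Sigmoid is computed in the numerically stable split form; BCE clips
  probabilities at 1e-12.

## Problem sizes

Tests and the acceptance script run grids of 20 replicate seeds per setup
at the default benchmark size (100 genes, 171 hidden nodes, 600 samples)
and 5 generator seeds for the recovery benchmark — sizes at which the full
suite completes in a few minutes on one CPU while leaving every phenomenon
of interest measurable.

## Known limitations

- Single binary outcome; no multi-class or survival endpoints.
- One hidden-node attribution family (rescale); integrated gradients or
  SHAP would require new completeness arguments.
- The deterministic control's "every feature perfectly informative"
  construction is only meaningful for feature blocks with a natural
  wild-type zero.
- CPU-only by design; the explicit numpy training loop is not intended for
  architectures beyond desk scale.
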