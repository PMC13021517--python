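# Methods

## Label space

The label space is a DAG of cell-type terms with directed child→parent
is_a edges. Terms may have several parents (the cell ontology is not a
tree), so descendant sets are always computed by graph reachability,
never by enumerating paths — a term reachable along two routes must
contribute exactly once to any sum over descendants. Node order is fixed
lexicographically by term ID at construction; index `i` in every matrix
and probability vector downstream refers to the `i`-th term in that
order, which keeps checkpoints, reports and reachability matrices
alignable across runs and files (checkpoints store the ordering and
loading verifies it).

The reachability matrix `R` is the transitive closure of the inverted
(parent→child) adjacency with the diagonal forced to one:
`R[i, j] = 1` iff `j` is `i` or a descendant of `i`. It is a partial
order — reflexive, antisymmetric, transitive — and all three properties
are asserted in tests against a brute-force per-node DFS oracle.

**Pruning.** Restricting the ontology to an observed label set keeps
exactly the observed terms and connects `u → v` iff `v` is an ancestor
of `u` in the full graph, reduced transitively so no edge is implied by
another (the full graph may route `u` to `v` through unobserved terms).
Ancestry among observed terms is preserved exactly; since the loss and
the evaluator consume only ancestry (through `R`), nothing downstream
depends on which representation of the ancestry relation is kept. The
transitive reduction is the minimal one.

**OBO ingestion** covers `[Term]` stanzas with `id`/`name`/`is_a`;
other relation types (`part_of`, `develops_from`, …) are dropped with a
logged warning, and obsolete terms are skipped. Edge-list TSV
(child⟨TAB⟩parent) is the round-trip format.

## Losses

With `p = softmax(z)` over `C` classes (softmax is the output map for
both architectures), true label `t`, and `s = R p`:

* flat CE: `−w_t · log(p_t + ε)`
* HCE: `−w_t · log(s_t + ε)`

`ε = 10⁻⁶` is added **after** descendant aggregation, inside the
logarithm, and the same ε is used in both losses so they remain
comparable. Class weights are inverse-frequency,
`w_i = N/(C·n_i)`, computed from the training split only; classes with
`n_i = 0` get weight 0 (the alternative, an infinite weight, is
undefined and an absent class cannot be learned anyway) and are flagged.
Batch reduction is the weighted mean — the sum of weighted per-sample
losses over the sum of participating weights — matching the common
weighted-NLL convention; a single probability vector returns the
per-sample value.

Two identities matter and are enforced by tests: on an edge-free
ontology `R = I` and HCE ≡ CE to machine precision; and `s_t ≥ p_t`
always, so HCE ≤ CE pointwise. When every training label is a leaf the
losses (and their gradients) coincide exactly, which is why the HCE
advantage must vanish as the coarsening rate γ → 0.

The analytic gradient with respect to the pre-softmax scores is

    ∂L/∂z_k = −(w_t / (s_t + ε)) · p_k · (R[t, k] − s_t),

one formula for both losses (CE is `R = I`). It is verified against
central finite differences at 10⁻⁵ on random instances.

## Classifiers and training

Two architectures: a linear softmax classifier and an MLP with one
ReLU hidden layer (width 64 by default). Parameters use He-scaled
normal initialisation; a single seed governs initialisation and batch
shuffling, so a run is bit-reproducible given (seed, data, config), and
the CE and HCE arms of a comparison share initialisation and batch
order — the loss term is the only difference.

The default optimizer is Adam (lr 5·10⁻³, batch 64, 60 epochs).
This is a deliberate choice: the stabilised logarithm `log(s + ε)`
flattens once a class's adjusted score falls well below ε — the gradient
factor `p_t/(s_t + ε)` vanishes — and plain SGD can permanently stall
there when early dynamics drive a class's probability to zero.  Adam's
per-parameter rescaling escapes that plateau; in our fixtures SGD froze
at train macro F1 ≈ 0.8 where Adam reaches 1.0. Plain SGD remains
available (`optimizer="sgd"`). Optional early stopping monitors
descendant-aware validation macro F1 with a patience counter and
restores the best parameters.

Inference argmaxes the **raw** distribution `p` (ties to the lowest
class index). Argmaxing the adjusted scores `s` is exposed behind a
flag but is not the default: `s` is monotone along edges, so its argmax
degenerates toward the root whenever mass is spread across a subtree.

## Evaluation protocol

A prediction is correct iff it equals the ground-truth label or is a
descendant of it (`R[truth, pred] = 1`); predicting an ancestor or an
unrelated term is incorrect. For per-class bookkeeping every
hierarchically correct prediction is remapped to its ground-truth class
before the one-vs-rest TP/FP/FN tally — the only bookkeeping consistent
with the per-cell rule. Per-class F1 defines 0/0 as 0 so classes without
support or predictions cannot inflate the average; macro F1 averages
over classes present in the evaluation ground truth by default
(`include="all"` is available). Hierarchical matching can only merge
errors into true positives, so it never lowers macro F1 relative to flat
matching — asserted as a property test.

**CE vs HCE comparison.** Per class, a two-sided paired t-test on the
per-run F1 differences; Holm–Bonferroni step-down (with monotonicity
enforcement) over the family of *testable* classes at α = 0.05. A class
whose difference vector has zero variance has no defined t-statistic;
it is flagged untestable and excluded from the family rather than
assigned a fabricated p-value.

## Synthetic atlas generator

The generator produces the three features the method addresses, and only
those:

* **Ontology**: a random rooted tree with exactly `n_leaves` leaves and
  depth ≤ `max_depth` (random 2–3-way branching), after which each
  non-root internal node gains an extra parent with probability
  `extra_edge_prob` (default 0.1), drawn from the non-descendant
  internal nodes — multi-parent terms without cycles and without
  changing the leaf set.
* **Counts**: each cell draws a leaf uniformly; the leaf's program
  elevates its `markers_per_leaf = 5` marker genes `marker_fold = 8`×
  over a flat baseline, rescaled to `library_size_target = 2000` total
  counts across `n_genes = 64` genes. Counts are negative binomial with
  dispersion θ = 2 (typical scRNA-seq overdispersion; θ = ∞ selects the
  Poisson limit used in calibration tests).
* **Study shift**: each of the `n_studies = 4` studies multiplies every
  gene's mean by `exp(N(0, 0.6))`, then cells are rescaled to the target
  library size, so the shift is compositional — the kind of batch effect
  that survives size-factor normalization.
* **Granularity mixing**: independently per cell, with probability
  `granularity_gamma = 0.4` the leaf label is replaced by a uniformly
  chosen strict ancestor (root included).
* **Donors**: 4 contiguous cell blocks per 400-cell study. Donors carry
  no expression effect of their own; they exist so the in-distribution
  split can be donor-partitioned (the OOD split holds out whole
  studies).

Defaults were chosen once as a realistic desk-scale configuration —
markers strong enough that leaves are linearly separable in the
noiseless limit (a nearest-centroid check reaches F1 = 1), study effects
strong enough that held-out studies are genuinely shifted — and are not
tuned per experiment. What the generator deliberately omits: doublets,
ambient RNA, donor-level expression variation, realistic gene–gene
correlation, and any real atlas's class composition. Passing benchmarks
therefore demonstrate that HCE recovers performance lost to
annotation-granularity mixing under distribution shift; they do not quantify the
gain on any real atlas.

Preprocessing mirrors standard atlas curation: counts are size-factor
normalized to 10,000 per cell and transformed `x ↦ log(x+1)` (natural
log); cells with zero totals are rejected by name. An inclusion filter
drops classes below configurable cell- and donor-count thresholds.

## Benchmark design

Each replicate seed simulates a fresh atlas (ontology, counts,
coarsening, split: last study held out, one donor per remaining study to
the ID test set) and trains all four (architecture × loss) models from
a shared per-arm initialisation. Ten seeds for the mixed-granularity
condition and four for the γ = 0 control keep the full run around ten
seconds on one CPU while leaving the paired t-test well powered — the
observed OOD gain (≈ 0.2 macro F1) is an order of magnitude larger than
its across-seed spread. Varying the atlas along with the initialisation
makes the comparison robust to any single simulated dataset; the
fixed-dataset, varying-training-seed design used for per-class
comparisons is available through the CLI `train`/`evaluate`/`compare`
path.

## Numerical choices and degenerate cases

* `ε = 10⁻⁶` inside the log; note `−log(1+ε) < 0`, so a perfectly
  explained label has a loss of −10⁻⁶, not 0.
* Probability vectors are validated to sum to 1 within 10⁻⁶.
* Argmax ties break to the lowest class index (numpy convention, made
  explicit in the contract).
* A batch whose every true class has weight 0 contributes zero loss and
  zero gradient, with a logged warning.
* Non-finite training loss aborts immediately with the epoch in the
  message rather than continuing on NaN parameters.
* Holm adjustment of an empty testable family is a no-op; a single
  testable class keeps its raw p.

## Known limitations

* The MLP is a single-hidden-layer NumPy implementation; it is meant
  for desk-scale experiments, not atlas-scale training, and there is no
  GPU path.
* The generator's study effect is gene-wise multiplicative only; real
  batch effects include library-preparation interactions it does not
  model.
* `evaluate` scores cells against their observed (possibly coarsened)
  labels, as in real atlases; there is no oracle mode scoring against
  the latent true leaf, though the atlas retains it (`true_label`) for
  custom analyses.
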