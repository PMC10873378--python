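# Methods

## The task and the model

`chemtrace` studies how an encoder–decoder Transformer acquires chemical
structure when trained to translate randomized SMILES into canonical
SMILES. A molecule has many valid SMILES strings (any atom can start the
traversal); the toolkit's canonicalization picks one. Translating an
arbitrary representation into the canonical one forces the model to
recover the molecular graph — atom counts, connectivity, and, hardest of
all, tetrahedral parity: the "@"/"@@" tokens written inside bracket atoms
depend jointly on the stereocenter's configuration and on the atom
ordering of the *output* string, so they cannot be copied from the input.

The model is the standard sequence-to-sequence Transformer: token
embeddings scaled by sqrt(d_model) plus sinusoidal positional encodings,
multi-head scaled dot-product attention, position-wise ReLU feed-forward
blocks, residual connections with layer normalization placed after each
residual add (post-LN, the default) or before each sublayer (pre-LN), a
causal mask in the decoder, and greedy decoding. Training is teacher
forced with token-level cross-entropy excluding padding, Adam (or AdamW)
under the inverse-square-root warmup schedule

    lr(step) = d_model^(-1/2) · min(step^(-1/2), step · warmup^(-3/2)),

with gradient accumulation over two half-budget batches per optimizer
step and length-bucketed token-budget batching. The reference
configuration (d_model 512, d_ff 2048, 6+6 layers, dropout 0.1, warmup
4000, 25,000 tokens/step, 80,000 steps) is exposed as
`harness.full_scale_config()`; it is GPU-scale work and is not exercised
by the test suite.

The whole network, including reverse-mode differentiation, runs on numpy
(`chemtrace.autodiff`); every op's gradient is checked against central
finite differences in the test suite. Both normalization variants carry a
final LayerNorm on the encoder and decoder stacks so that pre-LN and
post-LN models have identical parameter counts and differ only in graph
placement. Number of attention heads defaults to 8 at full scale (the
convention of the architecture family); He-normal initialization (zero
biases) and AdamW (decoupled decay 0.01, never applied to biases or
normalization gains) are available as interventions. Label smoothing is
not used. Greedy decoding is capped at the longest corpus target plus a
margin of five tokens.

## Metrics

All metrics operate on vocabulary tokens ("@@", "Cl" and "%NN" are single
units) between the start token and the first end token.

- **perfect accuracy** — fraction of molecules translated exactly.
- **partial accuracy** — per-molecule fraction of target positions
  predicted correctly (missing positions count as wrong), averaged over
  molecules. The per-molecule (macro) form is used because it guarantees
  perfect ≤ partial on any batch; the position-pooled (micro) form is
  exposed as `micro_token_accuracy` and reported for teacher-forced
  predictions as `tf_micro_accuracy`.
- **masked perfect accuracy** — perfect accuracy with one designated
  target token exempted from the match requirement; a large gain when a
  token is masked identifies that token as the dominant failure mode.
- **per-token accuracy** — for each token type, the fraction of its
  target positions predicted correctly under teacher forcing (the model
  sees the correct prefix, so late-position tokens are not penalized for
  earlier mistakes).
- **chirality-error classification** — each molecule is correct,
  chirality-only wrong (same length, all mismatches are "@"↔"@@"), or
  otherwise wrong.
- **fingerprint similarity** — mean Tanimoto similarity of MACCS keys and
  Morgan fingerprints (radius 1–3, folded to 2048 bits) between predicted
  and target molecules. Predictions that fail sanitization are excluded;
  across a multi-step trajectory a molecule invalid at any step is
  excluded at every step (`multi_step_similarity`), keeping the averaged
  subset fixed. Two empty bit-sets score 0 by convention.

Free-running (greedy) predictions feed perfect/partial/masked accuracy,
the chirality classification and the similarity report; teacher-forced
predictions feed the per-token table only.

## Synthetic corpus

The generator assembles valence-respecting molecular graphs over
{B,C,N,O,F,P,S,Cl,Br,I} (configurable subset) with a weighted, loosely
drug-like element distribution: random trees with a `linearity` bias
toward chain growth, optionally one ring (size 3–7) and one double bond,
and exact heavy-atom counts. A stereocenter is forced by attaching four
pairwise-distinct substituent chains to a central carbon (two adjacent
such centers in the two-stereocenter mode); the parity token printed in
the canonical SMILES is controlled exactly by emitting the enantiomer
whenever the canonical form shows the wrong token, so the "@@" fraction
converges to `at_at_balance`. Corpora are deduplicated at the
canonical-SMILES level and reproducible from the seed.

Two corpus modes matter for the learning-dynamics experiments:

- `enantiomer_pairs` — every chiral molecule is accompanied by its mirror
  image;
- `enumerate_stereoisomers` — all 2^k parity combinations of each chiral
  skeleton are included.

With all stereoisomers present, a skeleton carries no information about
its parity tokens: the model can only get them from the randomized source
string, where the written parity co-varies with the (random) atom
ordering. This makes enantiomer discrimination a genuine computation
rather than recall — the regime in which chirality dominates the error
budget.

Downstream labels are synthetic functions of structure: regression =
heavy-atom count + 2 × (number of oxygens) + Gaussian noise (σ = 1 by
default); classification = presence of a stereocenter. They let
descriptor quality be probed with no external data, but they are far
easier than real physico-chemical endpoints; results on them say nothing
quantitative about real property-prediction benchmarks.

## The scaled default experiment

The shipped desk-scale study conditions (`harness.scaled_default_config`)
are: 160 molecules of 8–14 heavy atoms over {C,N,O} (linearity 0.9, ring
probability 0.05, double-bond probability 0.1), 80% bearing two adjacent
stereocenters with all four stereoisomers enumerated; model d_model 64,
d_ff 128, 1+1 layers, 4 heads, dropout 0.05, warmup 250, 3,500 tokens per
optimizer step in two accumulated sub-batches, 1,300 steps, evaluation
every 100 steps on a 30% split. Evaluation uses fresh atom renumberings
of corpus molecules as sources ("train variants"): at this corpus size a
model cannot generalize to wholly unseen molecules, so the evaluation
measures generalization over representations — every test source string
is essentially new — which is the axis along which the partial/perfect
dissociation and the chirality lag arise.

Why these numbers: with two stereocenters and all four isomers present,
a model that has mastered structure but guesses parity has perfect
accuracy at most 1 − 0.75·(chiral fraction) ≈ 0.3, while partial accuracy
and achirality-insensitive fingerprints (MACCS) saturate above 0.9 — the
same qualitative picture as the full-scale experiments, where partial
accuracy converges long before perfect accuracy and stagnation plateaus
are composed mostly of chirality-only errors. Pilot runs showed exactly
this: partial accuracy reaches ≈0.9 while perfect accuracy sits near
0.25, mean MACCS Tanimoto exceeds 0.95, and half to two-thirds of
residual errors are parity-only. Dropout is 0.05 rather than the
full-scale 0.1 because at this model size the higher rate measurably
slows convergence without changing the dynamics. A control run takes a
few minutes on one CPU.

What passing the scaled dynamics tests does **not** show: anything about
30-million-molecule corpora, molecule-level (scaffold) generalization, or
the absolute step counts of full-scale stagnation; the miniature
reproduces the ordering and composition of the learning phases, not their
scale.

## Experiments and statistics

`run_experiment` factorizes randomness the way the multi-seed experiments
require: `init_seed` controls initial weights (and dropout noise),
`iteration_order_seed` controls batch composition and order, and a
separate `split_seed` keeps the test set fixed across a sweep. Runs can
abort once perfect accuracy reaches a threshold (default experiments use
0.95 at full scale). Step-0.7/step-0.95 are the first evaluated steps at
which perfect accuracy reaches 0.7/0.95, set to the end-of-training step
when never reached; a run is flagged stagnated when step-0.7 exceeds half
the training length (an explicit operationalization — the original
identification was visual). Interventions (pre-LN, AdamW, He-normal
initialization, chirality-enriched resampling that keeps all parity-token
molecules and half of the rest) are compared against the control by
two-sided Welch's t-test with Bonferroni correction over the number of
non-control conditions; two identical constant groups are rejected
because the statistic is undefined.

## Descriptor pooling and the downstream harness

The encoder memory (one hidden vector per non-padding source token,
including start/end) is pooled by four methods: mean; first token
(the start-token position); mean|max|first|last; and
mean|max|min|std|first|last — widths 1×, 1×, 4× and 6× d_model (512, 512,
2048, 3072 at the reference width). The standard deviation is the
population form so a single-token memory pools to zeros rather than NaN.
Baselines are uniform-[0,1] noise (width 2048) and folded Morgan
fingerprints (R=2, 2048 bits). Downstream prediction uses
gradient-boosted trees with a seeded bounded random search (20 candidate
configurations per fold by default; tests use fewer) scored on a
validation fold, refit on train+validation, and evaluated on the test
fold, for 5 rotating train/validation/test splits; regression reports
RMSE and classification AUROC, each with mean and unbiased (n−1) standard
deviation.

## Numerical and design notes

- float32 weights and activations; attention masking uses an additive
  −1e9 bias; softmax and log-sum-exp are max-shifted.
- Determinism: identical seeds give bitwise-identical runs on a fixed
  BLAS; loss history equality is asserted in the tests.
- The tokenizer is a greedy longest-match over {two-letter elements,
  "@@", "%NN", any single character}; bracket-atom interiors are
  tokenized symbol-wise (so "[C@@H]" → "[", "C", "@@", "H", "]").
  Unknown characters map to the unknown token by default (or raise).
- Bucket boundaries for batching are source-length deciles.
- InChI is available as an alternative source representation
  (`source_mode="inchi"`, vocabulary built the same way); the package
  offers it without further InChI-specific analyses.
- A non-finite training loss aborts the run with the step recorded.
- `filter_molecules` keeps the largest fragment of multi-fragment inputs
  (salt stripping) before applying the element and 3–50 heavy-atom rules;
  the stratified sampler caps each SMILES-length class and takes short
  classes whole.

## Known limitations

- The synthetic corpus emulates element composition, size range, string
  lengths and stereochemistry controls, not the property distributions or
  scaffold diversity of a real screening library.
- Greedy decoding only; no beam search.
- The desk-scale model cannot reach the full-scale regime where perfect
  accuracy approaches 1.0 and stagnation *resolves*; the package
  reproduces the plateau and its chirality composition, not the surge.
- Attention-probability dropout is not applied (dropout acts on sublayer
  outputs, embeddings and feed-forward hidden layers).
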