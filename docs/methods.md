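# Methods

## Problem setting and data model

A document is an annotated abstract: the text `title + " " + abstract`
(character offsets index this concatenation, the CDR corpus convention),
typed entity mentions with character spans and one or more MeSH identifiers,
and a set of gold ⟨chemical id, disease id⟩ relations.  Mentions normalised
to several identifiers (`D001|D002`) contribute each identifier
independently; mentions without an identifier are dropped at parse time,
since identifier-level candidates cannot use them.

**Candidate generation.** Every pair of a chemical identifier and a disease
identifier with at least one mention each becomes one candidate; the
candidate's instances are all mention-level cross pairs.  A document with m
chemical and n disease mentions therefore yields up to m × n instances,
grouped into far fewer identifier-level candidates.  Overlapping mention
pairs are skipped with a warning; candidates losing all instances that way
are dropped.  Labels come solely from the gold pair set.

## Instance construction

Each instance is rendered as

    S₋₁  ⟨ENTC⟩ chemical surface ⟨/ENTC⟩  S₀  ⟨ENTD⟩ disease surface ⟨/ENTD⟩  S₁

with "first"/"second" decided by character offset (marker type follows
entity type, so a disease-first instance starts with the ⟨ENTD⟩ block).
S₋₁ and S₁ are bounded by the sentence containing the first and second
mention respectively; S₀ is the full between-text, crossing sentence
boundaries when the mentions do.  The mention surface tokens are kept inside
the marker blocks.

Design choices the source setting leaves open, fixed here:

- **Tokenisation**: whitespace split, then leading/trailing punctuation
  peeled into separate tokens; internal punctuation (hyphens, decimal
  points, `mg/kg`) is kept.  Lowercasing applies to vocabulary lookup only.
- **Sentence splitting**: rule-based — sentence-final punctuation followed
  by whitespace and an uppercase letter or digit, with a configurable
  abbreviation list (`e.g`, `et al`, `vs`, ...).
- **Segment labels**: the three pooling segments must partition the token
  sequence, so the first marker block is labelled with S₋₁ and the second
  with S₀; labels are monotonically non-decreasing along the sequence.
- **Distances**: every token carries signed token distances to the chemical
  block and to the disease block, 0 on the block itself, ±k outside, so the
  token right after a closing marker has distance +1.

**Encoding.** All instances are padded (at the end) to a common length l —
the corpus maximum by default.  With an explicit smaller l, instances are
center-truncated keeping both marker blocks; an l smaller than the
marker-to-marker span is an error naming the document.  Distances are
clipped to [-(l-1), l-1] and bucketised into 2l-1 signed buckets plus one
dedicated padding bucket.  Unknown words map to UNK; padding cells carry the
PAD word, the padding bucket and mask 0.

## Model

Token i is embedded as x_i = [e_w; e_dc; e_da] with d_w = 30 word dimensions
and 5 + 5 position dimensions (40 total).  For each filter width k ∈ {3, 4},
a bank of 150 filters produces F[t, i] = ReLU(⟨t, x_{i:i+k-1}⟩ + b_t);
windows consisting only of padding are forced to zero (padding is trailing,
so a window is real iff its first token is).

**Pooling.** Plain max pooling takes the per-filter maximum over positions.
Class-attention pooling computes G = Fᵀ M W^classes (positions × classes),
normalises each class column over positions with a softmax, and pools filter
t as max_j (F A)_{t,j}.  With the piecewise strategy, pooling is applied
separately to the windows starting in S₋₁, S₀ and S₁ (a window belongs to
its first token's segment) and the three results are concatenated: the
instance vector has 3 × 150 × 2 = 900 dimensions (300 without piecewise).
An empty segment contributes zeros.  Two conventions worth noting: M and
W^classes are shared across the two filter widths (the banks have equal
width q = 150), and the M = 0 limit makes attention exactly uniform, i.e.
row-mean pooling — a property the tests pin down.

**Recurrence.** A candidate's instance vectors, ordered by *descending*
between-context length, drive a standard LSTM cell (150 hidden units,
forget-gate bias 1) from a zero state; the final hidden state h_m represents
the candidate, so the shortest-gap instance — typically the cleanest
evidence — has the last word.  The CNN baseline (`use_rnn=False`) instead
projects only the last-ordered instance's vector through one tanh layer.

**Knowledge features.** Each candidate pair is looked up in up to four
resources — CTD (tagged associations such as `marker/mechanism`,
`therapeutic`), MEDI (indications), SIDER (side effects) and a precomputed
MeSH ancestor/descendant table — supplied as TSV pair tables.  The feature
is the binary membership indicator over all (table, tag) slots, with a
fixed slot order derived once from the loaded tables; the exact layout used
by earlier feature-engineered systems is unpublished, so this simple
reproducible encoding of the same character (binary knowledge flags) is
used.  The MeSH table is precomputed rather than traversed live so nothing
is downloaded at run time.  One tanh layer densifies the bits to 120 units.

**Output.** v′ = [h_m; v] (270 units with knowledge, 150 without) passes
through dropout (p = 0.25, training only) and a single sigmoid unit with
bias: P(related) = σ(u·v′ + b).  The sign convention is the standard
logistic one, so larger evidence raises the probability.

### Initialisation and numerics

Everything is driven by `numpy.random.default_rng(seed)`: word embeddings
from the supplied table (fine-tuned) or uniform(-0.25, 0.25); position
embeddings uniform; filter banks, LSTM and dense layers Glorot-uniform; M
uniform; W^classes the first n_classes columns of the identity; the output
vector u zero (an untrained candidate scores exactly 0.5).  Two builds with
the same seed and config are bit-identical, as are their forward scores.

The network is differentiated by a small in-package reverse-mode tape over
numpy (`cid_rpcnn.autodiff`) — the model is a few hundred thousand
parameters and all heavy operations are batched matmuls, so no external
framework is needed.  Float64 is the default dtype and the one used by the
gradient checks (analytic vs central differences, tolerance 1e-4, per op and
through the full loss); training defaults to float32 for speed
(`TrainConfig.precision`), which leaves seed-determinism intact.  Softmax
and binary cross-entropy are computed in max-shifted / logit space for
stability; max pooling routes gradients to the first argmax.

## Training and evaluation

Loss, optimiser and schedule are not dictated by the extraction task, so
the defaults are conventional: mean binary cross-entropy on the sigmoid
output, Adam at 1e-3, batches of 32 candidates, at most 30 epochs.  A 10%
development split (seeded) drives checkpointing and early stopping: the
returned parameters are the best-dev-F snapshot (ties broken by dev loss),
and patience (5 epochs) only counts epochs where *neither* dev F improves
*nor* dev loss falls — thresholded F is a step function and would otherwise
starve training during the warm-up in which scores approach the 0.5
threshold from below.  Class reweighting is available (`pos_weight`) but off
by default.  Variable instance counts are handled by masked recurrence
unrolling, making predictions independent of batch composition (tested by
permutation).

Evaluation collapses predicted-positive (pmid, chem id, dis id) triples and
gold triples to sets and reports P, R and F as percentages, with the 0/0
convention that an empty denominator gives 0.  Matching is on identifier
pairs, consistent with counting relations per identifier pair at the
document level.  The ablation harness trains the model-variant family (CNN,
+piecewise, +attention, both, and the full recurrent model, each with and
without knowledge) under a shared seed and returns a pandas table.

## The synthetic corpus: what it emulates, and what it does not

The generator produces PubTator-format documents with MeSH-style
identifiers (`D` + 6 digits), multiple mentions per entity, sentence
structure with capitalised openings, and matching knowledge tables.  The
relation signal is a planted rule: a related pair has a trigger word
(`induced`, `caused`, `associated with`) in the between-context of its
mention pairs; unrelated pairs never do.  Knowledge tables list true pairs
with probability ρ (default 0.9; CTD tags them `marker/mechanism`) and
other pairs at ρ/10.

Each document carries one *focal* pair, related with probability π (default
0.3), plus optionally one distractor entity on one side only, which creates
guaranteed-negative candidates.  Placement is constrained — distractor
diseases first, distractor chemicals last, and in positive documents all
focal chemical mentions precede the trigger while all focal disease
mentions follow it — so that no negative candidate's between-context ever
spans a trigger.  This constraint is what makes the labelling *exactly*
recoverable from the between-context: a trivial trigger-word classifier
reaches F = 100 on generated corpora (a test asserts this), certifying that
the label logic is consistent before any model is trained.  Allowing
several independently related pairs per document would break exactness
structurally: a trigger between one pair's mentions unavoidably lies
between flanking mentions of some negative cross-pair.  Wider entity ranges
are supported in the config for stress-testing, at the cost of that
guarantee.

Consequently, passing the end-to-end study (F ≥ 90 on held-out documents of
a 500-document corpus) demonstrates that the pipeline is wired correctly
and that the architecture can exploit between-context, cross-sentence
evidence and knowledge features — it does *not* demonstrate performance on
real biomedical language, where relations are not marked by a closed
trigger lexicon, annotations are noisy, and many documents carry several
interacting relations.  Scores on the real CDR benchmark additionally
depend on large-scale pretrained embeddings and are out of scope here; the
pipeline accepts that corpus unchanged when available.

On the default study we observe that the knowledge-fused model converges in
fewer epochs than the text-only ablation and never scores lower on held-out
F (averaged over three seeds); the size of the gap varies with the corpus
seed — the direction, not the magnitude, is the stable finding.

## Problem sizes and runtime

Unit tests run a shrunken model (6 filters per width, 5 hidden units) on a
15-document corpus; the full-size configuration is exercised by the shape
contracts, the worked example and the end-to-end study (500 documents,
~900 candidates, instance length ≈ 40–60, seven trainings), which completes
in a few minutes on one CPU.  Checkpoints are single-file `.npz` archives
with an embedded JSON config and optional vocabulary.

## Known limitations

- Sentence splitting is rule-based; unusual abbreviations shift S₋₁/S₁
  boundaries (never S₀, which is offset-defined).
- The per-candidate instance cap (`max_instances`) defaults to unlimited;
  documents with very many mentions of both entities produce quadratically
  many instances.
- Knowledge features are binary per (table, tag); membership counts or
  graded scores are not represented.
- The CNN baseline's learned projection adds parameters the recurrent model
  does not have; comparisons across `use_rnn` settings share everything
  else but not that layer.
- Training is single-threaded numpy; GPU execution is out of scope.
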