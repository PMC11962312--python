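# Methods

## Pipeline model and assumptions

The toolkit models a privacy-preserving weak-annotation workflow for clinical
NER: synthetic documents stand in for private health records, an external
annotator returns entity surface strings per class under a JSON contract, the
surfaces are aligned back to the text as IOB2 token labels, and a downstream
tagger is trained on those weak labels. Two assumptions run through every
stage:

- **Annotators report surfaces, never offsets.** Chat-style models are
  unreliable at producing span indices, so the contract asks only for the
  surface strings per class; span recovery is the alignment module's job.
- **Everything is word-level.** Tokens are whitespace-separated chunks with
  leading/trailing punctuation peeled into separate tokens (Unicode
  punctuation categories). Originality scoring, alignment, tagging, and
  evaluation all operate on these tokens. No sentence splitting, lemmatization,
  or sub-word modeling.

## Originality scoring

For generated token sequence *x* and training sequence *y*, the plain score
is `LCS(x, y) / |x|`. The penalized score maximizes, over all
common-subsequence chains `(i₁,j₁) < … < (i_L,j_L)`, the value
`L − Σ_t min(g_t / k, 1)` where `g_t = max(i_{t+1}−i_t−1, j_{t+1}−j_t−1)` is
the larger number of tokens skipped between consecutive matches, normalized
by `|x|`. Choices that were genuinely open:

- **Gap convention.** `g` counts *skipped* tokens, so adjacent matches cost
  zero and a contiguous verbatim copy keeps its full score. Any leakage score
  that penalized contiguous copies would be useless, so this is forced in
  substance if not in letter.
- **Optimization target.** The penalty is maximized over all chains by a
  dynamic program over match pairs (O(P²) in the number of equal-token pairs),
  not applied post hoc to one classic-LCS backtrace, whose choice among ties
  is arbitrary. `mode="classic_path"` provides the post-hoc variant (ties
  broken toward contiguity) for comparison with implementations that penalize
  a single backtrace.
- **k = 20 by default**: large enough not to punish paraphrase-level
  reordering, small enough to discount matches scattered over hundreds of
  tokens. The penalized score is non-decreasing in `k` and never exceeds the
  plain score.
- **k = 1 versus longest common run.** With `k = 1` every junction with any
  gap costs a full unit, which *approximates* the normalized longest common
  contiguous run but is not identical to it: two long runs can out-score the
  single longest run. `longest_common_run` is provided as a diagnostic; the
  test suite verifies both the lower bound and the existence of strict
  differences.
- **Best match.** The report carries the training text maximizing the *plain*
  score (ties to the first in corpus order) and the penalized score against
  that same text. A short text can tie at plain score 1.0 against several
  pool texts; the first-occurrence winner may then have a penalized score
  below 1 even when a gap-free copy exists later in the pool. Filtering on
  the plain field is therefore the right choice when verbatim copies must be
  caught unconditionally.
- **Threshold.** The removal cutoff is a required argument with no default:
  it trades recall of leaked texts against yield of usable ones, and no
  universal value exists.
- Token comparison is case-sensitive by default (switchable); the filter
  removes texts with score ≥ threshold.

The plain-LCS row recurrence is vectorized with numpy (running-maximum
trick), giving roughly millisecond-scale scoring per text pair at ~100
tokens; the penalized DP runs once per generated text against its best match
only.

## Annotation contract and noise model

Four prompt styles are shipped: zero-shot, the same instruction in Estonian
(with class keys RAVIM/PROTSEDUUR/HAIGUS/SUITS), a variant with per-class
guideline definitions, and a few-shot variant with exactly five worked
input/output pairs. The shipped few-shot pairs are synthetic stand-ins built
from the generator's own vocabulary. Response parsing takes the **first**
balanced-brace substring that parses as a JSON object; a response counts as
parsed only if at least one configured class key is present. Unknown keys are
warned about and ignored; scalar values are coerced to one-element lists.
Parsing never raises — failure is data (`parsed=False`), mirroring how
unparseable model output is counted rather than crashed on.

The noise model corrupts gold annotations with four independent, seeded
error modes: per-mention omission (`drop_prob`), spurious mentions drawn as
random 1–3-token n-grams of the document at a Poisson rate per document
(`spurious_prob`), one-token boundary truncation/extension
(`boundary_shift_prob`), and whole-response garbling (`garble_prob`). Each
document gets its own RNG stream (seed ⊕ CRC32 of the document id), so
results are independent of corpus order. The three named profiles
(`strong`, `medium`, `weak_local`) are ordered by quality and emulate a
strong hosted annotator, a weaker one, and a small local model that often
fails to produce parseable output.

## Alignment

Reported surfaces are matched at whole-token boundaries, case-insensitively
by default, with whitespace normalized by matching token sequences rather
than raw strings. Every occurrence is annotated (a class→strings mapping
carries no per-occurrence information; annotating all occurrences is the
standard distant-supervision choice); both behaviors are policy switches.
Surfaces absent from the text are dropped with reason `not_found` — alignment
never invents text. Overlaps are resolved greedily: longer span first, then
earlier start, then class priority DRUG > PROCEDURE > DISEASE > SMOKING
(specificity first, deterministic always). A mention whose character span
ends mid-token claims the whole token.

## Evaluation

Entity-level exact span-and-class matching with lenient chunk starts: a
chunk opens at `B-X`, or at `I-X` after `O` or after a different class. The
0/0 convention for precision, recall, and F1 is 0. Wilson 95% intervals
(z = 1.96) are attached to precision and recall, computed from chunk counts;
they are not attached to F1. Interannotator agreement is per-class F1 with
one annotator as reference; it is symmetric because swapping annotators
exchanges false positives with false negatives, which F1 is invariant to.

## Synthetic data generator

Documents are assembled from sentence templates with typed slots filled from
invented pseudo-Estonian vocabularies. Structural guarantees, verified by
tests: every vocabulary token occurs in exactly one surface of one class and
never in a template, so gold mentions are exactly recoverable and class
collisions cannot occur; gold offsets are recorded at insertion time, never
re-derived by search, so alignment tests are non-circular. Defaults:

- 500 documents, two-thirds medical histories and one-third procedure notes
  (`round(n·f)` histories);
- per-class mention means per document: PROCEDURE 1.29, DISEASE 0.64,
  DRUG 0.44, SMOKING 0.12 (Poisson counts, surfaces sampled without
  replacement within a document) — matching the class mix of a 500-document
  expert-annotated evaluation set (procedures most frequent, smoking rarest);
- metadata: 13 five-year age bands spanning 15–80, two genders, diagnosis
  code C50.

Two template banks sharing no word tokens ("primary", "alternate") allow
constructing documents guaranteed to share no templates — needed for
leakage experiments where fresh documents must never be flagged.
`make_training_pool` builds pools of verbatim/mutated copies (each token
independently replaced by a unique substitution token at `mutation_rate`)
plus fresh filler documents, with provenance records.

What the generator deliberately does **not** emulate: realistic clinical
discourse, morphological inflection of mentions (real Estonian text inflects
entity surfaces, which the whole-token alignment would miss), ambiguous
surfaces shared between classes, and cross-template lexical diversity.
Passing tests therefore demonstrate the correctness of the machinery under
controlled conditions, not expected performance on real records.

## Downstream tagger

A dictionary tagger stands in for transformer fine-tuning (out of scope:
needs GPUs and a pretrained multilingual model; the CoNLL export keeps that
path open). Training extracts chunks from the weak labels, counts
(surface, class) pairs, assigns each surface its majority class (ties by
class priority), and prunes surfaces below a frequency threshold
(`min_frequency`, default 1 in the library, 2 in the experiment harness —
one-off surfaces are almost always spurious-noise artifacts). Tagging is
leftmost-longest dictionary matching; a 15% validation split
(`round(n·0.15)`, seeded shuffle) is held out before training.

A known and instructive limitation: with noisy annotations over template
generated text, the learning curve of this memorizing tagger can *decline*
with corpus size — spurious n-grams recur across documents (templates repeat
phrasing), survive frequency pruning at scale, and both pollute the
dictionary and, when they extend a true surface, steal its spans under
longest-match. A contextual model with a validation-based stopping rule
behaves differently; the harness measures the tagger it has.

## Experiment harness

The learning-curve harness generates a training corpus (default 4,100
documents), draws nested batches at the default ladder 250–4,000 in a 2:1
history:procedure ratio, annotates each batch with a named noise profile,
aligns, trains the tagger, and evaluates on a separately generated gold
corpus of 300 documents (half per type) whose ids are asserted disjoint from
every batch. Prompt comparison annotates one gold corpus once per style and
reports per-class metrics with parsed-response counts. Every harness is a
pure function of (config, seed); determinism is tested byte-for-byte.
These scales keep the full suite and the acceptance script in the seconds
range on one CPU.

## Numerical notes

- Wilson interval algebra yields exactly [p̂, 1] endpoints at p̂ ∈ {0, 1} up
  to ~1e-16 rounding; bounds are clipped to [0, 1].
- The penalized-value recurrence adds `1 − penalty ≥ 0` per extension, so
  chain values are always ≥ 1 when any match exists; the score of a pair with
  no shared token is 0.
- All RNG use is `random.Random` / explicit seeding; no global state.
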