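# synthner

A toolkit for building named-entity-recognition (NER) training data for
low-resource clinical text **without human annotation and without exposing
patient records**. The workflow it supports: a language model trained
locally on private electronic health records generates synthetic documents;
generated texts that leak training data are screened out with a penalized
longest-common-subsequence score; a large language model annotates the
surviving texts through a JSON prompt contract; the reported entity surfaces
are aligned back to character spans and exported as IOB2 training data; and
a downstream tagger trained on those weak labels is evaluated at the entity
level with Wilson confidence intervals.

The package targets four entity classes from Estonian-style health records —
`DRUG`, `PROCEDURE`, `DISEASE`, `SMOKING` — but is language-agnostic by
construction. Both ends of the real pipeline that cannot live in a public
toolkit (the locally trained generator over private records, and the hosted
annotation models) are replaced by first-class, seeded stand-ins: a
synthetic-corpus generator with generation-time gold annotations, and mock
annotators (a deterministic gazetteer and a configurable noise model for
dropped, spurious, boundary-shifted, and unparseable responses).

## The core statistic: penalized LCS originality scoring

A generative model can reproduce its training texts verbatim or near
verbatim. For a generated token sequence *x* and each training sequence
*y*, the plain originality score is

```
score(x, y) = LCS(x, y) / |x|        ∈ [0, 1]   (0 unique, 1 identical)
```

Plain LCS over long training texts accumulates matches scattered across
hundreds of tokens. The penalized variant subtracts, for each pair of
consecutive matched tokens, a penalty `min(d/k, 1)`, where `d` is the larger
of the two gaps (skipped tokens) in *x* and *y*, and `k` is the penalty
length (default 20). Adjacent matches cost nothing, so contiguous verbatim
copies keep a full score while scattered chains are discounted. The score is
maximized over **all** common-subsequence chains by dynamic programming, not
read off one arbitrary LCS backtrace. Texts whose best score against the
training corpus reaches a threshold are removed.

Evaluation follows the standard entity-level convention: a predicted chunk
counts only on exact span-and-class match, with lenient chunk starts
(an `I-X` after `O` opens a chunk), undefined ratios reported as 0, and 95%
Wilson score intervals on precision and recall.

## Worked example

```python
from synthner import (
    GeneratorConfig, generate_gold_corpus, make_training_pool,
    score_corpus, filter_corpus,
)

corpus = generate_gold_corpus(GeneratorConfig(n_documents=6, seed=1))
pool, _prov = make_training_pool(corpus[:3], copy_fraction=1.0,
                                 mutation_rate=0.0, seed=2)
reports = score_corpus([gd.document for gd in corpus], pool)
for r in reports:
    print(f"{r.generated_id}  lcs={r.lcs_score:.2f}  penalized={r.penalized_score:.2f}")
kept, removed = filter_corpus(reports, threshold=0.8)
print("removed:", removed)
```

prints

```
synth-00000  lcs=1.00  penalized=1.00
synth-00001  lcs=1.00  penalized=1.00
synth-00002  lcs=1.00  penalized=1.00
synth-00003  lcs=0.65  penalized=0.64
synth-00004  lcs=0.17  penalized=0.15
synth-00005  lcs=0.31  penalized=0.27
removed: ['synth-00000', 'synth-00001', 'synth-00002']
```

The first three documents have verbatim copies in the pool and score 1.0 on
both measures, so the 0.8 threshold removes exactly them; the other three
share only template phrasing and punctuation, which the gap penalty
discounts further (penalized ≤ plain).

The same stages are available on the command line:

```
synthner synthgen --n 500 --seed 1 --out corpus.jsonl --gold-out gold.tsv
synthner originality score --generated corpus.jsonl --training pool.jsonl --k 20 --out reports.tsv
synthner originality filter --reports reports.tsv --threshold 0.8 --field penalized
synthner annotate --corpus corpus.jsonl --annotator noisy --gold gold.tsv --out responses.jsonl
synthner align --corpus corpus.jsonl --responses responses.jsonl --out train.tsv
synthner downstream train --conll train.tsv --out model.tsv
synthner evaluate --pred pred.tsv --gold goldtags.tsv
synthner experiment learning-curve --seed 1 --out curve.tsv
```

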