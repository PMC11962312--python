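"""Originality scoring of generated texts against a training corpus.

A language model trained on private clinical notes can emit verbatim or
near-verbatim copies of its training data, so generated texts must be screened
before they leave the secure environment.  Screening by exact match misses
copies that differ by a single token, and fixed-length n-gram contamination
checks miss copies with scattered single-word substitutions.  The longest
common subsequence (LCS) handles both: for a generated token sequence ``x``
and each training sequence ``y``, the plain score is ``LCS(x, y) / len(x)``,
between 0 (nothing shared) and 1 (``x`` is entirely contained, in order,
in ``y``).

Long training texts inflate the plain score with matches scattered across
hundreds of tokens that never form a contiguous expression.  The penalized
variant subtracts, for each pair of consecutive matched tokens, a penalty
``min(distance / k, 1)`` where ``distance`` is the larger of the two gaps
(skipped-token counts) in ``x`` and ``y``.  Adjacent matches cost nothing, so
contiguous verbatim copies keep their full score, while widely scattered
chains are discounted by up to 1 per junction.  The penalty length ``k``
defaults to 20, small enough to discount scattered matches without flagging
texts that merely paraphrase.

The penalized score is computed by its own dynamic program that maximizes the
penalized value over *all* common-subsequence chains, not by penalizing one
arbitrary backtrace of the classic LCS table (backtrace choice is
nondeterministic); ``mode="classic_path"`` offers the post-hoc variant that
penalizes the canonical classic-LCS chain, with ties broken toward
contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import Document, tokenize

DEFAULT_K = 20


@dataclass(frozen=True)
class OriginalityReport:
    """Best-matching training text for one generated text, with both scores."""

    generated_id: str
    best_training_id: str
    lcs_score: float
    penalized_score: float
    k: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.penalized_score <= self.lcs_score <= 1.0 + 1e-12):
            raise ValueError(
                f"{self.generated_id}: scores out of order "
                f"(penalized {self.penalized_score}, plain {self.lcs_score})"
            )


def _encode(a: Sequence[str], b: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    vocab: dict[str, int] = {}
    enc_a = np.fromiter((vocab.setdefault(t, len(vocab)) for t in a), dtype=np.int64, count=len(a))
    enc_b = np.fromiter((vocab.setdefault(t, len(vocab)) for t in b), dtype=np.int64, count=len(b))
    return enc_a, enc_b


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Classic LCS length by dynamic programming (row-vectorized)."""
    if len(a) == 0 or len(b) == 0:
        return 0
    enc_a, enc_b = _encode(a, b)
    # row update: cur[j] = max(prev[j], prev[j-1] + eq[j], cur[j-1]);
    # because rows are non-decreasing, the cur[j-1] term is a running max.
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for x in enc_a:
        cand = prev[:-1] + (enc_b == x)
        cur = np.maximum(prev[1:], cand)
        np.maximum.accumulate(cur, out=cur)
        prev[1:] = cur
    return int(prev[-1])


def lcs_score(gen: Sequence[str], train: Sequence[str]) -> float:
    """``lcs_length(gen, train) / len(gen)``; the leakage score in [0, 1]."""
    if len(gen) == 0:
        raise ValueError("generated token sequence must be non-empty")
    return lcs_length(gen, train) / len(gen)


def _match_pairs(gen: Sequence[str], train: Sequence[str]) -> list[tuple[int, int]]:
    positions: dict[str, list[int]] = {}
    for j, t in enumerate(train):
        positions.setdefault(t, []).append(j)
    pairs = []
    for i, t in enumerate(gen):
        for j in positions.get(t, ()):
            pairs.append((i, j))
    return pairs


def _penalized_value(chain: Sequence[tuple[int, int]], k: int) -> float:
    value = float(len(chain))
    for (i0, j0), (i1, j1) in zip(chain, chain[1:]):
        gap = max(i1 - i0 - 1, j1 - j0 - 1)
        value -= min(gap / k, 1.0)
    return value


def _classic_chain(gen: Sequence[str], train: Sequence[str]) -> list[tuple[int, int]]:
    """One canonical classic-LCS chain: greedy backtrace preferring matches
    (ties broken toward contiguity), then the shorter-gap direction."""
    n, m = len(gen), len(train)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if gen[i] == train[j]:
                dp[i, j] = dp[i + 1, j + 1] + 1
            else:
                dp[i, j] = max(dp[i + 1, j], dp[i, j + 1])
    chain: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if gen[i] == train[j] and dp[i, j] == dp[i + 1, j + 1] + 1:
            chain.append((i, j))
            i += 1
            j += 1
        elif dp[i + 1, j] >= dp[i, j + 1]:
            i += 1
        else:
            j += 1
    return chain


def penalized_lcs_score(
    gen: Sequence[str],
    train: Sequence[str],
    k: int = DEFAULT_K,
    mode: str = "optimal",
) -> float:
    """Gap-penalized LCS score in [0, 1].

    ``mode="optimal"`` (default) maximizes ``L - sum(penalties)`` over all
    common-subsequence chains; ``mode="classic_path"`` penalizes the canonical
    classic-LCS backtrace instead.
    """
    if len(gen) == 0:
        raise ValueError("generated token sequence must be non-empty")
    if k < 1:
        raise ValueError(f"penalty length k must be >= 1, got {k}")
    if mode == "classic_path":
        chain = _classic_chain(gen, train)
        return max(_penalized_value(chain, k), 0.0) / len(gen) if chain else 0.0
    if mode != "optimal":
        raise ValueError(f"unknown mode {mode!r}")

    pairs = _match_pairs(gen, train)
    if not pairs:
        return 0.0
    pairs.sort()  # by (i, j): any predecessor of a pair sorts before it
    best = [1.0] * len(pairs)
    overall = 1.0
    for idx, (i, j) in enumerate(pairs):
        acc = 1.0
        for pidx in range(idx):
            pi, pj = pairs[pidx]
            if pi < i and pj < j:
                gap = max(i - pi - 1, j - pj - 1)
                cand = best[pidx] + 1.0 - min(gap / k, 1.0)
                if cand > acc:
                    acc = cand
        best[idx] = acc
        if acc > overall:
            overall = acc
    return overall / len(gen)


def longest_common_run(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common *contiguous* run (diagnostic: the k=1
    penalized score approximates but does not equal this normalized length,
    because two long contiguous runs can out-score the single longest run)."""
    if not a or not b:
        return 0
    enc_a, enc_b = _encode(a, b)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    best = 0
    for x in enc_a:
        cur = np.zeros_like(prev)
        cur[1:] = (prev[:-1] + 1) * (enc_b == x)
        best = max(best, int(cur.max()))
        prev = cur
    return best


def _doc_tokens(doc: Document, case_sensitive: bool) -> list[str]:
    toks = tokenize(doc.text, doc.id).surfaces()
    return toks if case_sensitive else [t.lower() for t in toks]


def best_match(
    gen: Document,
    training: Sequence[Document],
    k: int = DEFAULT_K,
    case_sensitive: bool = True,
) -> OriginalityReport:
    """Score ``gen`` against every training text; report the plain-LCS-best
    match (ties broken by corpus order) and the penalized score against that
    same text."""
    if not training:
        raise ValueError("training corpus must be non-empty")
    gen_toks = _doc_tokens(gen, case_sensitive)
    if not gen_toks:
        raise ValueError(f"generated document {gen.id!r} tokenizes to nothing")
    best_score = -1.0
    best_doc: Document | None = None
    best_toks: list[str] = []
    for tr in training:
        tr_toks = _doc_tokens(tr, case_sensitive)
        score = lcs_score(gen_toks, tr_toks)
        if score > best_score:
            best_score, best_doc, best_toks = score, tr, tr_toks
    assert best_doc is not None
    pen = penalized_lcs_score(gen_toks, best_toks, k=k)
    return OriginalityReport(
        generated_id=gen.id,
        best_training_id=best_doc.id,
        lcs_score=best_score,
        penalized_score=pen,
        k=k,
    )


def score_corpus(
    generated: Sequence[Document],
    training: Sequence[Document],
    k: int = DEFAULT_K,
    case_sensitive: bool = True,
) -> list[OriginalityReport]:
    return [best_match(g, training, k=k, case_sensitive=case_sensitive) for g in generated]


def filter_corpus(
    reports: Sequence[OriginalityReport],
    threshold: float,
    score_field: str = "penalized",
) -> tuple[list[str], list[str]]:
    """Partition generated ids into (kept, removed); removed iff the chosen
    score is >= threshold.  Order is preserved."""
    if threshold <= 0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if score_field not in ("plain", "penalized"):
        raise ValueError(f"score_field must be 'plain' or 'penalized', got {score_field!r}")
    kept, removed = [], []
    for rep in reports:
        score = rep.lcs_score if score_field == "plain" else rep.penalized_score
        (removed if score >= threshold else kept).append(rep.generated_id)
    return kept, removed
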