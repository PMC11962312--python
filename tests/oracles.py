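"""Independent oracles used by the test suite.

Everything here is computed by brute force or from a source independent of
the implementation path it checks: exhaustive enumeration of common
subsequence chains for LCS scores, and a separate transcription of the
default lenient chunking scheme for entity extraction.
"""

from __future__ import annotations

import random
from typing import Sequence


def enumerate_common_chains(a: Sequence[str], b: Sequence[str]) -> list[list[tuple[int, int]]]:
    """All nonempty strictly-increasing index chains (i, j) with a[i] == b[j]."""
    pairs = sorted(
        (i, j) for i in range(len(a)) for j in range(len(b)) if a[i] == b[j]
    )
    chains: list[list[tuple[int, int]]] = []

    def extend(chain: list[tuple[int, int]], start: int) -> None:
        if chain:
            chains.append(list(chain))
        for idx in range(start, len(pairs)):
            i, j = pairs[idx]
            if not chain or (i > chain[-1][0] and j > chain[-1][1]):
                chain.append((i, j))
                extend(chain, idx + 1)
                chain.pop()

    extend([], 0)
    return chains


def brute_lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    chains = enumerate_common_chains(a, b)
    return max((len(c) for c in chains), default=0)


def brute_penalized_score(a: Sequence[str], b: Sequence[str], k: int) -> float:
    """Max over all chains of (L - sum of per-junction penalties) / len(a)."""
    best = 0.0
    for chain in enumerate_common_chains(a, b):
        value = float(len(chain))
        for (i0, j0), (i1, j1) in zip(chain, chain[1:]):
            gap = max(i1 - i0 - 1, j1 - j0 - 1)
            value -= min(gap / k, 1.0)
        best = max(best, value)
    return best / len(a)


def reference_chunks(tags: Sequence[str]) -> set[tuple[str, int, int]]:
    """Default-scheme (lenient) chunk extraction, transcribed independently:
    mark chunk-opening positions first, then close each chunk at the next
    opening or O."""
    def cls_of(tag: str) -> str | None:
        return None if tag == "O" else tag.split("-", 1)[1]

    n = len(tags)
    opens = []
    for i, tag in enumerate(tags):
        if tag == "O":
            continue
        prev = tags[i - 1] if i > 0 else "O"
        if tag.startswith("B-") or cls_of(prev) != cls_of(tag):
            opens.append(i)
    chunks: set[tuple[str, int, int]] = set()
    for pos, start in enumerate(opens):
        end = n
        for j in range(start + 1, n):
            if tags[j] == "O" or j in opens[pos + 1 :]:
                end = j
                break
        chunks.add((cls_of(tags[start]), start, end))
    return chunks


IOB2_TAGSET = ["O"] + [f"{p}-{c}" for p in "BI" for c in ("DRUG", "PROCEDURE", "DISEASE", "SMOKING")]


def random_tag_sequence(rng: random.Random, length: int) -> list[str]:
    """Arbitrary tag sequences over the full B/I/O alphabet, including
    lenient-start cases such as I-X after O."""
    return [rng.choice(IOB2_TAGSET) for _ in range(length)]


def random_token_pair(
    rng: random.Random, max_len: int = 8, alphabet: str = "abcd"
) -> tuple[list[str], list[str]]:
    la = rng.randint(1, max_len)
    lb = rng.randint(0, max_len)
    return (
        [rng.choice(alphabet) for _ in range(la)],
        [rng.choice(alphabet) for _ in range(lb)],
    )
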