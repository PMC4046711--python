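"""Maximum expected accuracy (MEA) alignment by dynamic programming.

Given any nonnegative score matrix S — a message-passing confidence matrix
or a pair-HMM posterior match matrix — the MEA alignment is the monotone
matching maximizing the total score of its aligned pairs, with gaps scoring
zero::

    D(i, j) = max( D(i-1, j-1) + S(i, j), D(i-1, j), D(i, j-1) )

with D(0, .) = D(., 0) = 0 (Needleman-Wunsch recurrence with zero gap
scores).  Traceback tie-breaking is deterministic: diagonal, then up
(gap in y), then left (gap in x); a pair enters the alignment only if its
score is strictly positive, so all-zero regions stay unaligned.

:func:`enumerate_alignments` exhaustively lists every monotone matching of
two tiny sequences and serves as the brute-force oracle for the DP.
"""

from __future__ import annotations

from typing import Iterator, Union

import numpy as np

from .message_passing import ScoreMatrix
from .seqtypes import PairwiseAlignment

ENUMERATION_GUARD = 8


def mea_align(
    S: Union[ScoreMatrix, np.ndarray]
) -> tuple[PairwiseAlignment, float]:
    """Alignment maximizing the summed score of aligned pairs.

    Returns ``(alignment, total_score)``; ``total_score`` is the maximum of
    ``sum S(i, j)`` over all monotone matchings.  An empty matrix yields the
    empty alignment with score 0.
    """
    vals = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    if vals.ndim != 2:
        raise ValueError("score matrix must be two-dimensional")
    if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
        raise ValueError("scores must be finite and nonnegative")
    L, M = vals.shape
    if L == 0 or M == 0:
        return PairwiseAlignment([], (L, M)), 0.0
    D = np.zeros((L + 1, M + 1))
    for i in range(1, L + 1):
        # diagonal/up candidates vectorized; the left move D(i, j-1) is a
        # running maximum along the row (D(i, 0) = 0 <= every candidate)
        row = np.maximum(D[i - 1, :-1] + vals[i - 1], D[i - 1, 1:])
        D[i, 1:] = np.maximum.accumulate(row)
    pairs: list[tuple[int, int]] = []
    i, j = L, M
    while i > 0 and j > 0:
        here = D[i, j]
        if vals[i - 1, j - 1] > 0 and here == D[i - 1, j - 1] + vals[i - 1, j - 1]:
            pairs.append((i, j))
            i -= 1
            j -= 1
        elif here == D[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return PairwiseAlignment(pairs, (L, M)), float(D[L, M])


def enumerate_alignments(
    L: int, M: int
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every monotone matching of positions 1..L with 1..M exactly once.

    Exponential enumeration; refuses sizes above ``ENUMERATION_GUARD``.
    """
    if L > ENUMERATION_GUARD or M > ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration limited to L, M <= {ENUMERATION_GUARD}; "
            f"got ({L}, {M})"
        )
    if L < 0 or M < 0:
        raise ValueError("lengths must be nonnegative")

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        # matchings using positions >= i in x and >= j in y
        yield ()
        for a in range(i, L + 1):
            for b in range(j, M + 1):
                for rest in rec(a + 1, b + 1):
                    yield ((a, b),) + rest

    return rec(1, 1)
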