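"""Independent brute-force oracles for the test suite.

All computations here are probability-space exhaustive enumerations over
state paths or monotone matchings, written without reference to the
package's dynamic-programming code.  Usable only for tiny inputs.
"""

from __future__ import annotations

import itertools
import math

M, IX, IY = 0, 1, 2


def _emitted_lengths(path):
    L = sum(1 for s in path if s in (M, IX))
    My = sum(1 for s in path if s in (M, IY))
    return L, My


def all_paths(L, My):
    """Every state sequence emitting L symbols into x and My into y."""
    assert L + My <= 10, "oracle enumeration limited to L + M <= 10"
    for n in range(max(L, My), L + My + 1):
        for path in itertools.product((M, IX, IY), repeat=n):
            if _emitted_lengths(path) == (L, My):
                yield path


def path_probability(path, x, y, params):
    """P(path, x, y) in plain probability space.

    Semantics: termination is reachable from the virtual START with
    probability sum_s start(s) * terminate(s); a non-empty path carries the
    complementary (1 - tau_start) factor.
    """
    model = params.match_emission
    ins = params.insert_emission
    tau_start = float(params.start_dist @ params.terminate)
    if not path:
        return tau_start
    p = 1.0 - tau_start
    i = j = 0
    prev = None
    for s in path:
        if prev is None:
            p *= params.start_dist[s]
        else:
            p *= params.transitions[prev, s]
        if s == M:
            p *= model.joint[model.index(x[i + 1]), model.index(y[j + 1])]
            i += 1
            j += 1
        elif s == IX:
            p *= ins[model.index(x[i + 1])]
            i += 1
        else:
            p *= ins[model.index(y[j + 1])]
            j += 1
        prev = s
    return p * params.terminate[prev]


def brute_forward(x, y, params):
    """Total observation probability P(x, y) by path enumeration."""
    return sum(
        path_probability(p, x, y, params) for p in all_paths(len(x), len(y))
    )


def brute_posterior(x, y, params):
    """Posterior match matrix by path enumeration: entry (i-1, j-1) is the
    summed posterior weight of paths aligning x_i to y_j."""
    import numpy as np

    total = 0.0
    post = np.zeros((len(x), len(y)))
    for path in all_paths(len(x), len(y)):
        p = path_probability(path, x, y, params)
        if p == 0.0:
            continue
        total += p
        i = j = 0
        for s in path:
            if s == M:
                post[i, j] += p
                i += 1
                j += 1
            elif s == IX:
                i += 1
            else:
                j += 1
    return post / total


def brute_viterbi(x, y, params):
    """(best path, max path probability) by enumeration; ties broken toward
    the lexicographically smallest path (M < I_x < I_y)."""
    best, best_p = None, -1.0
    for path in sorted(all_paths(len(x), len(y))):
        p = path_probability(path, x, y, params)
        if p > best_p:
            best, best_p = path, p
    return best, best_p


def matching_score(matching, S):
    return sum(S[i - 1, j - 1] for i, j in matching)


def count_matchings(L, My):
    """Closed form: sum_k C(L, k) * C(M, k)."""
    return sum(
        math.comb(L, k) * math.comb(My, k) for k in range(min(L, My) + 1)
    )
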