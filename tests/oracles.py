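"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: local alignment by
exhaustive enumeration of match-column subsequences, and Levenshtein
distance by the textbook dynamic-programming recurrence.
"""

import itertools

from structannot.search import _score_grid


def oracle_best_local(query, target, params):
    """Best local-alignment score by brute-force enumeration.

    Every local alignment is determined by its ordered set of match
    columns (an optimal local alignment never starts or ends with a
    gap); gaps between consecutive match columns cost
    ``gap_open + run_length * gap_extend`` per run per sequence.
    """
    S = _score_grid(query, target, params)
    n, m = S.shape
    go, ge = params.gap_open, params.gap_extend
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for qi in itertools.combinations(range(n), k):
            for ti in itertools.combinations(range(m), k):
                sc = S[qi[0], ti[0]]
                for t in range(1, k):
                    di = qi[t] - qi[t - 1] - 1
                    dj = ti[t] - ti[t - 1] - 1
                    sc += S[qi[t], ti[t]]
                    if di > 0:
                        sc -= go + di * ge
                    if dj > 0:
                        sc -= go + dj * ge
                if sc > best:
                    best = sc
    return best


def levenshtein(a, b):
    """Textbook O(nm) edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
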