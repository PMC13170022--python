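"""Independent global-alignment oracle for identity tests.

Scores every global alignment (match +1, mismatch -1, gap -2) and picks
the lexicographic maximum of (score, matches, -columns): exhaustive path
enumeration below 8 nt, memoized recursion up to ~12 nt.
"""

from functools import lru_cache


def brute_force_identity(a: str, b: str) -> float:
    if len(a) <= 7 and len(b) <= 7:

        def paths(i, j):
            if i == len(a) and j == len(b):
                yield (0, 0, 0)
                return
            if i < len(a) and j < len(b):
                m = a[i] == b[j]
                for s, k, c in paths(i + 1, j + 1):
                    yield (s + (1 if m else -1), k + (1 if m else 0), c - 1)
            if i < len(a):
                for s, k, c in paths(i + 1, j):
                    yield (s - 2, k, c - 1)
            if j < len(b):
                for s, k, c in paths(i, j + 1):
                    yield (s - 2, k, c - 1)

        best = max(paths(0, 0))
    else:

        @lru_cache(maxsize=None)
        def rec(i, j):
            if i == len(a) and j == len(b):
                return (0, 0, 0)
            options = []
            if i < len(a) and j < len(b):
                m = a[i] == b[j]
                s, k, c = rec(i + 1, j + 1)
                options.append((s + (1 if m else -1), k + (1 if m else 0), c - 1))
            if i < len(a):
                s, k, c = rec(i + 1, j)
                options.append((s - 2, k, c - 1))
            if j < len(b):
                s, k, c = rec(i, j + 1)
                options.append((s - 2, k, c - 1))
            return max(options)

        best = rec(0, 0)
    _, matches, neg_cols = best
    return 100.0 * matches / (-neg_cols)
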