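"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: entropies are
computed by a direct formula, knapsacks by subset enumeration, and
hypergeometric tails by enumerating every possible draw.
"""

import itertools
import math


def set_partitions(items):
    """Yield every partition of ``items`` as a list of blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def entropy_bits(weights):
    """Shannon entropy (bits) of a weight vector, computed directly."""
    total = float(sum(weights))
    h = 0.0
    for w in weights:
        if w > 0:
            q = w / total
            h -= q * math.log2(q)
    return h


def brute_knapsack(values, weights, capacity):
    """Optimal 0/1 knapsack value by enumerating all 2^n subsets."""
    n = len(values)
    assert n <= 20, "enumeration oracle is for small instances"
    best_v, best_x = 0.0, tuple([0] * n)
    for mask in range(1 << n):
        w = v = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += weights[i]
                v += values[i]
        if w <= capacity and v > best_v:
            best_v = v
            best_x = tuple(mask >> i & 1 for i in range(n))
    return best_v, best_x


def hypergeom_tail_enum(k, K, n, N):
    """P(overlap >= k) by enumerating every size-n draw from an N-universe
    containing K marked elements."""
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total
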