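"""Independent brute-force oracles for entropy-based quantities.

Everything here works on plain Python sequences with ``collections.Counter``
and explicit subset enumeration — deliberately sharing no code path with the
package's encoded/bincount/cached implementations.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def joint_entropy_nats(columns) -> float:
    """Plug-in joint entropy of parallel symbol sequences, in nats."""
    n = len(columns[0])
    counts = Counter(zip(*columns))
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def normalized_joint_entropy(columns, bin_counts) -> float:
    hmax = sum(math.log(b) for b in bin_counts)
    if hmax == 0.0:
        return 0.0
    return joint_entropy_nats(columns) / hmax


def mmi_oracle(columns, bin_counts=None, normalized: bool = False) -> float:
    """MMI(S) = -sum over non-empty subsets T of (-1)^|T| H(T)."""
    idx = range(len(columns))
    total = 0.0
    for r in range(1, len(columns) + 1):
        for subset in combinations(idx, r):
            if normalized:
                h = normalized_joint_entropy(
                    [columns[i] for i in subset], [bin_counts[i] for i in subset]
                )
            else:
                h = joint_entropy_nats([columns[i] for i in subset])
            total -= ((-1.0) ** r) * h
    return total


def tc_oracle(columns, bin_counts=None, normalized: bool = False) -> float:
    if normalized:
        marg = sum(
            normalized_joint_entropy([c], [b]) for c, b in zip(columns, bin_counts)
        )
        return marg - normalized_joint_entropy(columns, bin_counts)
    return sum(joint_entropy_nats([c]) for c in columns) - joint_entropy_nats(columns)


def brute_force_min_mmi(columns, bin_counts, min_size: int = 3, max_size: int | None = None):
    """Global minimum normalized MMI over all subsets of the given sizes.

    Returns ``(best_indices, best_mmi)``; ties resolved toward the
    lexicographically smallest index tuple. Subset entropies are cached, but
    every MMI is still the explicit inclusion–exclusion sum.
    """
    n = len(columns)
    max_size = max_size if max_size is not None else n
    h_cache: dict[tuple, float] = {}

    def h(subset: tuple) -> float:
        val = h_cache.get(subset)
        if val is None:
            val = normalized_joint_entropy(
                [columns[i] for i in subset], [bin_counts[i] for i in subset]
            )
            h_cache[subset] = val
        return val

    best, best_val = None, math.inf
    for size in range(min_size, max_size + 1):
        for subset in combinations(range(n), size):
            total = 0.0
            for r in range(1, size + 1):
                sign = -((-1.0) ** r)
                for t in combinations(subset, r):
                    total += sign * h(t)
            if total < best_val - 1e-15 or (
                abs(total - best_val) <= 1e-15 and (best is None or subset < best)
            ):
                best, best_val = subset, total
    return best, best_val
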