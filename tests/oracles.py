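"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the LIS oracle
enumerates every subset of triplets with a vectorized bit-mask sweep, and
the variance oracle is a direct transcription of the definition.
"""

import numpy as np


def brute_force_lis_length(triplets) -> int:
    """Longest chain strictly increasing in both coordinates, by exhaustive
    enumeration of all subsets (feasible for up to ~16 triplets)."""
    n = len(triplets)
    if n == 0:
        return 0
    masks = np.arange(1 << n, dtype=np.uint32)
    valid = np.ones(1 << n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # pairs that cannot coexist in a chain: equal or inverted order
            # in either coordinate (i before j in sorted order is irrelevant:
            # a chain is a set here, order is implied by the coordinates)
            if i < j:
                ok = (
                    (triplets[i].p1 < triplets[j].p1 and triplets[i].p2 < triplets[j].p2)
                    or (triplets[j].p1 < triplets[i].p1 and triplets[j].p2 < triplets[i].p2)
                )
                if not ok:
                    pair = np.uint32((1 << i) | (1 << j))
                    valid &= (masks & pair) != pair
    sizes = np.bitwise_count(masks)
    return int(sizes[valid].max())


def gap_variance_oracle(chain) -> float:
    """Population variance of adjacent gap differences, written long-hand."""
    if len(chain) < 3:
        return 0.0
    ds = []
    for a, b in zip(chain, chain[1:]):
        ds.append((b.p1 - a.p1) - (b.p2 - a.p2))
    mean = sum(ds) / len(ds)
    return sum((d - mean) ** 2 for d in ds) / len(ds)
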