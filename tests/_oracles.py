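"""Independent oracles used by the test suite (never the implementation path)."""

from itertools import combinations

import numpy as np
from scipy.integrate import quad


def shell_volume_by_integration(radius_cm: float, height_cm: float, depth_cm: float) -> float:
    """Numerical shell volume: integrate the circumference over the annulus."""
    val, _ = quad(lambda s: 2.0 * np.pi * s, radius_cm - depth_cm, radius_cm)
    return val * height_cm


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for k, block in enumerate(smaller):
            yield smaller[:k] + [[first] + block] + smaller[k + 1 :]
        yield [[first]] + smaller


def max_merge_partition(coords: np.ndarray, cutoff: float):
    """Exhaustive maximal-merging partition under the pairwise distance bound.

    Among partitions whose blocks all have diameter <= cutoff, picks the one
    with (fewest blocks, smallest total within-block pairwise distance rounded
    to 1e-6, lexicographically smallest canonical form).
    """
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    best = None
    for p in set_partitions(list(range(n))):
        pairs = [(a, b) for blk in p for a, b in combinations(blk, 2)]
        if any(d[a, b] > cutoff for a, b in pairs):
            continue
        dist = round(sum(d[a, b] for a, b in pairs), 6)
        canon = tuple(sorted(tuple(sorted(b)) for b in p))
        key = (len(p), dist, canon)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2]
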