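"""Partition-comparison metrics for ground-truth recovery checks."""

from __future__ import annotations

from collections import Counter
from typing import Hashable, Mapping, Sequence

from scipy.special import comb


def adjusted_rand_index(
    labels_a: Mapping[Hashable, Hashable] | Sequence[Hashable],
    labels_b: Mapping[Hashable, Hashable] | Sequence[Hashable],
) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Accepts either two equal-length label sequences or two item->label
    mappings sharing the same keys. 1 = identical partitions, ~0 =
    chance-level agreement. Pair-counting closed form.
    """
    if isinstance(labels_a, Mapping) != isinstance(labels_b, Mapping):
        raise TypeError("labels must both be mappings or both sequences")
    if isinstance(labels_a, Mapping):
        keys = sorted(labels_a, key=str)
        if set(keys) != set(labels_b):
            raise ValueError("partitions cover different item sets")
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        a, b = list(labels_a), list(labels_b)
        if len(a) != len(b):
            raise ValueError("label sequences differ in length")
    n = len(a)
    if n < 2:
        return 1.0
    contingency: Counter[tuple[Hashable, Hashable]] = Counter(zip(a, b))
    sum_nij = sum(comb(c, 2, exact=True) for c in contingency.values())
    sum_ai = sum(comb(c, 2, exact=True) for c in Counter(a).values())
    sum_bj = sum(comb(c, 2, exact=True) for c in Counter(b).values())
    n_pairs = comb(n, 2, exact=True)
    expected = sum_ai * sum_bj / n_pairs
    max_index = (sum_ai + sum_bj) / 2
    if max_index == expected:  # both partitions all-singleton or all-one
        return 1.0
    return (sum_nij - expected) / (max_index - expected)
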