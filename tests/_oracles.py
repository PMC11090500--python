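"""Brute-force reference implementations shared across test modules."""

import numpy as np


def footprint_oracle(counts, threshold, min_len=5, max_len=50):
    """Enumerate protected regions directly from their definition."""
    n = len(counts)
    hits = []
    for s in range(1, n):
        if counts[s] >= threshold or counts[s - 1] < threshold:
            continue  # not the start of a maximal below-threshold run
        e = s
        while e < n and counts[e] < threshold:
            e += 1
        if e == n:
            continue
        if not (min_len <= e - s <= max_len):
            continue
        if counts[s - 1] > threshold and counts[e] > threshold:
            hits.append((s, e))
    return hits
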