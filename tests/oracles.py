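"""Independent oracles used to cross-check the implementation.

These deliberately avoid the library's code paths: the brute-force scanner
walks characters directly instead of using compiled regex machinery, the
expected-density oracle is an exact renewal-theory computation, and the
Fisher oracle sums the hypergeometric distribution explicitly.
"""

from __future__ import annotations

import itertools
from math import comb


def brute_force_scan(seq: str, min_track_len=3, min_tracks=4, loop_min=1, loop_max=12):
    """Enumerate maximal G runs by direct character inspection and chain them.

    Returns (start, end, n_tracks) triples of maximal non-overlapping hits.
    """
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_track_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    hits = []
    k = 0
    while k < len(runs):
        m = k
        while m + 1 < len(runs) and loop_min <= runs[m + 1][0] - runs[m][1] <= loop_max:
            m += 1
        if m - k + 1 >= min_tracks:
            hits.append((runs[k][0], runs[m][1], m - k + 1))
        k = m + 1
    return hits


def chain_continuation_probability(g: float, loop_max: int = 12, min_track_len: int = 3) -> float:
    """Exact P(the next qualifying G run starts within loop_max bases after a
    run end) for an i.i.d. sequence with per-base G probability ``g``.

    Computed by exhaustive enumeration over the loop_max + min_track_len - 1
    bases following a run end (the base at the run end is non-G by run
    maximality).
    """
    L = loop_max + min_track_len - 1
    total = 0.0
    for bits in itertools.product((0, 1), repeat=L):
        seq = (0,) + bits
        if any(
            seq[p - 1] == 0 and all(seq[p + q] for q in range(min_track_len))
            for p in range(1, loop_max + 1)
        ):
            w = 1.0
            for b in bits:
                w *= g if b else 1.0 - g
            total += w
    return total


def expected_hit_density_per_mbp(
    gc: float, loop_max: int = 12, min_track_len: int = 3, min_tracks: int = 4
) -> float:
    """Exact expected PQS density (hits/Mbp, both strands) in an i.i.d.
    genome with symmetric G/C split, under the greedy chain rule.

    Qualifying runs start at rate (1-g) g^k per base (previous base non-G,
    then >= k Gs); runs chain independently with probability p_c, so chains
    arrive at rate (1-g) g^k (1-p_c) and a chain reaches >= m tracks with
    probability p_c^(m-1). The expected fraction of hits with more than m
    tracks is p_c itself.
    """
    g = gc / 2.0
    pc = chain_continuation_probability(g, loop_max, min_track_len)
    per_base = (1.0 - g) * g**min_track_len * (1.0 - pc) * pc ** (min_tracks - 1)
    return 2.0 * per_base * 1e6  # both strands


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p by explicit hypergeometric summation."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> float:
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
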