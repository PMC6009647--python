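"""Brute-force oracle for the monotone label-to-site matching objective.

Enumerates every monotone partial matching between labels and sites and
scores it under the same objective as the dynamic program: taper (or flat)
match scores inside the window, penalties for skipped sites and extra
labels, free terminal site-gaps under free_ends.  Exponential — for tiny
instances only.
"""

from itertools import combinations

import numpy as np


def enumerate_matchings(L, S):
    """All monotone injective partial matchings of L labels to S sites."""
    for k in range(min(L, S) + 1):
        for labels in combinations(range(L), k):
            for sites in combinations(range(S), k):
                yield list(zip(labels, sites))


def score_matching(pairs, pos, sites, params):
    """Score one matching; None if any pair violates the match window."""
    L, S = len(pos), len(sites)
    total = 0.0
    for i, j in pairs:
        d = abs(pos[i] - sites[j])
        if d > params.match_width:
            return None
        total += (params.match_score if params.flat_score
                  else params.match_score * (1.0 - d / params.match_width))
    total -= params.extra_label_penalty * (L - len(pairs))
    matched_sites = {j for _, j in pairs}
    if params.free_ends:
        if pairs:
            j_first, j_last = pairs[0][1], pairs[-1][1]
            interior = [j for j in range(S)
                        if j not in matched_sites and j_first < j < j_last]
        else:
            interior = []
        total -= params.miss_site_penalty * len(interior)
    else:
        total -= params.miss_site_penalty * (S - len(matched_sites))
    return total


def oracle_align(pos, sites, params):
    """Best (score, pairs) by exhaustive enumeration.

    Tie-break mirrors the DP: higher score, then more matches, then the
    lexicographically smallest pair list.
    """
    pos = np.asarray(pos, dtype=float)
    sites = np.asarray(sites, dtype=float)
    best = None
    for pairs in enumerate_matchings(len(pos), len(sites)):
        s = score_matching(pairs, pos, sites, params)
        if s is None:
            continue
        key = (s, len(pairs), [(-i, -j) for i, j in pairs])
        if best is None or _better(key, best[0]):
            best = (key, pairs)
    assert best is not None  # the empty matching is always feasible
    return best[0][0], best[1]


def _better(key_a, key_b):
    """True if key_a beats key_b: score, matches desc; pair list lex-min."""
    if abs(key_a[0] - key_b[0]) > 1e-12:
        return key_a[0] > key_b[0]
    if key_a[1] != key_b[1]:
        return key_a[1] > key_b[1]
    return key_a[2] > key_b[2]  # negated pairs: larger == lex-smaller
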