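"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against different algorithms than
the package (full / banded dynamic programming instead of case-split
string checks) so the two routes can disagree if either is wrong.
"""

from __future__ import annotations


def levenshtein(a: str, b: str) -> int:
    """Full-matrix Levenshtein distance; 'N' matches nothing."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cost = 0 if (ca == cb and ca != "N") else 1
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost))
        prev = cur
    return prev[-1]


def min_distance_at(read: str, start: int, pattern: str, band: int = 1) -> int:
    """min over window ends of lev(pattern, read[start:end]), banded.

    Considers windows from len(pattern)-band to len(pattern)+band read
    bases; returns band+1 when everything in the band exceeds it.
    """
    m = len(pattern)
    limit = band + 1
    max_j = min(m + band, len(read) - start)
    # d[i][j] = lev(pattern[:i], read[start:start+j]) within the band
    prev = {j: j for j in range(0, min(band, max_j) + 1)}
    for i in range(1, m + 1):
        cur: dict[int, int] = {}
        lo, hi = max(0, i - band), min(max_j, i + band)
        for j in range(lo, hi + 1):
            best = limit
            if j == 0:
                best = i
            else:
                ca = pattern[i - 1]
                cb = read[start + j - 1]
                cost = 0 if (ca == cb and ca != "N") else 1
                if j - 1 in prev:
                    best = min(best, prev[j - 1] + cost)
                if j in prev:
                    best = min(best, prev[j] + 1)
                if j - 1 in cur:
                    best = min(best, cur[j - 1] + 1)
            cur[j] = best
        prev = cur
    out = limit
    for j in range(max(0, m - band), max_j + 1):
        if j in prev:
            out = min(out, prev[j])
    return out


def scan_linker(read: str, linker: str, max_edits: int = 1):
    """All (distance, start) with a window within max_edits, by brute force."""
    hits = []
    for s in range(len(read)):
        d = min_distance_at(read, s, linker, band=max_edits)
        if d <= max_edits:
            hits.append((d, s))
    return hits


def whitelist_candidates(block: str, entries, max_edits: int = 1):
    """Whitelist entries within max_edits of block, by exhaustive DP."""
    if block in entries:
        return [block]
    if max_edits == 0:
        return []
    return [e for e in entries if levenshtein(block, e) <= max_edits]
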