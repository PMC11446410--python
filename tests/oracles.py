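"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — published
tables typed in by hand, quadratic scans, exhaustive searches — and shares
no code with the library paths it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

# ---------------------------------------------------------------------------
# Unified nearest-neighbor duplex thermodynamics (SantaLucia 1998 / Allawi &
# SantaLucia 1997 parameter set). dH kcal/mol, dS cal/(mol K); values for
# the 16 top-strand dinucleotides follow from the 10 unique stacks via
# dH(XY) = dH(revcomp(XY)).
# ---------------------------------------------------------------------------

NN_DH_DS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)   # per terminal A:T pair
INIT_GC = (0.1, -2.8)  # per terminal G:C pair
R_GAS = 1.987  # cal/(mol K)


def tm_nearest_neighbor(
    seq: str,
    na_molar: float,
    total_conc_molar: float,
    formamide_pct: float = 0.0,
) -> float:
    """Brute-force NN summation Tm (degC) for a non-self-complementary
    DNA:DNA duplex: stack-by-stack dH/dS sums, terminal initiation terms,
    SantaLucia 1998 entropic salt correction, C_T/4 concentration term,
    linear formamide offset of 0.6 degC per percent."""
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_DH_DS[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_AT if terminal in "AT" else INIT_GC
        dh += h
        ds += s
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na_molar)
    tm_k = 1000.0 * dh / (ds_salt + R_GAS * math.log(total_conc_molar / 4.0))
    return tm_k - 273.15 - 0.6 * formamide_pct


# ---------------------------------------------------------------------------
# Non-overlapping interval selection
# ---------------------------------------------------------------------------

def max_nonoverlap_subsets_bruteforce(intervals, min_gap: int) -> int:
    """Maximum number of mutually compatible intervals by enumerating every
    subset. Exponential; use only for small n."""
    n = len(intervals)
    best = 0
    for mask in range(1 << n):
        chosen = sorted(
            (intervals[i] for i in range(n) if mask >> i & 1),
            key=lambda iv: iv[0],
        )
        if all(
            b[0] >= a[1] + min_gap for a, b in zip(chosen, chosen[1:])
        ):
            best = max(best, len(chosen))
    return best


def max_nonoverlap_dp(intervals, min_gap: int) -> int:
    """Exact maximum via top-down recursion over (index, last_end) —
    independent of the greedy earliest-end implementation."""
    ivs = sorted(intervals, key=lambda iv: (iv[0], iv[1]))

    @lru_cache(maxsize=None)
    def best(i: int, last_end: int) -> int:
        if i == len(ivs):
            return 0
        skip = best(i + 1, last_end)
        take = 0
        if last_end < 0 or ivs[i][0] >= last_end + min_gap:
            take = 1 + best(i + 1, ivs[i][1])
        return max(skip, take)

    result = best(0, -1)
    best.cache_clear()
    return result


# ---------------------------------------------------------------------------
# Maximal exact substring matches (off-target oracle)
# ---------------------------------------------------------------------------

def maximal_exact_matches(query: str, subject: str, min_len: int):
    """All maximal contiguous exact matches of length >= min_len between
    query and subject, by the quadratic diagonal scan: every (i, j) start
    with mismatching (or absent) previous characters is extended forward.
    Returns a set of (query_start, subject_start, length); N never matches.
    """
    out = set()
    for i in range(len(query)):
        for j in range(len(subject)):
            if query[i] != subject[j] or query[i] == "N":
                continue
            if i > 0 and j > 0 and query[i - 1] == subject[j - 1] \
                    and query[i - 1] != "N":
                continue  # not a maximal start
            length = 0
            while (
                i + length < len(query)
                and j + length < len(subject)
                and query[i + length] == subject[j + length]
                and query[i + length] != "N"
            ):
                length += 1
            if length >= min_len:
                out.add((i, j, length))
    return out


# ---------------------------------------------------------------------------
# All-pairs colocalization oracle
# ---------------------------------------------------------------------------

def coloc_counts_bruteforce(a, b, radius, strict=True):
    """Directional near counts by explicit all-pairs distance comparison."""

    def near(p, others):
        for q in others:
            d = math.dist(p, q)
            if (d < radius) if strict else (d <= radius):
                return True
        return False

    n_ab = sum(near(p, b) for p in a)
    n_ba = sum(near(q, a) for q in b)
    return n_ab, n_ba
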