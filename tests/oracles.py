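"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
windowed/cached implementations: plain string scanning, explicit
hypergeometric/binomial enumeration and O(n^2) pair comparison.
"""
from __future__ import annotations

import itertools
import math
from math import comb

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
IUPAC_SETS = {
    "a": "A", "c": "C", "g": "G", "t": "T",
    "r": "AG", "y": "CT", "s": "CG", "w": "AT", "k": "GT", "m": "AC",
    "b": "CGT", "d": "AGT", "h": "ACT", "v": "ACG", "n": "ACGT",
}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def pattern_fits(tri: str, pattern: str) -> bool:
    return all(tri[i] in IUPAC_SETS[pattern[i]] for i in range(3))


def brute_force_counts(records, sequences, motif_text: str, window: int = 20):
    """(mut_motif, mut_class, ctx_motif, ctx_base) by base-by-base scanning.

    ``records`` are (chrom, pos1, ref, alt) tuples already restricted to the
    motif's base-change class; ``sequences`` maps chrom -> string.
    """
    left, right = motif_text.split(">")
    pattern = left.lower()
    ref_base, alt_base = left[1].upper(), right[1].upper()
    mut_motif = 0
    ctx_motif = 0
    ctx_base = 0
    for chrom, pos, ref, alt in records:
        seq = sequences[chrom]
        # does the mutation itself match the motif (either strand)?
        if 2 <= pos <= len(seq) - 1:
            tri = seq[pos - 2 : pos + 1]
            if ref == ref_base and alt == alt_base and pattern_fits(tri, pattern):
                mut_motif += 1
            elif (ref == COMP[ref_base] and alt == COMP[alt_base]
                  and pattern_fits(rc(tri), pattern)):
                mut_motif += 1
        # scan every base of the +/- window independently
        for w in range(pos - window, pos + window + 1):
            if w < 1 or w > len(seq):
                continue
            b = seq[w - 1]
            if b == ref_base or b == COMP[ref_base]:
                ctx_base += 1
            if 2 <= w <= len(seq) - 1:
                tri = seq[w - 2 : w + 1]
                if tri[1] == ref_base and pattern_fits(tri, pattern):
                    ctx_motif += 1
                if rc(tri)[1] == ref_base and pattern_fits(rc(tri), pattern):
                    ctx_motif += 1
    return mut_motif, len(records), ctx_motif, ctx_base


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by explicit hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if n - col1 < row1 - k:
            continue
        p += comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
    return min(p, 1.0)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all tables no more probable than observed."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)

    def prob(k):
        if row1 - k > n - col1 or k > col1 or k < 0:
            return 0.0
        return comb(col1, k) * comb(n - col1, row1 - k) / denom

    p_obs = prob(a)
    total = sum(prob(k) for k in range(0, min(row1, col1) + 1)
                if prob(k) <= p_obs * (1 + 1e-9))
    return min(total, 1.0)


def binom_two_sided(k: int, n: int) -> float:
    """min(1, 2*min(tails)) by full pmf summation at p = 1/2."""
    pmf = [comb(n, i) * 0.5 ** n for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def _ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _rho(rx, ry):
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_perm(x, y, sided="one"):
    """(rho, p) by enumerating all n! permutations of one variable."""
    rx, ry = _ranks(x), _ranks(y)
    rho_obs = _rho(rx, ry)
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _rho(rx, [ry[i] for i in perm])
        total += 1
        if sided == "one":
            count += r >= rho_obs - 1e-12
        else:
            count += abs(r) >= abs(rho_obs) - 1e-12
    return rho_obs, count / total


def ranksum_exact(x, y, sided="two"):
    """Exact rank-sum p by enumerating all rank splits."""
    pooled = list(x) + list(y)
    ranks = _ranks(pooled)
    n1 = len(x)
    obs = sum(ranks[:n1])
    stats = [sum(ranks[i] for i in combo)
             for combo in itertools.combinations(range(len(pooled)), n1)]
    mean = sum(stats) / len(stats)
    if sided == "two":
        hits = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    else:
        hits = sum(s >= obs - 1e-12 for s in stats)
    return hits / len(stats)


def hotspot_oracle(svs, window):
    """All-pairs O(n^2) hotspot flags over (chrom1,pos1,chrom2,pos2,donor) tuples."""
    n = len(svs)
    flags = [False] * n
    for i in range(n):
        for j in range(n):
            if svs[i][4] == svs[j][4]:
                continue
            for ci, pi in ((svs[i][0], svs[i][1]), (svs[i][2], svs[i][3])):
                for cj, pj in ((svs[j][0], svs[j][1]), (svs[j][2], svs[j][3])):
                    if ci == cj and abs(pi - pj) <= window:
                        flags[i] = True
    return flags
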