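"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (quadratic dynamic
programs, exhaustive enumeration, union-find) and deliberately shares no
code with the package.
"""

from __future__ import annotations

import itertools


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook unit-cost edit distance."""
    m, n = len(a), len(b)
    row = list(range(n + 1))
    for i in range(1, m + 1):
        prev, row[0] = row[0], i
        for j in range(1, n + 1):
            cur = row[j]
            row[j] = min(row[j] + 1, row[j - 1] + 1, prev + (a[i - 1] != b[j - 1]))
            prev = cur
    return row[n]


def free_divergence_brute(barcode: str, window: str) -> int:
    """Minimum Levenshtein distance from the barcode to any prefix of the
    window, by explicit enumeration of every prefix."""
    return min(levenshtein_dp(barcode, window[:k]) for k in range(len(window) + 1))


def fit_score_dp(read: str, template: str, match=1, mismatch=-1, gap=-1) -> int:
    """Best score aligning the full template against a prefix of the read
    ('N' in the template matches anything).  Quadratic DP, no vectorisation."""
    tl, rl = len(template), len(read)
    NEG = -(10**9)
    H = [[NEG] * (rl + 1) for _ in range(tl + 1)]
    H[0][0] = 0
    for j in range(1, rl + 1):
        H[0][j] = gap * j
    for i in range(1, tl + 1):
        H[i][0] = gap * i
        tc = template[i - 1]
        for j in range(1, rl + 1):
            s = match if (tc == "N" or tc == read[j - 1]) else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    return max(H[tl])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def dedup_umis_brute(counts: dict[str, int]) -> int:
    """Directional-network UMI collapse by explicit rule application.

    Full pairwise free-divergence matrix; directed edge A->B iff
    fd(A, B) == 1 and n_A >= 2*n_B - 1; then one incoming edge per node
    (highest-count parent, ties to the lexicographically smallest
    sequence); weak components counted with union-find.
    """
    if not counts:
        return 0
    umis = sorted(counts)
    edges = []
    for a, b in itertools.permutations(umis, 2):
        if free_divergence_brute(a, b) == 1 and counts[a] >= 2 * counts[b] - 1:
            edges.append((a, b))
    parents: dict[str, list[str]] = {}
    for a, b in edges:
        parents.setdefault(b, []).append(a)
    uf = _UnionFind(umis)
    for child, cands in parents.items():
        keep = min(cands, key=lambda p: (-counts[p], p))
        uf.union(keep, child)
    return len({uf.find(u) for u in umis})


def bh_adjust_brute(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-squared for a 2x2 table, no continuity
    correction: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def binom_interval(n: int, p: float, alpha: float = 0.05) -> tuple[int, int]:
    """Central (equal-tail) binomial acceptance interval for a count."""
    from scipy.stats import binom

    return int(binom.ppf(alpha / 2, n, p)), int(binom.ppf(1 - alpha / 2, n, p))
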