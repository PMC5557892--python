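"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results by exhaustive enumeration or direct
summation, sharing no code with the package's optimized paths.
"""

from __future__ import annotations

import itertools
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# seed-site scanner: enumerate every site variant string, scan leftmost

def seed_site_variants(mirna: str) -> list[tuple[str, list[tuple[str, int]]]]:
    """[(category, [(site_string, detail), ...]), ...] in priority order."""
    s8 = rc(mirna[1:8]) + "A"
    s7m8 = rc(mirna[1:8])
    s7a1 = rc(mirna[1:7]) + "A"
    s6 = rc(mirna[1:7])
    s5 = rc(mirna[1:6])
    out = [
        ("8mer", [(s8, None)]),
        ("7mer-m8", [(s7m8, None)]),
        ("7mer-A1", [(s7a1, None)]),
        ("6mer", [(s6, None)]),
        ("5mer", [(s5, None)]),
    ]
    for cat, base in (("mismatch-8mer", s8), ("mismatch-7mer", s7m8), ("mismatch-6mer", s6)):
        variants = []
        for i in range(len(base)):
            for b in "ACGT":
                if b != base[i]:
                    variants.append((base[: i] + b + base[i + 1 :], i))
        out.append((cat, variants))
    for cat, base in (("bulged-8mer", s8), ("bulged-7mer", s7m8)):
        variants = []
        for i in range(1, len(base)):
            for b in "ACGT":
                variants.append((base[:i] + b + base[i:], i))
        out.append((cat, variants))
    return out


def classify_seed_bruteforce(mirna: str, target: str):
    """(category, leftmost position, detail) by scanning every variant."""
    for cat, variants in seed_site_variants(mirna):
        best = None
        for var, detail in variants:
            p = target.find(var)
            while p != -1:
                # a mismatch variant must not be the exact canonical site
                if best is None or p < best[0]:
                    best = (p, detail)
                p = target.find(var, p + 1)
        if best is not None:
            return cat, best[0], best[1]
    return "none", -1, None


# ---------------------------------------------------------------------------
# duplex enumeration under the gap caps

PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def _legal(a: int, b: int, loop_cap: int = 15, bulge_cap: int = 5) -> bool:
    if a == 0 and b == 0:
        return True
    if a > 0 and b > 0:
        return a <= loop_cap and b <= loop_cap
    return max(a, b) <= bulge_cap


def enumerate_duplexes(mirna: str, target: str, forced=frozenset()):
    """All legal pair lists [(i, k)] in (miRNA index, reversed-target
    index) coordinates, yielded with (score incl. forced bonus, npairs)."""
    t_rev = target[::-1]
    n, m = len(mirna), len(t_rev)
    pairable = [
        (i, k)
        for i in range(n)
        for k in range(m)
        if (mirna[i], t_rev[k]) in PAIR_SCORES
    ]

    def extend(structure):
        yield list(structure)
        last = structure[-1] if structure else None
        for i, k in pairable:
            if last is not None:
                a, b = i - last[0] - 1, k - last[1] - 1
                if a < 0 or b < 0 or not _legal(a, b):
                    continue
            yield from extend(structure + [(i, k)])

    for st in extend([]):
        score = sum(
            PAIR_SCORES[(mirna[i], t_rev[k])] + (1000 if i in forced else 0)
            for i, k in st
        )
        yield st, score, len(st)


def best_duplex_bruteforce(mirna: str, target: str, forced=frozenset()):
    """Optimal (score, npairs, lexicographically smallest pair list)."""
    best_val = (0, 0)
    best_structs = [[]]
    for st, score, npairs in enumerate_duplexes(mirna, target, forced):
        val = (score, npairs)
        if val > best_val:
            best_val, best_structs = val, [st]
        elif val == best_val:
            best_structs.append(st)
    return best_val[0], best_val[1], min(best_structs)


# ---------------------------------------------------------------------------
# hypergeometric tails by direct summation

def hypergeom_tail_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] summed directly from binomial coefficients."""
    if k <= 0:
        return 1.0
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if N - K >= n - x >= 0:
            acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating the margin-fixed tables."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    total = comb(N, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / total

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


# ---------------------------------------------------------------------------
# ceRNA windows by brute force

def cerna_bruteforce(clusters, min_clusters=3, min_chimeras=5, window=3000):
    """All (chrom, strand) maximal merged regions where some <=window-bp
    window anchored at a qualifying cluster start holds >= min_clusters
    qualifying clusters."""
    strong = [c for c in clusters if c.chimera_count >= min_chimeras]
    spans = []
    for anchor in strong:
        group = [
            c
            for c in strong
            if c.span.chrom == anchor.span.chrom
            and c.span.strand == anchor.span.strand
            and c.span.start >= anchor.span.start
            and c.span.end - anchor.span.start <= window
        ]
        if len(group) >= min_clusters:
            spans.append(
                (
                    anchor.span.chrom,
                    anchor.span.strand,
                    anchor.span.start,
                    max(c.span.end for c in group),
                )
            )
    merged = []
    for chrom, strand, s, e in sorted(spans):
        if merged and merged[-1][0] == chrom and merged[-1][1] == strand and s <= merged[-1][3]:
            prev = merged[-1]
            merged[-1] = (chrom, strand, prev[2], max(prev[3], e))
        else:
            merged.append((chrom, strand, s, e))
    return merged


def all_kmers(k: int):
    for tup in itertools.product("ACGT", repeat=k):
        yield "".join(tup)
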