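"""Constrained miRNA:target duplex prediction and binding-mode clustering.

The duplex model is a maximum-score intermolecular co-fold: the miRNA
(5'->3') pairs antiparallel with the target, pairs may not cross, no
intramolecular structure is considered, and consecutive pairs may be
separated by bounded unpaired stretches (internal loops up to 15 nt per
side, bulges up to 5 nt per side; dangling ends are free).  Pair scores
are GC=3, AU=2, GU=1.  Perfect canonical seed matches force pairing of
the matched seed positions; mismatch/bulge sites trigger two constrained
runs (forcing miRNA positions 3-4 or 5-6) of which the structure with
more seed-region pairs is kept.  The result is a binary pairing vector
over miRNA positions, the substrate for k-means binding-mode groups.

Optima are tie-broken deterministically: maximize score, then number of
pairs, then take the lexicographically smallest pair list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.cluster import KMeans

from . import seq
from .intervals import GenomicInterval
from .seeds import SeedMatch, classify_seed

LOOP_CAP = 15  # max unpaired nt per side in an internal loop
BULGE_CAP = 5  # max unpaired nt on the bulged side
FORCED_BONUS = 1000  # added to the score of any pair at a forced miRNA position
_NPAIR_BITS = 7  # packs (score, npairs) into one int; npairs < 128

TARGET_WINDOW = 75
MAX_CLUSTER_SPAN = 100


@dataclass(frozen=True)
class DuplexStructure:
    pairing_vector: tuple  # 0/1 per miRNA position (1-based position i -> index i-1)
    score: int
    pairs: tuple  # ((mirna_pos_0based, target_pos_0based), ...)
    constraints_used: tuple = ()
    fallback_unconstrained: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _legal_gap(a: int, b: int) -> bool:
    """Legality of (a, b) unpaired nucleotides between consecutive pairs."""
    if a == 0 and b == 0:
        return True
    if a > 0 and b > 0:
        return a <= LOOP_CAP and b <= LOOP_CAP
    return max(a, b) <= BULGE_CAP


_GAP_MASK = np.array(
    [[_legal_gap(a, b) for b in range(LOOP_CAP + 1)] for a in range(LOOP_CAP + 1)],
    dtype=bool,
)


def _pair_matrix(mirna: str, target_rev: str, forced: frozenset[int]) -> np.ndarray:
    """Encoded base value of pairing miRNA i with reversed-target k
    (packed (score, 1) with the forced-position bonus); 0 where no pair."""
    n, m = len(mirna), len(target_rev)
    base = np.zeros((n, m), dtype=np.int64)
    for i, a in enumerate(mirna):
        for k, b in enumerate(target_rev):
            s = seq.pair_score(a, b)
            if s:
                if i in forced:
                    s += FORCED_BONUS
                base[i, k] = (s << _NPAIR_BITS) + 1
    return base


def _suffix_dp(base: np.ndarray) -> np.ndarray:
    """G[i,k] = best encoded value of a structure whose first pair is (i,k)."""
    n, m = base.shape
    G = np.zeros((n, m), dtype=np.int64)
    legal = [
        (a, b)
        for a in range(LOOP_CAP + 1)
        for b in range(LOOP_CAP + 1)
        if _GAP_MASK[a, b]
    ]
    for i in range(n - 1, -1, -1):
        row = np.full(m, -1, dtype=np.int64)
        for a, b in legal:
            ii = i + 1 + a
            if ii >= n:
                continue
            shift = 1 + b
            if shift >= m:
                continue
            row[: m - shift] = np.maximum(row[: m - shift], G[ii, shift:])
        succ = np.maximum(row, 0)
        G[i] = np.where(base[i] > 0, base[i] + succ, 0)
    return G


def _traceback(base: np.ndarray, G: np.ndarray) -> list[tuple[int, int]]:
    """Lexicographically smallest pair list among encoded-value optima."""
    best = int(G.max(initial=0))
    if best <= 0:
        return []
    pairs: list[tuple[int, int]] = []
    # first pair: smallest (i, k) achieving the optimum
    cand = np.argwhere(G == best)  # argwhere is row-major sorted
    i, k = map(int, cand[0])
    while True:
        pairs.append((i, k))
        remaining = int(G[i, k] - base[i, k])
        if remaining <= 0:
            return pairs
        found = None
        n, m = base.shape
        for a in range(LOOP_CAP + 1):
            ii = i + 1 + a
            if ii >= n or found is not None:
                break
            for b in range(LOOP_CAP + 1):
                kk = k + 1 + b
                if kk >= m:
                    break
                if _GAP_MASK[a, b] and G[ii, kk] == remaining:
                    found = (ii, kk)  # a,b ascending -> first hit is lex-min
                    break
        if found is None:  # pragma: no cover - DP consistency guard
            raise RuntimeError("duplex traceback failed")
        i, k = found


def _optimal_duplex(
    mirna: str, target: str, forced: frozenset[int]
) -> tuple[list[tuple[int, int]], int, int]:
    """Best pair list; returns (pairs as (mirna_i, target_j), score, n_forced_paired).

    Pair indices are 0-based on the miRNA and on the target (5'->3')."""
    target_rev = target[::-1]
    base = _pair_matrix(mirna, target_rev, forced)
    G = _suffix_dp(base)
    pairs_rev = _traceback(base, G)
    m = len(target)
    pairs = [(i, m - 1 - k) for i, k in pairs_rev]
    raw_score = 0
    for i, j in pairs:
        raw_score += seq.pair_score(mirna[i], target[j])
    n_forced = sum(1 for i, _ in pairs if i in forced)
    return pairs, raw_score, n_forced


def _forced_positions(seed_match: SeedMatch, mirna_len: int) -> frozenset[int]:
    """0-based miRNA indices forced to pair for a perfect canonical site."""
    span = {
        "8mer": range(1, 8),  # positions 2-8 (A1 is target-encoded, not paired)
        "7mer-m8": range(1, 8),
        "7mer-A1": range(1, 7),
        "6mer": range(1, 7),
        "5mer": range(1, 6),
    }.get(seed_match.category)
    if span is None:
        return frozenset()
    return frozenset(i for i in span if i < mirna_len)


def predict_duplex(
    mirna_sequence: str,
    target_window: str,
    seed_match: Optional[SeedMatch] = None,
) -> DuplexStructure:
    """Predict the constrained duplex structure of a miRNA on a target.

    Perfect canonical seed -> matched seed positions forced; mismatch or
    bulged seed -> two runs forcing miRNA positions {3,4} and {5,6},
    keeping the run with more pairs in positions 2-8 (tie: more total
    pairs, then the {3,4} run); no seed -> unconstrained.  Infeasible
    constraints fall back to the unconstrained optimum, flagged.
    """
    m = seq.normalize(mirna_sequence)
    t = seq.normalize(target_window)
    if len(t) > MAX_CLUSTER_SPAN:
        raise ValueError(f"target window longer than {MAX_CLUSTER_SPAN} nt")
    if seed_match is None:
        seed_match = classify_seed(m, t)

    def run(forced: frozenset[int]) -> tuple[list, int, int, bool]:
        pairs, score, n_forced = _optimal_duplex(m, t, forced)
        feasible = n_forced == len(forced)
        return pairs, score, n_forced, feasible

    if seed_match.category in ("8mer", "7mer-m8", "7mer-A1", "6mer", "5mer"):
        forced = _forced_positions(seed_match, len(m))
        pairs, score, _, feasible = run(forced)
        if feasible:
            return DuplexStructure(
                _vector(pairs, len(m)), score, tuple(pairs), tuple(sorted(forced))
            )
        pairs, score, _, _ = run(frozenset())
        return DuplexStructure(
            _vector(pairs, len(m)), score, tuple(pairs), (), fallback_unconstrained=True
        )

    if seed_match.category.startswith(("mismatch-", "bulged-")):
        results = []
        for forced in (frozenset({2, 3}), frozenset({4, 5})):  # positions {3,4}, {5,6}
            pairs, score, _, feasible = run(forced)
            if feasible:
                seed_pairs = sum(1 for i, _ in pairs if 1 <= i <= 7)
                results.append((seed_pairs, len(pairs), forced, pairs, score))
        if results:
            # more seed-region pairs, then more total pairs, then the {3,4} run
            seed_pairs, _, forced, pairs, score = max(
                results, key=lambda r: (r[0], r[1], -min(r[2]))
            )
            return DuplexStructure(
                _vector(pairs, len(m)), score, tuple(pairs), tuple(sorted(forced))
            )
        pairs, score, _, _ = run(frozenset())
        return DuplexStructure(
            _vector(pairs, len(m)), score, tuple(pairs), (), fallback_unconstrained=True
        )

    pairs, score, _, _ = run(frozenset())
    return DuplexStructure(_vector(pairs, len(m)), score, tuple(pairs))


def _vector(pairs: Sequence[tuple[int, int]], mirna_len: int) -> tuple:
    v = [0] * mirna_len
    for i, _ in pairs:
        v[i] = 1
    return tuple(v)


# ---------------------------------------------------------------------------
# target window preparation

def prepare_target_window(
    span: GenomicInterval, genome, window: int = TARGET_WINDOW
) -> Optional[tuple[str, GenomicInterval, bool]]:
    """Fixed-width target window for duplex prediction.

    Cluster spans longer than 100 nt are omitted (returns None); spans
    of 76-100 nt are trimmed symmetrically to 75; shorter spans are
    extended symmetrically from the genome.  Returns (sequence, window
    interval, clipped_flag); the sequence is strand-oriented 5'->3'."""
    from .io import GenomeSequence

    gen = genome if isinstance(genome, GenomeSequence) else GenomeSequence(genome)
    length = len(span)
    if length > MAX_CLUSTER_SPAN:
        return None
    if length > window:
        trim = length - window
        left = trim // 2
        start = span.start + left
        end = start + window
    else:
        ext = window - length
        left = ext // 2
        start = span.start - left
        end = start + window
    clipped = False
    chrom_len = gen.chrom_length(span.chrom)
    if start < 0:
        start, clipped = 0, True
    if end > chrom_len:
        end, clipped = chrom_len, True
    iv = GenomicInterval(span.chrom, start, end, span.strand)
    return gen.fetch_interval(iv), iv, clipped


# ---------------------------------------------------------------------------
# structure clustering and per-miRNA group enrichment

@dataclass
class StructureGroupAssignment:
    labels: np.ndarray  # cluster id per structure, 1..k
    centroids: np.ndarray  # k x n_positions mean pairing vectors
    wcss_by_k: dict[int, float]  # within-cluster sum of squares, k=3..12


def pad_pairing_matrix(vectors: Sequence[Sequence[int]]) -> np.ndarray:
    """Right-pad pairing vectors with zeros to the longest miRNA."""
    width = max(len(v) for v in vectors)
    mat = np.zeros((len(vectors), width), dtype=float)
    for r, v in enumerate(vectors):
        mat[r, : len(v)] = v
    return mat


def cluster_structures(
    pairing_matrix: np.ndarray,
    k: int = 8,
    n_starts: int = 50,
    random_state: int = 1234,
    elbow_range: range = range(3, 13),
) -> StructureGroupAssignment:
    """k-means partition of binary pairing vectors into binding modes,
    with a within-cluster sum-of-squares curve over k for elbow support."""
    X = np.asarray(pairing_matrix, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} structures, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=random_state)
    labels = km.fit_predict(X) + 1
    wcss = {}
    for kk in elbow_range:
        if kk > X.shape[0]:
            break
        wcss[kk] = float(
            KMeans(n_clusters=kk, n_init=max(5, n_starts // 5), random_state=random_state)
            .fit(X)
            .inertia_
        )
    return StructureGroupAssignment(labels, km.cluster_centers_, wcss)


def group_enrichment(
    labels: Sequence[int], mirna_names: Sequence[str]
) -> "pd.DataFrame":  # noqa: F821
    """Two-sided Fisher exact test of each miRNA's distribution over
    structure groups against all interactions."""
    import pandas as pd

    labels = np.asarray(labels)
    names = np.asarray(mirna_names)
    rows = []
    for group in sorted(set(labels.tolist())):
        in_group = labels == group
        for mirna in sorted(set(names.tolist())):
            of_mirna = names == mirna
            a = int(np.sum(of_mirna & in_group))
            b = int(np.sum(of_mirna & ~in_group))
            c = int(np.sum(~of_mirna & in_group))
            d = int(np.sum(~of_mirna & ~in_group))
            if a + c == 0:  # empty group
                p = 1.0
            else:
                _, p = _stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"mirna": mirna, "group": group, "in_group": a, "total": a + b, "p": p}
            )
    return pd.DataFrame(rows)
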