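"""De novo 7mer motif enrichment on chimera target windows.

For each sufficiently sampled miRNA (>=50 chimeras in >=40 clusters),
foreground windows are tested against a 5x background sampled from the
chimeras of other miRNAs (same-seed families excluded).  Every 7mer is
scored by a hypergeometric upper-tail p-value on presence/absence, a
match score s against the reverse complement of the cognate miRNA, the
information content per bp of a PWM built from <=1-mismatch occurrences,
and the combined confidence

    c = (-log10(p) - 10)/10 + (s - 0.35) * 6.7

Motifs pass with s >= 0.35, IC/bp >= 1.75 and c >= 1.
"""

from __future__ import annotations

import itertools
import math
import sys
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import seq

MOTIF_LEN = 7
MIN_CHIMERAS = 50
MIN_CLUSTERS = 40
BACKGROUND_FOLD = 5
S_THRESHOLD = 0.35
IC_THRESHOLD = 1.75
C_THRESHOLD = 1.0
S_SLOPE = 6.7

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MotifResult:
    motif: str
    p_value: float
    s: float
    mirna_position: int
    fg_present: int
    bg_present: int
    ic_per_bp: float = float("nan")
    c: float = float("nan")
    pwm: Optional[np.ndarray] = None  # 4 x 7 column frequencies
    p_clamped: bool = False


@dataclass
class MotifRun:
    mirna: str
    foreground: list[str]
    background: list[str]
    replicate: int
    with_replacement: bool = False
    results: list[MotifResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# foreground / background construction

def build_motif_sets(
    windows_by_mirna: dict[str, list[str]],
    clusters_by_mirna: dict[str, int],
    family_by_mirna: dict[str, str],
    mirna: str,
    rng_seed: int = 0,
    n_replicates: int = 3,
) -> Optional[list[MotifRun]]:
    """Foreground and triplicate background sets for one miRNA.

    Returns None when the miRNA is ineligible (<50 chimeras or <40
    clusters).  Background windows (5x the foreground count) are drawn
    uniformly without replacement from chimeras of other miRNAs,
    excluding every miRNA sharing the cognate seed family; an
    insufficient pool triggers sampling with replacement, flagged.
    Replicate seeds are rng_seed, rng_seed+1, rng_seed+2."""
    foreground = windows_by_mirna.get(mirna, [])
    if len(foreground) < MIN_CHIMERAS or clusters_by_mirna.get(mirna, 0) < MIN_CLUSTERS:
        return None
    fam = family_by_mirna[mirna]
    pool = [
        w
        for other, ws in sorted(windows_by_mirna.items())
        if other != mirna and family_by_mirna.get(other) != fam
        for w in ws
    ]
    n_bg = BACKGROUND_FOLD * len(foreground)
    runs = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(rng_seed + rep)
        if len(pool) >= n_bg:
            idx = rng.choice(len(pool), size=n_bg, replace=False)
            flagged = False
        else:
            idx = rng.choice(len(pool), size=n_bg, replace=True)
            flagged = True
        runs.append(
            MotifRun(mirna, list(foreground), [pool[i] for i in idx], rep, flagged)
        )
    return runs


# ---------------------------------------------------------------------------
# enrichment statistics

def _presence_counts(sequences: Sequence[str], k: int = MOTIF_LEN) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in sequences:
        seen = {s[i : i + k] for i in range(len(s) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def motif_enrichment(
    foreground: Sequence[str], background: Sequence[str]
) -> pd.DataFrame:
    """Presence/absence hypergeometric enrichment of every 7mer.

    The universe is the pooled foreground+background window set; for a
    motif present in K pooled windows, the p-value is the upper tail of
    drawing the observed foreground presence in |fg| draws."""
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    fg_counts = _presence_counts(foreground)
    bg_counts = _presence_counts(background)
    n_fg, n_bg = len(foreground), len(background)
    N = n_fg + n_bg
    motifs = [
        m
        for m in sorted(set(fg_counts) | set(bg_counts))
        if len(m) == MOTIF_LEN and set(m) <= seq.VALID_BASES
    ]
    a = np.array([fg_counts.get(m, 0) for m in motifs])
    b = np.array([bg_counts.get(m, 0) for m in motifs])
    p = stats.hypergeom.sf(a - 1, N, a + b, n_fg)
    df = pd.DataFrame(
        {"motif": motifs, "fg_present": a, "bg_present": b, "p": np.minimum(p, 1.0)}
    )
    return df.sort_values(["p", "motif"], kind="stable").reset_index(drop=True)


def match_score(motif: str, mirna_sequence: str) -> tuple[float, int]:
    """Best gapless identity of the motif against the reverse complement
    of the mature miRNA.

    Returns (s, mirna_position) where s is the maximal fraction of
    identical positions over all full-overlap offsets and the position
    is the 1-based miRNA position aligned with the motif's 3' end (ties
    resolved toward the miRNA 5' end)."""
    if len(motif) != MOTIF_LEN:
        raise ValueError("motif must be 7 nt")
    m = seq.normalize(mirna_sequence)
    rc = seq.revcomp(m)
    L = len(rc)
    best_s, best_pos = 0.0, L - (MOTIF_LEN - 1)
    for offset in range(L - MOTIF_LEN + 1):
        ident = sum(a == b for a, b in zip(motif, rc[offset : offset + MOTIF_LEN]))
        s = ident / MOTIF_LEN
        pos = L - (offset + MOTIF_LEN - 1)  # miRNA position at the motif 3' end
        if s > best_s or (s == best_s and pos < best_pos):
            best_s, best_pos = s, pos
    return best_s, best_pos


class WindowArray:
    """All k-length windows of a sequence set as one uint8 matrix, for
    vectorized <=1-mismatch occurrence scans."""

    def __init__(self, sequences: Sequence[str], k: int = MOTIF_LEN):
        self.k = k
        chunks = []
        for s in sequences:
            if len(s) < k:
                continue
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            codes = np.full(arr.size, 255, dtype=np.uint8)
            for base, idx in _BASE_INDEX.items():
                codes[arr == ord(base)] = idx
            view = np.lib.stride_tricks.sliding_window_view(codes, k)
            chunks.append(view)
        self.windows = (
            np.vstack(chunks) if chunks else np.empty((0, k), dtype=np.uint8)
        )

    def encode(self, motif: str) -> np.ndarray:
        return np.array([_BASE_INDEX[b] for b in motif], dtype=np.uint8)


def build_pwm(
    sequences, motif: str, max_mismatch: int = 1
) -> Optional[np.ndarray]:
    """Column base frequencies over all motif occurrences allowing <=1
    mismatch; None when the motif never occurs.  ``sequences`` may be a
    list of strings or a prebuilt :class:`WindowArray`."""
    wa = sequences if isinstance(sequences, WindowArray) else WindowArray(sequences)
    if wa.windows.shape[0] == 0:
        return None
    mm = (wa.windows != wa.encode(motif)).sum(axis=1)
    sel = wa.windows[mm <= max_mismatch]
    if sel.shape[0] == 0:
        return None
    counts = np.zeros((4, MOTIF_LEN), dtype=float)
    for j in range(MOTIF_LEN):
        counts[:, j] = np.bincount(sel[:, j][sel[:, j] < 4], minlength=4)[:4]
    total = counts.sum(axis=0, keepdims=True)
    total[total == 0] = 1.0
    return counts / total


def ic_per_bp(pwm: np.ndarray) -> float:
    """Mean information content per column in bits, uniform background:
    (1/7) * sum_j (2 - H_j)."""
    safe = np.maximum(pwm, 1e-300)
    H = -(np.where(pwm > 0, pwm * np.log2(safe), 0.0)).sum(axis=0)
    return float(np.mean(2.0 - H))


def motif_confidence(p: float, s: float) -> tuple[float, bool]:
    """Combined confidence c = (-log10(p) - 10)/10 + (s - 0.35)*6.7.

    p = 0 is clamped to the smallest positive float, flagged."""
    clamped = False
    if p <= 0:
        p = sys.float_info.min
        clamped = True
    c = (-math.log10(p) - 10.0) / 10.0 + (s - S_THRESHOLD) * S_SLOPE
    return c, clamped


def score_motifs(
    run: MotifRun, mirna_sequence: str, top_p: float = 1e-3
) -> list[MotifResult]:
    """Per-run motif scoring for enrichment candidates.

    Only motifs enriched at p <= ``top_p`` are carried forward (mirroring
    a discovery tool that reports top enriched motifs); those get a match
    score, combined confidence and - when the confidence threshold is in
    reach - a PWM with its information content."""
    table = motif_enrichment(run.foreground, run.background)
    results = []
    fg_windows: Optional[WindowArray] = None
    for motif, a, b, p in table.itertuples(index=False):
        if p > top_p:
            continue
        s, pos = match_score(motif, mirna_sequence)
        res = MotifResult(motif, float(p), s, pos, int(a), int(b))
        if s >= S_THRESHOLD:
            c, clamped = motif_confidence(p, s)
            res.c, res.p_clamped = c, clamped
            if c >= C_THRESHOLD:
                if fg_windows is None:
                    fg_windows = WindowArray(run.foreground)
                pwm = build_pwm(fg_windows, motif)
                if pwm is not None:
                    res.pwm = pwm
                    res.ic_per_bp = ic_per_bp(pwm)
        results.append(res)
    run.results = results
    return results


def filter_motifs(results: Iterable[MotifResult]) -> list[MotifResult]:
    """Motifs passing s >= 0.35, IC/bp >= 1.75 and c >= 1."""
    return [
        r
        for r in results
        if r.s >= S_THRESHOLD
        and not math.isnan(r.ic_per_bp)
        and r.ic_per_bp >= IC_THRESHOLD
        and not math.isnan(r.c)
        and r.c >= C_THRESHOLD
    ]


# ---------------------------------------------------------------------------
# positional summary

def positional_heatmap(
    passing_by_mirna: dict[str, list[MotifResult]],
    foreground_by_mirna: dict[str, list[str]],
    max_position: int = 26,
) -> pd.DataFrame:
    """miRNA x miRNA-position matrix of percent foreground windows
    containing a passing motif mapped to that position, rows ordered by
    hierarchical clustering (average linkage, Euclidean)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    mirnas = sorted(foreground_by_mirna)
    mat = np.zeros((len(mirnas), max_position))
    for r, mirna in enumerate(mirnas):
        windows = foreground_by_mirna[mirna]
        if not windows:
            continue
        for res in passing_by_mirna.get(mirna, []):
            pos = res.mirna_position
            if not (1 <= pos <= max_position):
                continue
            present = sum(1 for w in windows if res.motif in w)
            pct = 100.0 * present / len(windows)
            mat[r, pos - 1] = max(mat[r, pos - 1], pct)
    df = pd.DataFrame(mat, index=mirnas, columns=range(1, max_position + 1))
    if len(mirnas) > 2 and np.ptp(mat) > 0:
        order = leaves_list(average(pdist(mat, metric="euclidean")))
        df = df.iloc[order]
    return df


def all_7mers() -> Iterable[str]:
    for tup in itertools.product(_BASES, repeat=MOTIF_LEN):
        yield "".join(tup)
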