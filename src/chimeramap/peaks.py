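"""Simple CLIP peak calling from deduplicated read-start coverage.

Read starts are extended by a fixed fragment length (default 53 nt,
matching the mean AGO-CLIP fragment size); peaks are maximal regions
with coverage at or above a height threshold, and summits closer than a
minimum inter-peak distance (default 75 nt) are merged.  Significance
here is a height threshold, not an enrichment model: the default is the
0.1% upper tail of a Poisson background at the library's mean coverage,
floored at 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

FRAGMENT_LENGTH = 53
MIN_PEAK_DISTANCE = 75


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    height: int
    summit: int
    normalized_height: float = 0.0


def coverage_from_read_starts(
    read_starts: Iterable[tuple[str, str, int]],
    chrom_lengths: dict[str, int],
    fragment_length: int = FRAGMENT_LENGTH,
) -> dict[tuple[str, str], np.ndarray]:
    """Coverage per (chrom, strand) from (chrom, strand, start) triples,
    each start extended by ``fragment_length`` toward the chromosome end."""
    diffs: dict[tuple[str, str], np.ndarray] = {}
    for chrom, strand, start in read_starts:
        L = chrom_lengths[chrom]
        key = (chrom, strand)
        if key not in diffs:
            diffs[key] = np.zeros(L + 1, dtype=np.int64)
        a = max(0, min(start, L))
        b = max(0, min(start + fragment_length, L))
        diffs[key][a] += 1
        diffs[key][b] -= 1
    return {k: np.cumsum(v)[:-1] for k, v in diffs.items()}


def default_min_height(coverage: dict[tuple[str, str], np.ndarray]) -> int:
    """max(2, Poisson 0.1%-tail at the library's mean genome coverage)."""
    total = sum(int(c.sum()) for c in coverage.values())
    length = sum(c.size for c in coverage.values())
    lam = total / length if length else 0.0
    return max(2, int(stats.poisson.isf(0.001, lam)) if lam > 0 else 2)


def call_peaks_simple(
    coverage: dict[tuple[str, str], np.ndarray],
    fragment_length: int = FRAGMENT_LENGTH,  # noqa: ARG001 - recorded in config
    min_distance: int = MIN_PEAK_DISTANCE,
    min_height: Optional[int] = None,
    library_size: Optional[int] = None,
) -> list[Peak]:
    """Call peaks on per-(chrom, strand) coverage arrays.

    ``library_size`` (uniquely mapped reads) scales normalized heights to
    per-million; when omitted, normalized heights are left at 0."""
    if min_height is None:
        min_height = default_min_height(coverage) if coverage else 2
    peaks: list[Peak] = []
    for (chrom, strand), cov in sorted(coverage.items()):
        above = cov >= min_height
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        regions = []
        for s, e in zip(starts, ends):
            summit = int(s + np.argmax(cov[s:e]))
            regions.append([int(s), int(e), summit, int(cov[summit])])
        # merge regions whose summits are closer than min_distance
        merged = [regions[0]]
        for reg in regions[1:]:
            if reg[2] - merged[-1][2] < min_distance:
                merged[-1][1] = reg[1]
                if reg[3] > merged[-1][3]:
                    merged[-1][2], merged[-1][3] = reg[2], reg[3]
            else:
                merged.append(reg)
        for s, e, summit, height in merged:
            norm = height / library_size * 1e6 if library_size else 0.0
            peaks.append(
                Peak(GenomicInterval(chrom, s, e, strand), height, summit, norm)
            )
    return peaks
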