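"""Seed-site classification on chimera target windows.

Target sites are written 5'->3' on the target; a canonical site is the
reverse complement of the miRNA 5'-end positions, with the 8mer and
7mer-A1 variants additionally requiring an adenosine opposite miRNA
position 1 (target-encoded, independent of the miRNA base there).
Single-defect variants allow one substitution (mismatch; a G:U wobble
counts here, not as canonical) or one extra unpaired target nucleotide
(bulge) inside the canonical span.  The highest-priority category wins
and the leftmost site is reported on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import seq

# categories in priority order (highest first); "none" is the sentinel
CATEGORY_PRIORITY = (
    "8mer",
    "7mer-m8",
    "7mer-A1",
    "6mer",
    "5mer",
    "mismatch-8mer",
    "mismatch-7mer",
    "mismatch-6mer",
    "bulged-8mer",
    "bulged-7mer",
)

CANONICAL = ("8mer", "7mer-m8", "7mer-A1", "6mer", "5mer")

# reporting collapse used in figures/tables: both 7mer subtypes -> "7mer"
REPORT_LABELS = {
    "8mer": "8mer",
    "7mer-m8": "7mer",
    "7mer-A1": "7mer",
    "6mer": "6mer",
    "5mer": "5mer",
    "mismatch-8mer": "mismatch",
    "mismatch-7mer": "mismatch",
    "mismatch-6mer": "mismatch",
    "bulged-8mer": "bulge",
    "bulged-7mer": "bulge",
    "none": "noncanonical",
}


@dataclass(frozen=True)
class SeedMatch:
    category: str
    site_start: int = -1  # offset of the site in the target window
    site_length: int = 0
    detail: Optional[int] = None  # mismatch/bulge position within the site


def canonical_sites(mirna_sequence: str) -> dict[str, str]:
    """Canonical target-side site strings for a mature miRNA."""
    m = seq.normalize(mirna_sequence)
    rc = seq.revcomp
    return {
        "8mer": rc(m[1:8]) + "A",
        "7mer-m8": rc(m[1:8]),
        "7mer-A1": rc(m[1:7]) + "A",
        "6mer": rc(m[1:7]),
        "5mer": rc(m[1:6]),
    }


def _find_exact(target: str, site: str) -> int:
    return target.find(site)


def _find_mismatch(target: str, site: str) -> tuple[int, Optional[int]]:
    """Leftmost window at Hamming distance exactly 1 from the site."""
    L = len(site)
    for start in range(len(target) - L + 1):
        mm_pos = None
        mm = 0
        for i in range(L):
            if target[start + i] != site[i]:
                mm += 1
                if mm > 1:
                    break
                mm_pos = i
        if mm == 1:
            return start, mm_pos
    return -1, None


def _find_bulged(target: str, site: str) -> tuple[int, Optional[int]]:
    """Leftmost window equal to the site with one internal insertion."""
    L = len(site)
    for start in range(len(target) - L):
        window = target[start : start + L + 1]
        for ins in range(1, L):  # strictly internal insertion points
            if window[:ins] == site[:ins] and window[ins + 1 :] == site[ins:]:
                return start, ins
    return -1, None


def classify_seed(mirna_sequence: str, target_window: str) -> SeedMatch:
    """Classify the best seed site of a miRNA within a target window."""
    target = seq.normalize(target_window)
    if len(target) < 8:
        raise ValueError("target window must be at least 8 nt")
    sites = canonical_sites(mirna_sequence)
    for cat in ("8mer", "7mer-m8", "7mer-A1", "6mer", "5mer"):
        pos = _find_exact(target, sites[cat])
        if pos != -1:
            return SeedMatch(cat, pos, len(sites[cat]))
    for cat, base in (
        ("mismatch-8mer", "8mer"),
        ("mismatch-7mer", "7mer-m8"),
        ("mismatch-6mer", "6mer"),
    ):
        pos, detail = _find_mismatch(target, sites[base])
        if pos != -1:
            return SeedMatch(cat, pos, len(sites[base]), detail)
    for cat, base in (("bulged-8mer", "8mer"), ("bulged-7mer", "7mer-m8")):
        pos, detail = _find_bulged(target, sites[base])
        if pos != -1:
            return SeedMatch(cat, pos, len(sites[base]) + 1, detail)
    return SeedMatch("none")
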