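"""Chimeric-read calling: miRNA detection in reads, target extraction,
genome mapping, PCR-duplicate collapsing and interaction clustering.

A chimera is a single sequencing read containing a mature miRNA fused to
a fragment of its bound target.  Detection tolerance mirrors short-read
aligner settings used for reverse-matching miRNAs into reads: at most
one mismatch within the first 18 nt of the miRNA, at most two mismatches
total, and an optional 1-nt truncation at either end.  When two miRNAs
match within 4 nt of each other only the first in case-insensitive
alphanumeric order is kept, so each locus yields one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import seq
from .annotation import AnnotationIndex
from .catalog import MiRNACatalog
from .intervals import GenomicInterval, cluster_intervals

MAX_MISMATCH_FIRST18 = 1
MAX_MISMATCH_TOTAL = 2
SEED_REGION_LEN = 18
MIN_TARGET_LEN = 19
PROXIMITY_NT = 4

MIRFIRST = "miRfirst"
MIRLAST = "miRlast"


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str  # barcode already stripped
    barcode: str
    replicate_id: str


@dataclass(frozen=True)
class MiRNAHit:
    mirna_name: str
    read_offset: int  # 0-based start of the matched miRNA in the read
    matched_length: int
    mismatches_first18: int
    total_mismatches: int
    truncation: str  # "none", "5p-1nt", "3p-1nt"

    @property
    def read_end(self) -> int:
        return self.read_offset + self.matched_length


@dataclass(frozen=True)
class TargetSegment:
    read: Read
    hit: MiRNAHit
    chimera_type: str  # miRfirst / miRlast
    sequence: str


@dataclass(frozen=True)
class MappedChimera:
    mirna_name: str
    family_key: str
    chimera_type: str
    target_interval: GenomicInterval
    target_sequence: str
    replicate_id: str
    barcode: str
    region_label: str = ""
    gene_id: Optional[str] = None
    mismatches: int = 0


@dataclass
class InteractionCluster:
    key: str
    span: GenomicInterval
    members: list = field(default_factory=list)
    region_label: str = ""
    gene_id: Optional[str] = None

    @property
    def chimera_count(self) -> int:
        return len(self.members)

    @property
    def bc(self) -> int:
        """Biological complexity: distinct replicates among members."""
        return len({m.replicate_id for m in self.members})


# ---------------------------------------------------------------------------
# miRNA detection in reads

_TRUNCATIONS = ("none", "5p-1nt", "3p-1nt")


def _variants(mirna_sequence: str):
    yield "none", mirna_sequence
    yield "5p-1nt", mirna_sequence[1:]
    yield "3p-1nt", mirna_sequence[:-1]


class MiRNAReadMatcher:
    """Pigeonhole index over catalog miRNAs for tolerant read scanning.

    The first 18 nt of each (possibly truncated) miRNA variant are split
    into two halves; with at most one mismatch permitted in that region,
    at least one half must occur exactly in the read, so exact dictionary
    lookups of read substrings enumerate all candidate placements.
    """

    def __init__(self, catalog: MiRNACatalog):
        self.catalog = catalog
        # half sequence -> list of (name, truncation, variant_seq, half_offset)
        self._halves: dict[str, list] = {}
        self._half_lengths: set[int] = set()
        for m in catalog:
            for trunc, var in _variants(m.sequence):
                region = var[:SEED_REGION_LEN]
                mid = (len(region) + 1) // 2
                for off, half in ((0, region[:mid]), (mid, region[mid:])):
                    self._halves.setdefault(half, []).append(
                        (m.name, trunc, var, off)
                    )
                    self._half_lengths.add(len(half))

    def find(self, read: Read) -> list[MiRNAHit]:
        """All retained miRNA hits in the read (<=1 per ~4-nt locus)."""
        s = read.sequence
        candidates: dict[tuple[str, int], MiRNAHit] = {}
        seen_placements: set[tuple] = set()
        for hlen in self._half_lengths:
            for p in range(0, len(s) - hlen + 1):
                entries = self._halves.get(s[p : p + hlen])
                if not entries:
                    continue
                for name, trunc, var, half_off in entries:
                    offset = p - half_off
                    placement = (name, trunc, offset)
                    if offset < 0 or offset + len(var) > len(s):
                        continue
                    if placement in seen_placements:
                        continue
                    seen_placements.add(placement)
                    hit = _verify(s, name, trunc, var, offset)
                    if hit is None:
                        continue
                    key = (name, offset)
                    prev = candidates.get(key)
                    if prev is None or _hit_rank(hit) < _hit_rank(prev):
                        candidates[key] = hit
        return _resolve_hits(list(candidates.values()))


def _verify(
    read_seq: str, name: str, trunc: str, var: str, offset: int
) -> Optional[MiRNAHit]:
    window = read_seq[offset : offset + len(var)]
    mm18 = mm_total = 0
    for i, (a, b) in enumerate(zip(var, window)):
        if a != b:
            mm_total += 1
            if i < SEED_REGION_LEN:
                mm18 += 1
    if mm18 > MAX_MISMATCH_FIRST18 or mm_total > MAX_MISMATCH_TOTAL:
        return None
    return MiRNAHit(name, offset, len(var), mm18, mm_total, trunc)


def _hit_rank(hit: MiRNAHit) -> tuple:
    # prefer fewer mismatches, then untruncated
    return (hit.total_mismatches, _TRUNCATIONS.index(hit.truncation))


def _resolve_hits(hits: list[MiRNAHit]) -> list[MiRNAHit]:
    """Keep one hit per miRNA per locus, then apply the 4-nt proximity
    rule: among miRNAs whose offsets lie within 4 nt (single linkage),
    only the first case-insensitive alphanumeric name survives."""
    best_per_mirna_locus: dict[tuple, MiRNAHit] = {}
    for hit in sorted(hits, key=lambda h: (h.mirna_name, h.read_offset)):
        placed = False
        for (name, off), prev in list(best_per_mirna_locus.items()):
            if name == hit.mirna_name and abs(off - hit.read_offset) <= PROXIMITY_NT:
                if (_hit_rank(hit), hit.read_offset) < (_hit_rank(prev), prev.read_offset):
                    del best_per_mirna_locus[(name, off)]
                    best_per_mirna_locus[(name, hit.read_offset)] = hit
                placed = True
                break
        if not placed:
            best_per_mirna_locus[(hit.mirna_name, hit.read_offset)] = hit

    remaining = sorted(
        best_per_mirna_locus.values(), key=lambda h: (h.read_offset, h.mirna_name.lower())
    )
    kept: list[MiRNAHit] = []
    i = 0
    while i < len(remaining):
        group = [remaining[i]]
        j = i + 1
        while (
            j < len(remaining)
            and remaining[j].read_offset - group[-1].read_offset <= PROXIMITY_NT
        ):
            group.append(remaining[j])
            j += 1
        kept.append(min(group, key=lambda h: (h.mirna_name.lower(), h.read_offset)))
        i = j
    return sorted(kept, key=lambda h: h.read_offset)


def find_mirna_in_read(read: Read, catalog) -> list[MiRNAHit]:
    """Convenience single-read entry point (builds a throwaway index for
    plain catalogs; pass a :class:`MiRNAReadMatcher` for bulk scanning)."""
    matcher = catalog if isinstance(catalog, MiRNAReadMatcher) else MiRNAReadMatcher(catalog)
    return matcher.find(read)


# ---------------------------------------------------------------------------
# target segment extraction

def extract_target_segments(read: Read, hit: MiRNAHit) -> list[TargetSegment]:
    """Upstream (miRlast) and downstream (miRfirst) candidate targets,
    dropping segments shorter than 19 nt.  Both sides may be emitted."""
    segments = []
    upstream = read.sequence[: hit.read_offset]
    downstream = read.sequence[hit.read_end :]
    if len(downstream) >= MIN_TARGET_LEN:
        segments.append(TargetSegment(read, hit, MIRFIRST, downstream))
    if len(upstream) >= MIN_TARGET_LEN:
        segments.append(TargetSegment(read, hit, MIRLAST, upstream))
    return segments


# ---------------------------------------------------------------------------
# genome mapping

class GenomeMapper:
    """Built-in short-segment mapper for toy genomes.

    Exact occurrences are located by substring search on both strands;
    when none exist a pigeonhole 6-mer index finds placements with up to
    two mismatches.  A segment is mapped only when a single best-scoring
    locus exists (multi-mappers are dropped)."""

    MAX_MM = 2
    SEED_K = 6

    def __init__(self, genome):
        from .io import GenomeSequence

        self.genome = genome if isinstance(genome, GenomeSequence) else GenomeSequence(genome)
        self._chroms = {c: self.genome.chrom_sequence(c) for c in self.genome.chrom_names}
        self._kmer_index: Optional[dict[str, list]] = None

    def _exact_hits(self, segment: str) -> list[tuple[str, int, str]]:
        hits = []
        for query, strand in ((segment, "+"), (seq.revcomp(segment), "-")):
            for chrom, cs in self._chroms.items():
                p = cs.find(query)
                while p != -1:
                    hits.append((chrom, p, strand))
                    p = cs.find(query, p + 1)
        return hits

    def _build_kmer_index(self) -> None:
        index: dict[str, list] = {}
        k = self.SEED_K
        for chrom, cs in self._chroms.items():
            for p in range(len(cs) - k + 1):
                index.setdefault(cs[p : p + k], []).append((chrom, p))
        self._kmer_index = index

    def _mismatch_hits(self, segment: str) -> list[tuple[str, int, str, int]]:
        if self._kmer_index is None:
            self._build_kmer_index()
        k = self.SEED_K
        hits = []
        for query, strand in ((segment, "+"), (seq.revcomp(segment), "-")):
            L = len(query)
            # three disjoint seed blocks; with <=2 mismatches one is exact
            offsets = (0, k, 2 * k) if L >= 3 * k else (0, (L - k) // 2, L - k)
            seen: set[tuple] = set()
            for off in offsets:
                for chrom, p in self._kmer_index.get(query[off : off + k], ()):
                    start = p - off
                    if start < 0 or start + L > len(self._chroms[chrom]):
                        continue
                    if (chrom, start) in seen:
                        continue
                    seen.add((chrom, start))
                    window = self._chroms[chrom][start : start + L]
                    mm = sum(a != b for a, b in zip(query, window))
                    if mm <= self.MAX_MM:
                        hits.append((chrom, start, strand, mm))
        return hits

    def map_segment(self, segment: str) -> tuple[Optional[GenomicInterval], int, str]:
        """Map one segment; returns (interval or None, mismatches, status).

        status is one of 'unique', 'multi', 'unmapped'."""
        exact = self._exact_hits(segment)
        if exact:
            if len(exact) > 1:
                return None, 0, "multi"
            chrom, p, strand = exact[0]
            return GenomicInterval(chrom, p, p + len(segment), strand), 0, "unique"
        hits = self._mismatch_hits(segment)
        if not hits:
            return None, -1, "unmapped"
        best_mm = min(h[3] for h in hits)
        best = [h for h in hits if h[3] == best_mm]
        if len(best) > 1:
            return None, best_mm, "multi"
        chrom, p, strand, mm = best[0]
        return GenomicInterval(chrom, p, p + len(segment), strand), mm, "unique"


# ---------------------------------------------------------------------------
# mapping + deduplication

def map_and_dedup(
    segments: Iterable[TargetSegment],
    mapper: GenomeMapper,
    precursor_loci: Sequence[GenomicInterval] = (),
    annotation: Optional[AnnotationIndex] = None,
    counters: Optional[dict] = None,
    catalog: Optional[MiRNACatalog] = None,
) -> list[MappedChimera]:
    """Map target segments, keep unique hits, collapse PCR duplicates and
    remove targets inside miRNA precursor loci.

    Duplicates are collapsed on (target coordinates, strand, miRNA,
    barcode) within each replicate library, the degenerate 5'-linker
    barcode distinguishing independent ligation events at identical
    coordinates.  The operation is idempotent.
    """
    counters = counters if counters is not None else {}
    seen: set[tuple] = set()
    out: list[MappedChimera] = []
    for segment in segments:
        iv, mm, status = mapper.map_segment(segment.sequence)
        if status != "unique":
            counters[status] = counters.get(status, 0) + 1
            continue
        if any(iv.overlaps(p, stranded=False) for p in precursor_loci):
            counters["precursor"] = counters.get("precursor", 0) + 1
            continue
        key = (
            iv.chrom,
            iv.start,
            iv.end,
            iv.strand,
            segment.hit.mirna_name,
            segment.read.barcode,
            segment.read.replicate_id,
        )
        if key in seen:
            counters["duplicate"] = counters.get("duplicate", 0) + 1
            continue
        seen.add(key)
        label, gene_id = annotation.annotate(iv) if annotation else ("", None)
        fam = (
            catalog[segment.hit.mirna_name].family_key
            if catalog is not None and segment.hit.mirna_name in catalog
            else ""
        )
        out.append(
            MappedChimera(
                mirna_name=segment.hit.mirna_name,
                family_key=fam,
                chimera_type=segment.chimera_type,
                target_interval=iv,
                target_sequence=segment.sequence,
                replicate_id=segment.read.replicate_id,
                barcode=segment.read.barcode,
                region_label=label,
                gene_id=gene_id,
                mismatches=mm,
            )
        )
    return out


def call_chimeras(
    reads: Iterable[Read],
    catalog: MiRNACatalog,
    mapper: GenomeMapper,
    precursor_loci: Sequence[GenomicInterval] = (),
    annotation: Optional[AnnotationIndex] = None,
    counters: Optional[dict] = None,
) -> list[MappedChimera]:
    """End-to-end chimera calling for a set of barcode-stripped reads."""
    matcher = MiRNAReadMatcher(catalog)
    segments: list[TargetSegment] = []
    for read in reads:
        for hit in matcher.find(read):
            segments.extend(extract_target_segments(read, hit))
    return map_and_dedup(
        segments, mapper, precursor_loci, annotation, counters, catalog=catalog
    )


# ---------------------------------------------------------------------------
# chimera table serialization

CHIMERA_COLUMNS = [
    "mirna",
    "family",
    "chimera_type",
    "chrom",
    "start",
    "end",
    "strand",
    "target_sequence",
    "replicate",
    "barcode",
    "region",
    "gene_id",
    "mismatches",
]


def chimeras_to_frame(chimeras: Sequence[MappedChimera]) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        [
            (
                c.mirna_name,
                c.family_key,
                c.chimera_type,
                c.target_interval.chrom,
                c.target_interval.start,
                c.target_interval.end,
                c.target_interval.strand,
                c.target_sequence,
                c.replicate_id,
                c.barcode,
                c.region_label,
                c.gene_id if c.gene_id is not None else "",
                c.mismatches,
            )
            for c in chimeras
        ],
        columns=CHIMERA_COLUMNS,
    )


def frame_to_chimeras(df: "pd.DataFrame") -> list[MappedChimera]:  # noqa: F821
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MappedChimera(
                mirna_name=row.mirna,
                family_key=row.family,
                chimera_type=row.chimera_type,
                target_interval=GenomicInterval(
                    row.chrom, int(row.start), int(row.end), row.strand
                ),
                target_sequence=row.target_sequence,
                replicate_id=str(row.replicate),
                barcode=str(row.barcode),
                region_label=str(row.region) if isinstance(row.region, str) else "",
                gene_id=row.gene_id if isinstance(row.gene_id, str) and row.gene_id else None,
                mismatches=int(row.mismatches),
            )
        )
    return out


# ---------------------------------------------------------------------------
# interaction clustering

def build_interaction_clusters(
    chimeras: Sequence[MappedChimera],
    level: str = "miRNA",
    annotation: Optional[AnnotationIndex] = None,
    max_gap: int = 0,
) -> list[InteractionCluster]:
    """Cluster deduplicated chimera targets into interactions.

    ``level`` keys clusters by individual miRNA or by seed family; the
    cluster's biological complexity (BC) is the number of distinct
    replicates among its members."""
    if level not in ("miRNA", "family"):
        raise ValueError("level must be 'miRNA' or 'family'")
    keyfn = (lambda c: c.mirna_name) if level == "miRNA" else (lambda c: c.family_key)
    raw = cluster_intervals(
        chimeras, same_key=keyfn, interval_of=lambda c: c.target_interval, max_gap=max_gap
    )
    clusters = []
    for rc in raw:
        label, gene_id = annotation.annotate(rc.span) if annotation else ("", None)
        clusters.append(
            InteractionCluster(rc.key, rc.span, rc.members, label, gene_id)
        )
    return clusters


# ---------------------------------------------------------------------------
# AGO-loaded miRNA profiling and novel-arm discovery

def profile_ago_mirnas(
    read_sequences: Iterable[str], catalog: MiRNACatalog
) -> tuple[dict[str, int], list[str]]:
    """Count reads matching mature miRNAs with zero mismatches.

    A read counts toward a miRNA iff the full read is an exact contiguous
    substring of the mature sequence (reads 17-26 nt); multi-matching
    reads count toward the first case-insensitive alphanumeric name.
    Returns (counts, unmatched read sequences)."""
    names_sorted = sorted(catalog.names, key=str.lower)
    counts = {name: 0 for name in names_sorted}
    unmatched: list[str] = []
    for s in read_sequences:
        s = seq.normalize(s)
        if not (17 <= len(s) <= 26):
            unmatched.append(s)
            continue
        for name in names_sorted:
            if s in catalog[name].sequence:
                counts[name] += 1
                break
        else:
            unmatched.append(s)
    return counts, unmatched


@dataclass(frozen=True)
class NovelArmCandidate:
    sequence: str
    count: int
    hairpin: str
    proposed_name: str
    arm: str


def detect_novel_arm_candidates(
    unmatched_reads: Iterable[str],
    hairpins: Sequence,
    mapper: GenomeMapper,
    min_count: int = 100,
) -> list[NovelArmCandidate]:
    """Abundant unannotated sequences mapping to the free arm of a known
    precursor hairpin.

    ``hairpins`` are records with ``name``, ``locus`` (GenomicInterval)
    and ``annotated_arms``: dict arm -> mature GenomicInterval.  A
    candidate must be 17-25 nt, occur at least ``min_count`` times, map
    uniquely within a hairpin locus, avoid every annotated mature arm,
    and sit on the opposite arm of the hairpin."""
    tally: dict[str, int] = {}
    for s in unmatched_reads:
        s = seq.normalize(s)
        if 17 <= len(s) <= 25:
            tally[s] = tally.get(s, 0) + 1
    candidates = []
    for s, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
        if n < min_count:
            continue
        iv, _mm, status = mapper.map_segment(s)
        if status != "unique":
            continue
        for hp in hairpins:
            if not hp.locus.contains(iv):
                continue
            if any(iv.overlaps(arm_iv, stranded=False) for arm_iv in hp.annotated_arms.values()):
                continue
            mid = (hp.locus.start + hp.locus.end) / 2
            center = (iv.start + iv.end) / 2
            genomic_side = "5p" if center < mid else "3p"
            arm = genomic_side if hp.locus.strand == "+" else (
                "3p" if genomic_side == "5p" else "5p"
            )
            if arm in hp.annotated_arms:
                continue
            candidates.append(
                NovelArmCandidate(s, n, hp.name, f"{hp.name}-{arm}", arm)
            )
            break
    return candidates
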