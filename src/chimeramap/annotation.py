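"""Gene models, GTF ingest and genomic region annotation.

Region labels follow AGO-CLIP conventions: an interval overlapping an
annotated 3'UTR *or* the 10-kb region immediately downstream of a 3'UTR
end (a concession to incomplete UTR annotation) is labeled ``3UTR``;
precedence is 3UTR > CDS > 5UTR > intron > intergenic, with ties broken
by larger overlap and then lexicographic gene id.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .intervals import GenomicInterval

# region labels in precedence order (highest first)
UTR3 = "3UTR"
CDS = "CDS"
UTR5 = "5UTR"
INTRON = "intron"
INTERGENIC = "intergenic"

REGION_PRECEDENCE = (UTR3, CDS, UTR5, INTRON)

DOWNSTREAM_EXTENSION = 10_000


@dataclass
class GeneModel:
    """Single-transcript gene model with labeled regions."""

    gene_id: str
    chrom: str
    strand: str
    regions: dict = field(default_factory=dict)  # label -> list[GenomicInterval]

    def add_region(self, label: str, interval: GenomicInterval) -> None:
        self.regions.setdefault(label, []).append(interval)

    @property
    def span(self) -> GenomicInterval:
        ivs = [iv for lst in self.regions.values() for iv in lst]
        return GenomicInterval(
            self.chrom, min(i.start for i in ivs), max(i.end for i in ivs), self.strand
        )

    @property
    def mature_length(self) -> int:
        """Total exonic length (UTRs + CDS)."""
        return sum(
            len(iv)
            for label in (UTR5, CDS, UTR3)
            for iv in self.regions.get(label, [])
        )

    @property
    def downstream10k(self) -> Optional[GenomicInterval]:
        """10-kb interval abutting the 3'UTR end on the transcript strand."""
        utr3 = self.regions.get(UTR3)
        if not utr3:
            return None
        if self.strand == "+":
            start = max(iv.end for iv in utr3)
            return GenomicInterval(self.chrom, start, start + DOWNSTREAM_EXTENSION, "+")
        end = min(iv.start for iv in utr3)
        if end == 0:
            return None
        return GenomicInterval(
            self.chrom, max(0, end - DOWNSTREAM_EXTENSION), end, "-"
        )

    def infer_introns(self) -> None:
        """Fill intron regions between consecutive exonic intervals."""
        exonic = sorted(
            (iv for label in (UTR5, CDS, UTR3) for iv in self.regions.get(label, [])),
            key=lambda iv: iv.start,
        )
        introns = []
        for a, b in zip(exonic, exonic[1:]):
            if b.start > a.end:
                introns.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        if introns:
            self.regions[INTRON] = introns


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

_GTF_FEATURE_MAP = {
    "five_prime_utr": UTR5,
    "5utr": UTR5,
    "cds": CDS,
    "three_prime_utr": UTR3,
    "3utr": UTR3,
    "intron": INTRON,
}


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Parse a GTF into gene models (1-based inclusive -> half-open).

    Recognizes 5'UTR/CDS/3'UTR (and explicit intron) features; introns
    are otherwise inferred from gaps between exonic features.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            label = _GTF_FEATURE_MAP.get(feature.lower())
            if label is None:
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                continue
            gene = genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand))
            gene.add_region(
                label, GenomicInterval(chrom, int(start) - 1, int(end), strand)
            )
    for gene in genes.values():
        if INTRON not in gene.regions:
            gene.infer_introns()
    return genes


class AnnotationIndex:
    """Interval-tree index over gene model regions for region labeling."""

    def __init__(self, genes: Iterable[GeneModel], stranded: bool = True):
        self.stranded = stranded
        self._trees: dict[tuple, IntervalTree] = {}
        for gene in genes:
            entries = [
                (label, iv) for label, ivs in gene.regions.items() for iv in ivs
            ]
            ds = gene.downstream10k
            if ds is not None:
                entries.append((UTR3, ds))
            for label, iv in entries:
                key = (iv.chrom, iv.strand if stranded else ".")
                self._trees.setdefault(key, IntervalTree()).addi(
                    iv.start, iv.end, (label, gene.gene_id)
                )

    def annotate(self, interval: GenomicInterval) -> tuple[str, Optional[str]]:
        """Label an interval; returns (region_label, gene_id).

        Precedence 3UTR > CDS > 5UTR > intron; ties broken by larger
        overlap then lexicographic gene id.  Unknown chromosomes are
        intergenic (with a warning).
        """
        key = (interval.chrom, interval.strand if self.stranded else ".")
        tree = self._trees.get(key)
        if tree is None:
            if not any(k[0] == interval.chrom for k in self._trees):
                warnings.warn(
                    f"chromosome {interval.chrom!r} absent from annotation",
                    stacklevel=2,
                )
            return INTERGENIC, None
        hits = tree.overlap(interval.start, interval.end)
        if not hits:
            return INTERGENIC, None
        best = None
        for hit in hits:
            label, gene_id = hit.data
            ovl = min(interval.end, hit.end) - max(interval.start, hit.begin)
            rank = REGION_PRECEDENCE.index(label)
            cand = (rank, -ovl, gene_id)
            if best is None or cand < best:
                best = cand
        return REGION_PRECEDENCE[best[0]], best[2]

    def annotate_many(
        self, intervals: Iterable[GenomicInterval]
    ) -> list[tuple[str, Optional[str]]]:
        return [self.annotate(iv) for iv in intervals]
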