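"""Expression normalization, the AGO sequestration coefficient (ASC),
GO gene-set selection, cooperativity consensus clustering and ceRNA
region detection.

The ASC for a gene r and miRNA family f is

    ASC = log2( (chimeras_f(r) / chimeras_f(total)) / RPKM(r) )

i.e. the gene's share of the family's 3'UTR chimeras normalized by its
expression; high ASC marks disproportionately targeted transcripts.
Only families with >=500 3'UTR-bound chimeras are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import GenomicInterval

MIN_FAMILY_CHIMERAS = 500
EXPRESSION_TAG_MIN = 100

CERNA_MIN_CLUSTERS = 3
CERNA_MIN_CHIMERAS = 5
CERNA_WINDOW = 3000


# ---------------------------------------------------------------------------
# expression normalization

def compute_abundance(
    counts: pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """CPM/RPKM table from raw counts (genes x samples).

    ``gene_lengths`` are mature (exonic) lengths in nt.  The ``expressed``
    flag applies the <100-tag exclusion on the summed raw counts."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero library size")
    cpm = counts / totals * 1e6
    rpkm = cpm.div(lengths / 1e3, axis=0)
    out = pd.DataFrame(
        {
            "total_count": counts.sum(axis=1),
            "CPM": cpm.mean(axis=1),
            "RPKM": rpkm.mean(axis=1),
        }
    )
    out["expressed"] = out["total_count"] >= EXPRESSION_TAG_MIN
    return out


# ---------------------------------------------------------------------------
# ASC

@dataclass(frozen=True)
class ASCRecord:
    gene_id: str
    family_key: str
    family_chimeras_on_gene: int
    family_chimeras_total: int
    rpkm: float
    asc: Optional[float]  # None = non-targeted or undefined
    lloq: Optional[float]
    flagged: bool = False  # chimeras present but RPKM == 0


def compute_asc(
    family_chimera_counts: pd.DataFrame,
    expression: pd.DataFrame,
    min_family_chimeras: int = MIN_FAMILY_CHIMERAS,
) -> list[ASCRecord]:
    """Per (gene, family) ASC records.

    ``family_chimera_counts``: genes x families matrix of 3'UTR chimera
    counts (the 3'UTR definition includes the 10-kb downstream rule).
    Families with fewer than 500 total chimeras are skipped entirely.
    Genes with zero family chimeras carry the non-targeted sentinel
    (asc None) and never enter family means."""
    records: list[ASCRecord] = []
    rpkm = expression["RPKM"]
    for family in family_chimera_counts.columns:
        col = family_chimera_counts[family]
        total = int(col.sum())
        if total < min_family_chimeras:
            continue
        for gene_id, n in col.items():
            n = int(n)
            r = float(rpkm.get(gene_id, 0.0))
            if n == 0:
                records.append(ASCRecord(gene_id, family, 0, total, r, None, None))
                continue
            if r <= 0:
                records.append(
                    ASCRecord(gene_id, family, n, total, r, None, None, flagged=True)
                )
                continue
            asc = math.log2((n / total) / r)
            lloq = math.log2((1 / total) / r)
            records.append(ASCRecord(gene_id, family, n, total, r, asc, lloq))
    return records


def asc_matrix(records: Sequence[ASCRecord]) -> pd.DataFrame:
    """Genes x families matrix of ASC values (NaN where non-targeted)."""
    df = pd.DataFrame(
        [(r.gene_id, r.family_key, r.asc) for r in records],
        columns=["gene_id", "family", "asc"],
    )
    return df.pivot_table(index="gene_id", columns="family", values="asc", dropna=False)


def select_go_geneset(records: Sequence[ASCRecord], family: str) -> list[str]:
    """Genes with ASC strictly above the family mean (non-targeted genes
    excluded from the mean), sorted for export to external GO tools."""
    vals = [(r.gene_id, r.asc) for r in records if r.family_key == family and r.asc is not None]
    if not vals:
        return []
    mean = sum(v for _, v in vals) / len(vals)
    return sorted(g for g, v in vals if v > mean)


# ---------------------------------------------------------------------------
# cooperativity consensus clustering

@dataclass
class CooperativitySignature:
    families: frozenset
    support: int  # iterations in which the signature recurred
    cluster_ids: tuple


@dataclass
class CooperativityResult:
    signatures: list[CooperativitySignature]
    pairwise: pd.DataFrame  # family x family support counts
    iteration_signatures: list[set]


def cooperativity_consensus(
    matrix: pd.DataFrame,
    k: int = 45,
    n_starts: int = 1000,
    iterations: int = 3,
    min_support: int = 3,
    enrichment_margin: float = 1.0,
    min_cluster_genes: int = 6,
    random_state: int = 0,
) -> CooperativityResult:
    """Recurrent multi-family targeting signatures from repeated k-means.

    ``matrix``: genes x families ASC values with NaN for non-targeted
    cells; these are imputed to (min defined ASC - 1).  Each iteration
    runs k-means with ``n_starts`` restarts; a cluster's signature is the
    set of families whose within-cluster mean exceeds their global mean
    (over the imputed matrix) by at least ``enrichment_margin``; clusters
    of fewer than ``min_cluster_genes`` genes carry no signature (a lone
    extreme gene is not cooperative evidence).  Signatures with >=2
    families recurring in >= ``min_support`` iterations populate the
    cooperativity matrix."""
    X = matrix.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {X.shape[0]}")
    floor = np.nanmin(X) - 1.0 if np.isfinite(np.nanmin(X)) else -1.0
    X = np.where(np.isnan(X), floor, X)
    global_means = X.mean(axis=0)
    families = list(matrix.columns)

    per_iter: list[set[frozenset]] = []
    sig_clusters: dict[frozenset, list] = {}
    for it in range(iterations):
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=random_state + it)
        labels = km.fit_predict(X)
        sigs: set[frozenset] = set()
        for cid in range(k):
            members = X[labels == cid]
            if members.shape[0] < min_cluster_genes:
                continue
            enriched = frozenset(
                fam
                for j, fam in enumerate(families)
                if members[:, j].mean() >= global_means[j] + enrichment_margin
            )
            if len(enriched) >= 2:
                sigs.add(enriched)
                sig_clusters.setdefault(enriched, []).append((it, cid))
        per_iter.append(sigs)

    support: dict[frozenset, int] = {}
    for sigs in per_iter:
        for sig in sigs:
            support[sig] = support.get(sig, 0) + 1
    signatures = [
        CooperativitySignature(sig, n, tuple(sig_clusters[sig]))
        for sig, n in sorted(support.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
        if n >= min_support
    ]

    pairwise = pd.DataFrame(0, index=families, columns=families, dtype=int)
    for s in signatures:
        fams = sorted(s.families)
        for i, a in enumerate(fams):
            for b in fams[i + 1 :]:
                pairwise.loc[a, b] = max(pairwise.loc[a, b], s.support)
                pairwise.loc[b, a] = pairwise.loc[a, b]
    return CooperativityResult(signatures, pairwise, per_iter)


# ---------------------------------------------------------------------------
# ceRNA detection

@dataclass(frozen=True)
class CernaRegion:
    interval: GenomicInterval
    n_clusters: int
    cluster_keys: tuple
    region_label: str = ""
    gene_id: Optional[str] = None


def detect_cerna_regions(
    clusters: Sequence,
    annotation=None,
    min_clusters: int = CERNA_MIN_CLUSTERS,
    min_chimeras: int = CERNA_MIN_CHIMERAS,
    window: int = CERNA_WINDOW,
) -> list[CernaRegion]:
    """Candidate ceRNA regions: maximal genomic windows of at most
    ``window`` bp (per strand) containing >= ``min_clusters`` interaction
    clusters that each hold >= ``min_chimeras`` unique chimeras.

    ``clusters`` need ``span`` (GenomicInterval), ``chimera_count`` and
    ``key`` attributes.  Overlapping qualifying windows are merged into
    maximal reported regions."""
    strong = [c for c in clusters if c.chimera_count >= min_chimeras]
    by_cs: dict[tuple, list] = {}
    for c in strong:
        by_cs.setdefault((c.span.chrom, c.span.strand), []).append(c)

    regions: list[CernaRegion] = []
    for (chrom, strand), cs in sorted(by_cs.items()):
        cs = sorted(cs, key=lambda c: (c.span.start, c.span.end))
        windows = []
        for i in range(len(cs)):
            if len(cs[i].span) > window:
                continue
            group = [cs[i]]
            for j in range(i + 1, len(cs)):
                if cs[j].span.end - cs[i].span.start <= window:
                    group.append(cs[j])
                elif cs[j].span.start - cs[i].span.start > window:
                    break  # sorted starts: nothing further can fit
            if len(group) >= min_clusters:
                windows.append(group)
        # merge overlapping qualifying windows into maximal regions
        merged: list[list] = []
        for group in windows:
            start = group[0].span.start
            end = max(c.span.end for c in group)
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2].extend(group)
            else:
                merged.append([start, end, list(group)])
        for start, end, members in merged:
            iv = GenomicInterval(chrom, start, end, strand)
            label, gene_id = annotation.annotate(iv) if annotation else ("", None)
            keys = tuple(sorted({str(c.key) for c in members}))
            uniq = {id(c) for c in members}
            regions.append(CernaRegion(iv, len(uniq), keys, label, gene_id))
    return regions
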