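"""File format I/O: FASTA/FASTQ, BED, bedGraph, TSV tables, SAM ingest.

Small toy references are held fully in memory; random access to larger
genomes goes through :class:`pyfaidx.Fasta`.
"""

from __future__ import annotations

import json
from typing import Iterable, Iterator, Optional

import pandas as pd
import pyfaidx

from . import seq
from .intervals import GenomicInterval


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA into an ordered dict of normalized (U->T) sequences."""
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = seq.normalize("".join(parts))
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        records[name] = seq.normalize("".join(parts))
    return records


def write_fasta(path: str, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, s in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from an uncompressed FASTQ."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            s = fh.readline().rstrip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield header[1:].split()[0], seq.normalize(s)


def write_fastq(path: str, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for read_id, s in reads:
            fh.write(f"@{read_id}\n{s}\n+\n{'I' * len(s)}\n")


class GenomeSequence:
    """Genome access wrapper: in-memory dict or faidx-backed FASTA."""

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: seq.normalize(v) for k, v in source.items()}
            self._fa = None
        else:
            self._fa = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._seqs = None

    @property
    def chrom_names(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fa.keys())

    def chrom_length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Half-open fetch; minus strand returns the reverse complement."""
        if self._seqs is not None:
            s = self._seqs[chrom][start:end]
        else:
            s = str(self._fa[chrom][start:end])
        s = seq.normalize(s)
        return seq.revcomp(s) if strand == "-" else s

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)

    def chrom_sequence(self, chrom: str) -> str:
        return self.fetch(chrom, 0, self.chrom_length(chrom))


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path: str) -> pd.DataFrame:
    """Read BED (>=3 cols) into a DataFrame with canonical column names."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [
        f"extra{i}" for i in range(max(0, df.shape[1] - 6))
    ]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def write_bed(path: str, rows: Iterable[tuple]) -> None:
    """Write BED rows (iterables of fields), tab-separated."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path: str, coverage: dict[str, "np.ndarray"]) -> None:  # noqa: F821
    """Run-length encode per-chromosome coverage arrays to bedGraph."""
    import numpy as np

    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            cov = np.asarray(coverage[chrom])
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            for s, e in zip(starts, ends):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Tables and run summaries

def read_counts_tsv(path: str) -> pd.DataFrame:
    """Gene expression count table: gene_id index, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return df


def write_tsv(path: str, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_summary(path: str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SAM ingest (externally produced target-segment alignments)

def read_sam_alignments(path: str) -> list[dict]:
    """Load unique, primary alignments from a SAM file.

    Returns dicts with read name, interval and mismatch count (NM tag when
    present).  Secondary/supplementary/unmapped records are skipped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            out.append(
                {
                    "read_name": aln.query_name,
                    "interval": GenomicInterval(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        "-" if aln.is_reverse else "+",
                    ),
                    "mismatches": aln.get_tag("NM") if aln.has_tag("NM") else 0,
                }
            )
    return out
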