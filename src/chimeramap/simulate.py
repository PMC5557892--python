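"""Synthetic AGO-CLIP study generator.

Produces a toy reference (genome + gene models + miRNA hairpins), a
miRNome with seed-sharing families, planted miRNA-target interactions
with a configurable seed-type spectrum, CLIP read libraries with
replicate structure, PCR duplicates, background peak reads and
AGO-loaded small RNAs, and two-condition expression tables with a small
planted de-repression of targeted genes.  Every simulated read is
traceable to its provenance and the ground truth serializes losslessly
to JSON.

Defaults reflect the study conditions the analyses assume: chimeric
reads are a few percent of the library (default 2%, within the reported
0.5-5% range), PCR duplication is substantial (default 0.3), the planted
de-repression is a median log2 fold change of 0.11, and the seed-type
mix is dominated by canonical sites with mismatch/bulge minorities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import seq
from .annotation import CDS, UTR3, UTR5, GeneModel
from .catalog import MiRNA, MiRNACatalog
from .intervals import GenomicInterval
from .seeds import canonical_sites

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    n_genes: int = 50
    n_mirnas: int = 20
    n_families: int = 16  # < n_mirnas so some families hold two members
    n_hairpins: int = 4
    replicates: int = 3
    n_interactions: int = 60
    total_reads: int = 100_000
    chimera_fraction: float = 0.02
    small_rna_fraction: float = 0.2
    mirfirst_fraction: float = 0.8
    pcr_duplicate_rate: float = 0.3
    seed_type_mix: dict = field(
        default_factory=lambda: {
            "8mer": 0.35,
            "7mer": 0.25,
            "6mer": 0.15,
            "mismatch": 0.10,
            "bulge": 0.05,
            "noncanonical": 0.10,
        }
    )
    non_utr3_site_fraction: float = 0.1  # minority of sites in CDS
    mirna_mismatch_rate: float = 0.05
    mirna_truncation_rate: float = 0.05
    barcode_length: int = 5
    planted_log2fc: float = 0.11
    expression_dispersion: float = 0.1
    expression_mean_log: float = 6.0
    expression_replicates: int = 3
    novel_arm_count: int = 300
    # gene geometry (nt)
    utr5_len: int = 200
    cds_len: int = 600
    utr3_len: int = 1500
    intergenic_gap: int = 12_000

    def __post_init__(self) -> None:
        total = sum(self.seed_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"seed_type_mix must sum to 1, got {total}")
        if self.n_families > self.n_mirnas:
            raise ValueError("n_families cannot exceed n_mirnas")


@dataclass
class Hairpin:
    name: str
    locus: GenomicInterval
    annotated_arms: dict  # arm -> GenomicInterval
    unannotated_arm: str  # "5p" or "3p"
    unannotated_sequence: str


@dataclass
class Reference:
    genome: dict  # chrom -> mutable list of chars (finalized to str)
    genes: dict  # gene_id -> GeneModel
    hairpins: list

    def genome_sequences(self) -> dict[str, str]:
        return {c: "".join(s) for c, s in self.genome.items()}

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


@dataclass
class PlantedInteraction:
    interaction_id: int
    gene_id: str
    mirna: str
    family_key: str
    seed_type: str  # requested category from the mix
    site: GenomicInterval  # genomic coordinates of the planted site
    region: str  # 3UTR or CDS
    structure_archetype: int  # 0..7
    n_chimeras: int = 0


@dataclass
class ReadProvenance:
    kind: str  # background | smallrna | chimera | duplicate
    interaction_id: Optional[int] = None
    mirna: Optional[str] = None
    exact_mirna: bool = False
    chimera_type: Optional[str] = None
    target: Optional[tuple] = None  # (chrom, start, end, strand)
    barcode: str = ""
    replicate: str = ""
    duplicate_of: Optional[str] = None


@dataclass
class GroundTruth:
    config: SimulationConfig
    interactions: list
    provenance: dict  # read_id -> ReadProvenance
    targeted_genes: list
    mirna_weights: dict

    def to_json(self, path: str) -> None:
        payload = {
            "config": asdict(self.config),
            "interactions": [asdict(i) for i in self.interactions],
            "provenance": {k: asdict(v) for k, v in self.provenance.items()},
            "targeted_genes": self.targeted_genes,
            "mirna_weights": self.mirna_weights,
        }

        def default(o):
            if isinstance(o, GenomicInterval):
                return [o.chrom, o.start, o.end, o.strand]
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(payload, fh, default=default)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        config = SimulationConfig(**payload["config"])
        interactions = []
        for d in payload["interactions"]:
            site = d["site"]
            d["site"] = (
                GenomicInterval(**site) if isinstance(site, dict) else GenomicInterval(*site)
            )
            interactions.append(PlantedInteraction(**d))
        provenance = {
            k: ReadProvenance(**{**v, "target": tuple(v["target"]) if v["target"] else None})
            for k, v in payload["provenance"].items()
        }
        return cls(
            config,
            interactions,
            provenance,
            payload["targeted_genes"],
            payload["mirna_weights"],
        )


# ---------------------------------------------------------------------------
# reference and miRNome

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_reference(config: SimulationConfig, rng=None) -> Reference:
    """Toy genome + gene models + hairpin loci.

    Genes alternate strand and are separated by >10 kb so the
    10-kb-downstream-of-3'UTR annotation rule is exercised; hairpins sit
    in intergenic space beyond the downstream extensions."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    gene_len = config.utr5_len + config.cds_len + config.utr3_len
    unit = gene_len + config.intergenic_gap
    genes_per_chrom = (config.n_genes + 1) // 2
    genes: dict[str, GeneModel] = {}
    genome: dict[str, list] = {}
    hairpins: list[Hairpin] = []
    gi = 0
    for ci in range(2):
        chrom = f"chr{ci + 1}"
        n_here = min(genes_per_chrom, config.n_genes - gi)
        length = n_here * unit + config.intergenic_gap
        genome[chrom] = list(_random_seq(rng, length))
        for local in range(n_here):
            gene_id = f"gene{gi + 1:03d}"
            strand = "+" if gi % 2 == 0 else "-"
            start = config.intergenic_gap // 2 + local * unit
            model = GeneModel(gene_id, chrom, strand)
            if strand == "+":
                bounds = [
                    (UTR5, start, start + config.utr5_len),
                    (CDS, start + config.utr5_len, start + config.utr5_len + config.cds_len),
                    (UTR3, start + config.utr5_len + config.cds_len, start + gene_len),
                ]
            else:
                bounds = [
                    (UTR3, start, start + config.utr3_len),
                    (CDS, start + config.utr3_len, start + config.utr3_len + config.cds_len),
                    (UTR5, start + config.utr3_len + config.cds_len, start + gene_len),
                ]
            for label, s, e in bounds:
                model.add_region(label, GenomicInterval(chrom, s, e, strand))
            genes[gene_id] = model
            gi += 1
    # hairpins in the terminal intergenic gap of chr1, clear of downstream10k
    chrom = "chr1"
    tail = len(genome[chrom]) - config.intergenic_gap
    for hi in range(config.n_hairpins):
        start = tail + 10_500 // config.n_hairpins * hi + 300 * hi
        start = min(start, len(genome[chrom]) - 80)
        locus = GenomicInterval(chrom, start, start + 60, "+")
        arm5 = GenomicInterval(chrom, start, start + 22, "+")
        arm3 = GenomicInterval(chrom, start + 38, start + 60, "+")
        annotated = "5p" if hi % 2 == 0 else "3p"
        unannotated = "3p" if annotated == "5p" else "5p"
        arms = {"5p": arm5, "3p": arm3}
        unann_iv = arms[unannotated]
        hairpins.append(
            Hairpin(
                f"sim-mir-h{hi + 1}",
                locus,
                {annotated: arms[annotated]},
                unannotated,
                "".join(genome[chrom][unann_iv.start : unann_iv.end]),
            )
        )
    return Reference(genome, genes, hairpins)


def simulate_mirnome(
    config: SimulationConfig, reference: Reference, rng=None
) -> MiRNACatalog:
    """Mature miRNA catalog: family-structured free miRNAs plus the
    annotated arm of each hairpin."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    seeds = set()
    while len(seeds) < config.n_families:
        seeds.add(_random_seq(rng, 7))
    seeds = sorted(seeds)
    mirnas = []
    for i in range(config.n_mirnas):
        fam_seed = seeds[i % config.n_families]
        s = _random_seq(rng, 1) + fam_seed + _random_seq(rng, 14)
        mirnas.append(MiRNA(f"sim-miR-{i + 1:02d}", s))
    genome = reference.genome_sequences()
    for hp in reference.hairpins:
        for arm, iv in hp.annotated_arms.items():
            mature = genome[iv.chrom][iv.start : iv.end]
            mirnas.append(
                MiRNA(f"{hp.name}-{arm}", mature, precursor_locus=hp.locus, arm=arm)
            )
    return MiRNACatalog(mirnas)


# ---------------------------------------------------------------------------
# truth planting

_STRUCTURE_ARCHETYPES = np.array(
    [
        # 8 binding-mode templates over 22 miRNA positions
        [0] + [1] * 7 + [0] * 14,                       # seed only
        [0] + [1] * 7 + [0] * 4 + [1] * 5 + [0] * 5,    # seed + central auxiliary
        [0] + [1] * 7 + [0] * 8 + [1] * 6,              # seed + 3' auxiliary
        [0] * 10 + [1] * 9 + [0] * 3,                   # 3'-only (no seed)
        [0] + [1] * 7 + [0] * 3 + [1] * 3 + [0] * 3 + [1] * 4 + [0],  # bipartite aux
        [0] + [1] * 6 + [0] * 2 + [1] * 2 + [0] * 2 + [1] * 2 + [0] * 2 + [1] * 3 + [0] * 2,  # tripartite
        [1] * 9 + [0] * 13,                             # extended 5'
        [0] + [1] * 5 + [0] * 16,                       # short seed
    ],
    dtype=int,
)


def _plant(genome: dict, region: GenomicInterval, offset: int, site: str) -> GenomicInterval:
    """Write a transcript-orientation site into the genome; returns the
    genomic interval of the planted site."""
    if region.strand == "+":
        start = region.start + offset
        genome[region.chrom][start : start + len(site)] = list(site)
        return GenomicInterval(region.chrom, start, start + len(site), "+")
    end = region.end - offset
    start = end - len(site)
    genome[region.chrom][start:end] = list(seq.revcomp(site))
    return GenomicInterval(region.chrom, start, end, "-")


def _site_sequence(
    mirna_seq: str, seed_type: str, rng: np.random.Generator
) -> tuple[str, str, str]:
    """(site string, guard_before, guard_after) in transcript orientation.

    Guards are bases written immediately before/after the site to block
    accidental upgrades to a higher canonical category ('' = leave)."""
    sites = canonical_sites(mirna_seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if seed_type == "8mer":
        return sites["8mer"], "", ""
    if seed_type == "7mer":
        # m8 variant; block the trailing A that would make it an 8mer
        return sites["7mer-m8"], "", "C"
    if seed_type == "6mer":
        # block m8 extension before and A1 after
        bad_before = comp[mirna_seq[7]]
        guard = "G" if bad_before != "G" else "T"
        return sites["6mer"], guard, "C"
    if seed_type == "mismatch":
        s = list(sites["8mer"])
        pos = int(rng.integers(2, 6))
        choices = [b for b in "ACGT" if b != s[pos]]
        s[pos] = choices[int(rng.integers(0, len(choices)))]
        return "".join(s), "", ""
    if seed_type == "bulge":
        s = sites["8mer"]
        ins = int(rng.integers(2, 6))
        base = "ACGT"[int(rng.integers(0, 4))]
        return s[:ins] + base + s[ins:], "", ""
    return "", "", ""  # noncanonical: nothing planted


def simulate_truth(
    config: SimulationConfig, reference: Reference, catalog: MiRNACatalog, rng=None
) -> tuple[list[PlantedInteraction], dict[str, float]]:
    """Plant interaction sites into the reference (mutates the genome).

    Interactions draw miRNAs by a lognormal abundance profile and genes
    uniformly; sites go into 3'UTRs except a configured minority in CDS.
    Each interaction carries one of 8 structure archetypes."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    free_mirnas = [m.name for m in catalog if m.precursor_locus is None]
    weights = rng.lognormal(0.0, 1.0, size=len(free_mirnas))
    weights /= weights.sum()
    mirna_weights = dict(zip(free_mirnas, weights.tolist()))
    types = list(config.seed_type_mix)
    type_p = np.array([config.seed_type_mix[t] for t in types])
    gene_ids = sorted(reference.genes)
    interactions: list[PlantedInteraction] = []
    used_offsets: dict[tuple, list] = {}
    min_sep = 80
    for iid in range(config.n_interactions):
        mirna = free_mirnas[int(rng.choice(len(free_mirnas), p=weights))]
        seed_type = types[int(rng.choice(len(types), p=type_p))]
        placed = False
        for _attempt in range(50):
            gene = reference.genes[gene_ids[int(rng.integers(0, len(gene_ids)))]]
            in_cds = rng.random() < config.non_utr3_site_fraction
            region_label = CDS if in_cds else UTR3
            region = gene.regions[region_label][0]
            if len(region) < min_sep + 40:
                continue
            offset = int(rng.integers(20, len(region) - 40))
            key = (gene.gene_id, region_label)
            if any(abs(offset - o) < min_sep for o in used_offsets.get(key, [])):
                continue
            used_offsets.setdefault(key, []).append(offset)
            mseq = catalog[mirna].sequence
            site, guard_before, guard_after = _site_sequence(mseq, seed_type, rng)
            if site:
                site_iv = _plant(reference.genome, region, offset, site)
                if guard_before and offset >= 1:
                    _plant(reference.genome, region, offset - 1, guard_before)
                if guard_after:
                    _plant(reference.genome, region, offset + len(site), guard_after)
            else:  # noncanonical: the untouched local sequence is the "site"
                site_iv = _plant(
                    reference.genome,
                    region,
                    offset,
                    _fetch_transcript(reference, region, offset, 8),
                )
            interactions.append(
                PlantedInteraction(
                    iid,
                    gene.gene_id,
                    mirna,
                    catalog[mirna].family_key,
                    seed_type,
                    site_iv,
                    region_label,
                    int(rng.integers(0, len(_STRUCTURE_ARCHETYPES))),
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place interaction; enlarge the reference")
    return interactions, mirna_weights


def _fetch_transcript(
    reference: Reference, region: GenomicInterval, offset: int, length: int
) -> str:
    s = "".join(
        reference.genome[region.chrom][region.start : region.end]
    )
    if region.strand == "-":
        s = seq.revcomp(s)
    return s[offset : offset + length]


# ---------------------------------------------------------------------------
# CLIP read simulation

def structure_vectors(
    interactions: list, n_per_interaction: int, flip_rate: float = 0.05, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy binary pairing vectors drawn from each interaction's
    archetype (for binding-mode clustering tests); returns (matrix,
    archetype labels)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    rows, labels = [], []
    for inter in interactions:
        template = _STRUCTURE_ARCHETYPES[inter.structure_archetype]
        for _ in range(n_per_interaction):
            flips = rng.random(template.size) < flip_rate
            rows.append(np.where(flips, 1 - template, template))
            labels.append(inter.structure_archetype)
    return np.array(rows), np.array(labels)


def simulate_clip_reads(
    config: SimulationConfig,
    reference: Reference,
    catalog: MiRNACatalog,
    interactions: list,
    mirna_weights: dict,
    rng=None,
) -> tuple[dict[str, list], dict[str, ReadProvenance]]:
    """Per-replicate read lists [(read_id, full_sequence)] and provenance.

    Full sequences start with the degenerate barcode.  Background reads
    form coverage peaks at planted sites plus a uniform transcript
    component; chimeric reads are barcode + miRNA (with configured
    mismatch/truncation rates) + target fragment (miRfirst) or
    barcode + target + miRNA (miRlast); PCR duplicates re-emit existing
    reads verbatim at the configured rate."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 3)
    genome = reference.genome_sequences()
    reps = [f"rep{i + 1}" for i in range(config.replicates)]
    reads: dict[str, list] = {r: [] for r in reps}
    provenance: dict[str, ReadProvenance] = {}
    n_chim = int(round(config.total_reads * config.chimera_fraction))
    n_small = int(round(config.total_reads * config.small_rna_fraction))
    n_bg = config.total_reads - n_chim - n_small
    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:07d}"

    def barcode() -> str:
        return _random_seq(rng, config.barcode_length)

    # --- chimeric reads -----------------------------------------------
    alloc = rng.multinomial(n_chim, np.full(len(interactions), 1 / len(interactions)))
    for inter, n_reads in zip(interactions, alloc):
        inter.n_chimeras = int(n_reads)
        site = inter.site
        gene = reference.genes[inter.gene_id]
        region = gene.regions[inter.region][0]
        tx = genome[region.chrom][region.start : region.end]
        if region.strand == "-":
            tx = seq.revcomp(tx)
        # transcript-space site start
        if region.strand == "+":
            site_off = site.start - region.start
        else:
            site_off = region.end - site.end
        site_len = len(site)
        for _ in range(int(n_reads)):
            frag_len = int(rng.integers(25, 41))
            lead = int(rng.integers(0, max(1, frag_len - site_len)))
            fs = max(0, min(site_off - lead, len(tx) - frag_len))
            frag = tx[fs : fs + frag_len]
            # genomic interval of the fragment
            if region.strand == "+":
                giv = (region.chrom, region.start + fs, region.start + fs + frag_len, "+")
            else:
                giv = (region.chrom, region.end - fs - frag_len, region.end - fs, "-")
            mseq = catalog[inter.mirna].sequence
            exact = True
            if rng.random() < config.mirna_truncation_rate:
                mseq = mseq[1:] if rng.random() < 0.5 else mseq[:-1]
                exact = False
            if rng.random() < config.mirna_mismatch_rate:
                pos = int(rng.integers(0, min(18, len(mseq))))
                alt = [b for b in "ACGT" if b != mseq[pos]]
                mseq = mseq[:pos] + alt[int(rng.integers(0, 3))] + mseq[pos + 1 :]
                exact = False
            mirfirst = rng.random() < config.mirfirst_fraction
            bc = barcode()
            rep = reps[int(rng.integers(0, len(reps)))]
            body = mseq + frag if mirfirst else frag + mseq
            rid = new_id("chim")
            reads[rep].append((rid, bc + body))
            provenance[rid] = ReadProvenance(
                "chimera",
                inter.interaction_id,
                inter.mirna,
                exact,
                "miRfirst" if mirfirst else "miRlast",
                giv,
                bc,
                rep,
            )

    # --- AGO-loaded small RNAs ----------------------------------------
    small_names = [m.name for m in catalog if m.precursor_locus is None]
    w = np.array([mirna_weights[n] for n in small_names])
    w /= w.sum()
    n_hp = max(1, len(reference.hairpins))
    per_hairpin = min(config.novel_arm_count, n_small // (2 * n_hp))
    n_novel = per_hairpin * len(reference.hairpins)
    picks = rng.choice(len(small_names), size=max(0, n_small - n_novel), p=w)
    for k in picks:
        m = catalog[small_names[int(k)]]
        L = int(rng.integers(max(17, len(m) - 3), len(m) + 1))
        start = int(rng.integers(0, len(m) - L + 1))
        rep = reps[int(rng.integers(0, len(reps)))]
        bc = barcode()
        rid = new_id("srna")
        reads[rep].append((rid, bc + m.sequence[start : start + L]))
        provenance[rid] = ReadProvenance(
            "smallrna", None, m.name, True, None, None, bc, rep
        )
    for hp in reference.hairpins:
        for _ in range(per_hairpin):
            rep = reps[int(rng.integers(0, len(reps)))]
            bc = barcode()
            rid = new_id("novel")
            s = hp.unannotated_sequence[:20]
            reads[rep].append((rid, bc + s))
            provenance[rid] = ReadProvenance(
                "smallrna", None, hp.name, False, None, None, bc, rep
            )

    # --- background AGO reads -----------------------------------------
    n_peak = int(round(n_bg * 0.7))
    site_alloc = rng.multinomial(
        n_peak, np.full(len(interactions), 1 / len(interactions))
    )
    for inter, n_reads in zip(interactions, site_alloc):
        site = inter.site
        chrom_seq = genome[site.chrom]
        for _ in range(int(n_reads)):
            frag_len = int(rng.integers(35, 55))
            jitter = int(rng.integers(-15, 16))
            start = max(0, min(site.start + jitter - frag_len // 2, len(chrom_seq) - frag_len))
            frag = chrom_seq[start : start + frag_len]
            if site.strand == "-":
                frag = seq.revcomp(frag)
            rep = reps[int(rng.integers(0, len(reps)))]
            bc = barcode()
            rid = new_id("bg")
            reads[rep].append((rid, bc + frag))
            provenance[rid] = ReadProvenance(
                "background",
                inter.interaction_id,
                None,
                False,
                None,
                (site.chrom, start, start + frag_len, site.strand),
                bc,
                rep,
            )
    gene_ids = sorted(reference.genes)
    for _ in range(n_bg - n_peak):
        gene = reference.genes[gene_ids[int(rng.integers(0, len(gene_ids)))]]
        span = gene.span
        frag_len = int(rng.integers(30, 55))
        start = int(rng.integers(span.start, span.end - frag_len))
        frag = genome[span.chrom][start : start + frag_len]
        if span.strand == "-":
            frag = seq.revcomp(frag)
        rep = reps[int(rng.integers(0, len(reps)))]
        bc = barcode()
        rid = new_id("bg")
        reads[rep].append((rid, bc + frag))
        provenance[rid] = ReadProvenance(
            "background", None, None, False, None,
            (span.chrom, start, start + frag_len, span.strand), bc, rep,
        )

    # --- PCR duplicates ------------------------------------------------
    for rep in reps:
        pool = reads[rep]
        n_dup = int(round(len(pool) * config.pcr_duplicate_rate))
        if n_dup == 0 or not pool:
            continue
        idx = rng.integers(0, len(pool), size=n_dup)
        for k in idx:
            src_id, s = pool[int(k)]
            rid = new_id("dup")
            reads[rep].append((rid, s))
            src = provenance[src_id]
            provenance[rid] = ReadProvenance(
                "duplicate", src.interaction_id, src.mirna, src.exact_mirna,
                src.chimera_type, src.target, src.barcode, rep, duplicate_of=src_id,
            )
    return reads, provenance


# ---------------------------------------------------------------------------
# expression simulation

def simulate_expression(
    config: SimulationConfig,
    gene_ids: list,
    targeted_genes: set,
    rng=None,
) -> pd.DataFrame:
    """Gamma-Poisson two-condition count table (genes x samples).

    Targeted genes receive the planted de-repression (a log2 shift of
    the treated-condition mean); columns are ctrl_i / trt_i."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 4)
    n = len(gene_ids)
    base = rng.lognormal(config.expression_mean_log, 1.0, size=n)
    shape = 1.0 / config.expression_dispersion
    cols = {}
    effect = np.array(
        [config.planted_log2fc if g in targeted_genes else 0.0 for g in gene_ids]
    )
    for r in range(config.expression_replicates):
        lam = rng.gamma(shape, base / shape)
        cols[f"ctrl_{r + 1}"] = rng.poisson(lam)
    for r in range(config.expression_replicates):
        lam = rng.gamma(shape, base * (2.0 ** effect) / shape)
        cols[f"trt_{r + 1}"] = rng.poisson(lam)
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# full simulation + serialization

def write_gtf(path: str, genes: dict) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(genes):
            g = genes[gene_id]
            for label, ivs in sorted(g.regions.items()):
                for iv in ivs:
                    fh.write(
                        "\t".join(
                            [
                                iv.chrom,
                                "sim",
                                label,
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";',
                            ]
                        )
                        + "\n"
                    )


def simulate_study(config: SimulationConfig, outdir: Optional[str] = None):
    """Run the full generator; optionally write the file bundle
    (genome.fa, genes.gtf, mirnas.fa, reads_rep*.fq, counts.tsv,
    truth.json).  Returns (reference, catalog, truth, reads, counts)."""
    rng = np.random.default_rng(config.rng_seed)
    reference = simulate_reference(config, rng)
    catalog = simulate_mirnome(config, reference, rng)
    interactions, weights = simulate_truth(config, reference, catalog, rng)
    reads, provenance = simulate_clip_reads(
        config, reference, catalog, interactions, weights, rng
    )
    targeted = sorted({i.gene_id for i in interactions})
    counts = simulate_expression(config, sorted(reference.genes), set(targeted), rng)
    truth = GroundTruth(config, interactions, provenance, targeted, weights)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_fasta, write_fastq

        write_fasta(out / "genome.fa", reference.genome_sequences())
        write_gtf(out / "genes.gtf", reference.genes)
        write_fasta(out / "mirnas.fa", {m.name: m.sequence for m in catalog})
        for rep, rep_reads in reads.items():
            write_fastq(out / f"reads_{rep}.fq", rep_reads)
        counts.reset_index().to_csv(out / "counts.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
        write_hairpins_tsv(out / "hairpins.tsv", reference.hairpins)
    return reference, catalog, truth, reads, counts


def write_hairpins_tsv(path: str, hairpins: list) -> None:
    rows = []
    for hp in hairpins:
        for arm, iv in sorted(hp.annotated_arms.items()):
            rows.append(
                (hp.name, hp.locus.chrom, hp.locus.start, hp.locus.end,
                 hp.locus.strand, arm, iv.start, iv.end)
            )
    pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "strand", "arm", "arm_start", "arm_end"],
    ).to_csv(path, sep="\t", index=False)


def read_hairpins_tsv(path: str) -> list[Hairpin]:
    df = pd.read_csv(path, sep="\t")
    hairpins = {}
    for row in df.itertuples(index=False):
        hp = hairpins.get(row.name)
        if hp is None:
            hp = Hairpin(
                row.name,
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                {},
                "",
                "",
            )
            hairpins[row.name] = hp
        hp.annotated_arms[row.arm] = GenomicInterval(
            row.chrom, int(row.arm_start), int(row.arm_end), row.strand
        )
    return list(hairpins.values())
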