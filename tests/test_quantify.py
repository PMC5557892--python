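"""Expression normalization, ASC arithmetic and eligibility, GO gene-set
selection, cooperativity consensus and ceRNA region detection."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from chimeramap.intervals import GenomicInterval
from chimeramap.quantify import (
    ASCRecord,
    CernaRegion,
    asc_matrix,
    compute_abundance,
    compute_asc,
    cooperativity_consensus,
    detect_cerna_regions,
    select_go_geneset,
)
from oracles import cerna_bruteforce


class TestAbundance:
    def test_cpm_rpkm_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["g1", "g2"])
        counts.loc["filler"] = 10**6 - 10
        expr = compute_abundance(counts, pd.Series({"g1": 1000, "g2": 500, "filler": 1000}))
        assert expr.loc["g1", "CPM"] == pytest.approx(10.0)
        assert expr.loc["g1", "RPKM"] == pytest.approx(10.0)
        assert expr.loc["g2", "CPM"] == 0 and expr.loc["g2", "RPKM"] == 0

    def test_expressed_flag_100_tag_rule(self):
        counts = pd.DataFrame({"a": [50, 60], "b": [49, 40]}, index=["g1", "g2"])
        expr = compute_abundance(counts, pd.Series({"g1": 1000, "g2": 1000}))
        assert not expr.loc["g1", "expressed"]  # 99 tags
        assert expr.loc["g2", "expressed"]  # 100 tags

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0]}, index=["g1"])
        with pytest.raises(ValueError):
            compute_abundance(counts, pd.Series({"g1": 100}))


def _expr(rpkm: dict) -> pd.DataFrame:
    return pd.DataFrame({"RPKM": pd.Series(rpkm)})


class TestASC:
    def test_closed_form_value(self):
        fam = pd.DataFrame({"F": {"g1": 8, "g2": 56, "g3": 436}})
        records = compute_asc(fam, _expr({"g1": 1.0, "g2": 1.0, "g3": 1.0}))
        by_gene = {r.gene_id: r for r in records}
        assert fam["F"].sum() == 500
        assert by_gene["g1"].asc == pytest.approx(np.log2((8 / 500) / 1.0))

    def test_doubling_rpkm_shifts_by_minus_one(self):
        fam = pd.DataFrame({"F": {"g1": 100, "g2": 400}})
        a1 = {r.gene_id: r.asc for r in compute_asc(fam, _expr({"g1": 2.0, "g2": 1.0}))}
        a2 = {r.gene_id: r.asc for r in compute_asc(fam, _expr({"g1": 4.0, "g2": 1.0}))}
        assert a2["g1"] == pytest.approx(a1["g1"] - 1.0)
        assert a2["g2"] == pytest.approx(a1["g2"])

    def test_family_below_500_skipped(self):
        fam = pd.DataFrame({"F": {"g1": 499}})
        assert compute_asc(fam, _expr({"g1": 1.0})) == []

    def test_non_targeted_sentinel_and_lloq(self):
        fam = pd.DataFrame({"F": {"g1": 500, "g2": 0}})
        records = {r.gene_id: r for r in compute_asc(fam, _expr({"g1": 2.0, "g2": 1.0}))}
        assert records["g2"].asc is None
        assert records["g1"].lloq == pytest.approx(np.log2((1 / 500) / 2.0))
        assert records["g1"].asc >= records["g1"].lloq

    def test_zero_rpkm_with_chimeras_flagged(self):
        fam = pd.DataFrame({"F": {"g1": 500, "g2": 100}})
        records = {r.gene_id: r for r in compute_asc(fam, _expr({"g1": 1.0, "g2": 0.0}))}
        assert records["g2"].flagged and records["g2"].asc is None

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        fam = pd.DataFrame({"F": pd.Series(rng.integers(10, 100, 20), index=genes)})
        fam["F"] += 500 // 20
        rpkm = dict(zip(genes, rng.lognormal(0, 1, 20)))
        base = {r.gene_id: r.asc for r in compute_asc(fam, _expr(rpkm))}
        # RPKM x alpha shifts by -log2(alpha)
        scaled = {
            r.gene_id: r.asc
            for r in compute_asc(fam, _expr({g: v * 8 for g, v in rpkm.items()}))
        }
        for g in genes:
            assert scaled[g] == pytest.approx(base[g] - 3.0)
        # counts x beta leaves asc unchanged
        bscaled = {r.gene_id: r.asc for r in compute_asc(fam * 3, _expr(rpkm))}
        for g in genes:
            assert bscaled[g] == pytest.approx(base[g])


def _rec(gene, fam, asc):
    return ASCRecord(gene, fam, 1 if asc is not None else 0, 500, 1.0, asc,
                     -9.0 if asc is not None else None)


class TestGoGeneset:
    def test_above_mean_selection(self):
        records = [_rec("a", "F", -1.0), _rec("b", "F", -2.0), _rec("c", "F", -3.0)]
        assert select_go_geneset(records, "F") == ["a"]

    def test_non_targeted_excluded_from_mean(self):
        records = [_rec("a", "F", -1.0), _rec("b", "F", -3.0), _rec("z", "F", None)]
        assert select_go_geneset(records, "F") == ["a"]

    def test_all_equal_strict_inequality_empty(self):
        records = [_rec(g, "F", -2.0) for g in "abc"]
        assert select_go_geneset(records, "F") == []

    def test_order_invariance(self):
        records = [_rec("a", "F", -1.0), _rec("b", "F", -2.0), _rec("c", "F", -3.0)]
        assert select_go_geneset(records[::-1], "F") == select_go_geneset(records, "F")


class TestCooperativity:
    # null ASC columns use unit SD: the default enrichment margin (1.0
    # ASC units) is calibrated as ~1 column SD
    def _matrix(self, rng, n_genes=60, correlated=True, sigma=1.0):
        genes = [f"g{i}" for i in range(n_genes)]
        base = rng.normal(-8, sigma, n_genes)
        data = {}
        if correlated:
            base = base.copy()
            base[: n_genes // 5] += 3.0  # a strongly co-targeted gene group
            data["famA"] = base
            data["famB"] = base  # identical columns: the shared-seed control
        else:
            data["famA"] = rng.normal(-8, sigma, n_genes)
            data["famB"] = rng.normal(-8, sigma, n_genes)
        data["famC"] = rng.normal(-8, sigma, n_genes)
        data["famD"] = rng.normal(-8, sigma, n_genes)
        return pd.DataFrame(data, index=genes)

    def test_identical_columns_co_signature_all_iterations(self):
        rng = np.random.default_rng(6)
        mat = self._matrix(rng, correlated=True)
        res = cooperativity_consensus(mat, k=6, n_starts=20, random_state=1)
        pair_sigs = [s for s in res.signatures if {"famA", "famB"} <= s.families]
        assert pair_sigs and pair_sigs[0].support == 3
        assert res.pairwise.loc["famA", "famB"] == 3

    def test_null_columns_rarely_recurrent(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 10
        for i in range(n_runs):
            mat = self._matrix(rng, correlated=False)
            res = cooperativity_consensus(mat, k=6, n_starts=10, random_state=i)
            if res.signatures:
                hits += 1
        assert hits <= 1  # no recurrent multi-family signature in >=90%

    def test_min_support_two_retains_partial_signatures(self):
        rng = np.random.default_rng(8)
        mat = self._matrix(rng, correlated=True)
        res3 = cooperativity_consensus(mat, k=6, n_starts=20, min_support=3, random_state=2)
        res2 = cooperativity_consensus(mat, k=6, n_starts=20, min_support=2, random_state=2)
        assert len(res2.signatures) >= len(res3.signatures)

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(9)
        mat = self._matrix(rng)
        a = cooperativity_consensus(mat, k=5, n_starts=10, random_state=3)
        b = cooperativity_consensus(mat, k=5, n_starts=10, random_state=3)
        assert [s.families for s in a.signatures] == [s.families for s in b.signatures]
        assert a.pairwise.equals(b.pairwise)

    def test_k_exceeding_genes_errors(self):
        mat = pd.DataFrame({"famA": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            cooperativity_consensus(mat, k=5)

    def test_asc_matrix_shape(self):
        records = [_rec("a", "F", -1.0), _rec("a", "G", None), _rec("b", "F", -2.0)]
        mat = asc_matrix(records)
        assert mat.shape == (2, 2) and np.isnan(mat.loc["a", "G"])


@dataclass
class _Cluster:
    key: str
    span: GenomicInterval
    chimera_count: int


def _cl(start, end, n, key="F", chrom="chr1", strand="+"):
    return _Cluster(key, GenomicInterval(chrom, start, end, strand), n)


class TestCerna:
    def test_three_strong_clusters_within_3kb_reported(self):
        clusters = [_cl(0, 100, 5), _cl(1400, 1500, 5), _cl(2800, 2900, 6)]
        (region,) = detect_cerna_regions(clusters)
        assert (region.interval.start, region.interval.end) == (0, 2900)
        assert region.n_clusters == 3

    def test_weak_cluster_breaks_rule(self):
        clusters = [_cl(0, 100, 5), _cl(1400, 1500, 5), _cl(2800, 2900, 4)]
        assert detect_cerna_regions(clusters) == []

    def test_span_over_3kb_not_reported(self):
        clusters = [_cl(0, 100, 5), _cl(1500, 1600, 5), _cl(2950, 3050, 5)]
        assert detect_cerna_regions(clusters) == []

    def test_strand_separation(self):
        clusters = [
            _cl(0, 100, 5), _cl(1000, 1100, 5),
            _cl(2000, 2100, 5, strand="-"),
        ]
        assert detect_cerna_regions(clusters) == []

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(12)
        for trial in range(30):
            clusters = []
            for _ in range(int(rng.integers(5, 40))):
                start = int(rng.integers(0, 20_000))
                clusters.append(
                    _cl(start, start + int(rng.integers(50, 400)),
                        int(rng.integers(1, 9)),
                        strand="+" if rng.random() < 0.7 else "-")
                )
            got = sorted(
                (r.interval.chrom, r.interval.strand, r.interval.start, r.interval.end)
                for r in detect_cerna_regions(clusters)
            )
            expected = sorted(cerna_bruteforce(clusters))
            assert got == expected, trial
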