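"""Clonotype identity, pairing policy, replicate merging, expansion bins, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import anndata as ad
from clonotrack.clonotypes import (
    assign_expansion_bin,
    build_bulk_clonotypes,
    filter_productive,
    merge_replicates,
    pair_cells,
    qc_filter_cells,
)
from clonotrack.types import ClonotypeRecord, ContigRecord


def rec(nt="TGTGCCTTT", aa="CAF", v="TRBV9", j="TRBJ1-1", n=1, productive=True):
    return ClonotypeRecord(nt, aa, v, "", j, n, productive)


class TestProductiveFilter:
    def test_removes_nonproductive(self):
        records = [rec(), rec(productive=False), rec(), rec(productive=False), rec()]
        assert len(filter_productive(records)) == 3

    def test_identity_when_all_productive(self):
        records = [rec(), rec()]
        assert filter_productive(records) == records

    def test_all_nonproductive_gives_empty(self):
        assert filter_productive([rec(productive=False)] * 3) == []


class TestBulkClonotypes:
    def test_counts_aggregate_by_key(self):
        rep = build_bulk_clonotypes([rec(n=4), rec(n=6)])
        assert rep.n_clones == 1 and rep.total_reads == 10

    def test_nt_mode_separates_synonymous_junctions(self):
        # same amino acid junction, different nucleotides
        rep = build_bulk_clonotypes([rec(nt="TGTGCCTTT", n=1), rec(nt="TGTGCGTTT", n=1)])
        assert rep.n_clones == 2
        rep_aa = build_bulk_clonotypes(
            [rec(nt="TGTGCCTTT", n=1), rec(nt="TGTGCGTTT", n=1)], key_level="aa"
        )
        assert rep_aa.n_clones == 1

    def test_v_gene_is_part_of_the_key(self):
        rep = build_bulk_clonotypes([rec(v="TRBV9", n=1), rec(v="TRBV2", n=1)])
        assert rep.n_clones == 2

    def test_total_reads_conserved(self):
        records = [rec(n=k) for k in (1, 5, 9, 2)]
        assert build_bulk_clonotypes(records).total_reads == 17


def contig(bc, chain, nt, umi=5, productive=True, aa="CAF", v="V1", j="J1"):
    return ContigRecord(bc, chain, nt, aa, v, j, umi, productive)


class TestPairCells:
    def test_paired_cell_retained(self):
        cells = pair_cells([contig("b1", "TRA", "TGTGCCTTT"), contig("b1", "TRB", "TGTAGCTTC")])
        assert len(cells) == 1
        assert cells[0].tra.cdr3_nt == "TGTGCCTTT"

    def test_single_chain_cell_removed(self):
        cells = pair_cells([contig("b1", "TRB", "TGTAGCTTC")])
        assert cells == []

    def test_multi_chain_keeps_highest_umi(self):
        contigs = [
            contig("b1", "TRA", "TGTAAATTT", umi=7),
            contig("b1", "TRA", "TGTCCCTTT", umi=2),
            contig("b1", "TRB", "TGTAGCTTC", umi=3),
        ]
        cells = pair_cells(contigs)
        assert cells[0].tra.cdr3_nt == "TGTAAATTT"

    def test_umi_tie_broken_lexicographically(self):
        contigs = [
            contig("b1", "TRA", "TGTCCCTTT", umi=4),
            contig("b1", "TRA", "TGTAAATTT", umi=4),
            contig("b1", "TRB", "TGTAGCTTC"),
        ]
        cells = pair_cells(contigs)
        assert cells[0].tra.cdr3_nt == "TGTAAATTT"

    def test_drop_policy_discards_ambiguous_cells(self):
        contigs = [
            contig("b1", "TRA", "TGTAAATTT", umi=7),
            contig("b1", "TRA", "TGTCCCTTT", umi=2),
            contig("b1", "TRB", "TGTAGCTTC"),
        ]
        assert pair_cells(contigs, multi_chain="drop") == []

    def test_order_independent(self, rng):
        contigs = [
            contig("b1", "TRA", "TGTAAATTT", umi=4),
            contig("b1", "TRA", "TGTCCCTTT", umi=4),
            contig("b1", "TRB", "TGTAGCTTC"),
            contig("b2", "TRA", "TGTGGGTTT"),
            contig("b2", "TRB", "TGTTTTTTC"),
        ]
        baseline = pair_cells(contigs)
        for _ in range(5):
            shuffled = list(contigs)
            rng.shuffle(shuffled)
            assert pair_cells(shuffled) == baseline

    def test_nonproductive_contigs_ignored(self):
        contigs = [
            contig("b1", "TRA", "TGTGCCTTT", productive=False),
            contig("b1", "TRB", "TGTAGCTTC"),
        ]
        assert pair_cells(contigs) == []

    def test_barcode_missing_from_metadata_dropped(self):
        meta = pd.DataFrame(
            {"barcode": ["b1"], "donor": ["D1"], "sorted_gate": ["G"],
             "tissue": ["blood"], "timepoint": ["T0"], "cluster": ["C0"]}
        ).set_index("barcode", drop=False)
        contigs = [
            contig("b1", "TRA", "TGTGCCTTT"), contig("b1", "TRB", "TGTAGCTTC"),
            contig("b2", "TRA", "TGTGGGTTT"), contig("b2", "TRB", "TGTTTTTTC"),
        ]
        cells = pair_cells(contigs, meta)
        assert [c.barcode for c in cells] == ["b1"]
        assert cells[0].donor == "D1"


class TestMergeReplicates:
    def test_disjoint_union(self):
        from tests.conftest import make_repertoire

        a = make_repertoire({"A": 1, "B": 2}, donor="D1", subset="Tph", timepoint="T0")
        b = make_repertoire({"C": 1, "D": 2, "E": 3}, donor="D1", subset="Tph", timepoint="T0")
        m = merge_replicates(a, b)
        assert m.n_clones == 5 and m.total_reads == 9

    def test_identical_replicates_double_counts(self):
        from tests.conftest import make_repertoire

        a = make_repertoire({"A": 3, "B": 1}, donor="D1")
        m = merge_replicates(a, make_repertoire({"A": 3, "B": 1}, donor="D1"))
        assert m.clonotypes == {k: 2 * v for k, v in a.clonotypes.items()}

    def test_empty_replicate_is_identity(self):
        from tests.conftest import make_repertoire

        a = make_repertoire({"A": 3}, donor="D1")
        m = merge_replicates(a, make_repertoire({}, donor="D1"))
        assert m.clonotypes == a.clonotypes

    def test_label_mismatch_raises(self):
        from tests.conftest import make_repertoire

        a = make_repertoire({"A": 1}, donor="D1")
        b = make_repertoire({"A": 1}, donor="D2")
        with pytest.raises(ValueError, match="donor"):
            merge_replicates(a, b)


def oracle_bin(s: int) -> str:
    if s == 1:
        return "single"
    if s <= 5:
        return "small"
    if s <= 20:
        return "medium"
    if s <= 100:
        return "large"
    return "hyperexpanded"


class TestExpansionBins:
    @pytest.mark.parametrize(
        "size,label",
        [(1, "single"), (2, "small"), (5, "small"), (6, "medium"), (20, "medium"),
         (21, "large"), (100, "large"), (101, "hyperexpanded"), (500, "hyperexpanded"),
         (501, "hyperexpanded")],
    )
    def test_boundaries(self, size, label):
        assert assign_expansion_bin(size) == label

    def test_partition_of_1_to_500(self):
        for s in range(1, 501):
            assert assign_expansion_bin(s) == oracle_bin(s)

    def test_monotone_in_size(self):
        order = ["single", "small", "medium", "large", "hyperexpanded"]
        ranks = [order.index(assign_expansion_bin(s)) for s in range(1, 600)]
        assert ranks == sorted(ranks)

    def test_invalid_size_raises(self):
        with pytest.raises(ValueError):
            assign_expansion_bin(0)


class TestQcFilter:
    def _adata(self, X, genes):
        return ad.AnnData(
            X=np.asarray(X),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]),
            var=pd.DataFrame(index=genes),
        )

    def test_three_threshold_examples(self):
        n_genes_total = 600
        genes = [f"g{i}" for i in range(n_genes_total - 1)] + ["MT-1"]
        # cell 0: 150 expressed genes (< 200) -> removed
        # cell 1: 500 expressed genes, 12% mito -> removed
        # cell 2: 500 expressed genes, 2% mito -> retained
        X = np.zeros((3, n_genes_total), dtype=int)
        X[0, :150] = 1
        X[1, :499] = 1
        X[1, -1] = 68  # 68 / (499+68) = 12%
        X[2, :499] = 1
        X[2, -1] = 10  # ~2%
        keep = qc_filter_cells(self._adata(X, genes), mito_genes=["MT-1"])
        assert keep.tolist() == [False, False, True]

    def test_max_genes_threshold(self):
        genes = [f"g{i}" for i in range(3500)]
        X = np.zeros((2, 3500), dtype=int)
        X[0, :3100] = 1  # too many genes
        X[1, :1000] = 1
        keep = qc_filter_cells(self._adata(X, genes))
        assert keep.tolist() == [False, True]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=40))
def test_bin_assignment_total_on_positive_sizes(sizes):
    for s in sizes:
        assert assign_expansion_bin(s) in {"single", "small", "medium", "large", "hyperexpanded"}
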