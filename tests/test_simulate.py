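"""Synthetic cohort generator: planted structure and ground-truth consistency."""

import filecmp

import numpy as np
import pytest

from clonotrack.io import load_manifest_repertoires, read_sc_contigs
from clonotrack.simulate import (
    CohortConfig,
    generate_cohort,
    generate_sc_dataset,
    sample_clone_sizes,
)
from clonotrack.types import translate_cdr3
from tests.conftest import merged_samples


class TestCloneSizes:
    def test_cap_one_all_singletons(self, rng):
        assert (sample_clone_sizes(500, 2.5, 1, rng) == 1).all()

    def test_large_alpha_is_almost_all_singletons(self, rng):
        sizes = sample_clone_sizes(5000, 8.0, 500, rng)
        assert (sizes == 1).mean() > 0.99

    def test_log_log_slope_matches_exponent(self, rng):
        sizes = sample_clone_sizes(100_000, 2.0, 100, rng)
        s = np.arange(1, 31)
        counts = np.array([(sizes == k).sum() for k in s])
        slope = np.polyfit(np.log(s), np.log(counts), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_invalid_parameters(self, rng):
        with pytest.raises(ValueError):
            sample_clone_sizes(10, 1.0, 100, rng)
        with pytest.raises(ValueError):
            sample_clone_sizes(10, 2.0, 0, rng)


class TestCohortStructure:
    def test_every_clonotype_traceable_to_ground_truth(self, small_cfg, small_cohort):
        gt = small_cohort.ground_truth
        for rep in small_cohort.repertoires:
            truth = gt.clone_keys(rep.donor, subset=rep.subset, timepoint=rep.timepoint)
            assert set(rep.clonotypes) <= truth

    def test_replicates_sum_to_configured_depth(self, small_cfg, small_cohort):
        merged = merged_samples(small_cohort.repertoires)
        for rep in merged.values():
            assert rep.total_reads == small_cfg.bulk_depth

    def test_cdr3_translation_consistency(self, small_cohort):
        df = small_cohort.ground_truth.clones
        sampled = df.sample(50, random_state=0)
        for row in sampled.itertuples():
            assert translate_cdr3(row.cdr3_nt) == row.cdr3_aa
            assert row.cdr3_aa.startswith("C") and row.cdr3_aa.endswith("F")

    def test_identity_sharing_means_no_cross_subset_overlap(self):
        cfg = CohortConfig(n_donors=1, clones_per_subset=150, timepoints=("T0",),
                           sharing={}, n_ctl_clones=0, bulk_depth=6000, seed=3)
        res = generate_cohort(cfg)
        merged = merged_samples(res.repertoires)
        tph = merged[("D1", "Tph", "T0")].key_set()
        tfh = merged[("D1", "Tfh", "T0")].key_set()
        assert len(tph & tfh) == 0

    def test_full_persistence_keeps_every_baseline_clone(self):
        cfg = CohortConfig(n_donors=1, clones_per_subset=100, timepoints=("T0", "T1"),
                           persistence=1.0, bulk_depth=6000, seed=4)
        res = generate_cohort(cfg)
        df = res.ground_truth.clones
        baseline = df[df.timepoints.str.contains("T0")]
        assert baseline.timepoints.str.contains("T1").all()

    def test_planted_sharing_recovered_within_binomial_ci(self, small_cfg, small_cohort):
        merged = merged_samples(small_cohort.repertoires)
        n = small_cfg.clones_per_subset * small_cfg.n_donors
        shared = sum(
            len(merged[(d, "Tph", "T0")].key_set() & merged[(d, "Tfh", "T0")].key_set())
            for d in ("D1", "D2")
        )
        p = small_cfg.sharing[("Tph", "Tfh")]
        half_width = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(shared / n - p) <= half_width


class TestFileEmission:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(n_donors=1, clones_per_subset=80, timepoints=("T0",),
                           bulk_depth=4000, cells_per_cluster=20, n_genes=80, seed=9)
        for d in ("a", "b"):
            cohort = generate_cohort(cfg, out_dir=tmp_path / d)
            generate_sc_dataset(cfg, cohort, out_dir=tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").iterdir() if p.is_file())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name
        assert filecmp.cmp(tmp_path / "a/matrix/matrix.mtx", tmp_path / "b/matrix/matrix.mtx",
                           shallow=False)

    def test_emitted_files_reload_consistently(self, tmp_path, small_cfg, small_cohort):
        generate_cohort(small_cfg, out_dir=tmp_path)
        reps = load_manifest_repertoires(tmp_path / "manifest.tsv")
        by_id = {r.sample_id: r for r in reps}
        for rep in small_cohort.repertoires:
            assert by_id[rep.sample_id].clonotypes == rep.clonotypes


class TestScDataset:
    def test_private_ctl_clones_absent_from_tfh_bulk(self, small_cohort, small_sc):
        gt = small_sc.ground_truth
        for donor in ("D1", "D2"):
            ctl = gt.clone_keys(donor, ctl=True)
            assert ctl  # planted
            tfh_keys = set().union(*(
                r.key_set() for r in small_cohort.repertoires
                if r.donor == donor and r.subset == "Tfh"
            ))
            assert not (ctl & tfh_keys)

    def test_contigs_match_metadata_barcodes(self, small_sc):
        barcodes = {c.barcode for c in small_sc.contigs}
        assert barcodes == set(small_sc.metadata.index)

    def test_c5_cells_sorted_into_both_gates(self, small_sc):
        gates = small_sc.metadata.loc[small_sc.metadata.cluster == "C5", "sorted_gate"]
        assert gates.nunique() == 2

    def test_ctl_cluster_private_to_one_gate(self, small_sc):
        gates = small_sc.metadata.loc[small_sc.metadata.cluster == "C3", "sorted_gate"]
        assert set(gates) == {"CXCR5-PD-1hi"}

    def test_null_effect_hides_signature(self):
        # with delta = 0 the planted genes are indistinguishable from the rest
        from clonotrack.signatures import derive_marker_signature, lognormalize

        cfg = CohortConfig(n_donors=1, clones_per_subset=100, timepoints=("T0",),
                           bulk_depth=5000, cells_per_cluster=60, n_genes=200,
                           signature_effect=0.0, seed=21)
        sc_data = generate_sc_dataset(cfg)
        norm = lognormalize(sc_data.adata)
        sig = derive_marker_signature(norm, "cluster", "C5", n_top=200)
        planted = set(sc_data.ground_truth.signature_genes)
        # at alpha=0.05 a handful of false positives may appear; the planted
        # set must not be enriched
        assert len(planted & set(sig.genes)) <= max(2, 0.25 * len(sig.genes) + 1)
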