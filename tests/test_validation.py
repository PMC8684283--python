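import numpy as np
import pandas as pd
import pytest

from nfaascan.layout import GenomeLayout, WindowGrid
from nfaascan.scan import SegmentSet
from nfaascan.validation import (
    GenotypeMatrix,
    build_reference_haplotype,
    export_admixture_input,
    ingest_q_matrix,
    merge_and_biallelicize,
    merge_dense,
    nearest_label_on_pc,
    partition_sites_by_segments,
    run_pca,
)


def _sites(n, chrom="chr1", ref="A", alt="G", start=1):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start, start + n),
            "ref": ref,
            "alt": alt,
        }
    )


def _matrix(prefix, n_samples, sites, dosages=None, label="pop"):
    if dosages is None:
        dosages = np.zeros((n_samples, len(sites)), dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=[f"{prefix}{i}" for i in range(n_samples)],
        labels=[label] * n_samples,
        sites=sites,
        dosages=dosages,
    )


def _segments(rows, chrom_lengths={"chr1": 40_000_000}):
    grid = WindowGrid(GenomeLayout(dict(chrom_lengths)), 1_000_000)
    table = pd.DataFrame(
        rows, columns=["chrom", "start_mb", "end_mb", "total_delta", "size_mb"]
    )
    return SegmentSet(table=table, grid=grid, k_sd=1.5)


class TestReferenceHaplotype:
    def test_pseudo_sample_is_all_zero_dosage(self):
        ref = build_reference_haplotype(_sites(17))
        assert ref.dosages.shape == (1, 17)
        assert (ref.dosages == 0).all()

    def test_empty_site_index_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_reference_haplotype(_sites(0))

    def test_merging_pseudo_sample_twice_is_an_error(self):
        sites = _sites(5)
        ref = build_reference_haplotype(sites)
        other = _matrix("s", 2, sites)
        with pytest.raises(ValueError, match="duplicate sample ids"):
            merge_and_biallelicize([other, ref, ref])


class TestMerge:
    def test_counting_fixture_16_by_93(self, rng):
        """3 breeds x 5 samples + pseudo-sample over 100 sites, 7 multiallelic."""
        sites = _sites(100)
        mats = []
        for b in range(3):
            s = sites.copy()
            if b == 1:  # give 7 sites a third allele in one breed
                s.loc[:6, "alt"] = "T"
            dosages = rng.integers(0, 3, size=(5, 100)).astype(np.int8)
            mats.append(_matrix(f"b{b}_", 5, s, dosages))
        mats.append(build_reference_haplotype(sites))
        merged = merge_and_biallelicize(mats)
        assert merged.dosages.shape == (16, 93)

    def test_swapped_ref_alt_reconciled_by_dosage_flip(self):
        sites_a = _sites(3)
        sites_b = sites_a.copy()
        sites_b.loc[1, ["ref", "alt"]] = ["G", "A"]  # swapped at site 1
        m1 = _matrix("a", 2, sites_a, np.array([[0, 1, 2], [2, 0, 1]], dtype=np.int8))
        m2 = _matrix("b", 1, sites_b, np.array([[0, 2, 0]], dtype=np.int8))
        merged = merge_and_biallelicize([m1, m2])
        assert merged.n_sites == 3
        assert merged.dosages[2].tolist() == [0, 0, 0]  # flipped at site 1

    def test_identical_sites_concatenate_samples(self):
        sites = _sites(10)
        merged = merge_and_biallelicize([_matrix("a", 3, sites), _matrix("b", 2, sites)])
        assert merged.n_samples == 5 and merged.n_sites == 10

    def test_dense_merge_matches_general_merge(self, rng):
        sites = _sites(20)
        d1 = rng.integers(0, 3, size=(3, 20)).astype(np.int8)
        d2 = rng.integers(0, 3, size=(2, 20)).astype(np.int8)
        m1, m2 = _matrix("a", 3, sites, d1), _matrix("b", 2, sites, d2)
        general = merge_and_biallelicize([m1, m2])
        dense = merge_dense([m1, m2])
        assert (general.dosages == dense.dosages).all()


class TestPartition:
    def test_empty_segments_put_everything_outside(self):
        m = _matrix("s", 2, _sites(50))
        inside, outside = partition_sites_by_segments(m, _segments([]))
        assert inside.n_sites == 0 and outside.n_sites == 50

    def test_boundary_site_just_after_segment_start_is_inside(self):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [14_000_000, 14_000_001, 30_000_000, 30_000_001],
             "ref": "A", "alt": "G"}
        )
        m = _matrix("s", 1, sites)
        inside, outside = partition_sites_by_segments(
            m, _segments([("chr1", 14, 30, 0.0, 16)])
        )
        assert inside.sites["pos"].tolist() == [14_000_001, 30_000_000]
        assert outside.sites["pos"].tolist() == [14_000_000, 30_000_001]

    def test_partition_conserves_site_count(self, rng):
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.sort(rng.choice(40_000_000, 500, replace=False)) + 1,
                "ref": "A",
                "alt": "G",
            }
        )
        m = _matrix("s", 2, sites)
        inside, outside = partition_sites_by_segments(
            m, _segments([("chr1", 3, 7, 0.0, 4), ("chr1", 20, 22, 0.0, 2)])
        )
        assert inside.n_sites + outside.n_sites == 500


class TestPca:
    def _two_cluster_matrix(self, rng, n_sites=300):
        sites = _sites(n_sites)
        a = (rng.random((5, n_sites)) < 0.9).astype(np.int8) * 2
        b = (rng.random((5, n_sites)) < 0.1).astype(np.int8) * 2
        return GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(10)],
            labels=["A"] * 5 + ["B"] * 5,
            sites=sites,
            dosages=np.vstack([a, b]),
        )

    def test_identical_samples_coincide(self):
        sites = _sites(30)
        dosages = np.tile(np.arange(30, dtype=np.int8) % 3, (3, 1))
        dosages[2, :] = (dosages[2, :] + 1) % 3  # one distinct sample
        m = _matrix("s", 3, sites, dosages)
        pca = run_pca(m, n_components=2)
        assert np.allclose(pca.coordinates[0], pca.coordinates[1], atol=1e-6)

    def test_eigenvalues_non_increasing_and_fractions_bounded(self, rng):
        pca = run_pca(self._two_cluster_matrix(rng), n_components=4)
        assert (np.diff(pca.eigenvalues) <= 1e-9).all()
        assert ((pca.variance_fractions >= 0) & (pca.variance_fractions <= 1)).all()

    def test_pc1_separates_two_clusters(self, rng):
        pca = run_pca(self._two_cluster_matrix(rng), n_components=2)
        a = pca.coordinates[:5, 0]
        b = pca.coordinates[5:, 0]
        within = max(a.max() - a.min(), b.max() - b.min())
        between = abs(a.mean() - b.mean())
        assert between > within

    def test_sample_order_permutation_invariance_up_to_sign(self, rng):
        m = self._two_cluster_matrix(rng)
        perm = rng.permutation(m.n_samples)
        mp = GenotypeMatrix(
            sample_ids=[m.sample_ids[i] for i in perm],
            labels=[m.labels[i] for i in perm],
            sites=m.sites,
            dosages=m.dosages[perm],
        )
        p1 = run_pca(m, 2)
        p2 = run_pca(mp, 2)
        for c in range(2):
            orig = p1.coordinates[perm, c]
            new = p2.coordinates[:, c]
            assert np.allclose(orig, new, atol=1e-8) or np.allclose(orig, -new, atol=1e-8)

    def test_component_truncation_warns(self, rng):
        m = self._two_cluster_matrix(rng)
        pca = run_pca(m, n_components=50)
        assert pca.coordinates.shape[1] == m.n_samples - 1

    def test_nearest_label_assignment(self, rng):
        m = self._two_cluster_matrix(rng)
        pca = run_pca(m, 2)
        assert nearest_label_on_pc(pca, "s0", ["A", "B"]) == "A"
        assert nearest_label_on_pc(pca, "s9", ["A", "B"]) == "B"


class TestAdmixtureIo:
    def test_export_is_transposed_sites_by_samples(self, tmp_path, rng):
        m = _matrix("s", 4, _sites(25), rng.integers(0, 3, (4, 25)).astype(np.int8))
        path = tmp_path / "geno.txt"
        export_admixture_input(m, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 25
        assert all(len(line.split()) == 4 for line in lines)

    def test_valid_q_table_accepted(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("0.5 0.3 0.2\n0.1 0.1 0.8\n")
        q = ingest_q_matrix(path, sample_ids=["a", "b"])
        assert list(q.columns) == ["sample", "K1", "K2", "K3"]

    def test_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("0.5 0.4 0.2\n")
        with pytest.raises(ValueError, match="row 0 sums"):
            ingest_q_matrix(path)


class TestReferenceHaplotypePlacement:
    def test_pseudo_sample_follows_local_reference_ancestry(self):
        """PC1 puts the all-reference pseudo-sample with subspecies B outside
        planted segments and with subspecies A inside them."""
        from nfaascan.pipeline import scan_breeds
        from nfaascan.simulate import cattle_like_config, simulate_dataset
        from nfaascan.validation import (
            build_reference_haplotype,
            merge_dense,
            nearest_label_on_pc,
            partition_sites_by_segments,
            run_pca,
        )

        cfg = cattle_like_config(seed=2, small=True)
        ds = simulate_dataset(cfg, with_genotypes=True)
        res = scan_breeds(ds)
        mats = []
        for b in cfg.breeds:
            mats.append(
                GenotypeMatrix(
                    sample_ids=[f"{b.name}_{i}" for i in range(b.n_individuals)],
                    labels=[b.subspecies if b.q in (0.0, 1.0) else "admixed"]
                    * b.n_individuals,
                    sites=ds.sites[["chrom", "pos", "ref", "alt"]],
                    dosages=ds.genotypes[b.name],
                )
            )
        mats.append(build_reference_haplotype(ds.sites[["chrom", "pos", "ref", "alt"]]))
        merged = merge_dense(mats)
        inside, outside = partition_sites_by_segments(merged, res.segments)
        pca_in = run_pca(inside, 5)
        pca_out = run_pca(outside, 5)
        ref = "reference_haplotype"
        assert nearest_label_on_pc(pca_in, ref, ["A", "B"]) == "A"
        assert nearest_label_on_pc(pca_out, ref, ["A", "B"]) == "B"
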